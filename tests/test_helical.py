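import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardfil import (
    HelicalParams,
    RigidTransform,
    build_filament,
    filament_diameter,
    helical_pitch,
    make_synthetic_monomer,
    protrusion_spacing,
    recover_params_from_filament,
    screw_operator,
    subunit_count_in_span,
    subunits_per_turn,
    SyntheticMonomerSpec,
)
from cardfil.errors import NotAFilamentError
from cardfil.models import Atom, FilamentModel, Subunit

param_strategy = st.builds(
    HelicalParams,
    rise=st.floats(min_value=0.5, max_value=20.0, allow_nan=False),
    twist=st.floats(min_value=-180.0, max_value=180.0).filter(
        lambda t: abs(t) > 1e-3 and t > -180.0
    ),
)


class TestScrewOperator:
    def test_k0_is_identity(self, params):
        t = screw_operator(params, 0)
        assert np.allclose(t.rotation, np.eye(3))
        assert np.allclose(t.translation, 0.0)

    def test_k1_trigonometric_oracle(self, params):
        # direct trigonometric expectation for a point on the x-axis
        t = screw_operator(params, 1)
        moved = t.apply(np.array([10.0, 0.0, 0.0]))
        theta = math.radians(-101.4)
        expected = [10 * math.cos(theta), 10 * math.sin(theta), 4.936]
        assert np.allclose(moved, expected, atol=1e-12)

    def test_group_law_many_random_params(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            rise = rng.uniform(0.5, 20)
            twist = rng.uniform(-179.9, 180)
            if abs(twist) < 1e-3:
                continue
            p = HelicalParams(rise=rise, twist=twist)
            a, b = int(rng.integers(-20, 21)), int(rng.integers(-20, 21))
            lhs = screw_operator(p, a) @ screw_operator(p, b)
            rhs = screw_operator(p, a + b)
            assert np.allclose(lhs.rotation, rhs.rotation, atol=1e-9)
            assert np.allclose(lhs.translation, rhs.translation, atol=1e-9)

    @given(params=param_strategy, a=st.integers(-30, 30), b=st.integers(-30, 30))
    @settings(max_examples=50, deadline=None)
    def test_group_law_property(self, params, a, b):
        lhs = screw_operator(params, a) @ screw_operator(params, b)
        rhs = screw_operator(params, a + b)
        assert np.allclose(lhs.rotation, rhs.rotation, atol=1e-9)
        assert np.allclose(lhs.translation, rhs.translation, atol=1e-9)


class TestBuildFilament:
    def test_n1_equals_monomer(self, monomer, params):
        fil = build_filament(monomer, params, 1)
        assert fil.n_subunits == 1
        assert np.allclose(fil.subunits[0].coords, monomer.coords)

    def test_n_below_1_rejected(self, monomer, params):
        with pytest.raises(ValueError):
            build_filament(monomer, params, 0)

    def test_axial_extent_of_12mer_centroids(self, filament12):
        # 11 inter-subunit steps of 4.936 A
        z = np.array([s.centroid[2] for s in filament12.subunits])
        assert z.max() - z.min() == pytest.approx(11 * 4.936, abs=1e-9)

    def test_consecutive_centroid_offsets_equal_rise(self, filament12, params):
        z = np.array([s.centroid[2] for s in filament12.subunits])
        assert np.allclose(np.diff(z), params.rise, atol=1e-9)

    def test_subunit_k_matches_screw_operator(self, filament12, monomer, params):
        for k in (3, 7, 11):
            expected = screw_operator(params, k).apply(monomer.coords)
            assert np.allclose(filament12.subunits[k].coords, expected, atol=1e-9)

    def test_opposite_twists_are_mirror_images(self, monomer):
        # mirroring the monomer and flipping the twist sign yields the exact
        # mirror image of the original build; superposing one onto the other
        # therefore requires a reflection
        mirrored_atoms = [
            Atom(a.serial, a.name, a.element, a.residue_number, a.residue_name,
                 a.chain_id, a.position * np.array([1.0, -1.0, 1.0]))
            for a in monomer.atoms
        ]
        mirrored = monomer.with_atoms(mirrored_atoms)
        left = build_filament(monomer, HelicalParams(4.936, -101.4), 8)
        right = build_filament(mirrored, HelicalParams(4.936, +101.4), 8)
        a = np.vstack([s.coords for s in left.subunits])
        b = np.vstack([s.coords for s in right.subunits])
        # Kabsch-with-reflection oracle: allowing det=-1 must fit far better
        # than the best proper rotation
        rmsd_proper = _fit_rmsd(a, b, allow_reflection=False)
        rmsd_any = _fit_rmsd(a, b, allow_reflection=True)
        assert rmsd_any < 1e-6
        assert rmsd_proper > 1.0

    def test_chirality_sign_from_centroid_cross_products(self, monomer):
        for twist in (-101.4, 101.4):
            fil = build_filament(monomer, HelicalParams(4.936, twist), 8)
            acc = 0.0
            for s0, s1 in zip(fil.subunits[:-1], fil.subunits[1:]):
                c0, c1 = s0.centroid.copy(), s1.centroid.copy()
                c0[2] = c1[2] = 0.0  # remove axial projection
                acc += np.cross(c0, c1)[2]
            assert math.copysign(1.0, acc) == math.copysign(1.0, twist)


def _fit_rmsd(a: np.ndarray, b: np.ndarray, allow_reflection: bool) -> float:
    ac, bc = a - a.mean(axis=0), b - b.mean(axis=0)
    u, s, vt = np.linalg.svd(bc.T @ ac)
    d = np.sign(np.linalg.det(u @ vt))
    if allow_reflection:
        rot = u @ vt
    else:
        corr = np.diag([1.0, 1.0, d])
        rot = u @ corr @ vt
    resid = bc @ rot - ac
    return float(np.sqrt((resid**2).sum() / len(a)))


class TestPitchArithmetic:
    def test_helical_pitch_reference_params(self):
        assert helical_pitch(HelicalParams(4.936, -101.4)) == pytest.approx(
            17.524, abs=5e-4
        )

    def test_helical_pitch_half_turn(self):
        assert helical_pitch(HelicalParams(10.0, 180.0)) == 20.0

    def test_protrusion_spacing_printed_formula(self):
        assert protrusion_spacing(HelicalParams(4.96, 101.36)) == pytest.approx(
            35.23, abs=5e-3
        )

    def test_protrusion_spacing_refined_params(self):
        assert protrusion_spacing(HelicalParams(4.936, 101.4)) == pytest.approx(
            35.05, abs=5e-3
        )

    @given(params=param_strategy)
    @settings(max_examples=50, deadline=None)
    def test_spacing_is_twice_pitch(self, params):
        assert protrusion_spacing(params) == pytest.approx(
            2 * helical_pitch(params), rel=1e-12
        )

    def test_doubling_rise_doubles_spacing(self):
        s1 = protrusion_spacing(HelicalParams(4.936, -101.4))
        s2 = protrusion_spacing(HelicalParams(9.872, -101.4))
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    @pytest.mark.parametrize(
        "twist,expected",
        [(-101.4, 3.5503), (120.0, 3.0), (-101.0, 3.5644)],
    )
    def test_subunits_per_turn(self, twist, expected):
        assert subunits_per_turn(HelicalParams(5.0, twist)) == pytest.approx(
            expected, abs=5e-5
        )

    @pytest.mark.parametrize(
        "span,expected", [(60.0, 12), (4.936, 1), (59.2, 11)]
    )
    def test_subunit_count_in_span(self, span, expected):
        assert subunit_count_in_span(span, HelicalParams(4.936, -101.4)) == expected

    def test_subunit_count_rejects_nonpositive_span(self):
        with pytest.raises(ValueError):
            subunit_count_in_span(0.0, HelicalParams(4.936, -101.4))


class TestFilamentDiameter:
    def test_cylinder_of_radius_35(self):
        rng = np.random.default_rng(0)
        atoms = []
        for i, phi in enumerate(rng.uniform(0, 2 * np.pi, 200)):
            atoms.append(
                Atom(i, "CA", "C", 432 + i % 50, "ALA", "A",
                     [35 * np.cos(phi), 35 * np.sin(phi), rng.uniform(0, 50)])
            )
        fil = FilamentModel(subunits=[Subunit(0, RigidTransform.identity(), atoms)])
        assert filament_diameter(fil) == pytest.approx(70.0, abs=1e-9)

    def test_synthetic_filament_within_sanity_window(self, filament12):
        assert 50.0 <= filament_diameter(filament12) <= 90.0

    def test_single_atom_on_axis(self):
        atoms = [Atom(1, "CA", "C", 432, "ALA", "A", [0.0, 0.0, 5.0])]
        fil = FilamentModel(subunits=[Subunit(0, RigidTransform.identity(), atoms)])
        assert filament_diameter(fil) == 0.0


class TestRecoverParams:
    def test_round_trip_exact(self, filament12):
        rec = recover_params_from_filament(filament12)
        assert rec.rise == pytest.approx(4.936, abs=1e-6)
        assert rec.twist == pytest.approx(-101.4, abs=1e-6)

    def test_right_handed_sign(self, monomer):
        fil = build_filament(monomer, HelicalParams(5.1, +101.0), 6)
        rec = recover_params_from_filament(fil)
        assert rec.twist > 0
        assert rec.rise == pytest.approx(5.1, abs=1e-6)
        assert rec.twist == pytest.approx(101.0, abs=1e-6)

    def test_jittered_recovery_monte_carlo(self, monomer, params):
        rng = np.random.default_rng(42)
        fil = build_filament(monomer, params, 12)
        for s in fil.subunits:
            for a in s.atoms:
                a.position = a.position + rng.normal(0, 0.2, 3)
        rec = recover_params_from_filament(fil)
        assert rec.rise == pytest.approx(params.rise, abs=0.05)
        assert rec.twist == pytest.approx(params.twist, abs=0.5)

    def test_incongruent_subunits_rejected(self, monomer, params):
        fil = build_filament(monomer, params, 4)
        rng = np.random.default_rng(0)
        for a in fil.subunits[2].atoms:
            a.position = rng.uniform(-30, 30, 3)
        with pytest.raises(NotAFilamentError):
            recover_params_from_filament(fil)

    def test_needs_two_subunits(self, monomer, params):
        fil = build_filament(monomer, params, 1)
        with pytest.raises(ValueError):
            recover_params_from_filament(fil)


class TestHelicalParamsValidation:
    @pytest.mark.parametrize("rise,twist", [(0.0, 10.0), (-1.0, 10.0), (5.0, 0.0),
                                            (5.0, 181.0), (5.0, -180.0)])
    def test_invalid_params_rejected(self, rise, twist):
        with pytest.raises(ValueError):
            HelicalParams(rise=rise, twist=twist)

    def test_handedness_flag(self):
        assert HelicalParams(4.936, -101.4).is_left_handed
        assert not HelicalParams(4.936, 101.4).is_left_handed
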