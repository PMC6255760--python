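"""Screw-symmetry algebra: filament construction and pitch arithmetic.

Conventions: the filament axis is +z in a right-handed frame; positive twist
rotates counterclockwise viewed from +z, so a left-handed filament (e.g. the
refined CARD symmetry, twist -101.4 deg) steps clockwise per subunit.
"""

from __future__ import annotations

import math
from typing import List, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import NotAFilamentError
from .models import (
    DEFAULT_PARAMS,
    FilamentModel,
    HelicalParams,
    MonomerModel,
    RigidTransform,
    Subunit,
)

__all__ = [
    "HelicalParams",
    "RigidTransform",
    "DEFAULT_PARAMS",
    "screw_operator",
    "build_filament",
    "helical_pitch",
    "protrusion_spacing",
    "subunits_per_turn",
    "subunit_count_in_span",
    "filament_diameter",
    "recover_params_from_filament",
]


def screw_operator(params: HelicalParams, k: int) -> RigidTransform:
    """Rigid transform placing subunit k: rotate k*twist about +z, lift k*rise.

    Satisfies the group law S(a) o S(b) = S(a + b).
    """
    theta = math.radians(k * params.twist)
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return RigidTransform(rot, np.array([0.0, 0.0, k * params.rise]))


def build_filament(
    monomer: MonomerModel, params: HelicalParams, n: int
) -> FilamentModel:
    """Propagate a monomer into an n-subunit filament along +z."""
    if n < 1:
        raise ValueError(f"subunit count must be >= 1, got {n}")
    subunits: List[Subunit] = []
    base = monomer.atoms
    for k in range(n):
        t = screw_operator(params, k)
        moved = [
            type(a)(
                serial=a.serial,
                name=a.name,
                element=a.element,
                residue_number=a.residue_number,
                residue_name=a.residue_name,
                chain_id=a.chain_id,
                position=t.apply(a.position),
                is_heavy=a.is_heavy,
            )
            for a in base
        ]
        subunits.append(Subunit(index=k, transform=t, atoms=moved))
    return FilamentModel(subunits=subunits, params=params, monomer=monomer)


def helical_pitch(params: HelicalParams) -> float:
    """Axial distance per full 360-degree turn: (360/|twist|) * rise."""
    return (360.0 / abs(params.twist)) * params.rise


def protrusion_spacing(params: HelicalParams) -> float:
    """Distance between successive protrusion points on a 2D projection.

    For this lattice the visual repeat spans two turns: (720/|twist|) * rise.
    """
    return (720.0 / abs(params.twist)) * params.rise


def subunits_per_turn(params: HelicalParams) -> float:
    return 360.0 / abs(params.twist)


def subunit_count_in_span(span: float, params: HelicalParams) -> int:
    """Number of complete subunits whose rise fits into an axial span."""
    if span <= 0:
        raise ValueError(f"span must be > 0, got {span}")
    # epsilon guards against 4.936/4.936 -> 0.999... style float dust
    return int(math.floor(span / params.rise + 1e-9))


def filament_diameter(filament: FilamentModel) -> float:
    """Twice the 95th-percentile radial distance of heavy atoms from the axis."""
    coords = filament.heavy_coords
    if coords.size == 0:
        raise ValueError("filament has no heavy atoms")
    r = np.hypot(coords[:, 0], coords[:, 1])
    return 2.0 * float(np.percentile(r, 95))


def _screw_from_transform(
    rotation: np.ndarray, translation: np.ndarray
) -> Tuple[float, float]:
    """Signed (rise, twist deg) of a screw motion, axis taken along +z."""
    rotvec = Rotation.from_matrix(rotation).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-12:
        return float(translation[2]), 0.0
    axis = rotvec / angle
    # orient the screw axis along +z so the twist sign is well defined
    if axis[2] < 0:
        axis = -axis
        angle = -angle
    rise = float(np.dot(translation, axis))
    return rise, math.degrees(angle)


def recover_params_from_filament(
    filament: FilamentModel, rmsd_tol: float = 2.0
) -> HelicalParams:
    """Recover (rise, twist) by superposing consecutive subunits.

    Least-squares proper superposition of subunit k onto subunit k+1 gives a
    screw motion whose axial translation is the rise and whose rotation angle
    about the fitted axis is the signed twist. Estimates from all consecutive
    pairs are averaged. Raises NotAFilamentError when any pair superposes with
    an RMSD above ``rmsd_tol`` (subunits are not congruent copies).
    """
    if filament.n_subunits < 2:
        raise ValueError("need at least two subunits to recover parameters")
    filament.check_congruent()
    rises, twists = [], []
    for a, b in zip(filament.subunits[:-1], filament.subunits[1:]):
        pa, pb = a.coords, b.coords
        ca, cb = pa.mean(axis=0), pb.mean(axis=0)
        rot, rssd = Rotation.align_vectors(pb - cb, pa - ca)
        rmsd = rssd / math.sqrt(len(pa))
        if rmsd > rmsd_tol:
            raise NotAFilamentError(
                f"subunits {a.index} and {b.index} superpose with RMSD "
                f"{rmsd:.3f} A > {rmsd_tol} A"
            )
        R = rot.as_matrix()
        t = cb - R @ ca
        rise, twist = _screw_from_transform(R, t)
        rises.append(rise)
        twists.append(twist)
    return HelicalParams(rise=float(np.mean(rises)), twist=float(np.mean(twists)))
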