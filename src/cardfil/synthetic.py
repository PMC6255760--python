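"""Synthetic inputs with known ground truth: pseudo-atom monomer, filament,
noisy projection micrographs, and patch-label decoys.

The monomer is a five-helix pseudo-atom bundle (one bead per residue plus one
bead per charged side-chain terminus) sized ~40x25x25 A, carrying the six
interface patches at engineered positions: when propagated with the default
screw parameters, the "b" half-patches on a subunit's top/lateral face meet
the matching "a" half-patches of the partner subunit at a planned lattice
offset, so interface classification can be validated against construction
ground truth. Every generator is a pure function of its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import SpecError
from .helical import screw_operator
from .layerlines import ProjectionImage
from .models import (
    Atom,
    DEFAULT_PARAMS,
    FilamentModel,
    HelicalParams,
    MonomerModel,
)

__all__ = [
    "SyntheticMonomerSpec",
    "MicrographSpec",
    "make_synthetic_monomer",
    "render_micrograph",
    "make_patch_decoy",
    "noise_sigma_for_snr",
    "DEFAULT_HELIX_INTERVALS",
    "DEFAULT_PATCH_PLAN",
    "INTERFACE_OFFSETS",
]

#: Residue intervals of the five helices (full-length numbering, CARD 432-540).
DEFAULT_HELIX_INTERVALS: Dict[str, Tuple[int, int]] = {
    "H1": (435, 450),
    "H2": (455, 470),
    "H3": (473, 487),
    "H4": (490, 505),
    "H5": (510, 525),
}

#: Disjoint synthetic analogues of the six interface patches. The canonical
#: sets let K471/E472 belong to two patches; a synthetic residue carries one
#: label, so the type-III "a" patch uses its own residues instead.
DEFAULT_PATCH_PLAN: Dict[str, Tuple[int, ...]] = {
    "Ia": (444, 445, 492),
    "Ib": (458, 461, 471, 474),
    "IIa": (467, 472, 495, 497),
    "IIb": (449, 452, 513),
    "IIIa": (475, 476, 479, 480),
    "IIIb": (482, 483, 484, 488),
}

#: Wild-type identities at annotated positions; everything else is alanine.
DEFAULT_RESIDUE_IDENTITIES: Dict[int, str] = {
    439: "TRP", 444: "ARG", 445: "GLU", 449: "ASN", 452: "THR", 458: "ARG",
    461: "ASP", 467: "ASP", 471: "LYS", 472: "GLU", 474: "TYR", 475: "GLU",
    476: "SER", 479: "THR", 480: "SER", 482: "THR", 483: "ARG", 484: "THR",
    488: "ARG", 492: "ASP", 495: "ASP", 497: "GLN", 501: "PHE", 513: "LYS",
}

_CHARGE_BY_CODE = {"ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1}

#: Ground-truth lattice offset Delta-k carrying each interface type in the
#: synthetic filament (the source structure does not print this mapping, so
#: the synthetic lattice defines its own).
INTERFACE_OFFSETS: Dict[str, int] = {"I": 4, "II": 5, "III": 1}

#: Contact-point plan per interface type: (azimuth deg, z of the "b" anchor).
_ANCHOR_PLAN: Dict[str, Tuple[float, float]] = {
    "I": (0.0, 10.0),
    "II": (120.0, 11.5),
    "III": (240.0, 0.0),
}
_ANCHOR_RADIUS = 12.0
_CONTACT_GAP = 3.8  # A between facing patch-bead cluster centres

# deterministic in-cluster bead offsets (A), roughly 1.6 A apart
_CLUSTER_OFFSETS = np.array(
    [
        [0.0, 0.0, 0.0],
        [1.1, 0.6, -0.5],
        [-1.1, 0.6, 0.5],
        [0.0, -1.2, 0.6],
    ]
)


@dataclass(frozen=True)
class SyntheticMonomerSpec:
    """Recipe for the pseudo-atom monomer; pure function of ``seed``."""

    seed: int
    n_helices: int = 5
    sequence_range: Tuple[int, int] = (432, 540)
    helix_intervals: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_HELIX_INTERVALS)
    )
    bundle_dimensions: Tuple[float, float, float] = (40.0, 25.0, 25.0)
    radial_offset: float = 16.0
    patch_plan: Dict[str, Tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PATCH_PLAN)
    )
    residue_identities: Dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_IDENTITIES)
    )
    landmark_plan: Tuple[int, int, int] = (439, 474, 501)
    params: HelicalParams = DEFAULT_PARAMS
    body_jitter: float = 0.15

    def validate(self) -> None:
        if self.n_helices != 5:
            raise SpecError("the synthetic bundle is defined with five helices")
        seen: Dict[int, str] = {}
        for name, residues in self.patch_plan.items():
            for r in residues:
                if r in seen:
                    raise SpecError(
                        f"residue {r} planned for both {seen[r]} and {name}"
                    )
                seen[r] = name
        lo, hi = self.sequence_range
        for r in seen:
            if not lo <= r <= hi:
                raise SpecError(f"patch residue {r} outside sequence range")


@dataclass(frozen=True)
class MicrographSpec:
    """Rendering recipe for a noisy projection image."""

    seed: int
    pixel_size: float = 1.23
    box: int = 512
    noise_sigma: float = 0.0  # fraction of peak signal
    blur_sigma: float = 1.5  # A

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.box < 64:
            raise ValueError("box must be >= 64 pixels")


def _unit_radial(azimuth_deg: float) -> np.ndarray:
    a = np.radians(azimuth_deg)
    return np.array([np.cos(a), np.sin(a), 0.0])


def _body_positions(spec: SyntheticMonomerSpec, rng: np.random.Generator):
    """Bead positions for the helix bundle, scaled to the bundle box."""
    lo, hi = spec.sequence_range
    residues = list(range(lo, hi + 1))
    intervals = [spec.helix_intervals[h] for h in sorted(spec.helix_intervals)]
    # pentagon cross-section (y, z), helices run along x and alternate direction
    cross = 8.0 * np.array(
        [
            [np.sin(2 * np.pi * i / 5), np.cos(2 * np.pi * i / 5)]
            for i in range(5)
        ]
    )
    pos: Dict[int, np.ndarray] = {}
    for i, (a, b) in enumerate(intervals):
        n = b - a + 1
        xs = np.linspace(-0.5, 0.5, n)
        if i % 2:
            xs = xs[::-1]
        for j, r in enumerate(range(a, b + 1)):
            pos[r] = np.array([xs[j], cross[i, 0] / 12.5, cross[i, 1] / 12.5])
    # loops/termini: linear interpolation between flanking helix ends
    anchored = sorted(pos)
    for r in residues:
        if r in pos:
            continue
        before = [x for x in anchored if x < r]
        after = [x for x in anchored if x > r]
        if before and after:
            r0, r1 = before[-1], after[0]
            t = (r - r0) / (r1 - r0)
            pos[r] = (1 - t) * pos[r0] + t * pos[r1]
        elif after:
            pos[r] = pos[after[0]] + 0.04 * (r - after[0]) * np.array([1.0, 0, 0])
        else:
            pos[r] = pos[before[-1]] + 0.04 * (r - before[-1]) * np.array([1.0, 0, 0])
    raw = np.array([pos[r] for r in residues])
    raw += rng.normal(0.0, 0.01, raw.shape)  # tiny pre-scale jitter
    # scale each axis so the extent equals the bundle dimensions exactly
    span = raw.max(axis=0) - raw.min(axis=0)
    centre = (raw.max(axis=0) + raw.min(axis=0)) / 2
    scaled = (raw - centre) / span * np.asarray(spec.bundle_dimensions)
    scaled += np.array([spec.radial_offset, 0.0, 0.0])
    scaled += rng.normal(0.0, spec.body_jitter, scaled.shape)
    return residues, {r: scaled[i] for i, r in enumerate(residues)}


def _patch_positions(spec: SyntheticMonomerSpec) -> Dict[int, np.ndarray]:
    """Engineered patch-bead positions in the subunit-0 frame.

    For type T across lattice offset dk: the "b" cluster sits at the anchor
    point P on subunit 0; the "a" cluster of the partner subunit must land at
    P + gap (radially outward) in the filament frame, so in the monomer frame
    it is placed at S(-dk) applied to that point.
    """
    out: Dict[int, np.ndarray] = {}
    for t, dk in INTERFACE_OFFSETS.items():
        azimuth, z = _ANCHOR_PLAN[t]
        radial = _unit_radial(azimuth)
        anchor = _ANCHOR_RADIUS * radial + np.array([0.0, 0.0, z])
        b_res = spec.patch_plan.get(f"{t}b", ())
        for i, r in enumerate(b_res):
            out[r] = anchor + _CLUSTER_OFFSETS[i % len(_CLUSTER_OFFSETS)]
        back = screw_operator(spec.params, -dk)
        a_centre_filament = anchor + _CONTACT_GAP * radial
        a_res = spec.patch_plan.get(f"{t}a", ())
        for i, r in enumerate(a_res):
            p = a_centre_filament + _CLUSTER_OFFSETS[i % len(_CLUSTER_OFFSETS)]
            out[r] = back.apply(p)
    return out


def make_synthetic_monomer(spec: SyntheticMonomerSpec) -> MonomerModel:
    """Build the patch-labelled pseudo-atom monomer (deterministic per seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    residues, positions = _body_positions(spec, rng)
    for r, p in _patch_positions(spec).items():
        positions[r] = p
    patch_labels = {
        r: name for name, rs in spec.patch_plan.items() for r in rs
    }
    atoms: List[Atom] = []
    serial = 0
    for r in residues:
        code = spec.residue_identities.get(r, "ALA")
        serial += 1
        atoms.append(
            Atom(
                serial=serial,
                name="CA",
                element="C",
                residue_number=r,
                residue_name=code,
                chain_id="A",
                position=positions[r].copy(),
            )
        )
        charge = _CHARGE_BY_CODE.get(code, 0)
        if charge != 0:
            # side-chain terminus bead, nudged toward the filament axis plane
            # normal so charged beads sit on the residue's outward face
            centre = np.array([spec.radial_offset, 0.0, 0.0])
            direction = positions[r] - centre
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 1e-6 else np.array([1.0, 0, 0])
            serial += 1
            atoms.append(
                Atom(
                    serial=serial,
                    name="NZ" if charge > 0 else "OD1",
                    element="N" if charge > 0 else "O",
                    residue_number=r,
                    residue_name=code,
                    chain_id="A",
                    position=positions[r] + 1.0 * direction,
                )
            )
    model = MonomerModel(
        atoms=atoms,
        sequence_range=spec.sequence_range,
        helix_segments={h: tuple(v) for h, v in spec.helix_intervals.items()},
        patch_labels=patch_labels,
        landmark_residues=set(spec.landmark_plan),
    )
    model.source_spec = spec  # ground-truth bookkeeping
    return model


def formal_charge(residue_name: str) -> int:
    return _CHARGE_BY_CODE.get(residue_name.upper(), 0)


def render_micrograph(
    filament: FilamentModel, spec: MicrographSpec
) -> ProjectionImage:
    """Project heavy atoms along +x onto the (y, z) grid and add noise.

    Each heavy atom is splatted onto the pixel grid and blurred with an
    isotropic Gaussian of width ``blur_sigma``; white Gaussian noise with
    standard deviation ``noise_sigma`` x peak signal is added; the image is
    mean-subtracted. The filament axis runs vertically (axial = rows).
    """
    coords = filament.heavy_coords
    box, px = spec.box, spec.pixel_size
    z = coords[:, 2]
    z_centre = (z.max() + z.min()) / 2
    if (z.max() - z.min()) > box * px:
        warnings.warn(
            "filament longer than the field of view; projection truncated",
            stacklevel=2,
        )
    rows = np.round((z - z_centre) / px).astype(int) + box // 2
    cols = np.round(coords[:, 1] / px).astype(int) + box // 2
    keep = (rows >= 0) & (rows < box) & (cols >= 0) & (cols < box)
    image = np.zeros((box, box))
    np.add.at(image, (rows[keep], cols[keep]), 1.0)
    image = ndimage.gaussian_filter(image, sigma=spec.blur_sigma / px)
    peak = float(image.max())
    if spec.noise_sigma > 0 and peak > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sigma * peak, image.shape)
    image -= image.mean()
    result = ProjectionImage(pixels=image, pixel_size=px, axis_orientation="vertical")
    result.source_spec = spec
    return result


def noise_sigma_for_snr(
    filament: FilamentModel, spec: MicrographSpec, snr: float
) -> float:
    """Noise fraction giving the requested SNR = var(signal) / var(noise).

    Renders the filament noiselessly with the same geometry to measure the
    signal variance, then returns the ``noise_sigma`` (fraction of peak
    signal) whose additive white noise realizes the target SNR.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    from dataclasses import replace as dc_replace

    clean = render_micrograph(filament, dc_replace(spec, noise_sigma=0.0))
    peak = float(clean.pixels.max())
    var_signal = float(clean.pixels.var())
    return float(np.sqrt(var_signal / snr) / peak)


def make_patch_decoy(monomer: MonomerModel, seed: int) -> MonomerModel:
    """Permute patch labels among surface residues; geometry unchanged.

    The permutation pool is the labelled residues plus an equal-sized sample
    of unlabelled residues, so labels both move and vanish. Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(seed)
    labelled = sorted(monomer.patch_labels)
    unlabelled = [r for r in monomer.residue_numbers if r not in monomer.patch_labels]
    extra = rng.choice(
        unlabelled, size=min(len(labelled), len(unlabelled)), replace=False
    )
    pool = np.array(labelled + sorted(int(x) for x in extra))
    shuffled = pool[rng.permutation(len(pool))]
    new_labels = {
        int(shuffled[i]): monomer.patch_labels[r] for i, r in enumerate(labelled)
    }
    from dataclasses import replace as dc_replace

    return dc_replace(monomer, patch_labels=new_labels)
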