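"""Core domain types shared across cardfil modules.

Atomic coordinates are in Angstrom throughout; angles are degrees at every
public interface and radians only inside numerical kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import NotAFilamentError

PATCH_NAMES = ("Ia", "Ib", "IIa", "IIb", "IIIa", "IIIb")

#: Filament axis convention: +z, right-handed frame.
Z_AXIS = np.array([0.0, 0.0, 1.0])


@dataclass
class Atom:
    """One (pseudo-)atom record.

    ``is_heavy`` is derived from the element symbol unless set explicitly;
    hydrogens are retained by readers but flagged ``is_heavy=False``.
    """

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    is_heavy: Optional[bool] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")
        if self.is_heavy is None:
            self.is_heavy = self.element.strip().upper() != "H"


@dataclass
class MonomerModel:
    """A single subunit: atoms plus helix/patch/landmark annotation.

    Residue numbering follows the source protein (RIP2 CARD spans 432-540
    in full-length numbering); no local renumbering is ever applied.
    """

    atoms: List[Atom]
    sequence_range: Tuple[int, int]
    helix_segments: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    patch_labels: Dict[int, str] = field(default_factory=dict)
    landmark_residues: Set[int] = field(default_factory=lambda: {439, 474, 501})

    def __post_init__(self) -> None:
        lo, hi = self.sequence_range
        for res in self.patch_labels:
            if not lo <= res <= hi:
                raise ValueError(
                    f"patch residue {res} outside sequence range {self.sequence_range}"
                )

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def heavy_coords(self) -> np.ndarray:
        return np.array(
            [a.position for a in self.atoms if a.is_heavy], dtype=float
        ).reshape(-1, 3)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def residue_numbers(self) -> List[int]:
        seen: List[int] = []
        for a in self.atoms:
            if not seen or seen[-1] != a.residue_number:
                if a.residue_number not in seen:
                    seen.append(a.residue_number)
        return seen

    def residue_name_of(self, residue_number: int) -> Optional[str]:
        for a in self.atoms:
            if a.residue_number == residue_number:
                return a.residue_name
        return None

    def with_atoms(self, atoms: List[Atom]) -> "MonomerModel":
        return replace(self, atoms=atoms)

    def helix_of(self, residue_number: int) -> str:
        """Return the helix label for a residue, or ``"loop"``."""
        for name, (lo, hi) in self.helix_segments.items():
            if lo <= residue_number <= hi:
                return name
        return "loop"


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation determinant must be +1 (proper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)


@dataclass(frozen=True)
class HelicalParams:
    """Screw symmetry of a one-start helical filament.

    rise   -- axial translation per subunit, Angstrom, > 0
    twist  -- azimuthal rotation per subunit, degrees, in (-180, 180], != 0;
              negative twist means a left-handed filament
    """

    rise: float
    twist: float
    point_group: str = "C1"

    def __post_init__(self) -> None:
        if not self.rise > 0:
            raise ValueError(f"rise must be > 0, got {self.rise}")
        if self.twist == 0:
            raise ValueError("twist must be nonzero")
        if not (-180.0 < self.twist <= 180.0):
            raise ValueError(f"twist must lie in (-180, 180], got {self.twist}")
        if self.point_group != "C1":
            raise ValueError("only C1 point group is supported")

    @property
    def is_left_handed(self) -> bool:
        return self.twist < 0


#: Refined symmetry of the reference CARD filament (left-handed C1).
DEFAULT_PARAMS = HelicalParams(rise=4.936, twist=-101.4)


@dataclass
class Subunit:
    index: int
    transform: RigidTransform
    atoms: List[Atom]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def heavy_coords(self) -> np.ndarray:
        return np.array(
            [a.position for a in self.atoms if a.is_heavy], dtype=float
        ).reshape(-1, 3)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class FilamentModel:
    """Ordered subunit copies; subunit 0 carries the identity transform."""

    subunits: List[Subunit]
    params: Optional[HelicalParams] = None
    axis: np.ndarray = field(default_factory=lambda: Z_AXIS.copy())
    monomer: Optional[MonomerModel] = None

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        if len(self.subunits) == 0:
            raise ValueError("filament must contain at least one subunit")

    @property
    def n_subunits(self) -> int:
        return len(self.subunits)

    @property
    def heavy_coords(self) -> np.ndarray:
        return np.vstack([s.heavy_coords for s in self.subunits])

    def check_congruent(self, rmsd_tol: float = 2.0) -> None:
        """Raise NotAFilamentError unless all subunits share an atom count."""
        n0 = len(self.subunits[0].atoms)
        for s in self.subunits[1:]:
            if len(s.atoms) != n0:
                raise NotAFilamentError(
                    f"subunit {s.index} has {len(s.atoms)} atoms, expected {n0}"
                )
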