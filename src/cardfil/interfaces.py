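"""Inter-subunit contact mapping and death-fold interface classification.

Contacts are residue pairs whose minimum heavy-atom distance falls below a
cutoff (default 4.5 A, the standard criterion; configurable). Each subunit
pair is classified into Type I/II/III by majority vote over the patch
pairings (Ia:Ib, IIa:IIb, IIIa:IIIb) of its contacts. A residue belonging to
two patches votes for whichever pairing matches its partner; if both match,
the contact contributes half a vote to each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .models import FilamentModel, HelicalParams

__all__ = [
    "InterfacePatch",
    "ContactPair",
    "InterfaceClassification",
    "CANONICAL_PATCHES",
    "find_contacts",
    "neighbor_geometry",
    "classify_interface",
    "classify_filament_interfaces",
    "surface_sides",
    "surface_residues",
]


@dataclass(frozen=True)
class InterfacePatch:
    name: str
    residues: FrozenSet[int]
    location: str = ""


#: The six canonical patches (full-length RIP2 numbering). K471 and E472
#: genuinely belong to two patches each.
CANONICAL_PATCHES: Tuple[InterfacePatch, ...] = (
    InterfacePatch("Ia", frozenset({444, 445, 492}), "helices 1 and 4"),
    InterfacePatch("Ib", frozenset({458, 461, 471, 474}), "helices 2 and 3"),
    InterfacePatch("IIa", frozenset({495, 497, 472, 467}), "turns H2/3 and H4/5"),
    InterfacePatch("IIb", frozenset({449, 452, 513}), "turn H1/2"),
    InterfacePatch("IIIa", frozenset({479, 475, 471, 472}), "helix 2"),
    InterfacePatch("IIIb", frozenset({483, 482, 484, 488}), "turn H3/4"),
)

_TYPE_PAIRINGS = {"I": ("Ia", "Ib"), "II": ("IIa", "IIb"), "III": ("IIIa", "IIIb")}


@dataclass
class ContactPair:
    subunit_i: int
    subunit_j: int
    residue_i: int
    residue_j: int
    min_heavy_distance: float
    patch_i: Optional[str] = None
    patch_j: Optional[str] = None

    def __post_init__(self) -> None:
        if self.subunit_i >= self.subunit_j:
            raise ValueError("contacts are stored with subunit_i < subunit_j")


@dataclass
class InterfaceClassification:
    subunit_i: int
    subunit_j: int
    assigned_type: str  # I | II | III | unclassified
    support: float
    evidence: List[ContactPair] = field(default_factory=list)

    @property
    def delta_k(self) -> int:
        return self.subunit_j - self.subunit_i


def _residue_atom_groups(subunit) -> Dict[int, np.ndarray]:
    groups: Dict[int, List[int]] = {}
    heavy = [a for a in subunit.atoms if a.is_heavy]
    coords = np.array([a.position for a in heavy]).reshape(-1, 3)
    for idx, a in enumerate(heavy):
        groups.setdefault(a.residue_number, []).append(idx)
    return {r: coords[ix] for r, ix in groups.items()}


def find_contacts(
    filament: FilamentModel,
    cutoff: float = 4.5,
    labels: Optional[Dict[int, str]] = None,
) -> List[ContactPair]:
    """All inter-subunit residue pairs with min heavy-atom distance <= cutoff.

    Intra-subunit pairs are excluded; a single-subunit filament yields an
    empty list. Patch labels default to the template monomer's labels.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if labels is None:
        labels = filament.monomer.patch_labels if filament.monomer else {}
    groups = [_residue_atom_groups(s) for s in filament.subunits]
    bounds = []
    for g in groups:
        allc = np.vstack(list(g.values()))
        bounds.append((allc.min(axis=0), allc.max(axis=0)))
    contacts: List[ContactPair] = []
    n = filament.n_subunits
    for i in range(n):
        for j in range(i + 1, n):
            lo_i, hi_i = bounds[i]
            lo_j, hi_j = bounds[j]
            # bounding boxes further apart than the cutoff cannot touch
            gap = np.maximum(lo_j - hi_i, lo_i - hi_j)
            if np.any(gap > cutoff):
                continue
            for ri, ci in groups[i].items():
                for rj, cj in groups[j].items():
                    d = float(cdist(ci, cj).min())
                    if d <= cutoff:
                        contacts.append(
                            ContactPair(
                                subunit_i=i,
                                subunit_j=j,
                                residue_i=ri,
                                residue_j=rj,
                                min_heavy_distance=d,
                                patch_i=labels.get(ri),
                                patch_j=labels.get(rj),
                            )
                        )
    return contacts


def _wrap_angle(theta: float) -> float:
    """Wrap degrees to (-180, 180]."""
    w = (theta + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


def neighbor_geometry(params: HelicalParams, max_offset: int) -> pd.DataFrame:
    """Lattice-neighbour table: axial and wrapped azimuthal offsets per dk."""
    if max_offset < 1:
        raise ValueError("max_offset must be >= 1")
    rows = [
        {
            "delta_k": dk,
            "delta_z": dk * params.rise,
            "delta_theta": _wrap_angle(dk * params.twist),
        }
        for dk in range(1, max_offset + 1)
    ]
    return pd.DataFrame(rows)


def _membership(
    patches: Optional[Sequence[InterfacePatch]],
    contacts: Sequence[ContactPair],
) -> Dict[int, Set[str]]:
    members: Dict[int, Set[str]] = {}
    if patches is not None:
        for p in patches:
            for r in p.residues:
                members.setdefault(r, set()).add(p.name)
    else:
        for c in contacts:
            if c.patch_i:
                members.setdefault(c.residue_i, set()).add(c.patch_i)
            if c.patch_j:
                members.setdefault(c.residue_j, set()).add(c.patch_j)
    return members


def classify_interface(
    contacts: Sequence[ContactPair],
    patches: Optional[Sequence[InterfacePatch]] = None,
) -> InterfaceClassification:
    """Majority-vote type assignment for one subunit pair's contacts.

    Support is the winning fraction over contacts in which both residues
    carry at least one patch label; such a contact votes for type T when its
    labels realize the (Ta, Tb) pairing in either order. A classified type
    requires support >= 0.5; ties break toward the smaller summed contact
    distance.
    """
    contacts = list(contacts)
    if not contacts:
        raise ValueError("cannot classify an empty contact list")
    pairs = {(c.subunit_i, c.subunit_j) for c in contacts}
    if len(pairs) != 1:
        raise ValueError(f"contacts span several subunit pairs: {sorted(pairs)}")
    (si, sj) = pairs.pop()
    members = _membership(patches, contacts)
    votes = {t: 0.0 for t in _TYPE_PAIRINGS}
    dist_sum = {t: 0.0 for t in _TYPE_PAIRINGS}
    n_labeled = 0
    for c in contacts:
        mi = members.get(c.residue_i, set())
        mj = members.get(c.residue_j, set())
        if not mi or not mj:
            continue
        n_labeled += 1
        matched = [
            t
            for t, (a, b) in _TYPE_PAIRINGS.items()
            if (a in mi and b in mj) or (b in mi and a in mj)
        ]
        for t in matched:
            votes[t] += 1.0 / len(matched)
            dist_sum[t] += c.min_heavy_distance
    if n_labeled == 0:
        return InterfaceClassification(si, sj, "unclassified", 0.0, contacts)
    best = max(votes, key=lambda t: (votes[t], -dist_sum[t]))
    support = votes[best] / n_labeled
    assigned = best if support >= 0.5 and votes[best] > 0 else "unclassified"
    return InterfaceClassification(si, sj, assigned, support, contacts)


def classify_filament_interfaces(
    filament: FilamentModel,
    cutoff: float = 4.5,
    patches: Optional[Sequence[InterfacePatch]] = None,
    labels: Optional[Dict[int, str]] = None,
) -> List[InterfaceClassification]:
    """Classify every subunit pair that is in contact."""
    contacts = find_contacts(filament, cutoff=cutoff, labels=labels)
    by_pair: Dict[Tuple[int, int], List[ContactPair]] = {}
    for c in contacts:
        by_pair.setdefault((c.subunit_i, c.subunit_j), []).append(c)
    return [
        classify_interface(cs, patches=patches)
        for _, cs in sorted(by_pair.items())
    ]


def surface_sides(
    patches: Optional[Sequence[InterfacePatch]] = None,
) -> Dict[str, Set[str]]:
    """Fixed partition of the half-patches onto the subunit's axial faces:
    top = {Ib, IIb}, bottom = {Ia, IIa}, lateral = {IIIa, IIIb}."""
    return {
        "top": {"Ib", "IIb"},
        "bottom": {"Ia", "IIa"},
        "lateral": {"IIIa", "IIIb"},
    }


def surface_residues(
    side: str, patches: Sequence[InterfacePatch] = CANONICAL_PATCHES
) -> Set[int]:
    """Union of patch residues on one face ('top', 'bottom' or 'lateral')."""
    sides = surface_sides(patches)
    if side not in sides:
        raise ValueError(f"side must be one of {sorted(sides)}")
    wanted = sides[side]
    out: Set[int] = set()
    for p in patches:
        if p.name in wanted:
            out |= p.residues
    return out
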