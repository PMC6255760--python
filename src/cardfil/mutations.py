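"""Charge-reversal mutation logic for filament interfaces.

A minimal electrostatic model: every residue carries a formal charge
(D/E -> -1, K/R -> +1, everything else 0; histidine is 0), and a contact
pair is attractive/repulsive/neutral by the sign of the charge product.
Predicted categories for a set of substitutions, evaluated over the native
cross-interface contact pairs:

    any pair turned repulsive                      -> loss
    a formerly neutral pair turned attractive      -> enhanced
    a formerly attractive pair kept attractive
    with the two charges swapped                   -> rescue
    nothing evaluable changed                      -> ambiguous
    no substitutions at all                        -> active (wild type)

No polar bonus is modelled: native N/Q/T contacts are neutral
(compatible-but-weak). Note that position 458 is treated as arginine: the
charge-reversal outcomes (E445R loss, R458E loss, E445R+R458E rescue) are
mutually consistent only for a natively charged 458.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

__all__ = [
    "CHARGE_BY_CODE",
    "WILD_TYPE_RESIDUES",
    "NATIVE_CONTACT_PAIRS",
    "Substitution",
    "MutantDesign",
    "formal_charge",
    "pair_category",
    "predict_activity",
    "silencing_mutations",
    "parse_substitution",
]

CHARGE_BY_CODE: Dict[str, int] = {"ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1}

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

#: Wild-type identities at the interface positions (full-length numbering).
WILD_TYPE_RESIDUES: Dict[int, str] = {
    444: "ARG", 445: "GLU", 449: "ASN", 452: "THR", 458: "ARG", 461: "ASP",
    467: "ASP", 471: "LYS", 472: "GLU", 474: "TYR", 475: "GLU", 479: "THR",
    482: "THR", 483: "ARG", 484: "THR", 488: "ARG", 492: "ASP", 495: "ASP",
    497: "GLN", 513: "LYS",
}

#: Native cross-interface contact pairs used by the predictor.
NATIVE_CONTACT_PAIRS: Tuple[Tuple[int, int], ...] = (
    (444, 461),  # type I salt bridge
    (445, 458),  # type I pair probed by charge reversal
    (449, 495),  # type II polar pair probed by charge reversal
    (467, 513),  # type II salt bridge
    (471, 492),  # type I salt bridge
)


def formal_charge(code: str) -> int:
    """Formal charge of a residue given as 1- or 3-letter code."""
    code = code.strip().upper()
    if len(code) == 1:
        code = _ONE_TO_THREE.get(code, code)
    return CHARGE_BY_CODE.get(code, 0)


def pair_category(charge_i: int, charge_j: int) -> str:
    """attractive / repulsive / neutral by the sign of the charge product."""
    for c in (charge_i, charge_j):
        if c not in (-1, 0, 1):
            raise ValueError(f"charges must be in {{-1, 0, +1}}, got {c}")
    product = charge_i * charge_j
    if product < 0:
        return "attractive"
    if product > 0:
        return "repulsive"
    return "neutral"


@dataclass(frozen=True)
class Substitution:
    site: int
    from_code: str
    to_code: str

    def __str__(self) -> str:
        return f"{self.from_code}{self.site}{self.to_code}"


@dataclass
class MutantDesign:
    substitutions: List[Substitution]
    affected_pairs: List[Tuple[Tuple[int, int], str, str]] = field(
        default_factory=list
    )
    prediction: Optional[str] = None

    @property
    def sites(self) -> Dict[int, str]:
        return {s.site: s.to_code for s in self.substitutions}


_SUB_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


def parse_substitution(token: str) -> Substitution:
    """Parse a one-letter mutation token like ``E445R``."""
    m = _SUB_RE.match(token.strip())
    if not m:
        raise ValueError(f"cannot parse substitution {token!r} (expected e.g. E445R)")
    f, site, t = m.groups()
    return Substitution(
        site=int(site),
        from_code=_ONE_TO_THREE[f.upper()],
        to_code=_ONE_TO_THREE[t.upper()],
    )


def _normalize(code: str) -> str:
    code = code.strip().upper()
    return _ONE_TO_THREE.get(code, code)


def predict_activity(
    design: MutantDesign,
    native_pairs: Sequence[Tuple[int, int]] = NATIVE_CONTACT_PAIRS,
    wild_type: Dict[int, str] = WILD_TYPE_RESIDUES,
) -> str:
    """Predict the categorical activity of a design; fills the design in place.

    Predictions are invariant to substitution order. A substitution at a site
    outside every native contact pair triggers a warning; a design touching no
    pair at all is ambiguous, and an empty design is wild-type active.
    """
    subs = {s.site: _normalize(s.to_code) for s in design.substitutions}
    for s in design.substitutions:
        wt = wild_type.get(s.site)
        if wt is not None and _normalize(s.from_code) != wt:
            warnings.warn(
                f"substitution {s} disagrees with the wild-type table "
                f"({wt}{s.site})",
                stacklevel=2,
            )
    if not subs:
        design.affected_pairs = []
        design.prediction = "active"
        return design.prediction

    pair_sites = {site for pair in native_pairs for site in pair}
    for site in subs:
        if site not in pair_sites:
            warnings.warn(
                f"substitution at residue {site} is outside every native "
                "contact pair; it cannot be evaluated",
                stacklevel=2,
            )

    affected: List[Tuple[Tuple[int, int], str, str]] = []
    transitions: List[Tuple[str, str, bool]] = []
    for (a, b) in native_pairs:
        if a not in subs and b not in subs:
            continue
        qa_nat = formal_charge(wild_type.get(a, "ALA"))
        qb_nat = formal_charge(wild_type.get(b, "ALA"))
        qa_mut = formal_charge(subs.get(a, wild_type.get(a, "ALA")))
        qb_mut = formal_charge(subs.get(b, wild_type.get(b, "ALA")))
        native_cat = pair_category(qa_nat, qb_nat)
        mutant_cat = pair_category(qa_mut, qb_mut)
        swapped = (
            mutant_cat == "attractive"
            and native_cat == "attractive"
            and (qa_mut, qb_mut) == (qb_nat, qa_nat)
            and qa_mut != qa_nat
        )
        affected.append(((a, b), native_cat, mutant_cat))
        transitions.append((native_cat, mutant_cat, swapped))

    design.affected_pairs = affected
    if not affected:
        design.prediction = "ambiguous"
    elif any(mut == "repulsive" for _, mut, _ in transitions):
        design.prediction = "loss"
    elif any(nat == "neutral" and mut == "attractive" for nat, mut, _ in transitions):
        design.prediction = "enhanced"
    elif any(swapped for _, _, swapped in transitions):
        design.prediction = "rescue"
    else:
        design.prediction = "ambiguous"
    return design.prediction


def silencing_mutations(side: str) -> MutantDesign:
    """Surface-silencing designs that kill self-oligomerization on one face.

    bottom -> R444E + E445R; top -> N449A + K513E. Both predict loss for
    self-assembly across the mutated face.
    """
    if side == "bottom":
        subs = [Substitution(444, "ARG", "GLU"), Substitution(445, "GLU", "ARG")]
    elif side == "top":
        subs = [Substitution(449, "ASN", "ALA"), Substitution(513, "LYS", "GLU")]
    else:
        raise ValueError("side must be 'top' or 'bottom'")
    design = MutantDesign(substitutions=subs)
    predict_activity(design)
    return design
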