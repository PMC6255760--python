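"""Read/write atomic coordinate files; annotate monomers with helix/patch labels.

Only ATOM/HETATM records are interpreted; everything else in a PDB file is
ignored. The first altloc wins. Helix segmentation is configuration-driven
(residue intervals), never computed from geometry.
"""

from __future__ import annotations

import math
import string
from dataclasses import replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ChainExhaustionError, ConfigError, EmptyInputError, ParseError
from .models import (
    Atom,
    FilamentModel,
    MonomerModel,
    RigidTransform,
    Subunit,
)

__all__ = [
    "read_structure",
    "write_structure",
    "assign_helices",
    "Atom",
    "MonomerModel",
    "FilamentModel",
]

#: 62 single-character chain identifiers accepted by the fixed-width format.
_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits

HELIX_NAMES = ("H1", "H2", "H3", "H4", "H5")


def _locate_bad_line(path: Path) -> str:
    """Best-effort scan for the first malformed ATOM/HETATM record."""
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.startswith(("ATOM", "HETATM")):
                    continue
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError):
                    return f" (line {lineno}: {line.rstrip()!r})"
    except OSError:
        pass
    return ""


def _atom_array_from_file(path: Path, format: str):
    import biotite.structure as struc

    if format == "pdb":
        import biotite.structure.io.pdb as pdb

        pdb_file = pdb.PDBFile.read(str(path))
        arr = pdb_file.get_structure(model=1, altloc="first")
    elif format == "mmcif":
        import biotite.structure.io.pdbx as pdbx

        cif = pdbx.CIFFile.read(str(path))
        arr = pdbx.get_structure(cif, model=1, altloc="first")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'pdb' or 'mmcif'")
    return arr


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def _chains_to_models(arr) -> List[MonomerModel]:
    models = []
    chain_ids = []
    for cid in arr.chain_id:
        if cid not in chain_ids:
            chain_ids.append(cid)
    for cid in chain_ids:
        sub = arr[arr.chain_id == cid]
        atoms = [
            Atom(
                serial=i + 1,
                name=str(sub.atom_name[i]),
                element=str(sub.element[i]),
                residue_number=int(sub.res_id[i]),
                residue_name=str(sub.res_name[i]),
                chain_id=str(cid),
                position=np.array(sub.coord[i], dtype=float),
            )
            for i in range(sub.array_length())
        ]
        res_ids = [a.residue_number for a in atoms]
        models.append(
            MonomerModel(atoms=atoms, sequence_range=(min(res_ids), max(res_ids)))
        )
    return models


def _chains_identical(models: Sequence[MonomerModel]) -> bool:
    ref = [(a.residue_number, a.residue_name, a.name) for a in models[0].atoms]
    return all(
        [(a.residue_number, a.residue_name, a.name) for a in m.atoms] == ref
        for m in models[1:]
    )


def _fit_transform(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst - cd, src - cs)
    R = rot.as_matrix()
    return RigidTransform(R, cd - R @ cs)


def read_structure(
    path: Union[str, Path], format: str | None = None
) -> Union[MonomerModel, FilamentModel, List[MonomerModel]]:
    """Read a PDB or mmCIF file.

    Returns a MonomerModel for a single chain, a FilamentModel when several
    identical chains are present (subunit transforms fitted against chain 0),
    and a list of MonomerModels otherwise. Hydrogens are retained but flagged
    ``is_heavy=False``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {fmt!r}; expected 'pdb' or 'mmcif'")
    try:
        arr = _atom_array_from_file(path, fmt)
    except Exception as exc:
        if "0 models" in str(exc):
            raise EmptyInputError(f"{path} contains no coordinates") from exc
        raise ParseError(
            f"could not parse {path} as {fmt}: {exc}{_locate_bad_line(path)}"
        ) from exc
    if arr.array_length() == 0:
        raise EmptyInputError(f"{path} contains no coordinates")
    models = _chains_to_models(arr)
    if len(models) == 1:
        return models[0]
    if _chains_identical(models):
        ref = models[0].coords
        subunits = [
            Subunit(index=k, transform=_fit_transform(ref, m.coords), atoms=m.atoms)
            for k, m in enumerate(models)
        ]
        subunits[0].transform = RigidTransform.identity()
        return FilamentModel(subunits=subunits, monomer=models[0])
    return models


def _format_atom_name(name: str) -> str:
    # standard PDB: names shorter than 4 chars are right-padded from col 14
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def _pdb_atom_line(a: Atom, serial: int, chain_id: str) -> str:
    x, y, z = a.position
    return (
        f"ATOM  {serial:5d} {_format_atom_name(a.name)} "
        f"{a.residue_name:>3s} {chain_id}{a.residue_number:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{a.element.strip().upper():>2s}\n"
    )


def write_structure(
    model: Union[MonomerModel, FilamentModel],
    path: Union[str, Path],
    format: str = "pdb",
) -> Path:
    """Write a model as fixed-width PDB; one chain per subunit for filaments."""
    if format != "pdb":
        raise ValueError("only PDB output is supported")
    path = Path(path)
    if isinstance(model, FilamentModel):
        chains = [s.atoms for s in model.subunits]
    else:
        if not model.atoms:
            raise EmptyInputError("cannot write an empty model")
        chains = [model.atoms]
    if not any(chains) or all(len(c) == 0 for c in chains):
        raise EmptyInputError("cannot write an empty model")
    if len(chains) > len(_CHAIN_IDS):
        raise ChainExhaustionError(
            f"{len(chains)} chains exceed the {len(_CHAIN_IDS)} available chain ids"
        )
    serial = 0
    with open(path, "w") as fh:
        for chain_idx, atoms in enumerate(chains):
            cid = _CHAIN_IDS[chain_idx]
            for a in atoms:
                serial += 1
                fh.write(_pdb_atom_line(a, serial % 100000, cid))
            fh.write("TER\n")
        fh.write("END\n")
    return path


def assign_helices(
    monomer: MonomerModel, table: Dict[str, Tuple[int, int]]
) -> MonomerModel:
    """Populate helix segments from a residue-interval table (H1..H5).

    Intervals must be disjoint, ordered, and inside the sequence range;
    residues outside every interval are implicitly "loop".
    """
    missing = [h for h in HELIX_NAMES if h not in table]
    if missing:
        raise ConfigError(f"helix table missing segments: {missing}")
    extra = [h for h in table if h not in HELIX_NAMES]
    if extra:
        raise ConfigError(f"unknown helix names: {extra}")
    lo, hi = monomer.sequence_range
    intervals = []
    for name in HELIX_NAMES:
        a, b = table[name]
        if a > b:
            raise ConfigError(f"{name}: interval start {a} > end {b}")
        if a < lo or b > hi:
            raise ConfigError(
                f"{name} interval ({a},{b}) outside sequence range ({lo},{hi})"
            )
        intervals.append((a, b, name))
    intervals.sort()
    for (a1, b1, n1), (a2, b2, n2) in zip(intervals, intervals[1:]):
        if a2 <= b1:
            raise ConfigError(f"helix intervals {n1} and {n2} overlap")
    order = [n for _, _, n in intervals]
    if order != list(HELIX_NAMES):
        raise ConfigError(f"helix intervals out of order along sequence: {order}")
    return replace(monomer, helix_segments={h: tuple(table[h]) for h in HELIX_NAMES})
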