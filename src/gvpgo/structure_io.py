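"""Reading and writing AlphaFold-style single-chain structure files.

AlphaFold DB deposits one polypeptide chain per file and stores the
per-residue pLDDT confidence (0-100) in the B-factor column of every atom.
Only the backbone N, CA and C atoms are retained here; pLDDT is normalized
to [0, 1] on read so that confidence thresholds can be quoted on the same
scale throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

__all__ = ["Residue", "ProteinStructure", "read_structure", "write_structure"]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_ONE_TO_THREE["X"] = "UNK"

#: canonical alphabet used for integer tokens; index 20 is the unknown token
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_TOKEN = len(ALPHABET)


class StructureParseError(ValueError):
    """Raised when a structure file violates the single-chain AlphaFold dialect."""


@dataclass(frozen=True)
class Residue:
    """One residue: 1-based author index, one-letter code, backbone coordinates (A), pLDDT in [0,1]."""

    index: int
    amino_acid: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    plddt: float

    def __post_init__(self) -> None:
        for name in ("n", "ca", "c"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"residue {self.index}: {name.upper()} coordinate must be a finite 3-vector")
            object.__setattr__(self, name, v)
        if not 0.0 <= self.plddt <= 1.0:
            raise ValueError(f"residue {self.index}: pLDDT {self.plddt} outside [0, 1]")


@dataclass
class ProteinStructure:
    """Backbone-plus-confidence representation of one predicted protein model."""

    protein_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("structure must contain at least one residue")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    @property
    def plddt(self) -> np.ndarray:
        return np.array([r.plddt for r in self.residues])

    def coords(self, atom: str = "ca") -> np.ndarray:
        """(L, 3) array of the requested backbone atom ('n' | 'ca' | 'c')."""
        return np.stack([getattr(r, atom) for r in self.residues])

    def backbone(self) -> np.ndarray:
        """(L, 3, 3) array ordered N, CA, C per residue."""
        return np.stack([np.stack([r.n, r.ca, r.c]) for r in self.residues])

    def tokens(self) -> np.ndarray:
        return np.array(
            [ALPHABET.index(r.amino_acid) if r.amino_acid in ALPHABET else UNKNOWN_TOKEN for r in self.residues],
            dtype=int,
        )

    def transformed(self, rotation: np.ndarray, translation: Sequence[float] = (0.0, 0.0, 0.0)) -> "ProteinStructure":
        """Copy with every backbone atom mapped through x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        residues = [
            Residue(r.index, r.amino_acid, R @ r.n + t, R @ r.ca + t, R @ r.c + t, r.plddt)
            for r in self.residues
        ]
        return ProteinStructure(self.protein_id, residues)

    def approx_equal(self, other: "ProteinStructure", coord_tol: float = 1e-3, plddt_tol: float = 1e-4) -> bool:
        if len(self) != len(other) or self.sequence != other.sequence:
            return False
        if [r.index for r in self] != [r.index for r in other]:
            return False
        if not np.allclose(self.backbone(), other.backbone(), atol=coord_tol):
            return False
        return bool(np.allclose(self.plddt, other.plddt, atol=plddt_tol))


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("pdb", "mmcif"):
            raise ValueError(f"unknown structure format {format!r}; expected 'pdb' or 'mmcif'")
        return format
    suffix = path.suffix.lower()
    return "mmcif" if suffix in (".cif", ".mmcif") else "pdb"


def read_structure(path: str | Path, format: str | None = None) -> ProteinStructure:
    """Parse a single-model, single-chain PDB or mmCIF file.

    The B-factor of the CA atom, divided by 100, becomes the residue pLDDT.
    Hetero records are skipped, non-standard residues map to 'X', and
    insertion codes or multi-model files are rejected.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "pdb":
        st = gemmi.read_pdb(str(path))
    else:
        st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
    st.setup_entities()
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models")
    if len(st) > 1:
        raise StructureParseError(f"{path}: {len(st)} models found; expected exactly one")
    model = st[0]
    chains = [ch for ch in model if any(not res.het_flag == "H" for res in ch)]
    if len(chains) == 0:
        raise StructureParseError(f"{path}: empty chain")
    if len(chains) > 1:
        raise StructureParseError(f"{path}: {len(chains)} polymer chains found; expected exactly one")
    chain = chains[0]

    residues: list[Residue] = []
    for res in chain:
        if res.het_flag == "H" and res.name not in _THREE_TO_ONE:
            continue  # waters, ligands
        if res.seqid.icode not in ("", " ", "\x00"):
            raise StructureParseError(f"{path}: insertion code on residue {res.seqid.num} not supported")
        atoms = {}
        for atom in res:
            if atom.name in ("N", "CA", "C") and atom.name not in atoms:
                atoms[atom.name] = atom
        missing = [a for a in ("N", "CA", "C") if a not in atoms]
        if missing:
            raise StructureParseError(
                f"{path}: residue {res.seqid.num} ({res.name}) missing backbone atom(s) {', '.join(missing)}"
            )
        aa = _THREE_TO_ONE.get(res.name, "X")
        plddt = atoms["CA"].b_iso / 100.0
        plddt = min(max(plddt, 0.0), 1.0)
        residues.append(
            Residue(
                index=res.seqid.num,
                amino_acid=aa,
                n=np.array([atoms["N"].pos.x, atoms["N"].pos.y, atoms["N"].pos.z]),
                ca=np.array([atoms["CA"].pos.x, atoms["CA"].pos.y, atoms["CA"].pos.z]),
                c=np.array([atoms["C"].pos.x, atoms["C"].pos.y, atoms["C"].pos.z]),
                plddt=plddt,
            )
        )
    if not residues:
        raise StructureParseError(f"{path}: chain contains no standard residues")
    protein_id = st.name or path.stem
    return ProteinStructure(protein_id=protein_id or path.stem, residues=residues)


def write_structure(structure: ProteinStructure, path: str | Path, format: str | None = None) -> Path:
    """Write the backbone to PDB or mmCIF, storing pLDDT*100 in the B-factor column."""
    path = Path(path)
    fmt = _infer_format(path, format)
    st = gemmi.Structure()
    st.name = structure.protein_id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for r in structure.residues:
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE.get(r.amino_acid, "UNK")
        res.seqid = gemmi.SeqId(r.index, " ")
        res.het_flag = "A"  # always ATOM records, even for 1-residue chains
        res.entity_type = gemmi.EntityType.Polymer
        for name, coord, element in (("N", r.n, "N"), ("CA", r.ca, "C"), ("C", r.c, "C")):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(*[round(float(x), 3) for x in coord])
            atom.b_iso = round(r.plddt * 100.0, 2)
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    try:
        if fmt == "pdb":
            st.write_pdb(str(path))
        else:
            st.make_mmcif_document().write_file(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write structure to {path}: {exc}") from exc
    return path
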