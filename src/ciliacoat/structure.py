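"""Atomic chain models reduced to the per-residue level used downstream.

Only Cα coordinates (all residues) and Sγ coordinates (cysteines) matter for
repeat segmentation, RMSD analysis and disulfide detection, so a
:class:`StructureModel` keeps exactly that, one model per chain.  Residues
are renumbered sequentially from 1; the author-assigned numbering is retained
as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import FormatError, ValidationError

__all__ = ["StructureModel", "read_structure", "write_structure", "three_to_one"]

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}


def three_to_one(name: str) -> str:
    return _AA3TO1.get(name.upper(), "X")


def one_to_three(code: str) -> str:
    return _AA1TO3.get(code.upper(), "UNK")


@dataclass
class StructureModel:
    """One protein chain: residue names, Cα and (for Cys) Sγ coordinates.

    ``resnames`` are 3-letter codes; ``ca`` is an (n, 3) array in Å (x, y, z);
    ``sg`` is (n, 3) with NaN rows for residues without an Sγ atom.
    ``original_numbers`` holds the residue numbering found in the source file.
    """

    chain_id: str
    resnames: list[str]
    ca: np.ndarray
    sg: np.ndarray | None = None
    original_numbers: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        if self.ca.ndim != 2 or self.ca.shape[1] != 3:
            raise ValidationError(f"ca must be (n, 3), got {self.ca.shape}")
        if len(self.resnames) != len(self.ca):
            raise ValidationError("resnames and ca length mismatch")
        if not np.all(np.isfinite(self.ca)):
            raise ValidationError("Cα coordinates contain non-finite values")
        if self.sg is not None:
            self.sg = np.asarray(self.sg, dtype=float)
            if self.sg.shape != self.ca.shape:
                raise ValidationError("sg must match ca shape")
        if not self.original_numbers:
            self.original_numbers = list(range(1, len(self.resnames) + 1))
        nums = self.original_numbers
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValidationError("original residue numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.resnames)

    @property
    def sequence(self) -> str:
        """1-letter sequence (X for non-standard residues)."""
        return "".join(three_to_one(r) for r in self.resnames)

    def sg_of(self, index: int) -> np.ndarray | None:
        """Sγ coordinate of 1-based residue ``index``, or None."""
        if self.sg is None:
            return None
        row = self.sg[index - 1]
        return None if np.any(np.isnan(row)) else row


def read_structure(path) -> list[StructureModel]:
    """Read a PDB or mmCIF file into one :class:`StructureModel` per chain.

    Chains without any Cα atom are dropped; if no chain has one, a
    :class:`FormatError` is raised.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read structure {path}: {exc}") from exc
    st.setup_entities()
    models: list[StructureModel] = []
    if len(st) == 0:
        raise FormatError(f"{path}: structure holds no models")
    for chain in st[0]:
        resnames, cas, sgs, numbers = [], [], [], []
        for residue in chain:
            ca = residue.find_atom("CA", "*")
            if ca is None:
                continue
            resnames.append(residue.name)
            cas.append([ca.pos.x, ca.pos.y, ca.pos.z])
            sg = residue.find_atom("SG", "*")
            sgs.append(
                [sg.pos.x, sg.pos.y, sg.pos.z] if sg is not None else [np.nan] * 3
            )
            numbers.append(residue.seqid.num)
        if not cas:
            continue
        models.append(
            StructureModel(
                chain_id=chain.name,
                resnames=resnames,
                ca=np.array(cas),
                sg=np.array(sgs),
                original_numbers=numbers,
            )
        )
    if not models:
        raise FormatError(f"{path}: no chain contains Cα atoms (empty model)")
    return models


def write_structure(models, path, fmt: str | None = None):
    """Write chains (Cα + Cys Sγ pseudo-atoms) as PDB or mmCIF.

    ``fmt`` defaults to the file extension (``.pdb`` / ``.cif``).
    """
    path = Path(path)
    if fmt is None:
        fmt = "cif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = gemmi.Structure()
    st.name = path.stem
    model = gemmi.Model("1")
    for sm in models:
        chain = gemmi.Chain(sm.chain_id)
        for i, (name, ca) in enumerate(zip(sm.resnames, sm.ca), start=1):
            res = gemmi.Residue()
            res.name = name
            res.seqid = gemmi.SeqId(i, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, ca))
            res.add_atom(atom)
            sgrow = sm.sg[i - 1] if sm.sg is not None else None
            if sgrow is not None and not np.any(np.isnan(sgrow)):
                sg = gemmi.Atom()
                sg.name = "SG"
                sg.element = gemmi.Element("S")
                sg.pos = gemmi.Position(*map(float, sgrow))
                res.add_atom(sg)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if fmt == "cif":
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))
    return path
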