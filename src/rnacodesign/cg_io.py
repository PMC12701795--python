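"""Domain types and I/O for the 3-bead coarse-grained (CG) representation.

Every RNA nucleotide is reduced to three backbone beads (P, C4', N1/N9) and
every protein residue to (N, CA, C).  All coordinates are Cartesian, in
Angstrom.  Arrays are shaped ``(L, 3, 3)``: residue x bead x (x, y, z), with
the bead order fixed as documented on each type.  Indexing is 0-based in
memory; PDB serial numbers are 1-based on write.

Purines (A, G) contribute their N9 atom, pyrimidines (C, U) their N1, as the
glycosidic-nitrogen bead.  Residues missing any required bead are dropped
with a logged warning; modified or unknown residue names are dropped the
same way.  For duplicated atoms (altlocs) the first occurrence is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = "ACGU"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"

RNA_BEAD_NAMES = ("P", "C4'", "N1/N9")
PROTEIN_BEAD_NAMES = ("N", "CA", "C")

#: glycosidic nitrogen per nucleotide: purines use N9, pyrimidines N1
GLYCOSIDIC_ATOM = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1_TO_3 = {v: k for k, v in _AA3_TO_1.items()}
_AA1_TO_3["X"] = "UNK"


class CGValidationError(ValueError):
    """A structure violates the coarse-grained invariants."""


def _check_coords(coords: np.ndarray, length: int, what: str) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (length, 3, 3):
        raise CGValidationError(
            f"{what}: coords shape {coords.shape} != ({length}, 3, 3)"
        )
    if not np.all(np.isfinite(coords)):
        raise CGValidationError(f"{what}: non-finite coordinates")
    return coords


@dataclass
class CGRNAStructure:
    """An RNA chain in the 3-bead CG representation.

    ``sequence`` is a string over {A, C, G, U}; ``coords`` has shape
    ``(Lr, 3, 3)`` with bead order (P, C4', N1/N9) in Angstrom.
    """

    sequence: str
    coords: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        bad = [c for c in self.sequence if c not in RNA_ALPHABET]
        if bad:
            raise CGValidationError(f"illegal RNA tokens {bad!r} in {self.id!r}")
        if len(self.sequence) == 0:
            raise CGValidationError("empty RNA sequence")
        self.coords = _check_coords(self.coords, len(self.sequence), "RNA")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CGProteinStructure:
    """A protein chain in the 3-bead CG representation.

    ``sequence`` uses the 20-letter amino-acid alphabet plus X; ``coords``
    has shape ``(Lp, 3, 3)`` with bead order (N, CA, C) in Angstrom.
    """

    sequence: str
    coords: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        bad = [c for c in self.sequence if c not in PROTEIN_ALPHABET]
        if bad:
            raise CGValidationError(f"illegal protein tokens {bad!r} in {self.id!r}")
        if len(self.sequence) == 0:
            raise CGValidationError("empty protein sequence")
        self.coords = _check_coords(self.coords, len(self.sequence), "protein")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinRNAComplex:
    """A protein chain paired with the RNA chain it binds."""

    protein: CGProteinStructure
    rna: CGRNAStructure
    id: str = ""

    def __post_init__(self) -> None:
        if len(self.protein) == 0 or len(self.rna) == 0:
            raise CGValidationError("complex members must be non-empty")
        if not self.id:
            self.id = self.rna.id or self.protein.id


def validate_complex(cplx: ProteinRNAComplex) -> None:
    """Re-run the shared CG invariants on an existing complex object."""
    CGRNAStructure(cplx.rna.sequence, cplx.rna.coords, cplx.rna.id)
    CGProteinStructure(cplx.protein.sequence, cplx.protein.coords, cplx.protein.id)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _first_atom(residue: gemmi.Residue, name: str) -> gemmi.Atom | None:
    for atom in residue:
        if atom.name == name:
            return atom
    return None


def _extract_rna_chain(chain: gemmi.Chain, source: str):
    seq, coords = [], []
    for residue in chain:
        name = residue.name.strip()
        if name not in GLYCOSIDIC_ATOM:
            logger.warning("%s: dropping RNA residue %s %s (unknown name)",
                           source, name, residue.seqid)
            continue
        wanted = ("P", "C4'", GLYCOSIDIC_ATOM[name])
        atoms = [_first_atom(residue, n) for n in wanted]
        if any(a is None for a in atoms):
            missing = [n for n, a in zip(wanted, atoms) if a is None]
            logger.warning("%s: dropping RNA residue %s %s (missing %s)",
                           source, name, residue.seqid, ",".join(missing))
            continue
        seq.append(name)
        coords.append([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
    return "".join(seq), np.array(coords, dtype=float)


def _extract_protein_chain(chain: gemmi.Chain, source: str):
    seq, coords = [], []
    for residue in chain:
        name = residue.name.strip()
        token = _AA3_TO_1.get(name, "X" if name == "UNK" else None)
        if token is None:
            logger.warning("%s: dropping protein residue %s %s (unknown name)",
                           source, name, residue.seqid)
            continue
        atoms = [_first_atom(residue, n) for n in PROTEIN_BEAD_NAMES]
        if any(a is None for a in atoms):
            missing = [n for n, a in zip(PROTEIN_BEAD_NAMES, atoms) if a is None]
            logger.warning("%s: dropping protein residue %s %s (missing %s)",
                           source, name, residue.seqid, ",".join(missing))
            continue
        seq.append(token)
        coords.append([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
    return "".join(seq), np.array(coords, dtype=float)


def read_cg_complex(pdb_path, protein_chain: str, rna_chain: str) -> ProteinRNAComplex:
    """Read one protein chain and one RNA chain from a PDB file as a CG complex.

    Residues missing any required bead are dropped with a warning.  Raises
    ``KeyError`` if a named chain is absent and ``CGValidationError`` if no
    residues survive extraction.
    """
    structure = gemmi.read_structure(str(pdb_path))
    structure.setup_entities()
    model = structure[0]
    names = [ch.name for ch in model]
    if protein_chain not in names:
        raise KeyError(f"protein chain {protein_chain!r} not in {pdb_path} "
                       f"(has {names})")
    if rna_chain not in names:
        raise KeyError(f"RNA chain {rna_chain!r} not in {pdb_path} (has {names})")

    pseq, pcoords = _extract_protein_chain(model[protein_chain], str(pdb_path))
    rseq, rcoords = _extract_rna_chain(model[rna_chain], str(pdb_path))
    if len(pseq) == 0:
        raise CGValidationError(f"no protein residues survived in {pdb_path}")
    if len(rseq) == 0:
        raise CGValidationError(f"no RNA residues survived in {pdb_path}")

    ident = structure.name or str(pdb_path)
    return ProteinRNAComplex(
        protein=CGProteinStructure(pseq, pcoords, id=f"{ident}_{protein_chain}"),
        rna=CGRNAStructure(rseq, rcoords, id=f"{ident}_{rna_chain}"),
        id=ident,
    )


def write_cg_complex(cplx: ProteinRNAComplex, pdb_path,
                     protein_chain: str = "A", rna_chain: str = "B") -> None:
    """Write a CG complex as standard ATOM records, one line per bead.

    The protein and RNA occupy distinct chains so that :func:`read_cg_complex`
    inverts this writer (round trip exact to the 3-decimal PDB coordinate
    format, i.e. +-0.001 A).
    """
    validate_complex(cplx)
    structure = gemmi.Structure()
    structure.name = cplx.id or "CG"
    model = gemmi.Model("1")

    def add_chain(name, sequence, coords, bead_names, resname_of):
        chain = gemmi.Chain(name)
        for i, token in enumerate(sequence):
            residue = gemmi.Residue()
            residue.name = resname_of(token)
            residue.het_flag = "A"
            residue.seqid = gemmi.SeqId(i + 1, " ")
            for bead, atom_name in enumerate(bead_names):
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(atom_name[0])
                atom.pos = gemmi.Position(*coords[i, bead])
                residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)

    add_chain(protein_chain, cplx.protein.sequence, cplx.protein.coords,
              PROTEIN_BEAD_NAMES, lambda t: _AA1_TO_3[t])

    # RNA bead names depend on the token (N9 for purines, N1 for pyrimidines),
    # so the generic helper cannot name them; build that chain explicitly.
    chain = gemmi.Chain(rna_chain)
    for i, token in enumerate(cplx.rna.sequence):
        residue = gemmi.Residue()
        residue.name = token
        residue.het_flag = "A"
        residue.seqid = gemmi.SeqId(i + 1, " ")
        for atom_name, xyz in zip(("P", "C4'", GLYCOSIDIC_ATOM[token]),
                                  cplx.rna.coords[i]):
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element(atom_name[0])
            atom.pos = gemmi.Position(*xyz)
            residue.add_atom(atom)
        chain.add_residue(residue)
    model.add_chain(chain)

    structure.add_model(model)
    structure.write_pdb(str(pdb_path))


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    id: str
    sequence: str


def read_fasta(path, molecule: str = "rna") -> list[SequenceRecord]:
    """Read FASTA records, validating the alphabet for ``molecule``
    ("rna" or "protein").  Raises ``ValueError`` naming the first illegal
    character's 1-based position."""
    alphabet = RNA_ALPHABET if molecule == "rna" else PROTEIN_ALPHABET
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in alphabet:
                raise ValueError(
                    f"record {rec.id!r}: illegal {molecule} character {ch!r} "
                    f"at position {pos}"
                )
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(path, records) -> None:
    """Write SequenceRecord (or any ``.id``/``.sequence`` objects) as FASTA."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")
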