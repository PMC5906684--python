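"""Core domain types and readers/writers for the standard formats the pipeline touches.

Sequences and alignments are read through Biopython, PDB coordinate files through
gemmi, and similarity matrices through pandas; the thin wrappers here enforce the
invariants the downstream analysis stages rely on (unique identifiers, rectangular
alignments, finite coordinates, square similarity tables) and normalise details
such as gap characters and altloc handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

__all__ = [
    "FormatError",
    "SequenceRecord",
    "Alignment",
    "Residue",
    "StructureModel",
    "SimilarityTable",
    "CladeNode",
    "CladeTree",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_structure",
    "write_pdb",
    "read_similarity_table",
    "write_similarity_table",
    "write_newick",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residue alphabet: the 20 standard letters plus X for unknown
SEQ_ALPHABET = frozenset(AMINO_ACIDS + "X")
GAP = "-"


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with its identifier and free-text description."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} has no residues")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A family multiple sequence alignment; rows may contain '-' gaps.

    Column indices are 1-based throughout the package, matching how alignment
    positions are cited in figures.
    """

    records: list[SequenceRecord]
    family_label: str = ""

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise FormatError("alignment needs at least 2 rows")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            bad = [r.id for r in self.records if len(r.residues) != len(self.records[0].residues)]
            raise FormatError(f"ragged alignment rows: {', '.join(bad)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate row ids in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    @property
    def n_rows(self) -> int:
        return len(self.records)

    def column(self, index: int) -> str:
        """Residues of 1-based column ``index``, top to bottom."""
        if not 1 <= index <= self.n_columns:
            raise IndexError(f"column {index} outside 1..{self.n_columns}")
        return "".join(r.residues[index - 1] for r in self.records)


@dataclass(frozen=True)
class Residue:
    """One residue of a Cα-level structure model."""

    number: int
    amino_acid: str
    ca: np.ndarray
    cb: Optional[np.ndarray] = None
    sg: Optional[np.ndarray] = None
    insertion_code: str = ""

    def __post_init__(self) -> None:
        for name in ("ca", "cb", "sg"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise FormatError(f"residue {self.number}: {name} must be a finite 3-vector")
            object.__setattr__(self, name, v)


@dataclass
class StructureModel:
    """Ordered Cα (plus optional Cβ/Sγ) coordinates for one chain."""

    chain_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"chain {self.chain_id!r} has no residues with Cα")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of Cα coordinates in residue order."""
        return np.array([r.ca for r in self.residues], dtype=float)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)


@dataclass
class SimilarityTable:
    """Square clade-by-clade evidence matrix; NaN marks missing entries.

    May be asymmetric on input (search hits are directional); symmetrisation is
    the consumer's decision.
    """

    labels: list[str]
    values: np.ndarray
    measure: str  # "evalue" or "zscore"

    def __post_init__(self) -> None:
        if self.measure not in ("evalue", "zscore"):
            raise FormatError(f"unknown measure {self.measure!r}")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise FormatError(f"similarity table must be {n}x{n}, got {self.values.shape}")
        if len(set(self.labels)) != n:
            raise FormatError("duplicate labels in similarity table")
        off = ~np.eye(n, dtype=bool)
        vals = self.values[off]
        if np.any(vals[~np.isnan(vals)] < 0):
            raise FormatError(f"negative {self.measure} entries are not allowed")


@dataclass
class CladeNode:
    """Node of a rooted consensus tree; leaves carry a label, internal nodes may carry a support count."""

    label: str = ""
    children: list["CladeNode"] = field(default_factory=list)
    support: Optional[int] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_labels())
        return out


@dataclass
class CladeTree:
    """A rooted tree over clade names, with optional support counts on internal nodes."""

    root: CladeNode

    def __post_init__(self) -> None:
        leaves = self.root.leaf_labels()
        if len(set(leaves)) != len(leaves):
            raise FormatError("leaf labels must be unique")

    @property
    def leaf_labels(self) -> list[str]:
        return self.root.leaf_labels()


# ---------------------------------------------------------------------------
# sequences and alignments


def _check_residues(text: str, record_id: str, allow_gap: bool) -> str:
    text = text.upper().replace(".", GAP)
    allowed = SEQ_ALPHABET | ({GAP} if allow_gap else set())
    bad = sorted(set(text) - allowed)
    if bad:
        raise FormatError(f"record {record_id!r}: illegal residue characters {bad}")
    return text


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, upper-casing residues.

    Raises :class:`FormatError` on an empty file, duplicate ids or residue
    characters outside the amino-acid alphabet.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = _check_residues(str(rec.seq), rec.id, allow_gap=False)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i:i + 60] + "\n")


_DIALECTS = {"aligned-fasta": "fasta", "stockholm": "stockholm"}


def read_alignment(path: str | Path, dialect: str = "aligned-fasta",
                   family_label: str = "") -> Alignment:
    """Read an aligned FASTA or Stockholm file; '.' gaps are normalised to '-'."""
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown alignment dialect {dialect!r}; use one of {sorted(_DIALECTS)}")
    path = Path(path)
    try:
        msa = AlignIO.read(str(path), _DIALECTS[dialect])
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    records = [
        SequenceRecord(id=rec.id, residues=_check_residues(str(rec.seq), rec.id, allow_gap=True))
        for rec in msa
    ]
    return Alignment(records=records, family_label=family_label or path.stem)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as aligned FASTA (gaps preserved)."""
    write_fasta(aln.records, path)


# ---------------------------------------------------------------------------
# structures

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items() if k != "MSE"}


def read_structure(path: str | Path, chain: str) -> StructureModel:
    """Read one chain of a PDB file into a Cα-level :class:`StructureModel`.

    Model 1 only; HETATM records are skipped; for alternate locations the first
    altloc encountered is kept. Residues without a Cα atom are dropped.
    """
    import gemmi

    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse PDB file: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models in file")
    model = st[0]
    chain_obj = model.find_chain(chain)
    if chain_obj is None:
        available = ", ".join(ch.name for ch in model)
        raise FormatError(f"{path}: chain {chain!r} not found (available: {available})")

    residues: list[Residue] = []
    for res in chain_obj:
        if res.het_flag != "A":  # skip HETATM
            continue
        coords: dict[str, np.ndarray] = {}
        for atom in res:
            if atom.name in ("CA", "CB", "SG") and atom.name not in coords:
                # first altloc wins
                coords[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        if "CA" not in coords:
            continue
        one = _THREE_TO_ONE.get(res.name.upper().strip(), "X")
        residues.append(Residue(
            number=res.seqid.num,
            amino_acid=one,
            ca=coords["CA"],
            cb=coords.get("CB"),
            sg=coords.get("SG"),
            insertion_code=(res.seqid.icode or "").strip(),
        ))
    if not residues:
        raise FormatError(f"{path}: chain {chain!r} has no ATOM residues with Cα")
    return StructureModel(chain_id=chain, residues=residues)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as minimal PDB ATOM records (CA, CB, SG only)."""
    serial = 1
    with open(path, "w") as fh:
        for res in model.residues:
            three = _ONE_TO_THREE.get(res.amino_acid, "UNK")
            for name, coord in (("CA", res.ca), ("CB", res.cb), ("SG", res.sg)):
                if coord is None:
                    continue
                elem = "S" if name == "SG" else "C"
                fh.write(
                    f"ATOM  {serial:5d}  {name:<3s}{three:>4s} {model.chain_id[:1]}"
                    f"{res.number:4d}{res.insertion_code or ' ':1s}   "
                    f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {elem:>2s}\n"
                )
                serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# similarity tables


def read_similarity_table(path: str | Path, measure: str) -> SimilarityTable:
    """Read a labelled square TSV matrix of E-values or Z-scores.

    Blank cells are retained as missing (NaN); negative values are rejected.
    """
    if measure not in ("evalue", "zscore"):
        raise FormatError(f"unknown measure {measure!r}; use 'evalue' or 'zscore'")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(c) for c in df.columns]
    row_labels = [str(r) for r in df.index]
    if labels != row_labels:
        raise FormatError(
            f"{path}: matrix is not square with matching labels "
            f"(rows {row_labels} vs columns {labels})"
        )
    values = df.to_numpy(dtype=float)
    return SimilarityTable(labels=labels, values=values, measure=measure)


def write_similarity_table(table: SimilarityTable, path: str | Path) -> None:
    df = pd.DataFrame(table.values, index=table.labels, columns=table.labels)
    df.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# Newick output

_NEWICK_UNSAFE = set("()[]{}:;,='\" \t\n")


def _quote_label(label: str) -> str:
    if label and not (set(label) & _NEWICK_UNSAFE):
        return label
    return "'" + label.replace("'", "''") + "'"


def _newick_node(node: CladeNode) -> str:
    if node.is_leaf:
        return _quote_label(node.label)
    inner = ",".join(_newick_node(c) for c in node.children)
    tag = "" if node.support is None else str(node.support)
    return f"({inner}){tag}"


def newick_string(tree: CladeTree) -> str:
    """Render a CladeTree as Newick, support counts as internal node labels."""
    return _newick_node(tree.root) + ";"


def write_newick(tree: CladeTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")
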