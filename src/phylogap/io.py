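"""Alignment containers and readers/writers for FASTA, PHYLIP matrices and Newick.

The package works on *aligned* sequences only: every record in an
:class:`Alignment` has the same number of columns, with ``'-'`` marking a gap.
Residues are stored uppercase; ``'.'`` is normalized to ``'-'`` and ``U`` to
``T`` for nucleotides.  Ambiguity codes (``X``, ``B``, ``Z`` ... for protein,
``N``, ``R``, ``Y`` ... for DNA) are retained in storage but are treated as
uninformative by the pair-statistics layer.
"""

from __future__ import annotations

import io as _stdio
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, TextIO, Union

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alphabet",
    "AlignedSeqRecord",
    "Alignment",
    "AlignmentError",
    "NewickParseError",
    "read_fasta",
    "write_fasta",
    "write_phylip_matrix",
    "write_newick",
    "parse_newick",
    "detect_alphabet",
]

GAP = "-"

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
NT_LETTERS = "ACGT"
# Uninformative in pair statistics but legal in storage.
AA_AMBIGUOUS = "BJOUXZ*"
NT_AMBIGUOUS = "NRYSWKMBDHV"


class Alphabet(str, Enum):
    """Residue alphabet of an alignment."""

    NUCLEOTIDE = "nucleotide"
    AMINO_ACID = "amino_acid"

    @property
    def canonical(self) -> str:
        return NT_LETTERS if self is Alphabet.NUCLEOTIDE else AA_LETTERS

    @property
    def ambiguous(self) -> str:
        return NT_AMBIGUOUS if self is Alphabet.NUCLEOTIDE else AA_AMBIGUOUS

    @property
    def size(self) -> int:
        """Number of canonical residues (4 or 20)."""
        return len(self.canonical)


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignment input."""


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


def detect_alphabet(residues: Iterable[str], threshold: float = 0.9) -> Alphabet:
    """Guess the alphabet: > ``threshold`` of characters in ``ACGTU-`` means DNA."""
    text = "".join(residues).upper()
    if not text:
        return Alphabet.AMINO_ACID
    nt_like = sum(1 for c in text if c in "ACGTU-")
    return Alphabet.NUCLEOTIDE if nt_like / len(text) > threshold else Alphabet.AMINO_ACID


def _normalize(raw: str, alphabet: Alphabet, record_id: str) -> str:
    s = raw.upper().replace(".", GAP)
    if alphabet is Alphabet.NUCLEOTIDE:
        s = s.replace("U", "T")
    allowed = set(alphabet.canonical) | set(alphabet.ambiguous) | {GAP}
    bad = set(s) - allowed
    if bad:
        raise AlignmentError(
            f"record {record_id!r}: illegal {alphabet.value} character(s) "
            f"{sorted(bad)!r}"
        )
    return s


@dataclass(frozen=True)
class AlignedSeqRecord:
    """One labeled row of an alignment (residues plus ``'-'`` gaps)."""

    id: str
    residues: str
    alphabet: Alphabet = Alphabet.AMINO_ACID

    def __post_init__(self) -> None:
        if not self.id:
            raise AlignmentError("record id must be non-empty")
        object.__setattr__(
            self, "residues", _normalize(self.residues, self.alphabet, self.id)
        )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def has_ambiguous(self) -> bool:
        return any(c in self.alphabet.ambiguous for c in self.residues)


@dataclass(frozen=True)
class Alignment:
    """An ordered multiple-sequence alignment (>= 2 rows, equal lengths)."""

    records: tuple[AlignedSeqRecord, ...]

    def __post_init__(self) -> None:
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        if len(records) < 2:
            raise AlignmentError("an alignment needs at least 2 records")
        length = len(records[0])
        for rec in records[1:]:
            if len(rec) != length:
                raise AlignmentError(
                    f"unaligned input: record {rec.id!r} has length {len(rec)}, "
                    f"expected {length}"
                )
        seen: set[str] = set()
        for rec in records:
            if rec.id in seen:
                raise AlignmentError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
        if length == 0:
            raise AlignmentError("alignment has zero columns")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AlignedSeqRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> AlignedSeqRecord:
        return self.records[i]

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rec.id for rec in self.records)

    @property
    def alphabet(self) -> Alphabet:
        return self.records[0].alphabet


def _as_handle(source: Union[str, Path, TextIO], mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def read_fasta(source: Union[str, Path, TextIO], alphabet: Alphabet | None = None) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Header lines are truncated at the first whitespace to form record ids.
    ``alphabet`` is auto-detected when not given (> 90 % ``ACGTU-`` characters
    means nucleotide).  Unequal sequence lengths raise :class:`AlignmentError`
    naming the offending record: input must be aligned beforehand (e.g. with
    MAFFT or ClustalW); running an aligner is outside this package's scope.
    """
    handle, close = _as_handle(source)
    try:
        raw = [(r.id, str(r.seq)) for r in SeqIO.parse(handle, "fasta")]
    finally:
        if close:
            handle.close()
    if not raw:
        raise AlignmentError("empty FASTA input")
    if alphabet is None:
        alphabet = detect_alphabet(s for _, s in raw)
    records = tuple(AlignedSeqRecord(i, s, alphabet) for i, s in raw)
    return Alignment(records)


def write_fasta(aln: Alignment, dest: Union[str, Path, TextIO]) -> None:
    """Write an alignment as FASTA, wrapping sequence lines at 60 columns."""
    handle, close = _as_handle(dest, "w")
    try:
        SeqIO.write(
            (SeqRecord(Seq(r.residues), id=r.id, description="") for r in aln),
            handle,
            "fasta",
        )
    finally:
        if close:
            handle.close()


def write_phylip_matrix(matrix, dest: Union[str, Path, TextIO], *, strict: bool = True) -> None:
    """Write a distance matrix as a square PHYLIP file.

    ``strict`` pads/truncates taxon names to the classic 10-character field;
    relaxed mode writes full names followed by two spaces.  Distances are
    printed with 6 decimals.
    """
    handle, close = _as_handle(dest, "w")
    try:
        handle.write(f"{len(matrix.labels)}\n")
        for label, row in zip(matrix.labels, matrix.values):
            name = f"{label[:10]:<10}" if strict else f"{label}  "
            cells = " ".join(f"{v:.6f}" for v in row)
            handle.write(f"{name}{cells}\n")
    finally:
        if close:
            handle.close()


def write_newick(tree: dendropy.Tree, dest: Union[str, Path, TextIO]) -> None:
    """Serialize a tree to Newick with branch lengths at 6 decimals."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
        unquoted_underscores=True,
    )
    handle, close = _as_handle(dest, "w")
    try:
        handle.write(text if text.endswith("\n") else text + "\n")
    finally:
        if close:
            handle.close()


def newick_string(tree: dendropy.Tree) -> str:
    """Newick serialization as a string (branch lengths at 6 decimals)."""
    buf = _stdio.StringIO()
    write_newick(tree, buf)
    return buf.getvalue().strip()


def parse_newick(source: Union[str, Path, TextIO]) -> dendropy.Tree:
    """Parse a Newick tree; malformed input raises :class:`NewickParseError`.

    Accepts a Newick string, a path, or an open text handle.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        text = source if ";" in source or "(" in source else Path(source).read_text()
    else:
        text = source.read()
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"malformed Newick near offset {len(stripped)}: missing terminating ';'"
        )
    try:
        return dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error classes
        offset = None
        m = re.search(r"[Cc]olumn (\d+)", str(exc))
        if m:
            offset = int(m.group(1))
        raise NewickParseError(
            f"malformed Newick{f' at offset {offset}' if offset else ''}: {exc}"
        ) from exc
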