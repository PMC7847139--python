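"""Per-pair sufficient statistics under the three gap treatments.

For one pair of aligned rows the statistics are column-count fractions over
the *comparable* columns ``L``:

* ``s_same``  (S) — both rows show the same residue,
* ``p_diff``  (P) — both rows show residues that differ,
* ``g1``/``g2``   — residue-vs-gap columns (gap in the first / second row),
* ``w_occ``   (w) — residue-occurrence probability of the pair, defined as the
  fraction of residue characters among the ``2 L`` characters compared:
  ``w = S + P + (g1 + g2) / 2``.  It equals 1 when the pair is gap-free.

Columns where *both* rows are gaps, or where either row carries an ambiguity
code, are excluded from ``L`` under every treatment: a shared gap is not an
event on the evolutionary path between the two sequences, and an ambiguous
residue is uninformative.  ``pairwise_deletion`` additionally drops every
column where either row is a gap (so ``w = 1``); ``complete_deletion`` drops
gap-containing columns across the whole alignment *before* pairs are formed.

For nucleotides the mismatch fraction is additionally split into transitions
(A<->G, C<->T) and transversions for the Kimura two-parameter distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .io import GAP, AlignedSeqRecord, Alignment, AlignmentError, Alphabet

__all__ = [
    "GapTreatment",
    "PairStats",
    "NoComparableSitesError",
    "complete_deletion",
    "pair_stats",
    "encode_alignment",
    "encode_sequence",
]

#: Integer code for a gap column.
GAP_CODE = 0
#: Integer code for an ambiguity character (excluded from statistics).
AMBIG_CODE = 255


class GapTreatment(str, Enum):
    """How gap columns enter the distance estimate."""

    PLUS_GAP = "plus_gap"
    PAIRWISE_DELETION = "pairwise_deletion"
    COMPLETE_DELETION = "complete_deletion"


class NoComparableSitesError(AlignmentError):
    """No columns remain after the gap treatment for a pair or alignment."""


def _code_table(alphabet: Alphabet) -> np.ndarray:
    table = np.full(256, AMBIG_CODE, dtype=np.uint8)
    for k, letter in enumerate(alphabet.canonical, start=1):
        table[ord(letter)] = k
    table[ord(GAP)] = GAP_CODE
    return table


_TABLES = {a: _code_table(a) for a in Alphabet}


def encode_sequence(residues: str, alphabet: Alphabet) -> np.ndarray:
    """Encode one row as uint8 codes: 0 = gap, 1..K = residues, 255 = ambiguous."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _TABLES[alphabet][raw]


def encode_alignment(aln: Alignment) -> np.ndarray:
    """Encode an alignment as an (n_rows, n_columns) uint8 code matrix."""
    return np.stack([encode_sequence(r.residues, aln.alphabet) for r in aln])


def decode_codes(codes: np.ndarray, alphabet: Alphabet) -> str:
    """Inverse of :func:`encode_sequence` for canonical codes and gaps."""
    letters = GAP + alphabet.canonical
    return "".join(letters[c] for c in codes)


@dataclass(frozen=True)
class PairStats:
    """Sufficient statistics of one sequence pair under a gap treatment."""

    n_columns: int
    p_diff: float
    s_same: float
    g1: float
    g2: float
    alphabet: Alphabet
    p_transition: float | None = None
    q_transversion: float | None = None

    @property
    def w_occ(self) -> float:
        """Residue-occurrence probability w = S + P + (g1 + g2) / 2."""
        return self.s_same + self.p_diff + (self.g1 + self.g2) / 2.0


def complete_deletion(aln: Alignment) -> Alignment:
    """Remove every column with a gap or ambiguity code in *any* record.

    Raises :class:`NoComparableSitesError` when nothing would remain.
    """
    codes = encode_alignment(aln)
    keep = np.all((codes != GAP_CODE) & (codes != AMBIG_CODE), axis=0)
    if not keep.any():
        raise NoComparableSitesError(
            "no sites remain after complete deletion of gap columns"
        )
    if keep.all():
        return aln
    records = tuple(
        AlignedSeqRecord(
            rec.id,
            "".join(np.array(list(rec.residues))[keep]),
            aln.alphabet,
        )
        for rec in aln
    )
    return Alignment(records)


def _count_stats(
    x: np.ndarray, y: np.ndarray, alphabet: Alphabet, drop_gap_cols: bool
) -> PairStats:
    informative = (x != AMBIG_CODE) & (y != AMBIG_CODE) & ~((x == GAP_CODE) & (y == GAP_CODE))
    if drop_gap_cols:
        informative &= (x != GAP_CODE) & (y != GAP_CODE)
    n = int(informative.sum())
    if n == 0:
        raise NoComparableSitesError("no comparable sites for this pair")
    xi, yi = x[informative], y[informative]
    both_res = (xi != GAP_CODE) & (yi != GAP_CODE)
    same = int(np.count_nonzero(both_res & (xi == yi)))
    diff = int(np.count_nonzero(both_res & (xi != yi)))
    g1 = int(np.count_nonzero(xi == GAP_CODE))
    g2 = int(np.count_nonzero(yi == GAP_CODE))
    p_transition = q_transversion = None
    if alphabet is Alphabet.NUCLEOTIDE:
        # codes A=1 C=2 G=3 T=4: purines are odd, pyrimidines even
        diff_mask = both_res & (xi != yi)
        transitions = int(np.count_nonzero(diff_mask & ((xi % 2) == (yi % 2))))
        p_transition = transitions / n
        q_transversion = (diff - transitions) / n
    return PairStats(
        n_columns=n,
        p_diff=diff / n,
        s_same=same / n,
        g1=g1 / n,
        g2=g2 / n,
        alphabet=alphabet,
        p_transition=p_transition,
        q_transversion=q_transversion,
    )


def pair_stats(
    a: AlignedSeqRecord, b: AlignedSeqRecord, treatment: GapTreatment
) -> PairStats:
    """Column statistics for one aligned pair under ``treatment``.

    ``complete_deletion`` at the pair level behaves like pairwise deletion;
    alignment-wide column removal is done by :func:`complete_deletion`.
    """
    if len(a) != len(b):
        raise AlignmentError(
            f"records {a.id!r} and {b.id!r} have different lengths"
        )
    if a.alphabet is not b.alphabet:
        raise AlignmentError("records have different alphabets")
    x = encode_sequence(a.residues, a.alphabet)
    y = encode_sequence(b.residues, b.alphabet)
    drop = treatment is not GapTreatment.PLUS_GAP
    return _count_stats(x, y, a.alphabet, drop_gap_cols=drop)
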