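"""Genetic-distance estimates and distance-matrix construction.

Implemented measures (combined orthogonally with a gap treatment):

* ``p_distance`` — raw mismatch fraction.  Under the ``plus_gap`` treatment a
  residue-vs-gap column counts as a difference, so ``d = P + g1 + g2``.
* ``jc`` — the Jukes–Cantor correction ``K = -a ln(1 - P/a)`` with
  ``a = 3/4`` for nucleotides and ``a = 19/20`` for amino acids.  Combined
  with ``plus_gap`` on amino acids it becomes the gap-aware extension

      K = -(19/20) * w * ln((S - P/19) / w)

  which treats insertions and deletions as evolutionary events at the same
  footing as substitutions: ``S``, ``P`` are the identical/different residue
  column fractions, ``w`` the residue-occurrence probability of the pair.
  When the pair is gap-free ``w = 1`` and ``S = 1 - P``, and the expression
  reduces exactly to the classical JC formula.
* ``k2p`` — Kimura two-parameter, ``K = -ln((1-2P-Q) sqrt(1-2Q)) / 2`` with
  transition fraction ``P`` and transversion fraction ``Q`` (nucleotides,
  gap-excluding treatments only; a gap-aware K2P is not provided here).

Distances that fall outside the log domain ("saturated" pairs) are reported
as the ``nan`` sentinel with a logged warning rather than raising, so a single
bad pair does not abort a whole matrix; tree building refuses matrices that
contain the sentinel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .io import Alignment, Alphabet
from .pairwise import (
    AMBIG_CODE,
    GAP_CODE,
    GapTreatment,
    NoComparableSitesError,
    PairStats,
    encode_alignment,
)

__all__ = [
    "DistanceMeasure",
    "DistanceMatrix",
    "jc_distance",
    "jc_gap_distance",
    "k2p_distance",
    "p_dist",
    "build_matrix",
]

logger = logging.getLogger(__name__)

#: Sentinel for a saturated / undefined distance.
UNDEFINED = math.nan


class DistanceMeasure(str, Enum):
    P_DISTANCE = "p_distance"
    JC = "jc"
    K2P = "k2p"


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric labeled matrix of genetic differences (``nan`` = undefined)."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("values must be square and match labels")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def has_undefined(self) -> bool:
        return bool(np.isnan(self.values).any())

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        ii, jj = np.nonzero(np.isnan(self.values))
        return [(self.labels[i], self.labels[j]) for i, j in zip(ii, jj) if i < j]

    def __getitem__(self, key: tuple[str, str]) -> float:
        i = self.labels.index(key[0])
        j = self.labels.index(key[1])
        return float(self.values[i, j])


def _saturated(context: str) -> float:
    logger.warning("saturated distance (%s); reporting undefined", context)
    return UNDEFINED


def jc_distance(st: PairStats) -> float:
    """Jukes–Cantor distance ``-a ln(1 - P/a)`` from gap-excluding stats."""
    a = 1.0 - 1.0 / st.alphabet.size
    if st.p_diff >= a:
        return _saturated(f"P={st.p_diff:.4f} >= a={a}")
    return -a * math.log(1.0 - st.p_diff / a) + 0.0  # +0.0 avoids -0.0


def jc_gap_distance(st: PairStats) -> float:
    """Gap-aware JC distance ``-(19/20) w ln((S - P/19)/w)`` (amino acids).

    Requires ``plus_gap`` statistics: both-gap columns excluded, residue-vs-gap
    columns counted in ``g1``/``g2``.  Non-negative on its whole domain because
    ``w - (S - P/19) = P + P/19 + (g1 + g2)/2 >= 0``.
    """
    if st.alphabet is not Alphabet.AMINO_ACID:
        raise ValueError("the gap-aware JC measure is defined for amino acids")
    r = st.alphabet.size - 1  # 19
    arg = st.s_same - st.p_diff / r
    if arg <= 0.0:
        return _saturated(f"S - P/{r} = {arg:.4f} <= 0")
    w = st.w_occ
    return -(r / (r + 1.0)) * w * math.log(arg / w) + 0.0


def k2p_distance(st: PairStats) -> float:
    """Kimura two-parameter distance from transition/transversion fractions."""
    if st.alphabet is not Alphabet.NUCLEOTIDE:
        raise ValueError("K2P is defined for nucleotide sequences")
    p, q = st.p_transition, st.q_transversion
    t1 = 1.0 - 2.0 * p - q
    t2 = 1.0 - 2.0 * q
    if t1 <= 0.0 or t2 <= 0.0:
        return _saturated(f"P={p:.4f}, Q={q:.4f} outside the log domain")
    return -0.5 * math.log(t1 * math.sqrt(t2)) + 0.0


def p_dist(st: PairStats) -> float:
    """Mismatch fraction; residue-vs-gap columns count as differences.

    Under gap-excluding treatments ``g1 = g2 = 0`` and this is plain ``P``.
    """
    return st.p_diff + st.g1 + st.g2


def _pair_counts(codes: np.ndarray, nucleotide: bool):
    """Column-count matrices for all row pairs of an encoded alignment.

    Both-gap and ambiguity columns are excluded everywhere.  Returns integer
    (n, n) arrays: same, diff, g1 (gap in row i), g2 (gap in row j), and
    transitions (None unless ``nucleotide``).
    """
    n = codes.shape[0]
    same = np.zeros((n, n), dtype=np.int64)
    diff = np.zeros_like(same)
    g1 = np.zeros_like(same)
    ts = np.zeros_like(same) if nucleotide else None
    for i in range(n - 1):
        x = codes[i]
        block = codes[i + 1 :]
        x_gap = x == GAP_CODE
        b_gap = block == GAP_CODE
        informative = (x != AMBIG_CODE) & (block != AMBIG_CODE) & ~(x_gap & b_gap)
        both_res = informative & ~x_gap & ~b_gap
        eq = both_res & (block == x)
        same_i = eq.sum(axis=1)
        diff_i = both_res.sum(axis=1) - same_i
        g1_i = (informative & x_gap).sum(axis=1)
        g2_i = (informative & b_gap).sum(axis=1)
        same[i, i + 1 :] = same[i + 1 :, i] = same_i
        diff[i, i + 1 :] = diff[i + 1 :, i] = diff_i
        g1[i, i + 1 :] = g1_i
        g1[i + 1 :, i] = g2_i
        if nucleotide:
            # codes A=1 C=2 G=3 T=4: a transition keeps ring parity
            ts_i = (both_res & (block != x) & ((block % 2) == (x % 2))).sum(axis=1)
            ts[i, i + 1 :] = ts[i + 1 :, i] = ts_i
    return same, diff, g1, g1.T, ts


def _check_comparable(n_cols: np.ndarray, labels) -> None:
    off = ~np.eye(len(labels), dtype=bool)
    if (n_cols[off] == 0).any():
        i, j = np.argwhere((n_cols == 0) & off)[0]
        raise NoComparableSitesError(
            f"no comparable sites for pair ({labels[i]!r}, {labels[j]!r})"
        )


def build_matrix(
    aln: Alignment, measure: DistanceMeasure, treatment: GapTreatment
) -> DistanceMatrix:
    """Distance matrix over all sequence pairs of an alignment.

    ``complete_deletion`` removes gap/ambiguity columns once at alignment
    level; the other treatments work per pair.  Saturated pairs yield ``nan``
    entries (the matrix is then flagged and refused by tree building).
    """
    measure = DistanceMeasure(measure)
    treatment = GapTreatment(treatment)
    nt = aln.alphabet is Alphabet.NUCLEOTIDE
    if measure is DistanceMeasure.K2P and not nt:
        raise ValueError("K2P requires nucleotide sequences")
    if (
        measure is DistanceMeasure.JC
        and treatment is GapTreatment.PLUS_GAP
        and nt
    ):
        raise ValueError(
            "the gap-aware JC measure is defined for amino acids; "
            "use pairwise or complete deletion for nucleotide JC"
        )

    codes = encode_alignment(aln)
    if treatment is GapTreatment.COMPLETE_DELETION:
        keep = np.all((codes != GAP_CODE) & (codes != AMBIG_CODE), axis=0)
        if not keep.any():
            raise NoComparableSitesError(
                "no sites remain after complete deletion of gap columns"
            )
        codes = codes[:, keep]

    same, diff, g1, g2, ts = _pair_counts(codes, nucleotide=nt)
    labels = aln.ids

    with np.errstate(divide="ignore", invalid="ignore"):
        if treatment is GapTreatment.PLUS_GAP:
            n_cols = same + diff + g1 + g2
        else:
            n_cols = same + diff
            g1 = g2 = np.zeros_like(same)
        _check_comparable(n_cols, labels)
        denom = np.where(n_cols > 0, n_cols, 1).astype(float)
        P = diff / denom
        S = same / denom
        G1 = g1 / denom
        G2 = g2 / denom

        if measure is DistanceMeasure.P_DISTANCE:
            d = P + G1 + G2
        elif measure is DistanceMeasure.K2P:
            Pt = ts / denom
            Qt = P - Pt
            t1 = 1.0 - 2.0 * Pt - Qt
            t2 = 1.0 - 2.0 * Qt
            d = np.where(
                (t1 > 0) & (t2 > 0), -0.5 * np.log(t1 * np.sqrt(np.abs(t2))), UNDEFINED
            )
        elif treatment is GapTreatment.PLUS_GAP:  # gap-aware JC, amino acids
            r = aln.alphabet.size - 1
            w = S + P + (G1 + G2) / 2.0
            arg = S - P / r
            d = np.where(
                arg > 0, -(r / (r + 1.0)) * w * np.log(arg / w), UNDEFINED
            )
        else:  # classical JC
            a = 1.0 - 1.0 / aln.alphabet.size
            d = np.where(P < a, -a * np.log(1.0 - P / a), UNDEFINED)

    d = np.asarray(d, dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.where(np.isnan(d), UNDEFINED, np.maximum(d, 0.0))
    m = DistanceMatrix(labels, d)
    for a_, b_ in m.undefined_pairs:
        logger.warning(
            "saturated %s distance for pair (%s, %s)", measure.value, a_, b_
        )
    return m
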