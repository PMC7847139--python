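"""Topology-recovery benchmark: which gap treatment reconstructs best?

For each simulation condition (taxa count x ancestral length x indel rate)
a number of replicates are generated with :mod:`phylogap.simulate`; from the
*same* true leaf alignment three distance matrices are estimated — classical
JC after complete deletion of gap columns, classical JC with pairwise
deletion, and the gap-aware JC extension using all columns — each matrix is
handed to neighbor joining, and a replicate is scored correct for a measure
when the unrooted Robinson–Foulds distance to the model tree is zero.

The default grid is 5 taxa counts x 4 lengths x 3 indel rates = 60
conditions with substitution probability 0.01 per site per branch.  The
default replication is 20 per condition (a desk-scale run; pass
``n_replicates=100`` for the full-size study).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMeasure, build_matrix
from .pairwise import GapTreatment, NoComparableSitesError
from .simulate import SimConfig, simulate_replicate
from .trees import nj, same_topology

__all__ = [
    "MEASURES",
    "ConditionResult",
    "GridResult",
    "run_condition",
    "run_grid",
    "DEFAULT_TAXA",
    "DEFAULT_LENGTHS",
    "DEFAULT_P_INDEL",
    "DEFAULT_P_SUB",
]

logger = logging.getLogger(__name__)

#: Benchmarked estimators: label -> (measure, gap treatment).
MEASURES: dict[str, tuple[DistanceMeasure, GapTreatment]] = {
    "jc_complete": (DistanceMeasure.JC, GapTreatment.COMPLETE_DELETION),
    "jc_pairwise": (DistanceMeasure.JC, GapTreatment.PAIRWISE_DELETION),
    "jc_plus_gap": (DistanceMeasure.JC, GapTreatment.PLUS_GAP),
}

DEFAULT_TAXA = (16, 32, 64, 128, 256)
DEFAULT_LENGTHS = (250, 500, 750, 1000)
DEFAULT_P_INDEL = (0.001, 0.002, 0.005)
DEFAULT_P_SUB = 0.01


@dataclass(frozen=True)
class ConditionResult:
    """Per-condition topology-recovery percentages for each estimator."""

    cfg: SimConfig
    accuracy: dict[str, float]  #: percentage in [0, 100] per MEASURES key
    n_replicates: int


def run_condition(cfg: SimConfig) -> ConditionResult:
    """Run one condition: simulate, reconstruct with all three estimators, score.

    A replicate whose matrix is saturated or has no comparable sites is
    scored incorrect for that estimator (logged), not dropped.
    """
    correct = {name: 0 for name in MEASURES}
    for rep in range(cfg.n_replicates):
        replicate = simulate_replicate(cfg, rep)
        aln = replicate.leaf_alignment
        for name, (measure, treatment) in MEASURES.items():
            try:
                matrix = build_matrix(aln, measure, treatment)
                tree = nj(matrix)
            except (NoComparableSitesError, ValueError) as exc:
                logger.info(
                    "replicate %d scored incorrect for %s: %s", rep, name, exc
                )
                continue
            if same_topology(tree, replicate.model_tree):
                correct[name] += 1
    accuracy = {
        name: 100.0 * k / cfg.n_replicates for name, k in correct.items()
    }
    return ConditionResult(cfg=cfg, accuracy=accuracy, n_replicates=cfg.n_replicates)


@dataclass(frozen=True)
class GridResult:
    """Results table of a condition grid, with the summary views used in
    gap-treatment comparisons."""

    table: pd.DataFrame  #: columns n_taxa, length, p_indel, measure, accuracy

    def _condition_means(self, subset: pd.DataFrame) -> pd.Series:
        return subset.groupby("measure", sort=False)["accuracy"].mean()

    def grand_average(self) -> pd.Series:
        """Unweighted mean accuracy over all conditions, per estimator (%)."""
        return self._condition_means(self.table)

    def by_p_indel(self) -> pd.DataFrame:
        """Mean accuracy per indel probability, per estimator (%)."""
        return (
            self.table.groupby(["p_indel", "measure"], sort=False)["accuracy"]
            .mean()
            .unstack("measure")
        )

    def excluding_length(self, length: int = 250) -> pd.Series:
        """Grand average over the conditions whose ancestral length differs
        from ``length`` (%)."""
        return self._condition_means(self.table[self.table["length"] != length])

    def grand_se(self) -> pd.Series:
        """Monte-Carlo standard error of each grand average, in points."""
        return mean_accuracy_se(self.table)


def mean_accuracy_se(table: pd.DataFrame) -> pd.Series:
    """Monte-Carlo standard error (in points) of the mean accuracy per
    estimator over the condition rows of ``table``.

    Per-condition binomial variances use the Agresti–Coull shrunken
    proportion so conditions at 0 % or 100 % still contribute spread.
    """
    out = {}
    for name, sub in table.groupby("measure", sort=False):
        n = sub["n_replicates"].to_numpy(dtype=float)
        p = (sub["accuracy"].to_numpy() / 100.0 * n + 1.0) / (n + 2.0)
        var = p * (1.0 - p) / n  # per-condition variance of a proportion
        out[name] = 100.0 * float(np.sqrt(var.sum()) / len(sub))
    return pd.Series(out)


def _condition_seed(master_seed: int, index: int) -> int:
    """Documented per-condition seed: (seed * 100003 + index) mod 2**31."""
    return (master_seed * 100003 + index) % (2**31)


def run_grid(
    taxa_list=DEFAULT_TAXA,
    length_list=DEFAULT_LENGTHS,
    p_indel_list=DEFAULT_P_INDEL,
    p_sub: float = DEFAULT_P_SUB,
    n_replicates: int = 20,
    seed: int = 0,
    progress: bool = False,
) -> GridResult:
    """Cartesian grid of conditions; deterministic given ``seed``.

    Condition order is (taxa, length, p_indel) row-major; each condition gets
    an independently reproducible seed derived from the master seed.
    """
    rows = []
    index = 0
    for n_taxa in taxa_list:
        for length in length_list:
            for p_indel in p_indel_list:
                cfg = SimConfig(
                    n_taxa=int(n_taxa),
                    ancestral_length=int(length),
                    p_sub=float(p_sub),
                    p_indel=float(p_indel),
                    n_replicates=int(n_replicates),
                    seed=_condition_seed(seed, index),
                )
                result = run_condition(cfg)
                if progress:
                    print(
                        f"[{index + 1}] taxa={n_taxa} len={length} "
                        f"p_indel={p_indel}: "
                        + " ".join(
                            f"{k}={v:.1f}%" for k, v in result.accuracy.items()
                        ),
                        flush=True,
                    )
                for name, acc in result.accuracy.items():
                    rows.append(
                        {
                            "n_taxa": int(n_taxa),
                            "length": int(length),
                            "p_indel": float(p_indel),
                            "measure": name,
                            "accuracy": acc,
                            "n_replicates": int(n_replicates),
                        }
                    )
                index += 1
    return GridResult(table=pd.DataFrame(rows))
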