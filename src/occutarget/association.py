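"""Stage-wise expression fold changes and occupancy-stratified comparison.

The association question: do transcription-factor-occupied genes stay more
highly expressed than non-occupied genes across erythroid differentiation
stages, despite the global expression decline?  It is answered per stage
with a one-sided Wilcoxon rank-sum test (occupied greater), computed
exactly by enumerating the rank-sum null distribution for small tie-free
samples and by a tie-corrected, continuity-corrected normal approximation
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import ExpressionMatrix

EXACT_CUTOFF = 20  # exact enumeration when n1 + n2 <= this and no ties


@dataclass(frozen=True)
class FoldChangeProfile:
    """log2 fold changes between consecutive stages, one row per gene."""

    genes: tuple[str, ...]
    stage_pairs: tuple[str, ...]
    values: np.ndarray  # genes x pairs
    epsilon: float

    def summaries(self) -> pd.DataFrame:
        """Median and quartiles per stage pair, for box-plot style display."""
        q1, med, q3 = np.percentile(self.values, [25, 50, 75], axis=0)
        return pd.DataFrame(
            {"q1": q1, "median": med, "q3": q3}, index=list(self.stage_pairs)
        )


@dataclass(frozen=True)
class WilcoxonResult:
    """One-sided rank-sum test result; W is the rank sum of group b."""

    statistic: float
    n1: int
    n2: int
    p_value: float
    method: str  # "exact" | "normal"

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")
        lo = self.n2 * (self.n2 + 1) / 2
        if not (lo <= self.statistic <= lo + self.n1 * self.n2):
            raise ValueError("rank-sum statistic outside combinatorial bounds")


def fold_change_profile(
    expr: ExpressionMatrix, epsilon: float = 0.1
) -> FoldChangeProfile:
    """Per-gene log2((RPKM_next + eps) / (RPKM_prev + eps)) for stage pairs.

    The pseudocount guards against zero RPKM; with epsilon 0 the ratio of a
    zero denominator is undefined and raises.
    """
    if len(expr.stages) < 2:
        raise ValueError("need at least two stages for fold changes")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    v = expr.values + epsilon
    if np.any(v[:, :-1] == 0):
        raise ValueError("zero RPKM with epsilon 0: fold change undefined")
    fc = np.log2(v[:, 1:] / v[:, :-1])
    pairs = tuple(
        f"{a}->{b}" for a, b in zip(expr.stages[:-1], expr.stages[1:])
    )
    return FoldChangeProfile(tuple(expr.genes), pairs, fc, epsilon)


def _exact_rank_sum_p(w_obs: float, n1: int, n2: int) -> float:
    """P(rank sum of the size-n2 group >= w_obs) by full enumeration.

    Tie-free case: the null distribution is the distribution of the sum of
    a uniformly random size-n2 subset of the ranks 1..n1+n2, counted by
    dynamic programming over items (equivalent to enumerating all
    C(n1+n2, n2) assignments).
    """
    n = n1 + n2
    max_sum = n * (n + 1) // 2
    # counts[k][s]: subsets of {1..i} of size k summing to s
    counts = np.zeros((n2 + 1, max_sum + 1), dtype=np.int64)
    counts[0, 0] = 1
    for item in range(1, n + 1):
        for k in range(min(item, n2), 0, -1):
            counts[k, item:] += counts[k - 1, : max_sum + 1 - item]
    total = comb(n, n2)
    w_min = int(np.ceil(w_obs - 1e-9))
    tail = int(counts[n2, w_min:].sum())
    return tail / total


def wilcoxon_rank_sum(
    group_a: list[float] | np.ndarray,
    group_b: list[float] | np.ndarray,
    exact_cutoff: int = EXACT_CUTOFF,
) -> WilcoxonResult:
    """One-sided Wilcoxon rank-sum test of H1: group b stochastically greater.

    Midranks are assigned to ties.  The p-value is exact (full enumeration
    of rank assignments) for tie-free samples with n1 + n2 <= exact_cutoff,
    else a normal approximation with tie-corrected variance and a 0.5
    continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    w = float(ranks[n1:].sum())
    has_ties = np.unique(pooled).size < n

    if not has_ties and n <= exact_cutoff:
        p = _exact_rank_sum_p(w, n1, n2)
        method = "exact"
    else:
        mean = n2 * (n + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0  # all observations identical: no evidence either way
        else:
            z = (w - mean - 0.5) / np.sqrt(var)
            p = float(stats.norm.sf(z))
        method = "normal"
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return WilcoxonResult(w, n1, n2, p, method)


def occupancy_expression_association(
    expr: ExpressionMatrix,
    targets: set[str],
    exact_cutoff: int = EXACT_CUTOFF,
) -> pd.DataFrame:
    """Per-stage comparison of occupied versus non-occupied gene expression.

    Returns one row per stage: stratum sizes and medians, the rank-sum
    statistic of the occupied stratum, and the one-sided p-value for
    occupied genes being the more highly expressed stratum.  No
    multiple-testing correction is applied across stages; p-values are
    reported per stage as-is.
    """
    unknown = targets - set(expr.genes)
    if unknown:
        raise ValueError(f"targets not in expression matrix: {sorted(unknown)[:5]}")
    occ_mask = np.array([g in targets for g in expr.genes])
    rows = []
    for j, stage in enumerate(expr.stages):
        occ = expr.values[occ_mask, j]
        non = expr.values[~occ_mask, j]
        if occ.size == 0 or non.size == 0:
            raise ValueError(f"empty occupancy stratum at stage {stage!r}")
        res = wilcoxon_rank_sum(non, occ, exact_cutoff=exact_cutoff)
        rows.append(
            {
                "stage": stage,
                "n_occupied": int(occ.size),
                "n_nonoccupied": int(non.size),
                "median_occupied": float(np.median(occ)),
                "median_nonoccupied": float(np.median(non)),
                "W": res.statistic,
                "p_one_sided": res.p_value,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows).set_index("stage")
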