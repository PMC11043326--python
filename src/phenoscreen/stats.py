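"""Rank-based comparison statistics for model and assay-group performance.

Modalities are compared with the Friedman rank-sum test using assays as
blocking factors (each assay ranks the modalities by its mean AUC), followed
by the Nemenyi post-hoc test on mean-rank differences.  Performance across
assay characteristics (target class, technology, ...) is compared with the
Kruskal-Wallis test followed by Conover-Iman pairwise tests with Holm
adjustment.

All tests are tie-corrected.  The Friedman statistic used here is the
Conover form ``(k-1) * sum_j (R_j - b(k+1)/2)^2 / (A - C)`` which reduces to
the classical ``12/(bk(k+1)) * sum R_j^2 - 3b(k+1)`` when no ties occur.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BlockedTable",
    "TestResult",
    "friedman_blocked",
    "kruskal_conover",
    "nemenyi_posthoc",
    "significance_stars",
]


@dataclass
class BlockedTable:
    """Complete blocks (e.g. assays) x treatments (e.g. modalities) value matrix."""

    values: np.ndarray  # (b, k)
    block_ids: list
    treatment_ids: list

    @classmethod
    def from_long(cls, frame: pd.DataFrame, block: str, treatment: str,
                  value: str) -> "BlockedTable":
        """Pivot a long table; blocks missing any treatment are dropped with a warning."""
        wide = frame.pivot_table(index=block, columns=treatment, values=value,
                                 aggfunc="mean")
        incomplete = wide.index[wide.isna().any(axis=1)]
        if len(incomplete):
            warnings.warn(
                f"dropping {len(incomplete)} incomplete blocks: {list(incomplete[:5])}...",
                stacklevel=2,
            )
            wide = wide.drop(index=incomplete)
        return cls(values=wide.to_numpy(float), block_ids=list(wide.index),
                   treatment_ids=list(wide.columns))


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    pairwise_p: pd.DataFrame | None = None  # symmetric, unit diagonal


def _check_blocked(table: BlockedTable) -> np.ndarray:
    values = np.asarray(table.values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need >= 2 blocks and >= 2 treatments")
    if np.isnan(values).any():
        bad = [table.block_ids[i] for i in np.unique(np.argwhere(np.isnan(values))[:, 0])]
        raise ValueError(f"incomplete blocks (missing treatments): {bad}")
    return values


def _within_block_ranks(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, values)


#: enumerate the exact permutation null when it has at most this many outcomes
_EXACT_NULL_LIMIT = 200_000


def _friedman_stat(col_sums: np.ndarray, b: int, k: int, A: float, C: float):
    return (k - 1) * ((col_sums - b * (k + 1) / 2.0) ** 2).sum(axis=-1) / (A - C)


def _exact_friedman_p(ranks: np.ndarray, stat: float, A: float, C: float) -> float:
    """Exact p over all (k!)^b equally likely within-block rank permutations."""
    from itertools import permutations, product

    b, k = ranks.shape
    perms = [np.array(p) for p in permutations(range(k))]
    block_variants = [np.stack([row[p] for p in perms]) for row in ranks]
    count = total = 0
    for combo in product(range(len(perms)), repeat=b):
        col_sums = np.zeros(k)
        for i, pi in enumerate(combo):
            col_sums += block_variants[i][pi]
        count += _friedman_stat(col_sums, b, k, A, C) >= stat - 1e-12
        total += 1
    return count / total


def friedman_blocked(table: BlockedTable) -> TestResult:
    """Friedman chi-square test with within-block midranks and tie correction.

    With few blocks the chi-square reference is a poor approximation of the
    (coarse, discrete) permutation null, so when the null has at most
    ~2 x 10^5 outcomes the p value is computed by exact enumeration of all
    within-block rank permutations; otherwise asymptotically from
    chi-square with k - 1 degrees of freedom.
    """
    values = _check_blocked(table)
    b, k = values.shape
    ranks = _within_block_ranks(values)
    col_sums = ranks.sum(axis=0)
    A = (ranks**2).sum()
    C = b * k * (k + 1) ** 2 / 4.0
    if np.isclose(A, C):  # every block entirely tied
        return TestResult("friedman", 0.0, 1.0)
    stat = float(_friedman_stat(col_sums, b, k, A, C))
    n_outcomes = float(math.factorial(k)) ** b if k <= 20 else np.inf
    if n_outcomes <= _EXACT_NULL_LIMIT:
        p = float(_exact_friedman_p(ranks, stat, A, C))
        method = "friedman-exact"
    else:
        p = float(sps.chi2.sf(stat, k - 1))
        method = "friedman"
    return TestResult(method, stat, p)


def nemenyi_posthoc(table: BlockedTable) -> TestResult:
    """Nemenyi all-pairs test on Friedman mean ranks.

    The standardised mean-rank difference ``|R_i - R_j| / sqrt(k(k+1)/(12b))``
    is referred to the studentized-range distribution (``q = d * sqrt(2)``,
    infinite degrees of freedom).
    """
    values = _check_blocked(table)
    b, k = values.shape
    mean_ranks = _within_block_ranks(values).mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * b))
    diff = np.abs(mean_ranks[:, None] - mean_ranks[None, :]) / se
    pmat = sps.studentized_range.sf(diff * np.sqrt(2.0), k, np.inf)
    np.fill_diagonal(pmat, 1.0)
    pmat = np.clip(pmat, 0.0, 1.0)
    frame = pd.DataFrame(pmat, index=table.treatment_ids, columns=table.treatment_ids)
    fried = friedman_blocked(table)
    return TestResult("nemenyi-friedman", fried.statistic, fried.p_value, pairwise_p=frame)


def kruskal_conover(values, groups, adjust: str = "holm") -> TestResult:
    """Kruskal-Wallis H test plus Conover-Iman pairwise comparisons.

    Groups with fewer than 2 members are dropped with a warning.  Pairwise
    t statistics follow Conover's rank formulation with the Kruskal H in the
    variance term; two-sided p values are adjusted with ``adjust``
    (``holm``, ``bonferroni`` or ``none``).
    """
    frame = pd.DataFrame({"value": np.asarray(values, dtype=float),
                          "group": list(groups)}).dropna()
    sizes = frame.groupby("group").size()
    small = sizes[sizes < 2].index
    if len(small):
        warnings.warn(f"dropping groups with < 2 members: {list(small)}", stacklevel=2)
        frame = frame[~frame["group"].isin(small)]
    names = sorted(frame["group"].unique())
    if len(names) < 2:
        raise ValueError("need at least two groups of size >= 2")
    samples = [frame.loc[frame["group"] == g, "value"].to_numpy() for g in names]

    all_equal = np.ptp(frame["value"].to_numpy()) == 0
    if all_equal:
        H, p = 0.0, 1.0
    else:
        H, p = sps.kruskal(*samples)

    # Conover-Iman pairwise t statistics on pooled ranks
    ranks = sps.rankdata(frame["value"].to_numpy())
    N = len(ranks)
    kgroups = len(names)
    group_arr = frame["group"].to_numpy()
    mean_ranks = np.array([ranks[group_arr == g].mean() for g in names])
    ns = np.array([(group_arr == g).sum() for g in names])
    S2 = (np.sum(ranks**2) - N * (N + 1) ** 2 / 4.0) / (N - 1)
    denom_scale = S2 * (N - 1 - H) / (N - kgroups) if N > kgroups else np.nan
    pmat = np.ones((kgroups, kgroups))
    raw = []
    pairs = []
    for i in range(kgroups):
        for j in range(i + 1, kgroups):
            if denom_scale <= 0 or not np.isfinite(denom_scale):
                praw = 1.0
            else:
                t = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(
                    denom_scale * (1.0 / ns[i] + 1.0 / ns[j]))
                praw = 2.0 * sps.t.sf(abs(t), N - kgroups)
            raw.append(min(praw, 1.0))
            pairs.append((i, j))
    if adjust == "none":
        adj = raw
    else:
        adj = multipletests(raw, method=adjust)[1]
    for (i, j), pv in zip(pairs, adj):
        pmat[i, j] = pmat[j, i] = pv
    frame_p = pd.DataFrame(pmat, index=names, columns=names)
    return TestResult("kruskal-conover", float(H), float(p), pairwise_p=frame_p)


def significance_stars(p: float) -> str:
    """Star bands used in report rendering."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return "ns"
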