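"""Nonparametric cohort statistics for territory- and pixel-level MBF.

MBF distributions are right-skewed, so groups are summarized as median
[IQR] and compared with the two-sided Mann-Whitney U test at alpha = 0.05,
without multiplicity correction (three uncorrected pairwise contrasts).

The exact two-sided p-value is computed from the tie-aware permutation null
of U — a dynamic program over the multiset of pooled values that counts,
for every possible allocation of observations to group A, the number of
allocations attaining each value of 2U (doubled to keep mid-rank ties on
integers).  The normal approximation (used for larger samples) is the
tie-corrected, continuity-corrected test as implemented in scipy, which is
also the analysis tool the emulated study used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "median_iqr",
    "mann_whitney_u",
    "compare_groups",
]

GROUP_LABELS = ("normal", "small_aneurysm", "affected")


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_iqr_a: tuple[float, float, float]
    median_iqr_b: tuple[float, float, float]
    U: float
    p_value: float
    method: str  # "exact" | "normal_approximation"
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "median_iqr_a": list(self.median_iqr_a),
            "median_iqr_b": list(self.median_iqr_b),
            "U": self.U,
            "p_value": self.p_value,
            "method": self.method,
            "alpha": self.alpha,
            "significant": self.significant,
        }


def median_iqr(values: Iterable[float]) -> tuple[float, float, float]:
    """(median, q1, q3) by linear interpolation of order statistics."""
    v = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if v.size == 0:
        raise ValueError("median_iqr requires at least one value")
    med, q1, q3 = np.percentile(v, [50, 25, 75], method="linear")
    return float(med), float(q1), float(q3)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a from joint mid-ranks."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # mid-ranks
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def _exact_u_distribution(pooled: np.ndarray, n_a: int) -> np.ndarray:
    """Permutation null of 2U over all allocations of ``n_a`` of the pooled
    values to group A, tie-aware.

    Returns an array ``counts`` with ``counts[u2]`` = number of allocations
    whose doubled U statistic equals ``u2``; ``sum(counts) = C(N, n_a)``.
    """
    n = pooled.size
    n_b = n - n_a
    max_u2 = 2 * n_a * n_b
    # dp[k][u2] = number of ways to assign k of the values seen so far to A
    # with doubled-U contribution u2
    dp = np.zeros((n_a + 1, max_u2 + 1), dtype=float)
    dp[0, 0] = 1.0
    seen = 0
    values = np.sort(pooled)
    for _, grp in groupby(values):
        g = len(list(grp))
        new = np.zeros_like(dp)
        for k in range(0, g + 1):
            # choose k of this tie group for A: each contributes one pair
            # (A-value, earlier B-value) with weight 1 and k*(g-k) within-tie
            # half-pairs
            comb = _comb(g, k)
            for ka in range(0, min(n_a, seen) + 1):
                if not dp[ka].any():
                    continue
                ka_new = ka + k
                if ka_new > n_a:
                    continue
                b_below = seen - ka
                # prune allocations that would overfill group B
                if b_below + (g - k) > n_b:
                    continue
                shift = 2 * k * b_below + k * (g - k)
                src = dp[ka]
                nz = np.nonzero(src)[0]
                new[ka_new, nz + shift] += comb * src[nz]
        dp = new
        seen += g
    return dp[n_a]


def _comb(n: int, k: int) -> float:
    from math import comb

    return float(comb(n, k))


def _exact_p(a: np.ndarray, b: np.ndarray, u: float) -> float:
    counts = _exact_u_distribution(np.concatenate([a, b]), a.size)
    total = counts.sum()
    u2 = int(round(2 * u))
    p_low = counts[: u2 + 1].sum() / total
    p_high = counts[u2:].sum() / total
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    mode: str = "auto",
    group_a: str = "a",
    group_b: str = "b",
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two samples.

    ``mode``: ``"exact"`` enumerates the tie-aware permutation null of U
    (two-sided p by doubling the smaller tail, capped at 1);
    ``"normal_approximation"`` uses the tie-corrected normal approximation
    with continuity correction; ``"auto"`` picks exact when
    ``min(n_a, n_b) <= 8`` and the enumeration is small enough to be cheap.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("exact", "normal_approximation", "auto"):
        raise ValueError(f"unknown mode {mode!r}")

    u = _u_statistic(a, b)
    if mode == "auto":
        mode = (
            "exact"
            if min(a.size, b.size) <= 8 and a.size * b.size <= 400
            else "normal_approximation"
        )
    if mode == "exact":
        p = _exact_p(a, b, u)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=int(a.size),
        n_b=int(b.size),
        median_iqr_a=median_iqr(a),
        median_iqr_b=median_iqr(b),
        U=u,
        p_value=p,
        method="exact" if mode == "exact" else "normal_approximation",
        alpha=alpha,
    )


def compare_groups(
    cohort: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = (
        ("affected", "normal"),
        ("affected", "small_aneurysm"),
        ("small_aneurysm", "normal"),
    ),
    alpha: float = 0.05,
    mode: str = "auto",
    value_col: str = "mbf",
    group_col: str = "group",
) -> list[GroupComparison]:
    """Pairwise group comparisons on a cohort table (one row per observation).

    Each requested pair yields medians/IQRs and a Mann-Whitney test; no
    multiple-comparison correction is applied.
    """
    out = []
    for ga, gb in pairs:
        va = cohort.loc[cohort[group_col] == ga, value_col].to_numpy()
        vb = cohort.loc[cohort[group_col] == gb, value_col].to_numpy()
        for name, v in ((ga, va), (gb, vb)):
            if v.size < 2:
                raise ValueError(f"group {name!r} missing or has fewer than 2 rows")
        out.append(
            mann_whitney_u(va, vb, mode=mode, group_a=ga, group_b=gb, alpha=alpha)
        )
    return out
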