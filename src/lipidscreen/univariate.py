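"""Rank-based two-group differential screening (Mann-Whitney U).

The U statistic counts pairs with x above y (ties count one half).  The
two-sided p-value is exact — by full enumeration of the U null
distribution — for small tie-free designs (max group size <= 8), and a
normal approximation with tie and continuity corrections otherwise.
Selection mirrors the screening convention of untargeted lipidomics
studies: raw p < alpha, no multiplicity adjustment (a Benjamini-
Hochberg column is reported alongside for reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from .feature_table import FeatureTable

__all__ = ["ComparisonResult", "mann_whitney_u", "differential_lipids"]

EXACT_MAX_N = 8


@dataclass(frozen=True)
class ComparisonResult:
    feature_id: str
    u: float
    p: float
    p_adj_bh: float
    direction: int  # sign of median(x) - median(y)
    median_a: float
    median_b: float
    significant: bool


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


@lru_cache(maxsize=128)
def _exact_u_pmf(n: int, m: int) -> np.ndarray:
    """Null pmf of U over all C(n+m, n) equally likely labelings
    (tie-free case), by direct enumeration of rank assignments."""
    from itertools import combinations

    counts = np.zeros(n * m + 1)
    offset = n * (n - 1) // 2
    for ranks in combinations(range(n + m), n):
        counts[sum(ranks) - offset] += 1
    return counts / counts.sum()


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p).

    U is computed for x against y.  Exact enumeration is used when both
    groups have <= 8 observations and the pooled data is tie-free;
    otherwise the normal approximation with tie and continuity
    corrections.  Fully tied data (zero variance) yields p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = x.size, y.size
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()

    if not has_ties and max(n, m) <= EXACT_MAX_N:
        pmf = _exact_u_pmf(n, m)
        dev = abs(u - n * m / 2.0)
        support = np.arange(n * m + 1)
        p = float(pmf[np.abs(support - n * m / 2.0) >= dev - 1e-12].sum())
        return u, min(p, 1.0)

    mu = n * m / 2.0
    tie_term = float((tie_counts**3 - tie_counts).sum())
    nm = n + m
    var = n * m / 12.0 * ((nm + 1) - tie_term / (nm * (nm - 1)))
    if var <= 0:
        return u, 1.0
    # continuity correction toward the mean
    dev = abs(u - mu)
    z = max(dev - 0.5, 0.0) / np.sqrt(var)
    p = 2.0 * _st.norm.sf(z)
    return u, float(min(p, 1.0))


def differential_lipids(
    table: FeatureTable, group_a: str, group_b: str, alpha: float = 0.05
) -> list[ComparisonResult]:
    """Per-feature Mann-Whitney screen between two sample groups.

    Significance is raw p < alpha; the BH-adjusted p is reported but not
    used for selection.
    """
    cols_a = table.group_columns(group_a)
    cols_b = table.group_columns(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = table.intensities[cols_a].to_numpy(dtype=float)
    b = table.intensities[cols_b].to_numpy(dtype=float)
    results = []
    pvals = np.empty(table.n_features)
    us = np.empty(table.n_features)
    for i in range(table.n_features):
        us[i], pvals[i] = mann_whitney_u(a[i], b[i])
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    med_a = np.median(a, axis=1)
    med_b = np.median(b, axis=1)
    for i, fid in enumerate(table.intensities.index):
        results.append(
            ComparisonResult(
                feature_id=str(fid),
                u=float(us[i]),
                p=float(pvals[i]),
                p_adj_bh=float(p_adj[i]),
                direction=int(np.sign(med_a[i] - med_b[i])),
                median_a=float(med_a[i]),
                median_b=float(med_b[i]),
                significant=bool(pvals[i] < alpha),
            )
        )
    return results


def results_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "U": [r.u for r in results],
            "p": [r.p for r in results],
            "p_adj_BH": [r.p_adj_bh for r in results],
            "direction": [r.direction for r in results],
            "significant": [r.significant for r in results],
        }
    )
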