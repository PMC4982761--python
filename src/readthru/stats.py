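"""Statistical comparisons: two-sample KS, exact Fisher on r x c tables,
Pearson co-occupancy matrices with clustering order, and Welch's t-test.

The KS statistic is the exact supremum of the ECDF difference over the
pooled sample; its p-value comes from the asymptotic Kolmogorov
distribution with effective sample size n1*n2/(n1+n2). Fisher's exact test
enumerates every table sharing the observed margins and sums the
probability of tables no more probable than the observed one
(probability-ordering two-sided definition). These are intended for the
moderate sample sizes of profile and contingency comparisons, not for
large-table approximations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy import stats as sps
from scipy.cluster.hierarchy import average as _average_linkage
from scipy.cluster.hierarchy import leaves_list
from scipy.spatial.distance import squareform


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test with asymptotic p-value.

    D = sup |F1 - F2| evaluated exactly at the pooled unique sample points
    (ties handled by right-continuous ECDFs); p = Q(sqrt(ne) * D) with
    Q the Kolmogorov survival function and ne = n1*n2/(n1+n2).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.unique(np.concatenate([x, y]))
    fx = np.searchsorted(x, grid, side="right") / x.size
    fy = np.searchsorted(y, grid, side="right") / y.size
    d = float(np.max(np.abs(fx - fy)))
    ne = x.size * y.size / (x.size + y.size)
    p = float(np.clip(special.kolmogorov(np.sqrt(ne) * d), 0.0, 1.0))
    return TestResult(d, p, x.size, y.size, "two-sample KS (asymptotic)")


def _log_table_prob(table: np.ndarray, lgamma=special.gammaln) -> float:
    """Log multivariate hypergeometric probability of a table given its margins."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        lgamma(r + 1).sum()
        + lgamma(c + 1).sum()
        - lgamma(n + 1)
        - lgamma(table + 1).sum()
    )


def fisher_exact(table, max_cells: int = 9, max_total: int = 500) -> TestResult:
    """Exact two-sided Fisher test on a small r x c contingency table.

    Enumerates all tables with the observed margins; the two-sided p-value
    sums the probability of every table whose probability does not exceed
    the observed table's (with a tiny relative slack for floating-point
    ties). Limited to r*c <= 9 cells and total <= 500.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.size == 0:
        raise ValueError("table must be 2-dimensional")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative integers")
    if t.size > max_cells or t.sum() > max_total:
        raise ValueError(
            f"table too large for exact enumeration (cells <= {max_cells}, "
            f"total <= {max_total}); use an approximate method"
        )
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    logp_obs = _log_table_prob(t)
    thresh = logp_obs + np.log1p(1e-12)

    total_p = 0.0
    work = np.zeros_like(t)

    def fill(row: int, remaining_cols: np.ndarray) -> None:
        nonlocal total_p
        if row == t.shape[0] - 1:
            work[row] = remaining_cols
            lp = _log_table_prob(work)
            if lp <= thresh:
                total_p += np.exp(lp)
            return
        for combo in _row_fills(int(rows[row]), remaining_cols):
            work[row] = combo
            fill(row + 1, remaining_cols - combo)

    fill(0, cols.copy())
    return TestResult(
        float(np.exp(logp_obs)),
        float(min(1.0, total_p)),
        int(rows.sum()),
        int(cols.sum()),
        "Fisher exact (probability ordering)",
    )


def _row_fills(row_sum: int, col_caps: np.ndarray):
    """All non-negative integer vectors summing to row_sum with per-cell caps."""
    k = len(col_caps)

    def rec(i: int, left: int, prefix: list[int]):
        if i == k - 1:
            if left <= col_caps[i]:
                yield np.array(prefix + [left], dtype=np.int64)
            return
        # prune: remaining capacity must cover what's left
        tail_cap = int(col_caps[i + 1:].sum())
        lo = max(0, left - tail_cap)
        hi = min(int(col_caps[i]), left)
        for v in range(lo, hi + 1):
            yield from rec(i + 1, left - v, prefix + [v])

    yield from rec(0, row_sum, [])


@dataclass
class CorrelationMatrix:
    labels: list[str]
    matrix: np.ndarray  # pairwise Pearson r
    leaf_order: list[int]  # average-linkage order on distance 1 - r

    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


def pearson_matrix(tracks: dict[str, np.ndarray]) -> CorrelationMatrix:
    """Pairwise Pearson correlation of equal-length signal vectors, with an
    average-linkage clustering leaf order on distance 1 - r."""
    labels = list(tracks)
    if len(labels) < 2:
        raise ValueError("need at least two tracks")
    vecs = []
    n = None
    for lab in labels:
        v = np.asarray(tracks[lab], dtype=float)
        if n is None:
            n = v.size
        if v.size != n or v.size < 3:
            raise ValueError(f"track {lab!r}: vectors must share length >= 3")
        if np.std(v) == 0:
            raise ValueError(f"track {lab!r} has zero variance")
        vecs.append(v)
    r = np.corrcoef(np.vstack(vecs))
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    dist = squareform(np.maximum(1.0 - r, 0.0), checks=False)
    link = _average_linkage(dist)
    order = [int(i) for i in leaves_list(link)]
    return CorrelationMatrix(labels=labels, matrix=r, leaf_order=order)


def t_test_two_tailed(x, y, equal_var: bool = False) -> TestResult:
    """Two-tailed t-test; Welch (unequal variance) by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    stat, p = sps.ttest_ind(x, y, equal_var=equal_var)
    method = "Student t-test (pooled)" if equal_var else "Welch t-test"
    return TestResult(float(stat), float(p), x.size, y.size, method)


def bin_coverage_vector(
    cov, chrom: str, chrom_length: int, bin_bp: int = 200, stranded: bool = False
) -> np.ndarray:
    """Genome-wide binned tag counts (both strands pooled unless stranded)."""
    n = int(np.ceil(chrom_length / bin_bp))
    out = np.zeros(n, dtype=float)
    strands = ("+",) if stranded else ("+", "-")
    for s in strands:
        pos = cov.positions(chrom, s)
        if pos.size:
            idx = pos // bin_bp
            out += np.bincount(idx, minlength=n)[:n]
    return out
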