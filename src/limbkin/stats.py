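"""Nonparametric statistics for cluster comparison.

Spearman rank correlation with a Fisher-z confidence interval, Kruskal-Wallis
with the epsilon-squared effect size (eps^2 = H / (n - 1)), the Steel-Dwass
all-pairs post-hoc test on the studentized-range scale, and Pearson
chi-squared tests for categorical demographics. Significance stars use the
0.05 / 0.01 / 0.001 thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("limbkin")

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in STAR_LEVELS:
        if p < thr:
            return stars
    return ""


@dataclass
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass
class KWResult:
    H: float
    df: int
    epsilon_sq: float
    p: float
    n: int


@dataclass
class PosthocMatrix:
    """Symmetric matrix of Steel-Dwass pairwise p-values (diagonal = 1)."""

    groups: list
    p_values: np.ndarray

    def p(self, i, j) -> float:
        return float(self.p_values[self.groups.index(i), self.groups.index(j)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p_values, index=self.groups, columns=self.groups)


# ---------------------------------------------------------------------------
# Spearman


def spearman_ci(x, y, level: float = 0.95) -> CorrelationResult:
    """Spearman rank correlation with t-approximation p-value and Fisher-z CI.

    rho is computed on average ranks; the two-sided p-value refers
    t = rho * sqrt((n-2) / (1-rho^2)) to a t distribution with n-2 degrees of
    freedom, and the CI back-transforms a normal interval of width
    z_{(1+level)/2} / sqrt(n-3) around atanh(rho).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero variance in ranks; correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return _rho_inference(rho, n, level)


def _rho_inference(rho: float, n: int, level: float = 0.95) -> CorrelationResult:
    """p-value and CI machinery given rho and n (shared with printed-value
    consistency checks)."""
    if abs(rho) >= 1.0:
        p = 0.0
        return CorrelationResult(rho, rho, rho, p, n)
    t = rho * math.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    z = math.atanh(rho)
    zq = sps.norm.ppf(0.5 + level / 2.0)
    half = zq / math.sqrt(n - 3)
    return CorrelationResult(rho, math.tanh(z - half), math.tanh(z + half),
                             float(p), n)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + epsilon squared


def kruskal_wallis(groups) -> KWResult:
    """Tie-corrected Kruskal-Wallis test with epsilon-squared effect size.

    eps^2 = H / (n - 1), which lies in [0, 1]. If every observation is
    identical the statistic is 0 and p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    n = sum(len(g) for g in groups)
    if n < 5:
        raise ValueError("need at least 5 observations in total")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return KWResult(H=0.0, df=df, epsilon_sq=0.0, p=1.0, n=n)
    H, p = sps.kruskal(*groups)
    return KWResult(H=float(H), df=df, epsilon_sq=float(H) / (n - 1),
                    p=float(p), n=n)


def epsilon_squared(H: float, n: int) -> float:
    """Kruskal-Wallis effect size eps^2 = H / (n - 1)."""
    if n < 2:
        raise ValueError("n must be at least 2")
    return H / (n - 1)


# ---------------------------------------------------------------------------
# Steel-Dwass


def _pairwise_rank_z(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected standardized Wilcoxon rank-sum statistic for one pair."""
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    N = nx + ny
    r = sps.rankdata(pooled)
    Rx = r[:nx].sum()
    expect = nx * (N + 1) / 2.0
    var = nx * ny / (N * (N - 1.0)) * ((r ** 2).sum() - N * (N + 1.0) ** 2 / 4.0)
    if var <= 0:
        return 0.0
    return float((Rx - expect) / math.sqrt(var))


def steel_dwass(groups, labels=None) -> PosthocMatrix:
    """Steel-Dwass all-pairs comparison.

    For each pair of groups the pooled pair is ranked with average ranks, the
    tie-corrected standardized rank-sum statistic z is computed, and
    q = |z| * sqrt(2) is referred to the studentized range distribution with
    k groups and infinite degrees of freedom. A fully tied pair gets p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    if labels is None:
        labels = list(range(1, k + 1))
    P = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            z = _pairwise_rank_z(groups[i], groups[j])
            q = abs(z) * math.sqrt(2.0)
            p = float(sps.studentized_range.sf(q, k, np.inf)) if q > 0 else 1.0
            P[i, j] = P[j, i] = min(1.0, p)
    return PosthocMatrix(groups=list(labels), p_values=P)


def steel_dwass_exact(groups, labels=None) -> PosthocMatrix:
    """Exact small-sample Steel-Dwass by exhaustive permutation.

    Enumerates every partition of the pooled sample into the observed group
    sizes and, for each, the maximum over pairs of q = |z| * sqrt(2) (the
    family-wise reference statistic). Each pair's p-value is the fraction of
    partitions whose maximum q reaches that pair's observed q. Exponential in
    the sample size — intended as a reference for small fixtures only.
    """
    from itertools import combinations

    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if labels is None:
        labels = list(range(1, k + 1))
    sizes = [len(g) for g in groups]
    pool = np.concatenate(groups)
    N = len(pool)
    if N > 14:
        raise ValueError(f"exhaustive enumeration infeasible for N = {N}")

    q_obs = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            q_obs[i, j] = abs(_pairwise_rank_z(groups[i], groups[j])) * math.sqrt(2)

    def partitions(idx, sizes):
        if len(sizes) == 1:
            yield (idx,)
            return
        for head in combinations(idx, sizes[0]):
            rest = tuple(x for x in idx if x not in head)
            for tail in partitions(rest, sizes[1:]):
                yield (head,) + tail

    max_qs = []
    for part in partitions(tuple(range(N)), sizes):
        gs = [pool[list(p)] for p in part]
        mq = 0.0
        for i in range(k):
            for j in range(i + 1, k):
                mq = max(mq, abs(_pairwise_rank_z(gs[i], gs[j])) * math.sqrt(2))
        max_qs.append(mq)
    max_qs = np.asarray(max_qs)

    P = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            p = float(np.mean(max_qs >= q_obs[i, j] - 1e-12))
            P[i, j] = P[j, i] = p
    return PosthocMatrix(groups=list(labels), p_values=P)


# ---------------------------------------------------------------------------
# Chi-squared for categorical demographics


def chi_squared_categorical(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence, no continuity correction.

    ``table`` is an r x c contingency array of counts. Returns (statistic,
    df, p). Expected counts below 5 trigger a logged warning; a zero row or
    column margin raises.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    stat, p, df, expected = sps.chi2_contingency(table, correction=False)
    if np.any(expected < 5):
        logger.warning("chi-squared test: %d expected cell count(s) below 5; "
                       "the asymptotic p-value may be inaccurate",
                       int((expected < 5).sum()))
    return float(stat), int(df), float(p)


# ---------------------------------------------------------------------------
# Cluster comparison report


def compare_clusters(
    data: pd.DataFrame,
    labels,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> dict:
    """Per-variable Kruskal-Wallis + Steel-Dwass (continuous/ordinal) and
    chi-squared (categorical) comparison across cluster labels.

    Returns a dict with

    - ``kw``: DataFrame (variable, H, df, epsilon_sq, p, stars)
    - ``posthoc``: {variable: PosthocMatrix}
    - ``pairwise``: long DataFrame (variable, cluster_i, cluster_j, p, stars)
    - ``categorical``: DataFrame (variable, statistic, df, p)

    Clusters with fewer than 2 members are excluded from the post-hoc family
    for that variable with a warning.
    """
    labels = np.asarray(labels)
    if len(labels) != len(data):
        raise ValueError("labels must align with the data rows")
    uniq = sorted(pd.unique(labels))
    if continuous is None:
        continuous = [c for c in data.columns
                      if c not in (categorical or []) and
                      pd.api.types.is_numeric_dtype(data[c])]
    kw_rows, pair_rows, posthoc = [], [], {}
    for var in continuous:
        values = data[var].to_numpy(dtype=float)
        groups = [values[labels == u] for u in uniq]
        res = kruskal_wallis(groups)
        kw_rows.append((var, res.H, res.df, res.epsilon_sq, res.p,
                        significance_stars(res.p)))
        ok = [(u, g) for u, g in zip(uniq, groups) if len(g) >= 2]
        if len(ok) < len(uniq):
            logger.warning("variable %s: cluster(s) with <2 members excluded "
                           "from the post-hoc test", var)
        if len(ok) >= 2:
            mat = steel_dwass([g for _, g in ok], labels=[u for u, _ in ok])
            posthoc[var] = mat
            for a in range(len(ok)):
                for b in range(a + 1, len(ok)):
                    p = mat.p_values[a, b]
                    pair_rows.append((var, ok[a][0], ok[b][0], p,
                                      significance_stars(p)))
    cat_rows = []
    for var in categorical or []:
        table = pd.crosstab(data[var], labels).to_numpy()
        stat, df, p = chi_squared_categorical(table)
        cat_rows.append((var, stat, df, p))
    return {
        "kw": pd.DataFrame(kw_rows, columns=["variable", "H", "df",
                                             "epsilon_sq", "p", "stars"]),
        "posthoc": posthoc,
        "pairwise": pd.DataFrame(pair_rows, columns=["variable", "cluster_i",
                                                     "cluster_j", "p", "stars"]),
        "categorical": pd.DataFrame(cat_rows, columns=["variable", "statistic",
                                                       "df", "p"]),
    }
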