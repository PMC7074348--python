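"""Statistical battery: Kruskal-Wallis, Dunn post-hoc, BH/Bonferroni
adjustment, one-way ANOVA with pairwise t-tests, and OLS regression.

Formulas are implemented explicitly (mid-rank tie handling, tie-corrected
Dunn variance) so the exact conventions are visible and testable; only the
reference distributions (chi-square, normal, t, F) come from scipy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _dist


@dataclass
class GroupedValues:
    """Labeled groups of real values, label order preserved."""

    labels: list[str]
    groups: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.groups):
            raise ValueError("labels and groups differ in length")
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        self.groups = [np.asarray(g, dtype=float) for g in self.groups]
        for lab, g in zip(self.labels, self.groups):
            if g.size == 0:
                raise ValueError(f"group {lab!r} is empty")

    @classmethod
    def from_dict(cls, d: dict[str, Sequence[float]]) -> "GroupedValues":
        return cls(labels=list(d), groups=[np.asarray(v, float) for v in d.values()])

    @property
    def n_total(self) -> int:
        return int(sum(g.size for g in self.groups))


@dataclass
class PairwiseResult:
    label_i: str
    label_j: str
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass
class TestResult:
    method: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    pairwise: list[PairwiseResult] = field(default_factory=list)


def _midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..N with ties sharing their average rank."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(g: GroupedValues) -> TestResult:
    """Kruskal-Wallis H test with mid-ranks and tie correction.

    H = [12 / (N(N+1))] * sum n_i (Rbar_i - (N+1)/2)^2, divided by
    C = 1 - sum(t^3 - t) / (N^3 - N); p from chi-square with k-1 df.
    If all pooled values are identical, H = 0 and p = 1 by convention.
    """
    pooled = np.concatenate(g.groups)
    n = pooled.size
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    k = len(g.groups)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", 0.0, k - 1, 1.0)
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for grp in g.groups:
        r = ranks[start : start + grp.size]
        h += grp.size * (r.mean() - (n + 1) / 2.0) ** 2
        start += grp.size
    h *= 12.0 / (n * (n + 1))
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    h /= correction
    p = float(_dist.chi2.sf(h, k - 1))
    return TestResult("kruskal_wallis", float(h), k - 1, p)


def dunn_posthoc(g: GroupedValues, adjust: str = "bh") -> TestResult:
    """Dunn's pairwise rank comparisons with tie-corrected variance.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)]
    with T = sum(t^3 - t) over pooled ties; two-sided normal p-values,
    adjusted by Benjamini-Hochberg ("bh") or Bonferroni ("bonferroni").
    """
    omnibus = kruskal_wallis(g)
    pooled = np.concatenate(g.groups)
    n = pooled.size
    if np.all(pooled == pooled[0]):
        pairwise = [
            PairwiseResult(li, lj, 0.0, 1.0, 1.0)
            for li, lj in itertools.combinations(g.labels, 2)
        ]
        omnibus.pairwise = pairwise
        omnibus.method = "dunn"
        return omnibus
    ranks = _midranks(pooled)
    mean_ranks = {}
    sizes = {}
    start = 0
    for lab, grp in zip(g.labels, g.groups):
        mean_ranks[lab] = float(ranks[start : start + grp.size].mean())
        sizes[lab] = grp.size
        start += grp.size
    tie = _tie_term(pooled)
    var_base = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    zs, praw, pairs = [], [], []
    for li, lj in itertools.combinations(g.labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[li] + 1.0 / sizes[lj]))
        z = (mean_ranks[li] - mean_ranks[lj]) / se
        p = float(2.0 * _dist.norm.sf(abs(z)))
        zs.append(z)
        praw.append(p)
        pairs.append((li, lj))
    if adjust == "bh":
        padj = bh_adjust(praw)
    elif adjust == "bonferroni":
        padj = [min(1.0, p * len(praw)) for p in praw]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    pairwise = [
        PairwiseResult(li, lj, float(z), p, pa)
        for (li, lj), z, p, pa in zip(pairs, zs, praw, padj)
    ]
    return TestResult("dunn", omnibus.statistic, omnibus.df, omnibus.p_value, pairwise)


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, returned in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        candidate = p[idx] * m / (rank_from_top + 1)
        running_min = min(running_min, candidate)
        adjusted[idx] = min(1.0, running_min)
    return adjusted.tolist()


def anova_oneway(g: GroupedValues) -> TestResult:
    """One-way fixed-effects ANOVA: F with (k-1, N-k) df."""
    pooled = np.concatenate(g.groups)
    n = pooled.size
    k = len(g.groups)
    if n <= k:
        raise ValueError("need more observations than groups")
    grand = pooled.mean()
    ss_between = sum(grp.size * (grp.mean() - grand) ** 2 for grp in g.groups)
    ss_within = sum(float(np.sum((grp - grp.mean()) ** 2)) for grp in g.groups)
    df_b, df_w = k - 1, n - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return TestResult("anova_oneway", 0.0, (df_b, df_w), 1.0)
        raise ValueError("zero within-group variance with nonzero between-group variance")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(_dist.f.sf(f, df_b, df_w))
    return TestResult("anova_oneway", float(f), (df_b, df_w), p)


def pairwise_t_bonferroni(g: GroupedValues) -> TestResult:
    """Pairwise pooled-variance two-sample t-tests, Bonferroni-corrected."""
    for lab, grp in zip(g.labels, g.groups):
        if grp.size < 2:
            raise ValueError(f"group {lab!r} needs n >= 2 for t-tests")
    omnibus = anova_oneway(g)
    pairs = list(itertools.combinations(range(len(g.labels)), 2))
    m = len(pairs)
    pairwise = []
    for i, j in pairs:
        a, b = g.groups[i], g.groups[j]
        na, nb = a.size, b.size
        df = na + nb - 2
        sp2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / df
        if sp2 == 0.0:
            t = 0.0 if a.mean() == b.mean() else np.inf
            p = 1.0 if t == 0.0 else 0.0
        else:
            t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            p = float(2.0 * _dist.t.sf(abs(t), df))
        pairwise.append(
            PairwiseResult(g.labels[i], g.labels[j], float(t), p, min(1.0, p * m))
        )
    return TestResult(
        "pairwise_t_bonferroni", omnibus.statistic, omnibus.df, omnibus.p_value, pairwise
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    r: float
    n: int


def linreg(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares y ~ x with Pearson r and the regression F-test.

    F = r^2 (n-2) / (1 - r^2) on (1, n-2) df.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("var(x) is zero")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if syy == 0.0:
        raise ValueError("var(y) is zero; correlation undefined")
    r = sxy / np.sqrt(sxx * syy)
    df = (1, n - 2)
    r2 = r * r
    if r2 >= 1.0:
        f = np.inf
        p = 0.0
    else:
        f = r2 * (n - 2) / (1.0 - r2)
        p = float(_dist.f.sf(f, *df))
    return RegressionResult(float(slope), intercept, float(f), df, p, float(r), n)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation; raises on zero variance in either input."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx = float(np.sum((x - x.mean()) ** 2))
    sy = float(np.sum((y - y.mean()) ** 2))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(sx * sy))
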