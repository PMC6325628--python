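"""Per-feature nonparametric statistics.

Every data point is one bioreactor chamber.  The layer mirrors the study
design: interquartile-rule outlier removal, Mann-Whitney (2 groups) or
Kruskal-Wallis with Dunn's post hoc (>2 groups), Benjamini-Hochberg
adjustment over a declared family size m (features x comparisons), and a
bootstrap estimate of the rescue size effect on a scale where the mutant
group mean is 0% and the wild-type group mean is 100%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# outlier removal

def remove_outliers_iqr(
    values,
    factor: float = 1.0,
    quartile_method: str = "linear",
) -> tuple[np.ndarray, np.ndarray]:
    """Interquartile outlier rule: drop points strictly above Q3 + factor*IQR
    or strictly below Q1 - factor*IQR; boundary values are kept.

    `quartile_method` is forwarded to ``numpy.percentile`` ("linear" is the
    type-7 interpolation convention; "averaged_inverted_cdf" gives the
    Matlab-like type-5 flavour).  Fewer than 4 values are returned unchanged
    with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        warnings.warn("fewer than 4 values; outlier rule skipped", stacklevel=2)
        return values.copy(), np.array([], dtype=float)
    q1, q3 = np.percentile(values, [25, 75], method=quartile_method)
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    keep = (values >= lo) & (values <= hi)
    return values[keep], values[~keep]


# ---------------------------------------------------------------------------
# multiple testing

def benjamini_hochberg(pvals, m: int | None = None) -> np.ndarray:
    """Step-up BH adjustment with an explicit family size `m`.

    `m` may exceed ``len(pvals)`` when the declared family (features x
    comparisons) is larger than the p-values supplied here; it defaults to
    ``len(pvals)``.  Adjusted p-values are monotone in the raw p-values,
    never smaller than them, and capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    n = p.size
    if m is None:
        m = n
    if m < n:
        raise ValueError(f"family size m={m} smaller than number of p-values ({n})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# group comparisons

@dataclass
class TestResult:
    feature: str
    comparison: str
    test: str
    statistic: float
    p_raw: float
    p_adjusted: float | None
    n_per_group: dict[str, int]


def _dunn_pairs(groups: dict[str, np.ndarray], pairs) -> list[tuple[str, str, float, float]]:
    """Dunn's rank-based z tests (two-sided, tie-corrected) on selected pairs."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, sizes, i0 = {}, {}, 0
    for g in names:
        n_g = groups[g].size
        mean_ranks[g] = ranks[i0 : i0 + n_g].mean()
        sizes[g] = n_g
        i0 += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    out = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        out.append((a, b, float(z), float(p)))
    return out


def compare_groups(
    table: pd.DataFrame,
    feature: str,
    group_col: str,
    post_hoc_pairs: list[tuple[str, str]] | None = None,
    m_adjust: int | None = None,
    remove_outliers: bool = True,
) -> list[TestResult]:
    """Nonparametric comparison of one feature across the levels of `group_col`.

    Two levels: two-sided Mann-Whitney.  More: Kruskal-Wallis, then Dunn's z
    tests on `post_hoc_pairs`.  Outliers are removed per group first (IQR
    rule) unless disabled.  BH adjustment uses family size `m_adjust`
    (declared explicitly by the caller; never inferred) across the returned
    p-values.
    """
    groups: dict[str, np.ndarray] = {}
    for level, sub in table.groupby(group_col, sort=False):
        vals = sub[feature].dropna().to_numpy(dtype=float)
        if remove_outliers and vals.size >= 4:
            vals, _ = remove_outliers_iqr(vals)
        if vals.size == 0:
            raise ValueError(f"group {level!r} empty for feature {feature!r}")
        groups[str(level)] = vals
    names = list(groups)
    n_per = {g: int(v.size) for g, v in groups.items()}
    results: list[TestResult] = []
    if len(names) < 2:
        raise ValueError("need at least two groups")
    if len(names) == 2:
        a, b = names
        stat, p = sps.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        results.append(TestResult(feature, f"{a} vs {b}", "mann-whitney", float(stat), float(p), None, n_per))
    else:
        stat, p = sps.kruskal(*groups.values())
        results.append(TestResult(feature, " vs ".join(names), "kruskal-wallis", float(stat), float(p), None, n_per))
        for a, b, z, pz in _dunn_pairs(groups, post_hoc_pairs or []):
            results.append(TestResult(feature, f"{a} vs {b}", "dunn", z, pz, None, n_per))
    adj = benjamini_hochberg([r.p_raw for r in results], m=m_adjust)
    for r, q in zip(results, adj):
        r.p_adjusted = float(q)
    return results


# ---------------------------------------------------------------------------
# bootstrap rescue size effect

@dataclass
class RescueEstimate:
    feature: str
    rescue_percent: float
    ci_low: float
    ci_high: float
    iterations: int
    k: int
    seed: int
    distribution: np.ndarray = field(repr=False, default=None)


def bootstrap_rescue(
    wt,
    mut,
    treated,
    iterations: int = 100_000,
    k: int = 10,
    seed: int = 0,
    feature: str = "",
    remove_outliers: bool = True,
    ci: float = 95.0,
) -> RescueEstimate:
    """Bootstrap rescue size effect of a treatment (or gene correction).

    Per iteration, `k` values are drawn with replacement from each group and
    the rescue is ``100 * (mean(treated) - mean(mut)) / (mean(wt) -
    mean(mut))`` — 0% means the treated group sits at the mutant mean, 100%
    at the wild-type mean.  Reports the bootstrap mean and the percentile
    confidence interval; deterministic under `seed`.
    """
    arrs = []
    for g in (wt, mut, treated):
        g = np.asarray(g, dtype=float)
        if g.size == 0:
            raise ValueError("all three groups must be non-empty")
        if remove_outliers and g.size >= 4:
            g, _ = remove_outliers_iqr(g)
        arrs.append(g)
    wt_a, mut_a, tr_a = arrs
    if np.mean(wt_a) == np.mean(mut_a):
        raise ValueError("rescue undefined: wild-type and mutant means coincide")
    rng = np.random.default_rng(seed)
    wt_m = wt_a[rng.integers(0, wt_a.size, size=(iterations, k))].mean(axis=1)
    mut_m = mut_a[rng.integers(0, mut_a.size, size=(iterations, k))].mean(axis=1)
    tr_m = tr_a[rng.integers(0, tr_a.size, size=(iterations, k))].mean(axis=1)
    denom = wt_m - mut_m
    bad = denom == 0
    if bad.mean() > 0.01:
        raise RuntimeError(
            f"degenerate bootstrap denominator in {bad.mean():.1%} of iterations "
            "(wild-type and mutant resamples coincide too often)"
        )
    rescue = 100.0 * (tr_m[~bad] - mut_m[~bad]) / denom[~bad]
    half = (100.0 - ci) / 2.0
    lo, hi = np.percentile(rescue, [half, 100.0 - half])
    return RescueEstimate(
        feature, float(rescue.mean()), float(lo), float(hi),
        iterations, k, seed, distribution=rescue,
    )
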