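"""Rank-based comparisons between reconstruction settings.

The comparison layer mirrors common phantom-study practice: paired
Wilcoxon signed-rank tests between two reconstruction settings (paired
by scan, or scan x sphere), Mann-Whitney U and Kruskal-Wallis tests
between contrast levels, percent relative differences, and a
deterministic contrast-recovery-versus-SNR tradeoff classification for
pairs of settings.  No multiple-testing correction is applied; the
conventional p < 0.05 threshold is used throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "TradeoffCell",
    "wilcoxon_paired",
    "mann_whitney_u",
    "kruskal_wallis",
    "relative_difference",
    "classify_tradeoff",
]

SMALL_SPHERES = ("17", "13", "10")


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    pvalue: float
    n: int
    method_a: str = ""
    method_b: str = ""
    metric: str = ""
    pairing: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class TradeoffCell:
    method_a: str
    method_b: str
    crpeak_verdict: str  # higher / equal / lower (A relative to B)
    snr_verdict: str


def wilcoxon_paired(x, y, metric: str = "", method_a: str = "", method_b: str = "",
                    pairing: str = "") -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's original treatment);
    the exact null distribution is used for n <= 25 without ties in
    the absolute differences, the tie-corrected normal approximation
    otherwise.  The reported statistic is the signed rank sum
    W+ - W-, which flips sign when x and y are swapped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return ComparisonResult(test="wilcoxon", statistic=0.0, pvalue=1.0, n=x.size,
                                method_a=method_a, method_b=method_b, metric=metric,
                                pairing=pairing, degenerate=True)
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                       method=method, correction=False)
    return ComparisonResult(test=f"wilcoxon-{method}", statistic=w_plus - w_minus,
                            pvalue=float(res.pvalue), n=n, method_a=method_a,
                            method_b=method_b, metric=metric, pairing=pairing)


def mann_whitney_u(a, b, metric: str = "", method_a: str = "", method_b: str = "") -> ComparisonResult:
    """Two-sided Mann-Whitney U test between two independent groups.

    Exact enumeration when the pooled size is <= 12 and tie-free;
    tie-corrected normal approximation (no continuity correction)
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = pooled.size <= 12 and not has_ties
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic",
                           use_continuity=False)
    return ComparisonResult(test="mann-whitney-" + ("exact" if exact else "asymptotic"),
                            statistic=float(res.statistic), pvalue=float(res.pvalue),
                            n=int(pooled.size), method_a=method_a, method_b=method_b,
                            metric=metric)


def _kruskal_h(ranks_by_group: list[np.ndarray], n_total: int, tie_term: float) -> float:
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        r.sum() ** 2 / r.size for r in ranks_by_group
    ) - 3.0 * (n_total + 1)
    if tie_term > 0:
        h /= 1.0 - tie_term / (n_total**3 - n_total)
    return h


def kruskal_wallis(groups, metric: str = "") -> ComparisonResult:
    """Kruskal-Wallis H test across k independent groups.

    Exact permutation enumeration (all assignments of the pooled
    observations to the group sizes) for pooled n <= 12; the
    chi-squared approximation via scipy otherwise.  Both paths use
    mid-ranks and the tie-corrected H.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if any(g.size < 3 for g in groups):
        raise ValueError("each group needs at least 3 observations")
    sizes = [g.size for g in groups]
    n_total = int(sum(sizes))
    pooled = np.concatenate(groups)
    if n_total > 12:
        res = sps.kruskal(*groups)
        return ComparisonResult(test="kruskal-asymptotic", statistic=float(res.statistic),
                                pvalue=float(res.pvalue), n=n_total, metric=metric)

    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    bounds = np.cumsum([0] + sizes)
    obs_h = _kruskal_h([ranks[bounds[i]:bounds[i + 1]] for i in range(len(sizes))],
                       n_total, tie_term)

    # enumerate all distinct assignments of indices to group sizes
    def partitions(indices: tuple[int, ...], szs: list[int]):
        if len(szs) == 1:
            yield (indices,)
            return
        for combo in itertools.combinations(indices, szs[0]):
            rest = tuple(i for i in indices if i not in set(combo))
            for tail in partitions(rest, szs[1:]):
                yield (combo,) + tail

    count_ge = 0
    total = 0
    for part in partitions(tuple(range(n_total)), sizes):
        h = _kruskal_h([ranks[list(p)] for p in part], n_total, tie_term)
        if h >= obs_h - 1e-12:
            count_ge += 1
        total += 1
    return ComparisonResult(test="kruskal-exact", statistic=float(obs_h),
                            pvalue=count_ge / total, n=n_total, metric=metric)


def relative_difference(a: float, b: float) -> float:
    """Percent difference of ``a`` relative to comparator ``b``:
    100 * (a - b) / b.  Not antisymmetric under swapping by design."""
    if b == 0:
        raise ValueError("comparator value must be non-zero")
    return 100.0 * (a - b) / b


def _mean_by_sphere(metrics: pd.DataFrame, spheres) -> dict[str, float]:
    sub = metrics[metrics["sphere"].astype(str).isin(spheres)]
    missing = set(spheres) - set(sub["sphere"].astype(str))
    if missing:
        raise ValueError(f"metrics table missing spheres: {sorted(missing)}")
    return sub.groupby(sub["sphere"].astype(str))["crpeak"].mean().to_dict()


def classify_tradeoff(
    metrics_a: pd.DataFrame,
    metrics_b: pd.DataFrame,
    small_spheres=SMALL_SPHERES,
    threshold_pct: float = 10.0,
    alpha: float = 0.05,
    method_a: str = "A",
    method_b: str = "B",
) -> TradeoffCell:
    """Classify a pair of settings on the CRpeak/SNR tradeoff.

    CRpeak: "higher" if A's mean CRpeak exceeds B's by more than
    ``threshold_pct`` percent of B for at least one of the small
    spheres, "lower" by the mirrored rule, "equal" otherwise (or when
    both directions trigger).  SNR: verdict from a paired Wilcoxon
    test over (SBR, scan) pairs at level ``alpha`` with the sign of
    the median difference.  Deterministic and permutation-covariant:
    swapping the tables maps higher <-> lower.
    """
    cr_a = _mean_by_sphere(metrics_a, small_spheres)
    cr_b = _mean_by_sphere(metrics_b, small_spheres)
    fac = 1.0 + threshold_pct / 100.0
    any_higher = any(cr_a[s] > fac * cr_b[s] for s in small_spheres)
    any_lower = any(cr_b[s] > fac * cr_a[s] for s in small_spheres)
    if any_higher and not any_lower:
        cr_verdict = "higher"
    elif any_lower and not any_higher:
        cr_verdict = "lower"
    else:
        cr_verdict = "equal"

    key = ["sbr", "scan"]
    snr_a = metrics_a.groupby(key)["snr"].first()
    snr_b = metrics_b.groupby(key)["snr"].first()
    common = snr_a.index.intersection(snr_b.index)
    if len(common) == 0:
        raise ValueError("no common (sbr, scan) cells between the two tables")
    xa = snr_a.loc[common].to_numpy()
    xb = snr_b.loc[common].to_numpy()
    res = wilcoxon_paired(xa, xb, metric="snr", method_a=method_a, method_b=method_b,
                          pairing="sbr x scan")
    if res.degenerate or res.pvalue >= alpha:
        snr_verdict = "equal"
    else:
        snr_verdict = "higher" if float(np.median(xa - xb)) > 0 else "lower"
    return TradeoffCell(method_a=method_a, method_b=method_b,
                        crpeak_verdict=cr_verdict, snr_verdict=snr_verdict)
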