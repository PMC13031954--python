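"""Treatment-effect metrics and nonparametric tests for the device analysis.

The treatment effect of a flow-modulating device is the relative change of a
summary (median intra-aneurysmal velocity, or normalized BB signal) against
the untreated model:

    delta = (value_with - value_without) / value_without

so an effective device gives delta_velocity < 0 (flow drops) and
delta_BB > 0 (suppression fails, signal rises).

Procedures: Spearman rank correlation (exact permutation p for small n),
Kruskal–Wallis with tie correction, Dunn pairwise post hoc z tests with
Benjamini–Hochberg adjustment, the two-sided Wilcoxon signed-rank test
(exact null enumeration for small tie-free samples), and ordinary
least-squares with R².  These thin implementations exist so that small-sample
p-values are exact and reproducible; independent library routines serve as
cross-checks in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TreatmentEffect",
    "CorrelationResult",
    "TestResult",
    "FitResult",
    "treatment_effect",
    "spearman_corr",
    "kruskal_wallis",
    "dunn_bh_posthoc",
    "wilcoxon_signed_rank",
    "linear_fit_r2",
    "effect_table_medians",
]

ALPHA = 0.05  # reporting threshold only; never baked into returned values


@dataclass(frozen=True)
class TreatmentEffect:
    delta: float
    device: str | None = None
    region: str | None = None
    metric: str | None = None


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int = 0
    pairwise: dict = field(default_factory=dict)  # (i, j) -> (z, p_raw, p_adj)


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    r_squared: float


# ---------------------------------------------------------------------------


def treatment_effect(
    value_with: float,
    value_without: float,
    device: str | None = None,
    region: str | None = None,
    metric: str | None = None,
) -> TreatmentEffect:
    """Relative change ``(with - without) / without``; scale-invariant."""
    if value_without == 0:
        raise ValueError("treatment effect undefined for a zero untreated baseline")
    delta = (value_with - value_without) / value_without
    return TreatmentEffect(delta=float(delta), device=device, region=region, metric=metric)


def effect_table_medians(
    table, with_col: str = "with", without_col: str = "without"
):
    """Median treatment effect from a per-device table of (with, without)
    summary values — e.g. per-model median velocities or BB medians.

    ``table`` is a pandas DataFrame (or path to a CSV with a header row)
    holding one row per device.  Returns ``(median_delta, deltas)``.
    """
    import pandas as pd

    if not hasattr(table, "columns"):
        table = pd.read_csv(table)
    deltas = np.array(
        [
            treatment_effect(row[with_col], row[without_col]).delta
            for _, row in table.iterrows()
        ]
    )
    return float(np.median(deltas)), deltas


# ---------------------------------------------------------------------------


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_corr(x, y, exact_max_n: int = 9) -> CorrelationResult:
    """Spearman rho on mid-ranks; two-sided p by exact permutation for
    ``n <= exact_max_n``, t-approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    rx, ry = _midranks(x), _midranks(y)

    def _rho(a, b):
        a = a - a.mean(axis=-1, keepdims=True)
        b = b - b.mean(axis=-1, keepdims=True)
        num = (a * b).sum(axis=-1)
        den = np.sqrt((a * a).sum(axis=-1) * (b * b).sum(axis=-1))
        return num / den

    rho = float(_rho(rx, ry))
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = _rho(np.broadcast_to(rx, (len(perms), n)), ry[perms])
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, p_value=min(p, 1.0), n=n)


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts ** 3 - counts))


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal–Wallis H with chi-square p (k-1 df).

    If every value across all groups is identical the statistic carries no
    information; H = 0 and p = 1 are returned by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    N = len(pooled)
    if np.ptp(pooled) == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="kruskal-wallis", n=N)
    ranks = _midranks(pooled)
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        H += len(g) * (r.mean() - (N + 1) / 2.0) ** 2
        start += len(g)
    H *= 12.0 / (N * (N + 1))
    H /= 1.0 - _tie_term(pooled) / (N ** 3 - N)
    p = float(sps.chi2.sf(H, df=len(groups) - 1))
    return TestResult(statistic=float(H), p_value=max(min(p, 1.0), np.nextafter(0, 1)),
                      method="kruskal-wallis", n=N)


def dunn_bh_posthoc(groups) -> TestResult:
    """Dunn pairwise z tests on pooled ranks with tie-corrected variance and
    Benjamini–Hochberg step-up adjustment across all pairs.

    Requires >= 3 groups; for two groups use :func:`kruskal_wallis` alone.
    The overall Kruskal–Wallis result is returned as the headline statistic,
    with per-pair ``(z, p_raw, p_adj)`` in ``pairwise``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("Dunn post hoc needs >= 3 groups; use kruskal_wallis for two")
    kw = kruskal_wallis(groups)
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = _midranks(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    tie_corr = _tie_term(pooled) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_corr
    pairs = list(itertools.combinations(range(len(groups)), 2))
    zs, ps = [], []
    for i, j in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        zs.append(z)
        ps.append(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    p_adj = multipletests(ps, method="fdr_bh")[1]
    pairwise = {
        pair: (float(z), float(p), float(pa))
        for pair, z, p, pa in zip(pairs, zs, ps, p_adj)
    }
    return TestResult(
        statistic=kw.statistic,
        p_value=kw.p_value,
        method="dunn-bh",
        n=N,
        pairwise=pairwise,
    )


def _signed_rank_exact_p(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact p for the signed-rank statistic by full enumeration of
    sign assignments, via a convolution over the (doubled, integer) ranks."""
    total = int(ranks2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(round(w2))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(deltas) -> TestResult:
    """Two-sided Wilcoxon signed-rank test of median(delta) = 0.

    Zeros are dropped (documented convention); exact enumeration of the
    2^n sign assignments (computed by convolution) for n <= 20 without
    tied magnitudes, normal approximation with tie correction otherwise.
    """
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all deltas are zero")
    if n < 5:
        raise ValueError("need at least 5 nonzero deltas")
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= 20 and not has_ties:
        p = _signed_rank_exact_p(2.0 * ranks, 2.0 * w_plus)
        method = "wilcoxon-exact"
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie = np.sum(counts ** 3 - counts) / 48.0
        sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie)
        z = (w_plus - mu) / sigma
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "wilcoxon-normal"
    return TestResult(statistic=w_plus, p_value=p, method=method, n=n)


def linear_fit_r2(x, y) -> FitResult:
    """Ordinary least squares ``y = slope*x + intercept`` with R².

    A constant response gives R² = 0 by the SS_tot = SS_res convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = float(((y - slope * x - intercept) ** 2).sum())
    ss_tot = float(((y - ym) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return FitResult(slope=float(slope), intercept=float(intercept), r_squared=float(r2))
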