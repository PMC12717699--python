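"""Comparative statistics: rank tests, trends, segmented fits, pre-ranked GSEA.

These are the statistical companions of the scoring pipeline: Wilcoxon
rank-sum comparisons of responder vs non-responder scores, linear trends of
senescence over ordered timepoints (aging cohorts), continuous two-segment
regression of induction time courses (a fast early rise followed by a
plateau), a Shapiro-Wilk gate routing two-group comparisons to a t-test or
rank test, and a directional pre-ranked GSEA where the up- and down-sets of
a signature are tested separately against a per-gene ranking metric (e.g.
Pearson correlation of expression with age).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats as ss

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Rank-sum test and gate
# --------------------------------------------------------------------------

def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      alternative: str = "two-sided") -> tuple[float, float]:
    """Two-sample Wilcoxon/Mann-Whitney test; returns (U, p).

    Exact enumeration when both samples are small (n_x + n_y <= 12) and
    tie-free; otherwise the normal approximation with tie and continuity
    correction.  U is the Mann-Whitney statistic of ``x`` relative to ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = ss.mannwhitneyu(x, y, alternative=alternative, method=method,
                          use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def shapiro_gate(x: Sequence[float], alpha: float = 0.05) -> str:
    """Route a two-group comparison: 'parametric' unless Shapiro-Wilk p < alpha."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    _, p = ss.shapiro(x)
    return "nonparametric" if p < alpha else "parametric"


def compare_groups(x: Sequence[float], y: Sequence[float],
                   alternative: str = "two-sided") -> dict:
    """Shapiro-gated two-group comparison (t-test or Wilcoxon)."""
    route_x, route_y = shapiro_gate(x), shapiro_gate(y)
    if route_x == "parametric" and route_y == "parametric":
        stat, p = ss.ttest_ind(x, y, alternative=alternative)
        test = "t"
    else:
        stat, p = wilcoxon_rank_sum(x, y, alternative)
        test = "wilcoxon"
    return {"test": test, "statistic": float(stat), "p": float(p)}


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_i in range(n - 1, -1, -1):
        i = order[rank_i]
        running = min(running, p[i] * n / (rank_i + 1))
        adj[i] = running
    return adj


# --------------------------------------------------------------------------
# Trends over timepoints
# --------------------------------------------------------------------------

def timepoint_trend(scores: Sequence[float], time: Sequence[float]
                    ) -> tuple[float, float, float]:
    """OLS slope of mean score per timepoint vs time: (slope, p, R^2).

    Scores are first averaged within each distinct timepoint so unequal cell
    counts per timepoint do not dominate the fit; the p-value is the t-test
    on the slope over the timepoint means.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    if len(s) != len(t):
        raise ValueError("scores and time must align")
    uniq = np.unique(t)
    if len(uniq) < 3:
        raise ValueError("need >= 3 distinct timepoints")
    means = np.array([s[t == u].mean() for u in uniq])
    fit = ss.linregress(uniq, means)
    return float(fit.slope), float(fit.pvalue), float(fit.rvalue ** 2)


@dataclass(frozen=True)
class SegmentedFit:
    """Continuous two-segment least-squares fit."""

    breakpoint: float
    slope_left: float
    slope_right: float
    intercept: float
    sse: float
    sse_single_line: float
    identifiable: bool  # False when the break improves SSE by < 1%

    @property
    def improvement(self) -> float:
        if self.sse_single_line == 0:
            return 0.0
        return 1.0 - self.sse / self.sse_single_line


def _fit_at_break(x: np.ndarray, y: np.ndarray, b: float) -> tuple[float, np.ndarray]:
    design = np.column_stack([np.ones_like(x), x, np.maximum(x - b, 0.0)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), coef


def default_breakpoint_grid(x: np.ndarray, n_fill: int = 200) -> np.ndarray:
    """Interior distinct x-values plus a dense fill strictly inside (min, max).

    Including the observed interior x-values makes a break located exactly
    at a sampled timepoint exactly recoverable on noiseless data.
    """
    xs = np.unique(x)
    interior = xs[1:-1]
    fill = np.linspace(xs[0], xs[-1], n_fill + 2)[1:-1]
    grid = np.unique(np.concatenate([interior, fill]))
    return grid[(grid > xs[0]) & (grid < xs[-1])]


def segmented_fit(x: Sequence[float], y: Sequence[float],
                  candidate_breakpoints: Sequence[float] | None = None,
                  min_improvement: float = 0.01) -> SegmentedFit:
    """Exhaustive-SSE continuous piecewise-linear fit with one breakpoint.

    The model is y = a + b1*x + (b2 - b1)*max(x - bp, 0); for each candidate
    breakpoint the remaining parameters are solved by least squares, and the
    candidate with minimal SSE wins.  When the best two-segment SSE improves
    on the single-line SSE by less than ``min_improvement`` the breakpoint is
    flagged unidentifiable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4 or len(np.unique(x)) < 3:
        raise ValueError("need >= 4 points spanning >= 3 distinct x")
    if candidate_breakpoints is None:
        grid = default_breakpoint_grid(x)
    else:
        grid = np.asarray(candidate_breakpoints, dtype=float)
        if ((grid <= x.min()) | (grid >= x.max())).any():
            raise ValueError("candidate breakpoints must lie strictly inside (x_min, x_max)")
    single = np.polyfit(x, y, 1)
    resid = y - np.polyval(single, x)
    sse_line = float(resid @ resid)

    sses = np.array([_fit_at_break(x, y, b)[0] for b in grid])
    # Near-zero SSE can tie across a whole interval (a kink between two
    # sampled x-values is not point-identified); among numerical ties prefer
    # a breakpoint at an observed timepoint, then the smallest candidate.
    tol = 1e-10 * (float(y @ y) + 1.0)
    tie = np.flatnonzero(sses <= sses.min() + tol)
    observed = np.isin(grid[tie], np.unique(x))
    if observed.any():
        tie = tie[observed]
    best_idx = int(tie[0])
    best_b = float(grid[best_idx])
    best_sse, best_coef = _fit_at_break(x, y, best_b)
    a, b1, delta = best_coef
    identifiable = (sse_line > 0) and (best_sse <= (1 - min_improvement) * sse_line)
    if not identifiable:
        logger.info("segmented fit: SSE improvement %.3g%% < %.3g%%; "
                    "breakpoint unidentifiable",
                    100 * (1 - best_sse / sse_line) if sse_line else 0.0,
                    100 * min_improvement)
    return SegmentedFit(
        breakpoint=float(best_b), slope_left=float(b1),
        slope_right=float(b1 + delta), intercept=float(a),
        sse=best_sse, sse_single_line=sse_line, identifiable=identifiable,
    )


# --------------------------------------------------------------------------
# Pre-ranked GSEA
# --------------------------------------------------------------------------

class GseaResult(NamedTuple):
    es: float
    nes: float
    p: float
    n_hits: int


def _running_es(metric_sorted: np.ndarray, is_hit: np.ndarray, weight: float) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    n = len(metric_sorted)
    n_hit = int(is_hit.sum())
    w = np.abs(metric_sorted) ** weight
    hit_w = np.where(is_hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit weights zero (possible at weight>0 with 0 metric)
        hit_w = is_hit.astype(float)
        denom = float(n_hit)
    miss = np.where(is_hit, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(hit_w / denom - miss)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def preranked_gsea(metric: pd.Series, genes: Sequence[str], weight: float = 1.0,
                   n_perm: int = 1000, seed: int = 0) -> GseaResult:
    """Directional pre-ranked GSEA of one gene set against a ranking metric.

    Genes are sorted by decreasing metric; hits advance the running sum by
    their weighted metric share, misses retreat by 1/(N - n_set); ES is the
    signed maximum deviation.  The null is ``n_perm`` size-matched random
    gene sets (seeded): NES = ES / mean |ES*| over same-sign nulls and the
    permutation p is (1 + #{|ES*| >= |ES|, same sign}) / (1 + #same-sign),
    so p is never 0.
    """
    metric = metric.astype(float)
    if len(metric) < 10:
        raise ValueError("ranking metric must cover >= 10 genes")
    gene_set = set(genes)
    hits = metric.index.isin(gene_set)
    if not hits.any():
        raise ValueError("gene set does not intersect the ranking metric")
    if n_perm < 100:
        logger.warning("n_perm=%d is low; permutation p will be coarse", n_perm)
    order = np.argsort(-metric.to_numpy(), kind="stable")
    m_sorted = metric.to_numpy()[order]
    hit_sorted = hits[order]
    es = _running_es(m_sorted, hit_sorted, weight)

    rng = np.random.default_rng(seed)
    n, k = len(metric), int(hits.sum())
    null_es = np.empty(n_perm)
    for i in range(n_perm):
        rand_hit = np.zeros(n, dtype=bool)
        rand_hit[rng.choice(n, size=k, replace=False)] = True
        null_es[i] = _running_es(m_sorted, rand_hit, weight)
    same_sign = null_es * np.sign(es) > 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        nes = np.inf * np.sign(es)
        p = 1.0 / (1.0 + n_perm)
    else:
        nes = es / np.abs(null_es[same_sign]).mean()
        p = (1 + int((np.abs(null_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
    return GseaResult(es=es, nes=float(nes), p=float(p), n_hits=k)


def rank_by_correlation(expression: pd.DataFrame, covariate: Sequence[float]) -> pd.Series:
    """Per-gene Pearson correlation of expression (genes x samples) with a covariate.

    The standard ranking metric for age-trend enrichment: positive values
    mark genes increasing with the covariate.  Constant genes get r = 0.
    """
    cov = np.asarray(covariate, dtype=float)
    if expression.shape[1] != len(cov):
        raise ValueError("covariate length must match sample count")
    x = expression.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    cc = cov - cov.mean()
    denom = np.sqrt((xc ** 2).sum(axis=1) * (cc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc @ cc) / denom, 0.0)
    return pd.Series(r, index=expression.index, name="pearson_r")
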