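"""Statistical kernel: empirical-Bayes moderated t, rank-sum test,
one-tailed Fisher exact test, Fisher's combined-probability method and
Benjamini–Hochberg adjustment.

The moderated t follows the hierarchical model in which each gene's sample
variance s_g^2 is chi-square distributed about a latent variance sigma_g^2
(d residual df), and 1/sigma_g^2 is itself chi-square about a prior
variance s0^2 with prior degrees of freedom d0.  The prior pair (d0, s0^2)
is estimated by the method of moments on log sample variances, using the
digamma/trigamma moments of the log chi-square distribution; the posterior
variance is the precision-weighted blend

    s_tilde^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

and the moderated t-statistic gains d0 extra degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "EmpiricalBayesParams",
    "fit_empirical_bayes",
    "moderated_t",
    "moderated_t_table",
    "rank_sum_test",
    "fisher_exact_one_tailed",
    "combine_fisher",
    "bh_adjust",
    "trigamma_inverse",
]

#: enumerate the exact rank-sum null when the pooled sample is this small
EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class EmpiricalBayesParams:
    """Prior degrees of freedom and prior variance of the variance model."""

    d0: float  # may be math.inf when the variances show no excess dispersion
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior degrees of freedom must be >= 0")
        if not self.s0_sq > 0:
            raise ValueError("prior variance must be > 0")


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0.

    Monotone Newton iteration on the strictly decreasing trigamma function,
    with a bisection fallback if a Newton step leaves the bracket.
    """
    if x <= 0:
        raise ValueError("trigamma is positive; cannot invert non-positive x")
    # trigamma(y) ~ 1/y + 1/(2y^2); invert the leading term for a start
    y = 0.5 + 1.0 / x
    lo, hi = 1e-12, max(1e6, 2 * y)
    for _ in range(max_iter):
        f = float(special.polygamma(1, y)) - x
        fprime = float(special.polygamma(2, y))  # < 0
        step = f / fprime
        y_new = y - step
        if y_new <= lo or y_new >= hi:
            # bisection fallback: trigamma decreasing, so f>0 means y too small
            if f > 0:
                lo = y
            else:
                hi = y
            y_new = 0.5 * (lo + hi)
        if abs(y_new - y) <= tol * (1 + abs(y)):
            return y_new
        y = y_new
    return y


def fit_empirical_bayes(sample_variances: np.ndarray,
                        residual_df: float) -> EmpiricalBayesParams:
    """Moment estimation of (d0, s0^2) from per-gene sample variances.

    Works on z_g = log s_g^2.  Under the model, e_g = z_g - psi(d/2) +
    log(d/2) has mean log s0^2 + psi(d0/2) - log(d0/2) and variance
    psi'(d/2) + psi'(d0/2); the trigamma equation is inverted for d0.
    Genes with non-positive variance are excluded.  If the observed
    dispersion of e_g does not exceed psi'(d/2), d0 is infinite and s0^2 is
    the mean variance (complete shrinkage).
    """
    v = np.asarray(sample_variances, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < 10:
        raise ValueError("need >=10 genes with positive variance")
    if residual_df < 1:
        raise ValueError("residual_df must be >= 1")
    d = float(residual_df)
    z = np.log(v)
    e = z - float(special.digamma(d / 2.0)) + math.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        return EmpiricalBayesParams(d0=math.inf, s0_sq=float(np.mean(v)))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0))
                     - math.log(d0 / 2.0))
    return EmpiricalBayesParams(d0=d0, s0_sq=s0_sq)


def _pooled_stats(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    n_a, n_b = a.size, b.size
    diff = float(np.mean(a) - np.mean(b))
    df = n_a + n_b - 2
    ss = float(np.sum((a - np.mean(a)) ** 2) + np.sum((b - np.mean(b)) ** 2))
    s_sq = ss / df
    return diff, s_sq, df


def moderated_t(group_a: np.ndarray, group_b: np.ndarray,
                params: EmpiricalBayesParams) -> tuple[float, float, float]:
    """Moderated t for one gene: returns (t_mod, p_two_sided, df_total).

    With d0 = 0 this is exactly the classical pooled two-sample t; with
    d0 = inf the variance is replaced by the prior s0^2 entirely.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 observations per group")
    diff, s_sq, df = _pooled_stats(a, b)
    d0 = params.d0
    if math.isinf(d0):
        s_tilde_sq = params.s0_sq
        df_total = math.inf
    else:
        s_tilde_sq = (d0 * params.s0_sq + df * s_sq) / (d0 + df)
        df_total = d0 + df
    se = math.sqrt(s_tilde_sq * (1.0 / a.size + 1.0 / b.size))
    if se == 0:
        t_mod = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        t_mod = diff / se
    if math.isinf(df_total):
        p = 2.0 * float(sps.norm.sf(abs(t_mod)))
    else:
        p = 2.0 * float(sps.t.sf(abs(t_mod), df_total))
    return t_mod, min(p, 1.0), df_total


def moderated_t_table(matrix: pd.DataFrame, group_a: list[str],
                      group_b: list[str],
                      params: EmpiricalBayesParams | None = None
                      ) -> pd.DataFrame:
    """Per-gene moderated-t table for group_a vs group_b columns.

    If ``params`` is None, the empirical-Bayes prior is fitted on the
    pooled per-gene variances of this matrix first.  Genes with fewer than
    two non-missing observations in either group are dropped (counted in a
    log entry).  Positive t means higher in group_a.

    Returns columns: log2_fc, t_mod, p, p_adj, df_total.
    """
    a = matrix[group_a].to_numpy(dtype=float)
    b = matrix[group_b].to_numpy(dtype=float)
    ok = (np.sum(~np.isnan(a), axis=1) >= 2) & (np.sum(~np.isnan(b), axis=1) >= 2)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("moderated_t_table: dropped %d genes with <2 obs per group",
                    dropped)
    genes = matrix.index[ok]
    a, b = a[ok], b[ok]
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    mean_a = np.nanmean(a, axis=1)
    mean_b = np.nanmean(b, axis=1)
    ss = (np.nansum((a - mean_a[:, None]) ** 2, axis=1)
          + np.nansum((b - mean_b[:, None]) ** 2, axis=1))
    df = n_a + n_b - 2
    s_sq = ss / df
    if params is None:
        params = fit_empirical_bayes(s_sq[s_sq > 0], float(np.median(df)))
    d0 = params.d0
    if math.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, params.s0_sq)
        df_total = np.full_like(s_sq, np.inf)
    else:
        s_tilde_sq = (d0 * params.s0_sq + df * s_sq) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s_tilde_sq * (1.0 / n_a + 1.0 / n_b))
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, diff / se,
                         np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    p = np.where(np.isinf(df_total),
                 2.0 * sps.norm.sf(np.abs(t_mod)),
                 2.0 * sps.t.sf(np.abs(t_mod), np.where(np.isinf(df_total), 1.0,
                                                        df_total)))
    p = np.minimum(p, 1.0)
    table = pd.DataFrame(
        {"log2_fc": diff, "t_mod": t_mod, "p": p,
         "p_adj": bh_adjust(p), "df_total": df_total},
        index=genes,
    )
    return table


# ---------------------------------------------------------------------------
# rank-sum test


def _rank_sum_statistic(x: np.ndarray, pooled_ranks: np.ndarray,
                        n_x: int) -> float:
    return float(np.sum(pooled_ranks[:n_x]))


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def rank_sum_test(x: np.ndarray, y: np.ndarray,
                  alternative: str = "two_sided") -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by enumeration of all C(n_x+n_y, n_x) assignments of the pooled
    mid-ranks when the pooled size is <= 12 (valid under ties); otherwise
    the normal approximation with tie correction and continuity correction.
    ``alternative='less'`` tests whether x tends to be smaller than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    if alternative not in ("less", "greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n_x, n_y = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w_obs = float(np.sum(ranks[:n_x]))
    if n_x + n_y <= EXACT_RANKSUM_MAX_N:
        stats_all = np.array(
            [ranks[list(idx)].sum() for idx in
             combinations(range(n_x + n_y), n_x)]
        )
        total = stats_all.size
        eps = 1e-9
        p_less = np.sum(stats_all <= w_obs + eps) / total
        p_greater = np.sum(stats_all >= w_obs - eps) / total
        if alternative == "less":
            return float(p_less)
        if alternative == "greater":
            return float(p_greater)
        return float(min(1.0, 2.0 * min(p_less, p_greater)))
    # normal approximation with tie correction
    n = n_x + n_y
    mu = n_x * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / float(n * (n - 1))
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    sd = math.sqrt(var)
    z_less = (w_obs - mu + 0.5) / sd
    z_greater = (w_obs - mu - 0.5) / sd
    p_less = float(sps.norm.cdf(z_less))
    p_greater = float(sps.norm.sf(z_greater))
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return float(min(1.0, 2.0 * min(p_less, p_greater)))


# ---------------------------------------------------------------------------
# Fisher exact (one-tailed, enrichment direction)


def fisher_exact_one_tailed(a: int, b: int, c: int, d: int) -> float:
    """One-tailed Fisher exact p for enrichment of the a-cell.

    Table rows are (a, b; c, d); the tail sums hypergeometric probabilities
    of tables with a-cell >= observed (the (2,0;0,2) direction).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        return 1.0
    # a ~ Hypergeom(M=n, n_success=a+b, N=a+c)
    return float(sps.hypergeom.sf(a - 1, n, a + b, a + c))


# ---------------------------------------------------------------------------
# Fisher's method


def combine_fisher(p_values: list[float] | np.ndarray) -> float:
    """Fisher's combined probability: -2 sum(ln p) ~ chi-square, 2k df.

    Zero p-values are floored at the smallest positive float with a logged
    warning; values outside (0, 1] (after flooring) are rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("combine_fisher needs at least one p-value")
    if np.any(p == 0):
        logger.warning("combine_fisher: flooring %d zero p-value(s) at %g",
                       int(np.sum(p == 0)), np.finfo(float).tiny)
        p = np.where(p == 0, np.finfo(float).tiny, p)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * float(np.sum(np.log(p)))
    return float(sps.chi2.sf(x, 2 * p.size))


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
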