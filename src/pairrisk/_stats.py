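"""Shared statistical primitives.

Hand-rolled pieces live here: the empirical-Bayes variance shrinkage behind
the moderated t-statistic, a Breslow-ties Cox partial log-likelihood used to
cross-validate the lasso penalty, a vectorised standardized two-group
log-rank statistic, and Kaplan-Meier step functions for censoring weights.
Everything routine (BH adjustment, t/chi2 tails) is delegated to
statsmodels/scipy.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

__all__ = [
    "bh_adjust",
    "fit_f_dist",
    "moderated_t",
    "trigamma_inverse",
    "cox_partial_loglik",
    "logrank_statistic",
    "km_step",
    "censoring_survival",
]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate prior df d0 and prior variance s0^2 from observed gene
    variances, assuming s2 ~ s0^2 * F(df, d0).

    Moment matching on log variances: returns (d0, s0sq); d0 may be inf
    when the observed variances are under-dispersed relative to chi^2.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise DataError("need at least two positive gene variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0sq = np.exp(emean)
    return float(d0), float(s0sq)


def moderated_t(
    mean_diff: np.ndarray,
    s2: np.ndarray,
    df: float,
    stdev_unscaled: float,
    moderate: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Moderated (or ordinary pooled) two-group t statistics.

    Parameters
    ----------
    mean_diff : per-gene difference of group means.
    s2 : per-gene pooled variance with ``df`` residual degrees of freedom.
    stdev_unscaled : sqrt(1/n1 + 1/n2), the scale of the mean difference.
    moderate : when True, shrink the per-gene variances toward the prior
        estimated across genes; when False (d0 = 0) the statistic reduces to
        the ordinary equal-variance t.

    Returns (t, p, total_df).
    """
    mean_diff = np.asarray(mean_diff, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if moderate:
        d0, s0sq = fit_f_dist(s2, df)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0sq)
            df_total = 1e12  # effectively normal tail
        else:
            s2_post = (d0 * s0sq + df * s2) / (d0 + df)
            df_total = d0 + df
    else:
        s2_post = s2
        df_total = df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / (np.sqrt(s2_post) * stdev_unscaled)
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p, float(df_total)


def cox_partial_loglik(time: np.ndarray, event: np.ndarray, lp: np.ndarray) -> float:
    """Cox partial log-likelihood with Breslow tie handling.

    ``lp`` is the linear predictor. Used as the cross-validation criterion
    when choosing the lasso penalty, so only differences matter.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    lp = np.asarray(lp, dtype=float)
    order = np.argsort(-time, kind="stable")
    t, d, x = time[order], event[order], lp[order]
    # cumulative log-sum-exp over the risk set (descending time)
    m = np.max(x)
    cum = np.cumsum(np.exp(x - m))
    # samples sharing a time share the full risk set at that time
    log_risk = np.log(cum) + m
    # ties: every subject with the same time uses the risk-set sum that
    # includes all of them -> the cumsum at the LAST subject with that time
    boundaries = np.r_[np.where(np.diff(t) != 0)[0], t.size - 1]
    full_log_risk = np.empty_like(log_risk)
    start = 0
    for b in boundaries:
        full_log_risk[start : b + 1] = log_risk[b]
        start = b + 1
    ll = float(np.sum((x - full_log_risk)[d == 1]))
    return ll


def logrank_statistic(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test.

    Returns ``(z, chi2)`` where ``z = (O1 - E1)/sqrt(V)`` is the standardized
    statistic for the ``group == True`` arm and ``chi2 = z**2``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=bool)
    if group.all() or (~group).all():
        raise DataError("log-rank test requires two non-empty groups")
    event_times = np.unique(time[event == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        raise DataError("log-rank variance is zero (no informative event times)")
    z = o_minus_e / np.sqrt(var)
    return float(z), float(z * z)


def km_step(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit estimate.

    Returns ``(times, surv)`` where ``surv[i]`` is S(times[i]) (right
    continuous), over the unique event times.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ts = np.unique(time[event == 1])
    surv = np.empty(ts.size)
    s = 1.0
    for i, t in enumerate(ts):
        n = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1.0 - d / n
        surv[i] = s
    return ts, surv


def _eval_step(ts: np.ndarray, surv: np.ndarray, at: np.ndarray, left: bool = False) -> np.ndarray:
    """Evaluate a right-continuous KM step function; ``left=True`` gives the
    left limit S(t-)."""
    at = np.atleast_1d(np.asarray(at, dtype=float))
    side = "left" if left else "right"
    idx = np.searchsorted(ts, at, side=side)
    out = np.where(idx == 0, 1.0, surv[np.clip(idx - 1, 0, max(len(ts) - 1, 0))] if len(ts) else 1.0)
    return out


def censoring_survival(time: np.ndarray, event: np.ndarray):
    """KM estimate of the censoring distribution G(t) = P(C > t).

    Returns a callable ``G(t, left=False)``; censoring events are the
    complement of the death indicator.
    """
    ts, surv = km_step(time, 1 - np.asarray(event, dtype=int))

    def G(at, left: bool = False):
        return _eval_step(ts, surv, at, left=left)

    return G
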