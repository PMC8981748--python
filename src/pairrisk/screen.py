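"""Screening: m6A-related lncRNAs and tumor-vs-normal differential expression.

Two filters gate entry into the pair feature space:

1. Co-expression with a panel of m6A regulator genes — Pearson (default) or
   Spearman correlation of log2(FPKM+1) across all samples, keeping lncRNAs
   with at least one regulator edge at |r| > r_min and P < p_max.
2. Differential expression tumor vs normal — moderated t-statistics with
   empirical-Bayes variance shrinkage (posterior variance
   (d0*s0^2 + d_g*s_g^2)/(d0 + d_g), prior estimated from the marginal
   distribution of gene variances), BH-adjusted, keeping genes with
   FDR <= fdr_max and |log2FC| >= lfc_min.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, moderated_t
from .datasets import DEFAULT_REGULATORS
from .errors import ConfigError, DataError
from .io import ExpressionMatrix

logger = logging.getLogger("pairrisk")

__all__ = ["coexpression_screen", "differential_expression"]


def _log2p1(values: pd.DataFrame) -> np.ndarray:
    return np.log2(values.to_numpy(dtype=float) + 1.0)


def coexpression_screen(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    regulators=DEFAULT_REGULATORS,
    r_min: float = 0.4,
    p_max: float = 0.001,
    method: str = "pearson",
) -> tuple[pd.DataFrame, list[str]]:
    """Correlate every lncRNA with every regulator across all samples.

    Returns ``(edges, selected)``: the edge table (lncrna, regulator, r, p)
    sorted by |r| descending, restricted to edges passing BOTH thresholds
    (|r| > r_min and p < p_max), and the selected lncRNA list (any passing
    edge). Zero-variance genes are skipped with a warning (r undefined).
    """
    if method not in ("pearson", "spearman"):
        raise ConfigError(f"unknown correlation method {method!r}")
    present = [g for g in regulators if g in expr.values.index]
    absent = sorted(set(regulators) - set(present))
    if absent:
        logger.info("regulators absent from matrix (skipped): %s", absent)
    if not present:
        raise DataError("no regulator genes present in the expression matrix")
    lnc = [g for g in expr.values.index if annotation.loc[g, "biotype"] == "lncRNA"] if len(annotation) else []
    if not lnc:
        raise DataError("no lncRNA rows to screen (check annotation biotypes)")

    X = _log2p1(expr.values.loc[lnc])      # lncRNAs x samples
    R = _log2p1(expr.values.loc[present])  # regulators x samples
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
        R = stats.rankdata(R, axis=1)
    n = X.shape[1]
    if n < 3:
        raise DataError("need at least 3 samples for a correlation p-value")

    sx = X.std(axis=1, ddof=1)
    sr = R.std(axis=1, ddof=1)
    const_lnc = np.array(lnc)[sx == 0]
    if const_lnc.size:
        warnings.warn(
            f"{const_lnc.size} constant lncRNAs skipped (correlation undefined)", stacklevel=2
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    Rc = R - R.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Xc @ Rc.T) / ((n - 1) * np.outer(sx, sr))
    corr = np.clip(corr, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = corr * np.sqrt((n - 2) / (1.0 - corr**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(corr), 1.0), 0.0, p)

    valid = np.isfinite(corr)
    passed = valid & (np.abs(corr) > r_min) & (p < p_max)
    li, ri = np.where(passed)
    edges = pd.DataFrame(
        {
            "lncrna": np.array(lnc)[li],
            "regulator": np.array(present)[ri],
            "r": corr[li, ri],
            "p": p[li, ri],
        }
    ).sort_values("r", key=np.abs, ascending=False, kind="stable").reset_index(drop=True)
    selected = sorted(edges["lncrna"].unique())
    neg = int((edges["r"] < 0).sum())
    if neg:
        logger.info("co-expression screen admitted %d negative-correlation edges", neg)
    logger.info("co-expression screen: %d lncRNAs selected of %d tested", len(selected), len(lnc))
    return edges, selected


def differential_expression(
    expr: ExpressionMatrix,
    lncrna_set,
    fdr_max: float = 0.05,
    lfc_min: float = 1.0,
    moderation: bool = True,
    welch: bool = False,
) -> pd.DataFrame:
    """Tumor-vs-normal differential expression on log2(FPKM+1).

    log2FC is the difference of group means of log2(x+1). The default
    statistic is the moderated t with empirical-Bayes pooled-variance
    shrinkage; ``moderation=False`` gives the ordinary equal-variance t, and
    ``welch=True`` switches to an unequal-variance Welch t instead.

    Returns a DataFrame indexed by gene with columns log2fc, stat, p, fdr,
    direction, significant — significant = (fdr <= fdr_max and
    |log2fc| >= lfc_min).
    """
    tumor = expr.tumor_samples()
    normal = expr.normal_samples()
    if len(tumor) < 2 or len(normal) < 2:
        raise DataError(
            f"differential expression needs >= 2 samples per group "
            f"(tumor={len(tumor)}, normal={len(normal)})"
        )
    genes = [g for g in expr.values.index if g in set(lncrna_set)]
    if not genes:
        raise DataError("no genes from lncrna_set present in the expression matrix")
    XT = np.log2(expr.values.loc[genes, tumor].to_numpy(dtype=float) + 1.0)
    XN = np.log2(expr.values.loc[genes, normal].to_numpy(dtype=float) + 1.0)
    n1, n2 = XT.shape[1], XN.shape[1]
    m1, m2 = XT.mean(axis=1), XN.mean(axis=1)
    log2fc = m1 - m2

    if welch:
        t, p = stats.ttest_ind(XT, XN, axis=1, equal_var=False)
    else:
        df = n1 + n2 - 2
        s2 = ((n1 - 1) * XT.var(axis=1, ddof=1) + (n2 - 1) * XN.var(axis=1, ddof=1)) / df
        t, p, _ = moderated_t(
            log2fc, s2, df, np.sqrt(1.0 / n1 + 1.0 / n2), moderate=moderation
        )
    fdr = bh_adjust(p)
    res = pd.DataFrame(
        {
            "log2fc": log2fc,
            "stat": t,
            "p": p,
            "fdr": fdr,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "significant": (fdr <= fdr_max) & (np.abs(log2fc) >= lfc_min),
        },
        index=pd.Index(genes, name="gene"),
    )
    n_up = int((res["significant"] & (res["direction"] == "up")).sum())
    n_down = int((res["significant"] & (res["direction"] == "down")).sum())
    logger.info("differential expression: %d up, %d down of %d tested", n_up, n_down, len(genes))
    return res
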