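"""Model evaluation: time-dependent ROC, cutoff, stratified survival, and
clinical comparisons.

The ROC estimator is the cumulative-case / dynamic-control one: at horizon t,
cases are subjects with an observed event by t, controls are subjects still
at risk beyond t, and censoring before t is handled by inverse-probability
weights from the Kaplan-Meier estimate of the censoring distribution
(case i weighs 1/G(T_i-)). With no censoring this reduces exactly to the
binary ROC on (event-by-t, score). AUC is the trapezoid rule over
(1-specificity, sensitivity).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from ._stats import bh_adjust, censoring_survival
from .errors import ConfigError, DataError

logger = logging.getLogger("pairrisk")

__all__ = [
    "TimeROC",
    "time_dependent_roc",
    "optimal_cutoff",
    "km_logrank",
    "independence_cox",
    "clinical_auc_comparison",
    "group_feature_tests",
]


@dataclass
class TimeROC:
    """ROC curve of a score for events by ``horizon``.

    ``thresholds`` are the sorted unique scores; sens/spec are evaluated for
    the classification rule score > threshold; ``n_high`` counts samples
    above each threshold (used for cutoff tie-breaking).
    """

    horizon: float
    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    n_high: np.ndarray
    n: int


def _align(scores: pd.Series, clinical: pd.DataFrame):
    common = [s for s in scores.index if s in clinical.index]
    if not common:
        raise DataError("no overlap between scores and clinical samples")
    sc = scores.loc[common].to_numpy(dtype=float)
    time = clinical.loc[common, "time"].to_numpy(dtype=float)
    event = clinical.loc[common, "event"].to_numpy(dtype=int)
    return common, sc, time, event


def time_dependent_roc(
    scores: pd.Series,
    clinical: pd.DataFrame,
    horizon: float,
    ipcw: bool = True,
) -> TimeROC:
    """Cumulative/dynamic time-dependent ROC at ``horizon`` (days).

    ``ipcw=False`` switches to the naive censoring-free estimator (subjects
    censored before the horizon are simply excluded) used as an oracle
    cross-check; with no censoring the two coincide.
    """
    _, sc, time, event = _align(scores, clinical)
    case = (time <= horizon) & (event == 1)
    control = time > horizon
    if case.sum() == 0:
        raise DataError(f"AUC undefined: no events by horizon {horizon}")
    if control.sum() == 0:
        raise DataError(f"AUC undefined: no subjects at risk beyond horizon {horizon}")

    if ipcw:
        G = censoring_survival(time, event)
        w_case = 1.0 / np.asarray(G(time[case], left=True), dtype=float)
        usable = np.isfinite(w_case) & (w_case > 0)
        w_case = w_case[usable]
        case_scores = sc[case][usable]
    else:
        w_case = np.ones(int(case.sum()))
        case_scores = sc[case]
    ctrl_scores = sc[control]

    thresholds = np.unique(sc)
    # sens(c) = weighted fraction of cases with score > c; spec(c) = fraction
    # of controls with score <= c
    order = np.argsort(case_scores, kind="stable")
    cs, ws = case_scores[order], w_case[order]
    cum = np.r_[0.0, np.cumsum(ws)]
    total_w = ws.sum()
    sens = (total_w - cum[np.searchsorted(cs, thresholds, side="right")]) / total_w
    ctrl_sorted = np.sort(ctrl_scores)
    spec = np.searchsorted(ctrl_sorted, thresholds, side="right") / ctrl_sorted.size
    all_sorted = np.sort(sc)
    n_high = sc.size - np.searchsorted(all_sorted, thresholds, side="right")

    fpr = np.r_[1.0, 1.0 - spec, 0.0]
    tpr = np.r_[1.0, sens, 0.0]
    o = np.lexsort((tpr, fpr))  # ties in FPR ordered by TPR -> monotone curve
    auc = float(np.trapezoid(tpr[o], fpr[o]))
    return TimeROC(
        horizon=float(horizon),
        thresholds=thresholds,
        sens=sens,
        spec=spec,
        auc=auc,
        n_high=n_high,
        n=sc.size,
    )


def optimal_cutoff(roc: TimeROC) -> float:
    """Youden cutoff: maximise sensitivity + specificity.

    Candidate cutoffs are midpoints between consecutive unique scores (the
    rule score > cutoff then matches score > lower-threshold exactly). Ties
    break toward the most balanced group split, then the smaller cutoff.
    """
    if roc.thresholds.size < 2:
        raise DataError("no discriminating threshold: all scores identical")
    j = roc.sens + roc.spec
    best = None
    for i in range(roc.thresholds.size - 1):
        cut = 0.5 * (roc.thresholds[i] + roc.thresholds[i + 1])
        imbalance = abs(2 * roc.n_high[i] - roc.n)
        key = (-j[i], imbalance, cut)
        if best is None or key < best[0]:
            best = (key, cut)
    return float(best[1])


def km_logrank(groups: pd.Series, clinical: pd.DataFrame):
    """Kaplan-Meier curves per group plus the two-group log-rank test.

    Returns ``(curves, chi2, p)`` where curves maps group label -> survival
    function DataFrame (index time, column survival).
    """
    common = [s for s in groups.index if s in clinical.index]
    groups = groups.loc[common]
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise DataError(f"log-rank needs two non-empty groups, got {labels}")
    time = clinical.loc[common, "time"]
    event = clinical.loc[common, "event"]
    curves = {}
    for lab in labels:
        mask = (groups == lab).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=str(lab))
        curves[lab] = kmf.survival_function_
    res = multivariate_logrank_test(time, groups, event)
    return curves, float(res.test_statistic), float(res.p_value)


def _encode_covariates(clinical: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric coding: sex male=1/female=0; grade & stage ordinal as given."""
    out = pd.DataFrame(index=clinical.index)
    for cov in covariates:
        if cov not in clinical.columns:
            continue
        col = clinical[cov]
        if cov == "sex":
            out[cov] = col.map({"male": 1.0, "female": 0.0})
        else:
            out[cov] = pd.to_numeric(col, errors="coerce")
    return out


def independence_cox(
    scores: pd.Series,
    clinical: pd.DataFrame,
    covariates=("age", "sex", "grade", "stage"),
) -> pd.DataFrame:
    """Uni- and multivariate Cox of survival on riskScore and clinical
    covariates (complete-case for the multivariate fit).

    Returns a long table: term, analysis in {univariate, multivariate}, hr,
    ci_low, ci_high, p.
    """
    common = [s for s in scores.index if s in clinical.index]
    if np.ptp(scores.loc[common].to_numpy(dtype=float)) == 0:
        raise DataError("riskScore is constant; independence analysis undefined")
    base = clinical.loc[common, ["time", "event"]].astype(float)
    X = _encode_covariates(clinical.loc[common], covariates)
    X.insert(0, "riskScore", scores.loc[common].to_numpy(dtype=float))

    rows = []

    def _fit(cols, analysis):
        df = pd.concat([base, X[cols]], axis=1).dropna()
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        for term in cols:
            s = cph.summary.loc[term]
            rows.append(
                (term, analysis, float(s["exp(coef)"]), float(s["exp(coef) lower 95%"]),
                 float(s["exp(coef) upper 95%"]), float(s["p"]))
            )
        return len(base) - len(df)

    for term in X.columns:
        if X[term].dropna().nunique() < 2:
            warnings.warn(f"covariate {term!r} constant or missing; skipped", stacklevel=2)
            continue
        _fit([term], "univariate")
    usable = [c for c in X.columns if X[c].dropna().nunique() >= 2]
    n_dropped = _fit(usable, "multivariate")
    if n_dropped:
        logger.info("independence Cox: %d incomplete cases dropped from multivariate fit", n_dropped)
    return pd.DataFrame(rows, columns=["term", "analysis", "hr", "ci_low", "ci_high", "p"])


def clinical_auc_comparison(
    clinical: pd.DataFrame,
    scores: pd.Series,
    horizon: float,
    covariates=("age", "sex", "grade", "stage"),
) -> pd.DataFrame:
    """Time-dependent AUC of the riskScore next to each clinical covariate
    used as a predictor (numeric-coded). AUC < 0.5 is reported as-is with a
    note that the covariate is inversely oriented."""
    out = []
    roc = time_dependent_roc(scores, clinical, horizon)
    out.append(("riskScore", roc.auc, ""))
    X = _encode_covariates(clinical, covariates)
    for cov in X.columns:
        col = X[cov].dropna()
        if col.nunique() < 2:
            warnings.warn(f"covariate {cov!r} constant or missing; skipped", stacklevel=2)
            continue
        auc = time_dependent_roc(col, clinical.loc[col.index], horizon).auc
        note = "inversely oriented (AUC < 0.5)" if auc < 0.5 else ""
        out.append((cov, auc, note))
    return pd.DataFrame(out, columns=["predictor", "auc", "note"])


def group_feature_tests(
    groups: pd.Series,
    features: pd.DataFrame,
    feature_types: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Association of risk group with clinicopathological features.

    Categorical features use the chi-square test on the contingency table;
    ordinal/continuous features the two-sided Wilcoxon rank-sum test.
    Feature type is taken from ``feature_types`` ('categorical' or
    'continuous'), defaulting to categorical for non-numeric columns.
    P-values are BH-adjusted across features.
    """
    common = [s for s in groups.index if s in features.index]
    groups = groups.loc[common]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise DataError(f"need exactly two groups, got {labels}")
    rows = []
    for feat in features.columns:
        col = features.loc[common, feat].dropna()
        if col.nunique() < 2:
            warnings.warn(f"feature {feat!r} has no variation; skipped", stacklevel=2)
            continue
        g = groups.loc[col.index]
        ftype = (feature_types or {}).get(
            feat, "continuous" if pd.api.types.is_numeric_dtype(col) else "categorical"
        )
        if ftype == "categorical":
            tab = pd.crosstab(g, col)
            stat, p, _, _ = stats.chi2_contingency(tab)
            test = "chi-square"
        else:
            a = col[g == labels[0]].to_numpy(dtype=float)
            b = col[g == labels[1]].to_numpy(dtype=float)
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "wilcoxon"
        rows.append((feat, test, float(stat), float(p)))
    res = pd.DataFrame(rows, columns=["feature", "test", "stat", "p"])
    res["fdr"] = bh_adjust(res["p"].to_numpy()) if len(res) else []
    return res
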