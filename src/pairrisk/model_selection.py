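"""Prognostic pair selection and the Cox risk model.

Three-stage funnel mirroring the signature-construction procedure:

1. univariate Cox per pair (Wald P < 0.001 -> candidates);
2. repeated LASSO-Cox: R subsamples (80% of patients, event-stratified,
   without replacement), each fitted over an L1 path with the penalty chosen
   by cross-validated partial likelihood inside the subsample; pairs with a
   nonzero coefficient in more than freq_min repetitions are selected;
3. multivariate Cox over the selected pairs -> riskScore coefficients.

When a grid of frequency thresholds is supplied, one candidate model per
threshold is fitted and the model with the highest 1-year time-dependent
AUC wins (ties: fewer pairs, then lower threshold).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError as LifelinesConvergence
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sklearn.base import BaseEstimator

from ._stats import cox_partial_loglik
from .errors import ConfigError, ConvergenceError, DataError
from .io import RiskModel

logger = logging.getLogger("pairrisk")

__all__ = [
    "univariate_cox_screen",
    "repeated_lasso_select",
    "fit_multivariate_cox",
    "select_best_model",
    "PairSignatureCox",
]


def _check_survival(clinical: pd.DataFrame, samples) -> pd.DataFrame:
    missing = [s for s in samples if s not in clinical.index]
    if missing:
        raise DataError(f"samples missing from clinical table: {missing[:5]}")
    surv = clinical.loc[list(samples), ["time", "event"]].astype(float)
    if surv["event"].sum() == 0:
        raise DataError("no events in the analysis cohort")
    return surv


def univariate_cox_screen(
    pm: pd.DataFrame, clinical: pd.DataFrame, p_max: float = 0.001
) -> tuple[pd.DataFrame, list[str]]:
    """Single-covariate Cox fit (Efron ties) per pair; Wald p-values.

    Returns ``(results, candidates)`` with columns pair, coef, hr, ci_low,
    ci_high, p; candidates are pairs with p < p_max. Pairs constant across
    the analysis samples are skipped with a warning.
    """
    surv = _check_survival(clinical, pm.columns)
    if surv["event"].sum() < 10:
        warnings.warn(
            f"only {int(surv['event'].sum())} events; univariate Cox p-values are unstable",
            stacklevel=2,
        )
    rows = []
    skipped = []
    for pair_id, c in pm.iterrows():
        x = c.to_numpy(dtype=float)
        if np.all(x == x[0]):
            skipped.append(pair_id)
            continue
        df = surv.copy()
        df["C"] = x
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except (LifelinesConvergence, Exception) as exc:  # noqa: BLE001
            warnings.warn(f"univariate Cox failed for {pair_id}: {exc}", stacklevel=2)
            continue
        s = cph.summary.loc["C"]
        rows.append(
            (
                pair_id,
                float(s["coef"]),
                float(s["exp(coef)"]),
                float(s["exp(coef) lower 95%"]),
                float(s["exp(coef) upper 95%"]),
                float(s["p"]),
            )
        )
    if skipped:
        warnings.warn(f"{len(skipped)} constant pairs skipped in univariate Cox", stacklevel=2)
    res = pd.DataFrame(rows, columns=["pair", "coef", "hr", "ci_low", "ci_high", "p"]).set_index(
        "pair"
    )
    candidates = list(res.index[res["p"] < p_max])
    logger.info("univariate Cox: %d candidates of %d pairs (p < %g)", len(candidates), len(res), p_max)
    return res, candidates


def _stratified_subsample(event: np.ndarray, frac: float, rng) -> np.ndarray:
    """Indices of an event-stratified subsample without replacement."""
    idx_e = np.where(event == 1)[0]
    idx_c = np.where(event == 0)[0]
    n_e = max(int(round(frac * idx_e.size)), 1)
    n_c = int(round(frac * idx_c.size))
    take = np.concatenate(
        [rng.choice(idx_e, size=n_e, replace=False), rng.choice(idx_c, size=n_c, replace=False)]
    )
    return np.sort(take)


def _stratified_folds(event: np.ndarray, k: int, rng) -> np.ndarray:
    """Fold assignment (0..k-1) per sample, event-stratified."""
    fold = np.empty(event.size, dtype=int)
    for val in (0, 1):
        idx = np.where(event == val)[0]
        perm = rng.permutation(idx)
        fold[perm] = np.arange(perm.size) % k
    return fold


def _surv_y(time: np.ndarray, event: np.ndarray):
    return np.array(
        list(zip(event.astype(bool), time)), dtype=[("event", "?"), ("time", "<f8")]
    )


def _cv_choose_alpha(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    alphas: np.ndarray,
    cv_folds: int,
    rng,
    rule: str,
) -> int:
    """Pick an index into ``alphas`` by K-fold cross-validated partial
    likelihood (Breslow). rule='min' takes the maximiser; rule='1se' the
    largest penalty within one standard error of it."""
    k = min(cv_folds, int(event.sum())) if event.sum() >= 2 else 2
    fold = _stratified_folds(event, k, rng)
    cvll = np.zeros((k, alphas.size))
    for f in range(k):
        tr, te = fold != f, fold == f
        if event[te].sum() == 0:
            continue
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=list(alphas), fit_baseline_model=False
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[tr], _surv_y(time[tr], event[tr]))
        coefs = model.coef_  # p x n_alphas (for the alphas that converged)
        fitted = np.asarray(model.alphas_)
        lp_all = X[te] @ coefs
        ll = np.array(
            [cox_partial_loglik(time[te], event[te], lp_all[:, j]) for j in range(fitted.size)]
        )
        # align to the requested grid (coxnet may truncate the path)
        aligned = np.interp(np.log(alphas), np.log(fitted[::-1]), ll[::-1])
        cvll[f] = aligned
    mean_ll = cvll.mean(axis=0)
    best = int(np.argmax(mean_ll))
    if rule == "1se":
        se = cvll.std(axis=0, ddof=1) / np.sqrt(k)
        ok = mean_ll >= mean_ll[best] - se[best]
        best = int(np.min(np.where(ok)[0]))  # alphas descending: min index = largest penalty
    return best


def repeated_lasso_select(
    pm_candidates: pd.DataFrame,
    clinical: pd.DataFrame,
    R: int = 1000,
    freq_min: int = 100,
    subsample: float = 0.8,
    seed: int = 0,
    cv_folds: int = 5,
    lambda_rule: str = "1se",
    n_alphas: int = 30,
) -> tuple[pd.DataFrame, list[str]]:
    """Repeated LASSO-Cox selection by nonzero-coefficient frequency.

    Each of the R repetitions draws an event-stratified ``subsample``
    fraction of patients without replacement (redrawn up to 10 times if it
    has fewer than 5 events), fits an L1-penalized Cox path, picks the
    penalty by cross-validated partial likelihood within the repetition, and
    records which pairs keep nonzero coefficients. Pairs nonzero in MORE
    than ``freq_min`` repetitions (strict) are selected. Deterministic given
    the seed.

    Returns ``(frequency_table, selected)``; the table has columns count, R,
    and the per-repetition chosen penalty is kept in ``table.attrs["lambdas"]``.
    """
    if pm_candidates.shape[0] < 2:
        raise DataError(f"need >= 2 candidate pairs, got {pm_candidates.shape[0]}")
    if R < 1:
        raise ConfigError("R must be >= 1")
    if not 0 < subsample <= 1:
        raise ConfigError("subsample fraction must be in (0, 1]")
    if lambda_rule not in ("min", "1se"):
        raise ConfigError(f"unknown lambda rule {lambda_rule!r}")
    surv = _check_survival(clinical, pm_candidates.columns)
    time = surv["time"].to_numpy()
    event = surv["event"].to_numpy().astype(int)
    X_full = pm_candidates.to_numpy(dtype=float).T  # samples x pairs
    pairs = list(pm_candidates.index)
    rng = np.random.default_rng(seed)

    counts = np.zeros(len(pairs), dtype=int)
    lambdas: list[float] = []
    for rep in range(R):
        for attempt in range(10):
            idx = (
                np.arange(X_full.shape[0])
                if subsample == 1.0
                else _stratified_subsample(event, subsample, rng)
            )
            if event[idx].sum() >= 5:
                break
        else:
            raise DataError(
                f"repetition {rep}: subsample has < 5 events after 10 redraws"
            )
        Xs, ts, es = X_full[idx], time[idx], event[idx]
        keep = Xs.std(axis=0) > 0
        if keep.sum() < 2:
            lambdas.append(np.nan)
            continue
        Xk = Xs[:, keep]
        path_model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.05, fit_baseline_model=False
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            path_model.fit(Xk, _surv_y(ts, es))
        alphas = np.asarray(path_model.alphas_)
        j = _cv_choose_alpha(Xk, ts, es, alphas, cv_folds, rng, lambda_rule)
        lambdas.append(float(alphas[j]))
        support = np.where(keep)[0][np.abs(path_model.coef_[:, j]) > 0]
        counts[support] += 1

    table = pd.DataFrame({"count": counts, "R": R}, index=pd.Index(pairs, name="pair"))
    table.attrs["lambdas"] = lambdas
    selected = list(table.index[table["count"] > freq_min])
    logger.info(
        "repeated LASSO: %d of %d pairs with frequency > %d / %d",
        len(selected), len(pairs), freq_min, R,
    )
    return table, selected


def fit_multivariate_cox(
    pm_selected: pd.DataFrame, clinical: pd.DataFrame
) -> RiskModel:
    """Joint Cox fit (Efron ties) over the selected pairs.

    Perfectly duplicated pair rows are collapsed (first kept) with a warning.
    Returns a RiskModel with coefficients but no cutoff yet; riskScore(s) =
    sum_j coef_j * C_j(s).
    """
    if pm_selected.shape[0] == 0:
        raise DataError("no pairs selected for the multivariate model")
    surv = _check_survival(clinical, pm_selected.columns)
    dup = pm_selected.duplicated(keep="first")
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicated pair rows collapsed before the joint fit",
            stacklevel=2,
        )
        pm_selected = pm_selected.loc[~dup]
    df = surv.copy()
    pair_ids = list(pm_selected.index)
    cols = {f"x{i}": pm_selected.iloc[i].to_numpy(dtype=float) for i in range(len(pair_ids))}
    df = pd.concat([df, pd.DataFrame(cols, index=df.index)], axis=1)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(df, duration_col="time", event_col="event")
    except LifelinesConvergence as exc:
        raise ConvergenceError(f"multivariate Cox did not converge: {exc}") from exc
    coef = cph.params_.to_numpy()
    separation = bool(np.any(np.abs(coef) > 15)) or any(
        "convergence" in str(w.message).lower() or "separation" in str(w.message).lower()
        for w in caught
    )
    if separation:
        warnings.warn(
            "possible monotone likelihood (perfect separation) in multivariate Cox",
            stacklevel=2,
        )
    model = RiskModel(
        pairs=[tuple(p.split("|")) for p in pair_ids],
        coef=coef,
        provenance={"n_samples": int(len(df)), "n_events": int(surv["event"].sum()),
                    "separation_flag": separation},
    )
    return model


def select_best_model(
    candidates: list[RiskModel],
    pm: pd.DataFrame,
    clinical: pd.DataFrame,
    horizon: float = 365.0,
) -> RiskModel:
    """Pick the candidate with the highest time-dependent AUC at ``horizon``.

    AUCs are compared rounded to 4 decimals; ties break toward fewer pairs,
    then toward the lower selection frequency threshold recorded in
    provenance. The winner is returned with ``auc_at_selection`` set.
    """
    from .evaluation import time_dependent_roc  # local: avoid module cycle

    if not candidates:
        raise DataError("no candidate models to choose from")
    scored = []
    for m in candidates:
        scores = m.score(pm)
        roc = time_dependent_roc(scores, clinical, horizon)
        scored.append((round(roc.auc, 4), m, roc.auc))
    scored.sort(
        key=lambda t: (-t[0], len(t[1].pairs), t[1].provenance.get("freq_min", 0))
    )
    _, best, auc = scored[0]
    best.auc_at_selection = float(auc)
    return best


class PairSignatureCox(BaseEstimator):
    """Sklearn-style estimator wrapping the full selection funnel.

    fit(X, y) with X = samples x pairs (binary DataFrame, e.g. from
    PairTransformer) and y a (time, event) DataFrame or structured array;
    predict(X) returns the riskScore; predict_group(X) the high/low label.

    Parameters mirror the procedure defaults: unicox_p_max=0.001, R=1000
    repetitions at 80% subsampling, frequency threshold 100 (strict >), and
    a 1-year AUC horizon for choosing among freq_grid candidates.
    """

    def __init__(
        self,
        unicox_p_max: float = 0.001,
        R: int = 1000,
        freq_min: int | None = 100,
        freq_grid: tuple = (),
        subsample: float = 0.8,
        cv_folds: int = 5,
        lambda_rule: str = "1se",
        horizon: float = 365.0,
        random_state: int = 0,
    ):
        self.unicox_p_max = unicox_p_max
        self.R = R
        self.freq_min = freq_min
        self.freq_grid = freq_grid
        self.subsample = subsample
        self.cv_folds = cv_folds
        self.lambda_rule = lambda_rule
        self.horizon = horizon
        self.random_state = random_state

    def _as_clinical(self, y) -> pd.DataFrame:
        if isinstance(y, pd.DataFrame):
            return y
        arr = np.asarray(y)
        if arr.dtype.names and set(arr.dtype.names) >= {"event", "time"}:
            return pd.DataFrame({"time": arr["time"], "event": arr["event"].astype(int)},
                                index=self._X_index)
        raise DataError("y must be a (time, event) DataFrame or structured array")

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise DataError("PairSignatureCox requires a samples x pairs DataFrame")
        self._X_index = X.index
        clinical = self._as_clinical(y)
        pm = X.T
        self.unicox_, candidates = univariate_cox_screen(pm, clinical, self.unicox_p_max)
        if not candidates:
            raise DataError("no pairs passed the univariate Cox screen")
        self.freq_table_, _ = repeated_lasso_select(
            pm.loc[candidates],
            clinical,
            R=self.R,
            freq_min=0,
            subsample=self.subsample,
            seed=self.random_state,
            cv_folds=self.cv_folds,
            lambda_rule=self.lambda_rule,
        )
        thresholds = list(self.freq_grid) or [self.freq_min]
        models = []
        for fm in thresholds:
            sel = list(self.freq_table_.index[self.freq_table_["count"] > fm])
            if not sel:
                continue
            m = fit_multivariate_cox(pm.loc[sel], clinical)
            m.provenance.update({"R": self.R, "freq_min": int(fm), "seed": self.random_state})
            models.append(m)
        if not models:
            raise DataError("no pairs exceeded any selection-frequency threshold")
        best = select_best_model(models, pm, clinical, horizon=self.horizon)

        from .evaluation import optimal_cutoff, time_dependent_roc  # avoid cycle

        scores = best.score(pm)
        roc = time_dependent_roc(scores, clinical, self.horizon)
        best.cutoff = optimal_cutoff(roc)
        best.provenance["frequencies"] = {
            p: int(c) for p, c in self.freq_table_["count"].items() if c > 0
        }
        self.model_ = best
        self.pairs_ = best.pairs
        self.coef_ = best.coef
        self.cutoff_ = best.cutoff
        self.auc_ = best.auc_at_selection
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        if not hasattr(self, "model_"):
            raise DataError("PairSignatureCox is not fitted")
        return self.model_.score(X.T)

    def predict_group(self, X: pd.DataFrame) -> pd.Series:
        return self.model_.assign_groups(self.predict(X))
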