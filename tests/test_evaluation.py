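"""Time-dependent ROC, Youden cutoff, KM/log-rank and clinical comparisons."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from pairrisk.errors import DataError
from pairrisk.evaluation import (
    clinical_auc_comparison,
    group_feature_tests,
    independence_cox,
    km_logrank,
    optimal_cutoff,
    time_dependent_roc,
)

from conftest import make_survival_cohort


def _clin(time, event, **cov):
    n = len(time)
    idx = [f"S{i}" for i in range(n)]
    return pd.DataFrame({"time": time, "event": event, **cov}, index=idx)


def _scores(vals):
    return pd.Series(vals, index=[f"S{i}" for i in range(len(vals))])


class TestTimeDependentROC:
    def test_perfect_marker_auc_one(self):
        # score equals the event indicator before the horizon, no censoring
        time = [100, 200, 800, 900, 300, 700]
        event = [1, 1, 1, 1, 1, 1]
        scores = _scores([1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        roc = time_dependent_roc(scores, _clin(time, event), horizon=365)
        assert roc.auc == 1.0

    def test_censoring_free_equals_binary_roc_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = 80
            time = rng.exponential(500, n)
            scores = _scores(rng.normal(size=n) + (time < 365))
            clin = _clin(time, np.ones(n, dtype=int))
            roc = time_dependent_roc(scores, clin, horizon=365)
            y = (time <= 365).astype(int)
            assert roc.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-10)

    def test_independent_marker_near_half(self):
        # null AUC sampling sd at n=400 is ~0.029: check the mean tightly and
        # individual draws at ~3.5 sigma
        aucs = []
        for seed in range(20):
            pm, clin, keys, _ = make_survival_cohort(seed=300 + seed, n=400, beta=0.0)
            rng = np.random.default_rng(seed)
            scores = pd.Series(rng.normal(size=len(clin)), index=clin.index)
            aucs.append(time_dependent_roc(scores, clin, horizon=365).auc)
        assert abs(np.mean(aucs) - 0.5) <= 0.02
        assert np.all(np.abs(np.array(aucs) - 0.5) <= 0.12)

    def test_ipcw_matches_sksurv_estimator(self):
        # independent cross-check of the censoring-weighted AUC
        from sksurv.metrics import cumulative_dynamic_auc

        for seed in (1, 2, 3):
            pm, clin, keys, truth = make_survival_cohort(seed=seed, n=300)
            betas = np.array([b for _, _, b in truth.prognostic_pairs])
            scores = pd.Series(
                betas @ pm.loc[[f"{a}|{b}" for a, b, _ in truth.prognostic_pairs]].to_numpy(),
                index=pm.columns,
            )
            roc = time_dependent_roc(scores, clin, horizon=365)
            y = np.array(
                list(zip(clin["event"].astype(bool), clin["time"])),
                dtype=[("event", "?"), ("time", "<f8")],
            )
            ref, _ = cumulative_dynamic_auc(y, y, scores.loc[clin.index].to_numpy(), [365.0])
            assert roc.auc == pytest.approx(float(ref[0]), abs=0.02)

    def test_no_events_before_horizon_errors(self):
        clin = _clin([500, 600, 700], [1, 1, 0])
        with pytest.raises(DataError, match="AUC undefined"):
            time_dependent_roc(_scores([1, 2, 3]), clin, horizon=100)

    def test_auc_invariant_under_monotone_transform(self):
        pm, clin, keys, _ = make_survival_cohort(seed=310, n=200)
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=len(clin)), index=clin.index)
        a1 = time_dependent_roc(scores, clin, 365).auc
        a2 = time_dependent_roc(np.exp(scores * 2), clin, 365).auc
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestOptimalCutoff:
    def test_separable_case_returns_midpoint(self):
        clin = _clin([100, 120, 800, 900], [1, 1, 1, 1])
        # events by 1y have the high scores
        scores = _scores([0.8, 0.9, 0.1, 0.2])
        roc = time_dependent_roc(scores, clin, horizon=365)
        cut = optimal_cutoff(roc)
        assert cut == pytest.approx(0.5)  # midpoint of (0.2, 0.8)
        i = np.searchsorted(roc.thresholds, cut) - 1
        assert roc.sens[i] + roc.spec[i] == 2.0

    def test_identical_scores_error(self):
        clin = _clin([100, 200, 800], [1, 1, 0])
        with pytest.raises(DataError, match="no discriminating"):
            optimal_cutoff(time_dependent_roc(_scores([1.0, 1.0, 1.0]), clin, 365))

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = 50
            time = rng.exponential(500, n)
            event = np.ones(n, dtype=int)
            scores = _scores(rng.normal(size=n))
            clin = _clin(time, event)
            roc = time_dependent_roc(scores, clin, 365)
            cut = optimal_cutoff(roc)
            # brute force over all midpoints
            s = np.sort(np.unique(scores.to_numpy()))
            y = (time <= 365).astype(int)
            best_j, best_cut = -np.inf, None
            for a, b in zip(s[:-1], s[1:]):
                c = (a + b) / 2
                sens = ((scores.to_numpy() > c) & (y == 1)).sum() / max(y.sum(), 1)
                spec = ((scores.to_numpy() <= c) & (y == 0)).sum() / max((1 - y).sum(), 1)
                if sens + spec > best_j + 1e-12:
                    best_j, best_cut = sens + spec, c
            j_at = lambda c: (
                ((scores.to_numpy() > c) & (y == 1)).sum() / y.sum()
                + ((scores.to_numpy() <= c) & (y == 0)).sum() / (1 - y).sum()
            )
            assert j_at(cut) == pytest.approx(best_j, abs=1e-12)


class TestKMLogrank:
    def test_null_pvalues_uniform(self):
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n = 40
            time = rng.exponential(500, n)
            event = (rng.random(n) < 0.7).astype(int)
            groups = pd.Series(
                np.where(rng.random(n) < 0.5, "a", "b"), index=[f"S{i}" for i in range(n)]
            )
            clin = _clin(time, event)
            if groups.nunique() < 2:
                continue
            _, _, p = km_logrank(groups, clin)
            pvals.append(p)
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_hazard_detected(self):
        pm, clin, keys, _ = make_survival_cohort(seed=320, n=400, beta=1.5, n_pairs=1)
        groups = pd.Series(
            np.where(pm.loc[keys[0]] > 0, "high", "low"), index=pm.columns
        )
        _, chi2, p = km_logrank(groups, clin)
        assert p < 0.001

    def test_single_group_errors(self):
        clin = _clin([100, 200], [1, 1])
        groups = pd.Series(["a", "a"], index=clin.index)
        with pytest.raises(DataError, match="two"):
            km_logrank(groups, clin)

    def test_km_without_censoring_is_empirical_survival(self):
        time = np.array([50.0, 100.0, 150.0, 200.0, 250.0, 600.0])
        clin = _clin(time, np.ones(6, dtype=int))
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=clin.index)
        curves, _, _ = km_logrank(groups, clin)
        sf = curves["a"]
        # empirical survival: 2/3 after first event, 1/3, then 0
        np.testing.assert_allclose(
            sf.iloc[:, 0].to_numpy(), [1.0, 2 / 3, 1 / 3, 0.0][: len(sf)], atol=1e-12
        )


class TestIndependenceCox:
    def test_riskscore_significant_when_covariates_are_noise(self):
        pm, clin, keys, truth = make_survival_cohort(seed=330, n=400)
        betas = np.array([b for _, _, b in truth.prognostic_pairs])
        scores = pd.Series(
            betas @ pm.loc[[f"{a}|{b}" for a, b, _ in truth.prognostic_pairs]].to_numpy(),
            index=pm.columns,
        )
        res = independence_cox(scores, clin)
        multi = res[res["analysis"] == "multivariate"].set_index("term")
        assert multi.loc["riskScore", "p"] < 0.05
        assert (multi.loc["riskScore", "ci_low"] <= multi.loc["riskScore", "hr"]
                <= multi.loc["riskScore", "ci_high"])

    def test_constant_score_errors(self):
        pm, clin, keys, _ = make_survival_cohort(seed=331, n=60)
        scores = pd.Series(1.0, index=clin.index)
        with pytest.raises(DataError, match="constant"):
            independence_cox(scores, clin)

    def test_single_covariate_multivariate_equals_univariate(self):
        pm, clin, keys, _ = make_survival_cohort(seed=332, n=200)
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.normal(size=len(clin)), index=clin.index)
        res = independence_cox(scores, clin, covariates=())
        uni = res[res["analysis"] == "univariate"].set_index("term")
        multi = res[res["analysis"] == "multivariate"].set_index("term")
        assert multi.loc["riskScore", "hr"] == pytest.approx(uni.loc["riskScore", "hr"], rel=1e-8)


class TestClinicalAUCComparison:
    def test_perfect_and_null_and_reversed_covariates(self):
        rng = np.random.default_rng(4)
        n = 200
        time = rng.exponential(500, n)
        event = np.ones(n, dtype=int)
        died_by_1y = (time <= 365).astype(float)
        clin = _clin(
            time, event,
            age=died_by_1y * 40 + 30,            # perfect marker
            grade=rng.integers(1, 4, n),          # independent
            stage=4 - 3 * died_by_1y,             # perfectly reversed
        )
        scores = pd.Series(rng.normal(size=n), index=clin.index)
        res = clinical_auc_comparison(clin, scores, horizon=365).set_index("predictor")
        assert res.loc["age", "auc"] == 1.0
        assert 0.4 <= res.loc["grade", "auc"] <= 0.6
        assert res.loc["stage", "auc"] < 0.5
        assert "inversely" in res.loc["stage", "note"]


class TestGroupFeatureTests:
    def test_null_features_uniform_and_extreme_association_detected(self):
        rng = np.random.default_rng(5)
        n = 300
        idx = [f"S{i}" for i in range(n)]
        groups = pd.Series(np.where(rng.random(n) < 0.5, "high", "low"), index=idx)
        features = pd.DataFrame(
            {
                "noise_cont": rng.normal(size=n),
                "noise_cat": rng.choice(list("abc"), n),
                "det": (groups == "high").astype(float),  # deterministic in group
            },
            index=idx,
        )
        res = group_feature_tests(groups, features).set_index("feature")
        assert res.loc["det", "p"] < 1e-6
        assert res.loc["noise_cont", "p"] > 0.001
        assert res.loc["noise_cat", "test"] == "chi-square"
        assert res.loc["noise_cont", "test"] == "wilcoxon"

    def test_constant_feature_skipped(self):
        idx = [f"S{i}" for i in range(10)]
        groups = pd.Series(["high"] * 5 + ["low"] * 5, index=idx)
        features = pd.DataFrame({"flat": np.ones(10)}, index=idx)
        with pytest.warns(UserWarning, match="no variation"):
            res = group_feature_tests(groups, features)
        assert len(res) == 0
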