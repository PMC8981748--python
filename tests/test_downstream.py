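"""TMB arithmetic, maximally selected cutpoint, mutation and score comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairrisk.datasets import simulate_maf
from pairrisk.downstream import (
    compare_scores_by_group,
    compute_tmb,
    mutation_frequency_by_group,
    surv_cutpoint,
)
from pairrisk.errors import ConfigError, DataError


def _maf(rows):
    return pd.DataFrame(rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"])


class TestComputeTMB:
    def test_nonsynonymous_only_counted(self):
        rows = [("TTN", "S1", "Missense_Mutation")] * 38 + [("TTN", "S1", "Silent")] * 10
        tmb = compute_tmb(_maf(rows), ["S1"], capture_mb=38.0)
        assert tmb.loc["S1", "tmb"] == 1.0
        assert tmb.loc["S1", "n_mut"] == 38

    def test_absent_samples_flagged_zero(self):
        tmb = compute_tmb(_maf([]), ["S1", "S2"])
        assert (tmb["tmb"] == 0).all()
        assert (~tmb["in_maf"]).all()

    def test_additive_over_disjoint_mafs(self):
        rng = np.random.default_rng(0)
        samples = [f"S{i}" for i in range(20)]
        a = simulate_maf(samples, rate_per_sample=3, seed=1)
        b = simulate_maf(samples, rate_per_sample=5, seed=2)
        ta = compute_tmb(a, samples)["n_mut"]
        tb = compute_tmb(b, samples)["n_mut"]
        tab = compute_tmb(pd.concat([a, b]), samples)["n_mut"]
        assert (tab == ta + tb).all()

    def test_nonpositive_capture_rejected(self):
        with pytest.raises(ConfigError):
            compute_tmb(_maf([]), ["S1"], capture_mb=0)


def _surv(n, seed, tmb_effect=None):
    rng = np.random.default_rng(seed)
    idx = [f"S{i}" for i in range(n)]
    tmb = pd.Series(rng.exponential(2.0, n), index=idx)
    if tmb_effect is None:
        rate = 1 / 500
    else:
        rate = np.where(tmb > tmb_effect, 0.5 / 500, 1 / 500)  # hazard halves above cut
    time = rng.exponential(1 / rate, n) if np.ndim(rate) else rng.exponential(500, n)
    event = (rng.random(n) < 0.8).astype(int)
    clin = pd.DataFrame({"time": time, "event": event}, index=idx)
    return tmb, clin


def brute_force_cutpoint(tmb, clin, min_prop=0.1):
    """Oracle: lifelines log-rank at every admissible observed value."""
    from lifelines.statistics import logrank_test

    v = tmb.to_numpy()
    uniq = np.unique(v)
    n = v.size
    best = None
    for c in uniq:
        le = (v <= c).sum() / n
        if le < min_prop or le > 1 - min_prop:
            continue
        hi = v > c
        if hi.all() or (~hi).all():
            continue
        r = logrank_test(
            clin["time"][hi], clin["time"][~hi], clin["event"][hi], clin["event"][~hi]
        )
        z = np.sqrt(r.test_statistic)
        if best is None or z > best[0]:
            best = (z, c)
    return best


class TestSurvCutpoint:
    def test_matches_brute_force_on_random_instances(self):
        for seed in range(5):
            tmb, clin = _surv(60, seed)
            res = surv_cutpoint(tmb, clin)
            z_ref, c_ref = brute_force_cutpoint(tmb, clin)
            assert res.cutpoint == pytest.approx(c_ref)
            assert res.max_stat == pytest.approx(z_ref, rel=1e-8)

    def test_recovers_planted_changepoint(self):
        hits = 0
        for seed in range(10):
            tmb, clin = _surv(400, seed, tmb_effect=2.0)
            res = surv_cutpoint(tmb, clin)
            hits += 1.5 <= res.cutpoint <= 2.5
        assert hits >= 8

    def test_candidate_window_excludes_extremes(self):
        idx = [f"S{i}" for i in range(12)]
        tmb = pd.Series(np.arange(12, dtype=float), index=idx)
        rng = np.random.default_rng(1)
        clin = pd.DataFrame(
            {"time": rng.exponential(500, 12), "event": np.ones(12, int)}, index=idx
        )
        res = surv_cutpoint(tmb, clin, min_prop=0.2)
        # cut leaving < 20% on a side can never be chosen
        frac_le = (tmb <= res.cutpoint).mean()
        assert 0.2 <= frac_le <= 0.8

    def test_constant_marker_rejected(self):
        idx = ["A", "B", "C"]
        tmb = pd.Series(1.0, index=idx)
        clin = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 1]}, index=idx)
        with pytest.raises(DataError, match="equal"):
            surv_cutpoint(tmb, clin)

    def test_restricting_grid_never_raises_max(self):
        tmb, clin = _surv(80, 3)
        wide = surv_cutpoint(tmb, clin, min_prop=0.1)
        narrow = surv_cutpoint(tmb, clin, min_prop=0.3)
        assert narrow.max_stat <= wide.max_stat + 1e-12


class TestMutationFrequency:
    def test_single_sample_single_gene(self):
        maf = _maf([("TTN", "S1", "Missense_Mutation")])
        groups = pd.Series({"S1": "high", "S2": "low"})
        per_gene, overall = mutation_frequency_by_group(maf, groups)
        assert per_gene.loc["TTN", "high"] == 1.0
        assert per_gene.loc["TTN", "low"] == 0.0
        assert overall["high"] == 1.0 and overall["low"] == 0.0

    def test_sample_without_rows_counts_in_denominator(self):
        maf = _maf([("TTN", "S1", "Silent")])
        groups = pd.Series({"S1": "high", "S2": "high"})
        per_gene, overall = mutation_frequency_by_group(maf, groups)
        assert per_gene.loc["TTN", "high"] == 0.5  # any class counts; S2 dilutes
        assert overall["high"] == 0.5

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(7)
        samples = [f"S{i}" for i in range(30)]
        maf = simulate_maf(samples, rate_per_sample=2, seed=7)
        groups = pd.Series(rng.choice(["high", "low"], 30), index=samples)
        per_gene, overall = mutation_frequency_by_group(maf, groups)
        for gene in per_gene.index:
            for lab in ("high", "low"):
                members = [s for s in samples if groups[s] == lab]
                expected = np.mean(
                    [
                        ((maf["Hugo_Symbol"] == gene) & (maf["Tumor_Sample_Barcode"] == s)).any()
                        for s in members
                    ]
                )
                assert per_gene.loc[gene, lab] == pytest.approx(expected)


class TestCompareScoresByGroup:
    def _setup(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"S{i}" for i in range(n)]
        groups = pd.Series(["high"] * (n // 2) + ["low"] * (n // 2), index=idx)
        risk = pd.Series(np.r_[rng.normal(1, 0.3, n // 2), rng.normal(0, 0.3, n // 2)], index=idx)
        return idx, groups, risk, rng

    def test_identity_feature_has_rho_one(self):
        idx, groups, risk, rng = self._setup()
        table = pd.DataFrame({"self": risk}, index=idx)
        res = compare_scores_by_group(table, groups, risk).set_index("feature")
        assert res.loc["self", "spearman_rho"] == pytest.approx(1.0)

    def test_identical_distribution_feature_is_null(self):
        idx, groups, risk, rng = self._setup()
        table = pd.DataFrame({"flat": np.ones(len(idx)), "noise": rng.normal(size=len(idx))}, index=idx)
        res = compare_scores_by_group(table, groups, risk).set_index("feature")
        assert res.loc["flat", "p"] == 1.0
        assert res.loc["flat", "spearman_rho"] == 0.0
        assert res.loc["noise", "p"] > 0.001

    def test_small_instance_matches_exact_permutation_enumeration(self):
        # n=8 (4 per arm): the rank-sum null distribution enumerated exactly
        idx = [f"S{i}" for i in range(8)]
        groups = pd.Series(["high"] * 4 + ["low"] * 4, index=idx)
        vals = np.array([1.3, 0.7, 2.9, 2.1, 0.4, 1.9, 0.2, 0.8])
        table = pd.DataFrame({"f": vals}, index=idx)
        risk = pd.Series(np.arange(8, dtype=float), index=idx)
        res = compare_scores_by_group(table, groups, risk).set_index("feature")

        ranks = stats.rankdata(vals)
        observed = ranks[:4].sum()
        null = [sum(c) for c in itertools.combinations(ranks, 4)]
        null = np.array(null)
        mu = null.mean()
        p_exact = np.mean(np.abs(null - mu) >= abs(observed - mu) - 1e-12)
        assert res.loc["f", "p"] == pytest.approx(p_exact, abs=1e-12)

    def test_sparse_feature_skipped(self):
        idx, groups, risk, rng = self._setup(n=10)
        col = pd.Series(rng.normal(size=10), index=idx)
        col.iloc[:4] = np.nan  # leaves 1 obs in 'high'
        table = pd.DataFrame({"sparse": col}, index=idx)
        with pytest.warns(UserWarning, match="skipped"):
            res = compare_scores_by_group(table, groups, risk)
        assert len(res) == 0
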