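import numpy as np
import pandas as pd
import pytest

import radstab as rs
from radstab.survival import (
    ModelConfig,
    compare_models,
    draw_bootstrap,
    evaluate_model,
    fdr_adjust,
    oob_fraction,
    rank_features_bootstrap,
    redundancy_filter,
    risk_dichotomize,
    select_pool,
    significance_stars,
)


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_bh_two_values(self):
        q = fdr_adjust([0.01, 0.04])
        assert np.allclose(q, [0.02, 0.04])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        assert (fdr_adjust(p) >= p - 1e-15).all()

    def test_monotone_in_p_rank(self):
        p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
        q = fdr_adjust(p)
        assert (np.diff(q) >= -1e-15).all()


class TestBootstrap:
    def test_oob_is_complement_of_inbag(self):
        rng = np.random.default_rng(1)
        in_bag, oob = draw_bootstrap(20, rng)
        assert len(in_bag) == 20
        assert set(oob) == set(range(20)) - set(in_bag)

    def test_closed_form_expectation(self):
        # E[OOB fraction] = (1 - 1/n)^n
        n = 140
        expect = (1 - 1 / n) ** n
        assert oob_fraction(n, 3000, seed=5) == pytest.approx(expect, abs=0.01)
        assert expect == pytest.approx(0.3666, abs=1e-4)


class TestDichotomize:
    def test_median_split(self):
        high = risk_dichotomize([1, 2, 3, 4], 2.5)
        assert list(high) == [False, False, True, True]

    def test_tie_at_median_goes_low(self):
        assert not risk_dichotomize([2.5], 2.5)[0]

    def test_all_equal_single_group(self):
        high = risk_dichotomize([1.0, 1.0, 1.0], 1.0)
        assert not high.any()


class TestRedundancy:
    @staticmethod
    def _corr(df):
        return df.corr()

    def test_duplicate_top_feature_excluded(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=50)
        df = pd.DataFrame({"a": a, "a2": a, "b": rng.normal(size=50)})
        kept = redundancy_filter(["a", "a2", "b"], df.corr(), 0.75)
        assert kept == ["a", "b"]

    def test_negative_duplicate_also_excluded(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=50)
        df = pd.DataFrame({"a": a, "neg": -a})
        assert redundancy_filter(["a", "neg"], df.corr(), 0.75) == ["a"]

    def test_orthogonal_features_kept_up_to_k(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(500, 5)), columns=list("abcde"))
        kept = redundancy_filter(list("abcde"), df.corr(), 0.75, max_size=3)
        assert kept == ["a", "b", "c"]

    def test_hand_walk_on_constructed_correlations(self):
        # z1..z3 independent; f1=z1, f2=0.95-correlated with f1, f3=z2,
        # f4 mixes z1/z2 at ~0.5 correlation with both, f5=z3
        rng = np.random.default_rng(5)
        n = 20000
        z = rng.normal(size=(n, 3))
        df = pd.DataFrame(
            {
                "f1": z[:, 0],
                "f2": 0.95 * z[:, 0] + np.sqrt(1 - 0.95**2) * rng.normal(size=n),
                "f3": z[:, 1],
                "f4": 0.5 * z[:, 0] + 0.5 * z[:, 1] + np.sqrt(0.5) * rng.normal(size=n),
                "f5": z[:, 2],
            }
        )
        # hand walk at R=0.75: keep f1; drop f2 (|r|~0.95); keep f3, f4, f5
        kept = redundancy_filter(["f1", "f2", "f3", "f4", "f5"], df.corr(), 0.75)
        assert kept == ["f1", "f3", "f4", "f5"]

    def test_empty_pool(self):
        assert redundancy_filter([], pd.DataFrame(), 0.75) == []


def _welch_oracle_on_logs(a, b):
    la, lb = np.log(a), np.log(b)
    na, nb = len(la), len(lb)
    va, vb = la.var(ddof=1) / na, lb.var(ddof=1) / nb
    tstat = (la.mean() - lb.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    from scipy import stats

    return tstat, float(stats.t.sf(tstat, df))


class TestCompareModels:
    def test_identical_vectors_p_half(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert compare_models(v, v)["p"] == pytest.approx(0.5)

    def test_textbook_welch_oracle(self):
        a = np.array([1.0, 2.0, 4.0, 8.0])
        b = np.array([1.0, 1.0, 2.0, 2.0])
        t_exp, p_exp = _welch_oracle_on_logs(a, b)
        res = compare_models(a, b)
        assert res["t"] == pytest.approx(t_exp, abs=1e-12)
        assert res["p"] == pytest.approx(p_exp, abs=1e-12)

    def test_shifted_distribution_detected(self):
        rng = np.random.default_rng(6)
        b = rng.chisquare(1, size=400) + 1e-6
        a = b * 3.0
        assert compare_models(a, b)["p"] < 1e-10

    def test_zeros_and_nans_dropped_with_count(self):
        a = np.array([np.nan, 0.0, 1.0, 2.0, 3.0])
        b = np.array([1.0, 1.0, 2.0, 2.0])
        res = compare_models(a, b)
        assert res["dropped_a"] == 2 and res["n_a"] == 3

    def test_too_few_rounds_flagged(self):
        res = compare_models([1.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(res["p"]) and res["stars"] == "na"

    @pytest.mark.parametrize("p,star", [(1e-6, "***"), (1e-4, "**"), (0.01, "*"), (0.2, "ns")])
    def test_stars(self, p, star):
        assert significance_stars(p) == star


class TestRanking:
    def test_planted_predictor_tops_ranking(self, planted_cohort):
        cohort, _ = planted_cohort
        pool = ["sig0_s", "null0_s", "null1_s", "null2_s"]
        ranks = rank_features_bootstrap(cohort, pool, n_boot=30, seed=3)
        assert ranks.idxmax() == "sig0_s"

    def test_duplicate_features_tie(self, planted_cohort):
        cohort, _ = planted_cohort
        dup = cohort.features.copy()
        dup["copy"] = dup["sig0_s"]
        c2 = rs.SurvivalCohort(dup, cohort.time, cohort.event)
        ranks = rank_features_bootstrap(c2, ["sig0_s", "copy"], n_boot=10, seed=1)
        assert ranks["sig0_s"] == pytest.approx(ranks["copy"])


class TestEvaluateModel:
    def test_pool_selection_applies_pq_then_cov(self, planted_cohort):
        cohort, _ = planted_cohort
        cfg = ModelConfig(cov_cutoff=5.0, p_cutoff=0.01, q_cutoff=0.05, n_boot=5, seed=0)
        pool = select_pool(cohort, cfg)
        assert set(pool) <= {"sig0_s", "sig1_s", "sig2_s"}
        assert pool  # clean planted features survive both screens

    def test_same_seed_identical_chi2(self, planted_cohort):
        cohort, _ = planted_cohort
        cfg = ModelConfig(cov_cutoff=5.0, n_boot=20, seed=42)
        e1 = evaluate_model(cohort, cfg)
        e2 = evaluate_model(cohort, cfg)
        assert np.array_equal(e1.chi2, e2.chi2, equal_nan=True)
        assert e1.final_model == e2.final_model

    def test_infeasible_on_empty_pool(self, planted_cohort):
        cohort, _ = planted_cohort
        cfg = ModelConfig(cov_cutoff=1e-9, p_cutoff=1e-12, q_cutoff=1e-12, n_boot=5, seed=0)
        ev = evaluate_model(cohort, cfg)
        assert ev.infeasible and np.isnan(ev.chi2).all()

    def test_null_pool_chi2_near_chi2_1df_median(self, null_cohort):
        # OOB is independent of in-bag selection, so under the null the
        # OOB logrank chi2 follows chi2(1df): median 0.4549
        cohort, _ = null_cohort
        cfg = ModelConfig(cov_cutoff=None, p_cutoff=1.0, q_cutoff=1.1, n_boot=150, seed=7)
        ev = evaluate_model(cohort, cfg)
        med = np.nanmedian(ev.chi2)
        assert 0.25 < med < 0.75

    def test_clinical_covariates_never_enter(self, planted_cohort):
        cohort, _ = planted_cohort
        cfg = ModelConfig(cov_cutoff=5.0, n_boot=5, seed=0)
        ev = evaluate_model(cohort, cfg)
        clinical_cols = set(cohort.clinical.columns)
        for sel in ev.selections:
            assert not (set(sel) & clinical_cols)

    def test_stable_config_beats_unfiltered(self, planted_cohort):
        cohort, _ = planted_cohort
        ev_a = evaluate_model(cohort, ModelConfig(cov_cutoff=5.0, n_boot=100, seed=5))
        ev_b = evaluate_model(cohort, ModelConfig(cov_cutoff=None, n_boot=100, seed=5))
        assert compare_models(ev_a.chi2, ev_b.chi2)["p"] < 0.05


class TestGrid:
    def test_single_cell_equals_direct_calls(self, planted_cohort):
        cohort, _ = planted_cohort
        base = ModelConfig(n_boot=20, seed=9)
        grid = rs.cutoff_grid(cohort, base, cov_cutoffs=(5.0,), pq_pairs=((0.01, 0.05),))
        from dataclasses import replace

        ev_a = evaluate_model(cohort, replace(base, cov_cutoff=5.0))
        ev_b = evaluate_model(cohort, replace(base, cov_cutoff=None))
        expect = compare_models(ev_a.chi2, ev_b.chi2)["p"]
        assert grid.p_matrix.iloc[0, 0] == pytest.approx(expect)

    def test_infeasible_cell_is_nan(self, planted_cohort):
        cohort, _ = planted_cohort
        grid = rs.cutoff_grid(
            cohort, ModelConfig(n_boot=5, seed=0), cov_cutoffs=(1e-9,), pq_pairs=((0.01, 0.05),)
        )
        assert np.isnan(grid.p_matrix.iloc[0, 0])
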