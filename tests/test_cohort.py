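import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crcest.cohort import (
    CohortModel,
    MissingColumnError,
    RankDeficiencyError,
    SingularFitError,
    compare_groups_rank,
    detect_interaction,
    fit_linear_models_per_muscle,
    fit_mixed_model,
    generate_cohort,
    summarize_cohort,
)
from crcest.cohort import test_normality as normality_pvalue


class TestNormality:
    def test_normal_draws_rarely_rejected(self):
        rng = np.random.default_rng(0)
        hits = sum(
            normality_pvalue(rng.normal(size=500)) > 0.05 for _ in range(100)
        )
        assert hits >= 90

    def test_exponential_draws_rejected(self):
        rng = np.random.default_rng(12)
        hits = sum(
            normality_pvalue(rng.exponential(size=500)) < 0.05
            for _ in range(100)
        )
        assert hits >= 95

    def test_preconditions(self):
        with pytest.raises(ValueError):
            normality_pvalue([1.0, 2.0])
        with pytest.raises(ValueError):
            normality_pvalue([3.0, 3.0, 3.0, 3.0])


class TestRankComparison:
    def test_identical_groups(self):
        stat, p = compare_groups_rank([1, 2, 3.0], [1, 2, 3.0])
        assert p > 0.9

    def test_all_tied_no_crash(self):
        stat, p = compare_groups_rank([2.0, 2.0], [2.0, 2.0, 2.0])
        assert stat == 0.0 and p == 1.0

    def test_small_case_matches_exhaustive_ranks(self):
        # brute-force two-group Kruskal–Wallis from the rank definition:
        # H = 12/(N(N+1)) Σ n_i (R̄_i − (N+1)/2)², no ties
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        pooled = np.array(a + b)
        ranks = stats.rankdata(pooled)
        n, N = 3, 6
        rbar_a, rbar_b = ranks[:3].mean(), ranks[3:].mean()
        h = 12.0 / (N * (N + 1)) * (
            n * (rbar_a - (N + 1) / 2) ** 2 + n * (rbar_b - (N + 1) / 2) ** 2
        )
        stat, _ = compare_groups_rank(a, b)
        assert stat == pytest.approx(h)

    def test_detects_large_shift(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 1, 20)
            b = rng.normal(3, 1, 20)  # 3 pooled sd shift
            _, p = compare_groups_rank(a, b)
            hits += p < 0.001
        assert hits >= 99

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(14)
        a = rng.normal(5, 1, 15)
        b = rng.normal(6, 1, 15)
        s1, p1 = compare_groups_rank(a, b)
        s2, p2 = compare_groups_rank(np.exp(a), np.exp(b))
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)


class TestGenerateCohort:
    def test_shape_and_determinism(self):
        t1 = generate_cohort(seed=5)
        t2 = generate_cohort(seed=5)
        assert len(t1) == 96
        assert t1["subject"].nunique() == 32
        pd.testing.assert_frame_equal(t1, t2)
        assert set(t1["muscle"]) == {"LG", "MG", "Sol"}

    def test_null_cohort_has_no_injected_effect(self):
        t = generate_cohort(seed=6, disease_effects={})
        means = t.groupby("disease")["tau_s"].mean()
        assert abs(means["FRDA"] - means["control"]) < 80


class TestMixedModel:
    def test_soleus_effect_recovered_within_ci(self):
        # +0.50 % soleus intercept injected; CI covers the truth in ≥ 90%
        # of replicates at the observed cohort size and dispersion;
        # soleus control median set to LG + 0.50
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            t = generate_cohort(
                seed=1000 + rep,
                disease_effects={},
                control_medians={"resting_pct": {"MG": 6.2, "Sol": 6.7,
                                                 "LG": 6.2}},
            )
            res = fit_mixed_model(t, "resting_pct", "Model 1")
            lo, hi = res.ci("muscle_Sol")
            hits += lo <= 0.5 <= hi
        assert hits >= 90

    def test_null_effects_covered_at_nominal_rate(self):
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            t = generate_cohort(seed=2000 + rep, disease_effects={})
            res = fit_mixed_model(t, "resting_pct", "Model 1")
            lo, hi = res.ci("FRDA")
            hits += lo <= 0.0 <= hi
        assert hits >= 85  # nominal 95% minus binomial slack

    def test_degenerate_table_raises_singular(self):
        t = generate_cohort(n_control=1, n_frda=1, seed=3)
        with pytest.raises(SingularFitError):
            fit_mixed_model(t, "resting_pct", "Model 1")

    def test_model_suite_covariates_present(self):
        t = generate_cohort(seed=4)
        res = fit_mixed_model(t, "resting_pct", "Model 2")
        assert "bmi" in set(res.terms["term"])
        assert res.n_observations == 96 and res.n_subjects == 32

    def test_missing_covariate_named(self):
        t = generate_cohort(seed=4).drop(columns=["bmi"])
        with pytest.raises(MissingColumnError, match="bmi"):
            fit_mixed_model(t, "resting_pct", "Model 2")

    def test_tau_models_exclude_implausible_rows(self):
        t = generate_cohort(seed=4)
        t.loc[t.index[:6], "status"] = "excluded_low"
        res = fit_mixed_model(t, "tau_s", "Model 1")
        assert res.n_observations == 90


class TestInteraction:
    def test_power_with_muscle_specific_effects(self):
        # muscle-specific disease effects at the observed median gaps:
        # interaction detected (p < 0.05) in ≥ 80% of replicates at n = 32
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            t = generate_cohort(seed=3000 + rep)  # default median-gap effects
            hits += detect_interaction(t, "tau_s") < 0.05
        assert hits >= 0.8 * n_rep

    def test_null_interaction_p_uniform(self):
        # additive generation: LR p-values uniform under the null
        rng_seeds = range(4000, 4100)
        pvals = []
        for seed in rng_seeds:
            t = generate_cohort(
                seed=seed,
                disease_effects={"tau_s": {"LG": 100.0, "MG": 100.0,
                                           "Sol": 100.0}},
            )
            pvals.append(detect_interaction(t, "tau_s"))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_single_muscle_errors(self):
        t = generate_cohort(seed=1)
        with pytest.raises(ValueError):
            detect_interaction(t[t["muscle"] == "LG"], "tau_s")


class TestPerMuscleModels:
    def test_disease_effect_recovered(self):
        # injected LG disease effect at the observed median gap (+136 s)
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            t = generate_cohort(seed=5000 + rep)
            res = fit_linear_models_per_muscle(t, "tau_s", ["Model 1"])
            lg = [r for r in res if r.muscle == "LG"][0]
            lo, hi = lg.ci("FRDA")
            hits += lo <= 136.0 <= hi
        assert hits >= 90

    def test_null_coverage(self):
        hits = 0
        for rep in range(100):
            t = generate_cohort(seed=6000 + rep, disease_effects={})
            res = fit_linear_models_per_muscle(t, "delta_pct", ["Model 1"])
            lg = [r for r in res if r.muscle == "LG"][0]
            lo, hi = lg.ci("FRDA")
            hits += lo <= 0.0 <= hi
        assert hits >= 85

    def test_collinear_covariates_raise(self):
        t = generate_cohort(seed=7)
        t["leg_lean_mass"] = t["height"]  # perfectly collinear pair
        from crcest.cohort import OLS_SUITES

        OLS_SUITES["tau_s"]["_collinear"] = ["height", "leg_lean_mass"]
        try:
            with pytest.raises(RankDeficiencyError):
                fit_linear_models_per_muscle(t, "tau_s", ["_collinear"])
        finally:
            del OLS_SUITES["tau_s"]["_collinear"]

    def test_labels_match_suite(self):
        t = generate_cohort(seed=8)
        res = fit_linear_models_per_muscle(t, "tau_s")
        labels = {(r.muscle, r.model) for r in res}
        assert labels == {
            (m, f"Model {i}") for m in ("LG", "MG", "Sol") for i in (1, 2, 3)
        }


class TestSummaries:
    def test_median_and_iqi(self):
        vals = np.array([1.0, 2, 3, 4, 5])
        t = pd.DataFrame(
            {
                "subject": [f"S{i}" for i in range(5)],
                "disease": "control",
                "muscle": "LG",
                "resting_pct": vals,
                "status": "ok",
            }
        )
        out = summarize_cohort(t)
        row = out.iloc[0]
        assert row["median"] == 3 and row["iqi_low"] == 2 and row["iqi_high"] == 4

    def test_percentiles_match_sort_oracle(self):
        rng = np.random.default_rng(20)
        t = generate_cohort(seed=20)
        out = summarize_cohort(t)
        sub = t[(t.disease == "control") & (t.muscle == "LG")]["tau_s"]
        row = out[(out.outcome == "tau_s") & (out.disease == "control")
                  & (out.muscle == "LG")].iloc[0]
        assert row["median"] == pytest.approx(np.percentile(sub, 50))
        assert row["iqi_low"] == pytest.approx(np.percentile(sub, 25))

    def test_constant_tau_summarized_exactly(self):
        t = generate_cohort(seed=21, residual_sd={"resting_pct": 0.0,
                                                  "delta_pct": 0.0,
                                                  "tau_s": 0.0},
                            subject_sd={"resting_pct": 0.0,
                                        "delta_pct": 0.0,
                                        "tau_s": 0.0},
                            disease_effects={})
        out = summarize_cohort(t)
        row = out[(out.outcome == "tau_s") & (out.muscle == "LG")
                  & (out.disease == "control")].iloc[0]
        assert row["median"] == pytest.approx(138.0)


class TestCohortModelFrontDoor:
    def test_round_trip_and_summary(self, tmp_path):
        t = generate_cohort(seed=30)
        path = tmp_path / "cohort.csv"
        t.to_csv(path, index=False)
        model = CohortModel.from_csv(path)
        res = model.fit_mixed("resting_pct")
        assert "FRDA" in res.summary()
        frame = res.to_frame()
        assert {"outcome", "model", "term", "beta", "p"} <= set(frame.columns)
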