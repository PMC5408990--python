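"""Weighted Cox engine: oracles, invariances, and the carrier model battery."""

import math

import numpy as np
import pandas as pd
import pytest

import carrierprs as cp
from carrierprs.cox import AgeTerm


def _frame(time, event, entry=None, **cols):
    n = len(time)
    df = pd.DataFrame(
        {
            "individual_id": [f"i{j}" for j in range(n)],
            "family_id": [f"f{j}" for j in range(n)],
            "study": "S1",
            "gene": "BRCA1",
            "affected": np.asarray(event, bool),
            "age_end": np.asarray(time, float),
            "age_entry": 18.0 if entry is None else np.asarray(entry, float),
        }
    )
    X = pd.DataFrame({k: np.asarray(v, float) for k, v in cols.items()})
    return df, X


def _exponential_two_group(n, rate_ratio, seed, rate0=0.05):
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n).astype(float)
    T = 18.0 + rng.exponential(1.0 / (rate0 * rate_ratio**x))
    C = 18.0 + rng.uniform(5.0, 60.0, n)
    time = np.minimum(np.minimum(T, C), 99.0)
    event = (T <= C) & (T < 99.0)
    return _frame(time, event, x=x)


class TestEngine:
    def test_recovers_exponential_rate_ratio(self):
        cohort, X = _exponential_two_group(10_000, 2.0, seed=0)
        fit = cp.fit_weighted_cox(cohort, X)
        assert fit.converged
        assert fit.params[0] == pytest.approx(math.log(2), abs=3 * fit.robust_se[0])

    def test_null_covariate(self):
        rng = np.random.default_rng(4)
        cohort, X = _exponential_two_group(4000, 1.0, seed=4)
        X["x"] = rng.normal(size=len(cohort))
        fit = cp.fit_weighted_cox(cohort, X)
        assert abs(fit.params[0]) < 3 * fit.robust_se[0] + 0.02

    def test_gradient_norm_at_optimum(self, scored_cohort):
        cohort, result = scored_cohort
        fit = cp.fit_continuous_prs(cohort, result.table["prs_std"])
        assert fit.gradient_norm < 1e-8

    def test_matches_lifelines_with_unit_weights(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(2)
        n = 200
        entry = rng.uniform(18, 30, n)
        T = entry + rng.exponential(25, n)
        C = entry + rng.uniform(5, 50, n)
        time = np.minimum(np.minimum(T, C), 99.9)
        event = (T <= C) & (T < 99.9)
        x1 = rng.normal(size=n)
        x2 = rng.binomial(2, 0.3, n).astype(float)
        cohort, X = _frame(time, event, entry=entry, x1=x1, x2=x2)
        fit = cp.fit_weighted_cox(cohort, X, weights=np.ones(n))
        cph = lifelines.CoxPHFitter()
        cph.fit(
            pd.DataFrame({"T": time, "E": event, "entry": entry, "x1": x1, "x2": x2}),
            duration_col="T", event_col="E", entry_col="entry",
        )
        assert np.abs(fit.params - cph.params_.to_numpy()).max() < 1e-6

    def test_matches_lifelines_with_sampling_weights(self):
        lifelines = pytest.importorskip("lifelines")
        import warnings

        rng = np.random.default_rng(3)
        n = 300
        entry = rng.uniform(18, 30, n)
        T = entry + rng.exponential(20, n)
        C = entry + rng.uniform(5, 40, n)
        time = np.minimum(T, C)
        event = T <= C
        x1 = rng.normal(size=n)
        x2 = rng.binomial(2, 0.3, n).astype(float)
        w = rng.uniform(0.3, 3.0, n)
        cohort, X = _frame(time, event, entry=entry, x1=x1, x2=x2)
        fit = cp.fit_weighted_cox(cohort, X, weights=w, cluster=None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = lifelines.CoxPHFitter()
            cph.fit(
                pd.DataFrame({"T": time, "E": event, "entry": entry,
                              "x1": x1, "x2": x2, "w": w}),
                duration_col="T", event_col="E", entry_col="entry",
                weights_col="w",
            )
        assert np.abs(fit.params - cph.params_.to_numpy()).max() < 1e-6

    def test_weight_scale_invariance(self, scored_cohort):
        cohort, result = scored_cohort
        z = result.table["prs_std"]
        w = np.random.default_rng(1).uniform(0.5, 2.0, len(cohort))
        f1 = cp.fit_continuous_prs(cohort, z, weights=w)
        f2 = cp.fit_continuous_prs(cohort, z, weights=2 * w)
        assert np.allclose(f1.params, f2.params, atol=1e-9)

    def test_slow_path_equals_fast_path(self):
        # an age term with a constant transform is an ordinary covariate
        cohort, X = _exponential_two_group(800, 1.6, seed=6)
        fast = cp.fit_weighted_cox(cohort, X)
        slow = cp.fit_weighted_cox(
            cohort, None,
            age_terms=[AgeTerm("x", X["x"].to_numpy(), lambda t: 1.0)],
        )
        assert np.allclose(fast.params, slow.params, atol=1e-8)
        assert np.allclose(fast.robust_cov, slow.robust_cov, rtol=1e-6, atol=1e-12)

    def test_efron_close_to_breslow_on_continuous_times(self):
        cohort, X = _exponential_two_group(600, 1.8, seed=8)
        b = cp.fit_weighted_cox(cohort, X, ties="breslow")
        e = cp.fit_weighted_cox(cohort, X, ties="efron")
        # no exact ties in continuous data: identical results
        assert np.allclose(b.params, e.params, atol=1e-10)

    def test_efron_differs_under_heavy_ties(self):
        rng = np.random.default_rng(9)
        n = 300
        x = rng.normal(size=n)
        T = 20.0 + np.round(rng.exponential(10.0 / np.exp(0.5 * x)))
        C = np.full(n, 45.0)
        time = np.minimum(np.minimum(T, C), 99.0)
        event = T <= C
        cohort, X = _frame(time, event, x=x)
        b = cp.fit_weighted_cox(cohort, X, ties="breslow")
        e = cp.fit_weighted_cox(cohort, X, ties="efron")
        assert not np.allclose(b.params, e.params, atol=1e-6)
        # Efron is closer to the generating value under ties
        assert abs(e.params[0] - 0.5) <= abs(b.params[0] - 0.5) + 0.02

    def test_strata_separate_baselines(self):
        # two strata with very different baseline rates but a shared effect
        c1, X1 = _exponential_two_group(2000, 1.7, seed=10, rate0=0.02)
        c2, X2 = _exponential_two_group(2000, 1.7, seed=11, rate0=0.10)
        c2["study"] = "S2"
        c2["individual_id"] = "b" + c2["individual_id"]
        cohort = pd.concat([c1, c2], ignore_index=True)
        X = pd.concat([X1, X2], ignore_index=True)
        fit = cp.fit_weighted_cox(cohort, X, strata="study")
        assert fit.params[0] == pytest.approx(math.log(1.7), abs=3.5 * fit.robust_se[0])

    def test_robust_equals_model_free_sandwich_per_individual(self):
        cohort, X = _exponential_two_group(500, 1.5, seed=12)
        f_default = cp.fit_weighted_cox(cohort, X, cluster=None)
        f_rows = cp.fit_weighted_cox(
            cohort, X, cluster=np.arange(len(cohort))
        )
        assert np.allclose(f_default.robust_cov, f_rows.robust_cov, atol=1e-12)

    def test_cluster_robust_tracks_frailty_variance(self):
        # shared family frailty inflates the sampling variance; the cluster
        # sandwich should track it while the model-based SE undercovers
        rng = np.random.default_rng(20)
        estimates, naive_se, robust_se = [], [], []
        for rep in range(25):
            spec = cp.make_study_spec(
                "brca1_bc", n_target=800, seed=500 + rep, hr_per_sd=1.0,
                family_frailty_sd=1.0, family_size=5,
                ascertain_prob_unaffected=1.0,
            )
            cohort, gmat, _ = cp.gen_cohort(spec)
            z = rng.standard_normal(len(cohort))
            # family-shared covariate: strongest clustering effect
            fam_codes = cohort["family_id"].astype("category").cat.codes
            z = np.asarray(pd.Series(z).groupby(fam_codes).transform("mean"))
            fit = cp.fit_continuous_prs(cohort, z, cluster="family_id")
            estimates.append(fit.params[0])
            naive_se.append(fit.se[0])
            robust_se.append(fit.robust_se[0])
        emp_sd = np.std(estimates, ddof=1)
        assert np.mean(robust_se) == pytest.approx(emp_sd, rel=0.35)
        assert np.mean(robust_se) > 1.2 * np.mean(naive_se)

    def test_separation_detected(self):
        # perfectly separating covariate: event iff x = 1 and x-ordering of
        # times is monotone
        time = np.array([30.0, 31, 32, 33, 60, 61, 62, 63])
        event = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        x = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
        cohort, X = _frame(time, event, x=x)
        with pytest.raises(cp.ConvergenceError):
            cp.fit_weighted_cox(cohort, X)

    def test_constant_covariate_rejected(self):
        cohort, X = _exponential_two_group(100, 1.0, seed=13)
        X["x"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cp.fit_weighted_cox(cohort, X)

    def test_nested_loglik_ordering(self, scored_cohort):
        cohort, result = scored_cohort
        z = result.table["prs_std"]
        reduced = cp.fit_continuous_prs(cohort, z)
        full = cp.fit_age_interaction(cohort, z)
        assert full.loglik >= reduced.loglik - 1e-8


class TestPercentileModel:
    def test_null_categories_flat(self):
        spec = cp.make_study_spec("brca1_bc", n_target=3000, seed=23, hr_per_sd=1.0)
        cohort, gmat, _ = cp.gen_cohort(spec)
        res = cp.score_cohort(cp.weight_table_for_spec(spec), gmat,
                              scheme=cp.PercentileScheme())
        fit = cp.fit_percentile_model(cohort, res.table["category"])
        assert np.all(np.abs(fit.params) < 3.5 * fit.robust_se + 0.05)

    def test_trend_and_match_to_theory(self):
        spec = cp.make_study_spec("brca1_bc", n_target=12_000, seed=24)
        cohort, gmat, _ = cp.gen_cohort(spec)
        res = cp.score_cohort(cp.weight_table_for_spec(spec), gmat,
                              scheme=cp.PercentileScheme())
        w = cp.build_weights(cohort, cp.marginal_incidence(spec))
        fit = cp.fit_percentile_model(cohort, res.table["category"], weights=w)
        labels = [t.removeprefix("prs_") for t in fit.terms]
        est = dict(zip(labels, fit.params))
        se = dict(zip(labels, fit.robust_se))
        edges = {"0-5": (0, 5), "95-100": (95, 100), "60-80": (60, 80)}
        for label, interval in edges.items():
            theory = math.log(
                cp.theoretical_category_hr(spec.beta_sd, interval)
            )
            assert est[label] == pytest.approx(theory, abs=3.5 * se[label])
        # monotone nondecreasing trend across ordered categories
        ordered = ["0-5", "5-10", "10-20", "20-40", "60-80", "80-90", "90-95", "95-100"]
        values = [est[o] for o in ordered]
        assert values[-1] > values[0]
        assert np.all(np.diff(values) > -0.25)

    def test_empty_category_rejected(self, scored_cohort):
        cohort, result = scored_cohort
        cats = pd.Categorical(
            ["40-60"] * (len(cohort) - 1) + ["95-100"],
            categories=cp.PercentileScheme().labels,
        )
        with pytest.raises(ValueError, match="coarser"):
            cp.fit_percentile_model(cohort, cats)


class TestAgeModels:
    def test_no_decay_interaction_near_one(self):
        spec = cp.make_study_spec("brca1_bc", n_target=6000, seed=25)
        cohort, gmat, _ = cp.gen_cohort(spec)
        res = cp.score_cohort(cp.weight_table_for_spec(spec), gmat)
        w = cp.build_weights(cohort, cp.marginal_incidence(spec))
        fit = cp.fit_age_interaction(cohort, res.table["prs_std"], weights=w)
        hr_year = math.exp(fit["prs_x_age"])
        assert hr_year == pytest.approx(
            1.0, abs=3.5 * fit.robust_se[fit.terms.index("prs_x_age")]
        )

    def test_fixed_covariate_fallback_runs(self, scored_cohort):
        cohort, result = scored_cohort
        fit = cp.fit_age_interaction(
            cohort, result.table["prs_std"], time_varying=False
        )
        assert set(fit.terms) == {"prs_per_sd", "prs_x_age"}

    def test_decaying_truth_youngest_band_strongest(self):
        spec = cp.make_study_spec(
            "brca1_bc", n_target=9000, seed=26,
            beta_age=(math.log(1.8), 0.99),
        )
        cohort, gmat, _ = cp.gen_cohort(spec)
        res = cp.score_cohort(cp.weight_table_for_spec(spec), gmat)
        w = cp.build_weights(cohort, cp.marginal_incidence(spec))
        fit = cp.fit_agegroup_model(cohort, res.table["prs_std"], weights=w)
        young = fit.params[0]
        old = fit.params[-1]
        assert young > old
        assert fit.band_contrasts is not None
        assert len(fit.band_contrasts) == 3

    def test_homogeneous_truth_bands_consistent(self):
        spec = cp.make_study_spec("brca1_bc", n_target=6000, seed=27)
        cohort, gmat, _ = cp.gen_cohort(spec)
        res = cp.score_cohort(cp.weight_table_for_spec(spec), gmat)
        fit = cp.fit_agegroup_model(cohort, res.table["prs_std"])
        assert (fit.band_contrasts["p_two_sided"] > 0.001).all()

    def test_empty_band_rejected(self, scored_cohort):
        cohort, result = scored_cohort
        with pytest.raises(ValueError, match="no events"):
            cp.fit_agegroup_model(
                cohort, result.table["prs_std"],
                age_bands=((18.0, 85.0), (85.0, np.inf)),
            )


class TestPairwiseScan:
    def test_single_snp_empty_table(self, scored_cohort):
        cohort, _ = scored_cohort
        dos = pd.DataFrame({"snp1": np.random.default_rng(0).integers(0, 3, len(cohort))})
        out = cp.pairwise_interaction_scan(cohort, dos.astype(float))
        assert len(out) == 0

    def test_monomorphic_skipped(self, scored_cohort):
        cohort, _ = scored_cohort
        rng = np.random.default_rng(1)
        dos = pd.DataFrame(
            {
                "snp1": rng.integers(0, 3, len(cohort)).astype(float),
                "snp2": np.ones(len(cohort)),
                "snp3": rng.integers(0, 3, len(cohort)).astype(float),
            }
        )
        with pytest.warns(UserWarning, match="monomorphic"):
            out = cp.pairwise_interaction_scan(cohort, dos)
        assert len(out) == 1  # only snp1 x snp3

    def test_injected_interaction_detected(self):
        rng = np.random.default_rng(30)
        n = 4000
        g1 = rng.binomial(2, 0.5, n).astype(float)
        g2 = rng.binomial(2, 0.5, n).astype(float)
        eta = 0.15 * g1 + 0.15 * g2 + 0.4 * g1 * g2
        T = 18.0 + rng.exponential(40.0 / np.exp(eta))
        C = 18.0 + rng.uniform(10, 60, n)
        time, event = np.minimum(np.minimum(T, C), 99.0), (T <= C) & (T < 99.0)
        cohort, _ = _frame(time, event)
        dos = pd.DataFrame({"snp1": g1, "snp2": g2})
        out = cp.pairwise_interaction_scan(cohort, dos)
        assert bool(out["significant"].iloc[0])
        assert out["coef"].iloc[0] == pytest.approx(0.4, abs=0.15)
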