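import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from oracles import efron_loglik_bruteforce
from priorcox.cox import (
    ConvergenceError,
    EfronPartialLikelihood,
    MCMCSettings,
    ModelSpec,
    PosteriorSummary,
    build_design,
    cox_partial_loglik,
    fit_bayes,
    fit_mle,
    read_trial_csv,
    shrinkage_report,
    summarise_posterior,
    write_trial_csv,
)
from priorcox.priors import BivariatePrior, build_vague_prior
from priorcox.simulate import SimulationConfig, generate_trial


def tied_dataset(seed=0, n=20):
    """Small dataset with heavy ties (integer days) and censoring."""
    rng = np.random.default_rng(seed)
    time = rng.integers(1, 6, size=n).astype(float)
    event = rng.random(n) < 0.8
    event[:2] = True  # ensure events exist
    X = np.column_stack([rng.integers(0, 2, n), rng.normal(size=n)])
    return time, event, X


class TestPartialLikelihood:
    def test_two_patient_null_closed_form(self):
        ll = cox_partial_loglik([1, 2], [1, 1], np.array([[1.0], [0.0]]), [0.0])
        assert ll == pytest.approx(-math.log(2), abs=1e-12)

    def test_two_patient_unit_beta_closed_form(self):
        ll = cox_partial_loglik([1, 2], [1, 1], np.array([[1.0], [0.0]]), [1.0])
        assert ll == pytest.approx(1 - math.log(math.e + 1), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_tied_data(self, seed):
        time, event, X = tied_dataset(seed)
        rng = np.random.default_rng(seed + 100)
        beta = rng.normal(scale=0.7, size=2)
        ours = cox_partial_loglik(time, event, X, beta)
        oracle = efron_loglik_bruteforce(time, event, X, beta)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_invariant_to_time_shift(self):
        time, event, X = tied_dataset(3)
        beta = np.array([0.5, -0.3])
        a = cox_partial_loglik(time, event, X, beta)
        b = cox_partial_loglik(time + 7.0, event, X, beta)
        assert a == pytest.approx(b, abs=1e-12)

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="no events"):
            cox_partial_loglik([1, 2], [0, 0], np.array([[1.0], [0.0]]), [0.0])

    def test_nonpositive_time_raises(self):
        with pytest.raises(ValueError, match="positive"):
            cox_partial_loglik([0, 2], [1, 1], np.array([[1.0], [0.0]]), [0.0])

    def test_non_finite_beta_raises(self):
        with pytest.raises(ValueError, match="finite"):
            cox_partial_loglik([1, 2], [1, 1], np.array([[1.0], [0.0]]), [np.inf])

    def test_gradient_matches_finite_differences(self):
        time, event, X = tied_dataset(4)
        pl = EfronPartialLikelihood(time, event, X)
        beta = np.array([0.3, -0.2])
        g = pl.gradient(beta)
        h = 1e-6
        for j in range(2):
            up, dn = beta.copy(), beta.copy()
            up[j] += h
            dn[j] -= h
            fd = (pl.loglik(up) - pl.loglik(dn)) / (2 * h)
            assert g[j] == pytest.approx(fd, abs=1e-5)


class TestMLE:
    def test_agrees_with_lifelines(self, trial_500, vague_spec):
        lifelines = pytest.importorskip("lifelines")
        mle = fit_mle(trial_500, vague_spec)
        time, event, X, names, _ = build_design(trial_500, vague_spec)
        df = pd.DataFrame(X, columns=names)
        df["T"] = time
        df["E"] = event.astype(int)
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        np.testing.assert_allclose(
            mle.beta, cph.params_[names].to_numpy(), atol=1e-4
        )
        np.testing.assert_allclose(
            mle.se, cph.standard_errors_[names].to_numpy(), atol=1e-4
        )

    def test_null_simulation_unbiased(self):
        # scaled down from 200 replicates at n=2000: 60 replicates suffice to
        # bound the mean within Monte-Carlo error of zero
        spec = ModelSpec(prior=build_vague_prior(), covariates=())
        estimates = []
        for seed in range(60):
            df = generate_trial(SimulationConfig(n=2000, seed=seed))
            mle = fit_mle(df, spec)
            estimates.append(mle.beta[:2])
        est = np.array(estimates)
        mc_err = est.std(axis=0) / np.sqrt(len(est))
        assert np.all(np.abs(est.mean(axis=0)) < 4 * mc_err + 0.005)

    def test_separation_warning(self):
        df = pd.DataFrame(
            {
                "id": [1, 2, 3, 4],
                "arm": [1, 0, 1, 0],
                "subgroup": pd.array([0, 0, 1, 1], dtype="Int64"),
                "time_days": [1.0, 2.0, 1.5, 2.5],
                "event": [1, 1, 1, 1],
            }
        )
        spec = ModelSpec(
            prior=build_vague_prior(), covariates=(), include_subgroup_main=False
        )
        with pytest.warns(UserWarning, match="separation"):
            fit_mle(df, spec)

    def test_too_few_events_raises(self):
        df = generate_trial(SimulationConfig(n=12, seed=0, censor_horizon_days=1.0))
        spec = ModelSpec(prior=build_vague_prior())
        with pytest.raises(ValueError):
            fit_mle(df, spec)

    def test_missing_subgroup_excluded_with_count(self):
        df = generate_trial(SimulationConfig(n=200, seed=1, missing_subgroup_n=3))
        spec = ModelSpec(prior=build_vague_prior())
        with pytest.warns(UserWarning, match="excluding 3"):
            mle = fit_mle(df, spec)
        assert mle.n_excluded == 3


class TestBayes:
    def test_vague_prior_matches_mle(self, trial_500, vague_spec, fast_mcmc):
        mle = fit_mle(trial_500, vague_spec)
        fit = fit_bayes(trial_500, vague_spec, fast_mcmc)
        for name in ("theta1", "theta2"):
            j = fit.names.index(name)
            post_med = np.log(fit.summaries[name].median_hr)
            assert post_med == pytest.approx(mle.beta[j], abs=0.05)

    def test_tiny_prior_variance_dominates_weak_data(self, fast_mcmc):
        prior = BivariatePrior(
            "clinical", np.array([0.5, -0.5]), np.eye(2) * 1e-6
        )
        df = generate_trial(SimulationConfig(n=150, seed=7))
        fit = fit_bayes(df, ModelSpec(prior=prior), fast_mcmc)
        assert np.log(fit.summaries["theta1"].median_hr) == pytest.approx(0.5, abs=0.01)
        assert np.log(fit.summaries["theta2"].median_hr) == pytest.approx(-0.5, abs=0.01)

    def test_matches_normal_normal_conjugate_approximation(self, fast_mcmc):
        # exponential event times (Weibull shape 1), informative prior; the
        # posterior should match the precision-weighted normal combination of
        # prior and observed information within 5%
        config = SimulationConfig(
            n=400, seed=9, weibull_shape=1.0, theta1=0.5, theta2=0.5,
            covariate_prevalence={},
        )
        df = generate_trial(config)
        prior = BivariatePrior(
            "clinical", np.array([0.2, 0.2]), np.eye(2) * 0.09
        )
        spec = ModelSpec(prior=prior, covariates=())
        mle = fit_mle(df, spec)
        fit = fit_bayes(df, spec, fast_mcmc)

        prior_prec_full = np.zeros((len(mle.names), len(mle.names)))
        prior_prec_full[:2, :2] = np.linalg.inv(prior.V)
        idx = np.arange(2, len(mle.names))
        prior_prec_full[idx, idx] = 1.0 / spec.vague_variance
        prior_mean_full = np.zeros(len(mle.names))
        prior_mean_full[:2] = prior.m
        info = np.linalg.inv(mle.cov)
        post_cov = np.linalg.inv(prior_prec_full + info)
        post_mean = post_cov @ (prior_prec_full @ prior_mean_full + info @ mle.beta)

        draws = fit.flat_draws
        for j, name in enumerate(("theta1", "theta2")):
            mcmc_mean = draws[:, j].mean()
            mcmc_sd = draws[:, j].std()
            conj_sd = np.sqrt(post_cov[j, j])
            assert mcmc_mean == pytest.approx(post_mean[j], abs=0.05 * conj_sd + 0.05 * abs(post_mean[j]))
            assert mcmc_sd == pytest.approx(conj_sd, rel=0.05)

    def test_informative_posterior_no_wider_than_vague(self, trial_500, fast_mcmc):
        prior = BivariatePrior("clinical", np.array([0.1, 0.2]), np.eye(2) * 0.04)
        vague = build_vague_prior()
        fit_inf = fit_bayes(trial_500, ModelSpec(prior=prior), fast_mcmc)
        fit_vag = fit_bayes(trial_500, ModelSpec(prior=vague), fast_mcmc)
        for j in range(2):
            assert fit_inf.flat_draws[:, j].var() <= fit_vag.flat_draws[:, j].var()

    def test_bitwise_reproducible_given_seed(self, trial_500, vague_spec):
        settings = MCMCSettings(seed=5, chains=2, iterations=1200)
        a = fit_bayes(trial_500, vague_spec, settings)
        b = fit_bayes(trial_500, vague_spec, settings)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.summaries["theta1"] == b.summaries["theta1"]

    def test_convergence_gate_raises_with_diagnostics(self, trial_500, vague_spec):
        settings = MCMCSettings(seed=5, chains=2, iterations=2000, min_ess=10**9)
        with pytest.raises(ConvergenceError) as excinfo:
            fit_bayes(trial_500, vague_spec, settings)
        assert "theta" in str(excinfo.value)
        assert excinfo.value.diagnostics


class TestSummarise:
    def test_all_positive_draws(self):
        s = summarise_posterior(np.abs(np.random.default_rng(0).normal(size=2000)) + 0.01, "theta1")
        assert s.p_hr_gt1 == 1.0

    def test_symmetric_draws(self):
        x = np.random.default_rng(1).normal(size=1000)
        draws = np.concatenate([x, -x])
        s = summarise_posterior(draws, "theta1")
        assert s.median_hr == pytest.approx(1.0, abs=1e-12)
        assert s.p_hr_gt1 == pytest.approx(0.5, abs=0.01)

    def test_standard_normal_interval(self):
        draws = np.random.default_rng(2).standard_normal(10**5)
        s = summarise_posterior(draws, "theta1")
        assert s.ci_lower == pytest.approx(np.exp(-1.959964), rel=0.02)
        assert s.ci_upper == pytest.approx(np.exp(1.959964), rel=0.02)

    def test_too_few_draws(self):
        with pytest.raises(ValueError, match="1000"):
            summarise_posterior(np.zeros(999), "theta1")

    def test_summary_invariants_enforced(self):
        with pytest.raises(ValueError, match="bracket"):
            PosteriorSummary("x", 2.0, 0.5, 1.5, 0.5)
        with pytest.raises(ValueError, match="p_hr_gt1"):
            PosteriorSummary("x", 1.0, 0.5, 1.5, 1.5)


class TestShrinkageReport:
    def test_vague_prior_ratio_near_one(self, trial_500, vague_spec, fast_mcmc):
        mle = fit_mle(trial_500, vague_spec)
        fit = fit_bayes(trial_500, vague_spec, fast_mcmc)
        report = shrinkage_report(vague_spec.prior, mle, fit)
        for name in ("theta1", "theta2"):
            assert report["parameters"][name]["interval_width_ratio"] == pytest.approx(
                1.0, abs=0.1
            )

    def test_informative_prior_narrows_interval(self, trial_500, fast_mcmc):
        prior = BivariatePrior("clinical", np.array([0.2, 0.3]), np.eye(2) * 0.02)
        spec = ModelSpec(prior=prior)
        mle = fit_mle(trial_500, spec)
        fit = fit_bayes(trial_500, spec, fast_mcmc)
        report = shrinkage_report(prior, mle, fit)
        for name in ("theta1", "theta2"):
            rec = report["parameters"][name]
            assert rec["interval_width_ratio"] < 1.0
            assert rec["between_mle_and_prior"]


class TestTrialCSV:
    def test_round_trip_with_missing_subgroup(self, tmp_path):
        df = generate_trial(SimulationConfig(n=50, seed=2, missing_subgroup_n=2))
        path = tmp_path / "trial.csv"
        write_trial_csv(df, path)
        back = read_trial_csv(path)
        pd.testing.assert_frame_equal(back, df, check_dtype=False)
        assert back["subgroup"].isna().sum() == 2

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,arm\n1,0\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_trial_csv(path)
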