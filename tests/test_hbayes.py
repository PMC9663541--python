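"""Hierarchical Bayesian estimation: likelihood bookkeeping, diagnostics,
posterior predictive behavior and parameter recovery on seeded data."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from voxtune.hbayes import (ConvergenceReport, HierarchicalModelSpec,
                            HierarchicalTuningModel, PosteriorDraws,
                            convergence_report, fit_model,
                            posterior_predictive)
from voxtune.simulate import ExperimentDesign, PriorSpec, simulate_dataset
from voxtune.tuning import VoxelTuningParams, to_doubled_angle, vtf_response


def _fake_draws(chains=2, draws=100, V=3, n_obs=10, rng=None, family="multiplicative"):
    """Hand-built PosteriorDraws with iid well-mixed chains."""
    rng = rng or np.random.default_rng(0)
    voxel = {
        "alpha": rng.normal(1.0, 0.1, (chains, draws, V)),
        "log_gamma": rng.normal(0.0, 0.1, (chains, draws, V)),
        "log_kappa": rng.normal(0.0, 0.1, (chains, draws, V)),
        "phi": rng.uniform(0, 2 * np.pi, (chains, draws, V)),
        "mod": rng.normal(0.3, 0.05, (chains, draws, V)),
        "log_sigma": rng.normal(-1.0, 0.05, (chains, draws, V)),
    }
    hyper = {"mu_alpha": rng.normal(1.0, 0.1, (chains, draws))}
    return PosteriorDraws(
        voxel=voxel, hyper=hyper,
        log_lik=rng.normal(-1.0, 0.1, (chains, draws, n_obs)),
        divergent=np.zeros((chains, draws), dtype=bool),
        family=family, voxel_keys=[(0, v) for v in range(V)],
        orientations_deg=np.arange(8) * 22.5,
        contrast_labels=("low", "high"),
        spec=HierarchicalModelSpec(chains=chains, draws=draws),
    )


def split_rhat_oracle(chains_matrix):
    """Plain (non-rank-normalized) split R-hat, computed from scratch."""
    c, n = chains_matrix.shape
    half = n // 2
    splits = np.concatenate([chains_matrix[:, :half],
                             chains_matrix[:, half:2 * half]], axis=0)
    m, n = splits.shape
    means = splits.mean(axis=1)
    w = splits.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    return np.sqrt(((n - 1) / n * w + b / n) / w)


class TestConvergenceReport:
    def test_well_mixed_chains_pass(self):
        draws = _fake_draws(chains=4, draws=250)
        report = convergence_report(draws)
        assert report.max_rhat < 1.1
        assert report.passed

    def test_agrees_with_split_rhat_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 1.0, (4, 400))
        import arviz as az
        used = float(np.asarray(
            az.rhat(az.from_dict(posterior={"x": x[..., None]}))["x"]).ravel()[0])
        oracle = split_rhat_oracle(x)
        # rank-normalization perturbs the plain estimate only slightly for
        # well-behaved Gaussian chains
        assert used == pytest.approx(oracle, abs=0.02)

    def test_disjoint_chains_fail(self):
        draws = _fake_draws(chains=2, draws=100)
        draws.voxel["alpha"][0] = 0.0
        draws.voxel["alpha"][1] = 10.0
        report = convergence_report(draws)
        assert report.max_rhat > 1.1
        assert not report.passed

    def test_constant_chains_nan_with_warning(self):
        draws = _fake_draws(chains=2, draws=50)
        for k in draws.voxel:
            draws.voxel[k][:] = 1.0
        draws.hyper["mu_alpha"][:] = 1.0
        with pytest.warns(UserWarning):
            report = convergence_report(draws)
        assert not report.passed

    def test_single_chain_rejected(self):
        draws = _fake_draws(chains=1)
        with pytest.raises(ValueError):
            convergence_report(draws)

    def test_divergent_draws_fail_verdict(self):
        draws = _fake_draws(chains=4, draws=250)
        draws.divergent[0, 0] = True
        report = convergence_report(draws)
        assert report.n_divergent == 1
        assert not report.passed


class TestFittedPosterior:
    def test_determinism_same_seed(self, tuned_mult_dataset, small_mult_fit):
        spec = small_mult_fit.spec
        again = fit_model(tuned_mult_dataset, spec, seed=77)
        np.testing.assert_array_equal(small_mult_fit.voxel["alpha"],
                                      again.voxel["alpha"])
        np.testing.assert_array_equal(small_mult_fit.log_lik, again.log_lik)

    def test_pointwise_loglik_matches_direct_recomputation(
            self, tuned_mult_dataset, small_mult_fit):
        # recompute Normal(VTF, sigma) log-density outside the sampler for
        # one stored draw and every observation
        draws = small_mult_fit
        c, d = 1, 17
        params = draws.voxel_params_at(c * draws.n_draws + d)
        key_to_param = dict(zip(draws.voxel_keys, params))
        ll = np.empty(len(tuned_mult_dataset))
        for i, row in enumerate(tuned_mult_dataset.itertuples()):
            v = key_to_param[(row.participant, row.voxel)]
            cond = ("baseline" if row.contrast == draws.contrast_labels[0]
                    else "modulated")
            mu = vtf_response(to_doubled_angle(row.orientation_deg), v, cond)
            ll[i] = sps.norm.logpdf(row.response, mu, v.sigma_v)
        np.testing.assert_allclose(draws.log_lik[c, d], ll, atol=1e-6)

    def test_gain_recovery_on_low_noise_data(self, tuned_mult_params,
                                             small_mult_fit):
        gains = np.array([p.gain for p in tuned_mult_params])
        g = small_mult_fit.natural_arrays()["gain"].reshape(-1, len(gains))
        lo, hi = np.quantile(g, [0.025, 0.975], axis=0)
        assert ((lo <= gains) & (gains <= hi)).mean() >= 0.8

    def test_voxel_lacking_one_condition_rejected(self, tuned_mult_dataset):
        broken = tuned_mult_dataset[
            ~((tuned_mult_dataset.voxel == 0)
              & (tuned_mult_dataset.contrast == "high"))]
        with pytest.raises(ValueError):
            fit_model(broken, HierarchicalModelSpec(chains=2, warmup=10,
                                                    draws=10), seed=0)

    def test_estimator_front_end(self, tuned_mult_dataset):
        est = HierarchicalTuningModel(chains=2, warmup=100, draws=50, thin=1,
                                      prior=PriorSpec.recovery_default(),
                                      random_state=0)
        est.fit(tuned_mult_dataset)
        assert est.draws_.n_draws == 50
        assert isinstance(est.convergence_, ConvergenceReport)
        pp = est.posterior_predictive(seed=0)
        assert {"voxel_index", "orientation_deg", "contrast"} <= set(pp.columns)


class TestPosteriorPredictive:
    def test_point_mass_posterior_collapses_to_curve(self):
        v = VoxelTuningParams(1.0, 2.0, 2.0, 0.7, 1.0, gain=1.5)
        draws = _fake_draws(chains=2, draws=200, V=1)
        draws.voxel["alpha"][:] = v.alpha_v
        draws.voxel["log_gamma"][:] = np.log(v.gamma_v)
        draws.voxel["log_kappa"][:] = np.log(v.kappa_v)
        draws.voxel["phi"][:] = v.phi_v
        draws.voxel["mod"][:] = np.log(v.gain)
        draws.voxel["log_sigma"][:] = np.log(1e-9)
        pp = posterior_predictive(draws, seed=0)
        for cond, label in (("baseline", "low"), ("modulated", "high")):
            sub = pp[pp.contrast == label]
            mu = vtf_response(
                np.asarray(to_doubled_angle(sub["orientation_deg"].to_numpy())),
                v, cond)
            np.testing.assert_allclose(sub["predictive_mean"], mu, atol=1e-6)
            np.testing.assert_allclose(sub["hi"] - sub["lo"], 0.0, atol=1e-6)

    def test_interval_nesting(self):
        draws = _fake_draws(chains=2, draws=300)
        pp50 = posterior_predictive(draws, credibility=0.5, seed=1)
        pp95 = posterior_predictive(draws, credibility=0.95, seed=1)
        assert (pp50["lo"] >= pp95["lo"] - 1e-9).all()
        assert (pp50["hi"] <= pp95["hi"] + 1e-9).all()

    def test_coverage_on_simulated_replicates(self, tuned_mult_params,
                                              small_design, small_mult_fit):
        # held-out replicate responses should fall inside the 95% predictive
        # intervals at roughly the nominal rate
        new_data = simulate_dataset(tuned_mult_params, small_design,
                                    "multiplicative", seed=5150)
        pp = posterior_predictive(small_mult_fit, seed=2)
        label_of = {0: "low", 1: "high"}
        merged = new_data.merge(
            pp, left_on=["voxel", "orientation_deg", "contrast"],
            right_on=["voxel_index", "orientation_deg", "contrast"])
        inside = ((merged["response"] >= merged["lo"])
                  & (merged["response"] <= merged["hi"])).mean()
        n = len(merged)
        se = np.sqrt(0.95 * 0.05 / n)
        assert inside == pytest.approx(0.95, abs=5 * se + 0.02)

    def test_invalid_credibility_rejected(self):
        with pytest.raises(ValueError):
            posterior_predictive(_fake_draws(), credibility=1.2)


class TestFlatVoxelIndistinguishability:
    def test_families_agree_on_flat_population(self):
        # with untuned voxels only, gain and shift produce the same cell
        # means; both fitted families should predict near-identical means
        design = ExperimentDesign(participants=1, voxels_per_participant=4,
                                  runs=4, repeats_per_run=1)
        params = [VoxelTuningParams(1.0, 1.0, 0.0, 0.0, 0.2,
                                    gain=1.5) for _ in range(4)]
        data = simulate_dataset(params, design, "multiplicative", seed=12)
        preds = {}
        for family in ("multiplicative", "additive"):
            spec = HierarchicalModelSpec(family=family,
                                         prior=PriorSpec.default(),
                                         chains=2, warmup=300, draws=150,
                                         thin=2)
            draws = fit_model(data, spec, seed=4)
            pp = posterior_predictive(draws, seed=0)
            preds[family] = pp.sort_values(
                ["voxel_index", "orientation_deg", "contrast"]
            )["predictive_mean"].to_numpy()
        # Monte-Carlo SE of each predictive cell mean is ~sigma/sqrt(draws)
        mc_se = 0.25 / np.sqrt(600)
        diff = np.abs(preds["multiplicative"] - preds["additive"])
        assert diff.max() < 0.1
        assert np.median(diff) < 5 * mc_se
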