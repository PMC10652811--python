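"""Likelihood, ensemble-MCMC fitting, PSIS-LOO and model selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from cycletrial.assays import (
    CellCycleAssayConfig,
    SynergyAssayConfig,
    default_truth,
    generate_cellcycle,
    generate_synergy,
)
from cycletrial.experiments import RECOVERY_TRUTH_VALUES, make_reduced_data
from cycletrial.inference import (
    LooResult,
    Posterior,
    SamplerConfig,
    default_priors,
    fit,
    log_likelihood,
    loo_ic,
    param_names,
    posterior_predictive,
)

TRUTH_THETA = dict(
    RECOVERY_TRUTH_VALUES,
    N0_syn=3000.0,
    N0_cc=500.0,
    sigma_syn=0.1,
    sigma_cc=0.2,
)


@pytest.fixture(scope="module")
def tiny_data():
    truth = default_truth("recovery_small")
    syn = generate_synergy(
        truth, SynergyAssayConfig(doses_P=(0.0, 50.0), doses_F=(0.0,), replicates=1,
                                  days=(0, 1, 2, 3, 4)), seed=5,
    )
    cc = generate_cellcycle(
        truth, CellCycleAssayConfig(levels_F=(), levels_P=(50.0,), include_combos=False,
                                    replicates=1, days=(0, 2, 4)), seed=6,
    )
    return syn, cc


class TestLogLikelihood:
    def test_pointwise_sums_to_scalar(self, tiny_data):
        total, pw = log_likelihood(TRUTH_THETA, tiny_data, m=2)
        assert total == pytest.approx(pw.sum())
        syn, cc = tiny_data
        # zero-count rows (synchronized day-0 S/G2M) are excluded
        n_expected = int((syn["count"] > 0.5).sum()) + int(
            ((cc["phase"] != "unassigned") & (cc["count"] > 0.5)).sum()
        )
        assert pw.size == n_expected

    def test_matches_brute_force_density_evaluation(self, tiny_data):
        """Direct log-normal density over explicitly simulated trajectories."""
        from cycletrial.assays import GroundTruth, noise_free_phases, noise_free_totals
        from cycletrial.cellcycle import CellCycleParams
        from cycletrial.response import InteractionParams

        syn, cc = tiny_data
        syn = syn[syn["count"] > 0.5].head(6)
        cc = cc[(cc["phase"] != "unassigned") & (cc["count"] > 0.5)].head(4)
        truth = GroundTruth(
            label="oracle",
            cell_cycle=CellCycleParams(m=2, lambda_alpha=2.0, lambda_beta=5.6,
                                       lambda_gamma=7.9),
            interaction=InteractionParams(C_F=1.49, C_P=18.0, h_F=1.1, h_P=1.5,
                                          a_FP=-0.113, lambda_ctrl=10.0),
            day0_synergy=3000.0,
            day0_cellcycle=500.0,
        )
        u = 0.10  # generator's phase-unassignment fraction
        expected = 0.0
        for _, row in syn.iterrows():
            mu = noise_free_totals(truth, row.dose_F, row.dose_P, [0, row.day])[-1]
            y = max(row["count"], 0.5)
            expected += norm.logpdf(math.log(y), math.log(max(mu, 0.5)), 0.1) - math.log(y)
        for _, row in cc.iterrows():
            phases = noise_free_phases(truth, row.dose_F, row.dose_P, [0, row.day])[-1]
            mu = max({"G1": phases[0], "S": phases[1], "G2M": phases[2]}[row.phase], 0.5)
            y = max(row["count"], 0.5)
            kept = (1 - u) * mu
            mean = math.log(kept) - u / (2 * kept)  # thinning mean shift
            sd = math.sqrt(0.2**2 + u / kept)  # thinning extra variance
            expected += norm.logpdf(math.log(y), mean, sd) - math.log(y)
        total, _ = log_likelihood(TRUTH_THETA, (syn, cc), m=2, unassigned_fraction=u)
        assert total == pytest.approx(expected, rel=1e-9)

    def test_maximized_at_generating_parameters(self):
        truth = default_truth("recovery_small")
        import dataclasses

        exact = dataclasses.replace(truth, sigma_synergy=0.0, sigma_cellcycle=0.0,
                                    unassigned_fraction=0.0)
        syn = generate_synergy(exact, SynergyAssayConfig(doses_P=(0.0, 50.0),
                                                         doses_F=(0.0, 2.6),
                                                         replicates=1), seed=0)
        cc = generate_cellcycle(exact, CellCycleAssayConfig(levels_F=(5.0,),
                                                            levels_P=(50.0,),
                                                            replicates=1), seed=0)
        theta = dict(TRUTH_THETA, sigma_syn=0.01, sigma_cc=0.01)
        best, _ = log_likelihood(theta, (syn, cc), m=2, unassigned_fraction=0.0)
        for name, bump in [("lambda_beta", 1.1), ("C_P", 1.2), ("lambda_ctrl", 0.9)]:
            other = dict(theta)
            other[name] = other[name] * bump
            val, _ = log_likelihood(other, (syn, cc), m=2, unassigned_fraction=0.0)
            assert val < best

    def test_param_names_exclude_lambda_alpha_at_m1(self):
        assert "lambda_alpha" not in param_names(1)
        assert "lambda_alpha" in param_names(2)
        assert param_names(2)[-2:] == ["sigma_syn", "sigma_cc"]


class TestPriors:
    def test_default_priors_center_day0_on_observed(self, tiny_data):
        priors = default_priors(2, tiny_data)
        syn_day0 = tiny_data[0].loc[tiny_data[0]["day"] == 0, "count"].mean()
        assert priors.normal["N0_syn"][0] == pytest.approx(math.log(syn_day0))
        assert set(priors.half_cauchy) == {"sigma_syn", "sigma_cc"}

    def test_invalid_scale_rejected(self):
        from cycletrial.inference import PriorSpec

        with pytest.raises(ValueError):
            PriorSpec(normal={"x": (0.0, -1.0)})


def _normal_posterior_fixture(n_obs=40, n_draws=2000, sigma=1.0, tau=10.0, seed=0):
    """Conjugate normal-mean model with analytically known LOO."""
    rng = np.random.default_rng(seed)
    y = rng.normal(0.7, sigma, size=n_obs)
    post_var = 1.0 / (n_obs / sigma**2 + 1.0 / tau**2)
    post_mean = post_var * y.sum() / sigma**2
    mu = rng.normal(post_mean, math.sqrt(post_var), size=n_draws)
    pointwise = norm.logpdf(y[None, :], mu[:, None], sigma)
    chain = mu.reshape(2, -1, 1)
    post = Posterior(
        samples=pd.DataFrame({"mu": mu}),
        chain=chain,
        log_prob=np.zeros(chain.shape[:2]),
        pointwise=pointwise,
        names=["mu"],
        m=1,
        seed=seed,
        diagnostics={},
    )
    # analytic elpd_loo: leave-one-out predictive is normal
    elpd = 0.0
    for i in range(n_obs):
        v_i = 1.0 / ((n_obs - 1) / sigma**2 + 1.0 / tau**2)
        m_i = v_i * (y.sum() - y[i]) / sigma**2
        elpd += norm.logpdf(y[i], m_i, math.sqrt(v_i + sigma**2))
    return post, elpd


class TestLoo:
    def test_psis_matches_analytic_loo_for_conjugate_normal(self):
        post, elpd_exact = _normal_posterior_fixture()
        res = loo_ic(post)
        assert abs(res.elpd - elpd_exact) < 2 * res.se

    def test_duplicating_data_doubles_elpd(self):
        post, _ = _normal_posterior_fixture()
        doubled = Posterior(
            samples=post.samples, chain=post.chain, log_prob=post.log_prob,
            pointwise=np.concatenate([post.pointwise, post.pointwise], axis=1),
            names=post.names, m=post.m, seed=post.seed, diagnostics={},
        )
        r1, r2 = loo_ic(post), loo_ic(doubled)
        assert r2.elpd == pytest.approx(2 * r1.elpd, rel=0.02)

    def test_pareto_k_reported_for_every_observation(self):
        post, _ = _normal_posterior_fixture(n_obs=25)
        res = loo_ic(post)
        assert res.pareto_k.size == 25
        assert isinstance(res, LooResult)
        assert res.looic == pytest.approx(-2 * res.elpd)


@pytest.fixture(scope="module")
def quick_fit():
    data = make_reduced_data(seed=3)
    cfg = SamplerConfig(n_walkers=28, n_steps=250, n_burn=100, thin=5)
    return data, fit(data, m=2, sampler_cfg=cfg, seed=3)


class TestFit:
    def test_fit_is_deterministic_given_seed(self, quick_fit):
        data, post = quick_fit
        cfg = SamplerConfig(n_walkers=28, n_steps=250, n_burn=100, thin=5)
        again = fit(data, m=2, sampler_cfg=cfg, seed=3)
        np.testing.assert_array_equal(post.chain, again.chain)

    def test_posterior_structure_and_supports(self, quick_fit):
        _, post = quick_fit
        assert list(post.samples.columns) == param_names(2)
        positive = [c for c in post.samples.columns if c != "a_FP"]
        assert (post.samples[positive] > 0).all().all()
        assert post.pointwise.shape[0] == len(post.samples)
        assert np.isfinite(post.pointwise).all()

    def test_diagnostics_reported_for_every_parameter(self, quick_fit):
        _, post = quick_fit
        assert set(post.diagnostics["rhat"]) == set(param_names(2))
        assert set(post.diagnostics["ess"]) == set(param_names(2))
        assert "converged" in post.diagnostics

    def test_requires_control_condition(self, quick_fit):
        data, _ = quick_fit
        syn, cc = data
        no_ctrl = syn[~((syn.dose_F == 0) & (syn.dose_P == 0))]
        with pytest.raises(ValueError, match="control"):
            fit((no_ctrl, cc), m=2)

    def test_posterior_predictive_bands(self, quick_fit):
        from cycletrial.experiments import reduced_cellcycle_config, reduced_synergy_config

        _, post = quick_fit
        bands = posterior_predictive(
            post, reduced_synergy_config(), reduced_cellcycle_config(),
            n_draws=30, seed=0,
        )
        assert {"lo", "median", "hi"} <= set(bands.columns)
        assert (bands["lo"] <= bands["hi"]).all()
        day0 = bands[(bands["assay"] == "synergy") & (bands["day"] == 0)]
        med_n0 = post.samples["N0_syn"].median()
        assert day0["median"].median() == pytest.approx(med_n0, rel=0.2)
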