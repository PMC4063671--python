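"""Factorial observer models: parameter counts, densities, likelihoods."""

import numpy as np
import pytest
from scipy.stats import kstest, norm

from bayesobs.config import TaskConfig
from bayesobs.gmm import GaussianMixture1D
from bayesobs.observers import (
    LikelihoodEngine,
    ObserverParams,
    ObserverSpec,
    REG_EPSILON,
    RelTrial,
    basic_model_set,
    derive_extended_equivalences,
    extended_model_set,
    gaussian_closed_form_response,
    log_likelihood,
    param_count,
    parse_model_string,
    response_density,
    response_probability,
)


@pytest.fixture(scope="module")
def params():
    return ObserverParams()


@pytest.fixture(scope="module")
def gauss_trial():
    return RelTrial(GaussianMixture1D([1.0], [0.0], [0.10]), "gaussian",
                    "training", "short", cue=0.07, response=0.04)


@pytest.fixture(scope="module")
def bimodal_trial():
    gm = GaussianMixture1D([0.4, 0.6], [-0.12, 0.08], [0.05, 0.05])
    return RelTrial(gm, "bimodal", "test", "long", cue=0.02, response=-0.05)


class TestModelSpace:
    @pytest.mark.parametrize(
        "model,expected",
        [("BDT", 4), ("SPK", 6), ("PPM", 4), ("PSA", 6),
         ("BDT-L", 6), ("SPK-P-L", 10), ("BDT-S-P-L", 10), ("PPM-S", 6)],
    )
    def test_param_counts(self, model, expected):
        assert param_count(parse_model_string(model)) == expected

    def test_model_string_roundtrip(self):
        for s in ("BDT", "SPK-P-L", "PSA-MV-L", "PPM-LA", "SPK-S-P-L"):
            assert str(parse_model_string(s)) == s
        with pytest.raises(ValueError):
            parse_model_string("XYZ-L")
        with pytest.raises(ValueError):
            parse_model_string("SPK-MV-LA")

    def test_basic_set_has_24_models(self):
        models = basic_model_set()
        assert len(models) == 24
        assert len({str(m) for m in models}) == 24

    def test_extended_set_collapses_to_18(self, cfg):
        models = extended_model_set(cfg)
        assert len(models) == 18
        merged = derive_extended_equivalences(cfg)
        # exact algebraic merges: sample-averaging a Gaussian = power of it
        assert merged[("PSA", "MV")] == ("SPK", "MV")
        assert merged[("PSA", "LA")] == ("SPK", "LA")
        # deterministic MAP-style rules coincide behaviorally
        assert merged[("BDT", "LA")] == ("BDT", "none")
        # the quadratic-loss (mean) rule stays distinct
        assert ("BDT", "MV") not in merged


class TestSharingRules:
    def test_test_session_long_sd_tied_by_training_ratio(self, params):
        p = params.replace(lik_sd_short_train=0.05, lik_sd_long_train=0.15,
                           lik_sd_short_test=0.08)
        assert p.internal_lik_sd("test", "long") == pytest.approx(0.24)

    def test_cue_est_sd_weber_scaling(self, params, cfg):
        p = params.replace(cue_est_sd_train=0.012)
        ratio = cfg.d_long_cm / cfg.d_short_cm
        assert p.cue_est_sd("training", "long", cfg) == pytest.approx(0.012 * ratio)

    def test_vector_roundtrip(self):
        spec = parse_model_string("SPK-S-P-L")
        p = ObserverParams(kappa_test=3.3, lapse_train=0.07)
        v = p.to_vector(spec)
        assert ObserverParams.from_vector(spec, v).to_vector(spec) == pytest.approx(v)


class TestNestingIdentities:
    def test_spk_kappa1_is_ppm(self, params, bimodal_trial, cfg):
        p = params.replace(kappa_train=1.0, kappa_test=1.0)
        for r in (-0.2, -0.05, 0.0, 0.1):
            a = response_probability(parse_model_string("SPK"), p, bimodal_trial, r, cfg)
            b = response_probability(parse_model_string("PPM"), params, bimodal_trial, r, cfg)
            assert a == pytest.approx(b, abs=1e-8)

    def test_psa_k1_is_ppm(self, params, bimodal_trial, cfg):
        p = params.replace(psa_k_train=1.0, psa_k_test=1.0)
        for r in (-0.2, 0.0, 0.1):
            a = response_probability(parse_model_string("PSA"), p, bimodal_trial, r, cfg)
            b = response_probability(parse_model_string("PPM"), params, bimodal_trial, r, cfg)
            assert a == pytest.approx(b, abs=1e-8)

    @pytest.mark.parametrize("factor,zero", [
        ("SPK-L", {"lapse_test": 0.0}),
        ("SPK-P", {"weber_prior_test": 0.0}),
        ("SPK-S", {"cue_est_sd_test": 0.0}),
    ])
    def test_factor_collapse(self, params, bimodal_trial, cfg, factor, zero):
        p = params.replace(**zero)
        for r in (-0.1, 0.05):
            a = response_probability(parse_model_string(factor), p, bimodal_trial, r, cfg)
            b = response_probability(parse_model_string("SPK"), params, bimodal_trial, r, cfg)
            assert a == pytest.approx(b, abs=1e-8)

    def test_gaussian_trial_deterministic_rules_agree(self, params, gauss_trial, cfg):
        # BDT, BDT-MV, BDT-LA all aim at the posterior mean on Gaussian trials
        vals = [
            response_probability(spec, params, gauss_trial, 0.03, cfg)
            for spec in (ObserverSpec("BDT"), ObserverSpec("BDT", "MV"),
                         ObserverSpec("BDT", "LA"))
        ]
        assert np.ptp(vals) < 1e-12


class TestResponseDensities:
    @pytest.mark.parametrize("model", [
        "BDT", "SPK", "PPM", "PSA", "SPK-MV", "SPK-LA", "BDT-P-L", "SPK-S-L",
        "PSA-L", "PPM-P",
    ])
    def test_normalization_on_mixture_trials(self, params, bimodal_trial, cfg, model):
        d = response_density(parse_model_string(model), params, bimodal_trial, cfg,
                             gh_order=10)
        assert d.integral() == pytest.approx(1.0, abs=1e-4)

    def test_closed_form_matches_numeric_path(self, params, cfg):
        trial = RelTrial(GaussianMixture1D([1.0], [0.0], [0.08]), "gaussian",
                         "test", "short", cue=0.05, response=0.0)
        for model in ("BDT", "SPK", "PPM", "SPK-S"):
            spec = parse_model_string(model)
            m, sd = gaussian_closed_form_response(spec, params, trial, cfg)
            for r in (-0.05, 0.02, 0.08):
                num = response_probability(spec, params, trial, r, cfg)
                assert norm.pdf(r, m, sd) == pytest.approx(num, abs=1e-6)

    def test_closed_form_requires_gaussian_prior(self, params, bimodal_trial, cfg):
        with pytest.raises(ValueError):
            gaussian_closed_form_response(parse_model_string("SPK"), params,
                                          bimodal_trial, cfg)

    def test_closed_form_matches_generative_simulation(self, params, cfg, rng):
        # observer simulation vs analytic response distribution (KS)
        from bayesobs.cohort import simulate_response
        from bayesobs.task import PriorSpec, TrialRecord, discretize_prior

        spec = parse_model_string("SPK-S")
        p = params.replace(kappa_train=2.0, cue_est_sd_train=0.015)
        prior = PriorSpec("gaussian", 3, GaussianMixture1D([1.0], [0.0], [0.08]),
                          False, 0.5)
        trial = TrialRecord("training", "gaussian", 3, "short", prior,
                            discretize_prior(prior), 0.5, 0.55, 6.0)
        draws = np.asarray([
            simulate_response(spec, p, trial, rng, cfg) for _ in range(20000)
        ])
        rel = RelTrial(prior.mixture, "gaussian", "training", "short", cue=0.05)
        m, sd = gaussian_closed_form_response(spec, p, rel, cfg)
        stat = kstest((draws - 0.5 - m) / sd, "norm").statistic
        assert stat < 0.012  # 3x the 99th percentile of the null at n = 20000

    def test_optimal_internal_model_mean_matches_linear_rule(self, cfg):
        # sigma~ = true sigma: response mean equals the optimal w * cue
        p = ObserverParams(lik_sd_short_train=cfg.sigma_short)
        trial = RelTrial(GaussianMixture1D([1.0], [0.0], [0.1]), "gaussian",
                         "training", "short", cue=0.06)
        m, _ = gaussian_closed_form_response(parse_model_string("BDT"), p, trial, cfg)
        w = 0.1**2 / (0.1**2 + cfg.sigma_short**2)
        assert m == pytest.approx(w * 0.06, rel=1e-12)


class TestLogLikelihood:
    def test_empty_dataset_zero(self, cfg):
        total, per = log_likelihood(parse_model_string("BDT"), ObserverParams(), [], cfg)
        assert total == 0.0 and per.size == 0

    def test_outlier_response_floored(self, params, cfg):
        trial = RelTrial(GaussianMixture1D([1.0], [0.0], [0.1]), "gaussian",
                         "training", "short", cue=0.0, response=1e9)
        total, per = log_likelihood(parse_model_string("SPK"), params, [trial], cfg)
        assert per[0] >= np.log(REG_EPSILON)
        assert np.isclose(REG_EPSILON, norm.pdf(5.0))

    def test_likelihood_translation_invariance(self, params, cfg):
        # the whole-trial shift lives in absolute coordinates; relative-frame
        # likelihood is constructed to be invariant by the coordinate map
        from bayesobs.observers import make_rel_trials
        from bayesobs.task import PriorSpec, TrialRecord, discretize_prior

        gm = GaussianMixture1D([0.4, 0.6], [-0.066, 0.044], [0.05, 0.05])
        out = []
        for loc in (0.3, 0.62):
            prior = PriorSpec("bimodal", 3, gm, False, loc)
            t = TrialRecord("test", "bimodal", 3, "long", prior,
                            discretize_prior(prior), loc, loc + 0.05, 14.0,
                            response_x=loc - 0.04)
            rel = make_rel_trials([t])
            out.append(log_likelihood(parse_model_string("SPK-L"), params, rel, cfg)[0])
        assert out[0] == pytest.approx(out[1], abs=1e-12)

    def test_profile_maximized_near_generating_kappa(self, cfg):
        # simulated SPK data: the kappa profile peaks near the truth
        from bayesobs.cohort import simulate_subject

        spec = parse_model_string("SPK")
        theta = ObserverParams(kappa_train=2.5, kappa_test=2.5, motor_sd=0.008)
        subj = simulate_subject("gaussian", spec, theta, seed=21, cfg=cfg)
        from bayesobs.observers import make_rel_trials

        rel = make_rel_trials(subj.dataset)
        engine = LikelihoodEngine(spec, rel, cfg)
        kappas = np.array([1.2, 1.8, 2.5, 3.5, 5.0])
        lls = [
            engine.loglik_params(theta.replace(kappa_train=k, kappa_test=k))
            for k in kappas
        ]
        assert kappas[int(np.argmax(lls))] == pytest.approx(2.5)
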