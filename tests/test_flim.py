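"""Bayesian decay inference: model evaluation, MLE, posteriors, BIC."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ktflim import flim
from ktflim.flim import (
    IRF,
    DecayHistogram,
    DecayModel,
    PosteriorGrid,
    combine_posteriors,
    decay_model_eval,
    fit_mle,
    fret_to_binding,
    infer_posterior,
    select_model_bic,
)
from ktflim.simulate import SimConfig, gen_decay


class TestDecayModelEval:
    def test_double_with_zero_fret_fraction_reduces_to_single(self, sim_config):
        irf = sim_config.make_irf()
        single = DecayModel("single", tau_d=3.75)
        double = DecayModel("double", tau_d=3.75, tau_fret=0.75, f_fret=0.0)
        p1 = decay_model_eval(single, sim_config.n_bins, sim_config.adc_ratio, irf)
        p2 = decay_model_eval(double, sim_config.n_bins, sim_config.adc_ratio, irf)
        np.testing.assert_allclose(p1, p2, atol=1e-15)

    def test_vanishing_amplitude_leaves_flat_noise_floor(self, sim_config):
        irf = sim_config.make_irf()
        model = DecayModel("single", tau_d=3.75, noise_a=1e-6)
        p = decay_model_eval(model, sim_config.n_bins, sim_config.adc_ratio, irf)
        assert np.ptp(p) < 1e-5
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_delta_irf_matches_exponential_closed_form(self, delta_irf_config):
        cfg, irf = delta_irf_config
        model = DecayModel("single", tau_d=3.75)
        p = decay_model_eval(model, cfg.n_bins, cfg.adc_ratio, irf)
        # per-coarse-bin mass of the (folded) exponential, computed directly
        edges = np.arange(cfg.n_bins + 1) * cfg.adc_ratio * cfg.bin_width
        direct = np.exp(-edges[:-1] / 3.75) - np.exp(-edges[1:] / 3.75)
        direct /= 1 - np.exp(-cfg.window / 3.75)
        np.testing.assert_allclose(p, direct, rtol=1e-9)

    @given(tau=st.floats(0.3, 8.0), noise_a=st.floats(0.5, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_probability_conserved_for_any_model(self, tau, noise_a):
        cfg = SimConfig()
        irf = IRF.delta(cfg.n_fine, cfg.bin_width)
        model = DecayModel("single", tau_d=tau, noise_a=noise_a)
        p = decay_model_eval(model, cfg.n_bins, cfg.adc_ratio, irf)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_bin_width_mismatch_rejected(self, sim_config):
        irf = IRF.delta(100, sim_config.bin_width)
        with pytest.raises(ValueError):
            decay_model_eval(DecayModel("single", tau_d=3.75),
                             sim_config.n_bins, sim_config.adc_ratio, irf)


class TestFitMle:
    def test_large_sample_single_exponential_recovery(self, delta_irf_config):
        cfg, irf = delta_irf_config
        cfg = SimConfig(photons_per_decay=10**6, n_bins=cfg.n_bins, seed=2)
        hist, _ = gen_decay(DecayModel("single", tau_d=2.0), irf, cfg)
        res = fit_mle(hist, "single", fixed={"noise_a": 1.0})
        assert res.model.tau_d == pytest.approx(2.0, abs=0.01)

    def test_all_parameters_fixed_returns_input_model(self, mixture_model,
                                                      sim_config):
        hist, _ = gen_decay(mixture_model, sim_config.make_irf(), sim_config)
        res = fit_mle(hist, "double", fixed=mixture_model.params())
        assert res.n_free == 0
        assert res.model == mixture_model
        assert np.isfinite(res.log_likelihood)

    def test_mixture_amplitude_recovered_within_3_se(self):
        cfg = SimConfig(photons_per_decay=10**5, seed=8)
        irf = cfg.make_irf()
        truth = DecayModel("double", tau_d=3.75, tau_fret=0.75, f_fret=0.5)
        hist, _ = gen_decay(truth, irf, cfg)
        res = fit_mle(hist, "double", fixed={"tau_d": 3.75, "noise_a": 1.0})
        assert abs(res.model.f_fret - 0.5) < 3 * res.se["f_fret"]

    def test_empty_histogram_rejected(self, sim_config):
        hist = DecayHistogram(counts=np.zeros(sim_config.n_bins, dtype=int),
                              adc_ratio=sim_config.adc_ratio,
                              irf=sim_config.make_irf())
        with pytest.raises(ValueError):
            fit_mle(hist, "single")


class TestInferPosterior:
    def test_posterior_mean_near_truth_at_calibration_amplitude(self):
        cfg = SimConfig(photons_per_decay=5000, seed=10)
        hist, _ = gen_decay(
            DecayModel("double", tau_d=3.75, tau_fret=0.75, f_fret=0.13),
            cfg.make_irf(), cfg,
        )
        post = infer_posterior(hist, "double",
                               fixed={"tau_d": 3.75, "tau_fret": 0.75,
                                      "noise_a": 1.0})
        assert abs(post.mean("f_fret") - 0.13) < 3 * post.sd("f_fret")

    def test_single_point_grid_concentrates_all_mass(self, mixture_model,
                                                     sim_config):
        hist, _ = gen_decay(mixture_model, sim_config.make_irf(), sim_config)
        post = infer_posterior(hist, "double",
                               fixed={"tau_d": 3.71, "tau_fret": 0.75,
                                      "noise_a": 1.0},
                               grids={"f_fret": np.array([0.2])})
        _, p = post.marginal("f_fret")
        assert p[0] == pytest.approx(1.0)

    def test_credible_interval_coverage_is_calibrated(self):
        # 95% CI should cover the generating amplitude in ~95% of replicates
        cfg = SimConfig(photons_per_decay=5000)
        irf = cfg.make_irf()
        truth = DecayModel("double", tau_d=3.75, tau_fret=0.75, f_fret=0.13)
        rng = np.random.default_rng(20)
        n_reps, covered = 200, 0
        for _ in range(n_reps):
            hist, _ = gen_decay(truth, irf, cfg, rng=rng)
            post = infer_posterior(hist, "double",
                                   fixed={"tau_d": 3.75, "tau_fret": 0.75,
                                          "noise_a": 1.0})
            lo, hi = post.credible_interval("f_fret", 0.95)
            covered += lo <= 0.13 <= hi
        assert abs(covered / n_reps - 0.95) <= 0.04

    def test_posterior_mode_agrees_with_mle(self):
        cfg = SimConfig(photons_per_decay=20_000, seed=13)
        hist, _ = gen_decay(
            DecayModel("double", tau_d=3.75, tau_fret=0.75, f_fret=0.3),
            cfg.make_irf(), cfg,
        )
        fixed = {"tau_d": 3.75, "tau_fret": 0.75, "noise_a": 1.0}
        mle = fit_mle(hist, "double", fixed=fixed)
        post = infer_posterior(hist, "double", fixed=fixed)
        grid_step = np.diff(post.axes["f_fret"])[0]
        assert abs(post.mode()["f_fret"] - mle.model.f_fret) <= grid_step + 1e-12

    def test_grid_and_gibbs_agree_on_two_parameter_problem(self):
        cfg = SimConfig(photons_per_decay=20_000, seed=14)
        hist, _ = gen_decay(
            DecayModel("double", tau_d=3.75, tau_fret=0.75, f_fret=0.25),
            cfg.make_irf(), cfg,
        )
        fixed = {"tau_d": 3.75, "tau_fret": 0.75}
        grid_post = infer_posterior(hist, "double", fixed=fixed)
        gibbs_post = flim._gibbs_posterior(hist, "double", fixed,
                                           ["f_fret", "noise_a"], 0,
                                           n_draws=4000, burn_in=1000, seed=3)
        se = np.hypot(grid_post.sd("f_fret"), gibbs_post.sd("f_fret"))
        assert abs(grid_post.mean("f_fret") - gibbs_post.mean("f_fret")) < 3 * se

    def test_empty_histogram_rejected(self, sim_config):
        hist = DecayHistogram(counts=np.zeros(sim_config.n_bins, dtype=int),
                              adc_ratio=sim_config.adc_ratio,
                              irf=sim_config.make_irf())
        with pytest.raises(ValueError):
            infer_posterior(hist, "double", fixed={"tau_d": 3.75, "tau_fret": 0.75})


class TestCombinePosteriors:
    @staticmethod
    def _gaussian_posterior(mean, sd, n=201):
        grid = np.linspace(0.0, 1.0, n)
        logd = -0.5 * ((grid - mean) / sd) ** 2
        return PosteriorGrid(axes={"f_fret": grid}, log_density=logd).normalize()

    def test_single_posterior_is_identity(self):
        post = self._gaussian_posterior(0.3, 0.05)
        est = combine_posteriors([post])
        assert est.mean_f_fret == pytest.approx(post.mean("f_fret"), abs=1e-12)
        assert est.n_kinetochores == 1

    def test_sem_shrinks_as_sqrt_n(self):
        post = self._gaussian_posterior(0.4, 0.08)
        single_sd = post.sd("f_fret")
        for n in (4, 9, 16):
            est = combine_posteriors([self._gaussian_posterior(0.4, 0.08)] * n)
            assert est.sem == pytest.approx(single_sd / np.sqrt(n), rel=0.02)

    def test_conflicting_posteriors_average_with_warning(self):
        lo = self._gaussian_posterior(0.02, 0.01)
        hi = self._gaussian_posterior(0.98, 0.01)
        with pytest.warns(RuntimeWarning, match="conflict"):
            est = combine_posteriors([lo, hi])
        assert est.mean_f_fret == pytest.approx(0.5, abs=0.02)

    def test_incompatible_grids_rejected(self):
        a = self._gaussian_posterior(0.3, 0.05, n=201)
        b = self._gaussian_posterior(0.3, 0.05, n=101)
        with pytest.raises(ValueError):
            combine_posteriors([a, b])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combine_posteriors([])


class TestSelectModelBic:
    def test_pure_single_exponential_prefers_single_model(self):
        cfg = SimConfig(photons_per_decay=5000)
        irf = cfg.make_irf()
        rng = np.random.default_rng(30)
        wins = 0
        for _ in range(30):
            hist, _ = gen_decay(DecayModel("single", tau_d=3.75), irf, cfg, rng=rng)
            wins += select_model_bic(hist) < 0
        assert wins >= 27

    def test_strong_mixture_prefers_double_model(self):
        cfg = SimConfig(photons_per_decay=5000)
        irf = cfg.make_irf()
        rng = np.random.default_rng(31)
        wins = 0
        for _ in range(30):
            hist, _ = gen_decay(
                DecayModel("double", tau_d=3.75, tau_fret=0.75, f_fret=0.5),
                irf, cfg, rng=rng,
            )
            wins += select_model_bic(hist) > 0
        assert wins >= 27


class TestFretToBinding:
    def test_metaphase_conversion(self):
        # 13% FRET corresponds to 31% of NDC80 bound
        assert round(100 * fret_to_binding(0.13), 0) == 31

    def test_anaphase_conversion(self):
        assert round(100 * fret_to_binding(0.18), 0) == 43

    def test_zero_maps_to_zero(self):
        assert fret_to_binding(0.0) == 0.0

    @given(f_bound=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_with_forward_conversion_is_identity(self, f_bound):
        assert fret_to_binding(0.42 * f_bound) == pytest.approx(f_bound, abs=1e-12)

    def test_excess_fret_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert fret_to_binding(0.9) == 1.0

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            fret_to_binding(0.1, slope=0.0)
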