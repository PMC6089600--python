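"""Aurora B activation / phosphorylation / binding model and its fits."""

import numpy as np
import pandas as pd
import pytest

from ktflim.simulate import gen_tension_table, gen_timecourse
from ktflim.tension import (
    AuroraActivationParams,
    IntensityCalibration,
    PhosBindingParams,
    SensorCalibration,
    UnidentifiableError,
    active_aurora,
    binding_fraction,
    binding_from_concentration,
    fit_conc_binding,
    fit_exp_timecourse,
    fit_phos_binding,
    incenp_to_concentration,
    ode_steady_state_oracle,
    phos_fraction,
    predict_binding_vs_kk,
    sensor_to_phos,
)


class TestClosedForms:
    def test_active_aurora_continuous_at_threshold(self, aurora_params):
        below = active_aurora(np.nextafter(4.6, 0), aurora_params)
        at = active_aurora(4.6, aurora_params)
        assert at == pytest.approx(below, abs=1e-12)
        assert at == pytest.approx(4.6 - 3.5)

    def test_active_aurora_above_threshold(self, aurora_params):
        assert active_aurora(10.0, aurora_params) == pytest.approx(6.5)

    def test_active_aurora_plateau_below_threshold(self, aurora_params):
        assert active_aurora(2.0, aurora_params) == pytest.approx(1.1)

    def test_invalid_threshold_ordering_rejected(self):
        with pytest.raises(ValueError):
            AuroraActivationParams(K=5.0, A_star=4.0)

    def test_phos_fraction_half_saturation(self):
        assert phos_fraction(19.0, 19.0) == pytest.approx(0.5)

    def test_phos_fraction_saturates(self):
        assert phos_fraction(1e9, 19.0) == pytest.approx(1.0, abs=1e-7)

    def test_phos_fraction_at_plateau_kinase_level(self):
        assert phos_fraction(1.1, 19.0) == pytest.approx(0.0547, abs=1e-4)

    def test_binding_fraction_unphosphorylated(self, phos_binding_params):
        assert binding_fraction(0.0, phos_binding_params) == pytest.approx(
            0.4115, abs=1e-4)

    def test_binding_fraction_at_late_prometaphase_phos_level(
        self, phos_binding_params
    ):
        assert binding_fraction(1.0 / 9.0, phos_binding_params) == pytest.approx(
            0.2257, abs=1e-4)

    def test_binding_insensitive_to_phos_when_coupling_absent(self):
        pb = PhosBindingParams(Kphos=19.0, K0=1.43, K0_prime=0.0)
        vals = {binding_fraction(f, pb) for f in (0.0, 0.3, 1.0)}
        assert len(vals) == 1

    def test_full_chain_at_fitted_parameters(self, aurora_params,
                                             phos_binding_params):
        assert binding_from_concentration(
            10.0, aurora_params, phos_binding_params) == pytest.approx(0.1425, abs=1e-4)

    def test_full_chain_plateau_value(self, aurora_params, phos_binding_params):
        for a in (0.0, 2.0, 4.5):
            assert binding_from_concentration(
                a, aurora_params, phos_binding_params) == pytest.approx(0.2928, abs=1e-4)

    def test_full_chain_continuous_and_monotone(self, aurora_params,
                                                phos_binding_params):
        grid = np.linspace(0.0, 15.0, 600)
        fb = np.array([binding_from_concentration(a, aurora_params,
                                                  phos_binding_params)
                       for a in grid])
        assert np.max(np.abs(np.diff(fb))) < 5e-3  # no jumps
        above = grid > 4.6
        assert np.all(np.diff(fb[above]) < 0)


class TestOdeOracle:
    def test_pool_below_activation_constant_deactivates(self):
        act, _, _ = ode_steady_state_oracle(
            [(1.0, 2.0)], [1.5], kp=1.0, kdp=19.0, kon=1.0, koff0=1.43,
            tol=1e-10,
        )
        assert act == pytest.approx(0.0, abs=1e-6)

    def test_pool_above_activation_constant_reaches_excess(self):
        act, _, _ = ode_steady_state_oracle(
            [(1.0, 2.0)], [5.0], kp=1.0, kdp=19.0, kon=1.0, koff0=1.43,
            tol=1e-10,
        )
        assert act == pytest.approx(3.0, abs=1e-6)

    def test_full_chain_matches_closed_form_at_fitted_parameters(
        self, aurora_params, phos_binding_params
    ):
        # two pools: haspin-dependent (Khd) and -independent (Khi)
        Khi, Khd = 1.0, 2.5
        Ahi = aurora_params.A_star - Khd  # A* = Khd + [Ahi]
        A = 10.0
        act, fp, fb = ode_steady_state_oracle(
            [(1.0, Khd), (1.0, Khi)], [A - Ahi, Ahi],
            kp=1.0, kdp=phos_binding_params.Kphos, kon=1.0,
            koff0=phos_binding_params.K0,
            koff_prime=phos_binding_params.K0_prime, tol=1e-10,
        )
        assert act == pytest.approx(active_aurora(A, aurora_params), abs=1e-6)
        assert fb == pytest.approx(
            binding_from_concentration(A, aurora_params, phos_binding_params),
            abs=1e-6)

    def test_closed_forms_match_oracle_over_parameter_lattice(self):
        # one-pool chain over a 5x5x5 lattice of (K, Kphos, total)
        for K in np.linspace(0.5, 4.0, 5):
            for Kphos in np.linspace(5.0, 30.0, 5):
                for total in np.linspace(K + 0.5, K + 8.0, 5):
                    act, fp, fb = ode_steady_state_oracle(
                        [(1.0, K)], [total], kp=1.0, kdp=Kphos, kon=1.0,
                        koff0=1.43, koff_prime=18.0, tol=1e-10,
                    )
                    assert act == pytest.approx(total - K, abs=1e-6)
                    assert fp == pytest.approx(phos_fraction(total - K, Kphos),
                                               abs=1e-6)
                    pb = PhosBindingParams(Kphos=Kphos, K0=1.43, K0_prime=18.0)
                    assert fb == pytest.approx(binding_fraction(fp, pb), abs=1e-6)


class TestFits:
    def test_phos_binding_noise_free_round_trip(self):
        fp = np.linspace(0.0, 0.12, 10)
        fb = 1.0 / (1.0 + 1.43 + 18.0 * fp)
        params, se, _ = fit_phos_binding(np.column_stack([fp, fb]))
        assert params.K0 == pytest.approx(1.43, abs=1e-8)
        assert params.K0_prime == pytest.approx(18.0, abs=1e-6)

    def test_phos_binding_recovery_under_noise(self, rng):
        fp = np.linspace(0.0, 0.12, 20)
        fb = 1.0 / (1.0 + 1.43 + 18.0 * fp) + rng.normal(0, 0.01, 20)
        params, se, _ = fit_phos_binding(np.column_stack([fp, fb]))
        assert abs(params.K0 - 1.43) < 3 * se["K0"]
        assert abs(params.K0_prime - 18.0) < 3 * se["K0_prime"]

    def test_phos_binding_constant_input_unidentifiable(self):
        data = np.column_stack([np.full(5, 0.1), np.full(5, 0.25)])
        with pytest.raises(UnidentifiableError):
            fit_phos_binding(data)

    def test_conc_binding_noise_free_round_trip(self, aurora_params,
                                                phos_binding_params):
        conc = np.linspace(1.0, 12.0, 11)
        fb = [binding_from_concentration(a, aurora_params, phos_binding_params)
              for a in conc]
        aur, kphos, se, _ = fit_conc_binding(np.column_stack([conc, fb]),
                                             phos_binding_params)
        assert aur.K == pytest.approx(3.5, abs=1e-4)
        assert aur.A_star == pytest.approx(4.6, abs=1e-4)
        assert kphos == pytest.approx(19.0, abs=1e-2)

    def test_conc_binding_recovery_under_noise(self, aurora_params,
                                               phos_binding_params, rng):
        conc = np.linspace(1.0, 12.0, 11)
        fb = np.array([binding_from_concentration(a, aurora_params,
                                                  phos_binding_params)
                       for a in conc]) + rng.normal(0, 0.005, 11)
        aur, _, se, _ = fit_conc_binding(np.column_stack([conc, fb]),
                                         phos_binding_params)
        assert abs(aur.A_star - 4.6) < 3 * se["A_star"]

    def test_conc_binding_plateau_only_data_flagged(self, aurora_params,
                                                    phos_binding_params):
        conc = np.linspace(0.5, 4.0, 8)  # entirely below A* = 4.6
        fb = [binding_from_concentration(a, aurora_params, phos_binding_params)
              for a in conc]
        with pytest.raises(UnidentifiableError):
            fit_conc_binding(np.column_stack([conc, fb]), phos_binding_params)

    def test_conc_binding_fit_is_calibrated(self, aurora_params,
                                            phos_binding_params):
        # the 95% CI for A* should cover the generating value in ~95% of
        # replicates at the fitted noise level
        rng = np.random.default_rng(77)
        conc = np.linspace(1.0, 12.0, 11)
        clean = np.array([binding_from_concentration(a, aurora_params,
                                                     phos_binding_params)
                          for a in conc])
        covered = n_ok = 0
        for _ in range(100):
            fb = clean + rng.normal(0, 0.005, 11)
            try:
                _, _, _, ci = fit_conc_binding(np.column_stack([conc, fb]),
                                               phos_binding_params)
            except UnidentifiableError:
                continue
            n_ok += 1
            covered += ci["A_star"][0] <= 4.6 <= ci["A_star"][1]
        assert n_ok >= 95
        assert abs(covered / n_ok - 0.95) <= 0.05

    def test_tension_table_round_trip(self, aurora_params, phos_binding_params):
        table, truth = gen_tension_table(
            (aurora_params, phos_binding_params), (-3.0, 12.0),
            n=11, noise_sd=0.005, seed=4, dkk_range_um=(0.0, 3.7),
        )
        aur, _, se, _ = fit_conc_binding(
            table[["aurora_uM", "f_bound"]], phos_binding_params)
        assert abs(aur.A_star - 4.6) < 3 * se["A_star"]


class TestSensorAndIntensityMaps:
    def test_anchor_points_map_exactly(self):
        cal = SensorCalibration()
        assert sensor_to_phos(0.540, cal) == pytest.approx(1 / 9, abs=1e-12)
        assert sensor_to_phos(0.368, cal) == pytest.approx(0.0, abs=1e-12)

    def test_affine_map_preserves_midpoints(self):
        assert sensor_to_phos(0.454) == pytest.approx(1 / 18, abs=1e-12)

    def test_extrapolation_below_zero_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert sensor_to_phos(0.2) == 0.0

    def test_degenerate_calibration_rejected(self):
        with pytest.raises(ValueError):
            SensorCalibration(f_sensor_WT=0.4, f_sensor_ZM=0.4)

    def test_peak_intensity_maps_to_peak_concentration(self):
        cal = IntensityCalibration(I_mid_bar=500.0, I_bg=100.0)
        norm, conc = incenp_to_concentration(500.0, cal)
        assert norm == pytest.approx(1.0)
        assert conc == pytest.approx(10.0)

    def test_background_intensity_maps_to_zero(self):
        cal = IntensityCalibration(I_mid_bar=500.0, I_bg=100.0)
        assert incenp_to_concentration(100.0, cal) == (0.0, 0.0)

    def test_linearity_in_background_subtracted_intensity(self):
        cal = IntensityCalibration(I_mid_bar=500.0, I_bg=100.0)
        _, c1 = incenp_to_concentration(300.0, cal)
        _, c2 = incenp_to_concentration(500.0, cal)
        assert c2 == pytest.approx(2 * c1)

    def test_inverted_calibration_rejected(self):
        with pytest.raises(ValueError):
            IntensityCalibration(I_mid_bar=100.0, I_bg=500.0)


class TestPredictBindingVsKk:
    def test_flat_intensity_line_gives_constant_prediction(
        self, aurora_params, phos_binding_params
    ):
        curve = predict_binding_vs_kk((0.0, 8.0), aurora_params,
                                      phos_binding_params,
                                      np.linspace(0.7, 1.6, 10))
        assert curve["f_bound"].nunique() == 1

    def test_decreasing_line_produces_plateau_then_rise(
        self, aurora_params, phos_binding_params
    ):
        # concentration falls below A* at large K-K distance -> binding
        # rises with distance then plateaus
        curve = predict_binding_vs_kk((-8.0, 14.0), aurora_params,
                                      phos_binding_params,
                                      np.linspace(0.7, 2.0, 40))
        fb = curve["f_bound"].to_numpy()
        assert np.all(np.diff(fb) >= -1e-12)
        plateau = curve["aurora_uM"] < 4.6
        assert fb[plateau.to_numpy()].std() < 1e-12

    def test_subthreshold_line_sits_on_plateau_everywhere(
        self, aurora_params, phos_binding_params
    ):
        curve = predict_binding_vs_kk((0.0, 2.0), aurora_params,
                                      phos_binding_params,
                                      np.linspace(0.7, 1.6, 5))
        assert np.allclose(curve["f_bound"], 0.2928, atol=1e-4)


class TestTimecourseFits:
    def test_noise_free_rising_curve_exact_recovery(self):
        t = np.linspace(-5, 20, 40)
        tc, _ = gen_timecourse("rising", A=0.088, tau=3.26, c=0.089, t=t)
        res = fit_exp_timecourse(tc, "rising")
        assert res.A == pytest.approx(0.088, abs=1e-6)
        assert res.tau == pytest.approx(3.26, abs=1e-4)
        assert res.c == pytest.approx(0.089, abs=1e-6)

    def test_rising_baseline_equals_offset_before_onset(self):
        t = np.linspace(-5, 20, 40)
        tc, _ = gen_timecourse("rising", A=0.1, tau=2.0, c=0.07, t=t)
        res = fit_exp_timecourse(tc, "rising")
        pre = tc["t_min"] < 0
        assert np.allclose(tc["y"][pre], res.c, atol=1e-9)

    def test_decaying_recovery_under_noise(self):
        t = np.linspace(-5, 20, 40)
        tc, _ = gen_timecourse("decaying", A=0.17, tau=1.95, c=0.37,
                               t=t, noise_sd=0.01, seed=6)
        res = fit_exp_timecourse(tc, "decaying")
        assert abs(res.tau - 1.95) < 3 * res.se["tau"]

    def test_requires_pre_and_post_onset_samples(self):
        tc = pd.DataFrame({"t_min": [1.0, 2.0, 3.0, 4.0], "y": [1, 2, 3, 4.0]})
        with pytest.raises(ValueError):
            fit_exp_timecourse(tc, "rising")
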