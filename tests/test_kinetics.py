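"""Input-function scaling, Patlak graphical analysis and the irreversible
two-tissue compartment fit."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from neuropet.imaging import TimeActivityCurve
from neuropet.kinetics import (
    InputFunction,
    PatlakModel,
    TwoTissueModel,
    fit_2tcm,
    patlak_modified,
    patlak_standard,
    scale_population_input,
)
from neuropet.simulate import NoiseSpec
from neuropet.simulate.pet import TcmTruth, simulate_2tcm_tac

KI_TRUE = 0.1 * 0.02 / (0.15 + 0.02)  # K1 k3 / (k2 + k3) = 0.011765


class TestScalePopulationInput:
    def test_exact_scalar_recovered(self, aif, schedule):
        mid = schedule.mid_times_min
        blood = TimeActivityCurve(mid, 2.0 * aif.cb_at(mid))
        scaled = scale_population_input(aif, blood, window=(0.0, 60.0))
        np.testing.assert_allclose(scaled.cb, 2.0 * aif.cb, rtol=1e-12)

    def test_empty_window_rejected(self, aif, schedule):
        blood = TimeActivityCurve(schedule.mid_times_min,
                                  aif.cb_at(schedule.mid_times_min))
        with pytest.raises(ValueError, match="window"):
            scale_population_input(aif, blood, window=(100.0, 200.0))

    def test_noisy_scale_recovery_within_2_percent(self, aif, schedule, rng):
        mid = schedule.mid_times_min
        clean = 3.7 * aif.cb_at(mid)
        blood = TimeActivityCurve(mid, clean * (1 + 0.01 * rng.standard_normal(mid.size)))
        scaled = scale_population_input(aif, blood, window=(0.0, 60.0))
        factor = scaled.cb.max() / aif.cb.max()
        assert factor == pytest.approx(3.7, rel=0.02)


class TestPatlakStandard:
    def test_exact_linear_data_recovered_to_machine_precision(self, aif, schedule):
        mid = schedule.mid_times_min
        cp = aif.cp_at(mid)
        x = aif.cumulative_cp(mid) / cp
        ct = cp * (0.005 * x + 0.1)
        res = patlak_standard(TimeActivityCurve(mid, ct), aif, t_star=20.0)
        assert res.ki == pytest.approx(0.005, rel=1e-12)
        assert res.v0 == pytest.approx(0.1, rel=1e-10)

    def test_irreversible_model_slope_recovers_macro_ki(self, aif, schedule):
        tac = simulate_2tcm_tac(aif, TcmTruth(0.1, 0.15, 0.02, 0.0), schedule)
        res = patlak_standard(tac, aif, t_star=20.0)
        assert res.ki == pytest.approx(KI_TRUE, rel=0.01)

    def test_slope_approaches_asymptote_at_late_t_star(self, aif, schedule):
        tac = simulate_2tcm_tac(aif, TcmTruth(0.1, 0.15, 0.02, 0.0), schedule)
        res = patlak_standard(tac, aif, t_star=30.0)
        assert res.ki == pytest.approx(KI_TRUE, rel=0.01)

    def test_no_trapping_gives_zero_slope(self, aif, schedule):
        tac = simulate_2tcm_tac(aif, TcmTruth(0.1, 0.15, 0.0, 0.0), schedule)
        res = patlak_standard(tac, aif, t_star=20.0)
        assert abs(res.ki) < 1e-4

    def test_whole_blood_correction_removes_vb_bias(self, aif, schedule):
        tac = simulate_2tcm_tac(aif, TcmTruth(0.1, 0.15, 0.02, 0.03), schedule)
        plain = patlak_standard(tac, aif, t_star=20.0)
        corrected = PatlakModel(t_star=20.0, vb=0.03).fit(tac, aif).result_
        assert corrected.ki == pytest.approx(KI_TRUE, rel=0.01)
        assert abs(corrected.ki - KI_TRUE) < abs(plain.ki - KI_TRUE)

    def test_window_monotone_in_t_star(self, aif, schedule):
        tac = simulate_2tcm_tac(aif, TcmTruth(), schedule)
        points = [patlak_standard(tac, aif, t_star=ts).n_points
                  for ts in (5.0, 10.0, 20.0, 30.0)]
        assert points == sorted(points, reverse=True)

    def test_too_few_points_rejected(self, aif, schedule):
        tac = simulate_2tcm_tac(aif, TcmTruth(), schedule)
        with pytest.raises(ValueError, match="3 frames"):
            patlak_standard(tac, aif, t_star=64.0)


class TestPatlakModified:
    def test_nested_consistency_without_efflux(self, aif, schedule):
        tac = simulate_2tcm_tac(aif, TcmTruth(0.1, 0.15, 0.02, 0.0), schedule)
        std = patlak_standard(tac, aif, t_star=20.0)
        mod = patlak_modified(tac, aif, t_star=20.0)
        assert mod.variant == "modified"
        assert mod.ki == pytest.approx(std.ki, rel=0.15)

    def test_exact_three_regressor_data_recovered(self, aif, schedule):
        mid = schedule.mid_times_min
        cp = aif.cp_at(mid)
        x = aif.cumulative_cp(mid) / cp
        # fixed-point construction of Ct satisfying the loss-term regression
        ki, v0, k_loss = 0.004, 0.08, 0.01
        ct = cp * (ki * x + v0)
        from scipy.integrate import cumulative_trapezoid

        for _ in range(200):
            cum_ct = cumulative_trapezoid(np.concatenate([[0.0], ct]),
                                          np.concatenate([[0.0], mid]),
                                          initial=0.0)[1:]
            ct_new = cp * (ki * x + v0) - k_loss * cum_ct
            if np.allclose(ct_new, ct, rtol=1e-14, atol=1e-14):
                ct = ct_new
                break
            ct = ct_new
        res = patlak_modified(TimeActivityCurve(mid, ct), aif, t_star=20.0)
        assert res.ki == pytest.approx(ki, rel=1e-6)
        assert res.v0 == pytest.approx(v0, rel=1e-5)
        assert res.k_loss == pytest.approx(k_loss, rel=1e-5)

    def test_efflux_data_bias_ordering(self, aif, schedule):
        """With true tracer loss, the loss-term regression is closer to the
        generating uptake constant than the standard slope."""
        ki, k_loss = 0.01, 0.01

        def rhs(t, y):
            return [ki * aif.cp_at(t) - k_loss * y[0]]

        sol = solve_ivp(rhs, (0.0, schedule.end_time_min), [0.0],
                        dense_output=True, rtol=1e-10, atol=1e-12)
        mid = schedule.mid_times_min
        tac = TimeActivityCurve(mid, sol.sol(mid)[0])
        std = patlak_standard(tac, aif, t_star=20.0)
        mod = patlak_modified(tac, aif, t_star=20.0)
        assert abs(mod.ki - ki) < abs(std.ki - ki)


class TestTwoTissueModel:
    def test_noiseless_inverse_crime_recovery(self, aif, schedule):
        truth = TcmTruth(0.1, 0.15, 0.02, 0.03)
        tac = simulate_2tcm_tac(aif, truth, schedule)
        res = fit_2tcm(tac, aif, schedule)
        assert res.converged
        assert res.k1 == pytest.approx(truth.k1, rel=5e-3)
        assert res.k2 == pytest.approx(truth.k2, rel=5e-3)
        assert res.k3 == pytest.approx(truth.k3, rel=5e-3)
        assert res.vb == pytest.approx(truth.vb, rel=5e-3)
        assert res.ki_macro == pytest.approx(truth.ki_macro, rel=5e-3)

    def test_zero_uptake_gives_zero_macro_ki(self, aif, schedule):
        tac = simulate_2tcm_tac(aif, TcmTruth(0.0, 0.1, 0.01, 0.0), schedule)
        res = fit_2tcm(tac, aif, schedule)
        assert abs(res.ki_macro) < 1e-5

    def test_ki_invariant_to_joint_rescaling(self, aif, schedule):
        import dataclasses

        truth = TcmTruth(0.1, 0.15, 0.02, 0.03)
        tac = simulate_2tcm_tac(aif, truth, schedule)
        scaled_tac = dataclasses.replace(tac, value=7.0 * tac.value)
        scaled_aif = InputFunction(aif.time_min, 7.0 * aif.cb)
        res = fit_2tcm(scaled_tac, scaled_aif, schedule)
        assert res.ki_macro == pytest.approx(truth.ki_macro, rel=5e-3)
        pat_scaled = patlak_standard(scaled_tac, scaled_aif, t_star=30.0)
        pat_plain = patlak_standard(tac, aif, t_star=30.0)
        assert pat_scaled.ki == pytest.approx(pat_plain.ki, rel=1e-9)

    def test_non_finite_tac_rejected(self, aif, schedule):
        tac = simulate_2tcm_tac(aif, TcmTruth(), schedule)
        tac.value[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_2tcm(tac, aif, schedule)
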