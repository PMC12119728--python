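"""Synthetic generators: analytic limits, independent numerical oracles and
seed determinism."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp
from scipy.stats import norm

from neuropet.imaging import SubjectMeta
from neuropet.simulate import (
    FENG_DEFAULTS,
    NoiseSpec,
    make_population_aif,
    simulate_2tcm_tac,
    simulate_dwi_series,
    simulate_feature_table,
    simulate_metabolomics,
    simulate_survival,
)
from neuropet.simulate.aif import feng_curve
from neuropet.simulate.asl_dwi import simulate_asl_pair
from neuropet.simulate.pet import TcmTruth, make_lesion_phantom
from neuropet.asl_dwi import AslAcquisition
from neuropet.stats import km_estimate


class TestPopulationAif:
    def test_zero_at_injection(self, aif):
        assert aif.cb[0] == pytest.approx(0.0, abs=1e-12)

    def test_auc_matches_quadrature_oracle(self, aif):
        p = FENG_DEFAULTS
        oracle, _ = quad(
            lambda t: feng_curve(t, p["a1"], p["a2"], p["a3"], p["l1"], p["l2"], p["l3"]),
            0.0, 60.0, limit=500,
        )
        sel = aif.time_min <= 60.0
        auc = np.trapezoid(aif.cb[sel], aif.time_min[sel])
        assert auc == pytest.approx(oracle, rel=1e-3)

    def test_no_decay_limit_is_monotone(self):
        aif = make_population_aif({"l1": 1e-9, "l2": 1e-9, "l3": 1e-9})
        assert np.all(np.diff(aif.cb) >= -1e-12)

    def test_negative_early_curve_rejected(self):
        with pytest.raises(ValueError):
            make_population_aif({"a1": 0.1, "a2": 500.0, "l1": 1e-6})


class TestSimulate2tcm:
    def test_k1_zero_gives_pure_blood_signal(self, aif, schedule):
        from neuropet.kinetics import frame_average

        tac = simulate_2tcm_tac(aif, TcmTruth(0.0, 0.1, 0.01, 0.05), schedule)
        blood = frame_average(aif.time_min, aif.cb, schedule)
        np.testing.assert_allclose(tac.value, 0.05 * blood, rtol=1e-12)

    def test_k3_zero_reaches_distribution_volume_plateau(self, aif, schedule):
        k1, k2 = 0.1, 0.5
        tac = simulate_2tcm_tac(aif, TcmTruth(k1, k2, 0.0, 0.0), schedule)
        late = tac.time_min > 40
        ratio = tac.value[late] / aif.cp_at(tac.time_min[late])
        np.testing.assert_allclose(ratio, k1 / k2, rtol=0.05)

    def test_matches_ode_integration_oracle(self, aif, schedule):
        """Frame-averaged closed-form curve vs explicit ODE solution."""
        k1, k2, k3, vb = 0.1, 0.15, 0.02, 0.03

        def rhs(t, y):
            cp = aif.cp_at(t)
            return [k1 * cp - (k2 + k3) * y[0], k3 * y[0]]

        sol = solve_ivp(rhs, (0.0, schedule.end_time_min), [0.0, 0.0],
                        dense_output=True, rtol=1e-10, atol=1e-12, max_step=0.05)
        t_fine = np.arange(0, schedule.end_time_min + 1e-9, 0.1 / 60.0)
        free, bound = sol.sol(t_fine)
        oracle_curve = (1 - vb) * (free + bound) + vb * aif.cb_at(t_fine)
        from neuropet.kinetics import frame_average

        oracle = frame_average(t_fine, oracle_curve, schedule)
        tac = simulate_2tcm_tac(aif, TcmTruth(k1, k2, k3, vb), schedule)
        np.testing.assert_allclose(tac.value, oracle, rtol=5e-3)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            TcmTruth(-0.1, 0.15, 0.02, 0.03)

    def test_noise_is_seed_reproducible(self, aif, schedule):
        kwargs = dict(noise=NoiseSpec("frame-gaussian", 0.05, 42))
        a = simulate_2tcm_tac(aif, TcmTruth(), schedule, **kwargs)
        b = simulate_2tcm_tac(aif, TcmTruth(), schedule, **kwargs)
        np.testing.assert_array_equal(a.value, b.value)


class TestLesionPhantom:
    def test_zero_radius_rejected(self, aif, schedule):
        with pytest.raises(ValueError, match="radius"):
            make_lesion_phantom(aif, TcmTruth(), schedule=schedule, lesion_radius=0.0)

    def test_4_to_1_contrast_gives_suvmax_ratio_4(self, aif, schedule, meta):
        from neuropet import static_pet

        # vb = 0 keeps the curve exactly linear in K1, so a quarter-scale
        # background gives a 4:1 uptake contrast by construction
        lesion = TcmTruth(0.1, 0.15, 0.02, 0.0)
        quarter = TcmTruth(0.025, 0.15, 0.02, 0.0)
        ph = make_lesion_phantom(aif, lesion, background_truth=quarter,
                                 schedule=schedule, shape=(24, 24, 24),
                                 lesion_radius=5.0)
        les = static_pet.suv_statistics(ph.image, ph.lesion_mask, meta)
        bg = static_pet.suv_statistics(ph.image, ph.background_mask, meta)
        assert les.suv_max / bg.suv_max == pytest.approx(4.0, rel=1e-9)

    def test_nested_sphere_dice_matches_voxel_count(self, aif, schedule):
        from neuropet.static_pet import overlap

        ph = make_lesion_phantom(aif, TcmTruth(), schedule=schedule,
                                 shape=(32, 32, 32), lesion_radius=6.0, ce_radius=5.0)
        v6 = ph.lesion_mask.n_voxels
        v5 = ph.ce_mask.n_voxels
        res = overlap(ph.lesion_mask, ph.ce_mask)
        assert res.dice == pytest.approx(2 * v5 / (v5 + v6))


class TestAslDwiSimulators:
    def test_zero_cbf_makes_control_equal_label(self):
        c, l, _ = simulate_asl_pair(0.0, AslAcquisition())
        np.testing.assert_array_equal(c, l)

    def test_dwi_closed_form_ratio(self):
        sig = simulate_dwi_series(800e-6, [0.0, 1000.0])
        assert sig[1] / sig[0] == pytest.approx(np.exp(-0.8), rel=1e-12)

    def test_zero_adc_gives_flat_series(self):
        sig = simulate_dwi_series(0.0, [0.0, 500.0, 1000.0])
        np.testing.assert_allclose(sig, sig[0])

    def test_duplicate_b_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            simulate_dwi_series(1e-3, [0.0, 500.0, 500.0])


class TestFeatureTable:
    def test_seed_reproducibility(self):
        a, ya, _ = simulate_feature_table(seed=7)
        b, yb, _ = simulate_feature_table(seed=7)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())
        np.testing.assert_array_equal(ya, yb)

    def test_null_effect_has_chance_auc(self):
        from neuropet.gpv import evaluate_classifier

        aucs = []
        for seed in range(30):
            x, y, _ = simulate_feature_table(n_lesions=100, effect_size=0.0, seed=seed)
            if np.unique(y).size < 2:
                continue
            aucs.append(evaluate_classifier(x.iloc[:, 0], y).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_large_effect_approaches_bayes_auc(self):
        # optimal score is the support sum; for shift d per feature the
        # normal-means AUC is Phi(d * sqrt(support) / sqrt(2))
        x, y, w = simulate_feature_table(n_lesions=400, effect_size=5.0,
                                         support=3, seed=3)
        from neuropet.gpv import evaluate_classifier

        score = x.iloc[:, :3].sum(axis=1)
        bayes = norm.cdf(5.0 * np.sqrt(3) / np.sqrt(2))
        assert bayes > 0.99
        assert evaluate_classifier(score, y).auc > 0.99

    def test_support_larger_than_features_rejected(self):
        with pytest.raises(ValueError):
            simulate_feature_table(n_features=5, support=6)


class TestSurvivalSimulator:
    def test_km_median_matches_exponential_truth(self):
        rec = simulate_survival(2000, np.log(2) / 15.0, seed=11)
        km = km_estimate(rec["time_months"], rec["event"])
        assert 14.0 <= km.median <= 16.0

    def test_full_censoring_leaves_median_undefined(self):
        rec = simulate_survival(50, np.log(2) / 4.0, censoring_rate=1.0, seed=1)
        assert not rec["event"].any()
        km = km_estimate(rec["time_months"], rec["event"])
        assert np.isnan(km.median)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_survival(10, 0.0)


class TestMetabolomicsSimulator:
    def test_null_panel_is_calibrated(self):
        from neuropet.stats import metabolite_screen

        matrix, groups, _ = simulate_metabolomics(
            n_metabolites=1000, n_carnitine=0, fold_change=1.0, seed=5
        )
        screen = metabolite_screen(matrix, groups, [("HGG", "LGG")])
        rate = np.mean(screen["p"] <= 0.05)
        assert 0.03 <= rate <= 0.07

    def test_elevated_block_tops_q_ranking(self):
        from neuropet.stats import metabolite_screen

        matrix, groups, truth = simulate_metabolomics(
            n_metabolites=200, n_carnitine=20, fold_change=6.0, seed=6
        )
        screen = metabolite_screen(matrix, groups, [("HGG", "LGG")])
        top = screen.sort_values("q").head(20)["metabolite"]
        hits = sum(name in truth["carnitine_block"] for name in top)
        assert hits >= 18

    def test_seed_reproducibility_and_small_groups_rejected(self):
        a, _, _ = simulate_metabolomics(seed=9)
        b, _, _ = simulate_metabolomics(seed=9)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())
        with pytest.raises(ValueError):
            simulate_metabolomics(n_per_group={"LGG": 1, "HGG": 3, "METS": 3})
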