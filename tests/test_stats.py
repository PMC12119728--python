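"""Group comparisons, Kaplan-Meier survival and the metabolomics screen."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neuropet.stats import (
    compare_groups,
    dichotomise_survival,
    km_estimate,
    metabolite_screen,
    pca_overview,
)


class TestCompareGroups:
    def test_identical_groups_are_not_significant(self):
        table = pd.DataFrame({"v": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        res = compare_groups(table, ["a"] * 3 + ["b"] * 3)
        assert res["p_value"].iloc[0] > 0.9

    def test_complete_separation_matches_exact_enumeration(self):
        """n = 10 vs 10 fully separated: two-sided exact p = 2 / C(20, 10)."""
        table = pd.DataFrame({"v": list(range(10)) + list(range(100, 110))})
        res = compare_groups(table, ["a"] * 10 + ["b"] * 10, method="exact")
        expected = 2.0 / math.comb(20, 10)
        assert res["p_value"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_null_rejection_rate_calibrated(self, rng):
        """10 000 null replicates: rank-sum alpha level within [0.04, 0.06]."""
        n = 20
        a = rng.standard_normal((10000, n))
        b = rng.standard_normal((10000, n))
        p = sps.mannwhitneyu(a, b, alternative="two-sided", axis=1).pvalue
        rate = np.mean(p <= 0.05)
        assert 0.04 <= rate <= 0.06

    def test_undersized_group_rejected(self):
        table = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            compare_groups(table, ["a", "b", "b"])


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survivor_function(self, rng):
        times = rng.exponential(10.0, 200)
        km = km_estimate(times, np.ones(200, bool))
        emp = np.array([np.mean(times > t) for t in km.time])
        np.testing.assert_allclose(km.survival, emp, atol=1e-12)

    def test_single_event_step(self):
        km = km_estimate([5.0], [True])
        assert km.survival[km.time < 5.0] == pytest.approx(1.0)
        assert km.survival[-1] == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [False, False, False])
        np.testing.assert_allclose(km.survival, 1.0)
        assert np.isnan(km.median)

    def test_five_record_hand_example(self):
        """Events at 1 and 3; censored at 2, 4, 5 (hand product-limit)."""
        km = km_estimate([1.0, 2.0, 3.0, 4.0, 5.0],
                         [True, False, True, False, False])
        s = dict(zip(km.time, km.survival))
        assert s[1.0] == pytest.approx(4 / 5)
        assert s[3.0] == pytest.approx(4 / 5 * 2 / 3)
        assert s[5.0] == pytest.approx(4 / 5 * 2 / 3)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [True, True])


class TestDichotomiseSurvival:
    def _records(self, low_times, high_times):
        return pd.DataFrame({
            "time_months": list(low_times) + list(high_times),
            "event": [True] * (len(low_times) + len(high_times)),
            "SUVmax": [1.0] * len(low_times) + [3.0] * len(high_times),
        })

    def test_small_sample_medians(self):
        rec = self._records([10.0, 15.0, 20.0], [2.0, 4.0, 6.0])
        comp = dichotomise_survival(rec, "SUVmax", 2.0)
        assert comp.median_low == pytest.approx(15.0)
        assert comp.median_high == pytest.approx(4.0)
        assert 0.0 < comp.p_mann_whitney <= 1.0
        assert 0.0 < comp.p_logrank <= 1.0

    def test_marker_relabelling_above_cutoff_is_irrelevant(self):
        rec = self._records([10.0, 15.0, 20.0], [2.0, 4.0, 6.0])
        relabelled = rec.assign(SUVmax=rec["SUVmax"].map({1.0: 0.3, 3.0: 99.0}))
        a = dichotomise_survival(rec, "SUVmax", 2.0)
        b = dichotomise_survival(relabelled, "SUVmax", 2.0)
        assert (a.median_low, a.median_high) == (b.median_low, b.median_high)
        assert a.p_mann_whitney == b.p_mann_whitney

    def test_empty_group_names_cutoff(self):
        rec = self._records([10.0, 15.0], [])
        with pytest.raises(ValueError, match="5.0"):
            dichotomise_survival(rec, "SUVmax", 5.0)


class TestMetaboliteScreen:
    def _matrix(self, a, b):
        return pd.DataFrame(
            [list(a) + list(b)], index=["m1"],
            columns=[f"s{i}" for i in range(len(a) + len(b))],
        )

    def test_identical_groups_fold_one_not_significant(self):
        m = self._matrix([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = metabolite_screen(m, ["g1"] * 3 + ["g2"] * 3, [("g1", "g2")])
        assert res["fold_change"].iloc[0] == pytest.approx(1.0)
        assert res["category"].iloc[0] == "ns"

    def test_welch_t_and_df_match_hand_formula(self):
        """Unequal-variance toy: t and the Welch-Satterthwaite df by hand."""
        a = np.log([1.0, 2.0, 3.0])
        b = np.log([2.0, 4.0, 9.0])
        va, vb = a.var(ddof=1), b.var(ddof=1)
        t_hand = (a.mean() - b.mean()) / np.sqrt(va / 3 + vb / 3)
        df_hand = (va / 3 + vb / 3) ** 2 / (
            (va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2
        )
        p_hand = 2 * sps.t.sf(abs(t_hand), df_hand)
        m = self._matrix(np.exp(a), np.exp(b))
        res = metabolite_screen(m, ["g1"] * 3 + ["g2"] * 3, [("g1", "g2")])
        assert res["t"].iloc[0] == pytest.approx(t_hand, rel=1e-12)
        assert res["p"].iloc[0] == pytest.approx(p_hand, rel=1e-12)

    def test_q_dominates_p_under_bh(self, rng):
        m = pd.DataFrame(np.exp(rng.standard_normal((50, 12))),
                         columns=[f"s{i}" for i in range(12)])
        res = metabolite_screen(m, ["g1"] * 6 + ["g2"] * 6, [("g1", "g2")])
        assert (res["q"] >= res["p"] - 1e-12).all()
        # q is a monotone non-decreasing function of the sorted p-values
        srt = res.sort_values("p")
        assert (np.diff(srt["q"]) >= -1e-12).all()

    def test_p_invariant_to_common_affine_rescale_of_logged_data(self, rng):
        data = rng.standard_normal((20, 10))
        cols = [f"s{i}" for i in range(10)]
        groups = ["g1"] * 5 + ["g2"] * 5
        base = metabolite_screen(pd.DataFrame(data, columns=cols), groups,
                                 [("g1", "g2")], already_log=True)
        scaled = metabolite_screen(pd.DataFrame(3.7 * data + 1.0, columns=cols),
                                   groups, [("g1", "g2")], already_log=True)
        np.testing.assert_allclose(scaled["p"], base["p"], rtol=1e-10)

    def test_zero_variance_flagged_not_crashed(self):
        m = self._matrix([2.0, 2.0, 2.0], [5.0, 5.0, 5.0])
        res = metabolite_screen(m, ["g1"] * 3 + ["g2"] * 3, [("g1", "g2")])
        assert res["category"].iloc[0] == "flagged"
        assert np.isnan(res["p"].iloc[0])


class TestPcaOverview:
    def test_collinear_data_loads_on_single_component(self, rng):
        t = rng.standard_normal(30)
        samples = np.outer([1.0, 2.0, -0.5], t) + 5.0  # metabolites x samples
        res = pca_overview(pd.DataFrame(np.exp(samples.T)).T, n_components=2)
        assert res.percent_variance[0] == pytest.approx(100.0, abs=1e-8)

    def test_variance_fractions_match_svd_oracle(self):
        m = pd.DataFrame(
            np.exp(np.array([[1.0, 2.0, 0.5], [0.2, 1.1, 3.0],
                             [2.2, 0.1, 1.0], [0.7, 0.7, 0.9]])).T,
            columns=list("abcd"),
        )
        res = pca_overview(m, n_components=3)
        centred = np.log(m.to_numpy()).T
        centred = centred - centred.mean(axis=0)
        sv = np.linalg.svd(centred, compute_uv=False)
        oracle = 100.0 * sv**2 / np.sum(sv**2)
        np.testing.assert_allclose(res.percent_variance, oracle[:3], atol=1e-10)

    def test_isotropic_gaussian_splits_variance_evenly(self, rng):
        data = rng.standard_normal((2, 4000))
        res = pca_overview(pd.DataFrame(data), n_components=2, already_log=True)
        assert res.percent_variance[0] == pytest.approx(50.0, abs=3.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pca_overview(pd.DataFrame({"s0": [1.0, 2.0]}))
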