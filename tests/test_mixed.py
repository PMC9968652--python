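"""Mixed-model year contrasts and the foraging -> song regression."""

import numpy as np
import pandas as pd
import pytest

from bluecall.mixed import (
    fit_year_lmm,
    foraging_reproduction_lmm,
    summer_subset,
    tukey_pairwise_labeled,
)


def make_panel(year_means, site_sd=2.0, noise_sd=5.0, n_sites=5, seed=0):
    rng = np.random.default_rng(seed)
    offs = rng.normal(0, site_sd, n_sites)
    rows = []
    for year, m in year_means.items():
        dates = pd.date_range(f"{year}-01-01", periods=59, freq="D")
        for i in range(n_sites):
            vals = m + offs[i] + rng.normal(0, noise_sd, len(dates))
            rows += [
                {"site_id": f"s{i}", "date": d, "dcall_count": v}
                for d, v in zip(dates, vals)
            ]
    return pd.DataFrame(rows)


class TestSummerSubset:
    def test_full_coverage_gives_59_days_per_site(self):
        daily = make_panel({2017: 10.0}, n_sites=3)
        sub = summer_subset(daily, [2017])
        assert (sub.groupby("site_id").size() == 59).all()

    def test_leap_february_29_excluded(self):
        dates = pd.date_range("2016-01-01", "2016-03-05", freq="D")
        daily = pd.DataFrame({"site_id": "a", "date": dates, "dcall_count": 1.0})
        sub = summer_subset(daily, [2016])
        assert len(sub) == 59
        assert pd.Timestamp("2016-02-29") not in set(sub["date"])

    def test_empty_window_rejected(self):
        daily = make_panel({2017: 10.0})
        with pytest.raises(ValueError, match="summer"):
            summer_subset(daily, [1999])


class TestFitYearLMM:
    def test_null_rarely_rejected(self):
        # sanity bound at unit-test scale; the tight type-I bound is
        # checked at 500 replicates in the acceptance suite
        rejections = 0
        n = 60
        for s in range(n):
            panel = summer_subset(make_panel({2016: 20, 2017: 20, 2018: 20}, seed=s),
                                  [2016, 2017, 2018])
            fit = fit_year_lmm(panel, "dcall_count")
            rejections += fit.p_value < 0.05
        assert rejections / n <= 0.15 + 1e-9

    def test_two_sd_shift_detected(self):
        hits = 0
        for s in range(20):
            # 2 SD of the daily noise
            panel = summer_subset(make_panel({2016: 20, 2017: 30, 2018: 20}, seed=100 + s),
                                  [2016, 2017, 2018])
            fit = fit_year_lmm(panel, "dcall_count")
            hits += fit.p_value < 0.01
        assert hits / 20 >= 0.95

    def test_chi_square_is_twice_loglik_gap_nonnegative(self):
        panel = summer_subset(make_panel({2016: 20, 2017: 25}, seed=1), [2016, 2017])
        fit = fit_year_lmm(panel, "dcall_count")
        assert fit.chi_square >= 0
        assert fit.df == 1

    def test_site_offsets_absorbed_by_random_intercept(self):
        panel = summer_subset(
            make_panel({2016: 20, 2017: 20}, site_sd=8.0, noise_sd=2.0, seed=2),
            [2016, 2017],
        )
        fit = fit_year_lmm(panel, "dcall_count")
        assert fit.random_intercept_sd > 2.0
        assert fit.p_value > 0.01

    def test_constant_response_degenerate(self):
        panel = summer_subset(make_panel({2016: 5, 2017: 5}, site_sd=0, noise_sd=0, seed=3),
                              [2016, 2017])
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_year_lmm(panel, "dcall_count")
        assert fit.degenerate

    def test_single_site_falls_back_with_warning(self):
        panel = summer_subset(make_panel({2016: 10, 2017: 20}, n_sites=1, seed=4),
                              [2016, 2017])
        with pytest.warns(UserWarning, match="single site"):
            fit = fit_year_lmm(panel, "dcall_count")
        assert fit.single_site_fallback
        assert fit.p_value < 0.05


class TestTukeyPairwise:
    def test_three_levels_three_contrasts(self):
        panel = summer_subset(make_panel({2016: 20, 2017: 25, 2018: 20}, seed=5),
                              [2016, 2017, 2018])
        fit = fit_year_lmm(panel, "dcall_count")
        contrasts = tukey_pairwise_labeled(fit, "2016")
        assert len(contrasts) == 3
        assert {tuple(sorted(c.pair)) for c in contrasts} == {
            ("2016", "2017"), ("2016", "2018"), ("2017", "2018"),
        }

    def test_planted_pattern_2017_stands_out(self):
        hits = 0
        n = 25
        for s in range(n):
            panel = summer_subset(make_panel({2016: 20, 2017: 30, 2018: 20}, seed=200 + s),
                                  [2016, 2017, 2018])
            fit = fit_year_lmm(panel, "dcall_count")
            p = {tuple(sorted(c.pair)): c.adjusted_p for c in tukey_pairwise_labeled(fit, "2016")}
            hits += (
                p[("2016", "2017")] < 0.05
                and p[("2017", "2018")] < 0.05
                and p[("2016", "2018")] >= 0.05
            )
        assert hits / n >= 0.80

    def test_identical_levels_rarely_significant(self):
        sig = 0
        n = 20
        for s in range(n):
            panel = summer_subset(make_panel({2016: 20, 2017: 20, 2018: 20}, seed=300 + s),
                                  [2016, 2017, 2018])
            fit = fit_year_lmm(panel, "dcall_count")
            p = [c.adjusted_p for c in tukey_pairwise_labeled(fit, "2016")]
            sig += any(q < 0.05 for q in p)
        assert sig / n <= 0.10 + 1e-9


def coupling_pairs(slope, seed, n_sites=5, years=(2016, 2017), noise_sd=0.2):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_sites):
        off = rng.normal(0, 0.3)
        for y in years:
            summer = rng.uniform(5, 30)
            fall = 2.0 + off + slope * summer + rng.normal(0, noise_sd)
            rows.append({"site_id": f"s{i}", "year": y,
                         "summer_dcall_mean": summer, "fall_sii_mean": fall})
    return pd.DataFrame(rows)


class TestForagingReproductionLMM:
    def test_positive_coupling_recovered(self):
        hits = 0
        for s in range(20):
            res = foraging_reproduction_lmm(coupling_pairs(0.08, seed=s))
            hits += res.slope > 0 and res.p_value < 0.05
        assert hits / 20 >= 0.90

    def test_null_coupling_ci_covers_zero(self):
        covered = 0
        for s in range(20):
            res = foraging_reproduction_lmm(coupling_pairs(0.0, seed=100 + s))
            covered += res.slope_ci[0] <= 0.0 <= res.slope_ci[1]
        assert covered / 20 >= 0.90

    def test_constant_fall_means_degenerate(self):
        pairs = coupling_pairs(0.0, seed=0, noise_sd=0.0)
        pairs["fall_sii_mean"] = 3.0
        with pytest.warns(UserWarning, match="degenerate"):
            res = foraging_reproduction_lmm(pairs)
        assert res.degenerate

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="4"):
            foraging_reproduction_lmm(coupling_pairs(0.1, seed=1).head(3))
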