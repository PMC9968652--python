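"""Synthetic-data generators: planted ground truth must be recoverable."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bluecall.synth import (
    GridSpec,
    NZ_REGION,
    measure_band_snr,
    synth_call_series,
    synth_catches,
    synth_clip,
    synth_env,
)
from bluecall.brt import extract_env_series


class TestSynthClip:
    def test_no_events_gives_pure_noise_and_empty_annotations(self):
        clip, anns = synth_clip(60.0, "song", [], seed=0)
        assert len(anns) == 0
        assert clip.duration_s == pytest.approx(60.0)
        assert np.all(np.isfinite(clip.samples))

    def test_same_seed_bit_identical(self):
        c1, _ = synth_clip(30.0, "dcall", [5.0, 15.0], snr_db=12, seed=42)
        c2, _ = synth_clip(30.0, "dcall", [5.0, 15.0], snr_db=12, seed=42)
        assert np.array_equal(c1.samples, c2.samples)

    def test_different_seed_differs(self):
        c1, _ = synth_clip(30.0, "song", [], seed=1)
        c2, _ = synth_clip(30.0, "song", [], seed=2)
        assert not np.array_equal(c1.samples, c2.samples)

    @pytest.mark.parametrize("call_type,snr", [("song", 20), ("song", 10), ("dcall", 15), ("dcall", 6)])
    def test_planted_event_band_snr_within_1p5_db(self, call_type, snr):
        clip, anns = synth_clip(120.0, call_type, [50.0], snr_db=snr, seed=snr)
        measured = measure_band_snr(clip, anns.entries[0])
        assert measured == pytest.approx(snr, abs=1.5)

    def test_annotation_box_matches_event(self):
        clip, anns = synth_clip(60.0, "dcall", [10.0], snr_db=20, seed=3)
        a = anns.entries[0]
        assert a.start_s == 10.0
        assert a.end_s == pytest.approx(13.0)
        assert (a.low_hz, a.high_hz) == (25.0, 90.0)

    def test_every_event_annotated_once(self):
        times = [5.0, 30.0, 55.0]
        _, anns = synth_clip(80.0, "song", times, seed=4)
        assert sorted(a.start_s for a in anns) == times

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            synth_clip(60.0, "dcall", [10.0, 11.0], seed=0)

    def test_event_outside_clip_rejected(self):
        with pytest.raises(ValueError):
            synth_clip(20.0, "song", [19.0], seed=0)


class TestSynthEnv:
    def test_no_heatwave_zero_noise_gives_zero_anomaly(self):
        dates = pd.date_range("2016-01-01", periods=40)
        env = synth_env(dates, GridSpec(nlon=4, nlat=4), sst_noise_sd=0.0, seed=0)
        assert np.allclose(env.data["sst_anom"], 0.0, atol=1e-12)

    def test_heatwave_window_mean_anomaly_recovers_amplitude(self):
        dates = pd.date_range("2016-01-01", periods=120)
        env = synth_env(
            dates,
            GridSpec(nlon=4, nlat=4),
            heatwave_windows=[("2016-02-01", "2016-03-15", 3.0)],
            seed=1,
        )
        d = env.data
        inwin = (d["date"] >= "2016-02-01") & (d["date"] <= "2016-03-15")
        assert d.loc[inwin, "sst_anom"].mean() == pytest.approx(3.0, abs=0.15)
        assert d.loc[~inwin, "sst_anom"].mean() == pytest.approx(0.0, abs=0.15)

    def test_npp_coupling_slope_recovered_by_regression(self):
        dates = pd.date_range("2016-01-01", periods=240)
        beta = -0.3
        env = synth_env(
            dates,
            GridSpec(nlon=5, nlat=5),
            heatwave_windows=[("2016-03-01", "2016-06-01", 3.0)],
            coupling=beta,
            seed=2,
            npp_noise_sd=0.05,
        )
        # composite NPP vs daily anomaly: regress on composite-window means
        d = env.data.copy()
        d["block"] = (d["date"] - d["date"].min()).dt.days // 8
        g = d.groupby(["block", "lon", "lat"]).agg(
            log_npp=("npp", lambda v: np.log(v.iloc[0])), anom=("sst_anom", "mean")
        )
        res = stats.linregress(g["anom"], g["log_npp"])
        assert res.slope == pytest.approx(beta, abs=0.03)

    def test_npp_positive_and_composited(self):
        dates = pd.date_range("2016-01-01", periods=32)
        env = synth_env(dates, GridSpec(nlon=3, nlat=3), seed=3)
        assert (env.data["npp"] > 0).all()
        one_cell = env.data[(env.data["lon"] == env.data["lon"].iloc[0]) &
                            (env.data["lat"] == env.data["lat"].iloc[0])]
        # 32 days -> exactly 4 distinct composite values
        assert one_cell["npp"].nunique() == 4

    def test_empty_dates_error(self):
        with pytest.raises(ValueError, match="empty"):
            synth_env(pd.DatetimeIndex([]), GridSpec())


class TestSynthCallSeries:
    @pytest.fixture(scope="class")
    @staticmethod
    def env_site():
        dates = pd.date_range("2016-01-01", periods=730)
        env = synth_env(
            dates, GridSpec(nlon=6, nlat=6),
            heatwave_windows=[("2016-11-01", "2017-02-28", 2.5)], seed=4,
        )
        return extract_env_series(env, (166.2, -45.5), radius_km=40.0)

    def test_zero_coefficients_long_run_mean_is_intercept_exp(self, env_site):
        coeffs = {"intercept": np.log(5.0), "log_npp": 0, "sst": 0,
                  "sst_anom": 0, "month_cos": 0, "month_sin": 0}
        _, series = synth_call_series(env_site, coefficients=coeffs, seed=5)
        # Poisson(5) over 730 days: mean within 4 SE
        se = np.sqrt(5 / len(series))
        assert series["dcall_count"].mean() == pytest.approx(5.0, abs=4 * se)

    def test_positive_lognpp_coefficient_gives_positive_correlation(self, env_site):
        coeffs = {"intercept": 1.0, "log_npp": 0.8, "sst": 0, "sst_anom": 0,
                  "month_cos": 0, "month_sin": 0}
        _, series = synth_call_series(env_site, coefficients=coeffs, seed=6)
        merged = env_site.merge(series, on="date")
        r = stats.pearsonr(merged["dcall_count"], merged["log_npp"])[0]
        assert r > 0

    def test_truth_records_generating_values(self, env_site):
        truth, series = synth_call_series(env_site, seed=7)
        assert len(truth.data) == len(series)
        assert (truth.data["planted_dcall_rate"] > 0).all()
        assert "log_npp" in truth.coefficients


class TestSynthCatches:
    def test_positions_inside_nz_region(self):
        catches = synth_catches(100, seed=0)
        df = catches.to_frame()
        assert df["lon"].between(NZ_REGION[0], NZ_REGION[1]).all()
        assert df["lat"].between(NZ_REGION[2], NZ_REGION[3]).all()

    def test_zero_sd_linear_growth_collinear(self):
        catches = synth_catches(80, conception_sd_days=0.0, seed=1)
        df = catches.to_frame().dropna(subset=["fetal_length_cm"])
        # all lengths lie on one line in days since the June-1 conception
        for _, row in df.iterrows():
            date = pd.Timestamp(row["date"])
            ages = [
                (date - (pd.Timestamp(year=y, month=1, day=1) + pd.Timedelta(days=151))).days
                for y in (date.year, date.year - 1)
            ]
            age = next(a for a in ages if 0 <= a <= 334)
            # one-day slack: catch dates are normalized to midnight
            assert row["fetal_length_cm"] == pytest.approx(
                700.0 * age / 334.0, abs=700 / 334 + 1e-6
            )

    def test_maximum_fetal_lengths_near_birth_doy(self):
        catches = synth_catches(600, seed=2)
        df = catches.to_frame().dropna(subset=["fetal_length_cm"])
        top = df.nlargest(30, "fetal_length_cm")
        doys = pd.DatetimeIndex(top["date"]).dayofyear.to_numpy()
        ang = doys / 365 * 2 * np.pi
        mean_doy = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi) * 365 % 365
        birth = (152 + 334) % 365  # day 121
        assert abs(mean_doy - birth) <= 20

    def test_catch_window_respected(self):
        catches = synth_catches(50, catch_window=(32, 151), seed=3)
        doys = pd.DatetimeIndex(catches.to_frame()["date"]).dayofyear
        assert ((doys >= 32) & (doys <= 151)).all()

    def test_impossible_window_warns_and_returns_partial(self):
        with pytest.warns(UserWarning, match="incompatible"):
            out = synth_catches(
                10, conception_sd_days=0.0, gestation_days=30.0,
                catch_window=(250, 260), seed=4,
            )
        assert len(out) < 10

    def test_determinism(self):
        a = synth_catches(40, seed=9).to_frame()
        b = synth_catches(40, seed=9).to_frame()
        pd.testing.assert_frame_equal(a, b)
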