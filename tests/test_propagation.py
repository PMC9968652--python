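"""Ambient-noise percentiles, transmission loss, and detection areas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bluecall.propagation import (
    band_noise_percentile,
    daily_mean_area,
    detection_area,
    make_grid,
    transmission_loss,
)
from bluecall.spectro import compute_spectrogram
from bluecall.synth import synth_clip
from bluecall.types import DetectionAreaEstimate, NoiseEstimate, PropagationParams

BAND = (20.0, 100.0)


def _noise(level):
    return NoiseEstimate("s", None, BAND, level)


class TestBandNoisePercentile:
    def test_constant_level_returns_level(self):
        clip, _ = synth_clip(300.0, "dcall", [], seed=0)
        spec = compute_spectrogram(clip)
        spec.power = np.full_like(spec.power, -60.0)
        est = band_noise_percentile(spec, BAND)
        rows = spec.band_rows(*BAND)
        expected = -60.0 + 10 * np.log10(rows.size)
        assert est.level_db == pytest.approx(expected)

    def test_first_percentile_robust_to_loud_transients(self):
        quiet, _ = synth_clip(600.0, "dcall", [], seed=1)
        spec_q = compute_spectrogram(quiet)
        base = band_noise_percentile(spec_q, BAND).level_db
        # same noise plus loud transients in ~5% of the hour
        loud, _ = synth_clip(600.0, "dcall", [100.0, 300.0, 500.0], snr_db=30, seed=1)
        spec_l = compute_spectrogram(loud)
        with_transients = band_noise_percentile(spec_l, BAND).level_db
        assert with_transients == pytest.approx(base, abs=0.5)

    def test_median_percentile_on_symmetric_distribution(self):
        clip, _ = synth_clip(600.0, "dcall", [], seed=2)
        spec = compute_spectrogram(clip)
        rows = spec.band_rows(*BAND)
        levels = 10 * np.log10((10 ** (spec.power[rows] / 10)).sum(axis=0))
        est = band_noise_percentile(spec, BAND, percentile=50)
        assert est.level_db == pytest.approx(np.median(levels))

    def test_no_frames_rejected_few_frames_warn(self):
        clip, _ = synth_clip(5.0, "dcall", [], seed=3)
        spec = compute_spectrogram(clip)
        with pytest.warns(UserWarning, match="fewer than 10"):
            band_noise_percentile(spec, BAND)


class TestTransmissionLoss:
    def test_spherical_reference_values(self):
        assert transmission_loss(1000.0, 30.0, "spherical") == pytest.approx(60.0)
        assert transmission_loss(1.0, 30.0, "spherical") == pytest.approx(0.0)

    def test_practical_between_cylindrical_and_spherical(self):
        r = 5000.0
        tl = transmission_loss(r, 30.0, "practical")
        assert 10 * np.log10(r) < tl < 20 * np.log10(r) + 0.1

    def test_hybrid_slope_transitions_at_water_depth(self):
        h = 1000.0
        r = np.logspace(1.5, 5, 400)
        tl = transmission_loss(r, 30.0, "hybrid", water_depth_m=h)
        logr = np.log10(r)
        slope = np.gradient(tl, logr)
        assert slope[r < h / 2].mean() == pytest.approx(20.0, abs=1.0)
        assert slope[(r > 3 * h) & (r < 3e4)].mean() == pytest.approx(10.0, abs=1.5)

    def test_pe_simple_runs_and_increases(self):
        tl1 = transmission_loss(2000.0, 30.0, "pe_simple", water_depth_m=300.0)
        tl2 = transmission_loss(20000.0, 30.0, "pe_simple", water_depth_m=300.0)
        assert np.isfinite(tl1) and np.isfinite(tl2)
        assert tl2 > tl1

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            transmission_loss(100.0, 30.0, "raytrace")


class TestDetectionArea:
    PARAMS = PropagationParams(source_level_db=174.0, band=BAND, detection_threshold_db=10.0)

    def test_flat_bathymetry_matches_analytic_circle(self):
        # SL 174, NL 84, DT 10 -> spherical limiting range 10 km
        grid = make_grid(166.0, -42.0, half_extent_km=15.0, depth_m=300.0)
        est = detection_area((166.0, -42.0), self.PARAMS, _noise(84.0), grid, "spherical")
        analytic = np.pi * 10.0**2
        assert est.area_km2 == pytest.approx(analytic, rel=0.05)

    def test_noise_up_20db_shrinks_area_100x(self):
        # finer grid keeps quantization error manageable at 1 km range
        grid = make_grid(166.0, -42.0, half_extent_km=12.0, resolution_arcmin=0.2, depth_m=300.0)
        a1 = detection_area((166.0, -42.0), self.PARAMS, _noise(84.0), grid, "spherical").area_km2
        a2 = detection_area((166.0, -42.0), self.PARAMS, _noise(104.0), grid, "spherical").area_km2
        assert a2 / a1 == pytest.approx(0.01, rel=0.15)

    def test_overwhelming_noise_zero_area(self):
        grid = make_grid(166.0, -42.0, half_extent_km=5.0, depth_m=300.0)
        est = detection_area((166.0, -42.0), self.PARAMS, _noise(200.0), grid, "spherical")
        assert est.area_km2 == 0.0

    def test_shallow_cells_excluded(self):
        grid = make_grid(166.0, -42.0, half_extent_km=15.0, depth_m=300.0)
        shallow = make_grid(166.0, -42.0, half_extent_km=15.0, depth_m=10.0)
        deep = detection_area((166.0, -42.0), self.PARAMS, _noise(84.0), grid, "spherical")
        none = detection_area((166.0, -42.0), self.PARAMS, _noise(84.0), shallow, "spherical")
        assert deep.area_km2 > 0
        assert none.area_km2 == 0.0  # water shallower than the calling whale

    @given(
        noise1=st.floats(min_value=60, max_value=120),
        noise_up=st.floats(min_value=0, max_value=30),
        model=st.sampled_from(["spherical", "practical", "hybrid"]),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=60, deadline=None)
    def test_area_monotone_in_noise_and_source_level(self, noise1, noise_up, model, seed):
        rng = np.random.default_rng(seed)
        grid = make_grid(
            166.0, -42.0, half_extent_km=12.0, resolution_arcmin=2.0,
            depth_m=rng.uniform(30.0, 3000.0),
        )
        grid.depth_m = rng.uniform(30.0, 3000.0, grid.lon.shape)
        a_low = detection_area((166.0, -42.0), self.PARAMS, _noise(noise1), grid, model)
        a_high = detection_area((166.0, -42.0), self.PARAMS, _noise(noise1 + noise_up), grid, model)
        assert a_high.area_km2 <= a_low.area_km2
        stronger = PropagationParams(
            source_level_db=self.PARAMS.source_level_db + 6.0, band=BAND,
            detection_threshold_db=10.0,
        )
        a_strong = detection_area((166.0, -42.0), stronger, _noise(noise1), grid, model)
        assert a_strong.area_km2 >= a_low.area_km2

    def test_area_equals_cell_count_times_cell_area(self):
        grid = make_grid(166.0, -42.0, half_extent_km=10.0, depth_m=300.0)
        est = detection_area((166.0, -42.0), self.PARAMS, _noise(84.0), grid, "spherical")
        assert est.area_km2 == pytest.approx(est.cell_count * est.cell_area_km2)


class TestDailyMeanArea:
    def _est(self, area, hour):
        return DetectionAreaEstimate(
            site_id="s", date=pd.Timestamp("2017-01-01"), call_type="dcall",
            area_km2=area, cell_count=max(int(area // 2), 0), cell_area_km2=2.0, hour=hour,
        )

    def test_equal_hours_mean_unchanged(self):
        daily = daily_mean_area([self._est(100.0, h) for h in range(24)])
        assert daily.area_km2 == pytest.approx(100.0)
        assert daily.n_hours == 24

    def test_half_zero_half_a(self):
        ests = [self._est(0.0, h) for h in range(12)] + [self._est(100.0, h) for h in range(12, 24)]
        assert daily_mean_area(ests).area_km2 == pytest.approx(50.0)

    def test_missing_hours_recorded(self):
        daily = daily_mean_area([self._est(60.0, h) for h in range(6)])
        assert daily.n_hours == 6
        assert daily.area_km2 == pytest.approx(60.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            daily_mean_area([])
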