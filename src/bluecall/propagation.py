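"""Detection-area estimation from the passive sonar equation.

A grid cell around the hydrophone is detectable when the source level
minus transmission loss to the receiver exceeds the ambient noise by the
required signal excess: SL - TL(r) - NL >= DT. Ambient noise is a low
percentile (default 1st) of per-frame in-band levels over the hour.
Transmission loss comes from a pluggable model family (spherical,
practical spreading with absorption, a spherical-to-cylindrical hybrid,
and an optional narrow-angle split-step parabolic-equation marcher);
full-physics range-dependent propagation is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import DetectionAreaEstimate, NoiseEstimate, PropagationParams, Spectrogram

EARTH_RADIUS_KM = 6371.0
ARC_MINUTE_DEG = 1.0 / 60.0


def band_noise_percentile(
    spec_hour: Spectrogram,
    band: tuple[float, float],
    percentile: float = 1.0,
    site_id: str | None = None,
    hour: pd.Timestamp | None = None,
) -> NoiseEstimate:
    """Percentile of per-frame in-band levels over an hour of frames.

    The in-band level of a frame is the dB sum of linear power across the
    band's bins; the low percentile is robust to transient signals in the
    hour.
    """
    if spec_hour.times.size == 0:
        raise ValueError("no frames in hour")
    if spec_hour.times.size < 10:
        warnings.warn("fewer than 10 frames in hour; noise percentile unstable", stacklevel=2)
    rows = spec_hour.band_rows(band[0], band[1])
    lin = 10.0 ** (spec_hour.power[rows, :] / 10.0)
    frame_levels_db = 10.0 * np.log10(np.maximum(lin.sum(axis=0), 1e-300))
    level = float(np.percentile(frame_levels_db, percentile))
    return NoiseEstimate(
        site_id=site_id or spec_hour.site_id,
        hour=hour,
        band=band,
        level_db=level,
        n_frames=int(spec_hour.times.size),
    )


def thorp_absorption_db_per_km(freq_hz: float) -> float:
    """Thorp's empirical seawater absorption (dB/km), f in Hz."""
    f2 = (freq_hz / 1000.0) ** 2
    return 0.11 * f2 / (1 + f2) + 44 * f2 / (4100 + f2) + 2.75e-4 * f2 + 0.003


def _pe_simple_tl(
    range_m: float,
    freq_hz: float,
    water_depth_m: float,
    source_depth_m: float,
    receiver_depth_m: float,
    sound_speed: float = 1500.0,
) -> float:
    """Narrow-angle split-step Fourier parabolic-equation transmission loss
    on a flat range-depth slice.

    Pressure-release surface, lossy fluid bottom absorbed through an
    attenuating sponge below the seafloor. Qualitative range dependence
    only — adequate for area integration, not for absolute predictions.
    """
    k0 = 2 * np.pi * freq_hz / sound_speed
    zmax = water_depth_m * 2.0
    nz = 512
    dz = zmax / nz
    z = np.arange(nz) * dz
    dr = max(min(50.0, range_m / 20.0), 5.0)

    # Gaussian starter at the source depth (odd extension handles the
    # pressure-release surface)
    w = max(2 / k0, 2 * dz)
    psi = np.exp(-((z - source_depth_m) ** 2) / w**2) - np.exp(
        -((z + source_depth_m) ** 2) / w**2
    )
    kz = 2 * np.pi * np.fft.fftfreq(nz, d=dz)
    prop = np.exp(-1j * kz**2 / (2 * k0) * dr)
    # sponge attenuation below the seafloor
    alpha = np.zeros(nz)
    below = z > water_depth_m
    alpha[below] = 0.05 * ((z[below] - water_depth_m) / (zmax - water_depth_m)) ** 2
    absorb = np.exp(-alpha * dr)

    r = dr
    while r < range_m:
        psi = np.fft.ifft(np.fft.fft(psi) * prop) * absorb
        r += dr
    iz = int(np.clip(round(receiver_depth_m / dz), 0, nz - 1))
    # cylindrical spreading factor restores pressure from the reduced field
    p = np.abs(psi[iz]) / np.sqrt(max(range_m, 1.0))
    p0 = 1.0  # starter normalized to unit source strength at 1 m
    return float(-20 * np.log10(max(p / p0, 1e-30)))


def transmission_loss(
    range_m: float | np.ndarray,
    freq_hz: float,
    model: str = "spherical",
    water_depth_m: float | np.ndarray | None = None,
    source_depth_m: float = 25.0,
    receiver_depth_m: float = 100.0,
) -> np.ndarray:
    """Transmission loss in dB at the given range(s).

    Models: ``spherical`` 20 log10 r; ``practical`` 15 log10 r plus Thorp
    absorption; ``hybrid`` spherical out to the water depth then
    cylindrical (10 log10) beyond, plus absorption; ``pe_simple`` the
    narrow-angle parabolic-equation marcher (scalar ranges only).
    """
    r = np.maximum(np.asarray(range_m, dtype=float), 1.0)
    if model == "spherical":
        return 20.0 * np.log10(r)
    if model == "practical":
        return 15.0 * np.log10(r) + thorp_absorption_db_per_km(freq_hz) * r / 1000.0
    if model == "hybrid":
        if water_depth_m is None:
            raise ValueError("hybrid model needs water_depth_m")
        h = np.maximum(np.asarray(water_depth_m, dtype=float), 1.0)
        tl_near = 20.0 * np.log10(np.minimum(r, h))
        tl_far = 10.0 * np.log10(np.maximum(r / h, 1.0))
        return tl_near + tl_far + thorp_absorption_db_per_km(freq_hz) * r / 1000.0
    if model == "pe_simple":
        if water_depth_m is None:
            raise ValueError("pe_simple model needs water_depth_m")
        rs = np.atleast_1d(r)
        hs = np.broadcast_to(np.atleast_1d(np.asarray(water_depth_m, float)), rs.shape)
        out = np.array(
            [
                _pe_simple_tl(ri, freq_hz, hi, source_depth_m, receiver_depth_m)
                for ri, hi in zip(rs, hs)
            ]
        )
        return out if np.ndim(range_m) else out[0]
    raise ValueError(f"unknown transmission-loss model {model!r}")


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


@dataclass
class Grid:
    """Regular lon/lat grid of cells with depth and per-cell area."""

    lon: np.ndarray  # cell centers, 1-D over cells
    lat: np.ndarray
    depth_m: np.ndarray  # positive down; <= 0 is land
    cell_area_km2: np.ndarray


def make_grid(
    site_lon: float,
    site_lat: float,
    half_extent_km: float = 30.0,
    resolution_arcmin: float = 1.0,
    depth_m: float | np.ndarray = 300.0,
) -> Grid:
    """Regular grid of cells centered on the site.

    Cell areas follow the local latitude (meridian arc times cos-latitude
    parallel arc); default resolution 1 arc minute.
    """
    step = resolution_arcmin * ARC_MINUTE_DEG
    dlat_km = np.radians(step) * EARTH_RADIUS_KM
    n_lat = int(np.ceil(half_extent_km / dlat_km))
    lats = site_lat + step * np.arange(-n_lat, n_lat + 1)
    dlon_km_mid = dlat_km * np.cos(np.radians(site_lat))
    n_lon = int(np.ceil(half_extent_km / dlon_km_mid))
    lons = site_lon + step * np.arange(-n_lon, n_lon + 1)
    glon, glat = np.meshgrid(lons, lats, indexing="ij")
    glon, glat = glon.ravel(), glat.ravel()
    area = (np.radians(step) * EARTH_RADIUS_KM) ** 2 * np.cos(np.radians(glat))
    depth = np.broadcast_to(np.asarray(depth_m, dtype=float), glon.shape).copy()
    return Grid(lon=glon, lat=glat, depth_m=depth, cell_area_km2=area)


def detection_area(
    site: tuple[float, float],
    params: PropagationParams,
    noise: NoiseEstimate,
    grid: Grid,
    tl_model: str = "spherical",
    call_type: str = "dcall",
    date: pd.Timestamp | None = None,
    hour: int | None = None,
) -> DetectionAreaEstimate:
    """Detectable area around the site for one noise estimate.

    A cell qualifies when SL - TL(distance, band center) - NL >= DT, the
    cell is wet, and the water is at least as deep as the calling whale.
    """
    site_lon, site_lat = site
    dist_km = haversine_km(site_lon, site_lat, grid.lon, grid.lat)
    wet = (grid.depth_m > 0) & (grid.depth_m >= params.whale_depth_m)
    if not wet.any():
        warnings.warn("grid contains no usable water cells", stacklevel=2)
    tl = transmission_loss(
        dist_km * 1000.0,
        params.band_center_hz,
        model=tl_model,
        water_depth_m=grid.depth_m,
        source_depth_m=params.whale_depth_m,
        receiver_depth_m=params.receiver_depth_m,
    )
    excess = params.source_level_db - tl - noise.level_db
    ok = wet & (excess >= params.detection_threshold_db)
    count = int(ok.sum())
    area = float(grid.cell_area_km2[ok].sum())
    return DetectionAreaEstimate(
        site_id=noise.site_id,
        date=date,
        call_type=call_type,
        area_km2=area,
        cell_count=count,
        cell_area_km2=area / count if count else float(grid.cell_area_km2.mean()),
        hour=hour,
    )


def daily_mean_area(hourly: list[DetectionAreaEstimate]) -> DetectionAreaEstimate:
    """Arithmetic mean of hourly detection areas for one site-day."""
    if not hourly:
        raise ValueError("need at least one hourly estimate")
    areas = np.array([h.area_km2 for h in hourly])
    mean_area = float(areas.mean())
    cell_area = float(np.mean([h.cell_area_km2 for h in hourly]))
    count = int(round(mean_area / cell_area)) if cell_area > 0 else 0
    return DetectionAreaEstimate(
        site_id=hourly[0].site_id,
        date=hourly[0].date,
        call_type=hourly[0].call_type,
        area_km2=mean_area,
        cell_count=count,
        cell_area_km2=mean_area / count if count else cell_area,
        n_hours=len(hourly),
    )
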