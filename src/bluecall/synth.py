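"""Synthetic fixtures: hydrophone audio with planted calls, gridded
environmental fields with heatwave episodes, environment-driven daily call
series, and whaling catch records with a planted conception-date
distribution.

The generators plant known ground truth (event boxes, regression
coefficients, conception peaks) so that every downstream stage — detector,
evaluation, boosted trees, mixed models, phenology — can be tested as a
recovery problem. They emulate the statistical structure the analysis
assumes, not the full acoustic or oceanographic realism of the study system
(see docs/methods.md for what is and is not reproduced).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Annotation, AnnotationSet, AudioClip, CatchRecord, CatchRecordSet

# ---------------------------------------------------------------------------
# Audio
# ---------------------------------------------------------------------------

#: Song unit: fixed tonal inside the 23-24 Hz index band. The real song's
#: multi-unit structure is not reproduced; unit duration is a placeholder
#: (the source recordings' unit timing is not public).
SONG_FREQ_HZ = 23.5
SONG_UNIT_DURATION_S = 8.0
SONG_BAND = (23.0, 24.0)

#: D call: linear downsweep, 90 -> 25 Hz over 3 s.
DCALL_F_START = 90.0
DCALL_F_END = 25.0
DCALL_DURATION_S = 3.0

#: Ambient-noise spectral slope, dB per octave (low-frequency ocean noise
#: falls with frequency in this band).
NOISE_SLOPE_DB_PER_OCTAVE = -5.0


def colored_noise(
    n: int,
    sample_rate: float,
    slope_db_per_octave: float = NOISE_SLOPE_DB_PER_OCTAVE,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Gaussian noise with a power-law spectrum, unit variance."""
    rng = rng or np.random.default_rng()
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    # power slope in dB/octave -> amplitude exponent on frequency
    expo = slope_db_per_octave / (20.0 * np.log10(2.0))
    f_ref = max(freqs[1], 1e-6)
    gain = np.ones_like(freqs)
    nz = freqs > 0
    gain[nz] = (freqs[nz] / f_ref) ** expo
    gain[0] = 0.0
    out = np.fft.irfft(spec * gain, n=n)
    return out / out.std()


def _taper(n: int, sample_rate: float, ramp_s: float = 0.5) -> np.ndarray:
    from scipy.signal.windows import tukey

    ramp = min(ramp_s, n / sample_rate / 2)
    alpha = 2 * ramp * sample_rate / n
    return tukey(n, alpha=min(alpha, 1.0))


def song_unit_waveform(
    sample_rate: float,
    duration_s: float = SONG_UNIT_DURATION_S,
    freq_hz: float = SONG_FREQ_HZ,
    harmonics: tuple[float, ...] = (),
) -> np.ndarray:
    """Tonal song unit near 23.5 Hz with optional weak harmonic amplitudes."""
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    x = np.sin(2 * np.pi * freq_hz * t)
    for k, amp in enumerate(harmonics, start=2):
        x = x + amp * np.sin(2 * np.pi * k * freq_hz * t)
    return x * _taper(n, sample_rate)


def dcall_waveform(
    sample_rate: float,
    duration_s: float = DCALL_DURATION_S,
    f_start: float = DCALL_F_START,
    f_end: float = DCALL_F_END,
) -> np.ndarray:
    """Linear downsweep D call."""
    from scipy.signal import chirp

    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    x = chirp(t, f0=f_start, f1=f_end, t1=duration_s, method="linear")
    return x * _taper(n, sample_rate)


def _band_power(x: np.ndarray, sample_rate: float, band: tuple[float, float]) -> float:
    """Mean-square power of ``x`` restricted to a frequency band."""
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sample_rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    # Parseval: sum |X|^2 over band, two-sided correction for rfft
    power = np.abs(spec[mask]) ** 2
    scale = np.ones(mask.sum())
    scale[(freqs[mask] > 0) & (freqs[mask] < sample_rate / 2)] = 2.0
    return float((power * scale).sum() / x.size**2)


def event_band(call_type: str) -> tuple[float, float]:
    if call_type == "song":
        return SONG_BAND
    if call_type == "dcall":
        return (DCALL_F_END, DCALL_F_START)
    raise ValueError(f"unknown call_type {call_type!r}")


def synth_clip(
    duration_s: float,
    call_type: str = "dcall",
    event_times: list[float] | np.ndarray = (),
    snr_db: float = 15.0,
    noise_slope_db_per_octave: float = NOISE_SLOPE_DB_PER_OCTAVE,
    sample_rate: float = 2000.0,
    seed: int | None = None,
    site_id: str = "site",
    song_duration_s: float = SONG_UNIT_DURATION_S,
    harmonics: tuple[float, ...] = (),
) -> tuple[AudioClip, AnnotationSet]:
    """Colored noise with calls planted at ``event_times`` at a requested
    band-limited SNR.

    The SNR is the ratio of the event's in-band power to the background's
    in-band power over the event duration. Events closer together than one
    event duration are rejected. Every planted event is returned as an
    annotation with its true time-frequency box.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    event_times = np.sort(np.asarray(event_times, dtype=float))

    if call_type == "song":
        event = song_unit_waveform(sample_rate, duration_s=song_duration_s, harmonics=harmonics)
        event_dur = song_duration_s
    else:
        event = dcall_waveform(sample_rate)
        event_dur = DCALL_DURATION_S
    band = event_band(call_type)

    if event_times.size and (event_times.min() < 0 or event_times.max() + event_dur > duration_s):
        raise ValueError("event_times must lie within [0, duration_s - event duration)")
    if event_times.size > 1 and np.any(np.diff(event_times) < event_dur):
        raise ValueError("planted events overlap: spacing below one event duration")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    noise = colored_noise(n, sample_rate, noise_slope_db_per_octave, rng)

    noise_band_power = _band_power(noise, sample_rate, band)
    sig_power = _band_power(event, sample_rate, band)
    gain = np.sqrt(noise_band_power * 10.0 ** (snr_db / 10.0) / sig_power)

    samples = noise.copy()
    meta: dict = {"snr_db": snr_db, "call_type": call_type, "low_snr_events": []}
    entries = []
    for i, t0 in enumerate(event_times):
        i0 = int(round(t0 * sample_rate))
        seg = gain * event
        samples[i0 : i0 + seg.size] += seg
        if np.max(np.abs(seg)) < 1e-7 * noise.std():
            meta["low_snr_events"].append(i)
        entries.append(
            Annotation(
                start_s=t0,
                end_s=t0 + event_dur,
                low_hz=band[0],
                high_hz=band[1],
                call_type=call_type,
            )
        )
    if meta["low_snr_events"]:
        warnings.warn("some planted events are below quantization", stacklevel=2)
    clip = AudioClip(samples=samples, sample_rate=sample_rate, site_id=site_id, meta=meta)
    return clip, AnnotationSet(entries=entries)


def measure_band_snr(
    clip: AudioClip, annotation: Annotation, flank_gap_s: float = 1.0
) -> float:
    """Measured band SNR of a planted event, dB.

    Band-passes the clip to the annotation band, compares mean-square power
    inside the event window with the average over two equal flanking
    noise-only windows, and returns 10*log10((P_in - P_noise)/P_noise).
    """
    sr = clip.sample_rate
    spec = np.fft.rfft(clip.samples)
    freqs = np.fft.rfftfreq(clip.samples.size, d=1.0 / sr)
    mask = (freqs >= annotation.low_hz) & (freqs <= annotation.high_hz)
    banded = np.fft.irfft(spec * mask, n=clip.samples.size)

    i0, i1 = int(annotation.start_s * sr), int(annotation.end_s * sr)
    width = i1 - i0
    gap = int(flank_gap_s * sr)
    p_in = np.mean(banded[i0:i1] ** 2)
    flanks = []
    if i0 - gap - width >= 0:
        flanks.append(np.mean(banded[i0 - gap - width : i0 - gap] ** 2))
    if i1 + gap + width <= banded.size:
        flanks.append(np.mean(banded[i1 + gap : i1 + gap + width] ** 2))
    if not flanks:
        raise ValueError("no room for flanking noise windows")
    p_noise = float(np.mean(flanks))
    excess = max(p_in - p_noise, 1e-300)
    return float(10 * np.log10(excess / p_noise))


# ---------------------------------------------------------------------------
# Environmental fields
# ---------------------------------------------------------------------------


@dataclass
class GridSpec:
    """Regular lon/lat grid of cell centers."""

    lon_min: float = 165.0
    lat_min: float = -46.0
    nlon: int = 12
    nlat: int = 12
    dlon: float = 0.25
    dlat: float = 0.25

    @property
    def lons(self) -> np.ndarray:
        return self.lon_min + np.arange(self.nlon) * self.dlon

    @property
    def lats(self) -> np.ndarray:
        return self.lat_min + np.arange(self.nlat) * self.dlat


@dataclass
class EnvGridSeries:
    """Daily gridded SST / SST anomaly / NPP in long format.

    ``data`` columns: date, lon, lat, sst, sst_anom, npp. NPP carries the
    8-day compositing cadence (values constant within composite blocks).
    """

    data: pd.DataFrame
    grid: GridSpec
    truth: dict = field(default_factory=dict)


# South Taranaki Bight-like defaults: austral seasonal cycle peaking in
# early February, warmer toward the equator.
SST_MEAN_C = 16.0
SST_SEASONAL_AMP_C = 3.0
SST_PEAK_DOY = 36
SST_LAT_GRADIENT_C_PER_DEG = 0.3
LOG_NPP_BASE = float(np.log(500.0))  # mg C m^-2 day^-1
NPP_SST_ANOM_COUPLING = -0.15  # d log(NPP) per degC of anomaly


def synth_env(
    dates: pd.DatetimeIndex,
    grid_spec: GridSpec | None = None,
    heatwave_windows: list[tuple] = (),
    coupling: float = NPP_SST_ANOM_COUPLING,
    seed: int | None = None,
    sst_noise_sd: float = 0.2,
    npp_noise_sd: float = 0.1,
    composite_days: int = 8,
) -> EnvGridSeries:
    """Seasonal SST field with optional heatwave anomalies and NPP
    log-linearly coupled to the anomaly.

    ``heatwave_windows`` are (start, end, anomaly_degC) with dates inside
    ``dates``. NPP is aggregated to ``composite_days`` blocks and forward
    filled, mirroring satellite compositing.
    """
    if len(dates) == 0:
        raise ValueError("empty date range")
    grid_spec = grid_spec or GridSpec()
    for w in heatwave_windows:
        s, e = pd.Timestamp(w[0]), pd.Timestamp(w[1])
        if s < dates[0] or e > dates[-1]:
            raise ValueError("heatwave window outside the date range")
    rng = np.random.default_rng(seed)

    lons, lats = np.meshgrid(grid_spec.lons, grid_spec.lats, indexing="ij")
    lons, lats = lons.ravel(), lats.ravel()
    ncell = lons.size
    doy = dates.dayofyear.to_numpy()

    seasonal = SST_SEASONAL_AMP_C * np.cos(2 * np.pi * (doy - SST_PEAK_DOY) / 365.25)
    spatial = SST_LAT_GRADIENT_C_PER_DEG * (lats - lats.mean())
    clim = seasonal[:, None] + spatial[None, :] + SST_MEAN_C

    anomaly = np.zeros((len(dates), ncell))
    for w in heatwave_windows:
        s, e = pd.Timestamp(w[0]), pd.Timestamp(w[1])
        amp = float(w[2]) if len(w) > 2 else 3.0
        inwin = np.asarray((dates >= s) & (dates <= e))
        anomaly[inwin, :] += amp

    sst = clim + anomaly + rng.normal(0, sst_noise_sd, (len(dates), ncell))
    sst_anom = sst - clim

    log_npp = LOG_NPP_BASE + coupling * sst_anom + rng.normal(0, npp_noise_sd, sst.shape)
    npp = np.exp(log_npp)

    # satellite-style compositing: block mean assigned to every day in block
    block = np.arange(len(dates)) // composite_days
    npp_df = pd.DataFrame(npp)
    npp_composited = npp_df.groupby(block).transform("mean").to_numpy()

    data = pd.DataFrame(
        {
            "date": np.repeat(dates.to_numpy(), ncell),
            "lon": np.tile(lons, len(dates)),
            "lat": np.tile(lats, len(dates)),
            "sst": sst.ravel(),
            "sst_anom": sst_anom.ravel(),
            "npp": npp_composited.ravel(),
        }
    )
    truth = {"coupling": coupling, "heatwave_windows": list(heatwave_windows)}
    return EnvGridSeries(data=data, grid=grid_spec, truth=truth)


# ---------------------------------------------------------------------------
# Daily call series
# ---------------------------------------------------------------------------

DEFAULT_COUNT_COEFFICIENTS = {
    "intercept": 1.0,
    "log_npp": 0.8,
    "sst": 0.0,
    "sst_anom": 0.0,
    "month_cos": 0.3,
    "month_sin": 0.0,
}

#: Song seasonal bump: peaks mid-May (austral fall, inside the Apr-Jun
#: song peak), ~1 month wide.
DEFAULT_SEASON_PROFILE = {"base": 1.0, "amp": 3.0, "peak_doy": 135.0, "width_days": 30.0}


@dataclass
class DailyCallTruth:
    """Planted generating process for one site's daily call series."""

    site_id: str
    coefficients: dict
    season_profile: dict
    coupling: float
    sii_noise_sd: float
    data: pd.DataFrame  # date, planted_dcall_rate, planted_song_intensity


def synth_call_series(
    env_at_site: pd.DataFrame,
    coefficients: dict | None = None,
    season_profile: dict | None = None,
    coupling: float = 0.5,
    sii_noise_sd: float = 0.3,
    seed: int | None = None,
    site_id: str = "site",
) -> tuple[DailyCallTruth, pd.DataFrame]:
    """Daily D-call counts and song intensity driven by the environment.

    Counts are Poisson with a log link on the planted linear predictor
    (log-NPP, SST, SST anomaly, and harmonic month terms). Song intensity is
    a seasonal bump whose height scales with the prior summer (Jan-Feb)
    foraging index (standardized mean D-call count), plus Gaussian noise.
    """
    coefficients = dict(DEFAULT_COUNT_COEFFICIENTS, **(coefficients or {}))
    season_profile = dict(DEFAULT_SEASON_PROFILE, **(season_profile or {}))
    rng = np.random.default_rng(seed)

    env = env_at_site.sort_values("date").reset_index(drop=True)
    dates = pd.DatetimeIndex(env["date"])
    month = dates.month.to_numpy()
    eta = (
        coefficients["intercept"]
        + coefficients["log_npp"] * env["log_npp"].to_numpy()
        + coefficients["sst"] * env["sst"].to_numpy()
        + coefficients["sst_anom"] * env["sst_anom"].to_numpy()
        + coefficients["month_cos"] * np.cos(2 * np.pi * (month - 1) / 12)
        + coefficients["month_sin"] * np.sin(2 * np.pi * (month - 1) / 12)
    )
    mu = np.exp(eta)
    counts = rng.poisson(mu)

    # summer foraging index: mean count over Jan 1 - Feb 28 of the same year
    df = pd.DataFrame({"date": dates, "count": counts, "mu": mu})
    df["year"] = dates.year
    summer = (month == 1) | ((month == 2) & (dates.day <= 28))
    summer_means = df[summer].groupby("year")["count"].mean()
    grand_sd = float(summer_means.std(ddof=0)) or 1.0
    grand_mean = float(summer_means.mean()) if len(summer_means) else 0.0
    forage_z = (
        df["year"].map(summer_means).fillna(grand_mean).to_numpy() - grand_mean
    ) / grand_sd

    doy = dates.dayofyear.to_numpy()
    ddoy = np.minimum(np.abs(doy - season_profile["peak_doy"]),
                      365 - np.abs(doy - season_profile["peak_doy"]))
    bump = np.exp(-0.5 * (ddoy / season_profile["width_days"]) ** 2)
    sii_mean = season_profile["base"] + season_profile["amp"] * bump * (1 + coupling * forage_z)
    sii = sii_mean + rng.normal(0, sii_noise_sd, len(dates))

    out = pd.DataFrame(
        {
            "site_id": site_id,
            "date": dates,
            "dcall_count": counts,
            "song_intensity_index": sii,
        }
    )
    truth_df = pd.DataFrame(
        {"date": dates, "planted_dcall_rate": mu, "planted_song_intensity": sii_mean}
    )
    truth = DailyCallTruth(
        site_id=site_id,
        coefficients=coefficients,
        season_profile=season_profile,
        coupling=coupling,
        sii_noise_sd=sii_noise_sd,
        data=truth_df,
    )
    return truth, out


# ---------------------------------------------------------------------------
# Whaling catch records
# ---------------------------------------------------------------------------

NZ_REGION = (145.0, 180.0, -50.0, -32.0)  # lon_min, lon_max, lat_min, lat_max

#: Conception spread: births concentrate in April-May, a two-month window
#: read as roughly +/- 2 SD around the peak.
DEFAULT_CONCEPTION_SD_DAYS = 15.0
FETAL_LENGTH_AT_TERM_CM = 700.0


def fetal_length_cm(
    age_days: np.ndarray,
    gestation_days: float,
    model: str = "linear",
    term_length_cm: float = FETAL_LENGTH_AT_TERM_CM,
    lag_frac: float = 0.1,
) -> np.ndarray:
    """Fetal length as a function of gestational age.

    ``linear`` grows from 0 at conception to term length; ``huggett_widdas``
    adds an initial lag phase (cube-root-of-mass growth implies near-linear
    length growth after a lag).
    """
    age = np.asarray(age_days, dtype=float)
    if model == "linear":
        return term_length_cm * age / gestation_days
    if model == "huggett_widdas":
        t0 = lag_frac * gestation_days
        return term_length_cm * np.clip(age - t0, 0, None) / (gestation_days - t0)
    raise ValueError(f"unknown fetal growth model {model!r}")


def synth_catches(
    n: int,
    conception_peak_doy: float = 152.0,
    conception_sd_days: float = DEFAULT_CONCEPTION_SD_DAYS,
    gestation_days: float = 334.0,
    catch_window: tuple[float, float] | None = None,
    region_spec: tuple[float, float, float, float] = NZ_REGION,
    seed: int | None = None,
    pregnant_frac: float = 1.0,
    growth_model: str = "linear",
    years: tuple[int, int] = (1960, 1970),
) -> CatchRecordSet:
    """Pregnancy catch records with a planted conception-date distribution.

    Conception day-of-year ~ Normal(peak, sd); each pregnant whale is caught
    at a uniform random time during its pregnancy, optionally restricted to
    ``catch_window`` (a day-of-year interval, possibly wrapping the year
    end). Fetal length follows the chosen growth law. Positions are uniform
    inside ``region_spec``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if gestation_days <= 0:
        raise ValueError("gestation_days must be positive")
    rng = np.random.default_rng(seed)
    lon0, lon1, lat0, lat1 = region_spec

    def in_window(doy: float) -> bool:
        if catch_window is None:
            return True
        a, b = catch_window
        return a <= doy <= b if a <= b else (doy >= a or doy <= b)

    records: list[CatchRecord] = []
    attempts = 0
    max_attempts = 200 * n
    while len(records) < n and attempts < max_attempts:
        attempts += 1
        year = int(rng.integers(years[0], years[1] + 1))
        conception = pd.Timestamp(year=year, month=1, day=1) + pd.to_timedelta(
            rng.normal(conception_peak_doy, conception_sd_days) - 1, unit="D"
        )
        pregnant = rng.random() < pregnant_frac
        age = float(rng.uniform(0, gestation_days)) if pregnant else float(
            rng.uniform(0, 365)
        )
        catch_date = conception + pd.to_timedelta(age, unit="D")
        if not in_window(catch_date.dayofyear):
            continue
        fetal = (
            float(fetal_length_cm(np.array([age]), gestation_days, growth_model)[0])
            if pregnant
            else None
        )
        records.append(
            CatchRecord(
                date=catch_date.normalize(),
                lat=float(rng.uniform(lat0, lat1)),
                lon=float(rng.uniform(lon0, lon1)),
                body_length_m=float(np.clip(rng.normal(21.5, 0.8), 19.0, 24.0)),
                fetal_length_cm=fetal,
                source_tag="synthetic",
            )
        )
    meta = {
        "conception_peak_doy": conception_peak_doy,
        "conception_sd_days": conception_sd_days,
        "gestation_days": gestation_days,
        "growth_model": growth_model,
    }
    if len(records) < n:
        warnings.warn(
            "catch_window incompatible with pregnancy intervals; returning "
            f"{len(records)} of {n} requested records",
            stacklevel=2,
        )
        meta["incomplete"] = True
    return CatchRecordSet(records=records, meta=meta)
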