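"""Song intensity index, daily call summaries, and day-of-year cycles.

The song intensity index is the ratio of linear spectral energy in the
23-24 Hz call band to the energy at background frequencies (the bins
nearest 11 and 39 Hz), aggregated as a ratio of daily mean band powers.
Being a ratio it cancels gain and calibration offsets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import DailyCallSummary, Detection, Spectrogram

SII_CALL_BAND = (23.0, 24.0)
SII_BACKGROUND_HZ = (11.0, 39.0)


def song_intensity_index(
    spec_day: Spectrogram,
    call_band: tuple[float, float] = SII_CALL_BAND,
    background_hz: tuple[float, float] = SII_BACKGROUND_HZ,
) -> float:
    """Daily song intensity index.

    Mean linear power over the call band across the whole day, divided by
    the arithmetic mean of the linear power at the two background bins
    (nearest bins to the stated frequencies). The ratio of daily means is
    used rather than the daily mean of per-frame ratios: it is stabler on
    sparse-call days.
    """
    lin = spec_day.linear_power()
    call_rows = spec_day.band_rows(call_band[0], call_band[1])
    call_power = lin[call_rows, :].mean()
    bg_vals = []
    for f in background_hz:
        row = int(np.argmin(np.abs(spec_day.freqs - f)))
        if abs(spec_day.freqs[row] - f) > spec_day.freq_step_hz:
            raise ValueError(f"background frequency {f} Hz outside spectrogram range")
        bg_vals.append(lin[row, :].mean())
    background = float(np.mean(bg_vals))
    if background <= 0:
        raise ValueError("background energy is zero")
    return float(call_power / background)


def song_intensity_index_for_day(
    clips,
    call_band: tuple[float, float] = SII_CALL_BAND,
    background_hz: tuple[float, float] = SII_BACKGROUND_HZ,
    window_samples: int = 3000,
) -> float:
    """SII over a day supplied as a sequence of audio chunks.

    Accumulates frame-weighted linear band means across chunks, so the
    result equals the index of one continuous day-long spectrogram
    without holding it in memory.
    """
    from .spectro import compute_spectrogram

    call_sum = bg_sum = 0.0
    n_frames = 0
    for clip in clips:
        spec = compute_spectrogram(clip, window_samples=window_samples)
        lin = spec.linear_power()
        rows = spec.band_rows(call_band[0], call_band[1])
        m = spec.times.size
        call_sum += lin[rows, :].mean(axis=0).sum()
        bg = 0.0
        for f in background_hz:
            row = int(np.argmin(np.abs(spec.freqs - f)))
            bg += lin[row, :].sum()
        bg_sum += bg / len(background_hz)
        n_frames += m
    if bg_sum <= 0 or n_frames == 0:
        raise ValueError("background energy is zero")
    return float(call_sum / bg_sum)


def _hours_present(detections: list[Detection]) -> int:
    hours = set()
    for d in detections:
        h0 = int(d.start_s // 3600)
        h1 = int(min(d.end_s, 24 * 3600 - 1e-9) // 3600)
        hours.update(range(h0, h1 + 1))
    return len(hours)


def daily_summary(
    site_id: str,
    date: pd.Timestamp,
    dcall_detections: list[Detection] = (),
    song_detections: list[Detection] = (),
    sii: float = float("nan"),
) -> DailyCallSummary:
    """Aggregate one site-day: D-call count, hours with D calls, hours with
    song, and the day's song intensity index.

    Detection times are seconds from the day's start; an hour counts as
    present when at least one detection overlaps it (a call spanning an
    hour boundary flags both hours).
    """
    day_s = 24 * 3600
    for d in list(dcall_detections) + list(song_detections):
        if d.start_s < 0 or d.start_s >= day_s:
            raise ValueError("detection outside the date")
    return DailyCallSummary(
        site_id=site_id,
        date=pd.Timestamp(date),
        song_hours=_hours_present(list(song_detections)),
        song_intensity_index=sii,
        dcall_count=len(list(dcall_detections)),
        dcall_hours=_hours_present(list(dcall_detections)),
    )


def summaries_frame(summaries: list[DailyCallSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "date": s.date,
                "song_hours": s.song_hours,
                "song_intensity_index": s.song_intensity_index,
                "dcall_count": s.dcall_count,
                "dcall_hours": s.dcall_hours,
            }
            for s in summaries
        ]
    )


def pooled_day_of_year(dates: pd.DatetimeIndex) -> np.ndarray:
    """Day-of-year with Feb 29 pooled into day 59 (Feb 28).

    In leap years every day from Feb 29 onward is shifted back one, so
    day-of-year values are comparable across years (1..365).
    """
    doy = np.asarray(dates.dayofyear, dtype=int)
    leap = np.asarray(dates.is_leap_year, dtype=bool)
    shift = leap & (doy >= 60)
    return np.where(shift, doy - 1, doy)


def annual_cycle(summaries: pd.DataFrame, field: str) -> pd.DataFrame:
    """Mean of ``field`` per day of the year across sites and years.

    Returns a frame with columns doy, mean, n; defined only for days with
    at least one contributing site-day.
    """
    if len(summaries) == 0:
        raise ValueError("need at least one summary")
    if field not in summaries.columns:
        raise ValueError(f"unknown field {field!r}")
    df = summaries.copy()
    df["doy"] = pooled_day_of_year(pd.DatetimeIndex(df["date"]))
    out = (
        df.groupby("doy")[field]
        .agg(mean="mean", n="count")
        .reset_index()
        .sort_values("doy")
        .reset_index(drop=True)
    )
    return out
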