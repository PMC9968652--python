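"""Spectrogram computation and the template-correlation detector.

The detector slides a time-frequency exemplar along the spectrogram and
scores zero-mean, unit-norm correlation restricted to the template's band;
per-frame scores from multiple templates are arbitrated by taking the
maximum, and strict local maxima above the call-type threshold are emitted
as detections.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve, find_peaks, get_window

from .types import Annotation, AudioClip, Detection, Spectrogram, Template

#: Review/detector windowing: song 3000-sample Hann, D calls 2048-sample
#: Hann, both 50% overlap. A 3072-point FFT is available via ``fft_size``.
SONG_WINDOW_SAMPLES = 3000
DCALL_WINDOW_SAMPLES = 2048
DEFAULT_OVERLAP = 0.5

#: Detection thresholds on the correlation score.
SONG_THRESHOLD = 0.75
DCALL_THRESHOLD = 0.80

_DB_FLOOR_GUARD = 1e-30


def compute_spectrogram(
    clip: AudioClip,
    window_samples: int = DCALL_WINDOW_SAMPLES,
    overlap_frac: float = DEFAULT_OVERLAP,
    fft_size: int | None = None,
    time_average_frames: int = 1,
) -> Spectrogram:
    """Hann-windowed STFT power in dB.

    Frames start at multiples of the hop; the frame count is
    floor((N - window) / hop) + 1 (no padding).

    ``time_average_frames`` applies a moving average of linear power over
    that many frames before the dB conversion (the long-term-spectral-
    average trick): single-periodogram pixels carry ~5.6 dB of exponential
    texture, and averaging reduces it without moving band levels, which
    steadies narrowband template correlation. The frame grid is unchanged.
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    fft_size = fft_size or window_samples
    if fft_size < window_samples:
        raise ValueError("fft_size must be >= window_samples")
    x = clip.samples
    if x.size < window_samples:
        raise ValueError("clip shorter than one analysis window")

    hop = int(round(window_samples * (1 - overlap_frac)))
    n_frames = (x.size - window_samples) // hop + 1
    win = get_window("hann", window_samples, fftbins=True)

    idx = np.arange(window_samples)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * win
    spec = np.fft.rfft(frames, n=fft_size, axis=1)
    # PSD scaling (per-Hz density); constant factors cancel in the
    # correlation and index ratios but keep levels interpretable
    scale = 1.0 / (clip.sample_rate * (win**2).sum())
    psd = (np.abs(spec) ** 2) * scale
    psd[:, 1:-1] *= 2.0
    if time_average_frames > 1:
        from scipy.ndimage import uniform_filter1d

        psd = uniform_filter1d(psd, size=time_average_frames, axis=0, mode="nearest")
    power_db = 10.0 * np.log10(psd + _DB_FLOOR_GUARD)

    freqs = np.fft.rfftfreq(fft_size, d=1.0 / clip.sample_rate)
    times = hop * np.arange(n_frames) / clip.sample_rate
    return Spectrogram(
        power=power_db.T,
        freqs=freqs,
        times=times,
        window_samples=window_samples,
        overlap_frac=overlap_frac,
        fft_size=fft_size,
        sample_rate=clip.sample_rate,
        start_time=clip.start_time,
        site_id=clip.site_id,
    )


def cut_template(
    spec: Spectrogram,
    annotation: Annotation,
    template_id: str = "t0",
    band_pad_hz: float = 2.0,
) -> Template:
    """Cut a template patch from an annotated spectrogram box.

    ``band_pad_hz`` widens the cut band each side so the patch carries the
    call's contrast against neighboring background bins, which sharpens
    the correlation peak for narrowband calls.
    """
    rows = spec.band_rows(
        max(annotation.low_hz - band_pad_hz, float(spec.freqs[0])),
        min(annotation.high_hz + band_pad_hz, float(spec.freqs[-1])),
    )
    cols = np.where((spec.times >= annotation.start_s) & (spec.times < annotation.end_s))[0]
    if cols.size < 2 or rows.size < 2:
        raise ValueError("annotation box too small to cut a template")
    patch = spec.power[np.ix_(rows, cols)].copy()
    return Template(
        patch=patch,
        call_type=annotation.call_type,
        band=(spec.freqs[rows[0]], spec.freqs[rows[-1]]),
        duration_s=cols.size * spec.time_step_s,
        template_id=template_id,
    )


def correlate_template(spec: Spectrogram, template: Template) -> np.ndarray:
    """Normalized correlation score series over time offsets.

    At each offset the template patch and the co-located spectrogram window
    (restricted to the template band) are zero-meaned; the score is their
    normalized inner product, in [-1, 1]. Zero-variance windows score 0.
    Valid-mode: the series has n_frames - template_frames + 1 entries.
    """
    rows = spec.band_rows(template.band[0], template.band[1])
    if rows.size != template.patch.shape[0]:
        # align by taking the first matching number of rows from the band
        if rows.size < template.patch.shape[0]:
            raise ValueError("spectrogram band has fewer bins than template patch")
        rows = rows[: template.patch.shape[0]]
    S = spec.power[rows, :]
    T = template.patch
    k, m = T.shape
    n = S.shape[1]
    if n < m:
        raise ValueError("spectrogram shorter than template")

    T0 = T - T.mean()
    t_norm = float(np.sqrt((T0**2).sum()))
    n_out = n - m + 1
    if t_norm < 1e-12:
        return np.zeros(n_out)

    # numerator: correlation of S with zero-mean template (flip = correlate)
    num = fftconvolve(S, T0[::-1, ::-1], mode="valid")[0]
    # sliding window sums for local mean/variance
    col_sum = S.sum(axis=0)
    col_sq = (S**2).sum(axis=0)
    csum = np.concatenate([[0.0], np.cumsum(col_sum)])
    csq = np.concatenate([[0.0], np.cumsum(col_sq)])
    w_sum = csum[m:] - csum[:-m]
    w_sq = csq[m:] - csq[:-m]
    w_var = np.maximum(w_sq - w_sum**2 / (k * m), 0.0)
    denom = t_norm * np.sqrt(w_var)
    score = np.zeros(n_out)
    ok = denom > 1e-12
    score[ok] = num[ok] / denom[ok]
    return np.clip(score, -1.0, 1.0)


def detect_calls(
    spec: Spectrogram,
    templates: list[Template],
    threshold: float,
    min_gap_s: float | None = None,
) -> list[Detection]:
    """Run the multi-template detector on one spectrogram.

    Per frame the maximum score over templates is taken; strict local maxima
    at or above ``threshold`` become detections carrying the winning
    template's id and box. Detections closer than ``min_gap_s`` (default:
    half the shortest template duration) are merged keeping the higher
    score, ties broken by earlier time.
    """
    if not templates:
        raise ValueError("empty template list")
    call_types = {t.call_type for t in templates}
    if len(call_types) > 1:
        raise ValueError("all templates must share one call_type")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if min_gap_s is None:
        min_gap_s = min(t.duration_s for t in templates) / 2

    n_frames = spec.times.size
    combined = np.full(n_frames, -np.inf)
    winner = np.zeros(n_frames, dtype=int)
    for j, t in enumerate(templates):
        s = correlate_template(spec, t)
        pad = np.full(n_frames - s.size, -np.inf)
        s_full = np.concatenate([s, pad])
        better = s_full > combined
        combined[better] = s_full[better]
        winner[better] = j

    peaks = list(find_peaks(combined, height=threshold)[0])
    # find_peaks skips boundary frames; admit them when they dominate
    # their single neighbor
    n_valid = int(np.isfinite(combined).sum())
    for edge in {0, n_valid - 1}:
        if 0 <= edge < n_frames and combined[edge] >= threshold:
            nb = combined[1] if edge == 0 else combined[edge - 1]
            if n_valid == 1 or combined[edge] > nb:
                peaks.append(edge)
    peaks = np.unique(peaks).astype(int)

    detections = []
    for p in peaks:
        t = templates[winner[p]]
        start = float(spec.times[p])
        detections.append(
            Detection(
                start_s=start,
                end_s=start + t.duration_s,
                low_hz=t.band[0],
                high_hz=t.band[1],
                score=float(combined[p]),
                template_id=t.template_id,
                call_type=t.call_type,
                site_id=spec.site_id,
            )
        )

    # merge near-coincident detections, higher score wins, earlier on ties
    detections.sort(key=lambda d: d.start_s)
    merged: list[Detection] = []
    for d in detections:
        if merged and d.start_s - merged[-1].start_s < min_gap_s:
            if d.score > merged[-1].score:
                merged[-1] = d
        else:
            merged.append(d)
    return merged
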