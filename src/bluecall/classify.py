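"""Spectral features for putative D calls and the random-forest
true-call vs false-positive classifier.

The feature set is a ten-measurement stand-in spanning the standard robust
spectrogram measurements (duration, band edges, peak/center frequency,
entropy, energy, ridge slope, SNR, time-of-peak); the classifier protocol
is a 100-tree random forest with 7 candidate variables per split, trained
on random 75% splits and evaluated on the withheld 25%, repeated over
bootstrap iterations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from dataclasses import dataclass
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .types import Detection, Spectrogram

logger = logging.getLogger(__name__)

FEATURE_NAMES = [
    "duration_s",
    "bandwidth_hz",
    "low_freq_hz",
    "high_freq_hz",
    "peak_freq_hz",
    "center_freq_hz",
    "aggregate_entropy",
    "band_energy_db",
    "freq_slope_hz_per_s",
    "time_of_peak_frac",
]

NTREE = 100
MTRY = 7
TRAIN_FRAC = 0.75
N_BOOT = 100


def extract_features(spec: Spectrogram, detection: Detection) -> dict:
    """Measurements on the box-restricted spectrogram.

    Peak frequency is the frequency of maximum power; center frequency the
    energy-weighted median; the slope is a least-squares fit to the
    per-frame peak-frequency ridge (negative for downsweeps); bandwidth is
    the 90%-energy spread around the center.
    """
    rows = spec.band_rows(detection.low_hz, detection.high_hz)
    cols = np.where((spec.times >= detection.start_s) & (spec.times < detection.end_s))[0]
    if cols.size == 0 or rows.size == 0:
        raise ValueError("empty detection box")
    box_db = spec.power[np.ix_(rows, cols)]
    box_lin = 10.0 ** (box_db / 10.0)
    freqs = spec.freqs[rows]
    times = spec.times[cols]

    marg_f = box_lin.sum(axis=1)
    total = marg_f.sum()
    cum = np.cumsum(marg_f) / total
    center = float(np.interp(0.5, cum, freqs))
    f_lo = float(np.interp(0.05, cum, freqs))
    f_hi = float(np.interp(0.95, cum, freqs))

    p = marg_f / total
    entropy = float(-(p * np.log2(np.maximum(p, 1e-300))).sum())

    ridge = freqs[np.argmax(box_db, axis=0)]
    if cols.size > 1:
        slope = float(np.polyfit(times, ridge, 1)[0])
    else:
        slope = 0.0

    frame_energy = box_lin.sum(axis=0)
    ipeak = int(np.argmax(frame_energy))

    # SNR vs flanking frames in the same band
    flank = np.setdiff1d(
        np.arange(max(cols[0] - cols.size, 0), min(cols[-1] + 1 + cols.size, spec.times.size)),
        cols,
    )
    if flank.size:
        noise = 10.0 ** (spec.power[np.ix_(rows, flank)] / 10.0)
        snr_db = float(10 * np.log10(box_lin.mean() / max(noise.mean(), 1e-300)))
    else:
        snr_db = 0.0

    return {
        "duration_s": float(detection.end_s - detection.start_s),
        "bandwidth_hz": max(f_hi - f_lo, float(spec.freq_step_hz)),
        "low_freq_hz": float(detection.low_hz),
        "high_freq_hz": float(detection.high_hz),
        "peak_freq_hz": float(freqs[np.argmax(marg_f)]),
        "center_freq_hz": center,
        "aggregate_entropy": entropy,
        "band_energy_db": float(10 * np.log10(total)),
        "freq_slope_hz_per_s": slope,
        "time_of_peak_frac": ipeak / max(cols.size - 1, 1),
    }


@dataclass
class SplitResult:
    model: RandomForestClassifier
    misclassification: float
    false_negative_rate: float
    true_positive_rate: float
    false_positive_rate: float
    true_negative_rate: float
    y_test: np.ndarray
    y_pred: np.ndarray


@dataclass
class ClassifierReport:
    """Mean and SD of the five rates over bootstrap runs."""

    means: dict
    sds: dict
    n_boot: int
    per_run: pd.DataFrame


def _rates(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    pos = y_true == 1
    neg = ~pos
    tpr = float((y_pred[pos] == 1).mean()) if pos.any() else np.nan
    tnr = float((y_pred[neg] == 0).mean()) if neg.any() else np.nan
    return {
        "misclassification": float((y_pred != y_true).mean()),
        "false_negative_rate": 1 - tpr,
        "true_positive_rate": tpr,
        "false_positive_rate": 1 - tnr,
        "true_negative_rate": tnr,
    }


def train_classifier(
    features: pd.DataFrame,
    labels: np.ndarray,
    ntree: int = NTREE,
    mtry: int = MTRY,
    train_frac: float = TRAIN_FRAC,
    seed: int | None = None,
) -> SplitResult:
    """Random forest on a random train split, evaluated on the holdout."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    if mtry > X.shape[1]:
        raise ValueError(f"mtry={mtry} exceeds n_features={X.shape[1]}")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_frac, random_state=seed, stratify=y
    )
    model = RandomForestClassifier(
        n_estimators=ntree, max_features=mtry, random_state=seed, n_jobs=1
    )
    model.fit(X_tr, y_tr)
    y_pred = model.predict(X_te)
    return SplitResult(model=model, y_test=y_te, y_pred=y_pred, **_rates(y_te, y_pred))


def bootstrap_evaluate(
    features: pd.DataFrame,
    labels: np.ndarray,
    n_boot: int = N_BOOT,
    seed: int | None = None,
    ntree: int = NTREE,
    mtry: int = MTRY,
    train_frac: float = TRAIN_FRAC,
) -> ClassifierReport:
    """Repeat the split-train-evaluate cycle with fresh random splits.

    Splits that lack a class are logged and redrawn. Reports mean and SD of
    the five rates.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    draws = 0
    while len(rows) < n_boot:
        split_seed = int(rng.integers(0, 2**31 - 1))
        draws += 1
        if draws > 10 * n_boot:
            raise RuntimeError("too many degenerate bootstrap splits")
        try:
            res = train_classifier(
                features, labels, ntree=ntree, mtry=mtry, train_frac=train_frac, seed=split_seed
            )
        except ValueError:
            logger.warning("bootstrap split lacked a class; resampling")
            continue
        rows.append(
            {
                k: getattr(res, k)
                for k in (
                    "misclassification",
                    "false_negative_rate",
                    "true_positive_rate",
                    "false_positive_rate",
                    "true_negative_rate",
                )
            }
        )
    per_run = pd.DataFrame(rows)
    return ClassifierReport(
        means=per_run.mean().to_dict(),
        sds=per_run.std(ddof=1).to_dict(),
        n_boot=n_boot,
        per_run=per_run,
    )


def compare_daily_counts(
    manual_series: np.ndarray, auto_series: np.ndarray
) -> dict:
    """Pearson correlation between aligned manual and automated daily
    counts, with paired data for plotting."""
    manual = np.asarray(manual_series, dtype=float)
    auto = np.asarray(auto_series, dtype=float)
    if manual.shape != auto.shape:
        raise ValueError("series must be aligned and equal length")
    if manual.std() == 0 or auto.std() == 0:
        return {"r": np.nan, "p_value": np.nan, "defined": False,
                "pairs": np.column_stack([manual, auto])}
    r, p = stats.pearsonr(manual, auto)
    return {"r": float(r), "p_value": float(p), "defined": True,
            "pairs": np.column_stack([manual, auto])}
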