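"""Readers and writers for the pipeline's on-disk formats.

Audio travels as WAV (float32 by default), annotations and detections as
Raven-style selection tables (tab-separated), environmental fields and catch
records as long-format CSV. All stages communicate only through these
formats, so any synthetic input can be swapped for real data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .types import Annotation, AnnotationSet, AudioClip, Detection

SELECTION_COLUMNS = [
    "Selection",
    "Begin Time (s)",
    "End Time (s)",
    "Low Freq (Hz)",
    "High Freq (Hz)",
    "Call Type",
]


def write_wav(path: str | Path, clip: AudioClip, dtype: str = "float32") -> None:
    """Write a clip as WAV; ``dtype`` is float32 or PCM16 ('int16')."""
    data = clip.samples
    if dtype == "float32":
        wavfile.write(path, int(clip.sample_rate), data.astype(np.float32))
    elif dtype == "int16":
        peak = np.max(np.abs(data)) or 1.0
        wavfile.write(path, int(clip.sample_rate), (data / peak * 32000).astype(np.int16))
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")


def read_wav(path: str | Path, site_id: str = "site") -> AudioClip:
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioClip(samples=np.asarray(data, dtype=np.float64), sample_rate=rate, site_id=site_id)


def write_selection_table(path: str | Path, items, extra_scores: bool = False) -> None:
    """Write annotations or detections as a Raven-style selection table.

    ``items`` may be an AnnotationSet or a list of Detections; detections
    get additional ``Score`` and ``Template`` columns when present.
    """
    if isinstance(items, AnnotationSet):
        df = items.to_frame()
    else:
        rows = []
        for i, d in enumerate(items):
            row = {
                "Selection": i + 1,
                "Begin Time (s)": d.start_s,
                "End Time (s)": d.end_s,
                "Low Freq (Hz)": d.low_hz,
                "High Freq (Hz)": d.high_hz,
                "Call Type": d.call_type,
            }
            if isinstance(d, Detection):
                row["Score"] = d.score
                row["Template"] = d.template_id
            rows.append(row)
        df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=SELECTION_COLUMNS + (["Score", "Template"] if extra_scores else []))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_selection_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SELECTION_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"selection table {path} missing columns {missing}")
    return df


def selections_to_annotations(df: pd.DataFrame) -> AnnotationSet:
    entries = [
        Annotation(
            start_s=row["Begin Time (s)"],
            end_s=row["End Time (s)"],
            low_hz=row["Low Freq (Hz)"],
            high_hz=row["High Freq (Hz)"],
            call_type=str(row.get("Call Type", "dcall")),
        )
        for _, row in df.iterrows()
    ]
    return AnnotationSet(entries=entries)


def selections_to_detections(df: pd.DataFrame, site_id: str = "site") -> list[Detection]:
    return [
        Detection(
            start_s=row["Begin Time (s)"],
            end_s=row["End Time (s)"],
            low_hz=row["Low Freq (Hz)"],
            high_hz=row["High Freq (Hz)"],
            score=float(row.get("Score", 1.0)),
            template_id=str(row.get("Template", "")),
            call_type=str(row.get("Call Type", "dcall")),
            site_id=site_id,
        )
        for _, row in df.iterrows()
    ]


def write_env_csv(path: str | Path, env: pd.DataFrame) -> None:
    env.to_csv(path, index=False, float_format="%.6f")


def read_env_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"date", "lon", "lat", "sst", "sst_anom", "npp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"environmental CSV missing columns {sorted(missing)}")
    return df


def write_catches_csv(path: str | Path, catches) -> None:
    df = catches.to_frame() if hasattr(catches, "to_frame") else catches
    df.to_csv(path, index=False, float_format="%.4f")


def read_catches_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"date", "lat", "lon", "body_length_m", "fetal_length_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catch CSV missing columns {sorted(missing)}")
    return df
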