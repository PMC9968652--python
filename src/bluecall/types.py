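"""Core domain containers shared across the pipeline.

Everything here is a thin, validated record type: audio clips, spectrograms,
time-frequency annotation/detection boxes, daily call summaries, propagation
parameters, and whaling catch records. Heavier tabular data (environmental
grids, model panels) travel as pandas DataFrames with documented columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

import numpy as np
import pandas as pd

#: Default hydrophone sampling rate, Hz.
DEFAULT_SAMPLE_RATE = 2000

#: Hydrophone system sensitivity, dB re 1 V/μPa, carried as calibration
#: metadata; waveforms are dimensionless unless this offset is applied.
DEFAULT_SENSITIVITY_DB = -145.5


@dataclass
class AudioClip:
    """A contiguous mono waveform from one site."""

    samples: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    start_time: Optional[datetime] = None
    site_id: str = "site"
    sensitivity_db: float = DEFAULT_SENSITIVITY_DB
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class Annotation:
    """A ground-truth time-frequency box for one call."""

    start_s: float
    end_s: float
    low_hz: float
    high_hz: float
    call_type: str = "dcall"
    truth: bool = True

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("end_s must exceed start_s")
        if not self.high_hz > self.low_hz:
            raise ValueError("high_hz must exceed low_hz")


@dataclass
class AnnotationSet:
    """Ordered collection of annotations for one clip."""

    entries: list[Annotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "Selection": i + 1,
                    "Begin Time (s)": a.start_s,
                    "End Time (s)": a.end_s,
                    "Low Freq (Hz)": a.low_hz,
                    "High Freq (Hz)": a.high_hz,
                    "Call Type": a.call_type,
                }
                for i, a in enumerate(self.entries)
            ]
        )


@dataclass
class Spectrogram:
    """STFT power in dB with its windowing metadata.

    ``power`` is frequency × time (rows = ``freqs``, columns = ``times``);
    ``times`` mark frame start offsets in seconds from the clip start.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    window_samples: int
    overlap_frac: float
    fft_size: int
    sample_rate: float
    start_time: Optional[datetime] = None
    site_id: str = "site"

    def __post_init__(self) -> None:
        if self.power.shape != (self.freqs.size, self.times.size):
            raise ValueError("power must be (n_freqs, n_times)")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("time axis must be strictly increasing")
        if not np.all(np.isfinite(self.power)):
            raise ValueError("power must be finite")

    @property
    def freq_step_hz(self) -> float:
        return self.sample_rate / self.fft_size

    @property
    def time_step_s(self) -> float:
        hop = int(round(self.window_samples * (1 - self.overlap_frac)))
        return hop / self.sample_rate

    def band_rows(self, low_hz: float, high_hz: float) -> np.ndarray:
        """Indices of frequency bins inside [low_hz, high_hz]."""
        rows = np.where((self.freqs >= low_hz) & (self.freqs <= high_hz))[0]
        if rows.size == 0:
            raise ValueError(f"band ({low_hz}, {high_hz}) Hz outside spectrogram range")
        return rows

    def linear_power(self) -> np.ndarray:
        return 10.0 ** (self.power / 10.0)


@dataclass
class Template:
    """A time-frequency exemplar cut from an annotated spectrogram."""

    patch: np.ndarray  # dB, frequency x time
    call_type: str
    band: tuple[float, float]
    duration_s: float
    template_id: str

    def __post_init__(self) -> None:
        if self.patch.ndim != 2 or min(self.patch.shape) < 2:
            raise ValueError("template patch must be at least 2x2")
        if not self.band[1] > self.band[0]:
            raise ValueError("template band must be (low, high) with high > low")

    @property
    def n_frames(self) -> int:
        return self.patch.shape[1]


@dataclass(frozen=True)
class Detection:
    """One emitted detector hit."""

    start_s: float
    end_s: float
    low_hz: float
    high_hz: float
    score: float
    template_id: str = ""
    call_type: str = "dcall"
    site_id: str = "site"

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("end_s must exceed start_s")


@dataclass
class MatchResult:
    """One-to-one matching of detections against annotations."""

    true_positives: list[tuple[Detection, Annotation]]
    false_positives: list[Detection]
    false_negatives: list[Annotation]

    @property
    def tp(self) -> int:
        return len(self.true_positives)

    @property
    def fp(self) -> int:
        return len(self.false_positives)

    @property
    def fn(self) -> int:
        return len(self.false_negatives)


@dataclass
class DetectionMetrics:
    """Precision, recall, and false alarms per hour of recording."""

    precision: float
    recall: float
    false_alarm_rate: float
    recording_hours: float
    n_detections: int
    n_annotations: int
    precision_defined: bool = True
    recall_defined: bool = True


@dataclass
class DailyCallSummary:
    """Per site-day calling summary."""

    site_id: str
    date: pd.Timestamp
    song_hours: int = 0
    song_intensity_index: float = float("nan")
    dcall_count: int = 0
    dcall_hours: int = 0

    def __post_init__(self) -> None:
        for v, name in ((self.song_hours, "song_hours"), (self.dcall_hours, "dcall_hours")):
            if not 0 <= v <= 24:
                raise ValueError(f"{name} must be within [0, 24]")
        if self.dcall_count < 0:
            raise ValueError("dcall_count must be non-negative")


@dataclass
class PropagationParams:
    """Sonar-equation source and geometry parameters for one call type."""

    source_level_db: float  # dB re 1 uPa @ 1 m
    band: tuple[float, float]  # Hz
    whale_depth_m: float = 25.0
    receiver_depth_m: float = 100.0
    detection_threshold_db: float = 10.0  # required signal excess

    def __post_init__(self) -> None:
        if self.source_level_db <= 0:
            raise ValueError("source_level_db must be positive")
        if not self.band[1] > self.band[0] > 0:
            raise ValueError("band must be (low, high) with 0 < low < high")
        if self.whale_depth_m <= 0 or self.receiver_depth_m <= 0:
            raise ValueError("depths must be positive")

    @property
    def band_center_hz(self) -> float:
        """Geometric-center frequency of the call band."""
        return float(np.sqrt(self.band[0] * self.band[1]))


#: Song parameters: 179 dB source level, 17-50 Hz dominant band.
SONG_PROPAGATION = PropagationParams(source_level_db=179.0, band=(17.0, 50.0))
#: D-call parameters: 174 dB source level, 20-100 Hz band.
DCALL_PROPAGATION = PropagationParams(source_level_db=174.0, band=(20.0, 100.0))


@dataclass
class NoiseEstimate:
    """In-band ambient noise level for one site-hour."""

    site_id: str
    hour: Optional[pd.Timestamp]
    band: tuple[float, float]
    level_db: float
    n_frames: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.level_db):
            raise ValueError("noise level must be finite")


@dataclass
class DetectionAreaEstimate:
    """Detectable sea-surface area around a site for one hour or day."""

    site_id: str
    date: Optional[pd.Timestamp]
    call_type: str
    area_km2: float
    cell_count: int
    cell_area_km2: float
    hour: Optional[int] = None
    n_hours: int = 1

    def __post_init__(self) -> None:
        if self.area_km2 < 0:
            raise ValueError("area must be non-negative")


@dataclass(frozen=True)
class CatchRecord:
    """One whaling catch record."""

    date: pd.Timestamp
    lat: float
    lon: float
    body_length_m: float
    fetal_length_cm: Optional[float] = None
    source_tag: str = ""

    def __post_init__(self) -> None:
        # NaN coordinates are allowed: they mark records that subspecies
        # assignment must flag as unassignable
        if not np.isnan(self.lat) and not -90 <= self.lat <= 90:
            raise ValueError("lat out of range")
        if not 0 < self.body_length_m < 35:
            raise ValueError("body_length_m out of plausible range (0, 35)")
        if self.fetal_length_cm is not None and self.fetal_length_cm < 0:
            raise ValueError("fetal_length_cm must be non-negative when present")


@dataclass
class CatchRecordSet:
    records: list[CatchRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "date": r.date,
                    "lat": r.lat,
                    "lon": r.lon,
                    "body_length_m": r.body_length_m,
                    "fetal_length_cm": r.fetal_length_cm,
                    "source_tag": r.source_tag,
                }
                for r in self.records
            ]
        )


@dataclass(frozen=True)
class AssignedCatch:
    """A catch record with its subspecies label and the rule that fired."""

    record: CatchRecord
    subspecies: str  # antarctic | pygmy | excluded | unassignable
    rule: str


@dataclass
class ConceptionEstimate:
    """Inferred birth and conception day-of-year windows."""

    birth_window: tuple[float, float]
    conception_window: tuple[float, float]
    birth_doy: float
    conception_doy: float
    gestation_months: int = 11
    flat_curve: bool = False
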