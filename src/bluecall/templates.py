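"""Template banks and the detector's spectrogram settings.

Templates are cut from annotated clips; the default banks come from clean
synthetic exemplars planted at staggered sub-hop offsets, so the bank
covers the alignment of an arbitrary call against the analysis frame grid
(the study this mirrors used 5 song and 13 D-call templates). The
detector's spectrogram applies 3-frame power averaging, which tempers the
single-periodogram pixel texture that otherwise dominates narrowband
correlation scores.
"""

from __future__ import annotations

from .spectro import (
    DCALL_WINDOW_SAMPLES,
    SONG_WINDOW_SAMPLES,
    compute_spectrogram,
    cut_template,
)
from .synth import synth_clip
from .types import AudioClip, Spectrogram, Template

N_SONG_TEMPLATES = 5
N_DCALL_TEMPLATES = 13
DETECTOR_TIME_AVERAGE_FRAMES = 3
TEMPLATE_EXEMPLAR_SNR_DB = 40.0
TEMPLATE_BAND_PAD_HZ = 0.7


def detector_window_samples(call_type: str) -> int:
    return SONG_WINDOW_SAMPLES if call_type == "song" else DCALL_WINDOW_SAMPLES


def detector_spectrogram(clip: AudioClip, call_type: str) -> Spectrogram:
    """Spectrogram with the detector's windowing for the call type."""
    return compute_spectrogram(
        clip,
        window_samples=detector_window_samples(call_type),
        time_average_frames=DETECTOR_TIME_AVERAGE_FRAMES,
    )


def make_template_bank(
    call_type: str,
    n_templates: int | None = None,
    exemplar_snr_db: float = TEMPLATE_EXEMPLAR_SNR_DB,
    band_pad_hz: float = TEMPLATE_BAND_PAD_HZ,
    seed: int = 1,
) -> list[Template]:
    """Cut a bank of templates from clean synthetic exemplars.

    Exemplars are planted at offsets staggered across one hop so the bank
    spans frame-grid alignments; each is cut from its own noise
    realization at high SNR.
    """
    if n_templates is None:
        n_templates = N_SONG_TEMPLATES if call_type == "song" else N_DCALL_TEMPLATES
    window = detector_window_samples(call_type)
    hop_s = window * 0.5 / 2000.0
    bank = []
    for i in range(n_templates):
        offset = 20.0 + i * hop_s / n_templates
        clip, anns = synth_clip(
            60.0, call_type, [offset], snr_db=exemplar_snr_db, seed=seed + i
        )
        spec = compute_spectrogram(
            clip, window_samples=window, time_average_frames=DETECTOR_TIME_AVERAGE_FRAMES
        )
        bank.append(
            cut_template(spec, anns.entries[0], f"{call_type}_t{i}", band_pad_hz=band_pad_hz)
        )
    return bank
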