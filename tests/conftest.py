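import numpy as np
import pytest

from bluecall.spectro import SONG_WINDOW_SAMPLES, compute_spectrogram, cut_template
from bluecall.synth import synth_clip
from bluecall.templates import make_template_bank


@pytest.fixture(scope="session")
def song_bank():
    return make_template_bank("song", seed=1)


@pytest.fixture(scope="session")
def dcall_bank():
    return make_template_bank("dcall", seed=21)


@pytest.fixture(scope="session")
def song_template(song_bank):
    return song_bank[0]


@pytest.fixture(scope="session")
def noise_clip():
    clip, _ = synth_clip(120.0, "song", [], seed=5)
    return clip


@pytest.fixture(scope="session")
def single_song_clip():
    """120 s clip with one song unit at 20 dB band SNR at t=50 s."""
    return synth_clip(120.0, "song", [50.0], snr_db=20.0, seed=6)


@pytest.fixture(scope="session")
def single_song_spec(single_song_clip):
    clip, _ = single_song_clip
    return compute_spectrogram(clip, window_samples=SONG_WINDOW_SAMPLES)
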