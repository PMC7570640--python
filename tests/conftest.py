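import numpy as np
import pytest

from lstmecoc.montage import FUNCTIONAL_CHANNELS, N_CHANNELS
from lstmecoc.recording import CLASSES, N_STEPS, SAMPLES_PER_STEP, RawRecording, StepSequence


def make_recording(wave: np.ndarray, fs: float = 1000.0,
                   label: str | None = None) -> RawRecording:
    """Broadcast a single waveform to all 63 channels."""
    sig = np.tile(np.asarray(wave, dtype=float), (N_CHANNELS, 1))
    return RawRecording(signal=sig, fs=fs, channel_names=FUNCTIONAL_CHANNELS,
                        label=label, id="test")


def toy_sequences(n_per_class: int = 4, offset: float = 3.0,
                  noise: float = 0.3, seed: int = 0) -> list[StepSequence]:
    """Linearly separable step sequences: constant per-class offsets plus noise."""
    rng = np.random.default_rng(seed)
    seqs = []
    for ci, label in enumerate(CLASSES):
        for j in range(n_per_class):
            data = offset * (ci - 1) + noise * rng.standard_normal(
                (N_STEPS, N_CHANNELS, SAMPLES_PER_STEP)
            )
            seqs.append(StepSequence(data=data, label=label, id=f"{label}-{j}"))
    return seqs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_dataset():
    return toy_sequences()
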