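"""Core data containers: raw recordings, step sequences, artifact masks.

A :class:`RawRecording` is a labelled multichannel discrete signal
``d_i[n] = a_i(n / fs)`` obtained by sampling the analog scalp potential of
channel *i* at ``fs`` Hz.  A :class:`StepSequence` is one fully pre-processed
recording arranged as 60 one-second time steps of 63 channels x 100 samples
(equivalently a 63 x 6000 matrix at 100 Hz), the fixed input contract of the
LSTM stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .montage import FUNCTIONAL_CHANNELS, N_CHANNELS

#: Class labels, in fixed order (used for tie-breaking and confusion matrices).
CLASSES: tuple[str, ...] = ("healthy", "mild", "moderate")

CLASS_TO_INDEX = {c: i for i, c in enumerate(CLASSES)}

N_STEPS = 60
SAMPLES_PER_STEP = 100
STEP_INPUT_DIM = N_CHANNELS * SAMPLES_PER_STEP  # 6300


def class_index(label: str) -> int:
    try:
        return CLASS_TO_INDEX[label]
    except KeyError:
        raise ValueError(
            f"unknown class label {label!r}; expected one of {CLASSES}"
        ) from None


@dataclass
class RawRecording:
    """Labelled multichannel EEG signal with sampling-rate metadata.

    Parameters
    ----------
    signal : ndarray, shape (63, n_samples)
        Channel-by-sample potentials in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : sequence of str
        63 labels following the 10-10 montage with CPz excluded.
    label : str or None
        Class label (``healthy`` / ``mild`` / ``moderate``) if known.
    id : str
        Recording identifier.
    artifact_log : list of (float, float)
        Ground-truth artifact burst intervals in seconds, when the recording
        was produced by the simulator (empty otherwise).
    """

    signal: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = FUNCTIONAL_CHANNELS
    label: str | None = None
    id: str = ""
    artifact_log: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (channels x samples) array")
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError(
                f"signal has {self.signal.shape[0]} channels but "
                f"{len(self.channel_names)} channel names were given"
            )
        if self.signal.shape[0] != N_CHANNELS:
            raise ValueError(
                f"expected exactly {N_CHANNELS} channels, got {self.signal.shape[0]}"
            )
        if self.signal.shape[1] < 1:
            raise ValueError("signal must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.label is not None:
            class_index(self.label)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def replace_signal(self, signal: np.ndarray, fs: float | None = None) -> "RawRecording":
        """Copy of this recording with a new signal (and optionally new fs)."""
        return dataclasses.replace(
            self, signal=signal, fs=self.fs if fs is None else fs
        )


@dataclass
class StepSequence:
    """One pre-processed recording as 60 steps x 63 channels x 100 samples."""

    data: np.ndarray
    label: str | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        expected = (N_STEPS, N_CHANNELS, SAMPLES_PER_STEP)
        if self.data.shape != expected:
            raise ValueError(
                f"StepSequence data must have shape {expected}, got {self.data.shape}"
            )
        if self.label is not None:
            class_index(self.label)

    @property
    def matrix(self) -> np.ndarray:
        """The 63 x 6000 channels-by-samples view of the sequence."""
        return self.data.transpose(1, 0, 2).reshape(N_CHANNELS, -1)

    def flattened_steps(self) -> np.ndarray:
        """Per-step inputs for the LSTM: shape (60, 6300)."""
        return self.data.reshape(N_STEPS, -1)


@dataclass
class ArtifactMask:
    """Time intervals (seconds, half-open) to excise from a recording."""

    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = [(float(a), float(b)) for a, b in self.intervals]
        for a, b in ivs:
            if not b > a:
                raise ValueError(f"empty or inverted interval ({a}, {b})")
        ivs.sort()
        for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError("artifact intervals overlap")
        self.intervals = ivs

    @property
    def total_duration(self) -> float:
        return sum(b - a for a, b in self.intervals)

    def validate_against(self, recording: RawRecording) -> None:
        if self.intervals and self.intervals[-1][1] > recording.duration + 1e-9:
            raise ValueError(
                f"artifact interval {self.intervals[-1]} extends past the "
                f"{recording.duration:.3f} s recording"
            )
        if self.intervals and self.intervals[0][0] < 0:
            raise ValueError("artifact interval starts before t=0")
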