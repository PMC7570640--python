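"""Recording and feature I/O: EDF, compressed array files, label tables.

Recordings round-trip through two formats:

* **EDF** (European Data Format): reading goes through MNE; writing uses a
  minimal built-in 16-bit EDF encoder (one-second data records, symmetric
  physical range per channel), so synthetic cohorts can be exported for
  inspection in standard EEG viewers.
* **npz** compressed array files holding the signal (microvolts), sampling
  rate, channel names and label — the lossless working format.

Datasets are directories of recording files plus a ``labels.csv`` sidecar
with columns ``recording_id,label``.
"""

from __future__ import annotations

import struct
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import EOG_CHANNEL, N_CHANNELS
from .recording import RawRecording, StepSequence

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(recording: RawRecording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF with one-second data records.

    Each channel gets a symmetric physical range spanning its extremes, so
    round-trip error is bounded by the 16-bit quantization step.  The
    recording is truncated to a whole number of seconds.
    """
    path = Path(path)
    fs = recording.fs
    spr = int(round(fs))  # samples per 1 s record
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_records = recording.n_samples // spr
    if n_records * spr != recording.n_samples:
        warnings.warn("recording truncated to a whole number of seconds for EDF",
                      stacklevel=2)
    sig = recording.signal[:, :n_records * spr]
    n_sig = sig.shape[0]

    phys_max = np.maximum(np.abs(sig).max(axis=1), 1e-6)
    phys_min = -phys_max
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (phys_max - phys_min)
    digital = np.round((sig - phys_min[:, None]) * scale[:, None] + _EDF_DIG_MIN)
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    header_bytes = 256 * (1 + n_sig)
    head = b"".join([
        _edf_field("0", 8),
        _edf_field(f"X X X {recording.id or 'synthetic'}", 80),
        _edf_field(f"Startdate 01-JAN-2020 {recording.id or 'synthetic'}", 80),
        _edf_field("01.01.20", 8),
        _edf_field("00.00.00", 8),
        _edf_field(header_bytes, 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(n_sig, 4),
    ])

    def per_signal(values, width):
        return b"".join(_edf_field(v, width) for v in values)

    head += per_signal(recording.channel_names, 16)
    head += per_signal(["AgAgCl electrode"] * n_sig, 80)
    head += per_signal(["uV"] * n_sig, 8)
    head += per_signal([f"{v:.6g}"[:8] for v in phys_min], 8)
    head += per_signal([f"{v:.6g}"[:8] for v in phys_max], 8)
    head += per_signal([_EDF_DIG_MIN] * n_sig, 8)
    head += per_signal([_EDF_DIG_MAX] * n_sig, 8)
    head += per_signal([""] * n_sig, 80)
    head += per_signal([spr] * n_sig, 8)
    head += per_signal([""] * n_sig, 32)
    assert len(head) == header_bytes

    with open(path, "wb") as fh:
        fh.write(head)
        # record-major layout: for each 1 s record, all channels in turn
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())
    return path


def read_recording_edf(path: str | Path, channels: list[str] | None = None,
                       label: str | None = None) -> RawRecording:
    """Read an EDF file via MNE; returns potentials in microvolts.

    A 64-channel file containing the EOG channel (CPz) has it dropped
    automatically; otherwise the channel count must be 63 unless an
    explicit ``channels`` selection is supplied.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = list(raw.ch_names)
    if channels is not None:
        missing = set(channels) - set(names)
        if missing:
            raise ValueError(f"requested channels not in file: {sorted(missing)}")
        raw.pick(channels)
    elif len(names) == N_CHANNELS + 1 and EOG_CHANNEL in names:
        raw.drop_channels([EOG_CHANNEL])
    elif len(names) != N_CHANNELS:
        raise ValueError(
            f"expected {N_CHANNELS} channels (or {N_CHANNELS + 1} including "
            f"{EOG_CHANNEL}), got {len(names)}; pass an explicit channel list"
        )
    data_uv = raw.get_data() * 1e6  # MNE loads EDF in volts
    return RawRecording(
        signal=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        label=label,
        id=path.stem,
    )


def write_recording_npz(recording: RawRecording, path: str | Path) -> Path:
    path = Path(path)
    np.savez_compressed(
        path,
        signal=recording.signal,
        fs=recording.fs,
        channel_names=np.array(recording.channel_names),
        label=recording.label or "",
        id=recording.id,
        artifact_log=np.array(recording.artifact_log, dtype=float).reshape(-1, 2),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_recording_npz(path: str | Path) -> RawRecording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path, allow_pickle=False) as z:
        label = str(z["label"]) or None
        return RawRecording(
            signal=z["signal"],
            fs=float(z["fs"]),
            channel_names=tuple(str(c) for c in z["channel_names"]),
            label=label,
            id=str(z["id"]),
            artifact_log=[tuple(iv) for iv in z["artifact_log"]],
        )


def read_recording(path: str | Path, format: str | None = None,
                   **kwargs) -> RawRecording:
    """Read a recording, dispatching on ``format`` or the file suffix."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        return read_recording_edf(path, **kwargs)
    if fmt == "npz":
        return read_recording_npz(path)
    raise ValueError(f"unsupported recording format {fmt!r}")


def write_dataset(recordings: list[RawRecording], out_dir: str | Path,
                  format: str = "npz") -> Path:
    """Write recordings plus the ``labels.csv`` sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        if format == "npz":
            write_recording_npz(rec, out_dir / f"{rec.id}.npz")
        elif format == "edf":
            write_recording_edf(rec, out_dir / f"{rec.id}.edf")
        else:
            raise ValueError(f"unsupported format {format!r}")
        rows.append({"recording_id": rec.id, "label": rec.label or ""})
    pd.DataFrame(rows).to_csv(out_dir / "labels.csv", index=False)
    return out_dir


def read_dataset(in_dir: str | Path) -> list[RawRecording]:
    """Read every recording listed in a directory's ``labels.csv``."""
    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / "labels.csv")
    recordings = []
    for _, row in table.iterrows():
        rid, label = str(row["recording_id"]), str(row["label"]) or None
        for suffix in (".npz", ".edf"):
            path = in_dir / f"{rid}{suffix}"
            if path.exists():
                rec = read_recording(path)
                rec.label = label
                rec.id = rid
                recordings.append(rec)
                break
        else:
            raise FileNotFoundError(f"no recording file for id {rid!r} in {in_dir}")
    return recordings


def write_sequence(seq: StepSequence, path: str | Path) -> Path:
    path = Path(path)
    np.savez_compressed(path, data=seq.data, label=seq.label or "", id=seq.id)
    return path


def read_sequence(path: str | Path) -> StepSequence:
    with np.load(Path(path), allow_pickle=False) as z:
        return StepSequence(data=z["data"], label=str(z["label"]) or None,
                            id=str(z["id"]))


def write_feature_table(features, path: str | Path) -> Path:
    """Feature vectors as CSV: ``id,label,v1..vH``."""
    rows = []
    for f in features:
        row = {"id": f.id, "label": f.label or ""}
        row.update({f"v{k + 1}": v for k, v in enumerate(f.values)})
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path):
    from .lstm import FeatureVector

    table = pd.read_csv(Path(path))
    cols = [c for c in table.columns if c.startswith("v")]
    out = []
    for _, row in table.iterrows():
        label = row["label"]
        label = None if pd.isna(label) or label == "" else str(label)
        out.append(FeatureVector(values=row[cols].to_numpy(dtype=float),
                                 id=str(row["id"]), label=label))
    return out
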