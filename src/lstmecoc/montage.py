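"""Electrode montage for the 64-channel 10-10 cap used by the pipeline.

The cap carries 64 electrodes in the international 10-10 arrangement; CPz is
wired as the electrooculography (EOG) channel and is therefore excluded from
analysis, leaving 63 functional EEG channels.
"""

from __future__ import annotations

# 64-electrode 10-10 layout (WaveGuard-style ordering), CPz included.
MONTAGE_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "M1", "T7", "C3", "Cz",
    "C4", "T8", "M2", "CP5", "CP1", "CP2", "CP6", "P7",
    "P3", "Pz", "P4", "P8", "POz", "O1", "Oz", "O2",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FC3", "FCz", "FC4", "C5", "C1", "C2", "C6", "CP3",
    "CPz", "CP4", "P5", "P1", "P2", "P6", "PO5", "PO3",
    "PO4", "PO6", "FT7", "FT8", "TP7", "TP8", "PO7", "PO8",
)

EOG_CHANNEL = "CPz"

#: The 63 functional EEG channels (montage with the EOG channel removed).
FUNCTIONAL_CHANNELS: tuple[str, ...] = tuple(
    ch for ch in MONTAGE_64 if ch != EOG_CHANNEL
)

N_CHANNELS = len(FUNCTIONAL_CHANNELS)  # 63


def scalp_region(channel: str) -> str:
    """Coarse scalp region of a 10-10 channel name.

    Returns one of ``"frontal"``, ``"central"``, ``"posterior"``.
    Classification is by label prefix: Fp/AF/F/FC/FT are frontal,
    C/CP/T/TP/M are central, P/PO/O are posterior.
    """
    name = channel.rstrip("0123456789z")
    if name in {"Fp", "AF", "F", "FC", "FT"}:
        return "frontal"
    if name in {"C", "CP", "T", "TP", "M"}:
        return "central"
    if name in {"P", "PO", "O"}:
        return "posterior"
    raise ValueError(f"unrecognized 10-10 channel label: {channel!r}")
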