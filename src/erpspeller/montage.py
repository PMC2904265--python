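"""Schematic 64-channel 10-10 montage.

Channel labels are ordered anterior to posterior, left to right within a
row. Scalp positions are schematic grid coordinates parsed from the label
(row letters give the anterior-posterior axis, the terminating digit the
laterality); they are good enough to parameterize smooth topographies and
spatial noise mixing, and make no claim to digitized electrode positions.
"""

from __future__ import annotations

import numpy as np

# Row blocks front to back, 64 channels total.
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

# Anterior/temporal periphery left out of the default classification subset
# (eye/muscle-artifact-prone sites); 64 - 9 = 55 channels remain.
EXCLUDED_9: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF8", "F7", "F8", "T7", "T8",
)

CHANNELS_55: tuple[str, ...] = tuple(
    ch for ch in CHANNELS_64 if ch not in EXCLUDED_9
)

# Electrode subsets on which component amplitudes are measured: the
# posterior set for P1/N1/N2, the midline set for P2/P3.
POSTERIOR_SUBSET: tuple[str, ...] = ("P5", "P6", "PO7", "PO8")
MIDLINE_SUBSET: tuple[str, ...] = ("Fz", "Cz", "Pz")

_ROW_Y = {
    "Fp": -1.0, "AF": -0.75, "F": -0.5, "FT": -0.25, "FC": -0.25,
    "T": 0.0, "C": 0.0, "TP": 0.25, "CP": 0.25, "P": 0.5,
    "PO": 0.75, "O": 1.0, "I": 1.15,
}


def _parse_label(label: str) -> tuple[float, float]:
    """Schematic (x, y) position: x lateral (left < 0), y posterior (> 0)."""
    i = 0
    while i < len(label) and not label[i].isdigit() and label[i] != "z":
        i += 1
    row, suffix = label[:i], label[i:]
    y = _ROW_Y[row]
    if suffix == "z":
        return 0.0, y
    n = int(suffix)
    x = ((n + 1) // 2) / 5.0  # laterality grows with the 10-10 digit
    return (-x if n % 2 == 1 else x), y


def channel_positions(channels: tuple[str, ...] = CHANNELS_64) -> np.ndarray:
    """Schematic (n_channels, 2) scalp coordinates for *channels*."""
    return np.array([_parse_label(ch) for ch in channels])


def topography(
    peak_channels: tuple[str, ...],
    channels: tuple[str, ...] = CHANNELS_64,
    falloff: float = 0.45,
) -> np.ndarray:
    """Smooth per-channel weight map peaking at *peak_channels*.

    Weight of a channel is the maximum over peak sites of a Gaussian in the
    schematic scalp distance, so the map has unit maximum at each peak site
    and decays with scale *falloff* (same units as the schematic coordinates).
    """
    pos = channel_positions(channels)
    idx = [channels.index(ch) for ch in peak_channels]
    d2 = ((pos[:, None, :] - pos[None, idx, :]) ** 2).sum(-1)
    return np.exp(-d2 / (2.0 * falloff**2)).max(axis=1)
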