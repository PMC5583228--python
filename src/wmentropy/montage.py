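"""Channel naming for the extended 10-20 (10-10) system.

The canonical 64-label list is ordered so that any prefix is a sensible
montage: the first 16 labels form a coarse whole-head cap that includes the
fronto-central row (FC3/FCz/FC4), the next tiers densify it.  Only the label
strings matter to the analysis; 2-D scalp positions for topographic maps are
resolved at render time from the standard 10-05 montage shipped with MNE.
"""

from __future__ import annotations

import numpy as np

#: 64 labels, prefix-ordered (first 16 = coarse cap containing FC4).
CHANNELS_64: list[str] = [
    # tier 1 — coarse 16-channel cap
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC3", "FCz", "FC4", "C3", "Cz", "C4", "P3", "Pz", "P4",
    # tier 2 — to 32
    "O1", "Oz", "O2", "T7", "T8", "P7", "P8",
    "CP3", "CPz", "CP4", "F1", "F2", "FC1", "FC2", "C1", "C2",
    # tier 3 — to 48
    "CP1", "CP2", "P1", "P2", "AF3", "AF4", "F5", "F6",
    "FC5", "FC6", "C5", "C6", "CP5", "CP6", "P5", "P6",
    # tier 4 — to 64
    "AF7", "AF8", "FT7", "FT8", "TP7", "TP8", "PO3", "PO4",
    "PO7", "PO8", "POz", "Fpz", "AFz", "Iz", "TP9", "TP10",
]


def default_channels(n_channels: int) -> list[str]:
    """First ``n_channels`` labels of the canonical 64-channel list."""
    if n_channels > len(CHANNELS_64):
        raise ValueError(
            f"at most {len(CHANNELS_64)} default labels available, got {n_channels}"
        )
    return CHANNELS_64[:n_channels]


def layout_positions(channels: list[str]) -> dict[str, np.ndarray]:
    """2-D scalp positions (azimuthal projection) for the given labels.

    Unknown labels are omitted from the returned mapping; callers decide
    whether that is an error or a warning.
    """
    import mne  # deferred: only topographic rendering needs it

    montage = mne.channels.make_standard_montage("standard_1005")
    pos3d = montage.get_positions()["ch_pos"]
    out: dict[str, np.ndarray] = {}
    for ch in channels:
        if ch not in pos3d:
            continue
        x, y, z = pos3d[ch]
        # simple azimuthal equidistant projection onto the axial plane
        rho = np.hypot(x, y)
        theta = np.arctan2(y, x)
        r = np.arctan2(rho, z)  # angular distance from vertex
        out[ch] = np.array([r * np.cos(theta), r * np.sin(theta)])
    return out
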