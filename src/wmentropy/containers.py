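"""In-memory containers for epoched EEG.

An :class:`EpochArray` holds one subject/session block of epoched EEG as a
``(trials, channels, samples)`` float array in microvolts, together with the
sampling rate, ordered channel labels, the epoch start time relative to
memory-array onset, and the trial identifiers that align rows to the
behavioral table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import UnsupportedInputError


@dataclass
class EpochArray:
    """One subject/session block of epoched EEG.

    Parameters
    ----------
    subject, session
        Identifiers; session is 1 or 2 in the two-session design.
    data
        ``(n_trials, n_channels, n_samples)`` array, microvolts.
    fs
        Sampling rate in Hz.
    channels
        Ordered, unique channel labels (extended 10-20 names).
    t0
        Epoch start time in seconds relative to memory-array onset
        (negative values mean the epoch begins before the stimulus).
    trial_ids
        Ordered unique ids aligning trial rows to the behavior table.
    """

    subject: int
    session: int
    data: np.ndarray
    fs: float
    channels: list[str]
    t0: float
    trial_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise UnsupportedInputError(
                f"data must be (trials, channels, samples); got ndim={self.data.ndim}"
            )
        if not np.all(np.isfinite(self.data)):
            raise UnsupportedInputError("data contains non-finite samples")
        if self.fs <= 0:
            raise UnsupportedInputError(f"fs must be > 0, got {self.fs}")
        self.channels = list(self.channels)
        if len(self.channels) != self.data.shape[1]:
            raise UnsupportedInputError(
                f"{len(self.channels)} channel labels for {self.data.shape[1]} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise UnsupportedInputError("channel labels must be unique")
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.data.shape[0])
        self.trial_ids = np.asarray(self.trial_ids)
        if self.trial_ids.shape[0] != self.data.shape[0]:
            raise UnsupportedInputError("trial_ids length must match trial count")
        if len(np.unique(self.trial_ids)) != len(self.trial_ids):
            raise UnsupportedInputError("trial_ids must be unique")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to memory-array onset."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def with_data(self, data: np.ndarray, **changes) -> "EpochArray":
        """Copy of this block with new data (and optional metadata changes)."""
        return replace(self, data=data, **changes)

    def equals(self, other: "EpochArray") -> bool:
        """Field-for-field equality with bit-exact array comparison."""
        return (
            self.subject == other.subject
            and self.session == other.session
            and self.fs == other.fs
            and self.channels == other.channels
            and self.t0 == other.t0
            and np.array_equal(self.trial_ids, other.trial_ids)
            and np.array_equal(self.data, other.data)
        )
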