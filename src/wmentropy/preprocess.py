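"""Epoch preprocessing: reference, filter, baseline, artifact rejection, retention cut.

The canonical order is reference -> band-pass -> baseline -> reject ->
extract-retention, bundled in :func:`preprocess_pipeline`.  All operations
are pure (they return new :class:`~wmentropy.containers.EpochArray` objects)
and never reorder or rename channels or trials; only ``reject_artifacts``
removes trials, and it reports which.

The average reference stands in for an infinity (REST) reference, which
would require a head model.  Windows are half-open ``[start, stop)`` in
seconds relative to memory-array onset; the retention default (0.2, 3.2) s
skips the 200 ms memory array and covers the full 3000 ms maintenance
interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .containers import EpochArray
from .errors import (
    ConfigurationError,
    EmptyResultError,
    UnsupportedInputError,
)


@dataclass
class PreprocessConfig:
    """Preprocessing parameters (defaults follow the emulated protocol)."""

    band: tuple = (0.5, 45.0)
    reject_uv: float = 100.0
    baseline_window: tuple = (-0.1, 0.0)
    retention_window: tuple = (0.2, 3.2)

    def validate(self, fs: float) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ConfigurationError(f"band: need 0 < low < high, got {self.band}")
        if high >= fs / 2:
            raise ConfigurationError(
                f"band: high edge {high} Hz >= Nyquist {fs / 2} Hz"
            )
        if self.reject_uv <= 0:
            raise ConfigurationError(f"reject_uv must be > 0, got {self.reject_uv}")


def rereference_average(e: EpochArray) -> EpochArray:
    """Subtract the instantaneous cross-channel mean (average reference)."""
    if e.n_channels < 2:
        raise UnsupportedInputError(
            "average reference requires >= 2 channels, got "
            f"{e.n_channels} (subject {e.subject}, session {e.session})"
        )
    return e.with_data(e.data - e.data.mean(axis=1, keepdims=True))


def bandpass(e: EpochArray, band: tuple = (0.5, 45.0), order: int = 4) -> EpochArray:
    """Zero-phase Butterworth band-pass (forward-backward, no group delay)."""
    low, high = band
    if not 0 < low < high or high >= e.fs / 2:
        raise ConfigurationError(
            f"band {band} invalid for fs={e.fs} (need 0 < low < high < Nyquist)"
        )
    sos = butter(order, band, btype="bandpass", fs=e.fs, output="sos")
    return e.with_data(sosfiltfilt(sos, e.data, axis=-1))


def _window_slice(e: EpochArray, window: tuple, what: str) -> slice:
    start, stop = window
    t_end = e.t0 + e.n_samples / e.fs
    if start < e.t0 - 1e-9 or stop > t_end + 1e-9 or stop <= start:
        raise ConfigurationError(
            f"{what} window {window} outside epoch [{e.t0}, {t_end}) "
            f"(subject {e.subject}, session {e.session})"
        )
    i0 = int(round((start - e.t0) * e.fs))
    n = int(round((stop - start) * e.fs))
    return slice(i0, i0 + n)


def baseline_correct(e: EpochArray, window: tuple = (-0.1, 0.0)) -> EpochArray:
    """Subtract the per-trial/channel mean over the baseline window."""
    sl = _window_slice(e, window, "baseline")
    return e.with_data(e.data - e.data[:, :, sl].mean(axis=-1, keepdims=True))


def reject_artifacts(e: EpochArray, threshold_uv: float = 100.0):
    """Drop trials whose peak absolute amplitude exceeds the threshold.

    Returns ``(clean, rejected_trial_ids)``; raises
    :class:`~wmentropy.errors.EmptyResultError` if nothing survives.
    """
    if threshold_uv <= 0:
        raise ConfigurationError(f"reject_uv must be > 0, got {threshold_uv}")
    peak = np.abs(e.data).max(axis=(1, 2))
    keep = peak <= threshold_uv
    rejected = e.trial_ids[~keep]
    if not keep.any():
        raise EmptyResultError(
            f"all {e.n_trials} trials rejected at +/-{threshold_uv} uV "
            f"(subject {e.subject}, session {e.session})"
        )
    return e.with_data(e.data[keep], trial_ids=e.trial_ids[keep]), rejected


def extract_retention(e: EpochArray, window: tuple = (0.2, 3.2)) -> EpochArray:
    """Cut the retention interval; sample count = round(fs * duration)."""
    sl = _window_slice(e, window, "retention")
    return e.with_data(e.data[:, :, sl], t0=window[0])


def preprocess_pipeline(e: EpochArray, cfg: PreprocessConfig = None):
    """Full cleaning chain; returns ``(retention_epochs, rejected_trial_ids)``."""
    cfg = cfg or PreprocessConfig()
    cfg.validate(e.fs)
    e = rereference_average(e)
    e = bandpass(e, cfg.band)
    e = baseline_correct(e, cfg.baseline_window)
    e, rejected = reject_artifacts(e, cfg.reject_uv)
    return extract_retention(e, cfg.retention_window), rejected


def read_edf_epochs(
    edf_path: str,
    events: "pandas.DataFrame",
    subject: int,
    session: int,
    epoch_span: tuple = (-0.1, 3.3),
) -> EpochArray:
    """Cut epochs from a continuous EDF recording (optional input path).

    ``events`` needs columns ``subject, session, trial, onset_s`` with onsets
    of the memory array in recording time.  Channels are taken as recorded;
    amplitudes are converted to microvolts.
    """
    import mne  # deferred; only the EDF path needs it

    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    fs = raw.info["sfreq"]
    data = raw.get_data() * 1e6  # volts -> microvolts
    sel = events[(events["subject"] == subject) & (events["session"] == session)]
    if sel.empty:
        raise UnsupportedInputError(
            f"no events for subject {subject}, session {session}"
        )
    n = int(round(fs * (epoch_span[1] - epoch_span[0])))
    trials = []
    for onset in sel["onset_s"]:
        i0 = int(round((onset + epoch_span[0]) * fs))
        if i0 < 0 or i0 + n > data.shape[1]:
            raise UnsupportedInputError(
                f"epoch at onset {onset}s exceeds recording bounds"
            )
        trials.append(data[:, i0 : i0 + n])
    return EpochArray(
        subject=subject,
        session=session,
        data=np.stack(trials),
        fs=fs,
        channels=list(raw.ch_names),
        t0=epoch_span[0],
        trial_ids=sel["trial"].to_numpy(),
    )
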