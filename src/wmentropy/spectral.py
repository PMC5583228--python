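"""Welch power spectra and normalized spectral entropy.

Spectral entropy treats the normalized power spectral density as a
probability distribution over frequency bins and takes its Shannon entropy
in base 10 (unit: dit).  A perfectly uniform spectrum over N bins has
entropy log10(N); a single-line spectrum has entropy 0.  Normalizing the
PSD by total band power makes the measure invariant to amplitude scaling.

PSDs are estimated with Welch's method (Hamming window, 1 s segments, 50%
overlap by default - 1 Hz resolution over a 3 s retention segment) and
restricted to the 0.5-45 Hz analysis band inclusive; the normalization and
the entropy sum run over exactly these bins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import welch

from .containers import EpochArray
from .errors import (
    ContractViolation,
    DegenerateInputError,
    EmptyResultError,
    UnsupportedInputError,
)

#: entropy summation convention: 0 * log 0 := 0 (by continuity)


@dataclass
class WelchConfig:
    """Welch estimator settings."""

    segment_s: float = 1.0
    overlap_frac: float = 0.5
    window: str = "hamming"
    band: tuple = (0.5, 45.0)
    aggregation: str = "trial_mean_entropy"  # or "entropy_of_mean_psd"


@dataclass
class PowerSpectrum:
    """One-sided PSD restricted to the analysis band."""

    frequencies: np.ndarray
    psd: np.ndarray
    band: tuple = (0.5, 45.0)

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.frequencies.ndim != 1 or self.psd.shape[-1] != self.frequencies.size:
            raise UnsupportedInputError(
                "psd's last axis must match the frequency grid"
            )
        if np.any(self.psd < 0):
            raise UnsupportedInputError("psd values must be non-negative")


def welch_psd(
    signal: np.ndarray,
    fs: float,
    segment_s: float = 1.0,
    overlap_frac: float = 0.5,
    window: str = "hamming",
    band: tuple = (0.5, 45.0),
) -> PowerSpectrum:
    """Welch PSD of a single-channel segment, restricted to ``band``.

    The last axis is time; leading axes (trials, channels) pass through, so
    the returned ``psd`` has shape ``signal.shape[:-1] + (n_bins,)``.
    """
    signal = np.asarray(signal, dtype=float)
    nperseg = int(round(fs * segment_s))
    if signal.shape[-1] < nperseg:
        raise UnsupportedInputError(
            f"segment of {signal.shape[-1]} samples shorter than one Welch "
            f"window of {nperseg}"
        )
    freqs, psd = welch(
        signal,
        fs=fs,
        window=window,
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap_frac)),
        axis=-1,
    )
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return PowerSpectrum(frequencies=freqs[sel], psd=psd[..., sel], band=band)


def normalize_psd(p: PowerSpectrum) -> PowerSpectrum:
    """Divide by total band power so the PSD sums to one."""
    total = p.psd.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise DegenerateInputError("cannot normalize an all-zero power spectrum")
    out = replace(p, psd=p.psd / total)
    return out


def spectral_entropy(p: PowerSpectrum) -> float:
    """Shannon entropy of a normalized PSD, base 10 (dit).

    Requires a normalized spectrum (|sum - 1| <= 1e-6); use
    :func:`normalize_psd` first.  Works on stacked spectra (last axis =
    frequency), returning an array of entropies.
    """
    total = p.psd.sum(axis=-1)
    if np.any(np.abs(total - 1.0) > 1e-6):
        raise ContractViolation(
            "spectral_entropy requires a normalized PSD (sum deviates from 1 "
            f"by up to {np.max(np.abs(total - 1.0)):.3g})"
        )
    q = p.psd
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * np.log10(np.where(q > 0, q, 1.0)), 0.0)
    sen = -terms.sum(axis=-1)
    return float(sen) if np.ndim(sen) == 0 else sen


def subject_entropy(
    epochs: EpochArray,
    cfg: WelchConfig = None,
) -> pd.DataFrame:
    """Per-channel spectral entropy for one subject/session block.

    Aggregation across trials (``cfg.aggregation``):

    * ``trial_mean_entropy`` (default) - entropy of each trial's normalized
      PSD, then the mean over trials;
    * ``entropy_of_mean_psd`` - entropy of the trial-averaged normalized PSD.

    Returns a table ``subject, session, channel, sen, n_trials``.
    """
    cfg = cfg or WelchConfig()
    if epochs.n_trials == 0:
        raise EmptyResultError(
            f"no retained trials for subject {epochs.subject}, "
            f"session {epochs.session}"
        )
    if cfg.aggregation not in ("trial_mean_entropy", "entropy_of_mean_psd"):
        raise ContractViolation(f"unknown aggregation '{cfg.aggregation}'")
    spec = welch_psd(
        epochs.data,
        fs=epochs.fs,
        segment_s=cfg.segment_s,
        overlap_frac=cfg.overlap_frac,
        window=cfg.window,
        band=cfg.band,
    )
    norm = normalize_psd(spec)  # (trials, channels, bins)
    if cfg.aggregation == "trial_mean_entropy":
        sen = spectral_entropy(norm).mean(axis=0)
    else:
        mean_psd = replace(norm, psd=norm.psd.mean(axis=0))
        sen = spectral_entropy(normalize_psd(mean_psd))
    return pd.DataFrame(
        {
            "subject": epochs.subject,
            "session": epochs.session,
            "channel": epochs.channels,
            "sen": sen,
            "n_trials": epochs.n_trials,
        }
    )


def cohort_entropy(epoch_list, cfg: WelchConfig = None) -> pd.DataFrame:
    """Concatenate :func:`subject_entropy` over a list of blocks."""
    return pd.concat(
        [subject_entropy(e, cfg) for e in epoch_list], ignore_index=True
    )
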