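"""Seeded synthetic cohorts of working-memory EEG and behavior.

The study design emulated here is a two-session delayed-match-to-sample
experiment: each subject performs 60 trials per session at memory loads of
2, 4 or 8 items, responding left or right hand within a maximum allowed time,
while 64-channel EEG is recorded; the 3000 ms retention interval is the
analyzed segment.

A latent per-subject ability drives both sides of the analysis:

* **Spectra** — on one designated target channel (FC4 by default) the trial
  power spectrum is a mixture of a flat 0.5-45 Hz plateau and a narrow alpha
  bump (10 Hz, sd 1 Hz) on a 1/f background.  The bump weight ``w`` (the
  *entropy driver*) is a decreasing logistic function of a Gaussian latent
  correlated with ability, so higher ability gives a flatter spectrum and
  hence higher spectral entropy.  The ability–latent Pearson correlation is
  set to ``2 sin(pi * coupling / 6)`` so the *rank* (Spearman) correlation
  between ability and the entropy driver equals ``coupling``.
* **Behavior** — accuracy is Bernoulli with a logistic link in ability and
  log2(load); response latency is lognormal with a median that decreases
  with ability, capped at the maximum allowed time (capped draws are scored
  as timeouts: incorrect with rt = mt).

Trial time series are synthesized in the frequency domain: independent
complex-Gaussian spectral coefficients (uniform random phases, Rayleigh
amplitudes) scaled to the target one-sided PSD, inverse-FFT'd to the epoch
length.  The PSD is therefore controlled exactly in expectation and every
trial is an independent circularly-stationary surrogate.

All randomness flows from ``SynthConfig.seed``; identical configs give
bit-identical cohorts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import EpochArray
from .errors import ConfigurationError, FormatError
from .montage import default_channels

# --- fixed model constants (see docs/methods.md for rationale) -------------
BAND = (0.5, 45.0)              # Hz, analysis band
BAND_POWER_UV2 = 100.0          # total in-band power -> ~10 uV rms signals
PINK_FRACTION = 0.25            # 1/f background share of band power
BUMP_CENTER_HZ = 10.0           # alpha bump location
BUMP_SD_HZ = 1.0
LOGISTIC_SLOPE = 1.2            # latent -> entropy-driver squashing slope
TRAIT_FRACTION = 0.7            # share of the entropy latent noise that is
                                # stable within subject across sessions
ABILITY_SESSION_SD = 0.2        # session-to-session ability wobble
ACC_INTERCEPT = 2.2             # P(correct) = expit(b0 + b1*a - b2*log2 load)
ACC_ABILITY = 1.2
ACC_LOAD = 0.45
RT_MEDIAN_S = 1.0               # latency median at ability 0, load 2
RT_ABILITY = 0.25               # median multiplier exp(-RT_ABILITY * ability)
RT_LOAD = 0.08                  # median grows with log2(load) - 1
RT_SIGMA = 0.35                 # lognormal shape
RT_MEDIAN_CLIP = (0.2, 2.5)     # seconds
ARTIFACT_UV = 150.0             # injected square transient amplitude
ARTIFACT_S = 0.2                # and duration
EPOCH_PRE_S = 0.1               # epoch starts 100 ms before memory array
STIM_S = 0.2                    # memory array on screen
EPOCH_POST_S = 0.1              # margin after retention end


def _pearson_for_spearman(rho_s: float) -> float:
    """Pearson correlation of a bivariate Gaussian whose Spearman is rho_s."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


@dataclass
class SynthConfig:
    """Configuration of a synthetic cohort.

    Defaults mirror the emulated study: 20 subjects, 2 sessions, 60 trials
    per session at equiprobable loads {2, 4, 8}, 64 channels, 3 s retention,
    target channel FC4.  ``fs`` defaults to 250 Hz for desk-scale speed
    (1000 Hz mimics the original recordings).
    """

    n_subjects: int = 20
    n_sessions: int = 2
    trials_per_session: int = 60
    loads: tuple = (2, 4, 8)
    n_channels: int = 64
    fs: float = 250.0
    retention_s: float = 3.0
    target_channel: str = "FC4"
    coupling: float = 0.8
    training_gain: float = 0.8
    artifact_rate: float = 0.0
    mt: float = 3.0
    seed: int = 0
    channels: list = field(default=None)

    def __post_init__(self):
        if self.channels is None:
            self.channels = default_channels(self.n_channels)

    def validate(self) -> None:
        for name in ("n_subjects", "n_sessions", "trials_per_session", "n_channels"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 <= self.coupling <= 1.0:
            raise ConfigurationError(f"coupling must be in [0, 1], got {self.coupling}")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ConfigurationError(
                f"artifact_rate must be in [0, 1], got {self.artifact_rate}"
            )
        n_ret = self.fs * self.retention_s
        if abs(n_ret - round(n_ret)) > 1e-9 or round(n_ret) < 64:
            raise ConfigurationError(
                f"fs * retention_s must be an integer >= 64, got {n_ret}"
            )
        if len(self.channels) != self.n_channels:
            raise ConfigurationError(
                f"channels: {len(self.channels)} labels for n_channels={self.n_channels}"
            )
        if self.target_channel not in self.channels:
            raise ConfigurationError(
                f"target_channel '{self.target_channel}' not in channel list"
            )
        if self.mt <= 0:
            raise ConfigurationError(f"mt must be > 0, got {self.mt}")
        if len(self.loads) < 1:
            raise ConfigurationError("loads must be non-empty")

    @property
    def epoch_span(self) -> tuple:
        """(start, stop) of the synthesized epoch in seconds re memory onset."""
        return (-EPOCH_PRE_S, STIM_S + self.retention_s + EPOCH_POST_S)

    @property
    def n_epoch_samples(self) -> int:
        start, stop = self.epoch_span
        return int(round(self.fs * (stop - start)))


@dataclass
class GroundTruth:
    """Latents of a generated cohort, for parameter-recovery tests.

    ``table`` has one row per subject x session with the latent ability and
    the entropy driver ``w`` (spectral bump weight; decreasing in ability).
    ``artifact_log`` lists injected artifact trials.
    """

    table: pd.DataFrame
    target_channel: str
    artifact_log: pd.DataFrame

    def equals(self, other: "GroundTruth") -> bool:
        return (
            self.target_channel == other.target_channel
            and self.table.equals(other.table)
            and self.artifact_log.equals(other.artifact_log)
        )


def _psd_components(freqs: np.ndarray, df: float):
    """Unit-power 1/f, flat and alpha-bump shapes on the rfft grid."""
    in_band = (freqs >= BAND[0]) & (freqs <= BAND[1])
    pink = np.where(in_band, 1.0 / np.maximum(freqs, BAND[0]), 0.0)
    flat = in_band.astype(float)
    bump = np.where(
        in_band, np.exp(-0.5 * ((freqs - BUMP_CENTER_HZ) / BUMP_SD_HZ) ** 2), 0.0
    )
    return tuple(c / (c.sum() * df) for c in (pink, flat, bump))


def generate_blocks(cfg: SynthConfig):
    """Yield ``(epoch, behavior_block, truth_row, artifact_block)`` lazily.

    Blocks arrive subject-major (subject 1 session 1, subject 1 session 2,
    ...).  The RNG stream is identical to :func:`generate_cohort`, which is
    simply the materialized version of this iterator; streaming keeps peak
    memory at one subject/session block regardless of cohort size.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, n_sess, n_tr = cfg.n_subjects, cfg.n_sessions, cfg.trials_per_session
    nch = cfg.n_channels
    target_idx = cfg.channels.index(cfg.target_channel)
    n_samp = cfg.n_epoch_samples
    freqs = np.fft.rfftfreq(n_samp, 1.0 / cfg.fs)
    df = cfg.fs / n_samp
    pink, flat, bump = _psd_components(freqs, df)

    rho_p = _pearson_for_spearman(cfg.coupling)
    sd_ability = np.sqrt(1.0 + ABILITY_SESSION_SD**2)
    a_base = rng.standard_normal(n)
    eps_trait = rng.standard_normal(n)
    loads = np.sort(np.asarray(cfg.loads))

    for i in range(n):
        for s in range(1, n_sess + 1):
            ability = (
                a_base[i]
                + cfg.training_gain * (s == 2)
                + ABILITY_SESSION_SD * rng.standard_normal()
            )
            eps = (
                np.sqrt(TRAIT_FRACTION) * eps_trait[i]
                + np.sqrt(1.0 - TRAIT_FRACTION) * rng.standard_normal()
            )
            latent = rho_p * ability / sd_ability + np.sqrt(1.0 - rho_p**2) * eps
            w_target = expit(-LOGISTIC_SLOPE * latent)
            w = expit(-LOGISTIC_SLOPE * rng.standard_normal(nch))
            w[target_idx] = w_target

            psd = BAND_POWER_UV2 * (
                PINK_FRACTION * pink
                + (1.0 - PINK_FRACTION)
                * ((1.0 - w)[:, None] * flat + w[:, None] * bump)
            )  # (nch, nf), one-sided density in uV^2/Hz
            # complex-Gaussian spectral draw: E|X_k|^2 = psd_k * fs * n / 2
            scale = np.sqrt(psd * cfg.fs * n_samp / 4.0)
            z = rng.standard_normal((n_tr, nch, freqs.size, 2)).view(np.complex128)[
                ..., 0
            ]
            z *= scale
            data = np.fft.irfft(z, n=n_samp, axis=-1)

            art_rows = []
            if cfg.artifact_rate > 0:
                hit = rng.random(n_tr) < cfg.artifact_rate
                n_art_samp = int(round(ARTIFACT_S * cfg.fs))
                for t in np.flatnonzero(hit):
                    ch = rng.integers(nch)
                    onset = rng.integers(0, n_samp - n_art_samp + 1)
                    data[t, ch, onset : onset + n_art_samp] += ARTIFACT_UV
                    art_rows.append(
                        {"subject": i + 1, "session": s, "trial": int(t)}
                    )

            epoch = EpochArray(
                subject=i + 1,
                session=s,
                data=data,
                fs=cfg.fs,
                channels=list(cfg.channels),
                t0=cfg.epoch_span[0],
                trial_ids=np.arange(n_tr),
            )

            trial_loads = rng.choice(loads, size=n_tr)
            hands = rng.choice(np.array(["left", "right"]), size=n_tr)
            p_correct = expit(
                ACC_INTERCEPT + ACC_ABILITY * ability - ACC_LOAD * np.log2(trial_loads)
            )
            median = np.clip(
                RT_MEDIAN_S
                * np.exp(-RT_ABILITY * ability)
                * (1.0 + RT_LOAD * (np.log2(trial_loads) - 1.0)),
                *RT_MEDIAN_CLIP,
            )
            rt = rng.lognormal(np.log(median), RT_SIGMA)
            correct = rng.random(n_tr) < p_correct
            timeout = rt >= cfg.mt
            rt = np.where(timeout, cfg.mt, rt)
            correct = np.where(timeout, False, correct)
            beh_block = pd.DataFrame(
                {
                    "subject": np.full(n_tr, i + 1),
                    "session": np.full(n_tr, s),
                    "trial": np.arange(n_tr),
                    "load": trial_loads.astype(int),
                    "hand": hands,
                    "accuracy": correct.astype(int),
                    "rt": rt.astype(float),
                    "mt": np.full(n_tr, float(cfg.mt)),
                }
            )
            truth_row = {
                "subject": i + 1,
                "session": s,
                "ability": float(ability),
                "entropy_driver": float(w_target),
            }
            art_block = pd.DataFrame(
                art_rows, columns=["subject", "session", "trial"]
            )
            yield epoch, beh_block, truth_row, art_block


def generate_cohort(cfg: SynthConfig):
    """Generate EEG epochs, a behavior table and the generating latents.

    Returns
    -------
    epochs : list of EpochArray
        One block per subject x session, subject-major order.
    behavior : pandas.DataFrame
        Columns ``subject, session, trial, load, hand, accuracy, rt, mt``.
    truth : GroundTruth
    """
    epochs, beh_blocks, truth_rows, art_blocks = [], [], [], []
    for epoch, beh, truth_row, art in generate_blocks(cfg):
        epochs.append(epoch)
        beh_blocks.append(beh)
        truth_rows.append(truth_row)
        art_blocks.append(art)
    behavior = pd.concat(beh_blocks, ignore_index=True)
    art_all = pd.concat(art_blocks, ignore_index=True).astype(
        {"subject": int, "session": int, "trial": int}
    )
    truth = GroundTruth(
        table=pd.DataFrame(truth_rows),
        target_channel=cfg.target_channel,
        artifact_log=art_all,
    )
    return epochs, behavior, truth


# --- fixture container ------------------------------------------------------

EEG_FILE = "eeg.h5"
BEHAVIOR_FILE = "behavior.csv"
TRUTH_FILE = "ground_truth.csv"
ARTIFACT_FILE = "artifact_log.csv"


def write_epochs_h5(path: str, epochs, root_attrs: dict = None) -> str:
    """Write a list of EpochArray blocks to one HDF5 container."""
    with h5py.File(path, "w") as f:
        for k, v in (root_attrs or {}).items():
            f.attrs[k] = v
        for e in epochs:
            g = f.create_group(f"sub-{e.subject:02d}/ses-{e.session}")
            g.create_dataset("data", data=e.data)
            g.create_dataset("trial_ids", data=e.trial_ids)
            g.attrs["fs"] = e.fs
            g.attrs["channels"] = e.channels
            g.attrs["t0"] = e.t0
            g.attrs["subject"] = e.subject
            g.attrs["session"] = e.session
    return path


def read_epochs_h5(path: str):
    """Read an epoch container; returns ``(epochs, root_attrs)``."""
    if not os.path.exists(path):
        raise FormatError(f"missing EEG container '{path}'")
    epochs = []
    with h5py.File(path, "r") as f:
        root_attrs = dict(f.attrs)
        for sub in sorted(f.keys()):
            for ses in sorted(f[sub].keys()):
                g = f[sub][ses]
                name = f"{sub}/{ses}"
                for attr in ("fs", "channels", "t0", "subject", "session"):
                    if attr not in g.attrs:
                        raise FormatError(
                            f"container missing attribute '{attr}' on group '{name}'"
                        )
                if "data" not in g:
                    raise FormatError(f"container missing dataset '{name}/data'")
                epochs.append(
                    EpochArray(
                        subject=int(g.attrs["subject"]),
                        session=int(g.attrs["session"]),
                        data=g["data"][()],
                        fs=float(g.attrs["fs"]),
                        channels=[str(c) for c in g.attrs["channels"]],
                        t0=float(g.attrs["t0"]),
                        trial_ids=g["trial_ids"][()],
                    )
                )
    return epochs, root_attrs


def write_fixture(cohort, path: str) -> list:
    """Write a cohort to ``path`` (a directory) as HDF5 + CSV files.

    The EEG container holds one ``sub-XX/ses-Y`` group per block with a
    ``data`` dataset (trials x channels x samples, microvolts) plus ``fs``,
    ``channels`` and ``t0`` attributes and a ``trial_ids`` dataset.  Floats
    round-trip bit-exactly.
    """
    epochs, behavior, truth = cohort
    os.makedirs(path, exist_ok=True)
    eeg_path = os.path.join(path, EEG_FILE)
    write_epochs_h5(eeg_path, epochs, {"target_channel": truth.target_channel})
    paths = [eeg_path]
    for name, frame in (
        (BEHAVIOR_FILE, behavior),
        (TRUTH_FILE, truth.table),
        (ARTIFACT_FILE, truth.artifact_log),
    ):
        p = os.path.join(path, name)
        # %.17g round-trips float64 exactly through text
        frame.to_csv(p, index=False, float_format="%.17g")
        paths.append(p)
    return paths


def read_fixture(path: str):
    """Read a cohort written by :func:`write_fixture`; inverse round trip."""
    eeg_path = os.path.join(path, EEG_FILE)
    epochs, root_attrs = read_epochs_h5(eeg_path)
    if "target_channel" not in root_attrs:
        raise FormatError("container missing root attribute 'target_channel'")
    target_channel = str(root_attrs["target_channel"])
    read = lambda p: pd.read_csv(p, float_precision="round_trip")
    behavior = read(os.path.join(path, BEHAVIOR_FILE)).astype(
        {"rt": float, "mt": float}
    )
    table = read(os.path.join(path, TRUTH_FILE)).astype(
        {"ability": float, "entropy_driver": float}
    )
    artifact_log = read(os.path.join(path, ARTIFACT_FILE))
    # preserve dtypes for an empty log (pandas reads empty columns as object)
    if artifact_log.empty:
        artifact_log = artifact_log.astype({"subject": int, "session": int, "trial": int})
    truth = GroundTruth(
        table=table, target_channel=target_channel, artifact_log=artifact_log
    )
    return epochs, behavior, truth
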