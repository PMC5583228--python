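# Methods

`wmentropy` implements a spectral-entropy analysis of working-memory EEG:
from epoched retention-period recordings and trial-level behavior to a
single-channel biomarker evaluated by cross-validated classification and
regression. Because the kind of study it targets rarely deposits raw EEG,
the package includes a synthetic cohort generator with a known
data-generating process, so every claim the pipeline makes can be tested as
parameter recovery.

## The analysis

**Behavioral score.** Each trial of the delayed-match-to-sample task
contributes a Signed Residual Time increment

    SRT = Σ_i (2·RACC_i − 1) · (MT − t_i)

where `RACC_i ∈ {0,1}` is accuracy, `t_i` the response latency and `MT` the
maximum allowed response time. Fast correct answers earn the residual time;
fast errors lose it. Timed-out or omitted responses are scored as incorrect
with `t = MT`, contributing zero (they neither reward nor punish). `MT` is a
configurable scalar (default 3.0 s, uniform across loads): it must exceed
typical latencies for the score to reward speed.

**Spectral entropy.** Per trial and channel, the Welch PSD of the 3000 ms
retention segment is restricted to 0.5–45 Hz inclusive, normalized to sum
to one over exactly those bins, and summarized by its Shannon entropy in
base 10 (unit *dit*):

    SEn = − Σ_f P̂(f) · log10 P̂(f),      0·log 0 := 0.

SEn is maximal (`log10 N_bins`) for a perfectly flat spectrum and 0 for a
single line; normalization makes it invariant to amplitude scale. Welch
defaults: Hamming window, 1.0 s segments, 50 % overlap — 1 Hz resolution,
five segments per 3 s trial; all configurable. Trials are aggregated by
averaging per-trial entropies (default); entropy of the trial-averaged
normalized PSD is exposed as an alternative, since either reading is
defensible and they agree in the degenerate identical-trial case.

**Preprocessing.** Average reference → zero-phase Butterworth band-pass
(order 4 per pass, 0.5–45 Hz) → 100 ms pre-stimulus baseline correction →
±100 μV amplitude rejection → retention cut (0.2–3.2 s after memory-array
onset; the array occupies 0–0.2 s). The average reference is a deliberate
stand-in for an infinity (REST) reference, which requires a head model;
source-separation-based ocular/muscle cleaning is likewise out of scope and
replaced by amplitude rejection. Windows are half-open `[start, stop)`
seconds relative to memory-array onset. The filter contract is attenuation
(≥90 % passband retention, ≤10 % far-stopband leakage), not a particular
realization.

**Channel fingerprint.** Each channel's entropy is Spearman-correlated with
SRT across subjects, within session 1, session 2, or the merged sessions
(each subject-session pair one observation). Ties use mid-ranks, reducing
to the classical `1 − 6Σd²/(m(m²−1))` shortcut for tie-free data. P-values
are Benjamini–Hochberg adjusted across channels; the selected channel
maximizes |r| (ties broken toward the lexicographically smallest label, with
a warning). Selecting once on the full cohort is optimistically biased —
the selection has seen every subject — which is why the single whole-cohort
selection is reported as the standard field protocol while the test suite
checks *recovery of a planted channel*, not absolute accuracy.

**Classification and prediction.** High/low performer labels come from the
within-session z-score of SRT (sample sd, n−1); `z > 0` strictly is "high",
so an exact zero lands in "low". A linear-kernel SVM on the selected
channel's entropy is evaluated with leave-one-out cross-validation within
each session and by train-on-one-session / test-on-the-other across
sessions. An RBF-kernel SVR predicts SRT under the same LOOCV. Protocol
choices that matter at n = 20:

- Standardization of the feature (and SVR target) uses training-fold
  statistics only; held-out samples are transformed, never refit.
- The SVM uses `class_weight="balanced"`. Leave-one-out folds are
  imbalanced *by construction*: removing the test subject tilts the
  training class ratio against its own class, and an unweighted
  margin classifier then votes with the majority, depressing null-data
  accuracy far below 0.5 (we measured ≈0.41 for the unweighted variant on
  pure-noise features). Balancing restores a chance-centered null without
  touching genuinely informative features. Set `SVMConfig(class_weight=None)`
  to reproduce the unweighted behavior.
- No hyperparameter search: `C = 1` (SVM and SVR), `ε = 0.1`, `γ = 1/var`
  of the standardized training feature (≈1). Twenty subjects cannot support
  nested tuning honestly; all constants are exposed in config.
- One ROC per scheme is built from held-out decision scores pooled across
  folds; AUC is the trapezoidal area and equals the normalized
  Mann–Whitney U statistic (asserted in tests).
- CA = (TP+TN)/total, SE = TP/(TP+FN), SP = TN/(TN+FP); a metric whose
  denominator is empty (one-class test set) is reported as NaN with a
  warning rather than silently dropped.
- Predicted-vs-actual correlation for the SVR is Pearson's r; RMSEP is the
  root mean squared error over pooled held-out predictions. P-values across
  the three prediction scopes share the BH helper.

**Change rates.** Training-induced change in any score T is
`CR = 2(T_A − T_B)/(T_A + T_B) × 100 %` (A = after, B = before), a
symmetric percent change that puts SRT and entropy on one scale. A subject
is *consistent* when `CR_SRT · CR_SEn > 0`; an exact zero on either side
counts as inconsistent and is flagged. `T_A + T_B = 0` raises an error
rather than producing an unbounded value.

**Hand × load ANOVA.** Per-cell behavior (mean per-trial signed residual
time per subject × hand × load — means, not sums, so random cell-count
imbalance does not masquerade as an effect) enters a 2×3 repeated-measures
ANOVA (pingouin). Greenhouse–Geisser-corrected p-values are used for the
three-level factor and the interaction when Mauchly's test on the load
factor rejects sphericity at 0.05; two-level effects are always spherical
(ε = 1). Fully degenerate designs (zero effect and zero error sums of
squares) report F = 0, p = 1 by convention. Partial eta squared is
`SS_effect/(SS_effect+SS_error)`.

## The synthetic cohort generator

The generator emulates the study design: `n_subjects = 20` × 2 sessions ×
60 trials at equiprobable memory loads {2, 4, 8}, 64 channels (extended
10-20 labels; any prefix of the canonical list is a usable montage and the
16-channel prefix contains FC4), 3 s retention epochs sampled at 250 Hz by
default (1000 Hz mimics typical recordings; 250 Hz keeps desk-scale runs
fast and leaves the 0.5–45 Hz analysis band untouched).

A latent ability `a_is = a_i + gain·1[s=2] + η_is` (`a_i ~ N(0,1)`,
session wobble η sd 0.2, training gain default 0.8) drives both sides:

- **Spectra.** The target channel's trial PSD is
  `P(f) ∝ 0.25·pink(f) + 0.75·[(1−w)·flat + w·bump(10 Hz, sd 1 Hz)]` over
  0.5–45 Hz, scaled to 100 μV² band power (≈10 μV rms, peaks well under
  the 100 μV rejection threshold). The *entropy driver*
  `w = logistic(−1.2·g)` shrinks the alpha bump as the latent `g` grows, so
  higher ability ⇒ flatter spectrum ⇒ higher entropy. `g` correlates with
  ability at Pearson `ρ' = 2·sin(π·coupling/6)`, the bivariate-Gaussian
  inversion that makes the realized *Spearman* correlation equal the
  `coupling` dial (default 0.8; 0 gives a fully null channel). 70 % of the
  non-ability variance in `g` is a stable subject trait, 30 % session
  noise — an individual's spectral character is trait-like, and this keeps
  session-to-session entropy changes aligned with ability changes rather
  than drowned in resampling noise. Non-target channels draw independent
  `w`s. Trial time series are inverse-FFT surrogates with independent
  complex-Gaussian spectral coefficients (uniform phases), so the PSD is
  controlled exactly in expectation and trials are circularly stationary.
- **Behavior.** `P(correct) = logistic(2.2 + 1.2·a − 0.45·log2 load)`;
  latency is lognormal (shape 0.35) with median
  `1.0·exp(−0.25·a)·(1 + 0.08(log2 load − 1))` s clipped to [0.2, 2.5],
  capped at `MT`; capped draws become timeouts (incorrect, `t = MT`).
  These constants give ≈70–90 % accuracy falling with load, ~1 s medians,
  and an SRT–ability correlation near 0.93 — strong but imperfect
  behavioral readout, matching the high-performing cohorts such tasks
  recruit. They were fixed once, at design time, so that the generator
  meets its own contracts (coupling dial realized, planted channel
  recoverable) and are not tuned per experiment.
- **Artifacts.** With probability `artifact_rate` a trial receives a
  150 μV, 200 ms square transient on one random channel — enough to trip
  the ±100 μV rejection deterministically, which is all the pipeline
  inspects. No attempt is made at ocular/muscle waveform realism, dipole
  forward models or volume conduction; channels are statistically
  independent, so the generator cannot exercise spatial-filtering methods,
  only label-respecting channel selection.

All randomness flows from one seed; equal configs give bit-identical
cohorts (HDF5 + CSV fixtures round-trip floats exactly via `%.17g`).

What passing tests therefore show: the pipeline *recovers planted structure
at realistic effect sizes and stays quiet on null data*. What they cannot
show: robustness to correlated channels, non-stationary rhythms, real
artifact morphology, or population differences — claims about real EEG
still require real EEG.

## Problem sizes in tests and the acceptance script

The test suite's Monte-Carlo checks use 100 seeded cohorts of 20 subjects —
16 channels for the planted-signal recovery conditions (coupling 0.8) and
64 channels for the null control (coupling 0), the size at which the
false-discovery check is meaningful — streamed block-wise so peak memory
stays at one subject/session. `scripts/acceptance.py` runs the full default
pipeline (20 × 2 × 60, 16 channels @ 250 Hz) once per seed and reports the
quantities it computes; at n = 20 these are honest but noisy — single-seed
correlations spread roughly ±0.2 around their means.

## Known limitations

- Best-channel selection on the full cohort inflates downstream accuracy;
  the optional fold-nested re-selection is off by default to mirror the
  standard protocol, and the caveat stands.
- The mid-rank Spearman p-value uses the t approximation, adequate at
  m ≥ 20 but approximate below.
- The EDF reading path converts whole recordings in memory and is intended
  for modest laboratory files, not continuous high-density archives.
- Sensitivity/specificity printed as NaN (one-class test sets) propagate
  into JSON as NaN, which some strict parsers reject.
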