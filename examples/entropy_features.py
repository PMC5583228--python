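"""Preprocess one subject's epochs and compute per-channel spectral entropy.

Spectral entropy (base-10 Shannon entropy of the normalized Welch PSD over
0.5-45 Hz, unit dit) measures how uniformly power spreads over frequency:
a flat spectrum scores near log10(45) ~ 1.65 dit, a sharp alpha peak lower.
"""

import wmentropy as wm

cfg = wm.SynthConfig(n_subjects=1, n_channels=16, trials_per_session=60, seed=7)
epochs, behavior, truth = wm.generate_cohort(cfg)

# reference -> band-pass -> baseline -> +/-100 uV rejection -> retention cut
retention, rejected = wm.preprocess_pipeline(epochs[0])
print(f"kept {retention.n_trials} trials ({len(rejected)} rejected), "
      f"{retention.n_samples} samples of retention-period EEG per trial")

features = wm.subject_entropy(retention)
print("\nPer-channel spectral entropy (dit), session 1:")
print(features[["channel", "sen"]].round(4).to_string(index=False))
w = truth.table.iloc[0].entropy_driver
print(f"\nTarget channel FC4 carries the subject's alpha-bump weight "
      f"w = {w:.3f}; higher w concentrates power at 10 Hz and lowers entropy.")
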