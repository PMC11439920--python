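"""Simulate one condition cell and measure its neural alignment.

Builds eight subjects who all hear the same 0.5-10 Hz band-limited
stimulus-driven signal through subject-specific sensor mixing (alignment
strength 1.0), runs 3-fold cross-validated MAXVAR MCCA, and tests the
intersubject correlation of the strongest canonical component against a
circular-shift bootstrap null.
"""

import numpy as np

import neuralign as na
from neuralign.syndata import SubjectForwardModel

rng = np.random.default_rng(0)
latent = na.make_latent_signal(duration_s=60, fs=100, band=(0.5, 10.0), rng=rng)

recordings = {}
for i in range(8):
    fm = SubjectForwardModel(mixing=rng.standard_normal(16), subject_id=f"s{i}")
    recordings[f"s{i}"] = na.synthesize_subject(latent, fm, snr=1.0, rng=rng)

result = na.crossval_alignment(recordings, k=3, pca_dim=8)
na.circular_null(result, n_shuffles=2000, seed=1)

print(f"combined intersubject correlation statistic z = {result.combined:.3f}")
print(f"equivalent correlation r = {result.r_equivalent:.3f}")
print(f"bootstrap p-value (2000 circular shifts)      = {result.p_value:.4f}")
print(f"selected component per fold: {[f.component for f in result.folds]}")
print("per-subject ISC (Fisher z):",
      np.round(result.subject_values, 3).tolist())
print()
print("The combined statistic averages |pooled Fisher z| of the strongest")
print("held-out canonical component over the three folds; the p-value is the")
print("fraction of per-subject circular time shifts that reach it by chance.")
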