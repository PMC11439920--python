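# Methods

`neuralign` implements a neural-alignment analysis for multi-subject
sensor-array recordings (MEG-style): MAXVAR multiset canonical correlation
analysis (MCCA) as a spatial filter, cross-validated intersubject
correlation (ISC) of the resulting canonical components, a circular-shift
bootstrap null, and a paired pre/post contrast layer. Because such studies
rarely deposit raw recordings, the package ships a synthetic-data generator
with known ground truth; every stage is testable end to end without any
download.

## The model

Each subject m contributes a data matrix Z^m (D x t: channels or PCA
dimensions by time samples). MCCA finds per-subject weight matrices W^m so
that the canonical variates

    Y^m = W^m Z^m

are mutually uncorrelated within a subject and maximally correlated across
subjects. We use the MAXVAR cost: at each stage, the direction (one row of
each W^m jointly) that maximizes the variance explained by a single common
component across all whitened datasets.

### Solver

1. Each subject's training data is centered and whitened via its SVD, with
   directions whose eigenvalue falls below 1e-10 of the largest dropped
   (deterministic, no other regularization).
2. The stage-wise solution: take the top eigenvector of the Gram matrix of
   the row-concatenated whitened data; its per-subject blocks (normalized)
   are the stage's filters in whitened coordinates.
3. Deflation: each subject's block direction is projected out of its rows
   of the Gram matrix before the next stage. This enforces *exact*
   within-subject decorrelation of training variates at every stage, which
   a one-shot joint SVD does not for M > 2 (its eigenvector blocks are
   orthonormal only across the whole stack). For M = 2 the stagewise and
   joint solutions coincide, and both reduce to classic two-set CCA — the
   correctness anchor used in the tests (independent generalized
   eigenvalue oracle, agreement to 1e-6).

Sign convention: each component's sign per subject is chosen so its
training variate correlates non-negatively with the across-subject mean
variate, with a deterministic global sign (largest-magnitude sample of the
mean variate positive). Downstream statistics use absolute values, so the
convention only stabilizes serialization and plots.

### Activation patterns

Spatial-filter weights are not physiologically interpretable; the forward
model A = Sigma_z W' Sigma_y is. `activation_pattern` computes one
component's column using only that component's variance (the
cross-component covariance vanishes on training data by construction, and
this stays defined when the full variate covariance is singular), with
optional back-projection through the subject's PCA loadings to the original
sensor space. In single-source simulations the pattern recovers the
ground-truth mixing vector (|cosine| > 0.95 at alignment strength 2) and is
equivariant under invertible re-mixing of a subject's sensors.

## The alignment statistic

For one condition cell (one group x session x stimulus-version x condition):

1. Split the t samples into k = 3 contiguous folds (sizes differ by at most
   one sample).
2. Per fold: fit per-subject PCA on the training samples only (no
   train/test leakage), fit MAXVAR on the training samples, project the
   held-out fold.
3. Compute all M(M-1)/2 pairwise Pearson correlations of each component's
   held-out variates, pool with Fisher's z (|r| clipped to 1 - 1e-12
   before arctanh), and select the component with the strongest pooled
   |z̄| (ties: lowest index).
4. Combine folds by the mean of absolute pooled values. Per-subject values
   (a subject's mean Fisher z with all others, combined the same way) feed
   the contrast layer.

Constant held-out variates make a pair's correlation undefined; such pairs
are excluded from pooling with a logged count.

### Circular-shift bootstrap

Each draw circularly shifts every subject's held-out variates (all
components together, one independent uniform lag in [1, t_fold - 1] per
subject per fold) and recomputes the full fold statistic *including the
top-component selection*, then combines folds exactly as the observed
statistic. Re-selecting per draw matters: the observed statistic is a
maximum over components, and a null that shifts only the selected
component is anti-conservative. The p-value uses the add-one rule
(1 + #{null >= observed}) / (1 + n_shuffles), one-sided, since the
mean-absolute statistic has a folded null. The implementation is exact and
fast: the correlation of circularly shifted standardized series is their
FFT circular cross-correlation at the lag difference (verified against a
brute-force roll-and-correlate oracle to machine precision).

The null shifts fitted variates and does not refit MCCA per draw; refitting
5,000 times per cell is not practical, and shifting the raw segment before
projecting is algebraically identical to shifting the variate. Two
consequences, both verified by simulation and documented here on purpose:

- The per-fold test is exactly calibrated for models whose dimensionality
  is modest relative to the training data. Fitting *full-rank* models at
  small scale leaves cross-fold dependence (each fold's test segment is the
  other folds' training data) that independent per-fold shifts do not
  capture, inflating the combined test's type-I error to ~0.066 at
  alpha = 0.05. The emulated pipeline reduces 248 channels to 50 PCA
  dimensions against ~24,000 training samples per fold (complexity ratio
  D/t ≈ 0.002); desk-scale runs in this package mirror that ratio (e.g. 8
  channels, PCA to 4, 2,000 training samples per fold), where the measured
  type-I error is 0.047-0.055 over 1,000 simulated no-signal cells and
  p-values are uniform (KS).
- The null scales with the marginal autocorrelation of the variates —
  that is its purpose — so nulls of cells with different spectra are not
  comparable, and for strongly aligned cells with autocorrelated shared
  signals the shared signal's autocorrelation leaks into shifted
  cross-correlations, making the null conservative there (measured 40-60%
  null-mean excess). The invariant "shifting destroys alignment, not
  marginal structure" holds exactly for spectrally white shared signals
  (null means agree within 10% between aligned and non-aligned cells).

### Multiple comparisons

Benjamini-Hochberg step-up adjustment (via statsmodels) across all cells
analysed in one run.

## The contrast layer

Within-group pre/post tests are paired: a one-sample t-test on post-minus-
pre per-subject ISC with df = n - 1, with Cohen's d = t / sqrt(n) for the
within-subject design. Subjects' values are averaged over the two
counterbalanced stimulus versions before pairing. Between-group
comparisons of MCCA values are deliberately not offered — values from
different MCCA models are not comparable — and only summary-score Welch
tests (with pooled-SD Cohen's d) exist for questionnaire-style measures.
The sensitivity power analysis inverts the noncentral-t power function of
the paired design (Brent root-finding, tolerance 1e-6): at n = 37,
two-sided alpha 0.05 and 80% power the minimal detectable d is 0.47.

## The synthetic-data generator

A study is a full factorial of 2 groups x 2 sessions x 2 stimulus versions
x 4 narrative conditions (political/nonpolitical x congruent/incongruent).
Each stimulus cell (session, version, condition) has one latent signal —
Gaussian white noise band-passed to 0.5-10 Hz by the same zero-phase FIR
used in preprocessing, standardized, edge-padded during generation so the
returned series carries no filter transients. Every subject receives that
latent through a fixed per-subject mixing vector (standard normal gains,
constant across sessions and versions) scaled by the cell's alignment
strength, plus unit-variance white sensor noise. A channel with gain g at
strength s then correlates across subjects at (gs)^2 / ((gs)^2 + 1), the
closed form the tests verify.

Parameters (defaults = the emulated study's conditions):

- `n_subjects_per_group`: {intervention: 37, control: 42} — the analysed
  cohort sizes.
- `n_channels` 248, `duration_s` 90, `fs` 400 Hz, `band` (0.5, 10) Hz.
- `base_snr` 0.5: shared-signal-to-noise amplitude ratio in a unit-gain
  channel, giving pairwise channel correlations ~0.2 — the order of
  magnitude of reported sensor-level ISC values in this literature.
- `delta_post` 0.5: the alignment increment applied *only* to
  intervention-group political cells in the post session — the ground-truth
  intervention effect.
- `snr_jitter` 0.2: log-normal SD of a per-recording multiplicative jitter
  on alignment strength, modelling session-to-session variation in a
  subject's engagement. Without it all subjects are statistically
  exchangeable and the between-subject variance of ISC values collapses to
  shared cell-level noise, which no real cohort shows; 0.2 makes the
  subject-level variance dominate (chosen once from the measured shared-
  noise scale, ~0.003 in Fisher-z units, against the jitter's ~0.067).
- `seed`: one master seed; latents, mixing vectors and noise draw from
  separate `SeedSequence` spawn-key streams ((0, cell), (1, group,
  subject), (2, cell, group, subject)), so any subset of the study
  regenerates bit-identically.

Bad-segment masks place up to three non-overlapping intervals per recording
totalling a requested fraction of samples; `zero_pad` zeroes them in place,
preserving length, which is what keeps multi-subject matrices
length-matched for MCCA. Studies round-trip through an HDF5 container (one
dataset per recording, ground truth and rates as attributes/datasets).

What the generator does *not* emulate: realistic head geometry or forward
physics, 1/f or spatially correlated sensor noise, eye-blink/cardiac
artifacts, sensor dropout, or per-sentence latent structure (one latent per
1.5-minute condition, matching how the analysis treats the concatenated
series). Passing tests therefore demonstrate the statistical machinery, not
robustness to physiological artifact structure.

## Preprocessing

Zero-phase band-pass filtering: Hamming-window FIR designed from the band
edges and a 0.5 Hz transition width, applied forward-backward (`filtfilt`),
giving ~1 pass-band gain, zero lag and > 100 dB effective stop-band
attenuation. Resampling uses polyphase filtering with the rational rate
ratio (e.g. 1,017 Hz acquisition to the 400 Hz analysis rate); output
length is round(n · fs_out/fs_in); upsampling is refused. PCA is
covariance-based on mean-centered channels (scikit-learn, full SVD solver),
with the requested dimension truncated to the numerical rank under a
logged warning. Padded-then-filtered samples are kept in subsequent
correlations rather than re-zeroed; with zero-phase FIR filtering the
spread into padded regions is symmetric and the choice is documented here.

## Desk-scale problem sizes

Tests and simulations use sizes chosen to mirror the full analysis's
complexity ratios rather than its absolute dimensions: condition cells of
8-20 subjects, 8-16 channels, 3,000-36,000 samples at 100-400 Hz, PCA to
4-8 dimensions, 200-2,000 bootstrap draws. The calibration study (1,000
no-signal cells) and the intervention-recovery study (20 seeds x 32 cells,
M = 12/group) regenerate from fixed seeds at run time; nothing is stored.

## Known limitations

- **Naive paired t on ISC values is overdispersed under the null.**
  Per-subject ISC values are pairwise-coupled: every pair's correlation
  noise is shared by its two members, and any subject-level variability
  (engagement jitter) couples all of that subject's pairs. The paired
  differences therefore have exchangeable positive correlation
  (rho between 1/(M-1) and ~0.25), and Var(t) ≈ (1 + (M-1)rho)/(1 - rho)
  ≈ 2-5 instead of ~1. Measured: sd(t) = 2.2-2.5 across 80 simulated null
  contrasts; ~30% of null rows reach FDR-adjusted significance at the
  nominal 0.05 across 20 simulated studies. This is a property of the
  analysis design itself (the same construction applied to real data
  carries it), not of the simulation; the contrast table is therefore best
  read as ranking effects — the true intervention rows exceed null rows by
  an order of magnitude in t — rather than as providing exact false-positive
  control. A mixed-effects or subject-level permutation scheme would fix
  it, but is outside this package's scope.
- The circular-shift null is conservative for strongly aligned cells with
  autocorrelated shared signals (see above) and assumes approximate
  circular stationarity of the variates.
- The MCCA null does not refit per draw; model dimensionality should stay
  modest relative to training samples (D/t of order 0.002, as in the
  emulated pipeline) for calibrated p-values.
- `fit_maxvar` stores training variates by default for the projection
  round-trip contract; disable `store_variates` at full scale (50
  components x 36,000 samples x 40 subjects is ~0.5 GB).
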