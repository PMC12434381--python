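# Methods

## The prediction framework

The package evaluates how well nine resting-state fMRI feature subtypes
predict behavioral targets, and how that performance scales with sample
size and scan time. The unit of analysis is one (feature, target, model)
triple evaluated over 10 random family-respecting train/test partitions.

**Splits.** Families must never straddle the train/test boundary (siblings
share genetics and environment; splitting them inflates test performance).
Partitions are built by shuffling whole families and filling the test set
until it reaches `test_fraction` (default 0.15) of the cohort, so test
sizes vary with family granularity. Three deterministic inner folds on the
training set select hyperparameters (contiguous folds for regression,
label-stratified round-robin for classification); the winner by mean inner
score (first in grid order on ties) is refit on the full training set and
scored once on the test set. Feature standardization statistics come from
training data only; this is re-derived inside every inner fold as well.

**Models.** Elastic net (`alpha` ∈ 10^{−3..3}, 7 points; `l1_ratio` ∈
{0.1, 0.5, 0.9}), linear kernel ridge (`alpha` ∈ 10^{−3..3}), elastic-net
logistic classifier (same grid shape over `C`), and linear SVM (`C` ∈
10^{−2..2}). Grids are deliberately small and configurable; the inner CV
loop is implemented directly (not via a meta-estimator) so that the
selected hyperparameters and scaler statistics are observable — the
leakage tests mutate test data and assert both are unchanged. Continuous
targets are scored with R² = 1 − SS_res/SS_tot (which may be negative);
sex with accuracy.

**Significance.** For each split the target vector is freely reshuffled
over the whole cohort `n_permutations` times (default 100) and the
identical pipeline refit, giving `splits × permutations` (default 1000)
null scores. A feature counts as predictive iff the mean real score
strictly exceeds the null's 95th percentile; the reported p-value is the
+1-smoothed fraction of null scores at or above the mean real score.

A property of this rule worth knowing: the real statistic is a *mean over
splits* while the null is a distribution of *individual* split scores, so
unless split scores are almost perfectly correlated the rule is
conservative. In the package's own Monte-Carlo (independent targets,
reduced cohort sizes, several feature dimensionalities) it fired in 0 of
100 runs — its empirical false-positive rate is well below the nominal
5 %. It never inflates significance; detected effects are if anything
understated.

**Scaling.** The pipeline is repeated over training-set fractions
{0.2, 0.4, 0.6, 0.8, 1.0} and session amounts {0.25, 0.5, 1, 2, 4}.
Training subsets are family-respecting and *nested* across fractions
(prefix of a per-split family shuffle) to reduce Monte-Carlo noise in the
curves; test sets are identical across fractions within a split. Scan-time
truncation always keeps a prefix of frames starting at the beginning of
session one, applied to *preprocessed* (post-discard) frames; a quarter
session corresponds to 3.6 min (1200 frames × 0.72 s TR per session =
14.4 min), four sessions to 57.6 min. Features are recomputed per cell;
for GSP features the consensus connectome is additionally recomputed from
each cell's training subjects.

## Preprocessing

Parcel-level denoising only (the input is already region × frame): drop
the first 6 frames of each session (scanner drift), regress an OLS design
of intercept + 6 motion regressors + their backward-difference derivatives
(first element 0) + linear trend, then high-pass filter at 0.01 Hz with a
zero-phase order-2 Butterworth applied forward-backward (order-4 magnitude
response). Zero-phase filtering avoids the phase distortion that would
corrupt successive-difference statistics (MSSD). Detrending is folded into
the confound design rather than run separately; the filter family/order is
a package choice since only the cutoff is externally specified. Note that
effective mean removal by a 0.01 Hz high-pass requires records long
relative to the 100 s cutoff period; very short test sessions retain edge
transients.

## Connectome harmonics

The consensus SC is `mask ⊙ mean(subject SCs)` where the mask keeps edges
ranked by across-subject occurrence (ties: mean weight, then edge index)
down to a target edge density (default: the mean subject density).
Occurrence ranking stands in for distance-binned consensus thresholding,
which would need fiber-length data the package does not model; the
strategy is isolated behind `consensus_mask` so a distance-binned variant
can be added. The *symmetric* normalized Laplacian is used (rather than
the random-walk variant) because its eigenvectors are orthonormal, which
Parseval-based identities and the GFT round trip require. Eigenvector
signs are fixed (largest-magnitude entry positive) so graph Fourier
coefficients reproduce across runs and platforms.

Graph PSD is defined as the ℓ2 norm over time of each graph coefficient
series, so Σ_k PSD_k² equals total signal energy — the identity the test
suite leans on. The coupled/decoupled cutoff is ⌊R/2⌋ (low band keeps
harmonic indices [0, ⌊R/2⌋)). SDI is reported untransformed (no log).
Sessions are concatenated along time after per-session preprocessing,
treating scan time as cumulative frames.

fALFF uses the amplitude (not power) spectrum of a plain untapered
periodogram; the 0.01–0.08 Hz band is endpoint-inclusive and DC is
excluded from the denominator. Beware spectral leakage when validating
with sinusoids: only coherently sampled frequencies give ratios near 0/1.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes,
with known ground truth:

* **SC**: one base weighted stochastic-block-model-like graph
  (within-community edge probability 0.8, weight scale 1.0; between 0.15 /
  0.4; lognormal weights). Subjects get multiplicative lognormal jitter
  (σ = 0.2) plus 2 % edge deletion/addition, making consensus construction
  nontrivial. Isolated nodes are reconnected.
* **BOLD**: per subject, x(t) = U diag(e^{−γλ}) w(t) · s + ε(t) on the
  subject's *own* harmonics, with white w and ε, decay γ = 2 (so ≥ 90 % of
  graph-spectral energy sits in the lower half of harmonics), s chosen for
  unit average per-region signal variance, and noise SD 0.5. A small
  multiple (0.1) of the summed motion regressors leaks into the signal so
  confound regression has something to remove.
* **Targets**: each continuous target is √e·z + √(1−e)·noise where z is a
  standardized projection of the subject-level ground-truth feature matrix
  (FC edges, regional SD, or low-harmonic graph PSD) onto a fixed random
  weight vector and e is the requested effect size. Defaults: cognition
  e = 0.3 on FC edges, age e = 0.3 on low-harmonic PSD (then mapped to the
  22–37 year range, mean 28.68, SD 3.71), mental health / processing
  speed / substance use e = 0 (pure noise). Sex thresholds a latent with
  e = 0.5 on regional SD. These defaults mirror which targets the
  framework is expected to recover and which not.
* **Families**: sizes 1–5 drawn from (0.40, 0.35, 0.15, 0.07, 0.03) — a
  plausible young-adult-twin-study mix, configurable, not a claim about
  any real cohort. **Confounds**: six smoothed random walks per session.

What it does *not* emulate: hemodynamics, autocorrelated BOLD spectra,
spatial smoothness of parcels, site/scanner effects, heritable targets
(family structure is independent of targets), non-linear brain-behavior
relationships. Passing tests therefore demonstrate correctness of the
machinery and recoverability of linear effects under the stated noise
model — not expected performance on real cohorts.

## Numerical choices

* Factor-subset partition: smallest family-respecting holdout ≥ n via
  subset-sum DP, deterministic in cohort order.
* Zero-variance guards: correlations raise on (numerically) constant
  regions; filtered-signal variance is judged against the *unfiltered*
  signal scale so a vanished band is caught (tolerance 1e−10 relative).
* All randomness flows from one master seed through BLAKE2-based child
  seeds keyed by (stage, split, permutation), so stages are reproducible
  independently and in parallel.
* Matrices are exchanged as TSV with `# rows cols` headers; floats are
  written with round-trip precision so a written cohort reloads
  bit-identically.
* Tie-breaks (consensus edges, hyperparameter candidates) are documented
  and deterministic.

## Problem sizes in tests and the acceptance script

Unit and acceptance runs use reduced cohorts chosen to exercise every code
path at desk scale: 10–40 regions, tens to hundreds of subjects, sessions
of 40–100 frames; the planted-effect recovery runs at n = 300 subjects
with 16 regions, and the type-I calibration at n = 40 with 5 splits × 40
permutations per run. The defaults in `CohortConfig` (274 regions, four
1200-frame sessions) reproduce the full-scale geometry when desired.

## Known limitations

* The significance rule's conservatism (above) means its false-positive
  rate sits below nominal for weakly correlated split scores.
* Consensus thresholding ignores fiber length; see above.
* The exact algebraic reading of the graph PSD, the session-combination
  rule (concatenate vs average), and whether SDI should be
  log-transformed are open choices; the package picks the variants stated
  here and exposes them at module boundaries.
* Inner folds do not enforce family grouping (outer splits do); with the
  default family sizes the residual optimism affects only hyperparameter
  selection, not test scores.
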