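# Methods

## Signal model and feature space

Epochs are 768 voltage samples at 512 Hz spanning −500…1000 ms around
stimulus onset. The time-frequency decomposition convolves each epoch with
complex Morlet wavelets at the 146 integer center frequencies 4…149 Hz
(one 1-Hz row each; the printed row count fixes the half-open reading of
the 4–150 Hz range). The wavelet at f₀ has σ_t = n_cycles/(2π f₀) and
σ_f = 1/(2π σ_t), with n_cycles stepping 3/4/5/6 at the theta/alpha/beta/
gamma band edges (8→9, 14→15, 30→31 Hz; no interpolation). Wavelets are
unit-energy normalized — only post/baseline ratios are used downstream, so
the energy convention cancels — and carry the standard admissibility
(zero-mean) correction: without it a DC offset leaks visibly into the
3-cycle theta rows. Epochs are reflection-padded by the widest wavelet's
half-support before convolution and cropped after, and the −500…−100 ms
baseline leaves a 400 ms guard before onset.

Each frequency row is divided by its own mean baseline power and averaged
over 48 contiguous 16-sample bins (31.25 ms), giving the 146 × 48 feature
matrix (7008 features, row-major flattening).

**Known bias.** Per-epoch baseline normalization divides by a mean over
~400 ms; under the wide theta wavelets that window holds only ~2
independent power samples, so E[post/baseline] is biased upward at the
lowest rows (grand mean ≈ 1.8 at 4 Hz, ≈ 1.1 at 20 Hz, ≈ 1.0 above
~50 Hz for stationary noise). The bias is label-independent and therefore
harmless to decoding and to the paired responsiveness test, but absolute
ratio values at low frequencies should not be read as calibrated effect
sizes. Tests of the "noise ratio ≈ 1" property are restricted to rows
≥ 15 Hz for this reason.

## Responsiveness screen

Per frequency row, the matched pairs are one trial's mean post-stimulus
(0…1000 ms) power versus the same trial's mean baseline power (raw, not
normalized). Wilcoxon signed-rank p-values (ties → p = 1) are
Benjamini–Hochberg adjusted across the 146 rows; a probe is responsive
with ≥ 2 rows at adjusted p ≤ 0.005. The per-trial pairing is the only
reading of "average post-stimulus vs baseline power" that yields a
matched-pairs test. Note the screen averages over *all* trials: a
modulation confined to one of the eight categories (1/8 of trials) is
strongly diluted, so single-category synthetic probes — especially
suppressions — can be decodable yet fail the screen. The recovery
experiments therefore exercise decode→attribute→cluster directly, and the
screen's type-I behaviour is tested separately on null probes.

## Decoding protocol

Each probe is an independent dataset (balanced 8 × n trials × 7008
features). The forest uses Gini splits, bootstrap per tree, sqrt-feature
subsampling, unlimited depth (the reference implementation's defaults) and
3000 trees at full scale. Cross-validation is stratified 5-fold
(stratification is the only way folds preserve per-class balance);
out-of-fold predictions are pooled so every trial is predicted once, and
per-class F1 is computed on the pooled predictions, with the fold-wise F1
standard deviation retained as a noise estimate. Per-probe RNG seeds
derive from the master seed by hashing the probe id (sha256, mod 2³¹), so
results are reproducible and independent of probe iteration order.

A probe is predictive of a category when its F1 strictly exceeds the
threshold (default 0.390278, the full-scale 99.999th percentile of
per-class F1 under label permutation). `permutation_threshold` re-estimates
the threshold at any scale, pooling all per-class F1 values across
permutations and probes; scaled runs (fewer permutations, lower
percentile) are labeled as such by their returned pool.

**Measured null behaviour (synthetic).** On pure-noise probes run through
the full TF pipeline (400 trials, 200 trees, stratified 5-fold CV), the
pooled per-class F1 null is mean ≈ 0.125, sd ≈ 0.05, 99.9th percentile
≈ 0.27. The full-scale reference threshold 0.390278 sits ≈ 4.3 sd above
the null mean — conservative for these clean synthetic nulls, whose tail
is thinner than a heterogeneous real-electrode permutation pool. The
acceptance check of the threshold bracket is retained at its stated band
and documents this gap rather than rescaling it.

Band-restricted decoding repeats the identical protocol on row subsets:
low 4–50 Hz (46 rows), broadband gamma 50–150 Hz (100 rows), full
spectrum (146 rows). Group comparisons of per-probe F1 use two-sided
Mann–Whitney U with Bonferroni correction over the three pairs.

## Importance attribution

Node importance is the sample-fraction-weighted impurity reduction
I = f_p G_p − f_l G_l − f_r G_r (the unweighted difference of Gini values
can be negative for valid splits; the weighted form is the impurity
*reduction* and is nonnegative by concavity). Global importance sums node
importances per split feature, normalizes per tree, averages over trees
and renormalizes to sum 1. Category-specific importance assigns each leaf
to its majority training class, walks each category leaf back to the
root, and credits every split node on the path with its full node
importance (once per node per leaf-path; repeated features accumulate).
This keeps the union of the eight category supports identical to the
global support. Per-probe maps are normalized to sum 1 before cross-probe
averaging so high-importance probes do not dominate group means.

Map contrasts fit a normal distribution to the cell-wise difference of two
maps and flag cells beyond μ + kσ (default k = 4, chosen to tolerate about
one false positive among 7008 cells; the symmetric lower tail is computed
but reported separately). Group contrasts z-score each group's mean map
against its own cells; cells with z ≥ 2 in both groups are
"both-important", and dominance (difference beyond 4σ) overlays that
layer.

Importance concentration properties depend on the split-event budget: with
sqrt-feature subsampling a sole informative feature among 7008 collects
only a few percent of total importance (deep noise splits dilute it), and
null-importance maps only smooth out (max cell < 5× mean) once each
feature receives enough split events (≈ 400 trees at 400 trials). The
tests exercise these properties in the regimes where they are
well-defined: max_features=None for the single-feature attribution check,
400 trees for the null-spread check.

## Masking and clustering

A signature mask keeps cells with importance > μ + σ of the source map
(category-level mean map by default; a per-probe mode unions per-probe
masks). Masked activity vectors keep the baseline-ratio values of retained
cells only (dropped cells are excluded, not zero-filled) and are shifted
by −1 so increases are positive and suppressions negative — cosine
distance on raw all-positive ratios could never place increase and
decrease patterns at large angles. Probes whose centered vector is
all-zero are excluded and logged. Complete-linkage agglomeration under
cosine distance (d ∈ [0, 2]) is cut at a configurable distance (default
0.7); clusters are renumbered by decreasing size with ties broken by
lowest member probe id (a deterministic stand-in for the original
manual inspection), and the four most populated clusters are summarized
(member count, mean member F1 for the category, polypredictive fraction,
mean pattern).

## Synthetic cohort generator

The generator is a statistical stand-in, not a biophysical model; real
recordings of this kind are restricted patient data. Per trial each
contact receives private 1/f^α noise (α = 1 by default, unit RMS), a
shaft-shared component (amplitude 0.5) so bipolar derivation has a
measurable effect, optional ongoing rhythms (fixed frequency ± 0.5 Hz
trial jitter, random phase, whole-epoch duration — present equally in
baseline and post-stimulus windows, hence invisible to the responsiveness
screen), and the signatures matching the trial's category.

Signatures specify a (frequency band × time window) rectangle, a gain and
a category (`None` = all categories, producing responsive-but-
nonpredictive probes). Increases add independent band-limited noise whose
spectrum follows the trace's own smoothed spectral shape; suppressions
attenuate the trace's own band-passed component (multiplicative, as in
physiological desynchronization — suppression requires pre-existing band
power, so decrease probes are given an ongoing rhythm in the band).
Envelopes use 25 ms raised-cosine ramps against spectral splatter. Implant
amplitudes are pre-compensated for the analysis wavelets' band-edge
dilution (the PSD-weighted in-band capture κ of each row's Gaussian
window) and for the envelope, so the *binned ratio* in the rectangle lands
at the requested gain in expectation; the deepest reachable suppression is
bounded by band-edge leakage (full removal of the band component leaves
the out-of-band power a row's wavelet still collects). Per-trial gains
jitter lognormally (log-sd 0.25 by default, chosen so a gain-3 signature
probe lands at F1 ≈ 0.7 — decodable but noisy, in the intended 0.4–0.8
band straddling the predictivity threshold).

The manifest classifies each probe from its specification: no signatures →
non-responsive; signatures shared identically by all eight categories →
responsive-only; otherwise mono-/polypredictive by the count of categories
with non-shared signatures.

What the generator does *not* emulate: non-stationary noise, cross-trial
adaptation, latency jitter of responses, correlated noise across shafts,
artifacts other than amplitude outliers, volume conduction beyond the
shared-shaft term. Passing recovery tests therefore demonstrates the
pipeline's correctness on its stated feature model, not clinical
performance on patient data.

## Study conditions used by the acceptance checks

Scales are the package's desk-scale study conditions, fixed before the
checks were run and documented here:

- Chance level: 10⁵ simulated uniform predictions on balanced labels.
- Permutation threshold: 2 null probes through the full TF pipeline,
  12 permuted-label 5-fold CV runs at 200 trees (pool of 96 per-class F1
  values), 99.9th percentile, compared against 0.390278 ± 0.08.
- Oracle equivalence: depth-≤3 forests vs brute-force path enumeration
  from the training data; 6-vector complete-linkage vs exhaustive
  agglomeration.
- Parameter recovery: 10 gamma-increase (61–90 Hz, 100–400 ms, ×3) and
  10 alpha-decrease (9–14 Hz, 200–700 ms, ÷3, over an ongoing 11 Hz
  rhythm) face probes plus 4 pure-noise probes; 50 trials/category,
  300 trees, fixed seed; thresholds: ≥ 90 % signature recovery, ≥ 95 %
  noise specificity, ≥ 60 % top-decile importance mass inside the ±4 Hz /
  ±2 bin dilated implant rectangle, family separation ARI ≥ 0.8.
- Type-I control: 500 pure-noise probes of 24 trials; flagged fraction
  compared against 2 × 0.005.

## Numerical choices and degenerate inputs

- Artifact rejection uses a single-pass σ over all of a probe's epochs; it
  is idempotent and never re-estimated after exclusion. All-epochs-excluded
  probes are flagged unusable and skipped downstream.
- Bipolar pairing is adjacent-contact with anode at the lower contact
  index; a derivation inherits the MNI midpoint of its pair. Contacts with
  unequal retained-trial bases are skipped with a warning.
- Zero baseline power raises an error naming the frequency row; all-tied
  Wilcoxon rows get p = 1; forests without splits yield zero importance
  maps with a warning; a category never predicted by any leaf yields a
  zero category map with a warning; empty masks exclude the probe from
  clustering; σ = 0 difference fields yield empty contrast masks.
- Functional-area boxes use closed intervals (as printed); the left FFA
  box is nested inside the left VWFA box, so points there belong to both.
  Finer anatomical labelling is a pluggable lookup defaulting to
  "unmapped" (no atlas is bundled).

## Limitations

- The permutation-threshold bracket against the full-scale value is not
  reachable from clean synthetic nulls (see Decoding protocol); the check
  documents the gap.
- Cohort-level counts of the original study (predictive-probe totals,
  per-area counts) depend on the restricted recordings and are out of
  scope.
- The low-frequency ratio bias above is inherent to per-epoch baseline
  normalization with 3-cycle wavelets.
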