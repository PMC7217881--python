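# spectrosig

Decoding perceptual categories from intracranial field potentials and
extracting the spectrotemporal signatures that carry the information.

## The problem

Depth electrodes implanted for epilepsy monitoring record local field
potentials (LFPs) while a patient views images from eight categories
(houses, faces, animals, scenes, tools, pseudowords, characters, scrambled
controls). Which recording sites carry category information, in which
frequency bands and at which latencies? `spectrosig` implements an
interpretable decoding pipeline that answers this per probe:

1. **Preprocessing** — linear detrend, exclusion of epochs containing
   values ≥ 10 σ (σ computed per probe over all its epochs), bipolar
   re-referencing along each electrode shaft.
2. **Time-frequency features** — complex Morlet decomposition (cycle count
   f₀/σ_f = 3 in theta 4–8 Hz, 4 in alpha 9–14 Hz, 5 in beta 15–30 Hz, 6 in
   both gamma ranges 31–150 Hz), per-frequency baseline normalization
   (−500…−100 ms window) and averaging into 48 bins of 31.25 ms: each
   epoch becomes a 146 × 48 matrix of power modulation ratios
   (P(t, f₀) = |w(t, f₀) · s(t)|²).
3. **Responsiveness screen** — per frequency, a Wilcoxon signed-rank test
   of per-trial post-stimulus vs baseline power, Benjamini–Hochberg
   corrected; a probe passes with ≥ 2 frequencies at adjusted p ≤ 0.005.
4. **Decoding** — per probe, a random forest (Gini splits, 3000 trees by
   default) under stratified 5-fold cross-validation; out-of-fold
   predictions are pooled and per-class F1 = 2·precision·recall /
   (precision + recall) is computed. A probe is *predictive* of a category
   when F1 exceeds the permutation-derived threshold 0.390278 (99.999th
   percentile of per-class F1 under label permutation); probes predictive
   of one category are *monopredictive*, of several *polypredictive*.
5. **Importance attribution** — global feature importance as the
   sample-weighted Gini impurity reduction G = Σᵢ pᵢ(1 − pᵢ) summed over
   split nodes, and *category-specific* maps obtained by tracing every
   leaf of a category back to the root and crediting the split nodes on
   the path. Maps are compared with Gaussian-fit difference masks
   (μ + 4σ, tolerating ~1 false positive among the 7008 cells).
6. **Signature clustering** — per category, probe activity is masked by
   the importance map (cells > μ + σ), centered (ratio − 1), and clustered
   with complete-linkage agglomeration under cosine distance
   d(u, v) = 1 − u·v/(‖u‖‖v‖), so power increases and decreases separate
   into distinct activity families.

Patient recordings are restricted, so the package ships a **synthetic-LFP
generator** producing cohorts with known ground truth: 1/f^α background,
shaft-shared noise, ongoing rhythms, and band-limited power
increases/suppressions implanted per category with calibrated gain. Every
downstream stage is validated against the generator's manifest.

## Worked example

```python
import numpy as np
from spectrosig import (SignatureSpec, ProbeSpec, generate_cohort,
                        PipelineConfig, run_pipeline)

burst = SignatureSpec(61, 90, 100, 400, 3.0, "face")   # gamma up, faces
cohort = generate_cohort(
    [ProbeSpec("P0"), ProbeSpec("P1", signatures=[burst])],
    trials_per_category=50, seed=0,
)
cfg = PipelineConfig(seed=0, n_trees=300, bipolar=False)
result = run_pipeline(cfg, cohort)
print(result.counts)
row = result.decoding.set_index("probe_id").loc["P1"]
print(f"face F1 = {row['f1_face']:.3f}  status = {row['status']}")
```

prints (seed 0):

```
{'n_probes': 2, 'n_responsive': 1, 'responsive_fraction': 0.5,
 'n_predictive': 1, 'n_monopredictive': 1, 'n_polypredictive': 0}
face F1 = 0.740  status = monopredictive
```

The pure-noise probe fails the responsiveness screen; the implanted probe
decodes faces at F1 ≈ 0.73, far above both the chance level 0.125 and the
0.390278 predictivity threshold, and is classified monopredictive — its
gamma-band importance map localizes to the implanted 61–90 Hz × 100–400 ms
rectangle.

A command-line interface wraps the same stages:

```bash
spectrosig simulate --out cohort.h5 --trials 50 --seed 0
spectrosig run --cohort cohort.h5 --trees 300 --seed 0 --outdir results/
```

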