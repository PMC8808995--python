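# Methods

This note documents the models, parameter choices and numerical decisions
behind gliaplex, and what the synthetic cohorts do and do not establish about
real cyclic multiplex IHC data.

## Data model of the synthetic cohorts

The generator emulates the structure the analysis assumes about per-cell
marker intensities in human cortical tissue:

* **Log-normal intensities.** For cell *i* of subject *s* in state *k*, the
  measured MGI of marker *m* is exp(µ_{km} + b_s + ε), ε ~ N(0, σ_m),
  b_s ~ N(0, σ_subj). Intensity-based expression measurements are commonly
  log-normal, and the ln/z-score normalization downstream assumes as much.
  Defaults: σ_m = 0.35, σ_subj = 0.15 — enough within-state spread that
  states overlap visibly, and a within-subject intraclass correlation that
  exercises the mixed-model stage.
* **State signatures.** ln-mean matrices encode the qualitative signatures of
  the three states: reactive astrocytes high GFAP/YKL-40 (+1.3 ln units over
  homeostatic), modest VIM/TSPO/EAAT1, reduced GS; intermediate astrocytes
  high EAAT2 (+1.0), modest GS, mid GFAP/YKL-40; reactive microglia elevated
  in all five markers; intermediate microglia elevated FTL/TMEM119 with mid
  CD68. Constitutive channels (ALDH1L1, IBA1) are state-independent.
* **Diagnosis-dependent composition.** State proportions default to the
  published CTRL (49.5/33.1/17.5)% and AD (19.6/36.2/44.2)% vectors. These
  printed percentages sum to 100.1%; the validator tolerates 0.5% rounding
  and renormalizes at sampling time. An optional `diagnosis_shift` adds a
  direct AD elevation per marker (used with YKL-40 +0.15, TSPO +0.10 ln
  units in the classifier benchmarks, mirroring the per-marker AD effects
  seen in tissue beyond composition changes).
* **Scene geometry.** One field per (subject, cortical layer II–VI); square
  fields of 512 px at 0.5 µm/px. Plaques are disks with Poisson counts at
  25/mm² and areas uniform on 80–500 µm²; NFTs are points at 15/mm². Cells
  are placed uniformly except that reactive (×bias) and intermediate
  (×√bias) cells have their placement odds multiplied within 50 µm of a
  plaque edge (default bias 4), giving the monotone homeostatic <
  intermediate < reactive proximity ordering. Non-overlap is enforced by
  rejection sampling (14 µm minimum separation, 100 retries, then placed
  with a warning — manually boxed profiles may abut in real data too).
* **Rendering.** Astrocyte somata are ellipses (3.5–5.5 µm semi-axes),
  microglia a small soma plus 3–5 dilated line processes; within-mask pixel
  values equal the cell's MGI exactly, so a render with zero background and
  noise is lossless by construction. Background is baseline 100 plus a
  low-frequency field (Gaussian-filtered noise, σ = field/2, amplitude 40)
  — drifting on scales comparable to the whole field, the regime the
  200 px rolling ball is designed to remove — plus N(0, 3) pixel noise.
  Written TIFFs are 16-bit; in-memory stacks stay float.

**What passing tests show.** Recovery, clustering and classification results
on these cohorts validate the *pipeline machinery* — they do not establish
that real glial states are log-normal, three in number, or separable at these
distances. Real data add segmentation errors from crowded neuropil,
cross-cycle misalignment, autofluorescence and antibody variability that the
generator deliberately omits.

## Imaging

* **Background.** ImageJ-style rolling-ball subtraction. The structuring
  surface is a sliding paraboloid z = d²/(2r) with curvature radius r
  (default 200 px): scale-free in intensity, it follows any background whose
  curvature radius exceeds r while penetrating a cell-sized object of width
  w by only (w/2)²/(2r) (< 0.3 gray levels for a 20 px cell). A 3×3 mean
  pre-filter stops the surface from riding pixel-noise minima. For r > 32
  the background is estimated on an r/32-downsampled image (curvature
  rescaled by the square of the shrink factor) and re-expanded bilinearly,
  clipped from above by the image. A radius exceeding both image dimensions
  degrades to subtracting the global minimum, with a warning.
* **Segmentation.** Otsu's threshold per ROI crop over a 256-bin histogram
  of the crop's range, computed on the class's segmentation channel only
  (ALDH1L1 / IBA1 / Aβ / PHF1): profiles are defined by their constitutive
  marker, so that channel is the defensible driver. Tied maxima of the
  between-class variance — a plateau of empty bins between well-separated
  modes — resolve to the plateau average. All above-threshold pixels in the
  box are kept (no connected-component filtering): tightly drawn boxes are
  themselves the instance separator. Constant crops are flagged and
  excluded with a count, not an exception.
* **Measurement.** MGI is the arithmetic mean of background-subtracted pixel
  values under the mask; TSPO is measured in both cell types. Coordinates
  are 0-based pixels with half-open boxes; physical units µm = px ×
  pixel_size; centroids reported in µm within the field.

## Normalization and space

z-scores use the sample sd (ddof = 1), pooled across subjects and diagnoses
within a cell type — any within-subject or within-diagnosis stratum would
erase exactly the between-group differences the comparisons measure.
Non-positive MGIs get a one-gray-level offset before ln (16-bit scale, so
distortion is negligible); the count is logged. Plaque-edge distances clamp
at zero for centroids inside a plaque, and are computed within a field only:
lesions in neighboring crops are invisible, a known limitation shared with
per-crop coordinate systems. Proximity histograms normalize by the total
profile count of the selection, so proportions sum to 1 over (bin × state).

## State discovery

The affinity follows the similarity-network-fusion kernel (K = 20, µ = 0.5,
the cited tool's defaults) with **no** K-NN sparsification — K enters only
through the local scale ε. Embedding is Ng–Jordan–Weiss: symmetric
normalized Laplacian, k smallest eigenvectors, row-normalization, k-means
with 50 restarts at a fixed seed. Zero-degree nodes get a degree floor with
a warning. Cluster-count assessment:

* **Eigengap**: argmax over k of λ_{k+1} − λ_k (ascending spectrum).
* **Rotation cost**: the Procrustes misfit between the first k eigenvectors
  and the nearest rotated cluster-indicator matrix, weighted by the spectral
  ratio (1 − λ_{k+1})/(1 − λ_k). The misfit alone cannot punish
  under-clustering (dropping an indicator eigenvector merely merges
  clusters), which is why the eigen-ratio weight — small exactly when the
  indicator directions are exhausted — is part of the criterion.

The final k is the eigengap choice under `k="auto"`, with both reported and
a user override accepted: in practice the cluster count in this kind of
study is partly a human judgment over the heatmaps. Clusters are named by
ranking their mean z over the reactive panel (astrocytes: GFAP, VIM, YKL-40,
TSPO; microglia: CD68, MHC2, TSPO, FTL) — the "reactive" label always has
the highest score. Dense eigendecomposition (`scipy.linalg.eigh`, leading
subset) is exact and adequate to n ≈ 10⁴; no Nyström approximation.

## Supervised models

**GBM.** scikit-learn's `GradientBoostingClassifier` with learning rate 0.1,
minimum leaf 10, bag fraction 0.5 (the conventional values of the reference
implementation); only tree count (50–500) and depth (1–3) are tuned, by
stratified k-fold CV accuracy. Evaluation on the 20% hold-out: threshold by
exhaustive search over score midpoints maximizing accuracy; AUC as the rank
statistic; percentile bootstrap CIs over 500 test-set resamples (widened to
include the point estimate in the rare resampling corner case); NIR = the
majority-class share, compared by a one-sided exact binomial test on the
number of correct predictions. The 3-state classifier reports macro-averaged
one-vs-rest AUC. Permutation importance is the mean accuracy drop on
held-out data over ≥10 permutations per feature, max-scaled to 100, ties
broken by name; with correlated markers a redundant feature can legitimately
score near zero. Splits stratify by diagnosis by default; `group_by=
"subject"` assigns whole subjects to one side for leakage-free evaluation —
both modes exist because per-cell splitting lets subject effects leak
between train and test.

**CNN.** A four-conv network ([conv3×3 → ReLU → maxpool2 → dropout] ×3,
conv → ReLU, flatten, three hidden dense layers, softmax), implemented
directly on NumPy with explicit backprop (im2col convolutions), Adam / SGD /
RMSprop, cross-entropy loss, early stopping (patience 10, best-epoch weights
restored) and a random hyperparameter search maximizing 3-fold CV AUC, the
winner retrained on the full training set. Inputs are per-profile crops
bilinearly interpolated to 64×64 and z-scored per channel per image
(constant channels map to zeros). Desk-scale defaults — 4–16 conv channels,
n ≈ 2,000 images, ≤ 20 trials — train in minutes on one CPU core.
Gradients are verified against finite differences in the test suite.
Attribution: saliency (|∂logit/∂pixel|), integrated gradients over a zero
baseline (midpoint rule, ≥50 steps; completeness holds to quadrature error),
and Grad-CAM on the fourth conv layer's ReLU activations, bilinearly
upsampled. CNN evaluation flows through the same `evaluate_scores` as the
GBM, so thresholds/CIs/NIR are directly comparable.

## Statistics

* **Mixed models.** Random-intercept models fit by REML
  (`statsmodels.MixedLM`). Denominator df use a containment approximation:
  a between-subject factor tests against n_subjects − n_levels df (12 for
  14 subjects, two diagnoses); a within-subject factor against the residual
  df. For the balanced between-subject design this reproduces the exact
  subject-means t-test (the Wald SE matches it to four decimals), whose
  t-interval is exactly calibrated; simulation confirms ~95% CI coverage
  and type-I error near nominal. The `df_method` field flags the
  approximation in every output row.
* **Trend test.** Cochran–Armitage χ² with equally spaced scores 1..k over
  the ordinal state axis, df = 1, asymptotic p.
* **Table reconstruction.** Given grand total N, within-group percentage
  vectors p₁, p₂ and the share s of one state belonging to group 1, the
  group-1 total is C = s·p₂·N / (p₁(1−s) + s·p₂); rows are C·p₁ and
  (N−C)·p₂. Counts are returned unrounded; the trend test is run on rounded
  counts. Internal consistency: the cross-shares *not* used in the
  reconstruction are reproduced within 0.5 percentage points for both cell
  types, and the trend statistics land within 0.5% of the published values
  — the printed percentages are mutually consistent to rounding.

## Problem sizes and seeds

Benchmarks run at sizes chosen for a single CPU core: state recovery at
n ≈ 5,000 profiles (14 subjects × 358 cells) with planted states separated
by ≥2 sd on their signature markers (σ_m = 0.25, σ_subj = 0 — the planted
partition is the only structure present); classifier ordering over 10
cohorts of 2,100 cells; CI coverage over 600 simulations (Monte-Carlo SE
≈ 0.9 pp) and type-I error over 500; CNN sanity at 1,600 images. All
randomness flows from explicit integer seeds; per-simulation child streams
(`SeedSequence.spawn`) make each replicate independently reproducible.

## Known limitations

Segmentation trusts the annotation boxes — no automatic cell detection, no
DAPI-based nuclear segmentation, no connected-component instance splitting.
Distances do not cross field boundaries. The rotation-cost criterion, like
any cluster-count heuristic, can be indecisive on weakly separated data; the
package reports both heuristics rather than pretending a single rule.
Real-data deviations from log-normal intensities are untested here. The CNN
implementation favors clarity and reproducibility over speed and does not
attempt to match any particular trained model's weights.
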