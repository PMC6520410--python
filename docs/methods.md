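# Methods note

This note records the model implemented by `cortilam`, its parameters and
units, what the synthetic data generator does and does not emulate, the
numerical conventions chosen where the method leaves room, and the
limitations of both.

## Data model

A *location* is a 3D image stack of `z_max ≥ 2` horizontal slices
(voxel spacing default `(0.996, 0.996, 2.0)` µm in x, y, z) together with
a table of detected neuron centres (integer pixel coordinates `x, y, z`,
optional imaging `day`). A *labeling* assigns one string label per slice;
manual labelings are expected to be contiguous (each label occupies one
run of slices).

## Per-slice features

| Set | Columns | Inputs needed |
|-----|---------|---------------|
| F1  | density (neurons/mm² per slice) | neuron table + stack geometry |
| F2  | density, mean soma size (µm²) | table + stack |
| F3  | density, class-1/2 proportions, class-1/2 mean sizes | table + stack |
| F4  | F3 + overall mean size | table + stack |
| F5  | density, mean size, 4 texture measures | table + stack |
| F6  | contrast, correlation, energy, homogeneity | stack only |

- **Density** is the per-slice detection count divided by the slice area
  in mm²; when a table spans several imaging days, the per-day counts are
  averaged.
- **Soma measurement**: local background is the median intensity in an
  annulus (inner radius 8 px, outer 14 px) around the centre; the soma is
  the 8-connected region above `background + (centre − background)/2`
  within a 20 px radius cap. Size is the region area in µm²; the maximum
  diameter `d` is the largest pairwise pixel distance plus one pixel
  pitch; the shape measure is `πd²/(4A)` (1 for a disc, larger when
  elongated). A measurement is invalid when the centre does not rise
  above background; per-slice summaries use a robust (bisquare IRLS,
  c = 4.685) mean over valid somata, and slices with no valid soma are
  filled by linear interpolation in depth.
- **Two soma classes** come from a two-component full-covariance Gaussian
  mixture over (size, shape), seeded and deterministic; class 1 is the
  component with the smaller mean size.
- **Texture** is computed on each slice linearly quantized to 8 gray
  levels between its min and max; the co-occurrence matrix uses the
  horizontal unit offset, symmetric and normalized. Correlation is
  defined as 0 when either marginal variance is 0.
- **Standardization**: multi-feature sets are z-scored per column before
  clustering ("auto"); F1 is used raw (a single column's scale does not
  affect ward merges). For label transfer, the scaler is learned on the
  reference and applied to the target.

## Iterative contiguity-refined clustering

Given the per-slice feature matrix, for `MC = MC0 … 1` (default
`MC0 = 10`):

1. ward-linkage agglomerative clustering (Euclidean distance) of the
   current per-c-layer feature rows into at most `MC` clusters;
2. every maximal contiguous run of slices sharing one cluster becomes a
   c-layer (contiguity refinement), numbered superficial → deep;
3. features of the new c-layers are the means of the **original**
   per-slice features over their slices (not means of previous-level
   averages), so level features remain slice-count-weighted.

Duplicate feature rows are deduplicated before linkage and mapped back
afterwards, which guarantees that identical rows co-cluster and that the
resulting partitions are nested. The hierarchy records every level; the
final level always has a single c-layer. Levels are numbered 1 (finest)
to `n_levels` (coarsest).

## Label transfer

The reference labeling (a chosen hierarchy level, optionally with
adjacent c-layers merged and renamed) trains an ensemble of `m = 200`
linear SVCs (cost C = 1, one-vs-one), each on a stratified 80 % sample of
reference slices drawn without replacement. Every member votes on every
target slice; a target c-layer's vote for reference label `r` is pooled
over its slices, `p(r) = n_r / (n_t · m)`, and its *d-layer* is the
argmax, with ties broken toward the most superficial reference label.
`select_target_level` picks the deepest target level whose c-layer count
is at least the reference label count.

## Evaluation

- **Boundary array ΔL**: for each consecutive slice pair, the first
  hierarchy level at which the pair shares a c-layer. The manual variant
  is a 0/1 boundary indicator; per-level binary arrays are `ΔL > ℓ`.
- **Smoothing**: 5-tap Gaussian kernel, σ = 1.0 slices, reflect padding
  (kernel shrunk to the largest odd width for shorter arrays).
- **κ** is the Pearson correlation of two smoothed boundary arrays,
  defined as 0 when either array has zero variance; **κ_m** is the
  maximum over hierarchy levels of κ between a level's binary array and a
  manual boundary array.
- **dM / f**: slice-wise agreement indicator between two labelings mapped
  to a common label set, and its mean. For unequal depths, `sliding_max`
  slides the shorter sequence over the longer and reports the best value
  and offset.
- **Perturbation control**: each manual boundary is shifted by a uniform
  draw in `±Nsa` slices (sequentially clipped so boundaries stay ordered
  and layers non-empty); the κ between original and perturbed labelings,
  averaged over repetitions, calibrates observed κ values.

## Synthetic data

`cortilam.synthetic` generates locations from a laminar specification:
flat layer slabs in z; per-layer neuron counts Poisson(density × layer
volume); positions uniform in the slab; class Bernoulli(small-class
fraction); sizes and shapes from class-specific normals truncated to
positive (shape ≥ 1). Rendering draws each soma as a 2D Gaussian blob
whose half-maximum area equals the drawn size, amplitude 150 over a
background of 20 with additive Gaussian noise (σ = 5), on a 512×512 px
field by default.

The default five-layer test bed (`default_laminar_spec`) uses expected
per-slice counts `(100, 500, 300, 900, 700)` and small-class fractions
`(0.9, 0.5, 0.7, 0.2, 0.4)`. The profile is deliberately non-monotone in
depth (as cortical densities are — a dense granular layer above a sparser
layer V), with adjacent-layer count gaps of at least five Poisson
standard deviations so that density alone separates neighbouring layers.
These values are study conditions, fixed before evaluation.

**What it emulates**: depth-varying neuron density, soma-size mixtures,
layer-thickness variability between locations, Poisson detection noise,
sensor noise in the rendered images.

**What it does not emulate**: curved or tilted laminae, realistic optics
(PSF anisotropy, depth-dependent scattering and attenuation are off by
default), vasculature shadows, soma overlap statistics of dense tissue,
detection errors (the neuron table is exact), and between-animal
variability.

## Numerical choices

- Ward linkage and tree cuts come from scipy; SVC and the Gaussian
  mixture from scikit-learn; co-occurrence matrices from scikit-image;
  the co-occurrence property formulas are computed in-package so the
  zero-variance correlation convention (0, not NaN) is explicit.
- Ward on a single feature is sensitive to heteroscedastic noise:
  Poisson count noise grows with the mean, so high-density layers carry
  more within-layer variance. The ≥ 5-SD gap condition in the default
  test bed keeps between-layer distances dominant.
- The maximum soma diameter adds one pixel pitch to the largest pairwise
  centre distance so that a single-pixel soma has diameter one pixel
  rather than zero; consequently a rasterized disc has a shape measure
  slightly above 1 (≈ 1.17 for radius 5 px) rather than exactly 1.
- All stochastic components (sampling, SVM subsampling, GMM
  initialization) run from explicit integer seeds; reruns with the same
  seed are bit-identical.

## Problem sizes

The shipped study conditions are scaled to desk hardware as this
package's own choice: clustering recovery uses 200-slice locations
without rendering; transfer uses rendered 80-slice pairs at 512×512 px
(≈ 20 s per seed pair); the feature-set comparison uses 40-slice
locations at 128×128 px with blob amplitude 0 so texture is constant by
construction. Nothing in the method limits it to these sizes; runtime is
dominated by soma measurement (≈ 0.5 ms per neuron) and scales linearly
in neuron count.

## Limitations

- Layers are assumed horizontal; a tilted boundary smears density across
  slices and degrades both clustering and κ.
- The contiguity refinement can fragment a level into many short
  c-layers when per-slice noise is high relative to layer contrast; the
  level-selection rule then picks a deeper level with fewer c-layers.
- κ is undefined (set to 0) for degenerate boundary arrays, e.g. a
  location clustered into a single layer.
- The SVM ensemble transfers labels based on feature similarity only; if
  reference and target differ systematically (staining, depth
  attenuation), the learned scaler does not correct for it.
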