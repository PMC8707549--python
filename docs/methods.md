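# Methods

This note documents the models, parameter choices and numerical
conventions behind `kernelharm`, and what the synthetic experiments do and
do not show about real CT data.

## Synthetic paired-kernel cohorts

Each synthetic patient is a lung-like phantom: a uniform background at
−800 HU containing one spherical lesion near 0 HU whose interior carries a
stationary correlated texture (white noise smoothed with a Gaussian of the
configured correlation length, rescaled to the configured contrast).
Lesion radius (±20%) and center (±1 voxel) are jittered per patient and
clamped to keep a 2-voxel margin, so shape features vary across a cohort
the way lesion sizes do in practice. A binary label multiplies both the
texture contrast and the correlation length by `label_effect` (default
1.5), giving texture features — not shape — a class signal, which is the
regime the univariate screening is meant to probe.

A reconstruction kernel is modeled as a radially symmetric frequency
response applied slice-wise in 2D Fourier space,

    R(f) = 1 + g · s(f / f_c),   s(u) = u²(3 − 2u) clamped to [0, 1],

followed by additive zero-mean Gaussian noise. `s` is a smoothstep ramp:
zero at DC (mean intensity is always preserved) and saturating at 1 above
the cutoff `f_c`. Smooth kernels use g < 0 (high-frequency attenuation,
little noise), sharp kernels g > 0 (high-frequency boost, much more
noise). This is the minimal model that reproduces the defining trade-off
of sharp clinical kernels — more resolution bought with more noise. It is
*not* a projection-domain CT simulation: there are no sinograms, no
scanner MTF curves, and no structured artifacts. Defaults: smooth
(g = −0.7, f_c = 0.20 cyc/voxel, σ = 5 HU), sharp (g = 1.0, f_c = 0.25,
σ = 40 HU); the validation cohort shifts these (f_c 0.18/0.27, σ 6/45) to
emulate a second scanner. The default grid is 64×64×24 voxels at 1 mm:
large enough to hold the σ = 2.5 Laplacian-of-Gaussian kernel (21 voxels
at 4σ truncation) with margin, small enough for desk-scale runs.

Determinism: every per-record seed is derived from the master seed through
`numpy` `SeedSequence` spawn keys, so regenerating a cohort with the same
parameters is bit-identical.

## The kernel converter

The converter is a 2D fully convolutional residual network applied
slice-by-slice: `n_layers` 3×3 convolutions (ReLU after all but the last),
a final 3×3 convolution to one channel, and the input added back. The
final layer is zero-initialized, making the untrained network *exactly*
the identity — a useful property both as a sanity baseline and because the
residual (the kernel-to-kernel difference) is small relative to the image.
Intensities are normalized as (x + 800)/1000 before the network and only
the predicted residual is rescaled back, so a zero residual returns the
input bit-for-bit.

Training minimizes the per-pixel mean squared error (proportional to a
sum-of-squares loss; the proportionality constant is the pixel count,
chosen for scale stability across slice sizes) with Adam. The
config defaults (learning rate 1e-4, 55 epochs) are a conservative
full-scale schedule; the pipeline's desk-scale preset uses 4 layers × 16 channels,
learning rate 1e-3, 20 epochs, batch 8, which converges well at the
64×64-slice, few-hundred-pair scale used here. Batch size is simply exposed as
configuration. Two independent models are
trained, one per direction; they share no weights. Training operates on
whole slices, not patches. If the final epoch's held-out loss exceeds the
identity baseline, the best-epoch weights are restored, so a returned
model is never worse than the identity on its held-out split.

The network and its backpropagation are implemented directly in numpy
(im2col convolutions in float32, hand-derived gradients verified against
finite differences in the test suite, standard Adam). Single-threaded
reruns with the same data, config and seed give bit-identical weights.

## Radiomic features

The registry holds 89 named features in 11 families, divided into 23
groups for grouped reporting; the name→group mapping is an editable dict.
Conventions that matter:

- **Quantization**: 32 equal-width bins over the in-mask intensity range;
  a constant ROI maps to level 1. Recorded in provenance.
- **GLCM**: distance-1 offsets over the 13 unique 3D directions, symmetric
  accumulation, pairs fully inside the mask, features read from one pooled
  matrix. Entropies use log2.
- **GLRLM**: runs confined to the mask, features computed per direction
  and averaged over the 13 directions. `Run_SPE` is short-run emphasis,
  `Run_PP` the run percentage.
- **GLSZM**: 26-connected same-level zones; **NGTDM**: only voxels whose
  complete 26-neighborhood is in-mask contribute; coarseness uses
  ε = 1e-12 with a documented cap of 1e12.
- **LoG**: explicit kernel at 4σ truncation, DC-corrected to zero sum,
  applied with edge-replicate padding (a constant volume responds exactly
  zero); responses histogrammed into 64 bins for entropy/uniformity. The
  `_p1`/`_p2` suffixes index the configured sigma list (1.5, 2.5 voxels).
  A kernel larger than the volume on any axis is rejected.
- **Edge frequency**: central-difference gradient magnitude summaries —
  the common reading of an otherwise unpublished in-house definition.
- **Sigmoid slope**: logistic fits `a + b/(1 + exp(−(t−t0)/s))` to radial
  profiles along 26 rays from the mask centroid (cubic interpolation,
  0.25-voxel steps, out to twice the boundary distance); reported as the
  mean |b|/(4s) over successful fits; fewer than 3 successes flags the
  feature undefined.
- **Laws / wavelet**: separable L5/E5/S5 kernels, the 27 ordered 3D
  combinations averaged into 10 axis-permutation (multiset) features; one
  one-level 3D Haar transform over the lesion bounding box with per-subband
  mean |coefficient| over the down-sampled mask support (bounding boxes
  under 8 voxels per axis flag the family undefined).
- Undefined values carry an explicit flag (NaN in tables), never a silent
  zero, so downstream CCC and AUC computations can exclude them with
  recorded counts.

Intensity-shift behavior: quantized-texture features are invariant under
affine intensity maps that preserve bin assignment; gradient, LoG, Laws
and wavelet features are homogeneous of degree 1 in intensity scale.

## Reproducibility and prediction metrics

Lin's CCC is computed with population (1/n) moments, matching Lin's original
estimator; the choice changes small-n values and is therefore fixed and
stated. A zero denominator (both vectors constant and equal) flags the
feature undefined, and summaries (mean ± sd, median, fraction strictly
above the 0.85 threshold, group means) run over defined entries only, with
per-feature pair counts recorded.

Univariate AUC is the normalized Mann–Whitney U with midrank ties,
orientation-corrected to max(A, 1−A) — direction-agnostic screening, so
reported AUCs are ≥ 0.5; the correction is toggleable. Group summaries are
median ± median absolute deviation, and converted groups are compared to
`ori_mix` with the two-tailed signed-rank test *across features* (the
feature set is the paired sample).

The signed-rank test drops zero differences (count reported), uses
midranks of |d|, and computes two-tailed p either exactly — the null
distribution of W by subset-sum dynamic programming, equivalent to
enumerating all 2^n sign patterns — or by normal approximation with tie
correction and a continuity correction. `auto` uses the exact path for
n ≤ 25 without ties; feature-level comparisons (n ≈ 89+) use the
approximation, which is what the Z statistics refer to. ANOVA and t-tests
wrap the standard scipy statistics with explicit degenerate-variance
handling (zero pooled variance: p = 1 for equal means, p → 0 otherwise,
both flagged).

## The two-phase experiment

Phase 1 trains both converter directions on the development cohort
(default n = 16; 14/32 of the patients contribute training slices, the
rest are held out for the RMSE check). Phase 2 generates a disjoint validation cohort (default
n = 60) under shifted kernel parameters, converts sharp→smooth and
smooth→sharp, extracts all four feature tables, and computes: three CCC
comparisons (original vs original and each converted vs its target),
grouped means, fractions above threshold, paired signed-rank tests between
CCC distributions, the mixed-group assignment (near-equal arms; odd
cohorts put the extra patient in the sharp arm), the three AUC
distributions and their paired comparisons, and a top-3 table joining each
high-AUC feature's CCCs and AUCs. Mixed-group feature tables are assembled
by row selection from the per-setting tables — extraction is deterministic,
so this is exactly equivalent to re-extracting the mixed volumes, which the
tests verify. Reports are CSV + JSON with sorted keys, no timestamps, and a
config hash, so two runs from one config are byte-identical.

The default problem sizes (16/60 patients, 64×64×24 voxels, 4×16-channel
converter, 20 epochs) are desk-scale choices that keep a full run to a few
minutes while leaving the directional findings clearly resolved; the
`clinical_scale_config` preset (32/223) covers full-evaluation cohort
sizes.

## What passing does and does not show

On the synthetic cohorts, harmonization to the smooth kernel raises mean
CCC and the fraction of highly reproducible features by a wide, strongly
significant margin, leaves shape features untouched (CCC = 1, masks
shared), and does not reduce — typically slightly raises — the median
univariate AUC of mixed-kernel cohorts. These are the method's directional
claims, and the synthetic generator was designed so they
are *testable*, not so they are inevitable: an untrained (identity)
converter reproduces the degraded baseline, and tests guard against
leakage by checking shuffled-label nulls. What the synthetic experiments
cannot show: behavior under real scanner MTFs, structured CT artifacts,
segmentation variability across kernels (masks here are shared by
construction), multi-lesion patients, or extended feature catalogs numbering
in the thousands — the registry implements 89 named features, every
specifically named one plus a representative per-family complement.
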