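# Methods

This note records the modelling conventions, numerical choices and design
decisions behind the package, and what the synthetic experiments do and do
not establish.

## Discretization

Absolute resampling (fixed-bin discretization) maps raw MR intensities to
integer gray levels `1..128` using population-fixed per-sequence bounds
(T2 175–3152, DWI 50–5300, ADC 20–2550, arbitrary scanner units):
`level = ⌊(I − min)/(max − min) · n⌋ + 1` after clamping to `[min, max]`,
with `I = max` folded into the top bin so no unreachable 129th level
exists. Conventions fixed here:

* **1-based levels.** Several features divide by the gray-level index
  (`1/i²` in the low-gray-level emphases), so level 0 must not occur.
* **Clamping, not rejection.** The published bounds are population
  estimates; out-of-range intensities (possible in both real tails and
  synthetic noise) saturate instead of crashing the pipeline.
* The per-lesion min/max estimator (`estimate_intensity_range`, sampling
  per-slice in-mask extrema on the largest-area "representative" slices) is
  a fallback for new sequences only; the default pipeline always uses the
  fixed published bounds, applied identically to training and validation —
  enforced structurally by serializing the discretization spec inside the
  locked descriptor.

## Texture features

37 features per sequence (6 histogram, 6 GLCM, 11 GLRLM, 3 NGLDM,
11 GLZLM), all computed in 3D on the discretized VOI; the raw in-VOI
min/max intensities are carried as extra first-order statistics outside
the panel.

* **Direction set.** The 13 unique unit offsets (26-neighborhood modulo
  sign). GLCM and GLRLM are *summed* over directions rather than averaged
  per direction — the common volumetric convention, fixed for determinism.
  Run percentage is normalized as `RP = N_r/(13 · N_v)` so it stays in
  (0, 1] under summation.
* **Mask semantics.** Runs and co-occurring pairs never cross out-of-mask
  voxels; the mask breaks adjacency. Zones are maximal 26-connected
  equal-level in-mask components (8-connected in a single-slice VOI).
* **Histogram features** are computed on the discretized levels (the
  discretization is the stated preprocessing for texture); skewness and
  kurtosis are population moments with kurtosis left raw (normal ≈ 3), and
  the area under the cumulative gray-level-volume curve (AUC_CSH) is
  computed exactly as the mean min-max-normalized level (the step-curve
  integral collapses to this identity).
* **Degenerate-input conventions** keep the feature map total: constant
  VOIs have skewness = kurtosis = 0, entropy 0, AUC_CSH 1; GLCM correlation
  is 0 when a marginal variance vanishes; NGLDM coarseness is regularized
  by ε = 1e-12. A VOI with no in-mask voxel pair (or no voxel with an
  in-mask neighbor) raises a distinct error instead of emitting zeros.
* **NGLDM variant.** Amadasun-style definitions: per-voxel absolute
  difference from the mean level of its in-mask 26-neighbors, aggregated
  into occurrence probabilities `p_i` and difference sums `s_i`; voxels
  with no in-mask neighbor are excluded from both.

The vectorized implementations (shift-based run-length fixpoint,
`scipy.ndimage` labelling and convolution) are verified against independent
brute-force enumeration oracles — direct pair counting, run walking, BFS
zone growth, per-voxel neighborhood loops — on hundreds of random masked
subgrids to 1e-10 relative tolerance, together with the conservation laws
`Σ_j j·r(i,j) = 13·N_v` and `Σ_s s·z(i,s) = N_v`.

## Screening and cut-offs

Between-class comparison uses the asymptotic Mann–Whitney U test with
tie-corrected variance and continuity correction; at cohort sizes around
40 the normal approximation is standard and an exact mode adds nothing.
Screening is deliberately unadjusted for multiplicity — it is exploratory,
and error control happens at the model level (a two-feature lock evaluated
on an independent cohort).

ROC analysis uses the empirical curve over the observed score values with
per-feature auto-orientation (stored, so that `A ≥ 0.5` and the locked
cut-off is unambiguous). The AUC is computed through the identity
`A = U/(n₊ n₋)`, which the curve's trapezoid reproduces exactly, ties
included. The Youden cut-off maximizes `J = Se + Sp − 1` over the observed
thresholds, with ties broken toward higher specificity and then a higher
cut-off; candidate thresholds are the observed values themselves, which
makes the scan deterministic and reproduces exhaustive search on every
instance.

## The locked descriptor

Derivation takes the top-AUC significant feature from T2 and from ADC —
one per sequence, enforcing cross-sequence complementarity (T2 reflects
morphology, ADC diffusion microstructure) and avoiding same-sequence
redundancy; the raw min/max extras are excluded so the descriptor remains
a texture signature. The AND rule uses strict inequality at the cut-off
("exceeds" reads as strict; a value exactly at the cut-off is negative).
Because the positive set is an intersection, the descriptor's specificity
is at least each component's — the rule trades sensitivity for
specificity by construction.

The descriptor's published form pairs T2 GLRLM-LRLGE (cut-off 3731.71)
with ADC GLRLM-SRLGE (cut-off 3785.45); `default_descriptor()` constructs
exactly this artifact.

Its binary decision yields a single ROC operating point, so the evaluation
reports `(Se + Sp)/2`, explicitly labelled "binary-rule AUC". No attempt is
made to imitate AUC constructions whose definition is not stated.

Locking is machine-checkable: the serialized JSON carries a SHA-256 over
the decision-relevant fields (components, rule, discretization), and
loading verifies it, so validation fails hard on any post-hoc edit rather
than silently re-tuning. Validation itself carries no tuning parameters
and is invariant to the cohort's processing order.

## Hanley–McNeil inference

With `Q₁ = A/(2−A)` and `Q₂ = 2A²/(1+A)`:

    se² = [A(1−A) + (n₊−1)(Q₁−A²) + (n₋−1)(Q₂−A²)] / (n₊ n₋)

where `n₊` counts invasive cases. The `Q₁` term carries the case count:
this assignment reproduces both reported standard errors (0.041 at
A = 0.934, 21/19; 0.053 at A = 0.871, 28/16), whereas the swapped
weighting gives ≈ 0.062 for the validation cohort. The 95% CI is the
normal approximation clipped to [0, 1] (the training upper bound 1.000 is
a clipped value). Power against AUC₀ = 0.5 uses the alternative-hypothesis
standard error throughout, `power = Φ(|A − 0.5|/se(A) − z_{0.975})`; a
two-variance (null + alternative) formulation would shift the minimally
detectable AUC from ≈ 0.72 to ≈ 0.75 at these cohort sizes. The minimally
detectable AUC solves `power(A*) = 0.80` by bisection on (0.5, 1) to 1e-6;
power is monotone in A for fixed counts, and the bisection is checked
against a dense grid scan.

## Synthetic cohorts

The generator emulates the study's data regime, not bladder anatomy. Per
patient: a connected tumor mask (ellipsoid perturbed by smoothed noise,
spanning 2–6 consecutive axial slices, ≥ 8 voxels, 1 × 1 × 4 mm spacing on
a 28 × 28 × 9 grid) shared across sequences, and per-sequence volumes built
from a correlated Gaussian random field (smoothing length 1.2 voxels)
min-max scaled into the sequence's nominal range plus 2% additive noise.

Texture heterogeneity comes from two independent axes:

* **Dark streaks** (the class axis). Every patient carries a small
  patient-varying fraction (uniform on 0–4% of VOI voxels) of coherent
  dark streaks at normalized intensity 0.08–0.20 — stand-ins for focal
  fibrosis/necrosis. Invasive patients additionally receive *deep* dark
  streaks (normalized ≤ 0.02 under the default `low_shift_mibc = 0.8`)
  with excess fraction `effect_size × Gamma(2, 0.04)` (mean 8% at the
  default `effect_size = 1`). Streaks are elongated in-plane runs (6–10
  voxels in T2, 1–2 in ADC, 3–5 in DWI) with a per-streak constant value,
  so they form genuine equal-level runs. Because the low-gray-level
  emphases weight levels as `1/i²`, the *depth* difference between
  baseline and deep streaks dominates those features, while
  amplitude-driven features (GLCM contrast, NGLDM busyness) see only a
  modest change — this is what makes the low-gray family, and not some
  arbitrary correlate, the discriminative one.
* **Bright speckles** (the nuisance axis). A class-independent fraction
  (0–12%) of isolated near-maximum voxels, varying per patient. This
  injects realistic between-patient variance into contrast/busyness-type
  features without touching low levels.

DWI volumes never receive class-dependent streaks, mirroring the finding
that DWI texture was uninformative and giving screening a true-negative
sequence. With `effect_size = 0` the label never enters generation at all,
so the classes are exchangeable by construction — the null tests rest on
this, not on sampling luck. Reproducibility: each patient consumes an RNG
stream keyed by `(seed, patient index)`, independent of generation order;
cohorts are byte-reproducible from their parameters, and the on-disk
manifest records parameters plus per-file SHA-256 hashes (volumes are
written as uncompressed `.nii` so bytes are deterministic).

What passing tests show — and don't. The simulations demonstrate that the
pipeline is statistically calibrated (type-I rate of the screen, chance
AUC under the null), that it recovers a known injected effect family, and
that the locking machinery prevents leakage. They say nothing about
scanner physics, segmentation variability, partial-volume effects or
cross-vendor shifts; the published cut-off magnitudes are not reproducible
from simulation and are carried only as the default descriptor artifact.

## Problem sizes

Simulation-backed tests use deliberately small study sizes: recovery runs
50 replicate cohorts of 24 patients; null calibration uses 1000 label
permutations on a 30-patient cohort and 200 null cohorts of 12 patients;
effect-size monotonicity uses 18 replicates per grid point at n = 12.
These sizes keep Monte-Carlo error well inside the asserted tolerances
while the whole suite stays comfortably re-runnable; the study-geometry
fixtures (40 = 21 + 19 training, 44 = 28 + 16 validation) match the
cohorts the pipeline is meant to serve.

## Known limitations

* The mask is shared across sequences (the pipeline accepts per-sequence
  masks read from disk, but the generator emits one per patient); no
  registration or resampling is performed, and volumes/masks must agree in
  shape exactly.
* The exact bin-edge convention of the original extraction software is not
  published; the floor-plus-clamp rule above is this package's fixed
  convention, applied uniformly, so absolute feature values may differ
  from other tools at bin boundaries.
* No filtered-image (wavelet/Laplacian), shape or 2D-averaged features; no
  multivariable models over the panel — the artifact reproduces the
  two-feature AND design, including its refusal to re-tune on validation
  data.
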