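# Methods

## Problem and scope

Acute ischemic lesions appear on CT-angiography source images (CTA-SI) as
hypoattenuated (locally darker) parenchyma.  The package implements an
end-to-end analysis that learns to segment such lesions with a patch-based
3D convolutional network, and asks whether giving the network the
*contralateral* intensity at each voxel — a hemispheric comparison channel —
reduces false positives caused by symmetric aging changes
(periventricular white-matter hypoattenuation, widened cortical sulci).
Because clinical CT volumes cannot be shipped, the entire analysis runs on
procedurally generated head phantoms; the published region-contingency
counts are additionally re-derived exactly from their printed table.

## Phantom model

A phantom head is a set of nested ellipsoids on a regular grid:

* **Skull**: bright shell (100 intensity units) between the outer head
  ellipsoid (semi-axes 0.46 × grid extent) and an inner surface 2–5 mm
  deeper (never thinner than ~2 voxels, or rasterization opens pinholes).
* **Brain**: parenchyma at 35 units inside the shell; background 0.
* **Ventricles**: two mirror-symmetric CSF (5 units) ellipsoids flanking
  the midline.
* **Periventricular hypoattenuation**: a rim around the ventricles whose
  intensity ramps down toward CSF, scaled by a severity in [0, 1].
* **Sulci**: radial grooves in the outer cortical shell, angularly periodic
  and even in the left–right coordinate, deepening and darkening with a
  severity in [0, 1].  Both confounders are exactly mirror-symmetric before
  pose perturbation.
* **Lesion** (group A only): an ellipsoid with the volume of a sphere of the
  requested radius (axis factors 0.78/1.25/1.03, mildly anisotropic like an
  MCA-territory lesion), centred at 45% of the inner x semi-axis, clipped to
  the brain and its hemisphere; its intensity is multiplied by
  (1 − lesion_contrast).  A lesion that cannot fit (midline crossing or
  protrusion through the cortex) raises a parameter error rather than being
  silently truncated.

The intensity scale is arbitrary pseudo-HU; preprocessing standardizes
intensities, so only relative contrast matters.  Acquisition is emulated by
a random rigid head pose (image and truth transformed jointly), additive
Gaussian noise, and an NCCT channel rendered from the same anatomy with
thicker-slice blurring (σ_z ≈ 2.5 mm vs 1 mm in-plane), 60% contrast and an
independent small pose offset that preprocessing must undo by registration.

Defaults: 96×96×64 grid at 1 mm, lesion radius 12 mm, contrast 0.35, noise
σ = 2 (≈ 6% of parenchymal intensity), pose within (2°, 2 mm).  Cohorts
randomize the lesion side with probability 0.5, the radius uniformly over
0.40–0.95 of the largest radius that fits (spanning roughly two orders of
magnitude in volume, the published range scaled to phantom size), the
contrast over 0.25–0.45 and the confounder severities over 0.3–0.9.
Per-case seeds are SHA-256 hashes of (cohort seed, index), so any case is
reproducible in isolation.

What the phantoms do **not** model: vessel trees and contrast-bolus physics,
realistic HU calibration, beam hardening, bilateral lesions, non-rigid
anatomy differences between subjects, or textured lesion interiors (the
lesion is a uniform intensity drop plus noise — no quantitative texture
description of CTA-SI hypoattenuation exists to emulate).  Passing tests
therefore demonstrate the *mechanics* of the analysis — conditioning,
learning, and both evaluation levels — not clinical performance.

## Preprocessing

* **Brain mask**: threshold the bright shell at half the robust maximum
  (99.9th percentile), fill its interior, keep the largest enclosed
  component, fill holes.  A morphological closing is applied only if the
  shell rasterizes with pinholes.
* **Crop** to the mask bounding box plus a margin; the origin shifts so
  physical coordinates are preserved.
* **Resample** to isotropic spacing — linear for images, nearest-neighbour
  for masks and atlases (preserving label sets).  Phantom default 1 mm
  (2 mm in the scaled-down test configurations); the clinical-scale 0.5 mm
  is a configuration away.
* **Standardize** to zero mean / unit variance over in-mask voxels, the same
  affine intensity map applied everywhere.
* **Hemispheric comparison**: flip the standardized CTA along the
  left–right axis and rigidly register it back onto the original
  (mean-squared-difference metric restricted to the brain mask, 3-level
  pyramid with shrink factors 4/2/1, regular-step gradient descent, 200
  iteration cap — registration is single-threaded for bit reproducibility).
  The original is normalized *before* the comparison channel is derived, so
  both channels share one intensity frame; deriving first and normalizing
  per-channel is available via configuration.
* **NCCT** is registered onto the CTA grid the same way, then standardized.

A note on tolerances: the flipped channel carries an independent noise
realization, so even a perfect registration of a symmetric head leaves an
RMS difference of √2·σ.  Sharp registration checks therefore use noiseless
symmetric phantoms (RMS ≪ the anatomical contrast), while noisy checks allow
2σ.

## Network

Two pathways of valid 3×3×3 convolutions with leaky rectifiers (slope 0.01):
a normal-resolution pathway over `output_patch + 2·L` voxels per side (L
conv layers) and a context pathway over a 3×-larger window block-averaged by
factor 3; the context features are nearest-neighbour upsampled, centre
cropped and concatenated with the normal features, then passed through
1×1×1 fused layers and a two-class softmax.  Weights are He-initialized from
a seeded generator; everything (initialization, sampling, optimization) is
deterministic given the seeds.

Default desk scale: 4 conv layers per pathway with 8/8/16/16 filters, one
24-wide fused layer, output patch 9³ (normal input 17³, context window 33³),
≈ 26k parameters — deliberately small enough to train on one CPU in minutes
while preserving the multi-scale mechanism.  An 11-weighted-layer
clinical-scale instance is reachable through `NetworkConfig`.  (A fixed
patch/depth pairing quoted for this family, 25³ input with 9³ output over
six 3³ layers, is geometrically inconsistent for valid convolutions; patch
sizes here are always derived from depth.)

**Training recipe** (the published hyperparameters, scaled only in epoch
counts and network size): batch size 10; L1 10⁻⁶ and L2 10⁻⁴ penalties on
convolution weights (penalty λ₁Σ|w| + λ₂Σw², gradients λ₁·sign(w) + 2λ₂w);
RMSprop ρ = 0.9, ε = 10⁻⁴ composed with Nesterov momentum 0.6 as

    r ← ρ r + (1−ρ) g²,  ĝ ← g/(√r + ε),  v ← μ v − η ĝ,  θ ← θ + μ v − η ĝ

(the exact composition is not published; this convention is frozen by a
hand-computed single-step test); 35 epochs × 15 sub-epochs with the initial
learning rate 10⁻³ halved at epochs 17, 19, 21, 23, 25, 27, 29, 31 (the
eight halving epochs are not published; late-phase halving is the
convention for this network family and the schedule is configurable).
Training patches are drawn only within the brain mask, 50% centred on
lesion voxels (unpublished; chosen because the class imbalance of a small
unilateral lesion otherwise stalls learning), with a fallback to uniform
sampling (logged) when a cohort has no lesions.

**Reflection augmentation** mirrors each example along the left–right axis
— all channels and labels in unison.  Unison reflection is already
self-consistent for the comparison channel, since the comparison channel of
a mirrored subject *is* the mirror of the original comparison channel.  An
optional channel-role swap (exchanging CTA and comparison after the flip)
is provided but off by default: empirically it inverts the lesion's
dark-here/bright-contralateral signature and collapses region-level
specificity, which is how the default was settled.

**Inference** tiles the brain-mask bounding box with disjoint output tiles
(seam-free stitching by construction), edge-pads the channels for boundary
windows, and zeroes probabilities outside the mask.

## Evaluation

* Voxel level: threshold 0.5 with ties positive (the tie rule must be fixed
  for exact reproduction and is tested); sensitivity TP/(TP+FN),
  specificity TN/(TN+FP), DSC 2TP/(2TP+FP+FN) over in-mask voxels.  Empty
  truth ⇒ sensitivity NaN with a reason attached; DSC 1 if the prediction
  is also empty, else 0.  ROC sweeps every distinct probability (≥ rule);
  trapezoidal AUC equals the pairwise concordance estimator, which the
  tests verify to 10⁻⁹ against an O(n²) oracle.
* Region level: 10 ASPECTS regions per hemisphere.  The phantom atlas is an
  ASPECTS *analogue*: four deep quadrant blobs (I, L, C, IC) inside 45% of
  the brain radius and six angular cortical wedges (M1–M6) outside it, per
  hemisphere — no published masks exist for the real regions.  A region is
  positive on a single positive voxel; the 2×2 tally over cases yields
  sensitivity, specificity and a region-count Dice 2TP/(2TP+FP+FN), which
  reproduces all six published Dice values from the printed counts.
  Lesion-free (group B) subjects contribute all 20 regions as negative
  truth, giving the pooled two-group Dice 2TP/(2TP+FP_A+FP_B+FN) — this
  assumption is implied by, and verified against, the printed arithmetic.
  ASPECTS score = 10 − positive regions, minimum over hemispheres.
  Metrics are compared to printed values after half-up rounding to 2
  decimals.
* Volumetry: largest connected component (26-connectivity — unpublished,
  standard for 3D lesions) × voxel volume, in cm³.

## Scaled-down study conditions

The published voxel-level results (sensitivity up to 0.74, AUC up to 0.93)
required 30 clinical subjects and ~100 GPU-hours per model and are not
reproducible at desk scale; they are replaced by property checks plus a
directional ablation.  The ablation uses 40×48×32 phantoms at 2 mm, 3+3
training and 3+3 test cases, the default small network and 150 optimization
steps per model, three training seeds per feature set — about four minutes
of CPU for the pair of models.  Under these conditions both the CTA-only
and the CTA+comparison model saturate the synthetic task (median region
specificity 1.0, voxel AUC ≈ 0.999), so the published *strict* specificity
gap does not re-emerge; the checked property is the non-strict ordering
(adding the comparison channel does not hurt specificity), which holds.
The phantom confounders, being procedurally regular, are learnable from
local texture alone — one more reason synthetic results must not be read as
clinical performance.

## Numerical and engineering choices

* Arrays are (x, y, z) with axis 0 the left–right axis; NIfTI I/O reorients
  to canonical axes on load.  Flips are array reversals (exact involutions).
* Registration, training and inference are seed-deterministic; ITK filters
  run single-threaded; reports are byte-identical across reruns of the same
  configuration.
* Degenerate inputs fail loudly with typed errors: empty masks, constant
  in-mask intensities, non-positive spacings, channel/grid mismatches
  (naming the offending channel), non-finite training loss (with
  diagnostics), single-class ROC truth.
* Per-case seeds and per-stage sub-seeds are derived by hashing, never by
  sequential draws, so cohort membership and training randomness are
  independent of each other.

## Known limitations

Phantom realism as listed above; the ASPECTS-analogue atlas is geometric,
not anatomical; the registration metric assumes same-modality intensities
(true here, approximately true for CTA/NCCT after standardization); the
numpy network trains small instances only — the clinical-scale 11-layer
configuration is expressible but impractical without GPU acceleration; and
the saturation of the desk-scale ablation means relative feature-set
rankings on phantoms carry limited evidence about clinical data.
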