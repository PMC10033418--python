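# Methods

This note records the models and estimators implemented in `mitomap`, the
parameter choices that matter, and what the synthetic ground truth does and
does not establish about real data.

## Imaging geometry

All volumes are `(z, y, x)` arrays with a physical voxel size `(dz, dy, dx)`
in nanometres, default `(50, 5, 5)`: serial block-face EM sections are
~10× coarser axially than laterally. Every distance, area and volume is
computed in physical units; any operation that is isotropic by construction
(meshing, skeletonization) first resamples to an isotropic grid. Voxel
`(k, j, i)` has its *center* at `origin + (k·dz, j·dy, i·dx)`; tabulated
lengths are µm, sub-voxel distances nm.

## Synthetic scenes

The generator emulates the statistical structure the analysis assumes, not
EM texture. A scene contains one ellipsoidal nucleus, `n` tubular
mitochondria and spherical lipid droplets, with per-class grayscale means
(background 0.8, nucleus 0.45, mitochondria 0.2, droplet 0.9 on [0, 1] —
dark organelles, bright lipid, as in backscatter EM) plus additive Gaussian
noise (σ = 0.05 by default; none of these values is prescribed by the
imaging, they are plausible and configurable).

Mitochondria are capsules around a smoothed 3D random-walk axis (25 nm
steps, direction perturbed by a wobble factor 0.25 per step). Axis length is
log-normal in physical length: "elongated" scenes default to mean 1.2 µm
(sd 0.6), "fragmented" to 0.4 µm (sd 0.15) — one generator covers both
phenotypes through the length distribution, since no quantitative
fragmented/elongated cutoff is established. Placement is "dispersed"
(uniform over cytoplasm) or "perinuclear" (start point within a 1 µm shell
outside the nucleus surface).

Rasterization on the anisotropic grid is the one numerically delicate step:
with a 100 nm tubule radius spanning only two 50 nm sections, a plain
center-in-radius test mis-sizes capsules by up to ~10%. Each voxel is
therefore tested at 8 z sub-positions (midpoint rule) and counted inside
when at least half are covered; planted capsule volumes then match the
analytic πr²L + (4/3)πr³ to a few percent.

Instances are placed by rejection sampling (cap: 1,000 retries per instance,
then an error naming the class) and keep **two** empty voxels of clearance
from everything already placed: one voxel guarantees that
connected-component labelling at any connectivity recovers the planted
count, the second guarantees the same for the classical pipeline, whose 3³
median filter would bridge single-voxel gaps. The per-instance table stores
class, centroid, exact voxel volume, planted axis length and radius — the
oracle for every downstream test.

Motility series are binary masks translated by `round(v·(n−1))` pixels per
frame from a reference frame, 10 frames at 20 s by default; a
grayscale-rendering helper adds Gaussian noise at a chosen SNR for
thresholding tests.

## Segmentation network

The architecture follows the U-Net encoder–decoder pattern with three
departures: residual blocks (one per stage; widths 32, 64, 128, 256, 256),
2× max-pooling after the first three stages only (total downsampling 8×, so
a 768×768 input bottoms out at 96×96 and organelle-scale detail survives),
and an ASPP block (3×3 convolutions at dilations 6, 12, 18, 24, concatenated
and fused 1×1) closing the encoder. The decoder mirrors the pooled stages
with nearest-neighbour upsampling and skip concatenations; a 1×1 head emits
three logits per pixel, argmax labels, ties to the lowest class id. Leaky
rectifier slope defaults to 0.01; weights are fan-in-scaled uniform,
seed-controlled. Blocks carry no normalization layers.

The engine is plain numpy: convolutions as shift-and-matmul over kernel taps
(BLAS `tensordot`), explicit backward passes, Adam (β₁ = 0.9, β₂ = 0.999).
Correctness is established by directional-derivative checks against
numerical differentiation (the loss uses the log-sum-exp form of
cross-entropy precisely so these checks are exact even with extreme logits).

Reference training schedule: per-pixel cross-entropy, batch 8, lr 1e-4
dropped to 1e-5 after epoch 150 of 200; augmentations (horizontal/vertical
flips, rotations in [−20°, 20°], Gaussian noise σ = 0.08, crops down to 90%
of each side resized back) each applied independently with probability 0.5,
geometric transforms applied identically to labels with nearest-neighbour
interpolation.

**Desk-scale training run.** The training sanity check overfits four
synthetic 128×128 slices. At that scale the recipe is deliberately reduced:
a narrow encoder (16, 32, 64, 64, 64), lr 1e-3 flat, 60 epochs, batch 4,
augmentation off — a pure memorization check that the engine optimizes this
architecture, reaching macro-DICE ≈ 0.98 in about a minute on one CPU. It
says nothing about generalization to real EM, which would need the full
schedule, the augmentations and annotated data.

Evaluation: per-class one-vs-rest confusion counts; DICE = 2TP/(2TP+FP+FN),
IoU = TP/(TP+FP+FN), precision, recall; macro average over the two
foreground classes (pixel-pooled precision/recall are also computed, macro
is reported). A class absent from both maps scores 1 on all four metrics —
vacuously perfect — so macro averages stay defined on sparse tiles.

## Classical instance segmentation

Median filter (3³) → optional percentile contrast rescale → threshold (Otsu
by default; a fixed value reproduces an interactive choice) → marker-based
watershed on the negated distance transform (markers: regional maxima of the
physical-units EDT within a configurable footprint, default 3 voxels) →
connected components, ids densified. An all-background threshold result
returns an empty labelling with a warning rather than an error.

## Morphometry

* **Volume** — voxel count × voxel volume, exact by construction.
* **Surface area** — marching-cubes mesh at level 0.5 of the instance
  resampled to isotropic spacing, after a σ = 1 voxel Gaussian smoothing of
  the binary field. Face-counting overestimates smooth surfaces by ~50% and
  an unsmoothed marching-cubes mesh by ~8% (staircase artifact); with
  smoothing a radius-20-voxel ball measures Ψ = 1.003. The isotropic target
  spacing is the finest axis spacing, coarsened just enough to keep an
  instance under ~0.5M voxels so meshing/skeletonization of large tubules
  stays tractable.
* **Length** — no standard estimator exists for curved tubules; the package
  defines length as the longest shortest-path through the 3D skeleton
  (26-connected graph, physical edge weights, tree-diameter double sweep)
  *plus* the distance-to-surface at the two path endpoints, so a straight
  capsule of axis L and radius r measures ≈ L + 2r. A principal-axis extent
  is available as an alternative (`length_method="major_axis"`).
* **Sphericity** — Ψ = π^(1/3)(6V)^(2/3)/A; discrete meshes can exceed 1 by
  a small tolerance (≤ ~1.05 accepted). Single-voxel instances use
  closed-form voxel-box measures so all functions are total.
* Default connectivity for labelling is 26; 6 and 18 are available.

Density summaries are normalized histograms (∑ density·Δbin = 1) over
volume, length, sphericity or nucleus distance.

## Nucleus distances

**2D (fluorescence).** The nucleus mask is summarized by its
moment-equivalent ellipse: centroid, semi-axes 2√λ of the second-moment
eigenvalues (with the 1/12 pixel-footprint correction), tilt from the
leading eigenvector, normalized to [0, π). For a point p and ellipse in its
standard frame, minimizing squared distance subject to the boundary
constraint and substituting x = ±a√(1−y²/b²) turns the stationarity
condition into the quartic

    (1 − y²/b²)·((b²−a²)y − b²p_y)² = a²p_x²y²,

solved via companion-matrix eigenvalues (robust near multiple roots; real
roots filtered at |Im| ≤ 1e-9·max(1,|root|)). Real roots are clamped to
[−b, b]; both x signs are evaluated (the substitution loses the sign), and
the four axis endpoints are appended to cover the degenerate on-axis
branches — extra candidates can never *lower* the true minimum, so the
reported distance is exact. The point at the exact center returns the
semi-minor endpoint (tie broken toward the minor axis, by convention).
`n_candidates` reports the real quartic roots examined (≤ 4 in general
position). Against a dense-sampling + local-refinement oracle the solver
agrees to ~1e-11 relative over thousands of random pairs.

**3D (volume EM).** Distances are read off `scipy`'s exact anisotropic
Euclidean distance transform of the nucleus mask: per instance either the
minimum over its voxels ("surface", default) or the value at its centroid
("centroid"). Voxels inside the nucleus footprint score 0. Distances are
center-to-center to the nearest nucleus voxel, so a face-adjacent voxel is
one lateral step (5 nm) away.

## Motility

Frame 1 is the reference. For n ≥ 2: overlap_area(n) = |mask(n) ∩ mask(1)|,
travel_area(n) = |mask(n)| − overlap_area(n), ratio(n) =
travel_area(n)/overlap_area(n) (areas in pixels; the ratio is
dimensionless). An OLS line ratio = a·t + b over t = (n−1)·dt gives the
readout a in s⁻¹. Frames with zero overlap have no defined ratio; they are
excluded from the regression and recorded with a reason (fewer than two
retained points is an error listing the exclusions). Thresholding of
grayscale series is per-frame Otsu by default (a shared frame-1 threshold
and fixed values are flags), optionally preceded by rolling-ball background
subtraction. The statistic is per field of view; per-object tracking is out
of scope. Note the statistic measures *progressive* displacement: a single
fixed offset repeated in every frame yields constant ratios and slope 0.

## Subpopulations and phenotyping

Per mitochondrion, two flags from distance transforms: `nucleus_near`
(surface distance to the nucleus ≤ 1 µm default) and `ld_contact` (surface
distance to any droplet ≤ 50 nm default — an organelle contact-site scale;
neither cutoff is canonical, both are configurable and echoed in outputs).
Labels by precedence PDM → PNM → CM: droplet contact wins when both flags
hold, because the peri-droplet class is defined by a specific physical
contact; the three labels are exclusive and per-cell percentages sum to 100.
A mitochondrion touching several droplets counts once. Droplet
quantification is count, per-droplet and total volume.

PET phenotyping: tumour-to-heart uptake ratio, HI iff ratio ≥ 0.5 (FBnTP,
membrane-potential tracer) or ≥ 0.2 (FDG, glucose tracer), boundaries
inclusive. Respiratory capacity is normalized to mitochondrial content by
straight division (OCR per fluorescence unit).

## Pipeline, formats, determinism

Multi-page TIFF is the volume interchange format (z spacing never read from
TIFF tags — always from config); MRC is read-only via gemmi. Tables are CSV.
The staged pipeline (`simulate → segment-* → instances → morph → distance →
motility → compartments → phenotype`) wires stages by documented filenames,
writes a manifest (config hash, seeds, versions, warnings) and is
byte-reproducible for a fixed config: every random draw flows from config
seeds, nothing reads the clock.

## Problem sizes

Test and acceptance runs use scenes of roughly 25–50 M voxels downward:
25 planted capsules (radius 100 nm, length 1 µm) on a (56, 560, 560) grid at
(50, 5, 5) nm for morphometry recovery; (10, 128, 128) at (50, 10, 10) nm
for the training slices; 1,000 random point–ellipse pairs for solver
validation. These sizes exercise every code path at full numerical fidelity
while keeping a complete run in minutes on a single CPU core.

## Known limitations

* The generator produces piecewise-tubular, non-branching mitochondria;
  real networks branch and fuse, and EM has texture, membranes and staining
  artifacts the intensity model does not attempt.
* Published segmentation accuracy on real annotated EM data cannot be
  verified here; the training check demonstrates optimizer/architecture
  correctness, not generalization.
* Sphericity and skeleton length lack field-standard estimators; other
  toolchains will differ at the few-percent level, so only property-level
  agreement (ordering, bounds, scaling) is claimed.
* The 2D distance route models the nucleus as a single ellipse; lobed or
  multiple nuclei are out of scope.
* Crista-level analysis (density, type classification) is not implemented.
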