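# mitomap

Quantitative mapping of mitochondrial networks in 3D electron-microscopy and
fluorescence imaging of tumour cells.

Serial block-face electron microscopy (SBEM) resolves whole tumour cells at
~5 nm in-plane and 50 nm section spacing — fine enough to see every
mitochondrion, the nucleus and lipid droplets, and coarse enough (and
anisotropic enough) that naive voxel arithmetic gets every physical
measurement wrong. `mitomap` implements the analysis stack that turns such
volumes, and companion live-cell time-lapse stacks, into per-organelle
biology:

* **Semantic segmentation** — a U-Net-style encoder–decoder with residual
  blocks (32, 64, 128, 256, 256 filters), downsampling capped at one-eighth
  of the input so small organelles survive, and an atrous spatial pyramid
  pooling block (rates 6, 12, 18, 24) closing the encoder. Trinary output:
  background / nucleus / mitochondria, argmax per pixel. Implemented as a
  self-contained numpy forward/backward engine with Adam and the standard
  augmentation set (flips, ±20° rotations, Gaussian noise σ = 0.08, crops to
  90%, each with probability 0.5).
* **Classical instance segmentation** — median filter → threshold (Otsu or
  fixed) → distance-transform watershed → connected components.
* **3D morphometry** — per mitochondrion: exact voxel volume, isosurface
  mesh area on an isotropically resampled grid, skeleton-geodesic length,
  and sphericity Ψ = π^(1/3)·(6V)^(2/3)/A (1 for a sphere, lower for
  tubules).
* **Nucleus distances** — in 2D fluorescence, the nucleus is its
  moment-equivalent ellipse and the minimum point-to-boundary distance is
  found *exactly*: the Lagrange stationarity condition in the ellipse's
  standard frame reduces to a quartic in y (at most four candidate boundary
  points), solved by companion-matrix roots. In 3D, an anisotropy-aware
  Euclidean distance transform.
* **Motility** — for a 10-frame series at 20 s spacing, per-frame
  displacement ratios against frame 1, `ratio(n) =
  travel_area(n)/overlap_area(n)`, and the slope of the ordinary
  least-squares line `ratio = a·t + b`; the slope `a` (s⁻¹) is the motility
  readout.
* **Subpopulations** — perinuclear (PNM), peri-droplet (PDM, droplet
  contact) and cytoplasmic (CM) mitochondria by distance-transform contact
  rules, plus lipid-droplet counts/volumes, tumour-to-heart PET uptake-ratio
  phenotyping (FBnTP ≥ 0.5 → HI, FDG ≥ 0.2 → HI, boundaries inclusive) and
  respiratory-capacity normalization to mitochondrial content.
* **Synthetic ground truth** — every stage is exercised on generated scenes
  (ellipsoidal nucleus, random-walk capsule mitochondria, spherical
  droplets, EM-like intensities) whose instance parameters are known
  exactly, so each measurement has an oracle.

## Worked example

The numbered drivers under `analysis/` run the pipeline end to end on two
synthetic cells — an "OXPHOS-high-like" cell (elongated, dispersed
mitochondria plus lipid droplets) and an "OXPHOS-low-like" cell (fragmented,
perinuclear mitochondria, no droplets):

```sh
python analysis/01_simulate_scenes.py
python analysis/02_instance_morphometry.py
python analysis/03_nucleus_distances.py
python analysis/04_motility.py
python analysis/05_compartments.py
python analysis/06_train_segmenter.py
```

Output of the morphometry, distance and compartment stages (written under
`results/`):

```
oxphos_hi_like: 16 mitochondria, median volume 0.0021 um^3, median length 0.491 um, median sphericity 0.648
oxphos_lo_like: 16 mitochondria, median volume 0.0013 um^3, median length 0.338 um, median sphericity 0.712
oxphos_hi_like: median nucleus distance 0.583 um over 16 instances
oxphos_lo_like: median nucleus distance 0.295 um over 16 instances
oxphos_hi_like: PNM 31.2%  PDM 31.2%  CM 37.5%  (droplets: 4)
oxphos_lo_like: PNM 100.0%  PDM 0.0%  CM 0.0%  (droplets: 0)
```

The fragmented cell's mitochondria are smaller, shorter, rounder and sit at
half the nuclear distance of the elongated cell's — the morphological
signature that separates low- from high-OXPHOS tumour cells — and only the
droplet-bearing cell has a peri-droplet subpopulation. The desk-scale
training driver reaches macro-DICE 0.986 on its four slices in about a
minute on one CPU.

A `mitomap` console command exposes the same stages
(`mitomap pipeline --stages simulate,instances,morph --out runs/demo`).

## Layout

```
src/mitomap/       library: synthetic, segmentation, nn, morphometry,
                   spatial, motility, compartments, io, config, pipeline, cli
analysis/          numbered narrative drivers over the library
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance script
docs/methods.md    models, estimators, parameter choices, limitations
```
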