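# Methods

## Problem and scope

The package automates the nodal part of pelvic MRI reading for prostate
cancer staging: segment every visible lymph node on a high-b-value
DWI volume, measure each node, flag the suspicious ones (short diameter
strictly greater than 0.8 cm), and emit the N0/N1 stage with the largest
node's measurements. It deliberately stops at the size criterion: no
malignancy diagnosis, no anatomical sub-region assignment, no DICOM/PACS
handling (NIfTI only), and no multi-sequence (T2/DCE) support.

## Coordinate and measurement conventions

All grids are indexed `(z, y, x)` with per-axis voxel spacing in mm;
pelvic DWI is strongly anisotropic (6–8 mm slices, ~1.5 mm in-plane), so
every distance and size is computed in physical mm, never in voxel units.
NIfTI volumes are reoriented to canonical axis order on read; the scanner
origin is carried for provenance but never used in measurements.

A node's **short diameter** is the smallest edge of the minimum-volume
oriented bounding box (OBB) of its voxel centers. Voxel centers
underestimate anatomical extent by one voxel, so OBB edges are padded by
the projection of one voxel box onto each OBB axis before the volume is
minimized: a single voxel at 1 mm isotropic spacing measures
(1, 1, 1) mm, and an axis-aligned solid block of `a×b×c` voxels measures
exactly `(a, b, c)` mm. With this convention, an axis-aligned or clearly
elongated node's diameter is recovered within one voxel spacing (the
rasterization rule — a voxel belongs to a shape iff its center is inside
— bounds the per-axis error). For *weakly elongated or oblate* nodes the
estimator is biased upward by more than one voxel: rasterization makes a
compromise orientation the true minimum-volume box of the voxel object
(verified against the exhaustive rotation-grid oracle), so its short
edge can exceed twice the smallest semi-axis by several voxels — e.g. a
1.25 cm near-oblate node measuring 1.7 cm at 1 mm isotropic voxels. This
is a property of the minimum-volume-box measurement itself, not of the
search; about 71% of randomly oriented phantom nodes recover within one
voxel and 82% within 1.5 voxels.

The OBB search is a candidate-orientation search: convex-hull
face-aligned frames with an exact in-plane minimum rectangle per face,
the principal-axis frame, a coarse 12° rotation grid, and a Nelder–Mead
refinement of the best candidate, all minimizing the *padded* volume.
The test suite checks it against an exhaustive 1°-rotation-grid oracle
(within 2% volume on random small components). Node **volume** is
reported as voxel count × voxel volume; the OBB volume is also exposed
(`Lesion.obb_volume_cm3`) but would systematically overestimate a
rounded node, so it is not the default.

"Contiguous voxels" defaults to 26-connectivity (nodes are compact 3D
blobs); 6 and 18 are available. The suspicious filter is strict
(`> 0.8 cm`): a node measuring exactly 0.8 cm is not suspicious. The
"largest" node is the one with the largest short diameter, ties broken by
volume and then label id; its fields are reported even when no node
exceeds the cutoff, and are absent only for an empty segmentation.

## Segmentation network

The segmenter is a standard 3D U-Net: two (3×3×3 convolution → instance
normalization → ReLU) blocks per resolution level, channel doubling per
level, 2×2×2 max pooling, 2×2×2 transposed-convolution upsampling, skip
concatenation, and a 1×1×1 sigmoid head producing per-voxel foreground
probability (binarized at 0.5 by default). Spatial dimensions must be
divisible by 2^(depth−1).

Training minimizes the soft Dice loss
`1 − (2Σpt + ε)/(Σp + Σt + ε)` with ε = 10⁻⁶ (small enough that the loss
is 0 exactly at a perfect binary prediction and matches hand arithmetic
on toy grids; Dice-type losses handle the extreme foreground/background
imbalance of small nodes better than cross-entropy). The optimizer is
Adam at initial learning rate 10⁻⁴. Augmentation applies, each with
probability 0.5 per sample per epoch: a skew (rotation about a random
principal axis, 0–5°), a shear in a random coordinate plane (0–5°), and
a translation of up to ±10% of each axis — images warped trilinearly,
masks by nearest neighbour. The sigmoid head's bias is initialized to −4 so
the network starts near the foreground prior (~1–2% of voxels are node)
instead of 0.5 — without this the background term dominates the Dice
denominator and the first several hundred steps are wasted deflating it.
Early stopping monitors validation loss with a patience counter and
restores the best-validation weights; the full-scale recipe caps at 300
epochs, the desk-scale runs at 24-30. Every input volume is z-score
normalized (the network never sees raw scanner units); an 8:1:1 split
utility is provided for phantom experiments.

The layers are implemented directly in numpy. Convolutions flatten the
padded volume per channel so each kernel offset is a slice of one long
array, accumulated with BLAS `sgemm` (β = 1); the backward pass reuses
the same machinery for the input gradient (flipped kernels) and computes
weight gradients from corner-embedded gradient buffers. A full
forward+backward on a 32×96×96 volume with a depth-3, 8-channel network
takes ~1.5 s on one CPU core, which puts a 24-epoch, 20-phantom training
run at roughly 14 minutes. Desk-scale training uses batch size 2 (the
full-scale recipe's batch of 10 would give only two gradient steps per
epoch with 20 training volumes).

## Phantoms

The generator emulates what makes nodal DWI reading hard, not pelvic
anatomy: ellipsoidal bright nodes (random orientation, short diameter
0.4–1.6 cm by default, moderate elongation ×1.0–1.6) on a dark
background, plus bright *tubular* distractors (capsules swept along
random polylines, radius 1.5–3 mm, intensity 0.75–0.95 of node
intensity) that mimic vessels/ureter/bowel — structures that look
blob-like in any single slice and are the main source of false
positives. A Gaussian partial-volume blur (σ = 0.6 voxel) and additive
Gaussian noise (sd 0.1 of node intensity by default) complete the image.
Default grid: 32×96×96 at (3, 1.5, 1.5) mm — the anisotropy of an axial
pelvic stack at desk scale; the full 64×256×256 network grid is
supported. Nodes are placed by rejection sampling with mutual clearance
so the truth mask always has exactly `n_nodes` 26-connected components,
and identical spec+seed is bitwise reproducible.

Deliberately not modelled: Rician noise statistics, coil-sensitivity
shading, susceptibility distortion, anatomy. Consequently, passing tests
demonstrate that the pipeline's machinery (training dynamics,
measurement, staging logic, metrics) is correct — not that the network
would reach any particular accuracy on patient data.

`degrade_mask` turns a perfect mask into a controllable imperfect
segmentation (independent boundary-voxel flips; whole-component drops),
so the evaluation stack can be tested without a trained network.

## Evaluation

Voxel metrics come from the confusion between prediction and reference:
Dice = 2TP/(2TP+FP+FN), PPV = TP/(TP+FP), TPR = TP/(TP+FN),
VS = 1 − |FN−FP|/(2TP+FP+FN). Note VS = 1 whenever FP = FN — even for
disjoint masks of equal size; this is asserted in the tests as a
documented property. Distance metrics operate on foreground voxel-center
point sets in mm: HD and AVD take the larger of the two directed values
(max, respectively mean, nearest-neighbour distance); for components
above 10⁴ voxels they are restricted to surface voxels, which leaves the
result unchanged for solid components. The Mahalanobis distance between
the set means uses the pooled within-set covariance
`S = ((n_A−1)Cov(A) + (n_B−1)Cov(B))/(n_A+n_B−2)`, ridge-regularized by
10⁻⁶·trace(S)/3 near singularity; under identity pooled covariance it
reduces to the Euclidean distance of the means, and it is invariant to a
common invertible linear map. Undefined metrics (empty mask, zero
denominator) are reported as explicit `None`, never coerced to 0 or 1.

Detection is overlap-based: a reference node is detected as soon as any
predicted voxel overlaps it (no IoU threshold). One predicted component
spanning k reference nodes detects all k and is not a false positive; a
reference node hit by several predictions is one true positive.
Suspiciousness is decided on each side by that side's own measured short
diameter; a suspicious prediction overlapping any reference annotation is
not counted as a false positive. F1 is the harmonic mean of precision
and recall, reported as 0 with an explicit `degenerate` flag when either
is undefined. Patient-level AUC of the hard N0/N1 classifier is the
single-operating-point ROC trapezoid, (sensitivity + specificity)/2.
Cohen's kappa is computed from observed and marginal-expected agreement;
Bland–Altman limits use the sample (n−1) standard deviation and
bias ± 1.96 sd.

## Numerical and degenerate-input choices

- z-score of a constant volume is all zeros (not NaN).
- Resampling preserves physical extent (spacing rescaled by shape
  ratio); nearest mode for masks never introduces new values.
- OBB of a single voxel: axis-aligned, extents equal to the spacing.
- Empty lesion set: report has stage N0 and absent largest-node fields.
- Non-finite training loss raises a training error carrying the epoch.
- All stochastic components (phantom placement, weight init, shuffling,
  augmentation) are driven by explicit integer seeds.

## Known limitations

- The numpy network is single-sample (gradient accumulation over a
  batch); it is meant for desk-scale experiments, not full-resolution
  clinical training.
- The OBB candidate search is not a certified global minimum; the 2%
  oracle bound is empirical over the tested component family.
- Phantom realism is intentionally limited (see above); reported phantom
  Dice says nothing quantitative about patient data.
- Lesion-wise metric aggregation across patients follows a
  per-patient-then-average convention where needed; other conventions
  exist and would change third-decimal results.
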