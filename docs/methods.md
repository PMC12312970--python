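# Methods

This note documents the models, conventions and numerical choices behind
`nucleomorph`, what the synthetic phantoms do and do not emulate, and the
known limitations.

## Image model and conventions

All images are scalar intensity arrays indexed `(z, y, x)` (2D images
`(y, x)`), carried with their physical voxel spacing in nm.  The default
acquisition geometry is 120 nm laterally and 150 nm axially, the settings
of the confocal stacks this pipeline targets; single-plane 35 nm-pixel
images serve the FRC analysis.  Distances stated "in voxels" (the watershed
merge rule) are isotropic voxel units; every physical quantity
(volume, surface, radii, radial distance) uses the per-axis spacing.
Integer images are rescaled to [0, 1] by their dtype maximum before
intensity statistics; float images are assumed already normalized.

## Feature bank

Nine feature maps per smoothing scale plus the raw intensity.  Scales
(default {1, 2, 4, 8}, stated in x/y voxel units) are divided per axis by
the spacing ratio so the physical smoothing length is isotropic.  Choices
within the bank:

- "derivatives" is implemented as the rotation-invariant gradient
  magnitude rather than per-axis partials, for classifier stability under
  orientation.
- The Hessian feature is the largest-magnitude eigenvalue: one map per
  scale, keeping nine families per scale.  Pure second derivatives are
  computed as two first-derivative passes of σ/√2 each so a constant image
  maps to exactly zero (one sampled second-derivative kernel leaks a small
  DC term at sub-voxel sigmas); the Laplacian is the Hessian trace.
- The structure-tensor feature is the largest eigenvalue of the
  Gaussian-integrated tensor of the scale-σ gradients.
- Canny edges have no canonical 3D form; the stand-in is gradient
  magnitude with non-maximum suppression along the interpolated gradient
  direction, per scale.
- Local mean/variance use a cubic reflected window of side 2σ+1 per axis.
- DoG is Gaussian(σ) − Gaussian(1.6σ), the standard blob-detection ratio.

## Segmentation

Step 1: a scikit-learn Random Forest (default 200 trees, seeded,
optionally subsampled per class to bound training cost) classifies voxels
from the feature bank; the nucleus-probability map is thresholded
(default 0.5) and holes are filled in 3D.  Objects below
`min_object_size` (default 500 voxels ≈ 1 µm³, settable to 0) are
dropped as debris before splitting.

Step 2 (shape-based splitting): seeds are local maxima of the Euclidean
distance transform of the mask with height ≥ `seed_threshold`
(default 2 voxels).  Distance-transform maxima, not intensity maxima, are
used: splitting is by shape, and the EDT peak is the standard shape seed.
Any two seeds at Euclidean distance < `min_seed_separation`
(default 10 voxels, strict inequality — "closer than 10 voxels are not
separated") are merged by union-find into one marker; a
marker-controlled watershed on the inverted EDT then partitions the mask.
The merge distance is seed-to-seed, in voxel units.  Consequences covered
by tests: merging is monotone in separation, the boundary sits exactly at
the configured value (splits first at 10 with the default), watershed
neither adds nor removes foreground voxels.

## Morphometry

- **Volume**: voxel count × physical voxel volume.
- **Surface**: marching cubes at level 0.5 on the zero-padded label with
  physical spacing.  The binary volume is first smoothed with a Gaussian
  of 1 voxel (`smoothing_vox`): meshing a raw binary overestimates smooth
  surfaces by ~9% through staircase facets, and one voxel of smoothing
  brings voxelized ellipsoids at acquisition spacing within 1% of the
  quadrature-exact area.  The smoothing rounds sharp edges, so it is a
  parameter (set 0 for polyhedral shapes, where the raw mesh is accurate).
- **Compactness**: `C = V²/S³` as printed in the source method, emitted
  together with `36π·V²/S³` (sphere = 1).  The raw formula gives ~0.0088
  for a sphere, which is incompatible with reported values around
  0.18–0.20 for near-spheroidal nuclei; both columns are emitted and the
  discrepancy is documented rather than resolved.
- **Ellipsoid fit**: eigen-decomposition of the second central moments of
  the voxel coordinates in physical units; for a solid ellipsoid the
  moment along a principal axis is r²/5, hence `rᵢ = √(5λᵢ)`.
- **Elongation**: `r1/r2` with r2 the intermediate semi-radius ("the two
  main radii"); a config switch (`elongation_mode="smallest"`) gives
  `r1/r3` since the original definition of r2 is ambiguous.
- **Chromatin density**: Σ(normalized intensity)/V with the total
  normalized per voxel volume, i.e. the mean normalized intensity over the
  label — a uniform unit-intensity nucleus measures exactly 1.  The
  absolute scale of previously reported densities is not recoverable
  without the original raw data; this normalization makes values
  comparable across acquisitions and bit depths.
- **G1 gating**: mean CDT1-marker intensity ≥ threshold (inclusive),
  default 0.1 on the normalized scale.

## Radial chromatin distribution

Within each nucleus the Euclidean distance transform (physical units) is
normalized by its maximum, so 0 is the envelope and 1 the deepest interior
point; marker intensity is averaged in equal-width distance bins.  The
peripheral-enrichment index divides the count-weighted mean intensity of
bins below `shell_fraction` (default 0.2) by that of the remaining bins.
Per-nucleus normalization makes nuclei of different sizes comparable; the
index is invariant to global intensity scaling and is reported as this
package's own operationalization of peripheral-vs-central localization —
the source study states that contrast only qualitatively.

## Fourier ring correlation

Inputs are mean-subtracted and Hann-apodized (edge discontinuities
otherwise inflate high-frequency correlation), Fourier transformed, and
correlated over annular rings: `FRC(r) = Re Σ F_A·conj(F_B) /
√(Σ|F_A|²·Σ|F_B|²)`.  Ring width is stated in frequency bins of the
smaller image dimension.  The resolution is the inverse of the first
crossing of a threshold, located by linear interpolation between adjacent
rings; with no crossing the result is "not determined" (None), a valid
outcome.  The fixed 1/7 threshold is the default (the field's dominant
convention; the source does not state its criterion) — any other
threshold value can be passed.  For single acquisitions,
`checkerboard_split` builds two half-images from complementary
checkerboard pixel sets (alternate columns with a one-pixel shear on odd
rows), halving the pixel count and doubling the column spacing.  Hann
leakage spreads the spectrum by ~2 frequency bins, which bounds how
sharply a band edge can be localized; tests therefore use ring widths of
2–3 bins.

## Synthetic phantoms

Phantoms are textured solid ellipsoids: interior intensity
`background + intensity × texture`, where the texture is a smoothed
Gaussian random field rescaled to [1−a, 1+a] (default a = 0.2,
correlation length 600 nm) — heterogeneity without a claim of biological
realism.  The stack is convolved with an anisotropic Gaussian PSF
(default σ = 130 nm lateral, 300 nm axial, a generic confocal-like blur)
and corrupted with Gaussian noise (default sd 0.02 of full scale;
Poisson noise optional).  Ground truth per nucleus is analytic: volume
4/3·π·r1·r2·r3, surface by adaptive quadrature of the parametric surface
element (no closed elementary form exists), elongation r1/r2, density
= interior intensity + background.  All outputs are bit-reproducible from
(spec, seed).

The two-population generator draws volume, elongation and chromatin
density from normals truncated at physical bounds (V > 0, E ≥ 1,
0 < D ≤ 1−background), builds prolate nuclei (r2 = r3) with random
orientation, and renders each sample in its own stack.  The default
groups encode the studied contrast — 638 vs 486 µm³ volume, 1.34 vs 1.86
elongation, 0.254 vs 0.319 density, n = 20 per group — with ~15%
coefficient of variation for volume and density and SD 0.2 for
elongation, chosen a priori as typical biological variability
(the source reports no dispersions).

What the phantoms do **not** emulate: nucleoli and lamina substructure,
STED photophysics, depth-dependent aberrations, uneven illumination and
autofluorescence.  A green pipeline test therefore establishes
correctness of the computation on well-posed images, not robustness to
every real acquisition artifact.

Known systematic effect: the PSF bleeds boundary intensity out of the
mask, so measured chromatin density reads ~3–5% below the generator's
interior intensity (size-dependent).  Volume and elongation, being
mask-based on ground-truth labels, are unaffected; the effect is common
to both groups and leaves group contrasts intact.

## Statistics

Group comparisons use the classic pooled-variance Student's t-test
(two-sided), matching the stated method; Welch's correction is available
via a flag.  Stars follow the inclusive mapping *p ≤ 0.05, **p ≤ 0.01,
***p ≤ 0.001.  Comparative-Cq averages technical replicates per
(sample, gene) before ΔCq = Cq_target − Cq_ref, then
ΔΔCq = mean ΔCq(group) − mean ΔCq(control) and fold = 2^(−ΔΔCq); this
makes the fold invariant to any constant Cq shift.  Amplification
efficiency is assumed to be 2 (no efficiency correction).  Plate-array
normalization is (signal − blank)/(reference − blank) per group,
expressed as percent of the control group's normalized value; a
reference signal at or below blank is an error.  No multiple-testing
correction is applied, matching the source analysis.

## Limitations

- The voxel classifier is trained per experiment (interactive annotations
  or phantom ground truth); no pre-trained model ships with the package.
- The compactness scale ambiguity above is inherited, not resolved.
- FRC on a checkerboard split shares noise between half-images at the
  highest frequencies; with strongly correlated noise the estimate is
  optimistic, as with any single-image FRC.
- Proprietary microscope formats (LIF/ND2) are out of scope; convert to
  OME-TIFF first.
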