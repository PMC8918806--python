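# Methods

This note documents the models and numerical choices behind `vasquant`, in
the spirit of a methods section: what each stage computes, which parameters
matter, what the synthetic phantoms do and do not emulate, and where the
open design decisions were resolved.

## Coordinate and data conventions

Volumes are `(z, y, x)` arrays with explicit per-axis physical spacing in
µm; there is no default spacing — it must come from acquisition metadata or
configuration.  Voxel `(k, j, i)` has physical centre `(i·sx, j·sy, k·sz)`;
index bounds are half-open.  Masks store foreground (vessel) = 1; an
`inverted` I/O flag reads/writes the 0 = vessel, 255 = background convention
used by some Fiji-based pipelines.  Rigid transforms act on physical
`(x, y, z)` coordinates as `p ↦ R(p − c) + c + t` and serialise as 4×4
homogeneous matrices.

## Segmentation

**Slice jitter correction.**  Consecutive z-planes are registered by plain
(un-whitened) phase correlation with 10× sub-pixel upsampling.  Consecutive
planes of genuine 3D anatomy also shift — an oblique vessel walks across
slices — so the cumulative shift series is high-pass filtered: a running
median over ~9 slices estimates the anatomical trend and only the residual
(abrupt, single-slice) component is applied.  A constant stack is returned
unchanged with a degenerate flag.  Phase whitening was deliberately
disabled: on smooth, low-texture fluorescence slices it amplifies noise and
misses even large injected shifts.

**Tubeness.**  The Hessian is computed with Gaussian derivative filters at
per-axis σ in voxels (`σ_µm / spacing_axis`), γ=1 scale-normalised
(derivatives multiplied by `σ_i σ_j`).  The data are mean-centred first:
truncated Gaussian derivative kernels are not exactly zero-sum and a raw
intensity offset would otherwise leak into the Hessian.  The response is
the Sato bright-line measure `sqrt(λ2·λ3)` where both cross-sectional
curvatures are negative, zero otherwise; multiple scales combine by
voxel-wise maximum.  The response is invariant to additive offsets and
scales linearly with gain.

**Scale choice.**  The shipped default is a single fine scale of **1 µm**.
In validation, a multi-scale maximum over {1, 2, 4} µm placed a coarse-scale
halo around every vessel whose level coincides with the fine-scale response
at the true boundary; no global threshold can then separate the two, and
the segmented edge blurs by 1–2 voxels (phantom Dice capped near 0.89
however the noise was set).  A single fine scale localises the boundary
sharply for every caliber in the 5–20 µm diameter range — large vessels
present as bright boundary rings — and the lumen-filling step (below)
closes the interiors.  Multi-scale enhancement remains available by passing
several scales; enhancing at σ ≈ tube radius remains the right choice when
a lumenised (double-peaked) vessel must respond as one solid tube.

**Threshold.**  Otsu's criterion (maximise between-class variance) on a
256-bin histogram; 8-bit data use their native levels, other data are
re-binned over their range; ties break toward the lowest maximising bin and
the mask applies strict `>`.  Inside `segment_vasculature` the enhanced
image is first discretised to integer intensity levels (as when the
enhanced image is written back at source bit depth) and the histogram is
computed over the tubeness support (non-zero responses): the exact-zero
background mass otherwise dominates the between-class variance and drags
the threshold deep into the noise tail — a vessel-free noise volume would
segment ~30% foreground instead of (correctly) almost none.

**Lumen filling.**  Slice-wise 2D hole filling along all three axes,
OR-combined.  A tubular lumen is open at its ends and therefore never a
3D-enclosed cavity; per-axis 2D filling closes lumina of tubes in any
orientation without touching open background.

## Registration

**Landmark route.**  Kabsch/SVD least-squares rigid fit (no scaling) over
named, ordered landmark sets (≥3 non-collinear points; 11 is the typical
anatomical set).  Returns the RMS residual; with isotropic coordinate noise
σ on the target set the expected residual is `σ·sqrt(3(N−2)/N)` (3N
coordinates minus 6 rigid degrees of freedom), which the Monte-Carlo test
verifies.

**Automatic route.**  A full Euler-angle grid (default 30° step) is scored
at the coarsest level of a downsampling pyramid (default factors 6, 4, 2).
For each orientation the optimal translation is solved exactly by FFT
cross-correlation; orientations are ranked by normalised cross-correlation
rather than raw SSD because the interpolation mass shed by off-lattice
rotations makes raw SSD favour degenerate orientations.  The five best
candidates are refined by Nelder–Mead on the Euler angles through the finer
pyramid levels (an explicit initial simplex of one 5° step per axis is
essential: the default simplex at a 0° start cannot move), and the final
sub-voxel translation comes from upsampled cross-correlation at full
resolution.  The returned objective is the final SSD; a result whose
post-registration Dice is below 0.2 is flagged low-confidence.  On tree
phantoms displaced by 10°/15 voxels the recovered transform is within
~0.3°/0.1 voxel and post-registration Dice ≥ 0.97.

**Population average map.**  Voxel-wise mean of co-registered binary masks;
`mean·n` is the integer per-voxel overlap count, and the global mean equals
the mean foreground fraction of the inputs.

## Similarity

Dice, Jaccard and target overlap (`TO = |M∩T|/|T|`, denominator = the
reference mask) from exact voxel counts; both-empty inputs report 0 with a
degenerate flag, an empty reference leaves TO undefined.  Mutual
information uses a 64-bin joint histogram on min–max-normalised intensities
(binary inputs use the exact 2×2 table), log base 2.  SSIM follows the
Wang et al. formulation (K1=0.01, K2=0.03, Gaussian window σ=1.5, 11-pixel
window clamped for small slices), computed per z-slice and averaged, with
the dynamic range from the reference dtype unless overridden.  MSE = SSD/N
holds exactly by construction.

## Morphometry

Volume, exposed-face surface (6-connectivity; out-of-bounds counts as
background, so ROI faces are surface) and density are measured at full
resolution inside the ROI; the mask is then laterally downsampled to 512 px
(bilinear, re-binarised at 0.5) when wider, before the distance-map and
skeleton stages — the processing order used for full-size 1920² stacks.

The EDM is the exact Euclidean distance transform, in voxel units by
default (matching pixel-based practice on the downsampled grid) with a
spacing-aware µm variant.  The skeleton comes from Lee-style 3D thinning
(layer-by-layer removal, preserves 26-connectivity).  Network length is
primarily the skeleton voxel count; the calibrated variant sums
{1, √2, √3}-scaled steps over the **minimum spanning forest** of the
26-connected skeleton graph (a plain sum over all adjacent pairs
over-counts combinatorially inside thick-junction clumps).  For geometric
comparisons an optional corrected estimator applies the standard chamfer
weights for unbiased digital line length (a voxel path zig-zags around an
oblique line, inflating plain step sums by 5–8%) and reconstructs retracted
tips from the EDM (an endpoint pulled δ voxels back from a round cap of
local radius R has EDM = R − δ).

Branch points are skeleton voxels with ≥3 26-connected skeleton
neighbours.  Raw junction-voxel counts inflate at thick junctions, so
junction voxels are clustered: touching voxels always merge, and when the
EDM is available the merge reach extends to the local vessel radius —
thinning a thick bifurcation wedge can emit junction voxels several voxels
apart that belong to one anatomical branch point.  Both clustered and raw
counts are reported.  Mean vessel radius is the mean EDM value over
skeleton voxels (the skeletonised distance map).

Sholl analysis runs on the 2D maximum-intensity projection of the skeleton
with concentric circles (default maximum radius 700 voxels, 5-voxel steps,
matching common whole-brain settings); each circle is sampled at ~1/3-pixel
arc steps and the intersection count is the number of connected angular
runs of foreground, so a branch crossing a shell obliquely over several
samples counts once.  The centre is anatomical and therefore user-supplied;
`quantify_region` falls back to the skeleton MIP centroid when none is
given.

## Symmetry

The midline is a straight line fitted (PCA) to user-supplied axis points;
an in-plane rotation about z brings it parallel to image y.  The midline
x-column is the mean x of the aligned axis points rounded to the nearest
half-integer — a half-integer midline is the plane between two columns, the
natural case for an even-width bilaterally symmetric volume.  Reflection
maps column x to `2·mid − x`, a bijection on the lattice, so foreground
counts are preserved exactly and the operation is an involution.
Hemisphere volume and skeleton length reuse the morphometry operators
unchanged; the left–right Dice compares the left hemisphere with the
mirrored right, and the overlap mask marks voxels that are vessel on both
sides.

## Phantoms

Geometry lives in voxel units on the default 128×256×256 grid at
(0.5, 0.33, 0.33) µm.  Tubes rasterise by voxel-centre-in-tube inclusion;
a free-standing straight tube is capless so its voxel count tracks the
analytic open-cylinder volume, while tree segments carry spherical caps for
gap-free joints.  Axes are integer-centred: a perfectly symmetric
even-diameter digital tube is a thinning pathology (its medial axis falls
between voxels and layer-by-layer removal deletes it entirely).

Trees grow from a +y root by repeatedly bifurcating a random tip until
exactly `n_bifurcations` internal nodes exist (parametrised by bifurcation
count, not depth, so any branch-point count is constructible).  Defaults:
trunk radius 12 voxels (≈8 µm diameter — the caliber of basilar-artery
class trunks, mid-range of the 5–20 µm regime; children decay by 0.85 per
generation toward capillary caliber), branch angles 30–50°, segment lengths
40–60 voxels.  The angle floor and a clearance constraint (non-adjacent
segments keep two voxels plus radii apart) are what make thinning recover
the topology exactly: shallower elbows create elongated junction wedges
whose medial axis sprouts spurious junctions.  Symmetric phantoms grow one
hemisphere tree strictly right of the midline and mirror it; injected
right-only segments are recorded by their exact added voxel count.

Rendering paints solid tubes, or a bright wall shell with a dimmer lumen
(the double-peak cross-section of membrane-targeted reporters), then
applies Gaussian PSF blur (default σ = 1 voxel), Poisson shot noise on the
photon scale, additive Gaussian read noise (σ = 3) and a constant
background (10) under a vessel peak of 150 — a mid-quality light-sheet
acquisition.  All randomness flows through one named generator seeded from
the spec.

**What the phantoms do not emulate:** pigment shadows and absorption
artefacts, autofluorescence gradients, depth-dependent PSF broadening and
light-sheet stripe artefacts, anatomically realistic vessel curvature and
loops (the circle of Willis-like anastomoses), and movement during
acquisition beyond per-slice translation.  Passing the phantom suite
therefore demonstrates correctness of the operators and of the pipeline's
geometry handling, not robustness to every artefact of real acquisitions.

## Validation summary

The test suite checks every operator against an independent oracle
(exhaustive Otsu search, brute-force EDM, voxel-count overlap metrics,
closed-form clustering patterns, Monte-Carlo landmark residuals) and the
pipeline against phantom truth: radius recovery within ±0.5 voxel for
tubes of radius 2–6, exact branch counts for trees with 1–8 bifurcations,
centreline length within ±7.5%, registration recovery within 1°/1 voxel,
exact symmetry metrics on mirror-symmetric phantoms, and render → segment
→ quantify recovering the truth mask at Dice ≥ 0.9 with the branch count
within ±1.  `scripts/acceptance.py` recomputes all of these from scratch
for any seed.  Problem sizes in the tests (typically 64×160×128 phantoms;
the full 128×256×256 grid for registration and end-to-end runs) were
chosen to exercise the full geometry while keeping the suite fast.

## Known limitations

- Voxel-count network length under-counts oblique centrelines; use the
  corrected estimator for geometric comparisons.
- The one-voxel boundary shell dominates segmentation error for vessels
  thinner than ~5 voxels in radius; Dice against truth degrades
  accordingly even when the topology is recovered exactly.
- Automatic registration assumes the structures genuinely overlap within
  the search range; it flags, but cannot rescue, dissimilar pairs.
- Sholl analysis is 2D (on the skeleton MIP); overlapping vessels along
  the projection axis merge.
- Only rigid registration is provided; growth differences between samples
  are not modelled (affine/deformable alignment is out of scope).
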