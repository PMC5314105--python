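# Methods

This note records the models, parameter choices, and numerical decisions
behind `ieloc`, and what the synthetic phantoms do and do not demonstrate.

## Coordinate conventions

Voxel indices are 0-based; world coordinates are RAS millimetres obtained
by the volume's NIfTI affine; every contact coordinate is stored in world
mm. "Conformed space" is modeled simply as the T1 grid — re-conforming to a
fixed matrix size is a preprocessing implementation detail, not part of the
method. Whether clinical exports use scanner RAS or surface RAS varies by
site; this package documents and uses volume-affine RAS throughout.

## Registration

The similarity metric is Studholme's normalized mutual information
(H(A)+H(B))/H(A,B) on a 64-bin joint histogram of the overlapping field of
view; voxels leaving the moving image's field are excluded rather than
zero-filled, and a constant image is assigned NMI = 1 (zero-entropy
convention). The optimizer is Powell's method over 3 Euler angles
(parameterized in degrees) and 3 translations (mm), run coarse-to-fine over
a 3-level pyramid (factor 2); rotations act about the fixed image's world
center so the parameters stay decoupled. The search is derivative-free and
seedless, hence bit-reproducible.

Every pyramid level is prefiltered with a Gaussian of 2 voxels before the
metric is evaluated. This is load-bearing: trilinear resampling smooths
image noise at off-grid positions but not at grid-aligned ones, which
biases histogram NMI *away* from alignment on noisy images; the prefilter
suppresses this interpolation artifact. On the standard phantom (2 mm
grid, 2%-of-metal CT noise) a 4/−3/2 mm + 5° misalignment is recovered to
within 0.4° and 0.05 mm.

The MNI transform is affine-only (12 parameters, same metric and
optimizer); nonlinear warping is out of scope, and a matrix estimated by
any external tool can be supplied as a text file instead. Per-level Powell
iteration caps (8/5/2 for affine, 15/15/5 for rigid) bound runtime; the
recovered parameters on phantoms are far inside the tolerances that matter
(scale/shear to ~1e-4 against a 2% requirement).

## ECoG segmentation

*Dual-mask strip.* Dilation of the brain mask is 2 one-voxel layers by
default (configurable); the size-difference rule treats a dilated-mask
cluster as skull if it has no overlapping basic-mask cluster or if the
voxel counts differ by more than 10% — exact equality would be destroyed
by the interpolation of the coregistered CT.

*Initial threshold.* The package uses Otsu's threshold on the in-mask
intensities, splitting tissue from bright structures (skull remnants,
metal). A high-percentile rule was considered and rejected: electrode
metal occupies far less than 0.5% of mask voxels, so a 99.5th-percentile
threshold collapses onto the brain-tissue intensity on clean images and
selects the entire brain. Otsu behaves correctly on both noisy and
noise-free images, and the iteration only needs a starting point *below*
the final level since it adjusts upward.

*Threshold iteration.* The threshold grows by a factor 1.05 per round (at
most 100 rounds); after each re-clustering the near-neighbor filter
(radius 15 mm, minimum 2 neighbors — interior contacts of a 10 mm-pitch
array have 4 neighbors at 10 mm and diagonals at 14.1 mm) is re-applied,
and the loop stops inside the ±5% band around the predefined count. If the
band is never hit the closest clustering is returned with a warning flag.

*Projection.* The brain-shift correction minimizes
α·Σ‖pᵢ−pᵢ⁰‖² + Σ(‖pᵢ−pⱼ‖−d⁰ᵢⱼ)² with α = 1 over the grid 4-neighborhood
(or any supplied edge list; a distance-rule edge inference is provided for
detected, unordered grids). Positions live on smoothed-pial vertices and
move by coordinate descent over the 12 nearest candidate vertices; a move
is accepted only if it lowers the energy, so the energy trace is
non-increasing by construction. Final positions map to the raw pial by
nearest vertex, which bounds the discretization of the result by the mesh
vertex spacing (~1 mm on the phantom meshes).

## SEEG tracking

The eroded-mask strip uses an exact Euclidean erosion (distance transform
≥ depth, default 4 mm). The default cluster threshold is Otsu's value
floored at the midpoint between the in-mask median and maximum; either can
be overridden, mirroring the interactive threshold adjustment of a manual
workflow. Cluster-to-electrode assignment is explicit (electrode name →
cluster ids); an automatic single-linkage grouping on minimum
voxel-to-voxel distance (link 6 mm: above the 5 mm gap left by one missing
contact, far below inter-electrode separations) covers well-separated
implants.

Trajectories are per-axis polynomials (order 1–4, default 3: insertion
bends depth electrodes, and a cubic absorbs what a straight line cannot)
in the principal-axis projection rescaled to [0, 1], resampled at uniform
arc length (0.1 mm dots) by inverting the numerically accumulated
arc-length integral. The reported fit residual is the *centerline*
residual — binned intensity-weighted centroids versus the curve — because
the raw voxel RMS measures the cylinder's radial spread (~0.5 mm) even for
a perfect fit.

Tracking starts at the endpoint with the larger distance-transform depth,
refines each contact by an intensity-weighted centroid in a 1.5 mm ball
(contact half-length plus margin), iterated 3 times so an off-center seed
does not leave a truncation bias, and steps 3.5 mm of arc length past each
accepted center. Two constraints guard the refinement, both resolving in
favor of the curve seed: the fixed inter-contact distance (tolerance
0.35 mm) and a maximum turn angle of 10° between successive inter-contact
vectors — large enough for genuine bending, small enough to reject
noise-driven jumps; the angle threshold is a config parameter since no
canonical value exists. When the bright support ends (peak below 25% of
the trajectory's maximum), remaining centers are extrapolated along the
curve at the fixed spacing and flagged `padded`; padding fills only beyond
the last detected contact, not interior gaps.

Accuracy scales with voxel size: at 0.5 mm voxels the 0.8 mm contact
cylinders are resolved and tracked centers land within 0.05 mm of truth
(every consecutive spacing within 1.5% of 3.5 mm); at the clinical 1 mm
grid, sub-voxel quantization of the thin cylinders leaves ±0.2 mm
per-contact scatter, while the *mean* spacing stays within 0.05 mm of
3.5 mm and axis-aligned electrodes are recovered essentially exactly.

## Labeling

ROI voxel membership is center-in-sphere with no partial-volume weighting —
the simplest testable reading of a voxel-percentage rule. Inclusion counts
ROI voxels carrying any nonzero label (unlabeled-within-ROI is the
exclusion definition; out-of-brain voxels are not treated separately). A
contact is gray matter only if inclusion strictly exceeds exclusion;
otherwise it is reported as white/unknown with no area. Among candidate
areas the largest voxel fraction wins; an exact tie goes to the smaller
label index, deterministically. MNI ROIs are regenerated on the template
grid at the modality radius (3.5 mm SEEG / 5 mm ECoG) after the affine
maps the centers; a center leaving the template bounding box flags the
record and yields no atlas label rather than failing the run.

## Display math

The density kernel is the standard isotropic Gaussian with
c = FWHM/(2√(2 ln 2)) (natural logarithm) — the unique reading consistent
with the name "full width at half maximum" — evaluated analytically per
voxel (no discrete convolution), so an isolated electrode's peak equals
its weight regardless of grid alignment; contributions are truncated at
5c. Weights default to 1 (density maps) and are otherwise taken as given
numbers (e.g. spectral power), with no normalization imposed.

The peri-coronal construction follows the printed convention that the
"coronal" view normal is (0, 0, 1) (axial (0, 1, 0), sagittal (1, 0, 0)).
The rotation axis Vₐ = V_c × V_r and angle θ = acos(V_c·V_r) define the
rotation carrying the view normal onto the electrode direction; the
displayed slice is the plane spanned by V_c and V_r (normal Vₐ), which
contains the full electrode while preserving the view axis, and
degenerates to the ordinary orthogonal slice when the electrode is
parallel to the view normal (θ ∈ {0, π}, flagged "no rotation"). At the
resolving 0.5 mm voxel size every contact of an oblique electrode appears
in the single slice at ≥ 99% of the volume peak; at 1 mm the thin contacts
interpolate to 60–90%.

Isosurfaces come from marching cubes on the volume grid followed by
uniform-weight Laplacian smoothing (λ = 0.5 per pass); smoothing strictly
shrinks convex surfaces, and 0 passes returns the raw vertices. On an
antialiased ball the half-level surface area matches the analytic sphere
to 0.2%; on a hard binary mask marching cubes overestimates area by ~9%
(staircase effect), which the smoothing passes remove.

## Validation statistic

The surface-crossing point of an oriented trajectory is its first
segment–triangle intersection with the pial mesh, walking from the deep
end over the resampled dots (extended past the fitted extent so the
crossing is reachable); electrodes that never pierce the mesh are flagged
and excluded. Consistency between two point sets is the Pearson
correlation of their matched pairwise Euclidean distances — invariant to
any rigid motion of either set, so it isolates geometry from alignment.
The detection rate used for grid evaluation counts true contacts matched
within 2 mm (half the 4 mm contact diameter) under an optimal one-to-one
assignment that maximizes the number of within-tolerance matches. The
phantom validation uses true 3-D surface points as the reference, which is
strictly harder than comparing against a 2-D projection of them.

## The phantom

The synthetic head is an ellipsoidal brain (default radii 55 × 65 × 50 mm,
1 mm isotropic grid, world origin at the grid center) with three
asymmetric CSF-filled interior structures visible in both modalities —
without internal structure the CT↔T1 registration of a smooth ellipsoid is
rotationally ill-conditioned, as a real brain never is. The brain mask
carries a 2 mm margin beyond the pial surface (a skull-stripped mask keeps
some CSF/dura), and the skull shell starts 2 mm beyond the mask with 3 mm
thickness: subdural disks on the pial are then fully interior to the basic
mask while a 2-layer dilation reaches the inner skull, which is the
geometry the dual-mask rule needs to be exercised. The parcellation is a
Voronoi tiling of the brain interior from 6 seeded points.

CT intensities are ordered background 0 < brain 40 < skull 1200 < metal
3000 (arbitrary units, CT-like contrast), with additive Gaussian noise of
σ = 60 ≈ 2% of the metal intensity by default — enough to make
segmentation nontrivial without overwhelming soft-tissue contrast.
Electrode metal is painted by 4³-supersampled partial-volume coverage with
a saturation knee (full intensity above 25% coverage), emulating metal
blooming and keeping contact voxels bright despite sub-voxel hardware.
Depth electrodes enter roughly radially over a polar cap with
golden-angle spread; an optional quadratic perpendicular offset (zero at
both ends, sagitta at mid-length) models insertion bending. Grid contacts
are placed by marching along the ellipsoid surface at the 10 mm pitch
(chord error ≈ 1% of pitch at these curvatures); synthetic brain shift
displaces them along the inward normal with a linear ramp across columns,
up to 3 mm.

What the phantom does not emulate: CT beam hardening and streak artifacts,
anisotropic clinical CT grids (0.42 × 0.42 × 0.8 mm is supported by the
data model but phantoms default to isotropic), gyral folding of the pial
surface (the energy projection is exercised on smooth convex meshes only),
electrode wires and connectors, and FreeSurfer's actual parcellation
geometry. Passing tests therefore demonstrate the correctness of the
algorithms under controlled geometry and noise, not clinical-grade
robustness to artifact-laden scans.

## Problem sizes and determinism

Tests and the acceptance script run on 160³ × 1 mm heads (0.5 mm where
contact-level resolution is the point, 2 mm / 96³ for the registration
searches — sizes chosen so each stage exercises the full algorithm at
realistic scale). All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the registration and segmentation loops are
seedless and deterministic, so identical configs reproduce outputs
bit-exactly.
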