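# Methods

## Problem setting

Serial CBCT scans of the same patient are compared by placing the follow-up
scan in the coordinate frame of the baseline scan with a rigid transform
estimated on structures assumed stable (superimposition). The quantities of
interest are (a) how accurately the transform is recovered, and (b) how
reproducible repeated superimpositions are, read off as closest-point
distances between the two bone surface models in four anatomic regions:
anterior cranial base (CB), forehead (FH), and the left/right zygomatic
arches (ZL/ZR). Two registration zones are compared: the anterior cranial
base (requires an extended-height field of view) and the left zygomatic arch
(visible in reduced-height, lower-dose scans).

## Coordinate and intensity conventions

A volume is a 3D scalar grid with `world(i,j,k) = origin + axes ·
(spacing ∘ (i,j,k))`, 0-based indices at voxel centers, spacing in mm.
Phantoms are axis-aligned (`axes = I`); oblique DICOM orientations are
honored on read. Intensities are signed floats on the Hounsfield scale
(air ≈ −1000, soft tissue ≈ 0–100, bone ≳ 250 HU). Rigid transforms are
`y = R(x − c) + c + t` with intrinsic Z-Y-X Euler angles in degrees at all
interfaces and matrices internally; they map moving-volume world
coordinates onto fixed-volume world coordinates.

## Synthetic phantom

The generator renders analytic solids into a pair of volumes:

| structure | solid | role |
|---|---|---|
| cranial vault | ellipsoidal shell (outer radii 28×34×20 mm, 2 mm thick) | CB (basal belt, z ∈ [−10, −2) mm of vault center) and FH (anterior patch) regions |
| cranial-base ridges | two 2.2 mm-radius cylinders crossing the vault base | part of CB; break the basal belt's rotational symmetry the way skull-base anatomy does |
| zygomatic arches | 240° torus arcs (major 8 mm, tube 2.4 mm) with a 4×5×4 mm zygomatic-body ellipsoid at the anterior end | ZL/ZR regions and the arch registration zone (zygomatic bone + process) |
| jaw block | axis-aligned box below the skull | the treatment change: translated by a displacement vector (default (2, 3, −1.5) mm) between timepoints |
| head | soft-tissue ellipsoid in air | grey-value context |

Default grid: 220×220×160 voxels at 0.4 mm (the scanner's canonical voxel
size) — a scaled-down skull that keeps registration fast; a `fullsize`
preset reproduces a 22×16 cm field of view, and `coarse` halves the
resolution. HU defaults: bone 1200, soft tissue 40, air −1000; optional
additive Gaussian noise in HU (independently per volume, seeded).

The fixed volume renders the scene at rest; the moving volume renders the
jaw-shifted scene at `T(x)` where `T` is the known true transform, so the
pair is related exactly by `T` with no second interpolation. Rendering
antialiases edges by 2× supersampling per axis, applied only to voxels whose
3³ neighborhood is non-uniform (exact on constant regions). Per-structure
ground-truth masks are voxel-center inclusion tests of the analytic solids;
for surface labeling they are dilated by 2 voxels (the iso-surface sits
slightly outside the solid boundary because the 300 HU level lies at ≈22%
bone coverage) with disjointness kept by the fixed priority CB > FH > ZL > ZR.

An optional reduced-height field-of-view crop keeps the inferior-most slab
(removing the cranial vault/base), with world coordinates preserved.

What the phantom does **not** model: real anatomy (surfaces are smooth
analytic solids with far less grey-value texture than bone), scanner physics
(scatter, beam hardening, cone-beam artifacts, metal streaks), true
segmentation ambiguity (teeth, thin trabecular bone), non-rigid change of
the "stable" structures over months, and inter-scanner differences. Passing
tests therefore demonstrate correctness of the algorithms and their
behavior under idealized conditions, not clinical performance; in
particular the phantom's absolute distance levels are much lower than
published patient values, which include real biological and acquisition
variation.

## Registration

Similarity: Shannon mutual information (bits) of the joint grey-value
histogram, hard binning, B = 64 bins over a clamp range of [−1000, 2000] HU.
Samples are fixed-volume positions inside the registration-zone ROI (the
structure mask dilated by 2 voxels); the moving volume is interpolated
trilinearly at the transform-mapped position; samples mapping outside the
moving grid are excluded and the count reported (a shrinking-overlap
pathology stays visible). At most 40 000 samples per pyramid level are used
(seeded subsampling).

Sample positions are jittered uniformly within each voxel (seeded), with
the fixed intensity interpolated trilinearly. This matters on near-noise-free
data with few distinct grey values: at voxel centers the moving-bin
partition can *refine* the fixed-bin partition over a whole neighborhood of
transforms, making MI exactly H(A) on a plateau (≈ ±0.05 mm wide) — jitter
restores a sharp, smooth optimum (measured self-registration error drops
from ≈0.07 mm to ≈0.0005 mm).

Optimization: three-level image pyramid (factor 2, block-mean downsampling;
levels whose downsampled ROI holds fewer than 500 voxels are skipped),
Powell direction-set search per level over (3 angles in degrees, 3
translations in mm) about the ROI centroid, initial steps 1°/1 mm,
parameter tolerance 10⁻³, MI tolerance 10⁻⁵, max 200 iterations; at the
finest level a second Powell pass restarts with 0.1× steps. The returned
transform never scores below the initialization (best-of safeguard). The
initialization comes from ≥3 paired landmarks by orthogonal Procrustes
(reflections excluded) or from an explicit transform file.

These optimizer settings, the histogram size, and the pyramid are this
package's own choices; the commercial tool that motivated the workflow
discloses only the metric, and nothing here claims to reproduce its
internals.

## Surface distances

Bone models are marching-cubes iso-surfaces at the segmentation threshold
(default 300 HU) in world mm, outward-oriented (flipped if the signed
volume is negative). Before extraction, volumes are smoothed with a
0.8-voxel Gaussian (configurable; 0 disables): this standard pre-meshing
step suppresses scan noise *and* the ≈spacing/8 iso-surface quantization
left by 2× supersampled rendering; without it a perfectly registered
noise-free pair already shows ≈0.06–0.09 mm regional means.

Distances are evaluated at the vertices of the follow-up (superimposed)
model against the baseline model — the direction is fixed and not
symmetric. Closest points are exact point-to-triangle results: a k-d tree
on triangle centroids proposes k = 8 candidates; any point whose best
distance does not already beat every unexamined centroid (k-th centroid
distance minus the largest centroid-to-vertex radius) is re-checked against
all triangles within `best + max_radius`, so the result equals an
exhaustive scan to machine precision. The sign is taken from the nearest
baseline triangle's outward normal: positive = in front of (outside) the
baseline surface, rendered green; negative = behind, rendered red; banded
colors use half-open bands `[k·w, (k+1)·w)` with w = 0.5 mm by default.

Regional summaries are mean/SD (n−1)/SE of absolute distances over labeled
vertices (a vertex is labeled by the region mask containing its enclosing
voxel); regions with fewer than two vertices are reported absent, not zero.
Regions larger than 20 000 vertices are subsampled deterministically.

## Statistics

Paired-sample t-tests on per-case differences: SE = SD/√n, df = n−1,
two-sided p, CI95 = mean ± t₀.₉₇₅,df·SE. Sample SD uses n−1 (this makes the
printed SE = SD/4 at n = 16 consistent). Zero-SD differences are reported
as degenerate (p undefined at mean 0, else below machine floor), never as a
numeric estimate. Pearson correlations require n ≥ 3 and non-constant
inputs. No multiple-testing correction is applied (5% significance
throughout). Derived cells (SE, CI, t, p) are always recomputed from
mean/SD/n; published tables contain two rows whose printed SE/CI/p are
internally inconsistent with their own mean/SD/n, and those cells are not
used as references.

## Study design

A study runs n = 16 synthetic cases. Per case: a random true transform
(translation ≤ 10 mm, rotation ≤ 10°, both uniform in magnitude and
direction, seeded), 50 HU noise, and five superimpositions — three on the
cranial base, two on the left arch (S1–S5) — each initialized from fresh
noisy landmarks (σ = 1 mm) plus an extra perturbation (σ = 1 mm / 1°),
emulating the operator redoing the semi-automated steps. Each
superimposition is scored by ground-truth recovery and by 4-region surface
distances; tables aggregate across cases (regional mean/SD/SE per repeat;
paired differences S1−S2, S4−S5, S4−S1; Pearson r per region).

Problem sizes used by the test suite and the acceptance script, chosen to
keep a full run on one CPU comfortable: parameter recovery and
self-registration run at the default 0.4 mm grid; the 16-case cohort runs
at 0.5 mm (176×176×128) with one registration per zone. The cohort
resolution matters for the zone-contrast mechanism: the arch ROI's voxel
count grows with resolution while the cranial-base ROI is already at the
sample cap, so only at sufficient resolution is the arch registration's
local precision reliably better than the cranial-base registration's
remote error at the arch (and the surface-distance floor low enough to
resolve the contrast).

## Numerical edge cases

Empty ROI, empty overlap, all-air segmentation, collinear landmarks,
constant correlation inputs and zero-variance differences all raise typed,
descriptive errors rather than returning silent values. MI of an empty
histogram is an error; 0·log 0 is 0 by convention. Inclusive (≥) comparison
at the segmentation threshold. Marching cubes requires an actual
iso-crossing. File geometry round-trips bit-exactly through NIfTI and
MHD; DICOM series are validated for single-series membership, shared
orientation and uniform slice spacing before any volume is built.

## Known limitations

Registration assumes rigid motion and HU-consistent scanners; no deformable
component, no groupwise registration, no GPU. The phantom's simplified
texture makes MI registration *easier* than on real scans at equal noise;
conversely its perfectly rigid "stable" structures make repeated
superimpositions agree more closely than patient data would. Distance-map
colors are per-vertex (no texture interpolation across large triangles).
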