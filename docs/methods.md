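# Methods

## Scene graph and the measurement model

The scene is a forest of nodes, each with a local transform of translation,
unit quaternion rotation and per-axis positive scale, composed in
scale–rotation–translation order (the dominant scene-graph convention).
World coordinates are right-handed, one world unit = 1 m. Internally every
transform is a 4×4 homogeneous matrix: composition and inversion are matrix
products, which keeps composites of anisotropic scale under rotation (which
have shear and no TRS form) exact; the TRS accessors decompose on demand
and refuse transforms carrying shear. Quaternions are normalised on
construction; pose-preservation assertions use a 1e-9 tolerance.

A volume enters the scene as a `VolumeNode` holding the user's pose/zoom
and flagged as the scene's unique *reference scale*; its internal
`image_space` child applies the fixed mm→world factor (1/1000 by default),
so anatomy lives at metre scale and children of `image_space` use physical
millimetres as local coordinates. Splitting the anatomical unit conversion
from the zoom is what makes the reference-scale correction dimensionally
clean: the accumulated uniform scale of the reference node is exactly the
user's zoom, 1 when untouched.

A measurement is a subtree under `image_space` with five children (start,
end, connector, label, label link). Distance is computed in world space and
divided by the reference node's accumulated uniform scale:
`d_mm = k · ‖world(end) − world(start)‖ / S`. Computing in volume-local
coordinates would be equally correct at rest but breaks during editing,
when an endpoint is re-parented to a controller and its local position is
controller-relative; the world-space route stays valid mid-edit. The
volume-local route is retained as `volume_space_distance`, an independent
cross-check valid whenever nothing is grabbed.

Editing uses grab/release: grab re-parents the element under the controller
while preserving its world pose (local transform rewritten through the
inverse parent world matrix); release restores the recorded original
parent the same way. Grabbing the connector redirects to the whole
measurement node so all five children move rigidly. Anisotropic scale
anywhere on the reference path is an error (`AnisotropicScaleError`), not
an approximation: the zoom correction is only defined for uniform zoom.
Near-isotropic scale (relative spread ≤ 1e-6) is accepted as its geometric
mean. How a renderer would propagate truly non-uniform parent scale through
rotated children is engine-specific, so the library refuses rather than
guesses.

## Display conventions

Reported distances are rounded to the tool's display precision — 0.1 mm
for the MPR reference tool and the immersive tool, 1 mm for the
screen-based volume-rendering tool — to the nearest multiple with ties away
from zero (the common clinical display convention; the rounding mode is a
parameter since vendors do not document theirs). Rounding goes through
`decimal` to avoid binary-float artefacts (3.45 at 0.1 mm must display as
3.5). Marker and label meshes are scaled by 1/zoom so their world size is
constant; dash layout of the connector places
`n = max(1, ⌊(d + gap)/(segment + gap)⌋)` segments centred symmetrically on
the chord. Marker geometry (sphere radius 1 mm, spoke length 4 mm) and dash
geometry (2 mm segment, 2 mm gap, at reference scale) are display defaults
with no measurement consequence.

## Volume I/O

NIfTI-1 and MetaImage are read and written through SimpleITK. Physical
space is LPS millimetres (DICOM convention; NIfTI's RAS is converted on
read by the reader). Continuous voxel indices are 0-based and
voxel-centred: `physical = origin + direction · (spacing ∘ ijk)`.

## Synthetic phantom and automated caliper

The phantom emulates the *appearance* of a scanned grey-scale calibration
phantom with cylindrical low-scatter inserts: binary cylinder masks (insert
intensity 30, background 180, arbitrary 8-bit-like units), optional
multiplicative unit-mean Rayleigh speckle (scale √(2/π), seeded), then an
isotropic Gaussian blur (σ = 0.3 mm default) standing in for the system
point-spread function. The default spec has three parallel cylinders of 4,
6 and 10 mm diameter, 14 mm long, in a 60×24×20 mm volume at 0.2 mm
default spacing, spaced so a caliper profile reaches a clean background
plateau before meeting a neighbour or the boundary. It is *not* an
acoustic simulation: no beamforming, attenuation, shadowing, anisotropic
or depth-dependent PSF, or scan-conversion geometry. Passing tests
therefore show the measurement and analysis machinery is correct on images
with known geometry — not that any tool performs identically on real
ultrasound.

The caliper samples the intensity profile along ± a direction through the
insert centre (step = half the smallest voxel spacing, linear
interpolation, out to 8 mm per side), estimates the insert plateau as the
mean within 1 mm of the centre and the background plateau as the mean of
the outermost 20% of each side, and localises each edge as the linearly
interpolated crossing of the half-contrast level (threshold fraction 0.5,
exposed as a parameter — half-contrast is the standard criterion for cyst
sizing). The diameter is the distance between the two crossings. Because
the criterion uses only the ratio between the two plateaus, the read-out is
invariant to affine intensity rescaling of the image.

Accuracy is limited by voxelisation and curvature: blurring a convex edge
pulls the half-contrast point inward by ≈ σ²/2R, i.e. ~0.01 mm for the
4 mm insert at σ = 0.3 mm, and binarisation contributes up to one voxel.
The worst case occurs when an insert boundary falls exactly on a voxel
centre while the profile line runs exactly between voxel rows (the default
10 mm insert at 0.4 mm spacing hits this alignment and reads one voxel
low). All read-outs are within one voxel of truth by construction of the
method, which is the guarantee the tests assert; at 0.1 mm spacing the
observed errors are ≤ 0.04 mm.

## Observer-study simulation

The protocol mirrors a five-reader comparison on 3D echocardiography: six
phantom tasks (three cyst sizes × horizontal/vertical) plus five standard
dimensions (aortic valve hingepoint, left atrial dimension, LV
end-diastolic, LV end-systolic, aortic end-systolic) on each of four
congenital-heart patient datasets — 26 tasks per reader. Patient truths are
a fixed table of plausible dimensions for four patients of increasing size
(pooled mean ≈ 28 mm, SD ≈ 13 mm, the scale typical of such cohorts);
phantom truths are the nominal diameters.

Observer error is applied to the *endpoints*, not the length: each endpoint
of a segment of the true length is perturbed by isotropic Gaussian noise of
the tool's sigma, and the perturbed chord length gets the tool's additive
bias and display quantization. Endpoint noise is the physically right
mechanism (the human error is edge localisation when placing a caliper) and
induces the correct positive length bias for short segments; the chord
length follows a 3-D noncentral-chi (Rice-analogue) law that the tests
check against numerical integration of its closed-form density. Default
tool models: reference MPR tool σ = 0.25 mm at 0.1 mm precision; the
screen-based 3D tool σ = 0.45 mm at 1 mm precision with a −1.57 mm bias;
the immersive tool σ = 0.70 mm at 0.1 mm precision with a +0.36 mm bias.
Sigmas are calibrated so simulated per-cell SDs across readers land in the
0.2–1.9 mm band observed in practice, and the biases reproduce the
systematic offsets such comparisons report; they are emulation parameters,
fixed once, not measurements of any product. A configurable number of
records is marked invalid uniformly at random (incorrectly recorded
observations), and all analyses use pairwise deletion.

## Evaluation statistics

Sample statistics use the n−1 denominator throughout (the usual choice for
small reader panels). Zero SD is representable — a 1 mm-precision tool can
make every reader report the same value — while an SD over fewer than two
values is NaN and flagged, never invented. Agreement counts pairs *strictly*
within the 2 mm threshold, pairs on (user, dataset, measurement), and fits
an ordinary least-squares regression of tool on reference with intercept
(flagged degenerate when the reference is constant). The paired t-test is
two-sided with df = n − 1; all-zero differences yield a "no variation"
result and identical nonzero differences an "infinite" flag rather than a
division error. Intra-user variability is, per (user, tool), the sample SD
of deviations from the per-(user, dataset, measurement) mean across tools;
combinations measured by fewer than two tools are excluded and counted.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated data.
Fine-resolution caliper checks use the default phantom at 0.1 mm isotropic
spacing (600×240×200 ≈ 29 M voxels, a few seconds to generate and
measure); convergence checks use a single-insert phantom at 0.4/0.2/0.1 mm
with blur tied to the grid (σ = 2·spacing) so the blur→0 limit is actually
approached; speckle-bias checks average 50 seeds at 0.4 mm. Statistical
calibration uses 1000 replicate null studies (two identical tools, 5
readers × 20 tasks) for the type-I error and 80 replicates for bias
recovery. Every stochastic path takes a NumPy `default_rng` seed;
fixed-seed runs are bit-reproducible, including speckle and record
invalidation.

## Known limitations

- Scene serialisation stores node trees (name, TRS, reference flag) but
  not volume pixel data; a deserialised `VolumeNode` round-trips as a plain
  node.
- The caliper assumes the profile reaches both plateaus within its maximum
  radius and that the centre given is inside the insert; it reports
  "edge not found" otherwise rather than extrapolating.
- The insert-overlap check treats cylinders as capsules (conservative: it
  can reject configurations that merely touch end-to-end).
- The phantom and observer simulators are appearance/statistics emulations;
  none of their parameters were fit to raw clinical data.
- 4-D (cine) data is handled only as a per-measurement frame index.
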