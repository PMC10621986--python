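# Methods

`zebra3d` reconstructs the 3-D pose of larval zebrafish from synchronized
multi-camera video of a water-filled glass tank. This note records the
models, the numerical choices behind them, and the limits of what the
synthetic tests demonstrate.

## Lab frame and cameras

The lab frame sits at the tank center with axes along the three camera
principal axes (right-handed, mm). Pixels are 0-based with centers at
integer coordinates, x right, y down. Each camera is a linear pinhole
model `[u, v, 1] ~ [x, y, z, 1] M K` (4x3 extrinsic times 3x3 intrinsic,
row-vector convention). The default simulated rig places three orthogonal
cameras 180 mm from the center with 2100 px focal length on a 648x488
sensor, so the central ~3 cm imaging volume fills the field of view at
roughly 15 px/mm.

### Refraction and the empirical projection

Inside the tank the mapping from lab points to pixels is bent by the
water -> glass -> air interfaces. Because the cameras are mutually
orthogonal and axis-aligned, each pixel coordinate depends only on one
transverse lab axis plus the camera's depth axis, so the projection
separates into two bivariate functions per camera; each is fitted as a
full bivariate cubic (10 monomials, least squares via QR). Calibration
correspondences come either from recorded dot-grid images or from the
built-in ray-tracing simulator, which solves the two-interface Snell
problem by a bracketed scalar root find on the exit-angle sine (total
internal reflection raises). The cubic basis cannot represent the exact
perspective division (`u = f x/(z+d)` is rational in depth), which floors
the fit residual at ~0.02 px over the calibrated volume — negligible
against the ~0.1 px dot-detection noise the calibration sees in practice.

Triangulation minimizes the squared pixel reprojection error of the
cubic projection with `scipy.optimize.least_squares`, started from the
tank center and bounded to the calibrated volume. On a simulated dot grid
with 0.1 px detection jitter the mean 3-D error is below 10 um; noiseless
round trips close to < 1e-6 mm.

Per-pixel rays (the reverse lookup) are obtained by inverting the
projection at three fixed depths (-30, 0, +30 mm; a seeded random mode
exists) and fitting a line; the stored origin lies on the plane through
the tank center perpendicular to the camera axis. Cross-view larva
matching scores every index triple by the maximum of the three pairwise
closed-form skew-line distances and accepts triples under `eps`
(default 1 mm) greedily by ascending score.

The dot-grid simulator replicates the planar target at four depth
offsets: a cubic in the depth coordinate needs at least four distinct
values, which the multiple target orientations of a real calibration
provide naturally.

## The body model

A pose is 22 adjustable parameters plus the length L: head position
(x0, y0, z0), head yaw/inclination/roll (theta0, phi0, gamma0, applied
Z-Y-X), and per-joint lateral and dorsal bending angles (dtheta_1..8,
dphi_1..8). The backbone is a chain of 9 rigid segments of length L/9;
segment directions accumulate the bending angles as azimuth/elevation in
the fish frame (X along the first segment, Y along the eye axis,
Z dorsal). The parameterization is invertible for |cumulative dorsal
bend| < pi/2, which covers observed swimming; the inverse
(`coordinates_to_pose`) fixes the roll sign by the never-belly-up
convention (dorsal axis has positive lab-z; gamma0 in (-pi/2, pi/2]).

Fixed body parameters (20 with L) describe the anterior: brightness and
(length, width, height) of eyes, head and belly, eye separation, and
placements along/off the first scaffold segment. The defaults
(L = 4.0 mm, eye separation 0.4 mm, eye 0.25x0.20x0.20 mm, head
0.60x0.40x0.40 mm, belly 0.70x0.40x0.40 mm, brightness 255:180:200) are
working values that produce plausible larva images; on real recordings
they would be estimated by template optimization, and every test here
depends only on self-consistency, never on these numbers.

### Rendering

The anterior intensity field is the maximum of four anisotropic Gaussian
densities (two eyes, head, belly) with covariance
`diag(dims)^2 / 16` — organ dimensions are specified as extents, not
variances, so the 2-sigma ellipsoid is matched to the stated size. Views are rendered by projecting every voxel center and
summing intensities per pixel (voxel pitch 15-30 um depending on
context; a fish-frame voxel template is cached and rotated per pose,
which is equivalent to re-voxelizing and much faster inside optimizers).
The tail is drawn in 2-D as eight trapezium/disk (capsule) segments on
the projected backbone with a Gaussian transverse profile
(sigma = L/40, scalable) and a linear longitudinal intensity falling
from 1.0 to 0.3 at the tip. Radiometric convention: the summed-voxel
anterior is normalized to the 8-bit scale per view before max-combining
with the tail, so the tail/anterior brightness ratio is fixed by the
model rather than by the voxel count; the final image is rescaled so its
brightest pixel is 255 and stored as uint8. Without this convention the
tail lands below realistic background noise and carries no cost signal.

The sprite cache ("fast" mode) stores orthographic anterior projections
over orientation and scale bins, and tail-segment patches over
orientation (5 degree steps), projected length (0.5 px), and subpixel
offset (0.2 px). Anterior orientation bins quantize the unit quaternion
(grid spacing matched to 5 degrees) rather than Euler angles, which
stay stable when the fish points into a camera. Fast renders correlate
with accurate ones at r > 0.85-0.93 on the rendered support.

## Synthetic training data

Real pose collections are dominated by straight larvae. The pipeline
resamples a collection uniformly over (mean |dtheta|, mean |dphi|) with
selection weights inversely proportional to a 2-D Gaussian KDE (density
floored at the 0.1% quantile before inversion), fits an 18-dimensional
Gaussian KDE (single scalar bandwidth, cross-validated over 50 values in
[0.01, 0.1] rad with 20-fold 1:9 splits) to the angle block, and samples
new poses: angles from the KDE, positions uniform in the imaging volume
(default the central 3x3x3 cm), yaw uniform on (-pi, pi].

Training examples render a view triplet, jitter the fixed parameters by
+-5%, displace the crop by 0-20 px per axis, overlay background noise and
quantize to uint8. The noise is hierarchical per image: background pixels
take values from N(m, s^2) with m = X*Y (X uniform on [0, 1/255], Y
Gaussian with mean 50, sd 10 for the bottom camera; mean 20, sd 10 for
side cameras) and s^2 uniform ([20, 70]/255^2 bottom, [10, 60]/255^2
side). The noise is an overlay (`max(rendered, noise field)`) — the
model describes background pixels, and an additive variant would dim the
larva relative to the rendered template and corrupt template fitting.
Because no real pose collection ships with the package, a generator of
realistic-looking collections (`prior_pose_ensemble`: low-pass filtered
joint noise with heavy-tailed bend amplitudes, small dorsal bending,
modest inclination and roll) bootstraps the KDE pipeline; it emulates
the *structure* of swim-bout statistics, not any measured distribution,
so tests passing on it say nothing about agreement with real larvae.

A temporally correlated bout generator (Gaussian-smoothed KDE samples
with a speed-capped centroid walk; the infinite-smoothness limit is a
constant pose) supplies tracking and kinematics fixtures.

## Template-based fitting

Frames are background-subtracted (per-pixel 90th-percentile background
over the video), Gaussian-filtered (5x5, sigma 1), thresholded by Otsu's
value scaled by 0.8 (a fixed manual threshold is also supported),
segmented, and cropped to 141x141 with border-sampled padding (5-px
border, values above mean + 3 sd excluded). Tracking associates
triangulated 3-D centroids to nearest neighbors across frames and
terminates after a configurable gap.

The cost is the sum over views of squared pixel differences between the
preprocessed crop and a re-render quantized to the same 8-bit scale.
Optimization is a coordinate-polling pattern search (opportunistic
acceptance, mesh doubling on success, halving on failure, stop at mesh
1e-3 in per-parameter scaled units). Design points that matter:

- The coarse round is staged — position only, then position plus head
  angles, then all 22 parameters — with the sprite renderer; an
  unstaged 22-parameter poll from a far start reliably walks into wrong
  basins.
- The search keeps roll inside (-1.9, 1.9) rad. The body is nearly
  symmetric under a 180-degree roll, and the upside-down cost basin is
  both spurious and attractive; excluding it is the optimizer-side
  counterpart of the never-belly-up reconstruction convention.
- The fine round runs anterior (position + head angles), posterior, and
  joint phases with the accurate renderer, caching the anterior image
  during the posterior phase. The posterior phase first sweeps the
  joints one at a time from head to tail (each joint levers everything
  behind it, restoring overlap for the next), then polls all bending
  angles together.
- Roll couples to the bending angles: shifting gamma0 while rotating the
  joint-angle pairs leaves the backbone fixed in lab space, so the cost
  is nearly flat along that curved valley and axis polls cannot follow
  it. The fine round scans this "twist" direction explicitly (exactly,
  by rolling the eye axis about the heading and re-deriving the pose).
- First frames (no initial guess) are seeded by brute-force orientation
  search with a straight backbone (yaw every 10 degrees, inclination
  +-60 in 10s, roll in 15s) at the triangulated centroid with a 4.5 mm
  initial length; the length is then estimated from the segmented
  extents of straight-pose frames and averaged.

At the default desk-scale budgets (coarse 900 evaluations, fine 350 per
phase, 50 um voxels) recovery from a 0.5 mm / 5-degree-per-angle
perturbed start on noisy synthetic frames reaches a mean backbone error
around 30 um in ~10-15 s per frame on one CPU.

## Keypoint network

The network maps the three preprocessed 141x141 views (three input
channels) to 72 outputs: per view, 12 keypoints (10 backbone + 2 eyes) as
(x, y), bounded to [0, 141] by a scaled sigmoid. Encoder: four bottleneck
residual blocks (1x1 reduce, 3x3 stride-2, 1x1 expand; projection
shortcut) with 32, 64, 128, 256 output channels; global average pooling;
decoder: dense layers of 288, 144, 72 units; batch normalization before
every convolution/dense layer and leaky rectifiers (slope 0.01) after.
Stride-2 transitions are a design choice — with stride 1 throughout, a
141x141 input could not reach the stated decoder sizes — and are
configurable. The implementation is a compact numpy engine (im2col
convolutions backed by BLAS, manual backpropagation, Adam); training with
a fixed seed is bit-reproducible on one platform.

The loss is the backbone RMSE over all 60 backbone coordinates plus
lambda = 5 times an eye term that is exactly symmetric in the two eye
labels: per camera, the smaller RMSE over the two complete eye
assignments. Defaults follow the full-scale recipe (Adam, learning rate
1e-3, batch 300, 120 epochs, 9:1 train/validation split); the desk-scale
profile used by the tests (a few thousand examples, 10-15 epochs, batch
64, 3-4x image downscale) trains in minutes on one CPU and is the same
code path.

## Reconstruction and scoring

Backbone keypoints are triangulated independently (tank-center start);
eye labels are resolved by enumerating all 8 per-view assignments and
keeping the least total residual (ties break lexicographically and are
flagged); the roll angle follows never-belly-up. The backbone is then
resampled on a parametric cubic spline. Two spacings are available: equal
arc length (the conventional midline parameterization, and the default of
`resample_spline`) and equal chord length, which matches the
rigid-segment model exactly; `reconstruct_pose` uses chord spacing
because arc spacing biases noise-free loop closure by ~0.04 mm at
realistic curvature. Equal-chord positions are found by bisecting on the
common chord so that nine chords end exactly at the tail tip.

The prediction score of a frame re-renders the predicted pose, masks to
the rendered non-zero support per view, computes the Pearson correlation
between input and render over the mask, and takes the minimum across
views. Identical images score exactly 1.0; empty or constant masks yield
NaN, are excluded from the minimum with a warning, and never count as
zero. For model-vs-model comparisons (both images rendered) the union of
the two masks is used by the caller; the frame score above always uses
the re-render's own mask. Bout filtering accepts a bout only if every
frame scores at least 0.85.

## Kinematics and statistics

Bout summaries unwrap each angle series, measure changes relative to the
first frame, and report the signed extremum of the deviation ("max
change"; a max-minus-min range mode exists) and the final-minus-initial
total change, for yaw, inclination, roll, and the mean lateral and dorsal
bending angles. Quartiles use linear interpolation. The
difference-of-means test pools both samples, draws 10,000 pairs of
same-size resamples, and reports the upper-tail probability of the
observed difference; by default the difference is oriented toward the
larger mean (so null p-values concentrate on (0, 0.5]), and a
fixed-direction mode gives uniform null p-values for calibration checks.
The asymmetry test is the exact binomial upper tail. Eigenshapes are the
right singular vectors of the (mean-centered by default) frames x 16
bending-angle matrix, with variance fractions from the squared singular
values and a lateral/dorsal label from the energy split between the two
angle blocks.

## Problem sizes in the shipped tests

The test suite works at deliberately modest sizes chosen to exercise
every claim on one CPU: a 9x9x4 dot grid for calibration, 100 poses for
loop closure, 50 noisy frames for template-fit recovery, and 2,000
training examples / 10 epochs / 4x downscale for the training smoke
test. All of these are configuration, not code paths: the full-scale
settings (500k examples, 120 epochs, full resolution) run through the
same functions.

## Known limitations

- The fixed body parameters are plausible defaults, not estimates from
  data; absolute image realism is out of scope.
- The renderer has no pectoral fins, no eye orientation dynamics, and no
  multi-fish composites.
- The pose chart is undefined past +-90 degrees of cumulative dorsal
  bending, and template fitting restricts roll to about +-109 degrees.
- The synthetic pose prior is structural, not empirical; distributional
  results on it do not transfer to real larvae.
- Background subtraction assumes a static background over the video.
- The numpy training engine is single-device and CPU-oriented; it is the
  right tool for desk-scale experiments, not for 500k-image runs.
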