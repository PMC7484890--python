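# Methods

This note documents the models, conventions and numerical choices behind
`cinemv`, and what the synthetic validation does and does not demonstrate.

## Coordinate frames and geometry

The room frame has its origin at the linac isocenter: X lateral, Y
longitudinal (gun–target), Z vertical. At gantry angle θ (degrees) the
source is at (SAD·sin θ, 0, SAD·cos θ); θ = 0 places it above the
isocenter and increasing θ (clockwise rotation) moves it toward +X. Signed
angles in (−180°, 180°] are accepted everywhere and reduced to [0°, 360°)
internally. The projection of a point is the intersection of the
source→point ray with the plane through the isocenter perpendicular to the
beam axis, reported along û(θ) = (cos θ, 0, −sin θ) (AB) and +Y (GT). The
auxiliary cone angle β between the central axis and the source→point ray is
reported with the convention that it is positive for θ ∈ [−90°, 90°]
(closed interval: both boundaries take the positive branch) and negative
otherwise.

Detector constants: 1024 × 1024 native pixels, source–detector distance
160 cm, 25.6 cm × 25.6 cm field of view at the isocenter. These force
SAD = 100 cm (magnification 1.6) and a native pixel pitch of 0.25 mm at
isocenter scale; after 2 × 2 binning the working resolution is 0.5 mm. All
errors are quoted at isocenter scale; multiply by 1.6 for panel-plane
distances. The beam axis is defined to pierce the image at native pixel
coordinate (511.5, 511.5).

Gantry-angle errors propagate through P(θ+ε) − P(θ). The error-sweep used
in validation places the object at 12.5 cm lateral offset — the panel-edge
region, chosen because it reproduces the ~2.5 mm/degree worst case; the
exact edge coordinate 12.8 cm would give ≈ 2.6 mm and is not what the
validation figure uses.

## Patient ↔ room bridge

DICOM patient coordinates map to room coordinates as X = (px−ix)/10,
Y = (pz−iz)/10, Z = −(py−iy)/10 (cm, isocenter i), assuming identity
(head-first supine) orientation; other orientations are rejected by the CT
reader. This convention is a package choice — the fixture writer generates
data in the same convention, so the bridge is exercised end to end by the
tests, but importing data in a different patient orientation is out of
scope.

## Voxelization and ray casting

ROIs are voxelized slice-wise on the planning-CT lattice by an even-odd
(ray-crossing) fill evaluated at voxel centers; contour vertices count as
inside, and multiple contours on one slice combine by exclusive-or so
annular structures keep their holes.

Projections cast one ray per 2 × 2 detector group from the source through
the group center on an ideal flat panel. The ray is tested against the
lattice planes of the occupied region taken at voxel *boundaries*: at each
crossing the intersection is rounded to the nearest voxel index
(half-away-from-zero), where the crossing coordinate itself is an exact tie
and both adjacent voxels of the crossed layer are tested. With
boundary planes every voxel the ray traverses produces a crossing on one of
its faces, so the test is exact — a pixel is set iff its ray meets an
occupied voxel — which center-plane crossings are not (they can miss
grazing corner chords; we measured real chords of 8 µm on the ball-bearing
fixture). Only crossings on the source-to-panel segment count. The binary
result is order-independent, so planes are evaluated vectorized over pixels
rather than walking each ray front-to-back; the early-exit of a sequential
implementation is an efficiency detail, not a semantic one.

Contours are the map pixels with value 1 that have a zero 8-neighbor or lie
on the map border. The overlay centroid is the area centroid of the
*filled* projection (not of the boundary pixels), because the timing
correction needs the projection's mass center column. Projections are
precomputed at 0.5° steps (720 per ROI) and serialized to a versioned JSON
container with an exact round trip.

Field eligibility: before monitoring, every control point of the plan is
checked so the primary field stays on the imager — per-leaf open rectangles
clipped by the jaws, rotated by the collimator angle, must stay within the
25.6 cm field of view less a security margin. The margin defaults to 5 mm
at isocenter scale (configurable; the requirement is only that it be
"small" relative to the imager).

## Frame timing

The panel reads its two lateral halves synchronously, column by column,
outside-in, over one integration time T = 0.433 s:
t(c) = TS − T + α(c)·T/511 with α(c) = c on the A side (c ≤ 511) and
1023 − c on the B side. Machine messages arrive at ≈ 4 Hz and are
timestamped on receipt; gantry angles are interpolated linearly on the
unwrapped angle (continuous across 0°/360°; unwrapping assumes < 180°
of travel between consecutive messages, safe by a factor of ~150 at
clinical speeds). Times up to one message interval outside the stream are
clamped; farther times are an error.

Per frame and ROI the assigned angle is computed with one refinement step:
interpolate at TS, read the projection centroid for that angle, convert the
binned centroid column to a native column by c = round(2·col), map through
t(c), re-interpolate. One step follows the described operating procedure;
an optional fixed-point mode (≤ 5 iterations, stop when the angle moves
< 0.05°) is available but off by default — at clinical speeds the
correction itself is ≤ ~2°, so the second-order residual of a single step
is far below the 0.5° projection grid.

## Image pipeline

Preprocessing order is fixed: dark subtraction, flood-field gain correction
(flood nearest in dose rate, no interpolation between floods; non-positive
denominators replaced by their local median; result rescaled by the mean
denominator to keep the intensity scale), panel-position translation,
median filter, 2 × 2 mean binning. Numerical choices the sources leave
open: the median kernel is 3 × 3 (smallest effective, edge-replicated);
binning uses the mean to preserve the 16-bit range; the translation is
integer-pixel at native resolution (the correction table stores offsets in
pixels and panel reproducibility is itself ~1 px, so sub-pixel resampling
would add blur for no accuracy).

Display contrast: pixels below 70% of the image maximum (fraction
configurable) are zeroed; retained pixels map onto 0–255 through their
empirical CDF, min-shifted so the lowest retained level maps to 0
(out = round(255·(cdf − cdf_min)/(1 − cdf_min))); a single retained level
maps to 255. The mapping is monotone and invariant under positive rescaling
of the input.

## Panel-position calibration

The ball bearing appears as an attenuated disk inside the bright field.
Detection masks the field above half maximum (eroded by 3 px away from the
penumbra), thresholds the inverted intensity halfway between the field
median and the darkest pixel, requires at least 10% relative attenuation
(else an explicit not-found error), keeps the largest connected blob and
returns its attenuation-weighted sub-pixel centroid. The correction table
is (511.5, 511.5) minus the per-angle average centroid over all runs,
resampled to a regular 1° grid with wrap-aware linear interpolation and
applied with the same interpolation; gaps > 5° in a run's angular coverage
are an error. Clockwise and counter-clockwise runs are averaged jointly by
default (per-direction tables are available for hysteresis inspection —
the sources do not say which was used, and the joint average is the
smaller-variance choice when no hysteresis is modelled).

## Simulator: what it emulates, and what not

The simulator renders each native column with the gantry geometry at that
column's own readout time — the rolling shutter is implemented from
scratch here, independently of the timing-correction code, so the
end-to-end test compares two separate implementations of the same physics.
Study conditions are fixed by the validation preset: an 8-mm BB at room
(−10, −5, 0) cm (10 cm lateral, 5 cm longitudinal from the isocenter — the
layout most sensitive to gantry-angle error), a 24 cm × 24 cm open field,
clockwise 360° arcs at 1.5°/s and 4.8°/s (the clinical minimum and maximum
VMAT gantry speeds), messages at 4 Hz. Message receive jitter is uniform
±50 ms applied to the timestamps (angles are sampled at the true times);
the true distribution of the machine's reporting latency is unknown, and
uniform jitter is an explicit modeling assumption surfaced in the
configuration. Detector noise defaults to Gaussian σ = 100 counts on a
30 000-count field (≈ 0.3% — modest flat-panel shot/readout noise); the BB
photometric model (40% attenuation, 1-px smooth edge) is arbitrary but
irrelevant to accuracy tests, which use centroids. Panel sag is a
whole-frame translation evaluated at θ(TS), sinusoidal per axis.

Not modelled: scatter, detector lag/ghosting and MTF, dose-rate dependent
gain, MLC leaf motion within a frame, couch and collimator rotations in the
projection geometry, and clock skew between the imager and the machine
stream. Consequently the synthetic validation demonstrates the *geometric
and timing* correctness of the chain — projection, readout model, angle
assignment, calibration — not the detectability of low-contrast anatomy in
real MV images, and the clinical marker-visibility statistics of real
treatments are out of its reach (the visibility bookkeeping itself is
implemented and tested on synthetic aperture masks).

## Accuracy evaluation

Per frame the signed error is contour centroid minus BB centroid, converted
at 0.5 mm per binned pixel. In the AB direction the polarity is inverted
for positive gantry angles — θ ∈ (0°, 180°) in the signed convention — so a
negative error always means the contour lags the object; the mean of the
adjusted errors then estimates systematic gantry-angle/timing bias and the
standard deviation the random timing error. Frames with an undetectable BB
or an empty overlay are excluded and counted. At the preset conditions the
desk-scale run yields |μ| ≲ 0.01 mm and σ(4.8°/s) ≈ 0.25 mm (the full
two-arc run is what `scripts/acceptance.py` recomputes); σ grows with
gantry speed at fixed jitter, while the GT direction is essentially
unaffected. The simulated random error is smaller than what linac hardware
shows, because only message-timestamp jitter is modelled — the numbers are
an accuracy floor of the method, not a reproduction of any particular
machine.

## Problem sizes

The validation runs at the frame counts the physics dictates
(554 frames at 1.5°/s, 173 at 4.8°/s — a full rotation each at one frame
per 433 ms) on the 0.5 / 0.5 / 1.0 mm BB planning grid; the panel-centering
check samples a sag-free arc at 72 angles. The property suites use ≤ 32³
lattices where brute-force oracles (point-in-polygon scans, per-voxel
ray/box intersection, 8-neighbor scans, sort-based medians) are exact and
fast.
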