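# Methods

## The skeleton model

The tracker's output is an 18-joint stick figure: nose (joint 0, the
root), chest (1), shoulder–elbow–wrist chains (2–4 right, 5–7 left),
hip–knee–ankle chains (8–10 right, 11–13 left), and eyes/ears (14–17).
For estimation the joints form a tree rooted at the nose: the chest
parents both shoulder chains and both hip chains, and the head joints
attach to the nose.  Exact ID↔name tables differ between tracker SDKs;
the packaged table pins the right arm to 2–4, the left arm to 5–7 and
the left eye/ear to 15/16, which fixes the remaining left/right
assignments.

Coordinates are meters in the depth camera's frame: y down, z outward
from the sensor, x completing a right-handed system.  *Global Up* is the
negated camera y axis (overridable for tilted sensors).  A joint the
tracker could not resolve is reported as exactly `(0, 0, 0)`; the
sentinel is matched exactly, not by norm threshold.

## Point-cloud-assisted estimation

The subject initially holds a default standing pose — arms by the side,
legs together, facing the sensor.  Among the first `window` frames
(default 30) in which all 18 joints are observed, the frame whose 18
depth values have the smallest standard deviation is the reference
frame; child–parent distances measured there are treated as rigid limb
lengths.  If no fully-observed frame exists the algorithm refuses to
start and asks for a longer calibration capture.

Each subsequent frame is processed in ascending joint-ID order (nose
first), so children are validated against already-corrected parents,
and the *corrected* previous frame is the temporal anchor.  A joint is
kept iff it is observed, moved at most `displacement_bound` (default
0.25 m/frame) since the previous frame, and lies within
`[lower, upper] × limb distance` (default [0.8, 1.2]) of its corrected
parent.  The temporal cap and the limb interval are deliberately
separate, independently configurable checks; their numeric defaults are
package choices — the bounds have no canonical published values.

A rejected or missing joint is re-estimated from the frame's segmented
point cloud (its own limb's segment; the root, which has no limb, pools
the segments of limbs incident to it).  The candidate is the cloud point
nearest to the joint's previous position whose distance to the corrected
parent lies in the limb interval (the root searches unconstrained);
ties take the lowest point index.  When the tracker did report a
position, candidate and report are averaged if they agree within the
displacement bound, or if averaging moves the estimate closer to the
previous frame — but only when the midpoint itself still satisfies the
limb interval, so that every non-fallback output joint respects the
interval by construction.  A joint that was missing entirely takes the
candidate directly (no mean update).  If no cloud point qualifies, the
previous position is carried forward and the joint is flagged
`fallback`.  Frames before the reference frame are dropped by default
(or processed backward from it, per config).

## Joint-angle extraction

Shoulders, hips and the spine-to-hip link are spherical joints; elbows
and knees are revolute.  All constructions use a handful of named body
vectors: *Left to Right Shoulder*, *Chest to Pelvis* (pelvis = hip
midpoint), their cross product *Forward Facing* (upper body);
*Right to Left Hip* × *Global Up* (lower body's forward).  Angles are in
degrees; projections shorter than 1e-8 m make the angle *undefined*
(NaN, flagged) rather than guessed.

* **Abduction (y)** — the proximal limb vector projected onto the plane
  normal to Forward Facing, measured from the side's lateral axis and
  made negative on the Chest-to-Pelvis (for legs: downward) side.  The
  hanging limb reads −90°, a T-pose arm 0°, an overhead arm +90°.
* **Flexion (z)** — the limb projected onto the plane normal to
  Chest-to-Pelvis (for legs: the transverse plane), measured from the
  lateral axis's in-plane projection, negative toward Forward Facing.
  Measuring against the *projected* lateral axis (the reference drawn
  in-plane) is a package choice; it makes the construction exactly
  invertible for skewed torsos (simultaneous spine twist and bend).
* **Axial rotation (x)** — read off the distal segment: the
  forearm/shank projected onto the plane normal to the proximal limb,
  measured from the (Backwards-)Forward-Facing projection, negative on
  the Cross-Elbow / Cross-Knee side.  The x angle needs the wrist/ankle
  and is undefined for a straight elbow/knee (the distal segment then
  carries no rotational information).
* **Elbow/knee** — the unsigned angle between the two adjacent limb
  vectors; 180° is straight.  Computed as `atan2(|u×v|, u·v)`, which
  keeps full precision at collinearity where the arccos form loses
  ~1e-6°.
* **Spine** — twist (x): shoulder line vs hip line, both projected onto
  the horizontal plane, signed right-handed about Global Up; bend (z):
  Pelvis-to-Chest projected onto the plane normal to the projected hip
  line, measured from Global Up, positive toward Forward Facing.  The
  sign conventions are package choices (the construction itself only
  defines magnitudes).

The y/z pair of a spherical joint are *projection* angles, not Euler
angles of a single rotation; a pair is realizable only when `cos z`
shares its sign with the limb's lateral-plane component (the
"hemisphere condition").  Forward kinematics validates this and the
random-pose sampler stays within |y|, |z| < 85°.  Hip and spine angles
reference Global Up and are therefore invariant only under rotations
about the vertical; elbow, knee and shoulder angles are invariant under
arbitrary rigid motions.

The hip y/z recipes mirror the shoulder construction with lower-body
vectors (y-plane normal = lower Forward Facing, negative side
downward; z-plane = transverse, negative side forward): the lower-body
construction is only pinned down for x by the named-vector recipe, so
the y/z mirroring is a documented reconstruction.

## Synthetic data

The generator emulates what the sensor studies show: smooth x,y tracks,
high-variance depth, `(0,0,0)` dropout, whole-frame losses, and point
clouds hugging the limbs.

* Forward kinematics from angle trajectories (keyframes, callables or
  constants) with rigid limb lengths from `BodyDimensions` (defaults:
  0.30 m upper arm, 0.27 m forearm, 0.42 m thigh, 0.41 m shank, 0.36 m
  shoulder width, 0.30 m hip width — adult-scale round numbers).
* Noise: zero-mean Gaussian, independent per joint per frame, depth sd
  0.05 m vs x/y sd 0.005 m by default.  The magnitudes are calibration
  knobs chosen to reproduce the *qualitative* smooth-xy / noisy-z
  contrast; no published noise magnitudes exist for this setup.
* Dropout: i.i.d. Bernoulli per joint (default 0.1) plus an optional
  burst mode dropping every joint for a run of frames.  Dropout is
  suppressed during an initial calibration segment (default 30 frames,
  1 s), mirroring the capture protocol in which the subject holds the
  default pose so an initialization frame exists.
* Clouds: per limb, uniform in a capsule of radius 0.04 m around the
  true (clean) limb segment — clouds reflect the body surface even when
  the tracker drops a joint.

What the generator does *not* model: occlusion geometry (dropout is
random, not ray-cast), soft tissue, cloth, segmentation errors in the
clouds, depth-noise correlation across joints or time, and multiple
people.  Passing tests therefore demonstrate algorithmic correctness
and noise-level behavior, not field performance on real captures.

The default demo motion is a reach-and-return of the right arm
(abduction to −25°, elbow to 120°, 40° of humeral rotation, a 10°
forward bend) after one second of standing calibration.

## Retargeting and export

Interpolation is piecewise linear per angle channel over its defined
samples; undefined gaps are bridged, endpoints preserved exactly.
Linear-per-angle is adequate between dense tracker frames but is a
documented limitation for sparse keyframes spanning large rotations
(no quaternion slerp).  Channels undefined over a whole capture (e.g.
flexion of a permanently hanging arm) are filled with their rest-pose
value and logged.

BVH export uses a y-up skeleton (subject's left = +x), channel order
Z,X,Y rotations per joint, root with 3 position + 3 rotation channels,
offsets from `BodyDimensions`.  Revolute joints ride the Z channel of a
fixed-axis triple.  The channels carry the anatomical projection angles
themselves; consumers reconstruct poses through the package's forward
kinematics (the projection angles are not a rotation-matrix hierarchy).
Values are printed at 1e-6 precision, so a re-parse recovers channels
to well under 1e-4°.

## Numerical choices and edge cases

* Missing sentinel: exact equality with `(0,0,0)`; an explicitly
  flagged observed joint at the origin is honored.
* Singularities: tolerance 1e-8 m on projection norms; strict per-joint
  operations raise, sequence extraction emits NaN + flag.
* Ties: equal depth-sd reference frames → earliest; equal-distance
  cloud candidates → lowest index.  All randomness flows from explicit
  seeds; two runs at one seed are byte-identical.
* Angle comparisons in tests use the clamped-arccos formulation and
  null-space plane bases as independent oracles.

## Benchmark behavior

At the default study conditions the repair stage cuts mean 3D joint
error on the demo capture from ≈0.23 m (dropout-ridden raw stream) to
≈0.038 m — about the capsule radius, which bounds attainable accuracy.
Per-angle RMSE improves more modestly: the validator intentionally
keeps depth noise inside the ±20% limb interval, and that accepted
noise dominates angle error on short limbs.  The end-to-end angle
benchmark therefore compares the two streams on entries resolvable in
both (and in the noiseless stream); the repair stage additionally
resolves the dropout entries the baseline cannot produce at all.
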