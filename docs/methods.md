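# Methods

This note documents the models, conventions, default parameters and
numerical choices behind the `righting` analysis pipeline, and what its
synthetic-data tests do and do not establish about real tracked data.

## Coordinate frames and attitude

The laboratory (spatial) frame is *XYZ* with *Z* vertical up; the ground
plane is fitted to in-contact foot points by total least squares (SVD of
the centred cloud) and all heights and contact tests are taken relative
to it, so a tilted calibration does not bias the results. The anatomical
body frame is *x* cranial, *y* lateral (left), *z* dorsal, with origin
at the cranial–caudal landmark midpoint. Body meshes handed to the
pipeline must be expressed in this frame (the packaged synthetic
ellipsoid is).

Attitude is the body→spatial rotation, estimated per frame by
least-squares rigid registration (Kabsch, via
`scipy.Rotation.align_vectors`) of all rigidly body-fixed landmarks
(cranial, caudal, dorsal midline point, and the six coxae when tracked)
against a reference configuration. The reference is the mean geometry of
the first five valid frames expressed in the anatomical frame; the
dorsal axis of that frame is taken from the dorsal midline point
relative to the mean coxa position when at least two coxae are present.
This choice matters: the dorsal point's offset from the cranial–caudal
axis is only a few tenths of a millimetre in a flattened nymph, and a
direction estimated from that short baseline is unusable at realistic
tracking noise, while the dorsum–coxa baseline is ~1.5 mm and stable.

Quaternions are scalar-first, body→spatial, hemisphere-continuous along
the series (sign flipped when q·q_prev < 0). Euler angles are intrinsic
Tait-Bryan *z-y′-x″* (yaw, pitch, roll); at gimbal lock (|pitch| = π/2)
roll is set to 0 and the residual freedom folded into yaw. The
overturning coordinate is `Z_dv`, the *Z*-component of the unit
dorsal→ventral axis: +1 supine, 0 at the flipping point, −1 upright.

Angular velocity comes from the finite relative rotation between
attitudes at adjacent frames, `q₂q₁⁻¹`, decomposed to axis–angle:
**ω** = (Δθ/Δt) r̂ in the spatial frame. "Spin" `ω_spin_rp` is the
magnitude of **ω**'s components along the body roll and pitch axes
(yaw-axis rotation does not raise the COM and is excluded).

## Smoothing and differentiation

All landmark series — and, equally, the attitude quaternion components —
are smoothed by local quadratic regression over a moving window: 25 ms
for the body and orientation, 5 ms for the faster-moving legs, at
1000 fps. Derivatives are the slope of the same local fit, with
one-sided windows at the series ends. The robust variant excludes
samples more than 6 mean absolute deviations from the local fit and
refits (two iterations), which removes isolated tracking glitches
exactly (a 100× spike in a constant series is restored to the constant
at machine precision). Quadratics are a fixed point of the smoother and
differentiate exactly; a 2 Hz sinusoid at 1000 fps is differentiated to
better than 1 %. Interior windows on clean uniform data use the
equivalent Savitzky–Golay convolution for speed; windows touching NaNs
or flagged outliers are re-fitted exactly. NaN samples carry zero weight
and propagate to the output only where a window has fewer than three
valid samples.

Smoothing the orientation as well as the coordinates is load-bearing:
differentiating unsmoothed per-frame registrations amplifies attitude
noise into a ~15 % RMS error on rotation rates at 0.2 mm landmark
noise, while the smoothed series recovers programmed rates to ~9 % RMS
(noise-free: < 0.1 %).

## Anchor model (articulated mass distribution)

The body (head+thorax+abdomen) is one rigid object; its mass properties
come from exact divergence-theorem volume integrals over the watertight
surface mesh at uniform density (`trimesh`), cross-checked in the tests
against closed forms (cube, triaxial ellipsoid at fine tessellation,
< 0.5 %). Each leg is two thin rods — distal tibia+tarsus, proximal
femur+trochanter+coxa — spanned between tracked endpoint landmarks, with
`I_rod = mL²/12` about transverse axes and zero axial inertia. Whole-
insect COM and the spin moment of inertia about any axis through it are
composed per frame with the parallel-axis theorem; rod masses are fixed
morphometric values while rod lengths follow the tracked endpoints. A
frame missing any endpoint yields flagged NaN outputs, never an
exception.

Uniform density is assumed for body and rods alike; no density map is
available for these animals and the rigid-mesh treatment implies it.

### Standardized morphology and default morphometrics

Trials from different specimens are pooled by isometric scaling: all
coordinates are multiplied by `L_std / L_body` with `L_std = 8.9 mm` and
the whole-insect mass set to `M_std = 28.4 mg`. The packaged default
morphometrics (`data/leg_morphometrics.yaml`) are a synthetic stand-in
constructed once from the gross facts known for this species: legs long
relative to the body (hindlegs longest — these are jumping insects),
leg mass a large fraction of the total (11.2 of 28.4 mg here), and a
fully splayed mid-righting posture in which the twelve rods carry about
two-thirds (65–72 %) of the whole-insect spin moment of inertia about a
diagonal (between roll and pitch) axis — the axis of the dominant
righting method. The splayed reference pose used for that composition
has feet ~7.5 mm from the midline, at the reach of the outstretched
two-segment legs. Per-specimen dissection values should replace this
file when available.

## Inverted-pendulum template

The template treats the insect as rigid and rotating about a fixed
ground pivot. The pivot is the time-mean position of the most stationary
in-contact landmark — body landmarks preferred over leg joints over feet
— estimated on the active-overturning window (resting frames would
otherwise dominate the stationarity ranking) and held fixed within an
attempt. Orbital angular velocity is `ω_orbital = v_orbital/d` with `d`
the COM–pivot distance; frames with `d` below a 1 mm guard are flagged
rather than clipped. `I_pendulum = I_spin(r̂) + M d²` uses the anchor's
spin inertia about the instantaneous rotation axis;
`KE_avail = ½ I_pendulum ω_orbital²`.

Torques about the pivot follow `τ_net = I_pendulum α_orbital`;
the gravity torque uses the moment arm `r_COM`, the horizontal distance
from the pivot to the COM's ground projection — the physically correct
arm for a vertical force — with a config switch (`gravity_arm='d'`) to
use the full COM–pivot distance instead for comparison with analyses
that did so. The reaction force `F_reaction = τ_reaction/r_⊥` uses the
mean 3D distance from in-contact tarsi to the pivot, and `F_leg` divides
by the number of tarsi in contact (flagged when zero).

Template validity, not just implementation correctness, is checked on
the simulator: for a rigid pivoted tip-over the measured
`ω_spin : ω_orbital` ratio is 1 within 2 % — the template's defining
identity — while articulated trials with swinging legs depart from it,
and the pipeline reports the ratio rather than assuming it. Estimator
bandwidth: with a 25 ms window the COM-speed estimate is biased low once
the stroke exceeds roughly 25 rad/s (the window then spans > 0.6 rad of
arc), so energy-budget closure is quoted within that operating regime.

## Energetics

`PE = M g Z` (g = 9.81 m s⁻²) with Z the whole-insect COM height above
the fitted ground plane, decomposed into body and leg contributions by
component masses. The barrier is `ΔPE(t) = PE_max − PE(t)` with the
maximum taken over the attempt; `RN = KE_avail/ΔPE`, with ΔPE below
10⁻¹⁰ J flagged saturated rather than reported as a divergence. The
apex is the PE maximum; the flipping point is the first downward zero
crossing of `Z_dv` (sub-frame by linear interpolation); active
overturning is the maximal contiguous interval around the flip where
|dZ_dv/dt| ≥ 50 % of its trial maximum (the threshold is configurable —
any operationalization of "fastest reorientation" involves one).

For a rigid body pivoting about a ground-level point below its COM the
PE apex comes *before* the 90° flip (the COM passes over the pivot at
less than a quarter turn), so apex and flip ordering is
geometry-dependent; the pipeline reports both times and the tests assert
their proximity, not an order.

The pitch–roll PE landscape rotates the body mesh through intrinsic
(yaw = 0, pitch, roll), drops it so its lowest vertex touches the
ground, and records `M_body g Z_COM`; yaw cannot change COM height for a
point contact, so the landscape is two-dimensional. Legs are excluded —
the full configuration space including twelve leg degrees of freedom is
deliberately out of scope.

## Stability margin

The support polygon is the 2D convex hull, in fitted-ground-plane
coordinates, of every landmark within the contact tolerance (default
twice the plane-fit residual SD, floored at 0.5 mm). SM is the signed
shortest distance from the COM projection to the hull boundary (negative
outside); ISM is that distance from the polygon's area centroid.
Degenerate supports of one or two points cannot enclose the COM, so SM
is the negated distance to the point or segment and ISM = 0. Note the
area centroid is near but not exactly the point that maximizes the
boundary distance (that is the Chebyshev centre), so SM:ISM can
marginally exceed 100 % for skewed polygons; it is reported as computed.
SM assumes purely pushing contacts — adhesive or grasping feet can
stabilize any SM, which is why negative-SM methods are observable at
all.

## Leg coordination

Foot motion is summarized as `z_tarsus`, the tarsus *z*-coordinate in
the body frame. Pairwise coordination of fore- and midlegs (hindlegs
serve mostly static roles) is the discrete normalized cross-correlation
of the zero-meaned series over the window from the first analyzed frame
to the apex, normalized by `n·rms_j·rms_k` — the biased 1/n estimator,
under which every autocorrelation is exactly 1 at zero lag (the RMS
reading of the normalization is the only one consistent with that
identity). Peaks are local maxima of the lag sweep, ties broken toward
smaller |lag|; the autocorrelation's peak excludes zero lag and uses
|value|, cross-pair peaks use the signed value.

## Ethogram

An attempt runs from the frame the dorsum leaves contact tolerance while
`Z_dv > 0.9` until success (all six tarsi in contact, `Z_dv < 0`, COM
speed below 5 mm/s sustained 100 ms) or failure (sustained dorsum
recontact with `Z_dv > 0.9`); both transitions are debounced over 10 ms
so single-frame contact flicker at realistic noise does not split
attempts. The 5 mm/s rest threshold operationalizes "came to rest"; the
observation limit is 30 s. Method classification: *lifted rotating* if
no body landmark touches the ground during active overturning; else
*pitching* if the dominant rotation axis lies within 30° of the body
pitch (lateral) axis *and* the pivot is the caudal landmark; else
*diagonal rotating*. The 30° cone and the caudal-pivot rule are
quantitative stand-ins for qualitative behavioural descriptions and are
configurable.

## Synthetic trials

The generator emulates the study conditions: 1000 fps sampling, 0.2 mm
Gaussian landmark noise, a flattened ellipsoidal body (semi-axes 4.45,
1.8, 1.1 mm ≈ half the standardized body length), total mass 28.4 mg
split body/legs by the default morphometrics, and stance/swing leg
programs realizing the three righting modes plus programmed failed
attempts. Dynamics integrate
`I θ̈ = τ_applied + τ_gravity(θ) − c θ̇` about a fixed horizontal axis
through the pivot with fixed-step RK4 at the sampling rate; the pendulum
inertia is that of the body with legs frozen at their starting pose, and
legs are otherwise kinematically prescribed, not force-coupled. A
behavioural controller produces the requested number of attempts: failed
pushes apply 1.05× the peak gravity torque (just above quasistatic) and
release at 40 % of the apex angle, so the fall-back is guaranteed by an
energy margin; the final push applies the configured torque (default
1.5×10⁻⁶ N·m, giving ~50–80 ms strokes at this scale) past the apex.
Mode geometry: pitching rotates about the lateral axis through the
caudal contact; diagonal rotating about a 45° axis through the caudal
contact with four stance feet enclosing the whole COM ground track (so
SM stays positive through the stroke); lifted rotating raises the body
2.5 mm on three ipsilateral stance feet (SM negative until the flip).
Swing-leg tarsus heights are sinusoids with per-leg phase offsets and
second harmonics, chosen to be strongly but imperfectly correlated as in
real righting strokes.

Identical configs and seeds are bit-identical. A `rigid_legs` option
freezes all legs to the body, making the generated trial exactly the
rigid pendulum the dynamics integrate — this is the configuration for
closure tests (energy conservation, `ω_spin:ω_orbital`, torque
recovery), because with planted feet the articulated assembly's COM is
genuinely not the frozen-leg COM the integrator evolves.

What passing tests show — and don't. The generator shares the analysis
pipeline's idealizations: rigid body, point landmarks, additive Gaussian
noise, a truly fixed pivot, no slipping, no soft-tissue deformation, no
occlusion-driven missing-data structure, and leg programs that are
kinematic rather than dynamic. Closure on it validates the mathematics
and the implementation, and noise-robustness tests validate the
filtering at realistic noise amplitudes; none of this certifies accuracy
on real video, where pivot drift, correlated tracking error and
occlusions dominate.

## Numerical choices

- Fixed-step RK4 at dt = 1 ms; ballistic energy drift < 10⁻⁷ relative.
  An instability guard rejects torque programs driving |ω| > 10³ rad/s.
- Registration requires ≥ 3 non-collinear landmarks; degenerate
  configurations raise geometry errors rather than returning garbage.
- Attitude accuracy scales with per-axis landmark spread: 0.1 mm noise
  on an isotropically spread 2 cm rig recovers rotations to < 0.5°,
  while thin flattened configurations are several times worse about
  their in-plane axes — an observability property, not an implementation
  artifact.
- `I_r̂` requires a unit axis (no silent normalization); tensors are
  symmetrized only within 10⁻¹² tolerance.
- All internal computation is SI; unit conversion (mm ⇄ m) happens only
  at the I/O boundary. Metrics CSVs round-trip finite values to 10⁻¹²
  relative and preserve missing values exactly.

## Known limitations

- Uniform-density body and rod legs; no per-segment density.
- The template's `d` is the distance to the pivot *point*; when the
  true rotation axis passes near but not through that point (diagonal
  axes through a caudal contact), `ω_orbital` is biased low by the
  along-axis offset — visible as `ω_spin:ω_orbital > 100 %` even before
  articulation effects.
- The ellipsoid body stand-in reproduces the scale and flattening of the
  real animal but not its antero-posterior asymmetry; mesh-dependent
  outputs (principal moments, PE landscape basins) are only
  qualitatively comparable to measurements on photogrammetric meshes.
- Segment-interior ground contacts are not interpolated; only tracked
  endpoints enter the support polygon.
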