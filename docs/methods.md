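# Methods

This note documents the models and procedures implemented in `kinemimic`,
the assumptions behind them, the defaults and why they were chosen, and the
limits of what the synthetic-data tests can show.

## Coordinates and conventions

Right-handed, z-up world frame; meters and radians. Quaternions are
scalar-first `[w, x, y, z]`, unit norm, canonicalized to non-negative
scalar part wherever a unique representative matters (the unit-quaternion
double cover maps `q` and `-q` to one rotation). "Egocentric" always means
the heading frame — the yaw-only part of the root rotation — so that the
gravity-direction observation stays informative while heading dependence is
removed. Rotation *differences* are reported as rotation vectors
(axis x angle, 3 channels) of the shortest arc.

## Body model and kinematic stand-in for physics

A `KinematicTree` is a parent-first list of rigid bodies with fixed local
offsets, articulated by hinge or slide joints with box ranges; at most one
free joint is allowed, only at the root. Marker sites and end effectors are
fixed offsets on bodies. Actuators are metadata (per-joint torque gain
`tau_max` and velocity limit `v_max`); there are no muscle dynamics.

There is no physics engine here, by design. The environment integrates at
the velocity level: `q <- clip(q + a * v_max * dt, range)` per joint, with
six analogous channels (world-frame translation, rotation-vector rotation)
for a free root. Torques are *reported* as `a * tau_max` in observations but
have no dynamical effect. Contacts reduce to height tests of end-effector
sites against the ground (threshold 5 mm by default). Consequences:

- Everything observational (rewards, terminations, observations,
  normalization, survival curves) is exact and testable.
- Nothing dynamical is: no inertia, momentum, contact forces, or
  fall dynamics. A "fall" only happens if a policy steers the root out of
  its healthy height band. Passing tests therefore validate the *learning
  and measurement contracts*, not the transferability of any trained gait
  to a physical simulator.

## Synthetic keypoints

The generator emulates multi-camera pose tracking: forward-kinematics site
positions plus isotropic Gaussian noise per coordinate, with a validity
mask for missing markers. Defaults used in tests: tracking noise 0-5 mm
(typical landmark accuracy of modern trackers at this body scale), 20-80
frame clips at 50 Hz, smooth sinusoidal whole-body trajectories that keep
every joint identifiable. Real tracking differs in ways the generator does
not model: outliers, correlated (not isotropic) errors, occlusion bursts,
and model mismatch between the skeleton and the animal. STAC results on
synthetic data are therefore upper bounds on real-data behavior.

## STAC

The maximum-likelihood registration objective under isotropic Gaussian
observation noise reduces to the summed squared site-to-keypoint distance,
jointly over per-frame poses and global marker offsets. The implementation
alternates:

1. **Tracking** (`solve_pose`, per frame, warm-started from the previous
   frame): projected gradient descent in three phases — root only, full
   body, per-part refinement. Plain fixed-step PGD crawls on this problem
   because root translation and distal joints have curvatures differing by
   orders of magnitude, so the gradient steps are preconditioned by the
   diagonal Gauss-Newton curvature (squared Jacobian column norms), and the
   phase sequence is finished by a full-Jacobian projected damped
   Gauss-Newton (Levenberg-Marquardt) polish plus exact coordinate-wise
   1-D minimizations (closed-form `atan2` rotation fit per hinge, Kabsch
   fit for the free root). For serial chains a greedy root-to-tip pass —
   each joint aligning only the markers it directly owns — hops out of the
   folded-chain local minima that descent methods find; the best pose seen
   is returned, so the returned objective never exceeds the initial one and
   every step respects the box projection.
2. **Calibration** (`calibrate_offsets`): SGD over sampled frames
   (without replacement per epoch by default) on the same objective; the
   per-frame, per-marker gradient is `2 R^T (site - v)`. Step size 0.25
   because the per-frame Hessian in the offset is exactly `2 I`.
3. **Joint refinement**: a damped Gauss-Newton over *all* poses and offsets
   with a Schur complement on the offset block. Pure alternation converges
   linearly along a nearly flat valley in which offset error is traded
   against joint angles; the joint step removes that coupling at a cost
   linear in the number of frames.

**Identifiability.** Marker offsets on a *leaf* body can be rotated rigidly
about that body's hinge axis while the joint angle absorbs the rotation —
an exact gauge freedom invisible to any keypoint data. A weak quadratic
prior (`offset_reg`, default 1e-4) pulls offsets toward the model's nominal
bindings, fixing the gauge as the orbit point nearest the nominal model
(equivalently, the MAP estimate under a broad Gaussian prior on marker
placement) while biasing well-constrained directions negligibly. Recovery
tests perturb true offsets only along identifiable directions; the gauge
directions are exercised separately (a never-observed marker must keep its
initial offset).

**Long sessions** are split into overlapping segments solved independently
(order-independent by construction). Overlaps are blended per channel with
the sigmoid crossfade weight `m_j = (1 + tanh(s (x_j - c)))/2` with
`c = 0.5`, `s = 10`; root quaternions use normalized linear interpolation
with the same weights and shortest-arc sign correction, because elementwise
blending of quaternion components leaves the unit sphere. Joint-range
feasibility survives blending since box constraints are convex. Per-segment
calibrated offsets are averaged for the final report and the stitched
trajectory's sites and objective are recomputed under those offsets.

Velocities are central finite differences at the series rate (one-sided at
the ends); angular velocity is the rotation-vector rate of the relative
root rotation.

## Imitation environment

Observations: proprioceptive block (joint angles and velocities, applied
torques, root height, gravity direction in the agent frame, egocentric
end-effector positions) plus a reference block of egocentric differences to
the next `L = 5` reference frames (root position, quaternion difference as
a rotation vector, joint differences, per-body position differences),
holding the final frame at clip end. The look-ahead length is the one
quantity here with a stated upstream value; all the rest are configurable
with these defaults, chosen at scales matching the fixture bodies
(~0.2-0.4 m, joint ranges ~1-1.5 rad):

| parameter | default | meaning |
|---|---|---|
| lambda (pos, quat, joint, ee) | 0.25 each | reward weights |
| sigma_pos | 0.1 m | position kernel scale |
| sigma_quat | 0.3 rad | orientation kernel scale |
| sigma_joint | 0.5 rad | joint-vector kernel scale |
| sigma_ee | 0.05 m | effector kernel scale |
| healthy z | [-0.5, 1.0] m | fall band |
| max pos / ori / joint error | 0.3 m / 1.5 rad / 5 rad | divergence cutoffs |
| n_init | 10 | random start frames per clip |
| reset noise | 0.01 | pose/velocity jitter at reset |
| dt | 1 / clip rate (0.02 s at 50 Hz) | control step |

Each reward term is `exp(-d^2 / (2 sigma^2))` in its own metric, so each
lies in (0, 1] and the total at perfect tracking equals the weight sum.
Observation normalization uses Welford/Chan streaming statistics (merge of
two stat sets equals the statistics of the concatenation, which is what
makes round-wise updates order-safe); statistics update after each
collection round and are frozen within one, and the standard deviation is
floored at 1e-6.

Survival curves count an episode as terminated from its first early
termination onward; reaching the end of the reference clip is a
*realignment* (fresh reset), not a termination.

## Policy and PPO

Encoder: reference observation -> diagonal Gaussian over the latent
intention `z` (reparameterized sampling; the mean at inference). Decoder:
`(z, proprio)` -> pre-squash Gaussian -> `tanh` (actions strictly inside
(-1, 1)); the log-density includes the change-of-variables correction via
the stable identity `log(1 - tanh(u)^2) = 2(log 2 - u - softplus(-2u))`.
Value: MLP on the full normalized observation (normalized rather than raw,
for symmetry with the actor). Hidden layers use SiLU + layer normalization
and LeCun-uniform fan-in init.

The AR(1) prior regularizes the latent sequence: first latent against
`N(0, I)`, later ones against `N(alpha z_{t-1}, (1 - alpha^2) I)` with
`alpha = 0.95` (stationary variance 0.0975, so the marginal latent scale
stays ~1). Its KL weight ramps linearly from 0 to 1e-3 over the first 10%
of training steps — the ramp keeps early exploration unconstrained; both
ramp length and final weight are config and were fixed before the
end-to-end checks were tuned around them.

PPO specifics: the stored log-probability is the *joint* density
`log q(z | s^g) + log p(a | z, s^p)` and the clipped ratio is taken over
that joint — this keeps the surrogate well-defined without marginalizing
the bottleneck. Advantages are GAE (`gamma = 0.97`, `lambda = 0.95`) with
episode boundaries cutting the recursion, normalized per batch (mean 0,
sd 1). A small sample-based entropy bonus (coefficient 1e-3) guards
against premature variance collapse. Toy-scale defaults: 16 environments,
32-frame unrolls, 4 minibatches of 8 trajectories, 8 epochs per batch,
Adam at 5e-4, latent dimension 8 and 2x64 hidden layers for the 1-DoF toy
(the 60-dim latent of the full-scale analyses is the package default for
`PolicyParams`).

Two toy environments ship with the trainer (`kinemimic train-toy`):
`track1d`, the welded-base 1-DoF pendulum following a sinusoid, and
`quadruped`, the free-root quadruped fixture following a scripted
gait-like clip (14 action channels). Training metrics stream as JSONL
rows with the per-term reward means (position, orientation, joint,
effector), the loss terms and the KL weight.

The end-to-end check trains on a 0.5 Hz, 0.8 rad sinusoid at 50 Hz for
2x10^5 steps per seed — sized so the oracle controller (clipped reference
delta) can track essentially perfectly and a PPO run on one CPU finishes in
about three minutes. Transfer reuses the decoder in three modes — frozen
(only the task head trains), learnable (decoder fine-tunes), scratch (no
decoder) — with the frozen contract enforced by which parameters receive
gradients, and verified bit-exactly in tests.

Networks are differentiated by a ~300-line reverse-mode tape over numpy
arrays (`kinemimic.autodiff`), gradient-checked against central finite
differences in the test suite.

## Bowl escape

Terrain defaults `N = 128`, `h = 2 m`, `v = 0.2 m`, bowl `sigma = 1.25`,
`A = -10`, noise periods `Rx = Ry = 8`, gate radii `0.05 N` / `0.25 N`.
Perlin gradients are unit 2-vectors at uniformly random angles per lattice
node from the seeded generator; lattice indexing is modulo the period
counts and sampling is on `[0, 1)`, which together make the tile seamless.
The quintic fade has zero value and slope at 0 and unit value with zero
slope at 1, so lattice nodes are exact zeros of the field. The composed
raw height is `(1 - w) B + w (B + lambda P~)` with the smoothstep radial
gate `w`; normalization to `[0, 1]` is exact (`min = 0`, `max = 1`).
World-to-grid index mapping floors `u (N - 1)` and clamps at the border.

Reward: `r = r_esc * r_up + r_spd` in `[0, 2]`. The linear tolerance is 1
inside its bounds and decays linearly to 0 at distance `margin` outside;
with coincident bounds it is the triangular peak used for the speed term
(1 at `v* = 0.75 m/s`, 0 at 0 and at `2 v*`). Uprightness averages the
torso and head tolerances on the dot of their local z-axes with world up,
bounds `[cos theta, inf)` and margin `1 + cos theta` (default tilt
`theta = 0`, so a fully inverted body scores exactly 0). In the kinematic
stand-in the head's local frame coincides with the root's unless supplied
explicitly. Failure: torso height at or below terrain height plus
`epsilon = 0.03 m` (boundary inclusive).

## Analyses

Contact (for gait segmentation) is a foot-site height below a configurable
threshold, default 5 mm. Stance onsets are rising edges of the contact
indicator, optionally debounced by a minimum contact duration; cycles run
from one onset of the reference (left fore) limb to the next, with the
trailing incomplete cycle discarded. Phase normalization resamples each
cycle to 100 points with a cubic spline (exact at the endpoints); cycles
shorter than 4 frames lack cubic support and are skipped with a log entry.
Time-delay embedding concatenates `window` consecutive frames (a 31-frame
window over 60 latent channels gives 1860 dimensions). PCA is
mean-centered with variance-explained fractions from the eigenvalue
ratios; clip/timestep structure can be reshaped back after projection.

## Determinism

Every stochastic entry point takes an explicit seed or `Generator`; a root
seed fans out to per-component seeds through `numpy.random.SeedSequence`
spawning (values truncated below 2^31). Under serial execution, repeated
runs are bit-identical; this is asserted for keypoint synthesis, rollout
collection, heightfield generation and the CLI's end-to-end STAC path.

## Known limitations

- The kinematic integrator cannot exhibit dynamical failure modes
  (slipping, falling under gravity, momentum transfer); termination
  statistics are only as meaningful as the thresholds that define them.
- The greedy chain pass assumes markers distal to every joint; a chain
  whose most distal joint has no downstream marker leaves that joint
  unobservable (the fixtures add a tail-tip marker for exactly this
  reason).
- STAC offset recovery is limited by the gauge freedoms described above;
  on real data the same degeneracy appears as arbitrariness in marker
  placement along symmetric directions.
- PPO at toy scale says nothing about the stability of billion-step
  training; it validates the estimator plumbing (ratios, GAE, KL ramp,
  normalization), not large-scale optimization behavior.
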