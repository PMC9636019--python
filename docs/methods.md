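# Methods

`acmpose` reconstructs full-body 3D skeletal kinematics of freely moving
rodents from multi-camera 2D surface-marker detections. This note
describes the model, the estimation machinery, the synthetic study
conditions the test suite runs under, and the design decisions taken
where more than one reasonable choice existed.

## The skeleton model

The skeleton is a rooted kinematic tree with joints as vertices and
bones as edges: one head edge, four spine edges (cervical, thoracic,
lumbar regions and sacrum), five tail edges, four edges per front limb
(clavicle, humerus, radius/ulna, metacarpal+phalanges) and five per
hind limb (pelvis, femur, tibia/fibula, tarsus, phalanges) — 28 edges
and 29 joints in total. In the resting pose every bone points along +z
of the world frame except the clavicle and pelvis edges, which lie in
the x–y plane and stay fixed during pose estimation. Each bone carries
a local frame in which rotations about x are flexion/extension, about y
abduction/adduction and about z internal/external rotation.

Bone rotations are Rodrigues (axis–angle) vectors whose individual
components are limited per axis. Axial bones (head, spine, tail) have
±90° limits on x and y and a frozen z axis; limb limits are authored
ranges of plausible quadruped mobility re-expressed relative to the
resting pose, shipped as editable YAML
(`acmpose/data/skeleton_rodent.yaml`) together with the marker layout
and the allometric priors. A degenerate (0°, 0°) pair freezes the axis:
it is removed from the state rather than squeezed through a zero-width
map.

The latent pose state per frame is the 3D root translation, a 3-DOF
global root orientation applied to all children of the root joint, and
the free bone-rotation variables: with the shipped configuration,
3 + 3 + 44 = 50 scalars, of which 47 are rotation variables. The global
orientation is attached to the root *joint* rather than to any single
bone: the root has several child bones (sacrum, tail, both pelvis
edges) whose own rotations could not all stand in for a shared body
orientation.

### Bounded angles

The smoother and the optimizers work with unconstrained variables; each
rotation component is mapped into its limit interval by an error
function sigmoid

    f(u) = m + r · erf(√π · u / (2r)),   m = midpoint, r = half-range,

which has slope exactly 1 at u = 0 and approaches the bounds
asymptotically, so every estimated pose respects every limit by
construction. f(0) is the interval midpoint (for symmetric limits, the
resting pose); the midpoint convention was an open choice and is fixed
here because it makes the all-zeros state a neutral, feasible pose for
any limit table. In floating point the map saturates to the bound
exactly for |u| ≳ 4r; outputs are clipped so containment is exact.

### Symmetry and allometry

The body is mirror-symmetric in the y–z plane (+x to the animal's
left). Bilateral bones share one length; bilateral marker offsets are
exact mirror images (negated x). Learning optimizes only the center and
left-side parameters and infers the right side by mirroring, so learned
skeletons are symmetric exactly, not approximately. Limb bone lengths
carry box priors: for rats a linear weight→length relationship
(intercept + slope · body weight), for mice adult constants, with
bounds mean ± 10 s.d. Axial bones are unconstrained.

### Markers

43 surface markers (14 anatomical landmarks + 29 painted spots), each
rigidly attached to one joint via a 3D offset in that joint's local
frame, with per-axis box bounds (±2 cm default; center-line markers
have x pinned to 0). Two layout rules matter for identifiability and
are deliberate:

- every joint carries at least one marker — a two-bone chain whose
  middle joint is unmarked leaves the two lengths only jointly
  constrained (the chain can trade bend against length);
- markers on terminal vertices (nose, finger/toe tips, tail tip) are
  pinned to the joint itself, because an offset along the last bone is
  exactly indistinguishable from that bone's length.

## Camera model

Standard pinhole with second-order radial distortion: normalized
coordinates are scaled by (1 + k1·r² + k2·r⁴) before the intrinsics.
Pixel origin top-left, x right, y down, pixel centers at integers.
Undistortion inverts the radial polynomial by Newton iteration on the
radius. Triangulation back-projects undistorted rays and takes their
least-squares intersection; when more than two detections are offered,
only the two with the highest confidence are used (the rule of the
skeleton-free surface baseline), ties broken by lower camera index.
Reprojection errors above 5 px are flagged for review, strictly
greater-than.

## Skeleton learning

Bone lengths and marker offsets are learned jointly with all per-frame
poses by minimizing the sum of squared pixel distances between manual
labels and the projected model markers, under the box constraints, with
the same bounded-angle parameterization as tracking. The joint problem
is severely nonconvex (collapsed-bone and flipped-joint local minima),
so the solver is staged:

1. **Initialization from the labels.** Labels are triangulated; each
   joint's position is estimated from the markers attached to it; a
   chain IK turns these into per-frame poses (minimal rotation of each
   bone toward its child-joint estimate, clipped 5% inside the limits;
   the hip-to-hip line pins the global lateral axis exactly because the
   pelvis edges are rigid in the root frame). Length classes start at
   the median adjacent-joint distance clipped to the prior box; offsets
   start at zero.
2. **3D alternation.** For fixed poses, marker positions are *affine*
   in the lengths, offsets and per-frame root translations, so the
   skeleton half is one exact box-constrained linear least-squares
   solve; for a fixed skeleton the poses split into independent small
   per-frame 3D fits. A few rounds of this alternation resolve the
   gross geometry.
3. **Joint pixel refinement.** Damped Gauss–Newton on the full pixel
   objective with the bundle-adjustment Schur complement: the per-frame
   pose blocks are eliminated analytically, leaving a ~100-variable
   skeleton system per iteration, so exact steps cost milliseconds.
4. **Reseed and repair.** Individual frames stuck in a wrong pose basin
   bias the shared skeleton; every frame is re-fit from a fresh
   label-based initialization and the better pose is kept, followed by
   re-polishing. Length classes that end far (>25% or >0.3 cm) from
   their direct triangulation-based estimates are reset and the fit
   retried, keeping whichever solution has the lower objective.

On noiseless labels this recovers the generator's skeleton to machine
precision; with 1 px label noise the worst bone is typically within
3–5% (the knee/tail region is the least identified). A known
limitation: under noise a rare label realization can leave one tail
bone in a collapsed configuration whose objective is within ~2% of the
correct basin; the repair stage usually, but not always, escapes it.

The squared-residual loss (rather than unsquared distances) was chosen
for smoothness; per-frame poses use the bounded parameterization so
limits hold during learning too.

## Probabilistic tracking

Tracking is a nonlinear state-space model: hidden states are poses,
the transition is a Gaussian random walk (identity mean — temporal
smoothness enters only through the learned transition covariance), and
the measurement function is bounding → forward kinematics → projection
of all markers into all cameras (up to 43 × 4 × 2 = 344 coordinates).
Detections with confidence below 0.9 are treated as missing; missing
coordinates are handled by updating on the observed block only, which
is algebraically identical to deleting those measurement rows.

Inference is an unscented Kalman filter with a Rauch–Tung–Striebel
backward pass. Because the transition mean is the identity, prediction
and the backward pass are exact; sigma points (scaled UT, defaults
α = 10⁻², β = 2, κ = 0; covariance square roots by Cholesky with
escalating jitter from 10⁻⁹) enter only in the measurement update. The
noise parameters — initial state mean and covariance, full transition
covariance, and the diagonal of the measurement covariance
(off-diagonals held at zero) — are learned by EM: the E-step is the
smoother, the M-step is closed form from the smoothed moments
(including lag-one covariances, which are exact for the identity
transition). All covariances are initialized as diagonal matrices with
0.001 in every entry; the initial state mean is a least-squares pose
fit to the detections of one of the first few frames (the
best-fitting of the first five — one badly occluded start frame
otherwise anchors the whole sequence in a wrong basin). The filter
log-likelihood is the monitored objective; EM stops on relative change
below 10⁻⁴ or at the iteration cap, and any decrease beyond tolerance
is reported in the trace rather than silently ignored. Posterior
uncertainty of 3D positions is obtained by sampling the smoothed
Gaussians and pushing the draws through bounding + forward kinematics
(1000 draws by default, deterministic given the seed).

Four model variants isolate the two constraint types: `acm` (limits +
smoothing), `temporal` (smoothing only), `joint_angle` (limits only,
per-frame fits initialized from the previous frame), `naive` (neither).
Relaxing replaces every non-degenerate limit pair by (−180°, 180°);
frozen (0°, 0°) axes stay frozen, so the state dimension is unchanged.
Per-frame fits carry the previous pose forward when fewer than 6
coordinates are observed, and retry from a fresh label-based
initialization when the residual RMS exceeds 10 px, so one bad frame
cannot derail the rest of the sequence. The skeleton-free `surface`
baseline triangulates each marker from its two highest-confidence
detections.

## Kinematic analyses

- **Animal-centric frame**: origin at the lumbosacral joint, x = the
  horizontal projection of the direction to the cervicothoracic joint,
  z world-vertical, y = z × x. Positions are re-expressed, not scaled
  by any body length (a scaling option exists but defaults off).
- **Derivatives**: central 8th-order finite differences (Fornberg
  weights) in the interior, one-sided same-order stencils at the four
  edge samples so trace lengths are preserved.
- **Gait cycles**: swing midpoints are strict local maxima of the
  anteroposterior velocity above 25 cm/s, with a prominence floor of 5%
  of the trace range to suppress noise ties; ±200 ms windows aligned by
  the peak are averaged into population mean ± s.d. traces.
- **Periodicity**: magnitude-spectrum argmax per limb (excluding DC)
  with a shared-bin flag; damped sinusoids A·exp(−λ|τ|)·cos(2πfτ) are
  fit to autocorrelations over positive lags (lag 0 is the
  normalization point — including it lets an arbitrarily fast decay
  explain a spike, which would score white noise as a good fit) by
  multi-start least squares seeded from the five largest spectral
  peaks; inter-extremum intervals use a sliding min/max filter equality
  test (120-frame default) with flat windows excluded.
- **Angular velocity from orientations**: per-step angle of
  R_nᵀR_{n+1} times the frame rate; the spin axis does not enter.
- **Jumps**: spine + hind-limb joint angles are averaged; the trace
  shows local min, local max, global min, local max, local min in
  order; start/end are the first/last local minima and the midpoint the
  global minimum. Jump distance is the planar (x–y) displacement of the
  hind-foot centroid (ankle, metatarsophalangeal and toe joints, both
  limbs pooled) between start and end.
- **Floor-truth evaluation**: planar paw-center error, paw-axis angle
  error (center → digit), and errors binned by frames since the nearest
  successful detection (minimum of past and future for smoothed
  variants, past only otherwise), dropping bins with fewer than 10
  samples.
- Rank correlations (with two-tailed p-values) and the comparison
  utilities wrap `scipy.stats`; constant series are flagged, not
  errors.

## Synthetic study conditions

The generator provides fully ground-truthed scenes so every stage is
testable without recordings. It emulates the structure the pipeline
assumes; it is **not** a biomechanical gait model, and passing on it
shows correctness of the estimation machinery, not performance on real
video (no fur, no detector-specific error structure, no soft-tissue
motion of markers relative to bones, no calibration error).

- Rig: four synchronized 1280×1024 px cameras on an overhead ring
  (radius 65 cm, height 85 cm, focal 1600 px, k1 = −0.1), every
  workspace point visible to ≥2 cameras.
- Gait scenes: limb flexion sinusoids at the stride frequency (default
  3 Hz) with diagonal pairs in phase and contralateral limbs in
  anti-phase, axial sway, a laterally-swept tail, forward translation
  at 10 cm/s, feet grazing the floor plane; 100 Hz, 5 s by default.
  Swing-velocity peaks exceed the 25 cm/s detection threshold by
  construction.
- Varied-pose scenes (for skeleton learning): every free DOF drawn
  uniformly within the central 60% of its limit range per frame with
  wandering position and heading, emulating the pose variety of a
  manual labeling session.
- Detections: exact projections plus i.i.d. Gaussian pixel noise
  (default σ = 1 px); occlusions are geometric bursts (mean 20 frames)
  per marker-camera pair at 10% stationary probability; occluded
  entries are dropped or assigned confidence uniform in [0, 0.9),
  visible entries get 0.9 + 0.1·(1 − noise-magnitude percentile).
- Ground-truth skeleton: limb lengths at the allometric prior means,
  axial lengths at authored constants for a ~300 g rat, marker offsets
  drawn once from a fixed seed inside 40% of their boxes.
- Floor truth: frames with a hind toe within 0.6 cm of the floor plane
  are stance; paw center (metatarsophalangeal) and digit (toe) x–y are
  recorded.

Problem sizes used by the test suite — 100 labeled frames for skeleton
learning, 10 s scenes for gait-frequency recovery, a 2.5 s scene for
the constraint-ablation comparison, 8 EM iterations for tracked scenes
— are the package's default desk-scale experiment sizes; the estimation
code itself has no such limits.

## Numerical choices

- Covariance repairs: symmetrization plus eigenvalue flooring at
  10⁻¹², applied after measurement updates and M-steps.
- Posterior sampling uses an eigendecomposition square root, exact for
  singular covariances.
- Triangulation declares rays degenerate when the normal-equation
  condition number exceeds 10⁸.
- The per-frame and learning optimizers box the unconstrained
  coordinates at ±50 (the sigmoid saturates far earlier) and the
  translation at ±10³ cm to keep ill-conditioned frames from running
  away.
- All randomness flows through explicit seeds; identical seeds give
  bit-identical scenes and posterior samples.

## Known limitations

- Skeleton learning can, for unlucky noisy label sets, return one tail
  bone in a collapsed configuration (see above); inspecting the
  objective trace and the deviation between learned lengths and the
  direct triangulation estimates exposes such cases.
- The EM-learned diagonal measurement variances will absorb systematic
  reconstruction errors (e.g., a limb stuck in a wrong basin) instead
  of flagging them; the likelihood alone is therefore not a quality
  certificate. The distal foot joints (tarsus, phalanges — short
  1-DOF hinges) are the most susceptible: a wrong hinge configuration
  can persist through a whole smoothed sequence, attenuating that
  foot's velocity trace while the rest of the body tracks well.
  Inspecting the learned per-marker variances exposes such limbs.
- The smoother is batch-only and O(T) per EM iteration with dense
  n = 50 covariances; no real-time operation is attempted.
- Mouse support reuses the rat topology with constant-length priors;
  no mouse-specific limit table is shipped.
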