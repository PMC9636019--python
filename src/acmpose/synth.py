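"""Fully ground-truthed synthetic scenes.

Generates everything the pipeline consumes — a known skeleton, gait-like
pose sequences, a virtual multi-camera rig, projected detections with
Gaussian pixel noise, burst occlusions and detector-style confidences, and
floor-contact truth — so that skeleton learning, smoothing and the
kinematic analyses can be validated against exact ground truth.

The motion generator is not a biomechanical gait model: it is a test
harness producing the structure the analyses assume — periodic limb
swings at a configurable stride frequency, diagonal limb pairs in phase
and contralateral limbs in anti-phase, forward translation, and angles
that always respect the configured joint limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cameras import CameraModel, CameraRig, project
from .skeleton import (
    BoneLengthPrior,
    JointAngleLimits,
    MarkerLayout,
    SkeletonGraph,
    SkeletonParams,
    build_default_skeleton,
    count_state_dim,
    forward_kinematics_batch,
    symmetrize,
    unbound_angles,
)

#: axial bone lengths (cm) used as ground truth for a ~300 g rat; limb
#: bones take their allometric prior mean
AXIAL_LENGTHS_CM = {
    "head": 3.0,
    "cervical": 2.5,
    "thoracic": 4.0,
    "lumbar": 4.0,
    "sacrum": 2.0,
    "tail_1": 3.0,
    "tail_2": 2.8,
    "tail_3": 2.5,
    "tail_4": 2.2,
    "tail_5": 2.0,
}

#: base orientation mapping the resting body frame (z forward-along-spine,
#: x left, y dorsal) onto the world frame (x forward, y left, z up)
R_BODY_TO_WORLD = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


def make_virtual_rig(
    n_cameras: int = 4,
    radius_cm: float = 65.0,
    height_cm: float = 85.0,
    image_size: tuple[int, int] = (1280, 1024),
    focal_px: float = 1600.0,
    k1: float = -0.1,
    k2: float = 0.0,
    target: tuple[float, float, float] = (0.0, 0.0, 3.0),
) -> CameraRig:
    """Cameras on an overhead ring, all aimed at the arena center."""
    if n_cameras < 2:
        raise ValueError("a rig needs at least two cameras")
    w, h = image_size
    target = np.asarray(target, dtype=float)
    cams = []
    for i in range(n_cameras):
        phi = 2.0 * math.pi * i / n_cameras
        center = np.array(
            [radius_cm * math.cos(phi), radius_cm * math.sin(phi), height_cm]
        )
        zc = target - center
        zc = zc / np.linalg.norm(zc)
        up = np.array([0.0, 0.0, 1.0])
        xc = np.cross(zc, up)
        if np.linalg.norm(xc) < 1e-9:
            xc = np.array([1.0, 0.0, 0.0])
        xc = xc / np.linalg.norm(xc)
        yc = np.cross(zc, xc)
        R = np.stack([xc, yc, zc])          # world -> camera rows
        t = -R @ center
        cams.append(
            CameraModel(
                fx=focal_px, fy=focal_px, cx=(w - 1) / 2.0, cy=(h - 1) / 2.0,
                k1=k1, k2=k2, R=R, t=t, width=w, height=h, name=f"cam{i}",
            )
        )
    return CameraRig(cameras=cams)


def make_true_params(
    graph: SkeletonGraph,
    layout: MarkerLayout,
    prior: BoneLengthPrior,
    offset_seed: int = 12345,
) -> SkeletonParams:
    """Ground-truth skeleton parameters for the generator.

    Limb bone lengths sit at their allometric prior mean, axial bones at
    authored constants; marker offsets are drawn once from a fixed-seed
    uniform distribution inside their boxes (zero where the box is
    degenerate) and mirrored to the right side.
    """
    lengths_half = dict(AXIAL_LENGTHS_CM)
    for b in graph.bones:
        cls = b.length_class
        if cls not in lengths_half:
            lengths_half[cls] = prior.mean.get(cls, 1.0)
    rng = np.random.default_rng(offset_seed)
    offsets_half = {}
    for m in layout.markers:
        if m.side == "right":
            continue
        lo, hi = m.bounds_cm[:, 0], m.bounds_cm[:, 1]
        # stay comfortably inside the box so learning never sits on a bound
        off = rng.uniform(-0.8, 0.8, size=3)
        off = np.clip(off, 0.4 * lo, 0.4 * hi)
        offsets_half[m.name] = off
    return symmetrize(graph, layout, lengths_half, offsets_half)


# --- gait pose synthesis ---------------------------------------------------

# sinusoidal joint programs: bone -> (amplitude deg on x, phase key)
# diagonal pairs (LF+RH, RF+LH) move in phase; contralateral limbs anti-phase
_LIMB_PROGRAM = {
    "femur_left": (27.0, 0.0),
    "tibia_left": (18.0, 0.5),
    "tarsus_left": (12.0, 0.25),
    "phalanges_left": (10.0, 0.25),
    "femur_right": (27.0, 1.0),
    "tibia_right": (18.0, 1.5),
    "tarsus_right": (12.0, 1.25),
    "phalanges_right": (10.0, 1.25),
    "humerus_left": (20.0, 1.0),
    "radius_left": (14.0, 1.5),
    "metacarpal_left": (10.0, 1.25),
    "humerus_right": (20.0, 0.0),
    "radius_right": (14.0, 0.5),
    "metacarpal_right": (10.0, 0.25),
}

# axial sway (deg): (bone, axis, amplitude, phase in half-cycles, static offset)
_AXIAL_PROGRAM = [
    ("sacrum", 1, 4.0, 0.0, 0.0),
    ("lumbar", 1, 6.0, 0.5, 0.0),
    ("thoracic", 1, 6.0, 1.0, 0.0),
    ("cervical", 0, 8.0, 0.0, -10.0),
    ("head", 0, 10.0, 0.5, 10.0),
    # tail: bends through y rotations (horizontal sweep in the world frame)
    # so it trails behind the body without diving below the floor plane
    ("tail_1", 0, 3.0, 0.0, 8.0),
    ("tail_1", 1, 6.0, 0.0, 75.0),
    ("tail_2", 0, 3.0, 0.5, 5.0),
    ("tail_2", 1, 6.0, 0.5, 55.0),
    ("tail_3", 1, 8.0, 0.0, 30.0),
    ("tail_4", 1, 8.0, 0.5, 10.0),
    ("tail_5", 1, 8.0, 1.0, 0.0),
]


def simulate_gait(
    graph: SkeletonGraph,
    params: SkeletonParams,
    gait_freq_hz: float = 3.0,
    speed_cm_s: float = 10.0,
    duration_s: float = 5.0,
    fps: float = 100.0,
    floor_clearance_cm: float = 0.3,
    heading_deg: float = 0.0,
) -> np.ndarray:
    """True pose sequence (T, state_dim) in unbounded state coordinates.

    Limb flexion angles follow sinusoids at the stride frequency with the
    quadruped phase pattern; the body translates forward at constant
    speed.  Raises if any programmed angle leaves its limits.
    """
    T = int(round(duration_s * fps))
    tgrid = np.arange(T) / fps
    lo, hi = graph.rotation_limits_rad()
    dofs = graph.rotation_dofs()
    n = count_state_dim(graph)

    # bounded rotation angles per DOF (radians)
    angles = 0.5 * (lo + hi) * np.ones((T, len(dofs)))
    omega = 2.0 * math.pi * gait_freq_hz

    def set_angle(bone_name, axis, values_deg):
        i = graph.bone_index[bone_name]
        for k, (ent, ax) in enumerate(dofs):
            if ent == i and ax == axis:
                angles[:, k] = np.radians(values_deg)
                return
        raise KeyError(f"{bone_name} axis {axis} is not a free DOF")

    for bone_name, (amp, phase) in _LIMB_PROGRAM.items():
        i = graph.bone_index[bone_name]
        mid = 0.5 * (graph.bones[i].limits_deg[0, 0] + graph.bones[i].limits_deg[0, 1])
        set_angle(bone_name, 0, mid + amp * np.sin(omega * tgrid + math.pi * phase))
    for bone_name, axis, amp, phase, offset in _AXIAL_PROGRAM:
        set_angle(
            bone_name, axis, offset + amp * np.sin(omega * tgrid + math.pi * phase)
        )

    # global orientation: heading about world z on top of the base mapping
    psi = math.radians(heading_deg)
    Rz = np.array(
        [[math.cos(psi), -math.sin(psi), 0.0],
         [math.sin(psi), math.cos(psi), 0.0],
         [0.0, 0.0, 1.0]]
    )
    from scipy.spatial.transform import Rotation

    rv = Rotation.from_matrix(Rz @ R_BODY_TO_WORLD).as_rotvec()
    for k, (ent, ax) in enumerate(dofs):
        if ent == -1:
            angles[:, k] = rv[ax]

    margin = 1e-6
    if np.any(angles <= lo + margin) or np.any(angles >= hi - margin):
        bad = np.where((angles <= lo + margin) | (angles >= hi - margin))[1]
        raise ValueError(
            f"programmed motion leaves the joint limits at DOF(s) {sorted(set(bad))}"
        )

    poses = np.zeros((T, n))
    poses[:, 3:] = unbound_angles(angles, lo, hi)
    heading_dir = np.array([math.cos(psi), math.sin(psi), 0.0])
    path = (tgrid - tgrid[-1] / 2.0)[:, None] * speed_cm_s * heading_dir
    poses[:, :3] = path

    # drop the body so the lowest foot joint grazes the floor plane z = 0
    joints, _, _ = forward_kinematics_batch(graph, params, poses)
    foot = [graph.joint_index[j] for j in graph.joints if j.startswith(("mtp", "toe"))]
    zmin = joints[:, foot, 2].min()
    poses[:, 2] -= zmin - floor_clearance_cm
    return poses


def simulate_varied_poses(
    graph: SkeletonGraph,
    params: SkeletonParams,
    n_frames: int = 100,
    amplitude_frac: float = 0.6,
    seed: int = 0,
    floor_clearance_cm: float = 1.0,
) -> np.ndarray:
    """Pose sequence with rich articulation, for skeleton-learning labels.

    Manual-label sets cover a wide variety of poses; this emulates that
    by drawing every free rotation DOF uniformly within a central
    fraction of its limit range per frame, with a wandering translation
    and heading.  Returns (n_frames, state_dim) unbounded states.
    """
    rng = np.random.default_rng(seed)
    lo, hi = graph.rotation_limits_rad()
    dofs = graph.rotation_dofs()
    n = count_state_dim(graph)
    mid = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    angles = mid + rng.uniform(-amplitude_frac, amplitude_frac,
                               size=(n_frames, len(dofs))) * half
    # keep the global orientation near upright gait headings
    from scipy.spatial.transform import Rotation

    headings = rng.uniform(-math.pi, math.pi, size=n_frames)
    pitches = rng.uniform(-0.25, 0.25, size=n_frames)
    for t in range(n_frames):
        Rz = Rotation.from_euler("zy", [headings[t], pitches[t]]).as_matrix()
        rv = Rotation.from_matrix(Rz @ R_BODY_TO_WORLD).as_rotvec()
        rv = np.clip(rv, lo[:3] + 1e-3, hi[:3] - 1e-3)
        for k, (ent, ax) in enumerate(dofs):
            if ent == -1:
                angles[t, k] = rv[ax]
    poses = np.zeros((n_frames, n))
    poses[:, 3:] = unbound_angles(angles, lo, hi)
    poses[:, 0] = rng.uniform(-8.0, 8.0, size=n_frames)
    poses[:, 1] = rng.uniform(-8.0, 8.0, size=n_frames)
    joints, _, _ = forward_kinematics_batch(graph, params, poses)
    poses[:, 2] = floor_clearance_cm - joints[..., 2].min(axis=1)
    return poses


def make_labeled_scene(
    seed: int = 0,
    n_frames: int = 100,
    species: str = "rat",
    body_weight_g: float = 300.0,
    noise_sigma_px: float = 0.0,
    n_cameras: int = 4,
):
    """Varied-pose scene with labeled frames for skeleton learning.

    Returns (scene-like tuple: graph, prior, layout, rig, params_true,
    poses_true, labels DataFrame).  With ``noise_sigma_px`` > 0 the
    labels carry i.i.d. Gaussian pixel noise (confidence stays 1).
    """
    graph, limits, prior, layout = build_default_skeleton(species, body_weight_g)
    params = make_true_params(graph, layout, prior)
    poses = simulate_varied_poses(graph, params, n_frames=n_frames, seed=seed)
    _, markers, _ = forward_kinematics_batch(graph, params, poses, layout)
    rig = make_virtual_rig(n_cameras=n_cameras)
    det, clean = render_detections(
        markers, rig, layout.names, noise_sigma_px=noise_sigma_px,
        occlusion_prob=0.0, seed=seed,
    )
    labels = det if noise_sigma_px > 0 else clean
    return graph, prior, layout, rig, params, poses, labels


# --- detection rendering ---------------------------------------------------

def render_detections(
    markers_xyz: np.ndarray,
    rig: CameraRig,
    marker_names: list[str],
    noise_sigma_px: float = 1.0,
    occlusion_prob: float = 0.1,
    mean_burst_frames: float = 20.0,
    drop_prob: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulated detector output: (noisy table, clean table).

    Occlusions are geometric-length bursts per (marker, camera) with the
    requested stationary occlusion probability.  Visible entries carry a
    confidence in [0.9, 1] that decreases with the drawn noise magnitude;
    occluded entries are either dropped (probability ``drop_prob``) or
    kept with a confidence uniform in [0, 0.9).  Points behind a camera
    or outside its image count as occluded.
    """
    if noise_sigma_px < 0:
        raise ValueError("noise sigma must be non-negative")
    if not 0.0 <= occlusion_prob <= 1.0:
        raise ValueError("occlusion probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    T, M, _ = markers_xyz.shape
    rows, clean_rows = [], []
    p_exit = 1.0 / max(mean_burst_frames, 1.0)
    if occlusion_prob in (0.0, 1.0):
        p_enter = occlusion_prob
    else:
        p_enter = min(1.0, occlusion_prob * p_exit / (1.0 - occlusion_prob))
    for ci, cam in enumerate(rig.cameras):
        pc = cam.world_to_camera(markers_xyz.reshape(-1, 3))
        ok_depth = pc[:, 2] > 1e-6
        px = np.full((T * M, 2), np.nan)
        if ok_depth.any():
            px[ok_depth] = project(
                markers_xyz.reshape(-1, 3)[ok_depth], cam
            )
        px = px.reshape(T, M, 2)
        in_img = (
            np.isfinite(px).all(axis=-1)
            & (px[..., 0] >= 0) & (px[..., 0] <= cam.width - 1)
            & (px[..., 1] >= 0) & (px[..., 1] <= cam.height - 1)
        )
        # two-state Markov chain per marker: occluded bursts
        occ = np.zeros((T, M), dtype=bool)
        state = rng.random(M) < occlusion_prob
        u = rng.random((T, M))
        if occlusion_prob >= 1.0:
            occ[:] = True
        elif occlusion_prob > 0.0:
            for t in range(T):
                state = np.where(state, u[t] > p_exit, u[t] < p_enter)
                occ[t] = state
        noise = rng.normal(0.0, noise_sigma_px, size=(T, M, 2))
        nmag = np.linalg.norm(noise, axis=-1)
        # percentile of each noise magnitude within this camera's draws
        ranks = nmag.ravel().argsort().argsort().reshape(T, M) / max(T * M - 1, 1)
        conf_vis = 0.9 + 0.1 * (1.0 - ranks)
        drop = rng.random((T, M)) < drop_prob
        conf_occ = rng.uniform(0.0, 0.9, size=(T, M))
        for t in range(T):
            for m in range(M):
                if in_img[t, m]:
                    clean_rows.append(
                        (t, ci, marker_names[m], px[t, m, 0], px[t, m, 1], 1.0)
                    )
                visible = in_img[t, m] and not occ[t, m]
                if visible:
                    rows.append(
                        (
                            t, ci, marker_names[m],
                            px[t, m, 0] + noise[t, m, 0],
                            px[t, m, 1] + noise[t, m, 1],
                            conf_vis[t, m],
                        )
                    )
                elif in_img[t, m] and not drop[t, m]:
                    rows.append(
                        (
                            t, ci, marker_names[m],
                            px[t, m, 0] + noise[t, m, 0],
                            px[t, m, 1] + noise[t, m, 1],
                            conf_occ[t, m],
                        )
                    )
    cols = ["frame", "camera", "marker", "x", "y", "confidence"]
    return (
        pd.DataFrame(rows, columns=cols),
        pd.DataFrame(clean_rows, columns=cols),
    )


def derive_floor_truth(
    joints_xyz: np.ndarray,
    graph: SkeletonGraph,
    floor_z: float = 0.0,
    contact_threshold_cm: float = 0.6,
) -> pd.DataFrame:
    """Synthetic analog of touch-sensing ground truth.

    Frames in which a hind toe is within ``contact_threshold_cm`` of the
    floor plane are marked stance; the paw center (metatarsophalangeal
    joint) and digit (toe) x-y positions are recorded.  Columns: frame,
    paw, point, x_cm, y_cm.
    """
    rows = []
    for side in ("left", "right"):
        mtp = graph.joint_index[f"mtp_{side}"]
        toe = graph.joint_index[f"toe_{side}"]
        near = np.abs(joints_xyz[:, toe, 2] - floor_z) < contact_threshold_cm
        for t in np.nonzero(near)[0]:
            rows.append(
                (t, f"hind_{side}", "center",
                 joints_xyz[t, mtp, 0], joints_xyz[t, mtp, 1])
            )
            rows.append(
                (t, f"hind_{side}", "digit",
                 joints_xyz[t, toe, 0], joints_xyz[t, toe, 1])
            )
    return pd.DataFrame(rows, columns=["frame", "paw", "point", "x_cm", "y_cm"])


# --- scene container -------------------------------------------------------

@dataclass
class SyntheticScene:
    graph: SkeletonGraph
    limits: JointAngleLimits
    prior: BoneLengthPrior
    layout: MarkerLayout
    params_true: SkeletonParams
    poses_true: np.ndarray          # (T, state_dim), unbounded coordinates
    joints_true: np.ndarray         # (T, n_joints, 3) cm
    markers_true: np.ndarray        # (T, n_markers, 3) cm
    rig: CameraRig
    detections: pd.DataFrame        # noisy + occluded, with confidences
    clean_detections: pd.DataFrame
    floor_truth: pd.DataFrame
    fps: float
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.poses_true.shape[0]


def generate_scene(
    seed: int = 0,
    species: str = "rat",
    body_weight_g: float = 300.0,
    duration_s: float = 5.0,
    fps: float = 100.0,
    gait_freq_hz: float = 3.0,
    speed_cm_s: float = 10.0,
    noise_sigma_px: float = 1.0,
    occlusion_prob: float = 0.1,
    mean_burst_frames: float = 20.0,
    n_cameras: int = 4,
    heading_deg: float = 0.0,
) -> SyntheticScene:
    """One fully ground-truthed gait scene under the default conditions.

    Defaults emulate the recording setup the pipeline targets: four
    synchronized 1280x1024 cameras above the arena at 100 Hz, ~1 px
    detector noise and intermittent burst occlusions.
    """
    graph, limits, prior, layout = build_default_skeleton(species, body_weight_g)
    params = make_true_params(graph, layout, prior)
    poses = simulate_gait(
        graph, params, gait_freq_hz=gait_freq_hz, speed_cm_s=speed_cm_s,
        duration_s=duration_s, fps=fps, heading_deg=heading_deg,
    )
    joints, markers, _ = forward_kinematics_batch(graph, params, poses, layout)
    rig = make_virtual_rig(n_cameras=n_cameras)
    det, clean = render_detections(
        markers, rig, layout.names, noise_sigma_px=noise_sigma_px,
        occlusion_prob=occlusion_prob, mean_burst_frames=mean_burst_frames,
        seed=seed,
    )
    floor = derive_floor_truth(joints, graph)
    cfg = dict(
        species=species, body_weight_g=body_weight_g, duration_s=duration_s,
        fps=fps, gait_freq_hz=gait_freq_hz, speed_cm_s=speed_cm_s,
        noise_sigma_px=noise_sigma_px, occlusion_prob=occlusion_prob,
        mean_burst_frames=mean_burst_frames, n_cameras=n_cameras,
        heading_deg=heading_deg,
    )
    return SyntheticScene(
        graph=graph, limits=limits, prior=prior, layout=layout,
        params_true=params, poses_true=poses, joints_true=joints,
        markers_true=markers, rig=rig, detections=det,
        clean_detections=clean, floor_truth=floor, fps=fps, seed=seed,
        config=cfg,
    )


def labeled_frames(
    scene: SyntheticScene, every: int = 5, max_frames: int | None = None
) -> pd.DataFrame:
    """Manual-label stand-in: clean detections subsampled every k frames."""
    frames = np.unique(scene.clean_detections["frame"])[::every]
    if max_frames is not None:
        frames = frames[:max_frames]
    df = scene.clean_detections[scene.clean_detections["frame"].isin(frames)]
    return df.reset_index(drop=True)
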