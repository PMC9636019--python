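"""Kinematic skeleton model for freely moving rodents.

The skeleton is a rooted tree: joints are vertices, bones are edges.  In
the resting pose every bone points along +z of the world frame except the
clavicle and pelvis edges, which lie in the x-y plane and stay fixed during
pose estimation.  Each bone carries a local frame in which rotations about
x correspond to flexion/extension, about y to abduction/adduction and
about z to internal/external rotation.  Per-axis angle limits freeze an
axis when the limit pair is degenerate (lower == upper); the remaining
free axes, together with the 3D root translation and a 3-DOF global root
orientation, form the latent pose state.

Bone rotations are parameterized by Rodrigues (axis-angle) vectors whose
individual entries are constrained to their limit interval through a
smooth error-function sigmoid: the state itself is unconstrained, the
mapped angle can never leave its limits.

Units: cm for lengths and positions, degrees in configuration files
(radians internally), grams for body weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from scipy.special import erf, erfinv

AXES = ("x", "y", "z")


# ---------------------------------------------------------------------------
# rotation utilities
# ---------------------------------------------------------------------------

def rodrigues(rotvec: np.ndarray) -> np.ndarray:
    """Rotation matrices from Rodrigues vectors, batched over leading axes.

    Parameters
    ----------
    rotvec : (..., 3) array of rotation vectors (radians).

    Returns
    -------
    (..., 3, 3) array of rotation matrices.
    """
    rotvec = np.asarray(rotvec, dtype=float)
    theta = np.linalg.norm(rotvec, axis=-1, keepdims=True)
    small = theta[..., 0] < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        axis = np.where(theta > 0, rotvec / theta, 0.0)
    K = _hat(axis)
    th = theta[..., None]
    eye = np.broadcast_to(np.eye(3), K.shape)
    R = eye + np.sin(th) * K + (1.0 - np.cos(th)) * (K @ K)
    if np.any(small):
        # first-order fallback keeps derivatives finite at the identity
        R_small = eye + _hat(rotvec)
        R = np.where(small[..., None, None], R_small, R)
    return R


def rodrigues_jacobian(rotvec: np.ndarray) -> np.ndarray:
    """Derivative of the rotation matrix w.r.t. each Rodrigues component.

    Returns an array of shape (..., 3, 3, 3) where [..., i, :, :] is
    dR/dr_i (Gallego & Yezzi closed form, with the exact limit at the
    identity).
    """
    rotvec = np.asarray(rotvec, dtype=float)
    R = rodrigues(rotvec)
    nsq = np.sum(rotvec**2, axis=-1)
    out = np.empty(rotvec.shape[:-1] + (3, 3, 3))
    eye = np.eye(3)
    small = nsq < 1e-16
    ImR = eye - R
    for i in range(3):
        e_i = eye[i]
        cross = np.cross(rotvec, ImR @ e_i)
        term = rotvec[..., i, None, None] * _hat(rotvec) + _hat(cross)
        with np.errstate(invalid="ignore", divide="ignore"):
            dRi = (term / np.where(nsq, nsq, 1.0)[..., None, None]) @ R
        dRi = np.where(small[..., None, None], _hat(e_i), dRi)
        out[..., i, :, :] = dRi
    return out


def _hat(v: np.ndarray) -> np.ndarray:
    """Skew-symmetric cross-product matrices, batched."""
    v = np.asarray(v, dtype=float)
    out = np.zeros(v.shape[:-1] + (3, 3))
    out[..., 0, 1] = -v[..., 2]
    out[..., 0, 2] = v[..., 1]
    out[..., 1, 0] = v[..., 2]
    out[..., 1, 2] = -v[..., 0]
    out[..., 2, 0] = -v[..., 1]
    out[..., 2, 1] = v[..., 0]
    return out


# ---------------------------------------------------------------------------
# bounded angle reparameterization
# ---------------------------------------------------------------------------

def bound_angles(u, lower, upper):
    """Map unbounded variables into (lower, upper) via an erf sigmoid.

    f(u) = m + r * erf(sqrt(pi) * u / (2 r)) with m the midpoint and r the
    half-range, so f(0) = m, f has slope exactly 1 at u = 0 and approaches
    the bounds asymptotically.  Works elementwise in whatever unit the
    limits are given in.
    """
    u = np.asarray(u, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if np.any(lower >= upper):
        raise ValueError("bound_angles requires lower < upper for every DOF")
    m = 0.5 * (lower + upper)
    r = 0.5 * (upper - lower)
    # clip: m + r*erf(...) can overshoot the bound by one ulp at saturation
    return np.clip(m + r * erf(math.sqrt(math.pi) * u / (2.0 * r)),
                   lower, upper)


def unbound_angles(a, lower, upper):
    """Inverse of :func:`bound_angles` on the open interval interior."""
    a = np.asarray(a, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    m = 0.5 * (lower + upper)
    r = 0.5 * (upper - lower)
    z = (a - m) / r
    if np.any(np.abs(z) >= 1.0):
        raise ValueError("angles must lie strictly inside their limits")
    return 2.0 * r / math.sqrt(math.pi) * erfinv(z)


def bound_angles_derivative(u, lower, upper):
    """d bound_angles / du — a Gaussian bump, equal to 1 at u = 0."""
    u = np.asarray(u, dtype=float)
    r = 0.5 * (np.asarray(upper, float) - np.asarray(lower, float))
    z = np.minimum(np.abs(u) / r, 1e8)
    return np.exp(-math.pi * z**2 / 4.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bone:
    name: str
    parent_joint: str
    child_joint: str
    segment: str          # head | spine | tail | front_limb | hind_limb
    side: str             # left | right | center
    rest_direction: np.ndarray          # unit 3-vector, parent frame
    limits_deg: np.ndarray              # (3, 2) per-axis [lower, upper]

    @property
    def dof_axes(self) -> tuple[int, ...]:
        """Indices of free rotation axes (non-degenerate limit pairs)."""
        return tuple(
            i for i in range(3) if self.limits_deg[i, 0] < self.limits_deg[i, 1]
        )

    @property
    def length_class(self) -> str:
        """Bilateral bones share one length; strip the side suffix."""
        for suf in ("_left", "_right"):
            if self.name.endswith(suf):
                return self.name[: -len(suf)]
        return self.name


@dataclass
class SkeletonGraph:
    """Rooted kinematic tree plus the state layout it induces."""

    bones: list[Bone]
    root_joint: str
    root_limits_deg: np.ndarray  # (3, 2) global-orientation limits

    # derived, filled in __post_init__
    joints: list[str] = field(default_factory=list)
    bone_index: dict[str, int] = field(default_factory=dict)
    joint_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        names = [b.name for b in self.bones]
        if len(set(names)) != len(names):
            raise ValueError("duplicate bone names")
        self.bone_index = {n: i for i, n in enumerate(names)}
        joints = [self.root_joint]
        seen_children: set[str] = set()
        for b in self.bones:
            if b.child_joint in seen_children or b.child_joint == self.root_joint:
                raise ValueError(
                    f"joint {b.child_joint!r} has more than one parent — not a tree"
                )
            if b.parent_joint not in joints:
                raise ValueError(
                    f"bone {b.name!r}: parent joint {b.parent_joint!r} not defined "
                    "before use (bones must be listed in topological order)"
                )
            seen_children.add(b.child_joint)
            joints.append(b.child_joint)
        self.joints = joints
        self.joint_index = {n: i for i, n in enumerate(joints)}
        # parent bone index per bone; -1 means the bone hangs off the root
        self._parent_bone = np.array(
            [
                -1
                if b.parent_joint == self.root_joint
                else self.bone_index[self._bone_to_joint(b.parent_joint)]
                for b in self.bones
            ]
        )
        self._validate()

    def _bone_to_joint(self, joint: str) -> str:
        for b in self.bones:
            if b.child_joint == joint:
                return b.name
        raise KeyError(joint)

    def _validate(self):
        for b in self.bones:
            if abs(np.linalg.norm(b.rest_direction) - 1.0) > 1e-9:
                raise ValueError(f"bone {b.name!r}: resting direction is not unit")
            if np.any(b.limits_deg[:, 0] > b.limits_deg[:, 1]):
                raise ValueError(f"bone {b.name!r}: lower limit exceeds upper")
        for b in self.bones:
            if b.side == "left":
                other = b.name.replace("_left", "_right")
                ob = self.bones[self.bone_index[other]]
                if not np.array_equal(b.limits_deg, ob.limits_deg):
                    raise ValueError(f"bilateral limits differ for {b.length_class!r}")
        if np.any(self.root_limits_deg[:, 0] >= self.root_limits_deg[:, 1]):
            raise ValueError("root orientation limits must be non-degenerate")

    # --- state layout ---------------------------------------------------

    @property
    def n_bones(self) -> int:
        return len(self.bones)

    def parent_bone_index(self) -> np.ndarray:
        return self._parent_bone

    def rotation_dofs(self) -> list[tuple[int, int]]:
        """State ordering of rotation variables as (entity, axis) pairs.

        Entity -1 is the global root orientation; entities >= 0 index
        bones.  Order: root x,y,z first, then each bone's free axes.
        """
        dofs = [(-1, a) for a in range(3)]
        for i, b in enumerate(self.bones):
            dofs.extend((i, a) for a in b.dof_axes)
        return dofs

    def rotation_limits_rad(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for ent, ax in self.rotation_dofs():
            lim = self.root_limits_deg if ent < 0 else self.bones[ent].limits_deg
            lo.append(math.radians(lim[ax, 0]))
            hi.append(math.radians(lim[ax, 1]))
        return np.array(lo), np.array(hi)

    def segment_bone_names(self, segment: str) -> list[str]:
        return [b.name for b in self.bones if b.segment == segment]

    def path_to_root(self, bone: int) -> list[int]:
        """Bone indices from the given bone up to (excluding) the root."""
        path = []
        i = bone
        while i >= 0:
            path.append(i)
            i = self._parent_bone[i]
        return path


def count_state_dim(graph: SkeletonGraph) -> int:
    """Latent pose dimension: 3 translation + all free rotation variables."""
    return 3 + len(graph.rotation_dofs())


@dataclass
class JointAngleLimits:
    """Per-bone per-axis rotation limits in degrees (x=flex, y=abd, z=rot)."""

    per_bone: dict[str, np.ndarray]      # bone name -> (3, 2)
    root: np.ndarray                     # (3, 2) global orientation

    @classmethod
    def from_graph(cls, graph: SkeletonGraph) -> "JointAngleLimits":
        return cls(
            per_bone={b.name: b.limits_deg.copy() for b in graph.bones},
            root=graph.root_limits_deg.copy(),
        )


@dataclass
class BoneLengthPrior:
    """Allometric box prior on limb bone lengths.

    ``mean`` is intercept + slope * body_weight for rats, a constant for
    mice; bounds are mean +/- 10 sd.  Bones without an entry (the axial
    skeleton) are unconstrained.
    """

    mean: dict[str, float]              # length class -> cm
    sd: dict[str, float]
    n_sd: float = 10.0

    def bounds(self, length_class: str) -> tuple[float, float]:
        if length_class not in self.mean:
            return (0.0, np.inf)
        m, s = self.mean[length_class], self.sd[length_class]
        return (max(m - self.n_sd * s, 0.0), m + self.n_sd * s)

    def is_constrained(self, length_class: str) -> bool:
        return length_class in self.mean


@dataclass(frozen=True)
class Marker:
    name: str
    joint: str
    side: str
    kind: str                       # landmark | spot
    bounds_cm: np.ndarray           # (3, 2) per-axis offset box

    @property
    def pair_base(self) -> str:
        for suf in ("_left", "_right"):
            if self.name.endswith(suf):
                return self.name[: -len(suf)]
        return self.name


@dataclass
class MarkerLayout:
    markers: list[Marker]

    def __post_init__(self):
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names")
        self.index = {n: i for i, n in enumerate(names)}

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    def __len__(self) -> int:
        return len(self.markers)

    def mirror_pairs(self) -> list[tuple[int, int]]:
        """(left_index, right_index) pairs of bilateral markers."""
        pairs = []
        for i, m in enumerate(self.markers):
            if m.side == "left":
                j = self.index[m.pair_base + "_right"]
                pairs.append((i, j))
        return pairs

    def validate_against(self, graph: SkeletonGraph):
        for m in self.markers:
            if m.joint not in graph.joint_index:
                raise ValueError(f"marker {m.name!r}: unknown joint {m.joint!r}")
            if m.side == "left":
                if m.pair_base + "_right" not in self.index:
                    raise ValueError(f"marker {m.name!r} has no right twin")


@dataclass
class SkeletonParams:
    """Learned per-animal quantities: bone lengths and marker offsets.

    ``bone_lengths`` aligns with ``graph.bones``; ``marker_offsets`` with
    ``layout.markers`` and lives in the attachment joint's local frame.
    """

    bone_lengths: np.ndarray          # (n_bones,)
    marker_offsets: np.ndarray        # (n_markers, 3)

    def copy(self) -> "SkeletonParams":
        return SkeletonParams(self.bone_lengths.copy(), self.marker_offsets.copy())


def symmetrize(
    graph: SkeletonGraph,
    layout: MarkerLayout,
    lengths_half: Mapping[str, float],
    offsets_half: Mapping[str, np.ndarray],
) -> SkeletonParams:
    """Expand one-sided parameters to a full bilaterally symmetric set.

    ``lengths_half`` maps length classes (side suffix stripped) to cm;
    ``offsets_half`` maps center and *one-sided* marker names to local
    offsets.  The missing side is inferred by mirroring in the y-z plane
    (x component negated).  Supplying both members of a bilateral pair is
    an error.
    """
    lengths = np.empty(graph.n_bones)
    for i, b in enumerate(graph.bones):
        cls = b.length_class
        side_keys = [k for k in (cls + "_left", cls + "_right") if k in lengths_half]
        if len(side_keys) == 2:
            raise ValueError(f"bone {cls!r} given on both sides")
        if cls in lengths_half:
            if side_keys:
                raise ValueError(f"bone {cls!r} given twice")
            lengths[i] = lengths_half[cls]
        elif side_keys:
            lengths[i] = lengths_half[side_keys[0]]
        else:
            raise KeyError(f"no length supplied for bone {cls!r}")

    offsets = np.zeros((len(layout), 3))
    seen = set()
    for name, off in offsets_half.items():
        if name not in layout.index:
            raise ValueError(f"unknown marker {name!r}")
        m = layout.markers[layout.index[name]]
        if m.pair_base in seen and m.side != "center":
            raise ValueError(f"marker pair {m.pair_base!r} given on both sides")
        seen.add(m.pair_base)
        off = np.asarray(off, dtype=float)
        offsets[layout.index[name]] = off
        if m.side in ("left", "right"):
            twin = m.pair_base + ("_right" if m.side == "left" else "_left")
            offsets[layout.index[twin]] = off * np.array([-1.0, 1.0, 1.0])
    return SkeletonParams(lengths, offsets)


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

def pose_to_rotvecs(graph: SkeletonGraph, poses: np.ndarray):
    """Split pose states into translation, root rotvec and per-bone rotvecs.

    Frozen axes are filled with the (degenerate) limit value.  Returns
    (translation (B,3), rotvecs (B, 1+n_bones, 3)) where slot 0 is the
    global root orientation; all angles in radians, already bounded.
    """
    poses = np.atleast_2d(np.asarray(poses, dtype=float))
    if poses.shape[1] != count_state_dim(graph):
        raise ValueError(
            f"pose dimension {poses.shape[1]} != state dim {count_state_dim(graph)}"
        )
    if np.any(~np.isfinite(poses)):
        raise ValueError("pose contains NaN or inf")
    B = poses.shape[0]
    lo, hi = graph.rotation_limits_rad()
    bounded = bound_angles(poses[:, 3:], lo, hi)
    rotvecs = np.zeros((B, 1 + graph.n_bones, 3))
    for i, b in enumerate(graph.bones):
        for ax in range(3):
            if ax not in b.dof_axes:
                rotvecs[:, 1 + i, ax] = math.radians(b.limits_deg[ax, 0])
    for k, (ent, ax) in enumerate(graph.rotation_dofs()):
        rotvecs[:, 1 + ent if ent >= 0 else 0, ax] = bounded[:, k]
    return poses[:, :3], rotvecs


def forward_kinematics_batch(
    graph: SkeletonGraph,
    params: SkeletonParams,
    poses: np.ndarray,
    layout: MarkerLayout | None = None,
):
    """Joint (and optionally marker) world positions for a batch of poses.

    Returns ``(joints (B, n_joints, 3), markers (B, n_markers, 3) | None,
    world_rot (B, 1 + n_bones, 3, 3))``.  ``world_rot[:, 0]`` is the root
    orientation; slot 1 + i belongs to bone i and is also the local frame
    of that bone's child joint.
    """
    t, rotvecs = pose_to_rotvecs(graph, poses)
    B = t.shape[0]
    nb = graph.n_bones
    local = rodrigues(rotvecs)                       # (B, 1+nb, 3, 3)
    world = np.empty_like(local)
    world[:, 0] = local[:, 0]
    joints = np.empty((B, nb + 1, 3))
    joints[:, 0] = t
    parent = graph.parent_bone_index()
    for i, b in enumerate(graph.bones):
        pw = world[:, 0] if parent[i] < 0 else world[:, 1 + parent[i]]
        world[:, 1 + i] = pw @ local[:, 1 + i]
        pj = joints[:, graph.joint_index[b.parent_joint]]
        joints[:, 1 + i] = pj + world[:, 1 + i] @ (
            b.rest_direction * params.bone_lengths[i]
        )
    markers = None
    if layout is not None:
        markers = np.empty((B, len(layout), 3))
        for k, m in enumerate(layout.markers):
            j = graph.joint_index[m.joint]
            R = world[:, 0] if j == 0 else world[:, j]  # joint j is child of bone j-1
            markers[:, k] = joints[:, j] + np.einsum(
                "bij,j->bi", R, params.marker_offsets[k]
            )
    return joints, markers, world


def forward_kinematics(
    graph: SkeletonGraph,
    params: SkeletonParams,
    pose: np.ndarray,
    layout: MarkerLayout | None = None,
):
    """Single-pose forward kinematics.

    Returns (dict joint -> 3-vector, dict marker -> 3-vector).  The second
    dict is empty when no marker layout is supplied.
    """
    joints, markers, _ = forward_kinematics_batch(
        graph, params, np.asarray(pose)[None, :], layout
    )
    jd = {name: joints[0, i] for i, name in enumerate(graph.joints)}
    md = {}
    if layout is not None:
        md = {m.name: markers[0, k] for k, m in enumerate(layout.markers)}
    return jd, md


def forward_kinematics_jacobian(
    graph: SkeletonGraph,
    params: SkeletonParams,
    poses: np.ndarray,
    layout: MarkerLayout,
):
    """Marker positions and their analytic derivatives.

    Returns a dict with

    - ``markers``: (B, M, 3) world positions,
    - ``jac_pose``: (B, M, 3, n) derivative w.r.t. the unbounded pose
      state (translation plus free rotation variables, chain rule through
      the erf bounding map included),
    - ``jac_length``: (B, M, 3, n_bones) derivative w.r.t. each bone's
      length,
    - ``joint_world_rot``: (B, 1 + n_bones, 3, 3) world rotations (slot 0
      = root), which double as d marker / d offset for the attachment
      joint's own markers.

    The derivative of a marker w.r.t. a Rodrigues component of bone b on
    its root path is A_b (dR_b/dr_i) q with A_b the parent world rotation
    and q the marker position expressed in b's local frame.
    """
    poses = np.atleast_2d(np.asarray(poses, dtype=float))
    t, rotvecs = pose_to_rotvecs(graph, poses)
    B = poses.shape[0]
    n = count_state_dim(graph)
    nb = graph.n_bones
    M = len(layout)

    local = rodrigues(rotvecs)                      # (B, 1+nb, 3, 3)
    dlocal = rodrigues_jacobian(rotvecs)            # (B, 1+nb, 3, 3, 3)
    world = np.empty_like(local)
    world[:, 0] = local[:, 0]
    joints = np.empty((B, nb + 1, 3))
    joints[:, 0] = t
    parent = graph.parent_bone_index()
    for i, b in enumerate(graph.bones):
        pw = world[:, 0] if parent[i] < 0 else world[:, 1 + parent[i]]
        world[:, 1 + i] = pw @ local[:, 1 + i]
        joints[:, 1 + i] = joints[:, graph.joint_index[b.parent_joint]] + world[
            :, 1 + i
        ] @ (b.rest_direction * params.bone_lengths[i])

    markers = np.empty((B, M, 3))
    for k, m in enumerate(layout.markers):
        j = graph.joint_index[m.joint]
        R = world[:, 0] if j == 0 else world[:, j]
        markers[:, k] = joints[:, j] + np.einsum(
            "bij,j->bi", R, params.marker_offsets[k]
        )

    # chain-rule factor through the bounding sigmoid, per rotation DOF
    lo, hi = graph.rotation_limits_rad()
    slope = bound_angles_derivative(poses[:, 3:], lo, hi)   # (B, n_rot)
    dofs = graph.rotation_dofs()
    # map (entity, axis) -> state column
    dof_col = {(ent, ax): 3 + k for k, (ent, ax) in enumerate(dofs)}

    jac_pose = np.zeros((B, M, 3, n))
    jac_pose[:, :, 0, 0] = 1.0
    jac_pose[:, :, 1, 1] = 1.0
    jac_pose[:, :, 2, 2] = 1.0
    jac_length = np.zeros((B, M, 3, nb))

    # bone path (including the root entity -1) per joint, cached
    paths: dict[int, list[int]] = {0: [-1]}
    for i in range(nb):
        paths[1 + i] = [i] + paths[graph.joint_index[graph.bones[i].parent_joint]]

    for k, m in enumerate(layout.markers):
        j = graph.joint_index[m.joint]
        p = markers[:, k]
        for ent in paths[j]:
            if ent == -1:
                A = None                        # identity
                slot = 0
                start = t
                free_axes = (0, 1, 2)
            else:
                pi = parent[ent]
                A = world[:, 0] if pi < 0 else world[:, 1 + pi]
                slot = 1 + ent
                start = joints[:, graph.joint_index[graph.bones[ent].parent_joint]]
                free_axes = graph.bones[ent].dof_axes
                jac_length[:, k, :, ent] = np.einsum(
                    "bij,j->bi", world[:, 1 + ent], graph.bones[ent].rest_direction
                )
            if not free_axes:
                continue
            q = np.einsum("bji,bj->bi", world[:, slot], p - start)
            for ax in free_axes:
                dRq = np.einsum("bij,bj->bi", dlocal[:, slot, ax], q)
                if A is not None:
                    dRq = np.einsum("bij,bj->bi", A, dRq)
                col = dof_col[(ent, ax)]
                jac_pose[:, k, :, col] = dRq * slope[:, col - 3, None]

    return {
        "markers": markers,
        "joints": joints,
        "jac_pose": jac_pose,
        "jac_length": jac_length,
        "joint_world_rot": world,
    }


# ---------------------------------------------------------------------------
# configuration loading
# ---------------------------------------------------------------------------

def default_config_path():
    return resources.files("acmpose.data") / "skeleton_rodent.yaml"


def load_skeleton_config(path=None) -> dict:
    if path is None:
        path = default_config_path()
    with open(str(path)) as fh:
        return yaml.safe_load(fh)


def build_default_skeleton(
    species: str, body_weight: float, config_path=None
) -> tuple[SkeletonGraph, JointAngleLimits, BoneLengthPrior, MarkerLayout]:
    """Build the generalized rodent skeleton for one animal.

    Parameters
    ----------
    species : "rat" or "mouse" — selects the allometric prior: a linear
        weight->length relationship for rats, adult constants for mice.
    body_weight : body weight in grams (> 0).
    """
    if species not in ("rat", "mouse"):
        raise ValueError(f"unknown species {species!r}")
    if not body_weight > 0:
        raise ValueError("body weight must be positive")
    cfg = load_skeleton_config(config_path)

    bones = []
    for bc in cfg["bones"]:
        limits = np.array([bc["limits"][a] for a in AXES], dtype=float)
        bones.append(
            Bone(
                name=bc["name"],
                parent_joint=bc["parent"],
                child_joint=bc["child"],
                segment=bc["segment"],
                side=bc["side"],
                rest_direction=np.asarray(bc["rest"], dtype=float),
                limits_deg=limits,
            )
        )
    root_lim = np.array(
        [cfg["root"]["orientation_limits_deg"][a] for a in AXES], dtype=float
    )
    graph = SkeletonGraph(bones=bones, root_joint=cfg["root"]["joint"],
                          root_limits_deg=root_lim)

    allo = cfg["allometry"][species]
    mean, sd = {}, {}
    for cls_name, entry in allo.items():
        if "slope" in entry:
            mean[cls_name] = entry["intercept"] + entry["slope"] * body_weight
        else:
            mean[cls_name] = entry["value"]
        sd[cls_name] = entry["sd"]
    prior = BoneLengthPrior(mean=mean, sd=sd)

    bound = float(cfg.get("marker_defaults", {}).get("bound_cm", 2.0))
    markers = []
    for mc in cfg["markers"]:
        b = np.array([[-bound, bound]] * 3, dtype=float)
        if mc["side"] == "center":
            b[0] = [0.0, 0.0]  # center markers sit on the mirror plane
        if "bounds" in mc:
            for i, a in enumerate(AXES):
                if a in mc["bounds"]:
                    b[i] = mc["bounds"][a]
        markers.append(
            Marker(
                name=mc["name"], joint=mc["joint"], side=mc["side"],
                kind=mc["kind"], bounds_cm=b,
            )
        )
    layout = MarkerLayout(markers=markers)
    layout.validate_against(graph)
    return graph, JointAngleLimits.from_graph(graph), prior, layout
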