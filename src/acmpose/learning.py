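"""Skeleton learning from manually labeled 2D marker positions.

Simultaneously fits all per-frame pose parameters (position + bone
rotations) and the time-invariant skeleton parameters (bone lengths,
marker-to-joint offsets) by minimizing squared 2D pixel distances between
labels and the projected model markers under box constraints.

Bilateral symmetry is built into the parameterization: only center and
left-side parameters are optimized; the right side is the mirror image
(offsets with negated x, shared bone lengths), so learned skeletons are
exactly symmetric by construction.  Pose rotations use the same bounded
(erf-sigmoid) reparameterization as the smoother, so joint-angle limits
hold during learning as well.

The joint problem is nonconvex with many near-degenerate directions, so
the fit proceeds in stages:

1. per-frame initialization: triangulate the labels, estimate every
   joint position from the markers attached to it, and run a chain IK
   (minimal rotations toward each child-joint estimate, clipped inside
   the limits) — extending the loose global alignment to the whole tree;
2. 3D alternation: with poses fixed, marker positions are affine in the
   bone lengths, marker offsets and per-frame root translations, so the
   skeleton half is an exact box-constrained linear solve; with the
   skeleton fixed, poses split into small independent per-frame 3D fits;
3. joint pixel-space refinement: damped Gauss-Newton on the squared
   pixel residuals with the bundle-adjustment Schur complement (the
   per-frame pose blocks are eliminated, leaving a small shared
   skeleton system), under box constraints by projection;
4. reseed/repair passes: frames stuck in a wrong pose basin are re-fit
   from a fresh label-based initialization (keeping the better pose per
   frame), and length classes far from their direct triangulation-based
   estimates are reset and re-polished, keeping the better overall fit.

Marker offsets start at zero (markers coincide with their joints) and
bone lengths at data-driven estimates clipped to the allometric boxes;
stages repeat until the objective stops improving.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.spatial.transform import Rotation

from .cameras import CameraRig, project_batch_with_jacobian, triangulate
from .skeleton import (
    BoneLengthPrior,
    MarkerLayout,
    SkeletonGraph,
    SkeletonParams,
    count_state_dim,
    forward_kinematics_jacobian,
    unbound_angles,
)

_HEAD_JOINTS = {"nose_tip", "head_cervical", "cervical_thoracic"}
_TAIL_JOINTS = {
    "tail_base", "lumbar_sacrum", "tail_joint_1", "tail_joint_2",
    "tail_joint_3", "tail_joint_4", "tail_tip",
}

_MIRROR = np.array([-1.0, 1.0, 1.0])


@dataclass
class LearnOptions:
    max_iter: int = 300          # damped Gauss-Newton iterations, pixel stage
    alternation_rounds: int = 6  # 3D pose/skeleton alternation rounds
    reseed_rounds: int = 5       # re-initialization passes for stuck frames
    grad_tol: float = 1e-8
    fun_tol: float = 1e-12


@dataclass
class LearnResult:
    params: SkeletonParams
    poses: np.ndarray             # (F, state_dim) unbounded coordinates
    frames: np.ndarray            # labeled frame indices
    objective: float              # sum of squared pixel residuals
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    grad_norm: float = np.nan
    success: bool = False


def triangulate_frame_markers(
    labels_frame: pd.DataFrame, rig: CameraRig
) -> dict[str, np.ndarray]:
    """Triangulated 3D position per marker seen in >= 2 cameras."""
    out = {}
    for marker, grp in labels_frame.groupby("marker"):
        if len(grp) < 2:
            continue
        dets = [
            (rig.cameras[int(r.camera)], np.array([r.x, r.y]), float(r.confidence))
            for r in grp.itertuples(index=False)
        ]
        try:
            out[marker] = triangulate(dets)
        except ValueError:
            continue
    return out


def coarse_align(
    labels_frame: pd.DataFrame,
    graph: SkeletonGraph,
    layout: MarkerLayout,
    rig: CameraRig,
) -> tuple[np.ndarray, np.ndarray]:
    """Loose global alignment of the skeleton to one frame's labels.

    Returns (translation, root rotation vector): the translation is the
    centroid of the triangulated markers; the orientation maps the
    resting-pose anteroposterior axis onto the tail-to-head direction of
    the triangulated marker cloud, keeping the dorsal axis as vertical as
    possible.
    """
    pts = triangulate_frame_markers(labels_frame, rig)
    if len(pts) < 3:
        raise ValueError("coarse alignment needs >= 3 triangulable markers")
    arr = np.array(list(pts.values()))
    if np.max(np.linalg.norm(arr - arr.mean(axis=0), axis=1)) < 1e-9:
        raise ValueError("triangulated markers are coincident")
    centroid = arr.mean(axis=0)
    joint_of = {m.name: m.joint for m in layout.markers}
    head = [p for k, p in pts.items() if joint_of[k] in _HEAD_JOINTS]
    tail = [p for k, p in pts.items() if joint_of[k] in _TAIL_JOINTS]
    if head and tail:
        d = np.mean(head, axis=0) - np.mean(tail, axis=0)
    else:  # fall back on the dominant axis of the cloud
        _, _, V = np.linalg.svd(arr - centroid)
        d = V[0]
    nd = np.linalg.norm(d)
    if nd < 1e-9:
        raise ValueError("degenerate body-axis direction")
    zb = d / nd
    up = np.array([0.0, 0.0, 1.0])
    yb = up - (up @ zb) * zb
    if np.linalg.norm(yb) < 1e-9:
        yb = np.array([0.0, 1.0, 0.0])
    yb = yb / np.linalg.norm(yb)
    xb = np.cross(yb, zb)
    R = np.stack([xb, yb, zb], axis=1)       # columns = body axes in world
    return centroid, Rotation.from_matrix(R).as_rotvec()


def _owned_markers(layout: MarkerLayout) -> list[int]:
    return [i for i, m in enumerate(layout.markers) if m.side != "right"]


def _length_classes(graph: SkeletonGraph) -> list[str]:
    seen: list[str] = []
    for b in graph.bones:
        if b.length_class not in seen:
            seen.append(b.length_class)
    return seen


def _expand_params(
    graph: SkeletonGraph,
    layout: MarkerLayout,
    lengths_cls: np.ndarray,
    offsets_owned: np.ndarray,
) -> SkeletonParams:
    classes = _length_classes(graph)
    cidx = {c: i for i, c in enumerate(classes)}
    lengths = np.array([lengths_cls[cidx[b.length_class]] for b in graph.bones])
    offsets = np.zeros((len(layout), 3))
    owned = _owned_markers(layout)
    for row, k in enumerate(owned):
        offsets[k] = offsets_owned[row]
        m = layout.markers[k]
        if m.side == "left":
            twin = layout.index[m.pair_base + "_right"]
            offsets[twin] = offsets_owned[row] * _MIRROR
    return SkeletonParams(lengths, offsets)


class _LearnProblem:
    """Residuals and sparse Jacobian of the label-reprojection fit."""

    def __init__(self, labels, graph, prior, layout, rig, include_offsets):
        self.graph, self.layout, self.rig = graph, layout, rig
        self.frames = np.sort(labels["frame"].unique())
        self.F = len(self.frames)
        self.n = count_state_dim(graph)
        self.M = len(layout)
        self.C = len(rig)
        self.classes = _length_classes(graph)
        self.nc = len(self.classes)
        self.owned = _owned_markers(layout)
        self.include_offsets = include_offsets

        cidx = {c: i for i, c in enumerate(self.classes)}
        self.cls_of_bone = np.array([cidx[b.length_class] for b in graph.bones])
        # per-marker owned-offset row and mirror flag
        self.off_row = np.full(self.M, -1)
        self.off_mirror = np.zeros(self.M, dtype=bool)
        own_row = {k: r for r, k in enumerate(self.owned)}
        for k, m in enumerate(layout.markers):
            if m.side == "right":
                left = layout.index[m.pair_base + "_left"]
                self.off_row[k] = own_row[left]
                self.off_mirror[k] = True
            else:
                self.off_row[k] = own_row[k]

        # free offset components (degenerate boxes are pinned at the bound)
        self.off_free = np.zeros((len(self.owned), 3), dtype=bool)
        self.off_lo = np.zeros((len(self.owned), 3))
        self.off_hi = np.zeros((len(self.owned), 3))
        for r, k in enumerate(self.owned):
            b = layout.markers[k].bounds_cm
            self.off_lo[r], self.off_hi[r] = b[:, 0], b[:, 1]
            self.off_free[r] = b[:, 0] < b[:, 1]
        if not include_offsets:
            self.off_free[:] = False
        self.n_off = int(self.off_free.sum())
        # column index into the variable vector per (owned row, axis)
        self.off_col = np.full((len(self.owned), 3), -1)
        self.off_col[self.off_free] = self.nc + np.arange(self.n_off)

        # label tensors
        self.lab = np.zeros((self.C, self.F, self.M, 2))
        self.seen = np.zeros((self.C, self.F, self.M), dtype=bool)
        frame_row = {f: i for i, f in enumerate(self.frames)}
        for r in labels.itertuples(index=False):
            c, f, k = int(r.camera), frame_row[r.frame], layout.index[r.marker]
            self.lab[c, f, k] = (r.x, r.y)
            self.seen[c, f, k] = True
        self.n_resid = 2 * int(self.seen.sum())
        self.pose_base = self.nc + self.n_off

        # bounds and prior init for lengths
        self.len_lo = np.empty(self.nc)
        self.len_hi = np.empty(self.nc)
        self.len_init = np.empty(self.nc)
        for i, cls in enumerate(self.classes):
            lo, hi = prior.bounds(cls)
            if lo > hi:
                raise ValueError(f"infeasible length bounds for {cls!r}")
            self.len_lo[i], self.len_hi[i] = lo, hi
            self.len_init[i] = 0.5 * (lo + hi) if np.isfinite(hi) else 0.0

        self.trace: list[float] = []

    # --- variable packing -------------------------------------------------

    def n_vars(self) -> int:
        return self.nc + self.n_off + self.F * self.n

    def bounds(self):
        lo = np.concatenate([
            self.len_lo, self.off_lo[self.off_free],
            np.full(self.F * self.n, -np.inf),
        ])
        hi = np.concatenate([
            self.len_hi, self.off_hi[self.off_free],
            np.full(self.F * self.n, np.inf),
        ])
        return lo, hi

    def pack(self, lengths_cls, offsets_owned, poses):
        return np.concatenate([
            lengths_cls, offsets_owned[self.off_free], poses.ravel()
        ])

    def unpack(self, v):
        lengths_cls = v[: self.nc]
        offsets = np.where(
            self.off_free, 0.0, 0.5 * (self.off_lo + self.off_hi)
        )
        offsets[self.off_free] = v[self.nc : self.nc + self.n_off]
        poses = v[self.pose_base :].reshape(self.F, self.n)
        return lengths_cls, offsets, poses

    # --- residuals / Jacobian ----------------------------------------------

    def _eval(self, v, want_jac):
        lengths_cls, offsets, poses = self.unpack(v)
        params = _expand_params(self.graph, self.layout, lengths_cls, offsets)
        fkj = forward_kinematics_jacobian(self.graph, params, poses, self.layout)
        markers = fkj["markers"]
        res_parts = []
        coo_rows, coo_cols, coo_data = [], [], []
        row0 = 0
        world = fkj["joint_world_rot"]
        joint_slot = np.array(
            [self.graph.joint_index[m.joint] for m in self.layout.markers]
        )
        for c in range(self.C):
            px, Jp = project_batch_with_jacobian(markers, self.rig.cameras[c])
            sf, sm = np.nonzero(self.seen[c])
            S = len(sf)
            r = (px[sf, sm] - self.lab[c, sf, sm]).ravel()
            res_parts.append(r)
            if want_jac and S:
                Jp_s = Jp[sf, sm]                                   # (S, 2, 3)
                rows = row0 + 2 * np.arange(S)[:, None, None] + np.array(
                    [0, 1]
                )[None, :, None]
                # pose block
                Jpose = np.einsum(
                    "sde,sen->sdn", Jp_s, fkj["jac_pose"][sf, sm]
                )                                                    # (S,2,n)
                cols = (self.pose_base + sf * self.n)[:, None, None] + np.arange(
                    self.n
                )[None, None, :]
                coo_rows.append(np.broadcast_to(rows, Jpose.shape).ravel())
                coo_cols.append(np.broadcast_to(cols, Jpose.shape).ravel())
                coo_data.append(Jpose.ravel())
                # length block, accumulated per class
                Jlen = np.einsum("sde,seb->sdb", Jp_s, fkj["jac_length"][sf, sm])
                Jcls = np.zeros((S, 2, self.nc))
                np.add.at(Jcls, (slice(None), slice(None), self.cls_of_bone),
                          Jlen)
                ccols = np.broadcast_to(
                    np.arange(self.nc)[None, None, :], Jcls.shape
                )
                coo_rows.append(np.broadcast_to(rows, Jcls.shape).ravel())
                coo_cols.append(ccols.ravel())
                coo_data.append(Jcls.ravel())
                # offset block (only free components)
                if self.n_off:
                    slot = joint_slot[sm]
                    W = world[sf, np.where(slot == 0, 0, slot)]      # (S,3,3)
                    sign = np.where(self.off_mirror[sm], -1.0, 1.0)
                    Wm = W.copy()
                    Wm[:, :, 0] *= sign[:, None]
                    Joff = np.einsum("sde,sea->sda", Jp_s, Wm)       # (S,2,3)
                    ocols = self.off_col[self.off_row[sm]]           # (S,3)
                    free = ocols >= 0
                    sel = np.broadcast_to(free[:, None, :], Joff.shape)
                    coo_rows.append(
                        np.broadcast_to(rows, Joff.shape)[sel].ravel()
                    )
                    coo_cols.append(
                        np.broadcast_to(ocols[:, None, :], Joff.shape)[sel].ravel()
                    )
                    coo_data.append(Joff[sel].ravel())
            row0 += 2 * S
        r = np.concatenate(res_parts)
        if not want_jac:
            return r, None
        J = sparse.coo_matrix(
            (np.concatenate(coo_data),
             (np.concatenate(coo_rows), np.concatenate(coo_cols))),
            shape=(self.n_resid, self.n_vars()),
        ).tocsr()
        return r, J

    def residual(self, v):
        return self._eval(v, want_jac=False)[0]

    def jac(self, v):
        # the solver evaluates the Jacobian only at accepted iterates, so
        # the cost recorded here traces the monotone objective decrease
        r, J = self._eval(v, want_jac=True)
        self.trace.append(float(r @ r))
        return J

    # --- per-frame blocks for the Schur-complement solver -----------------

    def eval_blocks(self, v):
        """Residuals and Jacobian blocks grouped by frame.

        Returns (cost, blocks) where blocks is a list of
        (r_f, Jpose_f (rows, n), Jskel_f (rows, nc + n_off)) per frame.
        """
        lengths_cls, offsets, poses = self.unpack(v)
        params = _expand_params(self.graph, self.layout, lengths_cls, offsets)
        fkj = forward_kinematics_jacobian(self.graph, params, poses, self.layout)
        markers = fkj["markers"]
        world = fkj["joint_world_rot"]
        joint_slot = np.array(
            [self.graph.joint_index[m.joint] for m in self.layout.markers]
        )
        ns = self.nc + self.n_off
        px_all, Jp_all = [], []
        for c in range(self.C):
            px, Jp = project_batch_with_jacobian(markers, self.rig.cameras[c])
            px_all.append(px)
            Jp_all.append(Jp)
        cost = 0.0
        blocks = []
        for f in range(self.F):
            r_parts, Jpose_parts, Jskel_parts = [], [], []
            for c in range(self.C):
                sm = np.nonzero(self.seen[c, f])[0]
                if len(sm) == 0:
                    continue
                Jp_s = Jp_all[c][f, sm]                     # (s, 2, 3)
                r = (px_all[c][f, sm] - self.lab[c, f, sm]).reshape(-1)
                r_parts.append(r)
                Jpose = np.einsum("sde,sen->sdn", Jp_s,
                                  fkj["jac_pose"][f, sm])
                Jpose_parts.append(Jpose.reshape(-1, self.n))
                Jlen = np.einsum("sde,seb->sdb", Jp_s,
                                 fkj["jac_length"][f, sm])
                Jsk = np.zeros((len(sm), 2, ns))
                np.add.at(
                    Jsk, (slice(None), slice(None), self.cls_of_bone), Jlen
                )
                if self.n_off:
                    slot = joint_slot[sm]
                    W = world[f, np.where(slot == 0, 0, slot)]
                    sign = np.where(self.off_mirror[sm], -1.0, 1.0)
                    Wm = W.copy()
                    Wm[:, :, 0] *= sign[:, None]
                    Joff = np.einsum("sde,sea->sda", Jp_s, Wm)
                    ocols = self.off_col[self.off_row[sm]]
                    for a in range(3):
                        valid = ocols[:, a] >= 0
                        if valid.any():
                            Jsk[valid, :, ocols[valid, a]] = Joff[valid, :, a]
                Jskel_parts.append(Jsk.reshape(-1, ns))
            r_f = np.concatenate(r_parts) if r_parts else np.zeros(0)
            cost += float(r_f @ r_f)
            blocks.append(
                (
                    r_f,
                    np.vstack(Jpose_parts) if Jpose_parts else np.zeros((0, self.n)),
                    np.vstack(Jskel_parts) if Jskel_parts else np.zeros((0, ns)),
                )
            )
        return cost, blocks

    def cost_only(self, v):
        r = self.residual(v)
        return float(r @ r)


def _lm_schur_solve(
    problem: _LearnProblem,
    x0: np.ndarray,
    max_iter: int,
    cost_tol: float = 1e-12,
    step_tol: float = 1e-10,
    mu0: float = 1e-3,
):
    """Damped Gauss-Newton with per-frame Schur elimination of the poses.

    The normal equations decouple into one pose block per frame plus a
    small shared skeleton block; eliminating the pose blocks leaves an
    ns x ns system, so each iteration takes an exact Levenberg-Marquardt
    step.  Box constraints on the skeleton parameters are enforced by
    projection of the candidate point (the accept/reject test keeps the
    iteration monotone).  Returns (x, trace, n_iter).
    """
    x = x0.copy()
    lo, hi = problem.bounds()
    ns = problem.nc + problem.n_off
    F, n = problem.F, problem.n
    mu = mu0
    cost, blocks = problem.eval_blocks(x)
    trace = [cost]
    it = 0
    for it in range(1, max_iter + 1):
        S = np.zeros((ns, ns))
        gs = np.zeros(ns)
        AinvC = []
        Ainvb = []
        for f in range(F):
            r_f, Jp, Js = blocks[f]
            A = Jp.T @ Jp + mu * np.eye(n)
            C = Jp.T @ Js
            b = Jp.T @ r_f
            Ai = np.linalg.inv(A)
            AinvC.append(Ai @ C)
            Ainvb.append(Ai @ b)
            S += Js.T @ Js - C.T @ AinvC[-1]
            gs += Js.T @ r_f - C.T @ Ainvb[-1]
        S += mu * np.eye(ns)
        try:
            ds = -np.linalg.solve(S, gs)
        except np.linalg.LinAlgError:
            mu *= 10.0
            continue
        cand = x.copy()
        new_s = np.clip(x[:ns] + ds, lo[:ns], hi[:ns])
        ds_eff = new_s - x[:ns]
        cand[:ns] = new_s
        for f in range(F):
            dp = -(Ainvb[f] + AinvC[f] @ ds_eff)
            cand[ns + f * n : ns + (f + 1) * n] += dp
        new_cost = problem.cost_only(cand)
        if new_cost < cost:
            step = np.max(np.abs(cand - x))
            rel = (cost - new_cost) / max(cost, 1e-300)
            x, cost = cand, new_cost
            _, blocks = problem.eval_blocks(x)
            trace.append(cost)
            mu = max(mu / 3.0, 1e-12)
            if rel < cost_tol or step < step_tol:
                break
        else:
            mu *= 4.0
            if mu > 1e12:
                break
    return x, trace, it


def _estimate_joints_3d(
    labels_frame: pd.DataFrame,
    graph: SkeletonGraph,
    layout: MarkerLayout,
    rig: CameraRig,
) -> dict[str, np.ndarray]:
    """Approximate per-joint 3D positions from triangulated markers.

    Each joint estimate is the centroid of the triangulated markers
    attached to it (marker offsets are small compared to bone lengths);
    joints without markers are filled by linear interpolation between
    the nearest estimated ancestor and descendant along the chain.
    """
    pts = triangulate_frame_markers(labels_frame, rig)
    acc: dict[str, list[np.ndarray]] = {}
    for m in layout.markers:
        if m.name in pts:
            acc.setdefault(m.joint, []).append(pts[m.name])
    est = {j: np.mean(v, axis=0) for j, v in acc.items()}
    parent_of = {b.child_joint: b.parent_joint for b in graph.bones}
    children_of: dict[str, list[str]] = {}
    for b in graph.bones:
        children_of.setdefault(b.parent_joint, []).append(b.child_joint)
    for j in graph.joints:
        if j in est:
            continue
        # nearest estimated ancestor
        a, na = j, 0
        while a in parent_of and a not in est:
            a, na = parent_of[a], na + 1
        # nearest estimated descendant (first found, breadth-first)
        frontier, nd, d = [j], 0, None
        while frontier and d is None:
            nxt = []
            nd += 1
            for q in frontier:
                for ch in children_of.get(q, []):
                    if ch in est:
                        d = ch
                        break
                    nxt.append(ch)
                if d:
                    break
            frontier = nxt
        if a in est and d is not None:
            est[j] = est[a] + (est[d] - est[a]) * (na / (na + nd))
        elif a in est:
            est[j] = est[a]
    return est


def ik_initial_pose(
    frame_labels: pd.DataFrame,
    graph: SkeletonGraph,
    layout: MarkerLayout,
    rig: CameraRig,
    margin: float = 0.05,
) -> np.ndarray:
    """Single-frame pose initialization from triangulated 2D positions.

    Extends the loose global alignment to the whole chain: each bone's
    initial rotation is the minimal rotation turning its resting
    direction toward the triangulated-marker estimate of its child
    joint, clipped ``margin`` (fraction of the range) inside the joint
    limits.  Raises ValueError when too few markers triangulate.
    """
    from .skeleton import rodrigues

    est = _estimate_joints_3d(frame_labels, graph, layout, rig)
    if graph.root_joint not in est or len(est) < 4:
        raise ValueError("too few triangulable markers for pose initialization")
    lo_rot, hi_rot = graph.rotation_limits_rad()
    dofs = graph.rotation_dofs()
    dof_col = {(ent, ax): 3 + k for k, (ent, ax) in enumerate(dofs)}
    parent = graph.parent_bone_index()
    angles = 0.5 * (lo_rot + hi_rot).copy()
    # global orientation: the pelvis edges are rigid in the root frame, so
    # the hip-to-hip line fixes the lateral (x) axis exactly; the local
    # sacrum direction anchors the longitudinal axis
    xb = None
    if "hip_left" in est and "hip_right" in est:
        d = est["hip_left"] - est["hip_right"]
        if np.linalg.norm(d) > 1e-6:
            xb = d / np.linalg.norm(d)
    zref = None
    for a, b2 in (("lumbar_sacrum", graph.root_joint),
                  ("cervical_thoracic", graph.root_joint)):
        if a in est and b2 in est:
            d = est[a] - est[b2]
            if np.linalg.norm(d) > 1e-6:
                zref = d / np.linalg.norm(d)
                break
    if xb is not None and zref is not None:
        zb = zref - (zref @ xb) * xb
        if np.linalg.norm(zb) < 1e-9:
            raise ValueError("degenerate body axes")
        zb /= np.linalg.norm(zb)
        yb = np.cross(zb, xb)
        rv = Rotation.from_matrix(np.stack([xb, yb, zb], axis=1)).as_rotvec()
    elif zref is not None:
        zb = zref
        up = np.array([0.0, 0.0, 1.0])
        yb = up - (up @ zb) * zb
        if np.linalg.norm(yb) < 1e-9:
            yb = np.array([0.0, 1.0, 0.0])
        yb /= np.linalg.norm(yb)
        xb = np.cross(yb, zb)
        rv = Rotation.from_matrix(np.stack([xb, yb, zb], axis=1)).as_rotvec()
    else:
        _, rv = coarse_align(frame_labels, graph, layout, rig)
    span = hi_rot[:3] - lo_rot[:3]
    angles[:3] = np.clip(rv, lo_rot[:3] + margin * span,
                         hi_rot[:3] - margin * span)
    world = [None] * (1 + graph.n_bones)
    world[0] = rodrigues(angles[:3])
    for bi, b in enumerate(graph.bones):
        Wp = world[0] if parent[bi] < 0 else world[1 + parent[bi]]
        rot = np.zeros(3)
        for ax in range(3):
            if ax not in b.dof_axes:
                rot[ax] = np.radians(b.limits_deg[ax, 0])
        free = list(b.dof_axes)
        if free and b.parent_joint in est and b.child_joint in est:
            d = est[b.child_joint] - est[b.parent_joint]
            nd = np.linalg.norm(d)
            if nd > 1e-6:
                d_local = Wp.T @ (d / nd)
                axis = np.cross(b.rest_direction, d_local)
                s = np.linalg.norm(axis)
                ang = math.atan2(s, float(b.rest_direction @ d_local))
                rv_b = axis / s * ang if s > 1e-9 else np.zeros(3)
                for ax in free:
                    lo = math.radians(b.limits_deg[ax, 0])
                    hi = math.radians(b.limits_deg[ax, 1])
                    sp = hi - lo
                    rot[ax] = np.clip(rv_b[ax], lo + margin * sp,
                                      hi - margin * sp)
        else:
            for ax in free:
                rot[ax] = 0.5 * (
                    math.radians(b.limits_deg[ax, 0])
                    + math.radians(b.limits_deg[ax, 1])
                )
        for ax in free:
            angles[dof_col[(bi, ax)] - 3] = rot[ax]
        world[1 + bi] = Wp @ rodrigues(rot)
    pose = np.zeros(3 + len(dofs))
    pose[:3] = est[graph.root_joint]
    pose[3:] = unbound_angles(angles, lo_rot, hi_rot)
    return pose


def _estimate_length_classes(
    labels: pd.DataFrame,
    graph: SkeletonGraph,
    layout: MarkerLayout,
    rig: CameraRig,
    frames: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    fallback: np.ndarray,
) -> np.ndarray:
    """Median adjacent-joint distances as data-driven length starting values."""
    classes = _length_classes(graph)
    dists: dict[str, list[float]] = {c: [] for c in classes}
    for f in frames:
        est = _estimate_joints_3d(labels[labels["frame"] == f], graph, layout, rig)
        for b in graph.bones:
            if b.parent_joint in est and b.child_joint in est:
                dists[b.length_class].append(
                    float(np.linalg.norm(est[b.child_joint] - est[b.parent_joint]))
                )
    out = fallback.copy()
    for i, c in enumerate(classes):
        if dists[c]:
            out[i] = float(np.clip(np.median(dists[c]), lo[i], hi[i]))
    return out


def _initial_poses(problem: _LearnProblem, labels, graph, layout, rig):
    """Per-frame initialization; failed frames fall back to the previous."""
    poses0 = np.zeros((problem.F, problem.n))
    for i, f in enumerate(problem.frames):
        try:
            poses0[i] = ik_initial_pose(
                labels[labels["frame"] == f], graph, layout, rig
            )
        except ValueError:
            if i:
                poses0[i] = poses0[i - 1]
    return poses0


# ---------------------------------------------------------------------------
# 3D alternation stage
# ---------------------------------------------------------------------------

def _triangulated_targets(problem: _LearnProblem, labels, rig):
    """(X (F, M, 3), seen (F, M)) triangulated marker positions."""
    X = np.zeros((problem.F, problem.M, 3))
    seen = np.zeros((problem.F, problem.M), dtype=bool)
    for i, f in enumerate(problem.frames):
        pts = triangulate_frame_markers(labels[labels["frame"] == f], rig)
        for name, p in pts.items():
            k = problem.layout.index[name]
            X[i, k] = p
            seen[i, k] = True
    return X, seen


def _skeleton_linear_step(problem: _LearnProblem, poses, X, seen):
    """Exact box-constrained linear solve for lengths and offsets.

    For fixed poses, every marker position is affine in the bone lengths
    and marker offsets (world rotations are known), so the 3D-target fit
    reduces to a bounded linear least-squares problem.
    """
    graph, layout = problem.graph, problem.layout
    from .skeleton import pose_to_rotvecs, rodrigues

    _, rotvecs = pose_to_rotvecs(graph, poses)
    local = rodrigues(rotvecs)
    world = np.empty_like(local)
    world[:, 0] = local[:, 0]
    parent = graph.parent_bone_index()
    for i in range(graph.n_bones):
        pw = world[:, 0] if parent[i] < 0 else world[:, 1 + parent[i]]
        world[:, 1 + i] = pw @ local[:, 1 + i]
    t = poses[:, :3]

    nvar = problem.nc + problem.n_off
    # per-bone world direction columns, then pooled into length classes
    dir_cols = np.einsum(
        "fbij,bj->fbi", world[:, 1:], np.stack([b.rest_direction for b in graph.bones])
    )                                                   # (F, nb, 3)
    paths = {0: []}
    for i in range(graph.n_bones):
        paths[1 + i] = paths[graph.joint_index[graph.bones[i].parent_joint]] + [i]

    sf, sm = np.nonzero(seen)
    S = len(sf)
    F = poses.shape[0]
    # unknowns: lengths, free offsets, and the per-frame root translations
    # (all enter the marker positions linearly for fixed rotations)
    ncols = nvar + 3 * F
    A = np.zeros((S, 3, ncols))
    rhs = X[sf, sm]
    joint_slot = np.array([graph.joint_index[m.joint] for m in layout.markers])
    for row in range(S):
        f, k = sf[row], sm[row]
        j = joint_slot[k]
        for b in paths[j]:
            A[row, :, problem.cls_of_bone[b]] += dir_cols[f, b]
        W = world[f, 0] if j == 0 else world[f, j]
        sign = -1.0 if problem.off_mirror[k] else 1.0
        orow = problem.off_row[k]
        for a in range(3):
            col = problem.off_col[orow, a]
            if col >= 0:
                Wa = W[:, a].copy()
                if a == 0:
                    Wa *= sign
                A[row, :, col] += Wa
        A[row, :, nvar + 3 * f : nvar + 3 * f + 3] = np.eye(3)
    lo = np.concatenate([problem.len_lo, problem.off_lo[problem.off_free],
                         np.full(3 * F, -np.inf)])
    hi = np.concatenate([problem.len_hi, problem.off_hi[problem.off_free],
                         np.full(3 * F, np.inf)])
    sol = optimize.lsq_linear(
        A.reshape(3 * S, ncols), rhs.ravel(), bounds=(lo, hi), method="trf",
        tol=1e-12,
    )
    lengths_cls = sol.x[: problem.nc]
    off = np.where(problem.off_free, 0.0,
                   0.5 * (problem.off_lo + problem.off_hi))
    off[problem.off_free] = sol.x[problem.nc : nvar]
    new_t = sol.x[nvar:].reshape(F, 3)
    return lengths_cls, off, new_t, float(sol.cost * 2.0)


def _pose_step_3d(problem: _LearnProblem, params, poses, X, seen):
    """Independent per-frame 3D pose fits against triangulated targets."""
    graph, layout = problem.graph, problem.layout
    new_poses = poses.copy()
    cost = 0.0
    for f in range(X.shape[0]):
        sm = np.nonzero(seen[f])[0]
        if len(sm) * 3 < problem.n + 3:
            continue
        target = X[f, sm]

        def resid(x):
            fkj = forward_kinematics_jacobian(graph, params, x[None], layout)
            return (fkj["markers"][0, sm] - target).ravel()

        def jac(x):
            fkj = forward_kinematics_jacobian(graph, params, x[None], layout)
            return fkj["jac_pose"][0, sm].reshape(-1, problem.n)

        # wide box keeps saturated sigmoid coordinates from running away
        lo = np.full(problem.n, -50.0)
        hi = np.full(problem.n, 50.0)
        lo[:3], hi[:3] = -1e4, 1e4
        x0 = np.clip(poses[f], lo + 1e-6, hi - 1e-6)
        sol = optimize.least_squares(
            resid, x0, jac=jac, method="trf", bounds=(lo, hi), max_nfev=60,
        )
        new_poses[f] = sol.x
        cost += 2.0 * float(sol.cost)
    return new_poses, cost


def learn_skeleton(
    labels: pd.DataFrame,
    graph: SkeletonGraph,
    prior: BoneLengthPrior,
    layout: MarkerLayout,
    rig: CameraRig,
    opts: LearnOptions | None = None,
) -> LearnResult:
    """Joint fit of per-frame poses and time-invariant skeleton parameters.

    ``labels`` is a detection-style table (frame, camera, marker, x, y,
    confidence); all rows are trusted.  Raises when no labels are given
    or a prior box is infeasible.
    """
    opts = opts or LearnOptions()
    if len(labels) == 0:
        raise ValueError("no labeled frames supplied")

    trace: list[float] = []
    n_iter = 0

    p2 = _LearnProblem(labels, graph, prior, layout, rig, include_offsets=True)
    poses = _initial_poses(p2, labels, graph, layout, rig)

    # stage 1: alternate closed-form skeleton solves with per-frame 3D pose
    # fits against the triangulated labels (affine in lengths/offsets for
    # fixed poses; small independent problems for fixed skeleton)
    X, seen3d = _triangulated_targets(p2, labels, rig)
    lengths_cls = _estimate_length_classes(
        labels, graph, layout, rig, p2.frames, p2.len_lo, p2.len_hi,
        p2.len_init,
    )
    offsets = np.zeros((len(p2.owned), 3))
    for _ in range(opts.alternation_rounds):
        params = _expand_params(graph, layout, lengths_cls, offsets)
        poses, _ = _pose_step_3d(p2, params, poses, X, seen3d)
        lengths_cls, offsets, new_t, c3d = _skeleton_linear_step(
            p2, poses, X, seen3d
        )
        poses[:, :3] = new_t
        n_iter += 1

    # stage 2: joint pixel-space refinement of everything
    x0 = p2.pack(lengths_cls, offsets, poses)
    x, tr2, it2 = _lm_schur_solve(p2, x0, opts.max_iter, cost_tol=opts.fun_tol)
    trace.extend(tr2)
    n_iter += it2

    # stage 3: individual frames can be stuck in a wrong pose basin and
    # bias the shared skeleton; re-fit every frame's pose from a fresh
    # label-based initialization using the current skeleton, keep the
    # better pose per frame, and polish again
    for _ in range(opts.reseed_rounds):
        if trace[-1] < 1e-8:     # already at a numerically exact fit
            break
        lengths_cls, offsets, poses = p2.unpack(x)
        _, blocks = p2.eval_blocks(x)
        costs = np.array([float(r_f @ r_f) for r_f, _, _ in blocks])
        params = _expand_params(graph, layout, lengths_cls, offsets)
        cand = poses.copy()
        for f in range(p2.F):
            try:
                pose_f = ik_initial_pose(
                    labels[labels["frame"] == p2.frames[f]], graph, layout, rig
                )
            except ValueError:
                continue
            refit, _ = _pose_step_3d(
                p2, params, pose_f[None], X[f : f + 1], seen3d[f : f + 1]
            )
            cand[f] = refit[0]
        _, blocks_c = p2.eval_blocks(p2.pack(lengths_cls, offsets, cand))
        costs_c = np.array([float(r_f @ r_f) for r_f, _, _ in blocks_c])
        improved = costs_c < costs
        if not improved.any():
            break
        poses[improved] = cand[improved]
        x0 = p2.pack(lengths_cls, offsets, poses)
        x, tr3, it3 = _lm_schur_solve(p2, x0, opts.max_iter,
                                      cost_tol=opts.fun_tol)
        trace.extend(tr3)
        n_iter += it3

    # stage 4: a bone stuck in a wrong configuration drags its length far
    # from the direct (triangulation-based) estimate; reset such lengths
    # to the estimate, re-polish, and keep whichever fit is better
    lengths_cls, offsets, poses = p2.unpack(x)
    if trace[-1] < 1e-8:
        est_cls = lengths_cls.copy()
    else:
        est_cls = _estimate_length_classes(
            labels, graph, layout, rig, p2.frames, p2.len_lo, p2.len_hi,
            lengths_cls,
        )
    dev = np.abs(lengths_cls - est_cls) > np.maximum(0.25 * est_cls, 0.3)
    if dev.any():
        alt = lengths_cls.copy()
        alt[dev] = est_cls[dev]
        params = _expand_params(graph, layout, alt, offsets)
        # fresh per-frame initialization: the old poses carry the basin
        # that produced the bad length in the first place
        cand_poses = poses.copy()
        for f in range(p2.F):
            try:
                pose_f = ik_initial_pose(
                    labels[labels["frame"] == p2.frames[f]], graph, layout, rig
                )
            except ValueError:
                continue
            refit, _ = _pose_step_3d(
                p2, params, pose_f[None], X[f : f + 1], seen3d[f : f + 1]
            )
            cand_poses[f] = refit[0]
        x_alt, tr4, it4 = _lm_schur_solve(
            p2, p2.pack(alt, offsets, cand_poses), opts.max_iter,
            cost_tol=opts.fun_tol,
        )
        n_iter += it4
        if tr4[-1] < trace[-1]:
            x = x_alt
            trace.extend(tr4)
    lengths_cls, offsets, poses = p2.unpack(x)

    # gradient of the squared-pixel objective at the solution
    _, blocks = p2.eval_blocks(x)
    gmax = 0.0
    for r_f, Jp, Js in blocks:
        if len(r_f):
            gmax = max(gmax, np.abs(2.0 * Jp.T @ r_f).max(),
                       np.abs(2.0 * Js.T @ r_f).max())

    return LearnResult(
        params=_expand_params(graph, layout, lengths_cls, offsets),
        poses=poses, frames=p2.frames, objective=float(trace[-1]),
        objective_trace=trace, n_iter=n_iter,
        grad_norm=gmax, success=bool(len(trace) > 1),
    )


def compare_bone_lengths(
    learned: SkeletonParams,
    graph: SkeletonGraph,
    reference: dict[str, float],
):
    """Per-bone absolute length error and rank agreement with a reference.

    Returns (DataFrame with bone, learned_cm, reference_cm, abs_error_cm;
    Spearman rank correlation across the common bones).
    """
    rows = []
    for i, b in enumerate(graph.bones):
        if b.name in reference:
            rows.append((b.name, learned.bone_lengths[i], reference[b.name]))
        elif b.length_class in reference:
            rows.append((b.name, learned.bone_lengths[i], reference[b.length_class]))
    if not rows:
        raise ValueError("no common bones between learned and reference sets")
    df = pd.DataFrame(rows, columns=["bone", "learned_cm", "reference_cm"])
    df["abs_error_cm"] = (df["learned_cm"] - df["reference_cm"]).abs()
    rho = stats.spearmanr(df["learned_cm"], df["reference_cm"]).statistic
    return df, float(rho)
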