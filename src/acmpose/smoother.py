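"""Probabilistic pose reconstruction.

Nonlinear state-space model: the latent state per frame is the pose
(translation + unbounded rotation variables), the transition is a Gaussian
random walk (identity mean — temporal smoothness enters only through the
learned transition covariance), and the measurement function pushes the
state through the bounding sigmoid, forward kinematics and the camera
projections of every surface marker.  Inference is an unscented Kalman
filter plus Rauch-Tung-Striebel backward pass; the noise parameters
(initial mean/covariance, transition covariance, diagonal measurement
covariance) are learned by EM.  Missing measurement coordinates (occluded
or low-confidence detections) are handled by updating only on the
observed block, which is exactly equivalent to deleting those rows from
the model.

Because the transition mean is the identity, the prediction step and the
backward pass are exact (linear); the unscented approximation enters only
through the measurement update.

Model variants: ``acm`` (limits + smoothing), ``temporal`` (smoothing,
relaxed limits), ``joint_angle`` (limits, per-frame fits), ``naive``
(relaxed limits, per-frame fits).  Relaxing replaces every non-degenerate
limit pair by (-180, 180); frozen axes stay frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .cameras import CameraRig
from .skeleton import (
    Bone,
    MarkerLayout,
    SkeletonGraph,
    SkeletonParams,
    count_state_dim,
    forward_kinematics_batch,
    forward_kinematics_jacobian,
)

VARIANTS = ("acm", "joint_angle", "temporal", "naive")


def relax_limits(graph: SkeletonGraph) -> SkeletonGraph:
    """Relax every non-degenerate angle limit to (-180, 180) degrees.

    Degenerate (0, 0) axes remain frozen, so the state dimension is
    unchanged; this is the anatomically unconstrained skeleton used by
    the temporal-only and naive variants.
    """
    bones = []
    for b in graph.bones:
        lim = b.limits_deg.copy()
        for ax in range(3):
            if lim[ax, 0] < lim[ax, 1]:
                lim[ax] = (-180.0, 180.0)
        bones.append(
            Bone(
                name=b.name, parent_joint=b.parent_joint,
                child_joint=b.child_joint, segment=b.segment, side=b.side,
                rest_direction=b.rest_direction, limits_deg=lim,
            )
        )
    return SkeletonGraph(
        bones=bones, root_joint=graph.root_joint,
        root_limits_deg=graph.root_limits_deg.copy(),
    )


# ---------------------------------------------------------------------------
# state-space specification
# ---------------------------------------------------------------------------

@dataclass
class StateSpaceSpec:
    """Measurement model tying the pose state to pixel observations.

    Measurement layout is camera-major: for camera c, marker k, the pixel
    coordinates occupy entries ``2 * (c * n_markers + k) + (0, 1)``.
    """

    graph: SkeletonGraph
    params: SkeletonParams
    rig: CameraRig
    layout: MarkerLayout

    @property
    def n(self) -> int:
        return count_state_dim(self.graph)

    @property
    def m(self) -> int:
        return len(self.rig) * len(self.layout) * 2

    def h(self, states: np.ndarray) -> np.ndarray:
        """Measurement function for a batch of states -> (B, m) pixels.

        Points at non-positive depth are projected with the depth clamped
        to stay finite; in a proper overhead rig this never triggers.
        """
        states = np.atleast_2d(states)
        _, markers, _ = forward_kinematics_batch(
            self.graph, self.params, states, self.layout
        )
        return self._project_markers(markers)

    def _project_markers(self, markers: np.ndarray) -> np.ndarray:
        B, M, _ = markers.shape
        out = np.empty((B, len(self.rig) * M * 2))
        for c, cam in enumerate(self.rig.cameras):
            pc = markers @ cam.R.T + cam.t
            z = np.maximum(pc[..., 2], 1e-3)
            xn = pc[..., :2] / z[..., None]
            r2 = np.sum(xn**2, axis=-1, keepdims=True)
            xd = xn * (1.0 + cam.k1 * r2 + cam.k2 * r2**2)
            px = xd * [cam.fx, cam.fy] + [cam.cx, cam.cy]
            out[:, 2 * c * M : 2 * (c + 1) * M] = px.reshape(B, 2 * M)
        return out


def make_measurements(
    detections: pd.DataFrame,
    rig: CameraRig,
    layout: MarkerLayout,
    confidence_threshold: float = 0.9,
    n_frames: int | None = None,
):
    """Fixed-size measurement vectors and observation masks per frame.

    Entries with confidence below the threshold, or absent from the
    table, are marked missing.  Returns (y (T, m), mask (T, m)) with the
    camera-major layout of :class:`StateSpaceSpec`.
    """
    M = len(layout)
    C = len(rig)
    if n_frames is None:
        n_frames = int(detections["frame"].max()) + 1 if len(detections) else 0
    y = np.zeros((n_frames, C * M * 2))
    mask = np.zeros((n_frames, C * M * 2), dtype=bool)
    midx = layout.index
    for row in detections.itertuples(index=False):
        if row.marker not in midx:
            raise KeyError(f"unknown marker {row.marker!r}")
        c = int(row.camera)
        if not 0 <= c < C:
            raise KeyError(f"unknown camera index {row.camera!r}")
        t = int(row.frame)
        if t >= n_frames or row.confidence < confidence_threshold:
            continue
        base = 2 * (c * M + midx[row.marker])
        y[t, base], y[t, base + 1] = row.x, row.y
        mask[t, base] = mask[t, base + 1] = True
    return y, mask


# ---------------------------------------------------------------------------
# unscented transform
# ---------------------------------------------------------------------------

@dataclass
class UTParams:
    alpha: float = 1e-2
    beta: float = 2.0
    kappa: float = 0.0


def _chol_psd(P: np.ndarray, jitter: float = 1e-9) -> np.ndarray:
    """Cholesky factor, escalating diagonal jitter only when needed."""
    try:
        return np.linalg.cholesky(P)
    except np.linalg.LinAlgError:
        pass
    for k in range(8):
        try:
            return np.linalg.cholesky(P + (jitter * 10**k) * np.eye(len(P)))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance not PSD even after jitter")


def _sqrt_psd(P: np.ndarray) -> np.ndarray:
    """Symmetric square root via eigendecomposition; exact for singular P."""
    w, V = np.linalg.eigh(0.5 * (P + P.T))
    return V * np.sqrt(np.maximum(w, 0.0))


def sigma_points(mean: np.ndarray, cov: np.ndarray, ut: UTParams):
    n = len(mean)
    lam = ut.alpha**2 * (n + ut.kappa) - n
    L = _chol_psd(cov)
    X = np.empty((2 * n + 1, n))
    X[0] = mean
    s = math.sqrt(n + lam)
    X[1 : n + 1] = mean + s * L.T
    X[n + 1 :] = mean - s * L.T
    wm = np.full(2 * n + 1, 1.0 / (2.0 * (n + lam)))
    wc = wm.copy()
    wm[0] = lam / (n + lam)
    wc[0] = lam / (n + lam) + (1.0 - ut.alpha**2 + ut.beta)
    return X, wm, wc


def unscented_transform(mean, cov, fn, ut: UTParams | None = None):
    """Scaled sigma-point estimate of the pushforward of a Gaussian.

    Returns (mean_y, cov_y, cross_cov_xy).  Exact for affine ``fn``.
    """
    ut = ut or UTParams()
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    X, wm, wc = sigma_points(mean, cov, ut)
    Y = np.atleast_2d(np.asarray(fn(X), dtype=float))
    if Y.shape[0] != X.shape[0]:
        raise ValueError("fn must map (B, n) -> (B, k) batched")
    my = wm @ Y
    Yd = Y - my
    Xd = X - mean
    Sy = (Yd * wc[:, None]).T @ Yd
    Cxy = (Xd * wc[:, None]).T @ Yd
    return my, Sy, Cxy


# ---------------------------------------------------------------------------
# noise parameters and results
# ---------------------------------------------------------------------------

@dataclass
class NoiseParams:
    mu0: np.ndarray              # (n,)
    P0: np.ndarray               # (n, n)
    Q: np.ndarray                # (n, n) transition covariance
    r: np.ndarray                # (m,) diagonal measurement variances

    @classmethod
    def default(cls, n: int, m: int, mu0: np.ndarray | None = None,
                scale: float = 0.001) -> "NoiseParams":
        """Diagonal initialization with 0.001 in every diagonal entry."""
        return cls(
            mu0=np.zeros(n) if mu0 is None else np.asarray(mu0, float).copy(),
            P0=scale * np.eye(n),
            Q=scale * np.eye(n),
            r=np.full(m, scale),
        )

    def validate(self):
        for name, Mx in (("P0", self.P0), ("Q", self.Q)):
            if np.abs(Mx - Mx.T).max() > 1e-8:
                raise ValueError(f"{name} is not symmetric")
            if np.linalg.eigvalsh(Mx).min() < -1e-8:
                raise ValueError(f"{name} is not PSD")
        if np.any(self.r < 0):
            raise ValueError("measurement variances must be non-negative")


def count_em_params(spec: StateSpaceSpec | tuple[int, int]) -> int:
    """Free parameters learned by EM: n + 2 * n(n+1)/2 + m."""
    if isinstance(spec, tuple):
        n, m = spec
    else:
        n, m = spec.n, spec.m
    return n + n * (n + 1) // 2 + n * (n + 1) // 2 + m


@dataclass
class SmootherResult:
    filtered_means: np.ndarray       # (T, n)
    filtered_covs: np.ndarray        # (T, n, n)
    smoothed_means: np.ndarray       # (T, n)
    smoothed_covs: np.ndarray        # (T, n, n)
    gains: np.ndarray                # (T-1, n, n) RTS smoother gains
    loglik: float
    loglik_per_frame: np.ndarray     # (T,)


@dataclass
class EMTrace:
    elbo: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    monotone: bool = True


def _symmetrize_floor(P: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    P = 0.5 * (P + P.T)
    w, V = np.linalg.eigh(P)
    if w.min() < floor:
        P = (V * np.maximum(w, floor)) @ V.T
        P = 0.5 * (P + P.T)
    return P


def ukf_rts_smooth(
    spec: StateSpaceSpec,
    noise: NoiseParams,
    y: np.ndarray,
    mask: np.ndarray,
    ut: UTParams | None = None,
) -> SmootherResult:
    """Unscented forward filter + exact RTS backward pass.

    The random-walk transition makes prediction and the backward pass
    linear; the measurement update uses sigma points through the full
    bounding/kinematics/projection chain, restricted to the observed
    coordinates of each frame (masked coordinates contribute nothing —
    identical to deleting those measurement rows).
    """
    ut = ut or UTParams()
    noise.validate()
    T = y.shape[0]
    if T < 1:
        raise ValueError("need at least one measurement frame")
    n = spec.n
    fm = np.empty((T, n))
    fP = np.empty((T, n, n))
    pm = np.empty((T, n))
    pP = np.empty((T, n, n))
    ll = np.zeros(T)

    m_t, P_t = noise.mu0.copy(), noise.P0.copy()
    for t in range(T):
        if t > 0:
            P_t = P_t + noise.Q
        pm[t], pP[t] = m_t, P_t
        obs = mask[t]
        if obs.any():
            my, Sy, Cxy = unscented_transform(m_t, P_t, spec.h, ut)
            o = np.nonzero(obs)[0]
            S = Sy[np.ix_(o, o)] + np.diag(noise.r[o])
            innov = y[t, o] - my[o]
            L = _chol_psd(S, 1e-12)
            sol = np.linalg.solve(L, innov)
            K = np.linalg.solve(L.T, np.linalg.solve(L, Cxy[:, o].T)).T
            m_t = m_t + K @ innov
            P_t = _symmetrize_floor(P_t - K @ S @ K.T)
            ll[t] = -0.5 * (
                sol @ sol + 2.0 * np.log(np.diag(L)).sum()
                + len(o) * math.log(2.0 * math.pi)
            )
        fm[t], fP[t] = m_t, P_t

    sm = fm.copy()
    sP = fP.copy()
    G = np.empty((max(T - 1, 0), n, n))
    for t in range(T - 2, -1, -1):
        G[t] = np.linalg.solve(pP[t + 1].T, fP[t].T).T     # fP @ inv(pP_next)
        sm[t] = fm[t] + G[t] @ (sm[t + 1] - pm[t + 1])
        sP[t] = _symmetrize_floor(
            fP[t] + G[t] @ (sP[t + 1] - pP[t + 1]) @ G[t].T
        )
    return SmootherResult(
        filtered_means=fm, filtered_covs=fP, smoothed_means=sm,
        smoothed_covs=sP, gains=G, loglik=float(ll.sum()), loglik_per_frame=ll,
    )


@dataclass
class EMOptions:
    max_iter: int = 100
    rel_tol: float = 1e-4
    decrease_tol: float = 1e-8
    ut: UTParams = field(default_factory=UTParams)
    cov_floor: float = 1e-12


def em_fit(
    spec: StateSpaceSpec,
    y: np.ndarray,
    mask: np.ndarray,
    init: NoiseParams,
    opts: EMOptions | None = None,
):
    """EM learning of the state-space noise parameters.

    E-step: unscented RTS smoothing with the current parameters.  M-step:
    closed-form updates of the initial mean and covariance, the full
    transition covariance (from smoothed pairwise moments) and the
    diagonal of the measurement covariance (off-diagonals held at zero).
    The filter log-likelihood serves as the monitored objective; a
    decrease beyond tolerance is reported in the trace, not silently
    ignored.

    Returns (NoiseParams, EMTrace, SmootherResult).
    """
    opts = opts or EMOptions()
    noise = NoiseParams(init.mu0.copy(), init.P0.copy(), init.Q.copy(),
                        init.r.copy())
    trace = EMTrace()
    result = ukf_rts_smooth(spec, noise, y, mask, opts.ut)
    trace.elbo.append(result.loglik)
    T = y.shape[0]
    for it in range(opts.max_iter):
        sm, sP, G = result.smoothed_means, result.smoothed_covs, result.gains
        new_mu0 = sm[0].copy()
        new_P0 = _symmetrize_floor(sP[0], opts.cov_floor)
        if T > 1:
            Qacc = np.zeros_like(noise.Q)
            for t in range(T - 1):
                C = sP[t + 1] @ G[t].T           # lag-one smoothed covariance
                dm = sm[t + 1] - sm[t]
                Qacc += sP[t + 1] + sP[t] - C - C.T + np.outer(dm, dm)
            new_Q = _symmetrize_floor(Qacc / (T - 1), opts.cov_floor)
        else:
            new_Q = noise.Q
        # measurement variances from smoothed moments
        new_r = noise.r.copy()
        resid_sum = np.zeros(spec.m)
        count = np.zeros(spec.m)
        for t in range(T):
            obs = mask[t]
            if not obs.any():
                continue
            my, Sy, _ = unscented_transform(sm[t], sP[t], spec.h, opts.ut)
            o = np.nonzero(obs)[0]
            resid_sum[o] += (y[t, o] - my[o]) ** 2 + np.diag(Sy)[o]
            count[o] += 1
        seen = count > 0
        new_r[seen] = np.maximum(resid_sum[seen] / count[seen], opts.cov_floor)

        noise = NoiseParams(new_mu0, new_P0, new_Q, new_r)
        result = ukf_rts_smooth(spec, noise, y, mask, opts.ut)
        trace.elbo.append(result.loglik)
        trace.n_iter = it + 1
        prev, cur = trace.elbo[-2], trace.elbo[-1]
        if cur < prev - opts.decrease_tol * max(1.0, abs(prev)):
            trace.monotone = False
        if abs(cur - prev) < opts.rel_tol * max(1.0, abs(prev)):
            trace.converged = True
            break
    return noise, trace, result


def propagate_uncertainty(
    result: SmootherResult,
    spec: StateSpaceSpec,
    n_samples: int = 1000,
    seed: int = 0,
):
    """Per-frame 3D joint/marker means and s.d. from posterior samples.

    Draws ``n_samples`` states per frame from the smoothed Gaussian and
    pushes them through the bounding map and forward kinematics.
    Deterministic given the seed.  Returns a dict with joint and marker
    mean/sd arrays of shape (T, n_joints|n_markers, 3).
    """
    rng = np.random.default_rng(seed)
    T, n = result.smoothed_means.shape
    nj = len(spec.graph.joints)
    M = len(spec.layout)
    jm = np.empty((T, nj, 3))
    js = np.empty((T, nj, 3))
    mm = np.empty((T, M, 3))
    ms = np.empty((T, M, 3))
    for t in range(T):
        L = _sqrt_psd(result.smoothed_covs[t])
        X = result.smoothed_means[t] + rng.standard_normal((n_samples, n)) @ L.T
        joints, markers, _ = forward_kinematics_batch(
            spec.graph, spec.params, X, spec.layout
        )
        jm[t], js[t] = joints.mean(axis=0), joints.std(axis=0)
        mm[t], ms[t] = markers.mean(axis=0), markers.std(axis=0)
    return {"joint_mean": jm, "joint_sd": js, "marker_mean": mm, "marker_sd": ms}


# ---------------------------------------------------------------------------
# per-frame fitting (no temporal smoothing)
# ---------------------------------------------------------------------------

def fit_single_pose(
    spec: StateSpaceSpec,
    y_t: np.ndarray,
    mask_t: np.ndarray,
    x0: np.ndarray,
    max_nfev: int | None = None,
):
    """Bounded-parameterization least-squares reprojection fit of one frame."""
    o = np.nonzero(mask_t)[0]
    M = len(spec.layout)
    C = len(spec.rig)

    def split(o_idx):
        cam = o_idx // (2 * M)
        rem = o_idx % (2 * M)
        return cam, rem // 2, rem % 2

    def residual(x):
        return spec.h(x[None])[0, o] - y_t[o]

    def jac(x):
        res = forward_kinematics_jacobian(spec.graph, spec.params, x[None],
                                          spec.layout)
        markers = res["markers"][0]
        Jm = res["jac_pose"][0]                      # (M, 3, n)
        from .cameras import project_batch_with_jacobian

        J = np.empty((len(o), spec.n))
        for c in range(C):
            sel = (o // (2 * M)) == c
            if not sel.any():
                continue
            _, Jp = project_batch_with_jacobian(markers, spec.rig.cameras[c])
            for row, oi in zip(np.nonzero(sel)[0], o[sel]):
                _, mk, coord = split(oi)
                J[row] = Jp[mk, coord] @ Jm[mk]
        return J

    # wide box: keeps saturated sigmoid coordinates and the translation
    # from running away on ill-conditioned frames
    lo = np.full(spec.n, -50.0)
    hi = np.full(spec.n, 50.0)
    lo[:3], hi[:3] = -1e3, 1e3
    x0 = np.clip(x0, lo + 1e-6, hi - 1e-6)
    sol = optimize.least_squares(
        residual, x0, jac=jac, method="trf", max_nfev=max_nfev,
        bounds=(lo, hi),
    )
    return sol.x, sol


def initial_pose_from_detections(
    detections: pd.DataFrame,
    graph: SkeletonGraph,
    layout: MarkerLayout,
    rig: CameraRig,
    spec: StateSpaceSpec,
    y: np.ndarray,
    mask: np.ndarray,
    confidence_threshold: float = 0.9,
    scan_frames: int = 5,
) -> np.ndarray:
    """Anchor pose fitted to auto-detected 2D markers.

    Each of the first few frames is initialized from its triangulated
    detections (the same chain scheme used when learning the skeleton)
    and refined by a least-squares reprojection fit; the pose with the
    lowest residual RMS is returned.  Scanning several frames guards the
    whole sequence against one badly occluded or ambiguous start frame.
    """
    from .learning import ik_initial_pose

    best, best_rms = None, np.inf
    for t in range(min(scan_frames, y.shape[0])):
        if mask[t].sum() < 6:
            continue
        frame = detections[
            (detections["frame"] == t)
            & (detections["confidence"] >= confidence_threshold)
        ]
        try:
            x0 = ik_initial_pose(frame, graph, layout, rig)
        except ValueError:
            continue
        x_fit, sol = fit_single_pose(spec, y[t], mask[t], x0, max_nfev=100)
        rms = math.sqrt(2.0 * sol.cost / mask[t].sum())
        if rms < best_rms:
            best, best_rms = x_fit, rms
        if rms < 2.0:      # already an excellent anchor
            break
    if best is None:
        best = np.zeros(spec.n)
        best[:3] = (0.0, 0.0, 5.0)
    return best


def track_sequence(
    detections: pd.DataFrame,
    graph: SkeletonGraph,
    params: SkeletonParams,
    rig: CameraRig,
    layout: MarkerLayout,
    variant: str = "acm",
    confidence_threshold: float = 0.9,
    n_frames: int | None = None,
    em_opts: EMOptions | None = None,
):
    """Run one model variant over a detection table.

    Returns a dict with ``poses`` (T, n; smoothed means for smoothing
    variants), ``graph`` (possibly limit-relaxed), and for smoothing
    variants ``noise``, ``em_trace`` and ``result``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    g = graph if variant in ("acm", "joint_angle") else relax_limits(graph)
    spec = StateSpaceSpec(g, params, rig, layout)
    y, mask = make_measurements(detections, rig, layout,
                                confidence_threshold, n_frames)
    x0 = initial_pose_from_detections(
        detections, g, layout, rig, spec, y, mask, confidence_threshold
    )
    out = {"graph": g, "variant": variant, "mask": mask}
    if variant in ("acm", "temporal"):
        init = NoiseParams.default(spec.n, spec.m, mu0=x0)
        noise, trace, result = em_fit(spec, y, mask, init,
                                      em_opts or EMOptions(max_iter=10))
        out.update(poses=result.smoothed_means, noise=noise,
                   em_trace=trace, result=result, spec=spec)
    else:
        from .learning import ik_initial_pose

        def reinit(t):
            frame = detections[
                (detections["frame"] == t)
                & (detections["confidence"] >= confidence_threshold)
            ]
            return ik_initial_pose(frame, g, layout, rig)

        poses, flags = fit_pose_per_frame(spec, y, mask, x0, reinit=reinit)
        out.update(poses=poses, flags=flags, spec=spec)
    return out


def surface_trajectories(
    detections: pd.DataFrame,
    rig: CameraRig,
    layout: MarkerLayout,
    confidence_threshold: float = 0.9,
    n_frames: int | None = None,
) -> np.ndarray:
    """Skeleton-free baseline: triangulate each marker per frame.

    Uses the two highest-confidence detections per (frame, marker);
    markers with fewer than two usable detections are NaN.  Returns
    (T, n_markers, 3).
    """
    from .cameras import triangulate

    if n_frames is None:
        n_frames = int(detections["frame"].max()) + 1 if len(detections) else 0
    out = np.full((n_frames, len(layout), 3), np.nan)
    usable = detections[detections["confidence"] >= confidence_threshold]
    for (frame, marker), grp in usable.groupby(["frame", "marker"]):
        if len(grp) < 2 or int(frame) >= n_frames:
            continue
        dets = [
            (rig.cameras[int(r.camera)], np.array([r.x, r.y]),
             float(r.confidence))
            for r in grp.itertuples(index=False)
        ]
        try:
            out[int(frame), layout.index[marker]] = triangulate(dets)
        except (ValueError, KeyError):
            continue
    return out


def fit_pose_per_frame(
    spec: StateSpaceSpec,
    y: np.ndarray,
    mask: np.ndarray,
    x0: np.ndarray,
    min_observed: int = 6,
    max_nfev: int | None = 40,
    reinit=None,
    reinit_rms_px: float = 10.0,
):
    """Frame-by-frame pose fits, each initialized from the previous frame.

    Frames with fewer than ``min_observed`` observed coordinates keep the
    previous pose and are flagged.  When a fit's residual RMS exceeds
    ``reinit_rms_px`` and a ``reinit(t)`` callable is given, the frame is
    retried from that fresh initialization (keeping the better fit) —
    this stops a single bad frame from derailing the rest of the
    sequence.  Returns (poses (T, n), flags (T,)).
    """
    T = y.shape[0]
    poses = np.empty((T, spec.n))
    flags = np.zeros(T, dtype=bool)
    x = np.asarray(x0, dtype=float).copy()

    def rms(sol, t):
        return math.sqrt(2.0 * sol.cost / max(mask[t].sum(), 1))

    for t in range(T):
        if mask[t].sum() < min_observed:
            poses[t] = x
            flags[t] = True
            continue
        x_new, sol = fit_single_pose(spec, y[t], mask[t], x, max_nfev=max_nfev)
        if reinit is not None and rms(sol, t) > reinit_rms_px:
            try:
                x_alt = reinit(t)
            except ValueError:
                x_alt = None
            if x_alt is not None:
                x_retry, sol_retry = fit_single_pose(
                    spec, y[t], mask[t], x_alt, max_nfev=max_nfev
                )
                if sol_retry.cost < sol.cost:
                    x_new, sol = x_retry, sol_retry
        x = x_new
        poses[t] = x
    return poses, flags
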