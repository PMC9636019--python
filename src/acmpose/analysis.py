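"""Kinematic quantities derived from pose sequences.

Animal-centric normalized coordinates, high-order finite-difference
velocities and accelerations, bone/joint angles, gait-cycle extraction
and population averaging, periodicity analyses (autocorrelation with a
damped-sinusoid fit, Fourier spectra, peak spacing), orientation-derived
angular velocity, jump segmentation with jump-distance correlations, and
floor-truth evaluation metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .skeleton import SkeletonGraph

ORIGIN_JOINT = "lumbar_sacrum"       # joint connecting lumbar spine and sacrum
AXIS_JOINT = "cervical_thoracic"     # joint linking cervical and thoracic spine


# ---------------------------------------------------------------------------
# normalized (animal-centric) coordinates
# ---------------------------------------------------------------------------

def normalize_coordinates(
    joints_xyz: np.ndarray,
    graph: SkeletonGraph,
    origin_joint: str = ORIGIN_JOINT,
    axis_joint: str = AXIS_JOINT,
) -> np.ndarray:
    """Re-express joint positions in the animal-centric frame, per frame.

    Origin at the lumbosacral joint; x = horizontal projection of the
    direction toward the cervicothoracic joint (anteroposterior axis);
    z stays world-vertical; y = z cross x.  Invariant to any rigid
    horizontal motion of the whole animal.
    """
    o = graph.joint_index[origin_joint]
    a = graph.joint_index[axis_joint]
    rel = joints_xyz - joints_xyz[:, o : o + 1, :]
    d = joints_xyz[:, a, :] - joints_xyz[:, o, :]
    d = d.copy()
    d[:, 2] = 0.0
    nrm = np.linalg.norm(d, axis=1)
    if np.any(nrm < 1e-9):
        raise ValueError("origin and axis joints coincide in the horizontal plane")
    x_ax = d / nrm[:, None]
    z_ax = np.broadcast_to([0.0, 0.0, 1.0], x_ax.shape)
    y_ax = np.cross(z_ax, x_ax)
    R = np.stack([x_ax, y_ax, z_ax], axis=1)          # (T, 3, 3) world->body rows
    return np.einsum("tij,tmj->tmi", R, rel)


# ---------------------------------------------------------------------------
# finite differences (central 8th order, one-sided at the edges)
# ---------------------------------------------------------------------------

def _fornberg_weights(x: np.ndarray, x0: float, m: int) -> np.ndarray:
    """Finite-difference weights for the m-th derivative at x0 on nodes x.

    Fornberg's recursive algorithm; returns one weight per node.
    """
    n = len(x)
    C = np.zeros((n, m + 1))
    C[0, 0] = 1.0
    c1 = 1.0
    c4 = x[0] - x0
    for i in range(1, n):
        mn = min(i, m)
        c2 = 1.0
        c5 = c4
        c4 = x[i] - x0
        for j in range(i):
            c3 = x[i] - x[j]
            c2 *= c3
            if j == i - 1:
                for k in range(mn, 0, -1):
                    C[i, k] = c1 * (k * C[i - 1, k - 1] - c5 * C[i - 1, k]) / c2
                C[i, 0] = -c1 * c5 * C[i - 1, 0] / c2
            for k in range(mn, 0, -1):
                C[j, k] = (c4 * C[j, k] - k * C[j, k - 1]) / c3
            C[j, 0] = c4 * C[j, 0] / c3
        c1 = c2
    return C[:, m]


def finite_diff(trace: np.ndarray, dt: float, order: int = 1) -> np.ndarray:
    """Central 8th-order finite-difference derivative along axis 0.

    Interior points use the symmetric 9-point stencil; the first/last
    four samples use one-sided stencils of the same order, so the output
    has the same length as the input.  ``order`` is 1 (velocity) or 2
    (acceleration).
    """
    trace = np.asarray(trace, dtype=float)
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    T = trace.shape[0]
    if T < 9:
        raise ValueError("need at least 9 samples for the 8th-order stencil")
    grid = np.arange(9, dtype=float)
    w_central = _fornberg_weights(grid, 4.0, order)
    out = np.empty_like(trace)
    # interior via correlation with the central stencil
    flat = trace.reshape(T, -1)
    interior = np.stack(
        [np.correlate(flat[:, c], w_central, mode="valid")
         for c in range(flat.shape[1])],
        axis=1,
    )
    out.reshape(T, -1)[4 : T - 4] = interior
    for i in range(4):
        w = _fornberg_weights(grid, float(i), order)
        out.reshape(T, -1)[i] = flat[:9].T @ w
        w = _fornberg_weights(grid, float(8 - i), order)
        out.reshape(T, -1)[T - 1 - i] = flat[T - 9 :].T @ w
    return out / dt**order


# ---------------------------------------------------------------------------
# angles
# ---------------------------------------------------------------------------

def bone_angles(
    norm_joints: np.ndarray, graph: SkeletonGraph, bones: list[str]
) -> np.ndarray:
    """Angle (deg) between the animal-centric x axis and each bone, (T, n)."""
    out = np.empty((norm_joints.shape[0], len(bones)))
    for i, name in enumerate(bones):
        b = graph.bones[graph.bone_index[name]]
        v = (
            norm_joints[:, graph.joint_index[b.child_joint]]
            - norm_joints[:, graph.joint_index[b.parent_joint]]
        )
        out[:, i] = np.degrees(
            np.arccos(np.clip(v[:, 0] / np.linalg.norm(v, axis=1), -1.0, 1.0))
        )
    return out


def joint_angles(
    joints_xyz: np.ndarray, graph: SkeletonGraph, joint_names: list[str]
) -> np.ndarray:
    """Angle (deg) between the two bones meeting at each named joint, (T, n).

    For joints with several children the first child bone in graph order
    is used.
    """
    out = np.empty((joints_xyz.shape[0], len(joint_names)))
    for i, jn in enumerate(joint_names):
        parent_bone = None
        child_bone = None
        for b in graph.bones:
            if b.child_joint == jn:
                parent_bone = b
            elif b.parent_joint == jn and child_bone is None:
                child_bone = b
        if parent_bone is None or child_bone is None:
            raise ValueError(f"joint {jn!r} does not connect two bones")
        u = (
            joints_xyz[:, graph.joint_index[parent_bone.child_joint]]
            - joints_xyz[:, graph.joint_index[parent_bone.parent_joint]]
        )
        v = (
            joints_xyz[:, graph.joint_index[child_bone.child_joint]]
            - joints_xyz[:, graph.joint_index[child_bone.parent_joint]]
        )
        c = np.sum(u * v, axis=1) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        out[:, i] = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    return out


# ---------------------------------------------------------------------------
# gait cycles
# ---------------------------------------------------------------------------

@dataclass
class GaitCycleSet:
    peaks: dict[str, np.ndarray]            # limb -> peak frame indices
    windows: dict[str, np.ndarray]          # limb -> (n_cycles, win) traces
    mean: dict[str, np.ndarray]             # limb -> (win,) population mean
    sd: dict[str, np.ndarray]               # limb -> (win,)
    window_frames: int = 0


def find_peaks_above(
    trace: np.ndarray, threshold: float, prominence_frac: float = 0.05
) -> np.ndarray:
    """Strict local maxima above a threshold with a relative prominence floor.

    The floor is a fraction of the 1st-99th percentile span (robust to a
    few outlier samples, which would otherwise inflate a range-based
    floor and mask genuine peaks).
    """
    span = float(np.percentile(trace, 99) - np.percentile(trace, 1))
    prom = prominence_frac * span if span > 0 else None
    peaks, _ = signal.find_peaks(trace, height=threshold, prominence=prom)
    return peaks


def extract_gait_cycles(
    velocity_traces: dict[str, np.ndarray],
    fps: float,
    v_threshold: float = 25.0,
    window_ms: float = 200.0,
) -> GaitCycleSet:
    """Swing-phase midpoints and population-averaged aligned windows.

    Midpoints of swing are peaks of the anteroposterior velocity above
    ``v_threshold`` (cm/s); traces of +-``window_ms`` around each peak
    are aligned by the peak and averaged.  Peaks whose window leaves the
    recording are discarded.
    """
    half = int(round(window_ms / 1000.0 * fps))
    out = GaitCycleSet(peaks={}, windows={}, mean={}, sd={},
                       window_frames=2 * half + 1)
    for limb, v in velocity_traces.items():
        peaks = find_peaks_above(v, v_threshold)
        peaks = peaks[(peaks >= half) & (peaks < len(v) - half)]
        wins = np.array([v[p - half : p + half + 1] for p in peaks]) if len(
            peaks
        ) else np.empty((0, 2 * half + 1))
        out.peaks[limb] = peaks
        out.windows[limb] = wins
        out.mean[limb] = wins.mean(axis=0) if len(wins) else np.full(
            2 * half + 1, np.nan
        )
        out.sd[limb] = wins.std(axis=0) if len(wins) else np.full(
            2 * half + 1, np.nan
        )
    return out


# ---------------------------------------------------------------------------
# periodicity
# ---------------------------------------------------------------------------

def autocorrelation(trace: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased autocorrelation normalized to 1 at lag 0, lags 0..max_lag."""
    x = np.asarray(trace, dtype=float) - np.mean(trace)
    full = np.correlate(x, x, mode="full")[len(x) - 1 :]
    if full[0] <= 0:
        raise ValueError("zero-variance trace has no autocorrelation")
    return full[: max_lag + 1] / full[0]


def fit_damped_sinusoid(
    autocorr: np.ndarray, fs: float, n_starts: int = 5
):
    """Fit A exp(-lambda |tau|) cos(2 pi f tau) to an autocorrelation.

    Multi-start (deterministic frequency seeds from the spectrum)
    gradient-based least squares.  Returns (frequency_hz, decay_hz, r2).
    """
    # fit over positive lags: the lag-0 value is the normalization point
    # and would otherwise let an arbitrarily fast decay explain a spike
    tau = np.arange(1, len(autocorr)) / fs
    y = np.asarray(autocorr, dtype=float)[1:]

    spec = np.abs(np.fft.rfft(y - y.mean()))
    freqs = np.fft.rfftfreq(len(y), 1.0 / fs)
    order = np.argsort(spec[1:])[::-1] + 1
    seeds = [freqs[i] for i in order[:n_starts] if freqs[i] > 0] or [1.0]

    def model(p, t):
        A, lam, f = p
        return A * np.exp(-lam * np.abs(t)) * np.cos(2.0 * math.pi * f * t)

    best = None
    for f0 in seeds:
        try:
            sol = optimize.least_squares(
                lambda p: model(p, tau) - y,
                x0=[1.0, 1.0, f0],
                bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, fs / 2.0]),
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("damped-sinusoid fit failed to converge")
    resid = model(best.x, tau) - y
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    A, lam, f = best.x
    return float(f), float(lam), float(r2)


def fourier_peak(traces: dict[str, np.ndarray], fs: float):
    """Dominant non-DC frequency per limb and a shared-peak flag.

    Returns (dict limb -> frequency Hz, all_limbs_share_one_bin: bool).
    Raises for constant traces (no non-DC peak).
    """
    peaks = {}
    bins = set()
    for limb, tr in traces.items():
        x = np.asarray(tr, dtype=float)
        spec = np.abs(np.fft.rfft(x - x.mean()))
        if np.all(spec[1:] < 1e-12 * max(1.0, np.abs(x).max())):
            raise ValueError(f"trace {limb!r} is constant: no spectral peak")
        k = 1 + int(np.argmax(spec[1:]))
        peaks[limb] = float(k * fs / len(x))
        bins.add(k)
    return peaks, len(bins) == 1


def peak_periodicity(
    trace: np.ndarray, fps: float, peak_type: str = "max", filter_len: int = 120
):
    """Inter-peak interval statistics from a sliding min/max filter.

    Extrema are samples equal to the sliding-window extremum centered on
    them (plateaus keep their first frame).  Returns (mean_ms, sd_ms,
    n_intervals).
    """
    trace = np.asarray(trace, dtype=float)
    if filter_len < 1:
        raise ValueError("filter length must be >= 1")
    if peak_type == "max":
        filt = maximum_filter1d(trace, size=filter_len, mode="nearest")
        anti = minimum_filter1d(trace, size=filter_len, mode="nearest")
    elif peak_type == "min":
        filt = minimum_filter1d(trace, size=filter_len, mode="nearest")
        anti = maximum_filter1d(trace, size=filter_len, mode="nearest")
    else:
        raise ValueError("peak_type must be 'min' or 'max'")
    # flat windows (filt == anti) carry no extremum information
    idx = np.nonzero((trace == filt) & (filt != anti))[0]
    # collapse plateaus / adjacent hits within half a window
    if len(idx):
        keep = [idx[0]]
        for i in idx[1:]:
            if i - keep[-1] > filter_len // 2:
                keep.append(i)
        idx = np.array(keep)
    if len(idx) < 2:
        raise ValueError("fewer than two extrema detected")
    intervals = np.diff(idx) / fps * 1000.0
    return float(np.mean(intervals)), float(np.std(intervals)), len(intervals)


def angular_velocity_from_orientation(
    orientations: np.ndarray, fps: float, tol: float = 1e-6
) -> np.ndarray:
    """Absolute angular velocity (deg/s) from per-frame rotation matrices.

    For each step the angle of the relative rotation R_n^T R_{n+1} is
    divided by the frame period; the rotation axis does not enter.
    Returns a trace of length T - 1.
    """
    R = np.asarray(orientations, dtype=float)
    if R.ndim != 3 or R.shape[1:] != (3, 3):
        raise ValueError("orientations must be (T, 3, 3)")
    err = np.abs(np.einsum("tij,tkj->tik", R, R) - np.eye(3)).max()
    if err > tol:
        raise ValueError(f"orientations not orthonormal (max deviation {err:.2e})")
    rel = np.einsum("tji,tjk->tik", R[:-1], R[1:])     # R_t^T R_{t+1}
    cos = np.clip((np.trace(rel, axis1=1, axis2=2) - 1.0) / 2.0, -1.0, 1.0)
    return np.degrees(np.arccos(cos)) * fps


def compare_traces_by_peaks(
    trace_a: np.ndarray,
    trace_b: np.ndarray,
    boundaries: np.ndarray,
    filter_len: int = 120,
    fps: float | None = None,
):
    """Segment-wise Pearson correlation and nearest-peak time differences.

    ``boundaries`` are segment edges (e.g. gait-period minima); returns
    (list of per-segment Pearson r, array of per-peak frame differences
    b-to-nearest-a).
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("traces must be synchronized and equal length")
    rs = []
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        sa, sb = a[lo:hi], b[lo:hi]
        if np.std(sa) == 0 or np.std(sb) == 0:
            raise ValueError("zero-variance segment")
        rs.append(float(stats.pearsonr(sa, sb).statistic))
    fa = maximum_filter1d(a, size=filter_len, mode="nearest")
    fb = maximum_filter1d(b, size=filter_len, mode="nearest")
    pa = np.nonzero(a == fa)[0]
    pb = np.nonzero(b == fb)[0]
    diffs = np.array([pb_i - pa[np.argmin(np.abs(pa - pb_i))] for pb_i in pb]) if len(
        pa
    ) else np.array([])
    return rs, diffs


# ---------------------------------------------------------------------------
# jumps
# ---------------------------------------------------------------------------

@dataclass
class JumpSegmentation:
    start: int
    mid: int
    end: int
    trace: np.ndarray = field(repr=False, default=None)


def segment_jump(
    joint_angle_traces: np.ndarray, prominence_frac: float = 0.02
) -> JumpSegmentation:
    """Segment one jump from averaged spine + hind-limb joint angles.

    The averaged trace of a jump shows, in order: local minimum, local
    maximum, global minimum, local maximum, local minimum.  Start/end are
    the first/last local minima, the midpoint is the global minimum.
    Raises when the pattern is absent or ambiguous.
    """
    trace = np.asarray(joint_angle_traces, dtype=float)
    if trace.ndim == 2:
        trace = trace.mean(axis=1)
    rng = np.ptp(trace)
    if rng <= 0:
        raise ValueError("flat trace: jump pattern absent")
    prom = prominence_frac * rng
    minima, _ = signal.find_peaks(-trace, prominence=prom)
    maxima, _ = signal.find_peaks(trace, prominence=prom)
    if len(minima) < 3 or len(maxima) < 2:
        raise ValueError("jump pattern absent (need 3 minima and 2 maxima)")
    gmin = minima[np.argmin(trace[minima])]
    left_min = minima[minima < gmin]
    right_min = minima[minima > gmin]
    left_max = maxima[(maxima < gmin)]
    right_max = maxima[(maxima > gmin)]
    ok = (
        len(left_min) and len(right_min)
        and len(left_max[left_max > left_min[-1] if len(left_min) else left_max])
        and len(right_max[right_max < right_min[0]])
    )
    if not ok:
        raise ValueError("jump extremum pattern ambiguous")
    return JumpSegmentation(
        start=int(left_min[-1]), mid=int(gmin), end=int(right_min[0]), trace=trace
    )


HIND_FOOT_JOINTS = ("ankle", "mtp", "toe")


def jump_distance(
    joints_xyz: np.ndarray,
    graph: SkeletonGraph,
    start: int,
    end: int,
) -> float:
    """Planar jump distance (cm) from hind-foot centroids at start/end.

    The foot point is the average of the ankle, metatarsophalangeal and
    toe joints, pooled over both hind limbs; the distance ignores z.
    """
    idx = []
    for side in ("left", "right"):
        for j in HIND_FOOT_JOINTS:
            name = f"{j}_{side}"
            if name not in graph.joint_index:
                raise KeyError(f"missing hind-foot joint {name!r}")
            idx.append(graph.joint_index[name])
    p0 = joints_xyz[start, idx].mean(axis=0)
    p1 = joints_xyz[end, idx].mean(axis=0)
    return float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))


def correlate_kinematics(pairs: dict[str, tuple[np.ndarray, np.ndarray]]):
    """Spearman rank correlations with two-tailed p-values per named pair.

    Each value is (x, y) of paired observations (>= 3).  Constant series
    are flagged with NaN coefficients rather than raising.
    """
    rows = []
    for name, (x, y) in pairs.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y) or len(x) < 3:
            raise ValueError(f"pair {name!r}: need >= 3 paired observations")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((name, np.nan, np.nan, True))
            continue
        res = stats.spearmanr(x, y)
        rows.append((name, float(res.statistic), float(res.pvalue), False))
    return pd.DataFrame(rows, columns=["pair", "spearman_r", "p_value", "constant"])


def lagged_correlation_sweep(
    outcomes: np.ndarray,
    predictor_traces: np.ndarray,
    reference_frame: int,
    lags: np.ndarray,
):
    """Spearman correlation of an outcome with a predictor at earlier times.

    ``predictor_traces`` is (n_trials, T); for each lag the predictor is
    sampled at ``reference_frame - lag`` per trial and rank-correlated
    with the per-trial outcomes (e.g., jump distances against spine
    angular velocities at time points before the jump's end).  Returns a
    DataFrame with lag, spearman_r, p_value.
    """
    outcomes = np.asarray(outcomes, dtype=float)
    rows = []
    for lag in lags:
        t = reference_frame - int(lag)
        if not 0 <= t < predictor_traces.shape[1]:
            raise ValueError(f"lag {lag} leaves the recording")
        x = predictor_traces[:, t]
        res = stats.spearmanr(x, outcomes)
        rows.append((int(lag), float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["lag", "spearman_r", "p_value"])


# ---------------------------------------------------------------------------
# floor-truth evaluation
# ---------------------------------------------------------------------------

def evaluate_against_floor_truth(
    recon_points: pd.DataFrame,
    floor_truth: pd.DataFrame,
    detected_mask: pd.DataFrame | None = None,
    smoothed: bool = True,
    min_bin_count: int = 10,
):
    """Position/orientation errors of reconstructed paws vs floor truth.

    Both tables carry columns frame, paw, point ('center'/'digit'), x_cm,
    y_cm.  Position error is the planar distance between reconstructed
    and true paw centers; the orientation error is the angle between the
    center->digit axes.  When ``detected_mask`` (frame, paw, detected) is
    given, errors are additionally binned by occlusion duration: frames
    since the nearest successful detection (minimum of past and future
    distance for smoothed variants, past only otherwise); bins with fewer
    than ``min_bin_count`` samples are dropped.

    Returns (per-frame DataFrame, occlusion-bin DataFrame | None).
    """
    key = ["frame", "paw"]
    ra = recon_points.pivot_table(index=key, columns="point",
                                  values=["x_cm", "y_cm"])
    tr = floor_truth.pivot_table(index=key, columns="point",
                                 values=["x_cm", "y_cm"])
    common = ra.index.intersection(tr.index)
    if len(common) == 0:
        raise ValueError("no synchronized (frame, paw) rows between tables")
    rows = []
    for frame, paw in common:
        r = ra.loc[(frame, paw)]
        t = tr.loc[(frame, paw)]
        rc = np.array([r[("x_cm", "center")], r[("y_cm", "center")]])
        tc = np.array([t[("x_cm", "center")], t[("y_cm", "center")]])
        pos_err = float(np.linalg.norm(rc - tc))
        ang_err = np.nan
        if ("x_cm", "digit") in r.index and ("x_cm", "digit") in t.index:
            rd = np.array([r[("x_cm", "digit")], r[("y_cm", "digit")]]) - rc
            td = np.array([t[("x_cm", "digit")], t[("y_cm", "digit")]]) - tc
            nr, nt = np.linalg.norm(rd), np.linalg.norm(td)
            if nr > 0 and nt > 0:
                ang_err = float(
                    np.degrees(np.arccos(np.clip(rd @ td / (nr * nt), -1, 1)))
                )
        rows.append((frame, paw, pos_err, ang_err))
    per_frame = pd.DataFrame(
        rows, columns=["frame", "paw", "position_error_cm", "angle_error_deg"]
    )
    if detected_mask is None:
        return per_frame, None

    binned_rows = []
    for paw, grp in per_frame.groupby("paw"):
        det = detected_mask[detected_mask["paw"] == paw].set_index("frame")[
            "detected"
        ]
        det_frames = np.array(sorted(det.index[det]))
        if len(det_frames) == 0:
            continue
        for r in grp.itertuples(index=False):
            past = det_frames[det_frames <= r.frame]
            future = det_frames[det_frames >= r.frame]
            d_past = r.frame - past[-1] if len(past) else np.inf
            d_future = future[0] - r.frame if len(future) else np.inf
            dist = min(d_past, d_future) if smoothed else d_past
            if np.isfinite(dist):
                binned_rows.append((paw, int(dist), r.position_error_cm))
    binned = pd.DataFrame(binned_rows, columns=["paw", "occlusion_frames",
                                                "position_error_cm"])
    agg = (
        binned.groupby("occlusion_frames")["position_error_cm"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return per_frame, agg[agg["count"] >= min_bin_count].reset_index(drop=True)
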