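"""Pinhole camera model with second-order radial distortion.

Projection, undistortion, multi-view triangulation, reprojection error and
ray-floor intersection.  Pixel convention: origin at the top-left corner,
x right, y down, pixel centers at integer coordinates.  Distortion acts on
normalized camera coordinates before the intrinsics are applied; only the
two radial terms k1, k2 are modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

#: reprojection errors strictly above this many pixels are flagged for review
REPROJECTION_FLAG_PX = 5.0


@dataclass
class CameraModel:
    fx: float
    fy: float
    cx: float
    cy: float
    k1: float
    k2: float
    R: np.ndarray          # (3, 3) world -> camera rotation
    t: np.ndarray          # (3,) world -> camera translation, cm
    width: int
    height: int
    name: str = ""

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError(f"camera {self.name!r}: focal lengths must be positive")
        if (
            np.abs(self.R @ self.R.T - np.eye(3)).max() > 1e-6
            or np.linalg.det(self.R) < 0
        ):
            raise ValueError(f"camera {self.name!r}: R is not a proper rotation")

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates."""
        return -self.R.T @ self.t

    def world_to_camera(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.R.T + self.t

    def distort(self, xn: np.ndarray) -> np.ndarray:
        """Apply radial distortion to normalized coordinates (..., 2)."""
        xn = np.asarray(xn, dtype=float)
        r2 = np.sum(xn**2, axis=-1, keepdims=True)
        return xn * (1.0 + self.k1 * r2 + self.k2 * r2**2)

    def undistort(self, xd: np.ndarray, tol: float = 1e-12) -> np.ndarray:
        """Invert the radial distortion by Newton iteration on the radius."""
        xd = np.asarray(xd, dtype=float)
        rd = np.linalg.norm(xd, axis=-1)
        r = rd.copy()
        for _ in range(50):
            f = r * (1.0 + self.k1 * r**2 + self.k2 * r**4) - rd
            df = 1.0 + 3.0 * self.k1 * r**2 + 5.0 * self.k2 * r**4
            step = f / df
            r = r - step
            if np.max(np.abs(step)) < tol:
                break
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(rd > 0, r / np.where(rd > 0, rd, 1.0), 1.0)
        return xd * scale[..., None]


def project(points: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Project world points (..., 3) in cm to pixel coordinates (..., 2).

    Raises for points at or behind the camera plane.
    """
    pc = camera.world_to_camera(points)
    z = pc[..., 2]
    if np.any(z <= 0):
        raise ValueError("point has non-positive depth in the camera frame")
    xn = pc[..., :2] / z[..., None]
    xd = camera.distort(xn)
    return xd * np.array([camera.fx, camera.fy]) + np.array([camera.cx, camera.cy])


def project_batch_with_jacobian(points: np.ndarray, camera: CameraModel):
    """Pixels (..., 2) and d pixel / d world-point (..., 2, 3).

    Unlike :func:`project` this does not raise on non-positive depth; such
    points yield non-finite outputs the caller is expected to mask.
    """
    points = np.asarray(points, dtype=float)
    pc = camera.world_to_camera(points)
    z = pc[..., 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        xn = pc[..., :2] / z[..., None]
    r2 = np.sum(xn**2, axis=-1)
    d = 1.0 + camera.k1 * r2 + camera.k2 * r2**2
    dd_dr2 = camera.k1 + 2.0 * camera.k2 * r2
    f = np.array([camera.fx, camera.fy])
    px = xn * d[..., None] * f + np.array([camera.cx, camera.cy])
    # d(xd)/d(xn) = d * I + 2 dd_dr2 * xn xn^T
    J_dist = d[..., None, None] * np.eye(2) + 2.0 * dd_dr2[..., None, None] * (
        xn[..., :, None] * xn[..., None, :]
    )
    # d(xn)/d(pc): [[1/z, 0, -x/z^2], [0, 1/z, -y/z^2]]
    with np.errstate(invalid="ignore", divide="ignore"):
        inv_z = 1.0 / z
    J_norm = np.zeros(points.shape[:-1] + (2, 3))
    J_norm[..., 0, 0] = inv_z
    J_norm[..., 1, 1] = inv_z
    J_norm[..., 0, 2] = -xn[..., 0] * inv_z
    J_norm[..., 1, 2] = -xn[..., 1] * inv_z
    J = f[:, None] * (J_dist @ J_norm) @ camera.R
    return px, J


def backproject_ray(camera: CameraModel, pixel: np.ndarray):
    """World-frame (origin, unit direction) of the ray through a pixel."""
    pixel = np.asarray(pixel, dtype=float)
    xn = camera.undistort(
        (pixel - [camera.cx, camera.cy]) / [camera.fx, camera.fy]
    )
    d_cam = np.concatenate([xn, np.ones(xn.shape[:-1] + (1,))], axis=-1)
    d_world = d_cam @ camera.R          # R^T @ d, batched
    d_world = d_world / np.linalg.norm(d_world, axis=-1, keepdims=True)
    return camera.center, d_world


def triangulate(
    detections: list[tuple[CameraModel, np.ndarray, float]],
    cond_threshold: float = 1e-8,
) -> np.ndarray:
    """Least-squares intersection of back-projected rays.

    ``detections`` is a list of (camera, pixel, confidence).  When more
    than two detections are supplied, only the two with the highest
    confidence are used (ties broken by lower camera position in the
    list), mirroring the surface-marker baseline's triangulation rule.
    """
    if len(detections) < 2:
        raise ValueError("triangulation needs at least two detections")
    if len(detections) > 2:
        order = sorted(
            range(len(detections)), key=lambda i: (-detections[i][2], i)
        )[:2]
        detections = [detections[i] for i in sorted(order)]
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for cam, px, _ in detections:
        o, d = backproject_ray(cam, np.asarray(px, dtype=float))
        P = np.eye(3) - np.outer(d, d)
        A += P
        b += P @ o
    # rays parallel -> A singular (rank deficiency)
    if np.linalg.cond(A) > 1.0 / cond_threshold:
        raise ValueError("rays are (near-)parallel; triangulation is degenerate")
    return np.linalg.solve(A, b)


def reprojection_error(
    labels: pd.DataFrame,
    points3d: dict[str, np.ndarray],
    rig: "CameraRig",
    flag_px: float = REPROJECTION_FLAG_PX,
) -> pd.DataFrame:
    """Per-row pixel distance between labels and projected 3D points.

    ``labels`` needs columns frame, camera, marker, x, y.  Rows whose
    error strictly exceeds ``flag_px`` are flagged for manual review.
    """
    errors = np.empty(len(labels))
    for i, row in enumerate(labels.itertuples(index=False)):
        if row.marker not in points3d:
            raise KeyError(f"no 3D point for marker {row.marker!r}")
        px = project(points3d[row.marker], rig.cameras[int(row.camera)])
        errors[i] = float(np.hypot(px[0] - row.x, px[1] - row.y))
    out = labels.copy()
    out["error_px"] = errors
    out["flagged"] = errors > flag_px
    return out


def ray_floor_intersection(
    camera: CameraModel, pixel: np.ndarray, floor_z: float = 0.0
) -> np.ndarray:
    """World (x, y) where the back-projected ray meets the plane z = z0."""
    o, d = backproject_ray(camera, np.asarray(pixel, dtype=float))
    if abs(d[2]) < 1e-12:
        raise ValueError("ray is parallel to the floor plane")
    s = (floor_z - o[2]) / d[2]
    if s <= 0:
        raise ValueError("floor intersection lies behind the camera")
    p = o + s * d
    return p[:2]


@dataclass
class CameraRig:
    cameras: list[CameraModel]

    def __post_init__(self):
        if len(self.cameras) < 2:
            raise ValueError("a rig needs at least two cameras for triangulation")

    def __len__(self) -> int:
        return len(self.cameras)

    def to_yaml(self, path):
        data = {
            "cameras": [
                {
                    "name": c.name or f"cam{i}",
                    "fx": float(c.fx), "fy": float(c.fy),
                    "cx": float(c.cx), "cy": float(c.cy),
                    "k1": float(c.k1), "k2": float(c.k2),
                    "R": [float(v) for v in c.R.ravel()],
                    "t": [float(v) for v in c.t],
                    "width": int(c.width), "height": int(c.height),
                }
                for i, c in enumerate(self.cameras)
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CameraRig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cams = []
        for i, c in enumerate(data["cameras"]):
            try:
                cams.append(
                    CameraModel(
                        fx=c["fx"], fy=c["fy"], cx=c["cx"], cy=c["cy"],
                        k1=c["k1"], k2=c["k2"], R=np.array(c["R"]),
                        t=np.array(c["t"]), width=c["width"], height=c["height"],
                        name=c.get("name", f"cam{i}"),
                    )
                )
            except ValueError as e:
                raise ValueError(f"calibration entry {i}: {e}") from e
        return cls(cameras=cams)

    def validate_reprojection(
        self, check_points: np.ndarray, check_pixels: np.ndarray, tol_px: float = 1.0
    ) -> np.ndarray:
        """Max reprojection error per camera on supplied check points."""
        errs = np.empty(len(self.cameras))
        for i, cam in enumerate(self.cameras):
            px = project(check_points, cam)
            errs[i] = np.max(np.linalg.norm(px - check_pixels[i], axis=-1))
        return errs


# ---------------------------------------------------------------------------
# detection tables
# ---------------------------------------------------------------------------

DETECTION_COLUMNS = ["frame", "camera", "marker", "x", "y", "confidence"]


def write_detections(df: pd.DataFrame, path):
    df.to_csv(path, index=False, columns=DETECTION_COLUMNS)


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detection table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["frame", "camera", "marker"])
    if dup.any():
        raise ValueError(
            f"duplicate (frame, camera, marker) rows at index {df.index[dup][0]}"
        )
    return df
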