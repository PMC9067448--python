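"""Landmark-based registration of the arterial model to a tracked view.

The arterial model lives in scanner (world, mm) coordinates; the tracked
face is represented by the common 68-point facial landmark scheme, either in
3-D (subject/model space) or 2-D (camera pixels).  Matching is a 7-parameter
similarity transform (scale, rotation, translation) estimated in closed form
(Umeyama least squares), or — when only a 2-D view is available — a rigid
camera pose estimated by Gauss-Newton minimization of landmark reprojection
error through a pinhole camera.

Landmark scheme (fixed indexing):
    0-16  jawline (17), 17-26 eyebrows (10), 27-35 nose (9),
    36-47 eyes (12), 48-67 mouth (20).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

N_LANDMARKS = 68

#: Landmark indices by anatomical group.
LANDMARK_GROUPS = {
    "jawline": tuple(range(0, 17)),
    "eyebrows": tuple(range(17, 27)),
    "nose": tuple(range(27, 36)),
    "eyes": tuple(range(36, 48)),
    "mouth": tuple(range(48, 68)),
}

#: The nine landmarks lying on the midsagittal plane (chin tip, nasal
#: bridge and tip, philtrum and lip midpoints).
MIDLINE_INDICES = (8, 27, 28, 29, 30, 33, 51, 57, 62)


class DegeneracyError(ValueError):
    """Point configuration too degenerate to estimate a transform."""


class ProjectionError(ValueError):
    """Points at or behind the camera plane cannot be projected."""


class ConvergenceError(RuntimeError):
    """Iterative pose estimation failed to converge."""

    def __init__(self, msg: str, last_residual: float):
        super().__init__(msg)
        self.last_residual = last_residual


@dataclass
class LandmarkSet:
    """68 facial landmarks, 3-D (mm) or 2-D (pixels)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] != N_LANDMARKS:
            raise ValueError(
                f"expected {N_LANDMARKS} landmarks, got shape {self.points.shape}"
            )
        if self.points.shape[1] not in (2, 3):
            raise ValueError("landmarks must be 2-D or 3-D")
        if not np.isfinite(self.points).all():
            raise ValueError("landmark coordinates must be finite")

    @property
    def ndim(self) -> int:
        return self.points.shape[1]

    @classmethod
    def read(cls, path: str | os.PathLike) -> "LandmarkSet":
        """Read landmarks from CSV (``index,x,y[,z]``, optional header) or JSON."""
        path = str(path)
        if path.endswith(".json"):
            with open(path) as fh:
                return cls(points=np.asarray(json.load(fh)["points"], dtype=float))
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line[0].isalpha():
                    continue
                rows.append([float(v) for v in line.split(",")])
        arr = np.asarray(sorted(rows, key=lambda r: r[0]))
        return cls(points=arr[:, 1:])

    def write(self, path: str | os.PathLike) -> None:
        path = str(path)
        if path.endswith(".json"):
            with open(path, "w") as fh:
                json.dump({"points": self.points.tolist()}, fh)
        else:
            cols = "xyz"[: self.ndim]
            with open(path, "w") as fh:
                fh.write("index," + ",".join(cols) + "\n")
                for i, p in enumerate(self.points):
                    fh.write(f"{i}," + ",".join(f"{v:.10g}" for v in p) + "\n")


@dataclass
class SimilarityTransform:
    """x -> scale * rotation @ x + translation (mm)."""

    scale: float = 1.0
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return self.scale * points @ self.rotation.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        rot_inv = self.rotation.T
        return SimilarityTransform(
            scale=1.0 / self.scale,
            rotation=rot_inv,
            translation=-rot_inv @ self.translation / self.scale,
        )

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Transform applying ``other`` first, then ``self``."""
        return SimilarityTransform(
            scale=self.scale * other.scale,
            rotation=self.rotation @ other.rotation,
            translation=self.scale * self.rotation @ other.translation
            + self.translation,
        )


@dataclass
class CameraModel:
    """Pinhole camera: intrinsics in pixels plus a world->camera pose.

    A world point x is mapped to camera coordinates X = R x + t and then
    projected to pixels u = fx X/Z + cx, v = fy Y/Z + cy.  Points must have
    strictly positive depth Z.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def world_to_camera(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    @classmethod
    def read(cls, path: str | os.PathLike) -> "CameraModel":
        with open(path) as fh:
            d = json.load(fh)
        pose = d.get("pose", {})
        return cls(
            fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"],
            rotation=np.asarray(pose.get("rotation", np.eye(3).tolist())),
            translation=np.asarray(pose.get("translation", [0.0, 0.0, 0.0])),
        )

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
                    "pose": {
                        "rotation": self.rotation.tolist(),
                        "translation": self.translation.tolist(),
                    },
                },
                fh,
            )


def estimate_similarity(
    source: LandmarkSet, target: LandmarkSet
) -> tuple[SimilarityTransform, float]:
    """Closed-form least-squares similarity fit (Umeyama).

    Finds scale s, proper rotation R and translation t minimizing
    ``sum_i || s R x_i + t - y_i ||^2`` via centroid alignment, SVD of the
    cross-covariance with a reflection guard, and the variance-ratio scale.

    Returns
    -------
    (SimilarityTransform, float)
        The transform and the RMS residual in mm, reported per coordinate
        axis: ``sqrt(SSR / (3 n))``.
    """
    if source.ndim != 3 or target.ndim != 3:
        raise ValueError("similarity estimation needs 3-D landmark sets")
    x = source.points
    y = target.points
    n = len(x)
    mx, my = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mx, y - my
    var_x = (xc**2).sum() / n
    if var_x < 1e-12:
        raise DegeneracyError("source landmarks are coincident")
    cov = yc.T @ xc / n
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0  # reflection guard: flip the smallest singular axis
    if D[1] < 1e-12 * max(D[0], 1.0):
        raise DegeneracyError("source landmarks are collinear")
    R = U @ S @ Vt
    s = float(np.trace(np.diag(D) @ S) / var_x)
    if s <= 0:
        raise DegeneracyError("degenerate configuration: non-positive scale")
    t = my - s * R @ mx
    xf = SimilarityTransform(scale=s, rotation=R, translation=t)
    ssr = ((xf.apply(x) - y) ** 2).sum()
    rms = float(np.sqrt(ssr / (3 * n)))
    return xf, rms


def apply_transform(geometry, xf: SimilarityTransform):
    """Map any supported 3-D geometry through a similarity transform.

    Accepts :class:`LandmarkSet`, :class:`SurfaceMesh`,
    :class:`CenterlinePolyline` or a bare ``(n, 3)`` array; returns the same
    type with identical topology.
    """
    from .segmentation import CenterlinePolyline
    from .volume_io import SurfaceMesh

    if isinstance(geometry, LandmarkSet):
        return LandmarkSet(points=xf.apply(geometry.points))
    if isinstance(geometry, SurfaceMesh):
        return SurfaceMesh(vertices=xf.apply(geometry.vertices), faces=geometry.faces)
    if isinstance(geometry, CenterlinePolyline):
        return CenterlinePolyline(
            points=xf.apply(geometry.points),
            label=geometry.label,
            mean_radius_mm=(
                None
                if geometry.mean_radius_mm is None
                else geometry.mean_radius_mm * xf.scale
            ),
        )
    return xf.apply(np.asarray(geometry, dtype=float))


def project_points(points: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Pinhole projection of world-mm points to pixel coordinates."""
    pts_cam = camera.world_to_camera(np.atleast_2d(points))
    z = pts_cam[:, 2]
    behind = np.nonzero(z <= 0)[0]
    if len(behind):
        raise ProjectionError(
            f"points at or behind the camera plane at indices {behind.tolist()}"
        )
    u = camera.fx * pts_cam[:, 0] / z + camera.cx
    v = camera.fy * pts_cam[:, 1] / z + camera.cy
    return np.column_stack([u, v])


def _rodrigues(w: np.ndarray) -> np.ndarray:
    """Rotation matrix from an axis-angle vector."""
    theta = np.linalg.norm(w)
    if theta < 1e-14:
        return np.eye(3)
    k = w / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * K @ K


def estimate_pose(
    model_points: np.ndarray,
    image_points: np.ndarray,
    camera: CameraModel,
    max_iter: int = 100,
    step_tol: float = 1e-10,
    nominal_depth_mm: float = 500.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rigid model->camera pose from 2-D/3-D correspondences (Gauss-Newton).

    The deterministic initial pose back-projects the image points to 3-D at
    a nominal depth and fits a similarity transform to the model points; the
    similarity's scale is folded into the initial depth.  Gauss-Newton then
    refines rotation (axis-angle increments composed on the left) and
    translation to minimize the pixel reprojection residual.

    Returns ``(R, t, mean_reprojection_error_px)`` with camera coordinates
    ``X = R x + t``.
    """
    X = np.asarray(model_points, float)
    uv = np.asarray(image_points, float)
    n = len(X)

    # --- deterministic initialization -----------------------------------
    back = np.column_stack(
        [
            (uv[:, 0] - camera.cx) / camera.fx * nominal_depth_mm,
            (uv[:, 1] - camera.cy) / camera.fy * nominal_depth_mm,
            np.full(n, nominal_depth_mm),
        ]
    )
    src = LandmarkSet.__new__(LandmarkSet)  # bypass the 68-point check
    src.points = X
    tgt = LandmarkSet.__new__(LandmarkSet)
    tgt.points = back
    xf, _ = estimate_similarity(src, tgt)
    # rigid pose approximating s R x + t: keep R, rescale the offset so the
    # model centroid projects to the same pixel at depth z_c / s
    R = xf.rotation
    centroid_cam = xf.apply(X.mean(axis=0))
    t = centroid_cam / xf.scale - R @ X.mean(axis=0)

    def residual(R, t):
        pc = X @ R.T + t
        z = pc[:, 2]
        if np.any(z <= 0):
            return None, None
        u = camera.fx * pc[:, 0] / z + camera.cx
        v = camera.fy * pc[:, 1] / z + camera.cy
        r = np.column_stack([u - uv[:, 0], v - uv[:, 1]]).ravel()
        return r, pc

    r, pc = residual(R, t)
    if r is None:
        raise ConvergenceError("initial pose places points behind camera", np.inf)
    for _ in range(max_iter):
        # Gauss-Newton step.  The pose increment acts on the camera-space
        # point: pc -> dR pc + dt with dR = exp([w]_x), i.e. R <- dR R and
        # t <- dR t + dt, so d pc / d w = -[pc]_x and d pc / d dt = I.
        z = pc[:, 2]
        J = np.zeros((2 * n, 6))
        fx, fy = camera.fx, camera.fy
        x, y = pc[:, 0], pc[:, 1]
        du = np.column_stack([fx / z, np.zeros(n), -fx * x / z**2])
        dv = np.column_stack([np.zeros(n), fy / z, -fy * y / z**2])
        for a, d_ in ((0, du), (1, dv)):
            J[a::2, 0] = -d_[:, 1] * pc[:, 2] + d_[:, 2] * pc[:, 1]
            J[a::2, 1] = d_[:, 0] * pc[:, 2] - d_[:, 2] * pc[:, 0]
            J[a::2, 2] = -d_[:, 0] * pc[:, 1] + d_[:, 1] * pc[:, 0]
            J[a::2, 3:6] = d_
        try:
            step = np.linalg.lstsq(J, -r, rcond=None)[0]
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular normal equations: {exc}", float(np.sqrt((r**2).mean()))
            )
        w, dt = step[:3], step[3:]

        def apply_step(lam: float):
            dR = _rodrigues(lam * w)
            return dR @ R, dR @ t + lam * dt

        R_new, t_new = apply_step(1.0)
        r_new, pc_new = residual(R_new, t_new)
        if r_new is None or (r_new**2).sum() > (r**2).sum() * (1 + 1e-12):
            # damped fallback: halve the step until the residual decreases
            lam, ok = 0.5, False
            for _ in range(20):
                R_try, t_try = apply_step(lam)
                r_try, pc_try = residual(R_try, t_try)
                if r_try is not None and (r_try**2).sum() < (r**2).sum():
                    R_new, t_new, r_new, pc_new = R_try, t_try, r_try, pc_try
                    ok = True
                    break
                lam *= 0.5
            if not ok:
                break
        R, t, pc, r = R_new, t_new, pc_new, r_new
        if np.linalg.norm(np.concatenate([w, dt])) < step_tol:
            break
    err = float(np.mean(np.linalg.norm(r.reshape(-1, 2), axis=1)))
    return R, t, err


def register_model_to_view(
    model_landmarks3d: LandmarkSet,
    view_landmarks2d: LandmarkSet,
    camera: CameraModel,
    arterial_geometry: list | None = None,
) -> dict:
    """Match the 3-D arterial model to a tracked 2-D landmark view.

    Estimates the rigid model->camera pose from the 68 landmark
    correspondences, applies it to the arterial geometry (a list of
    :class:`CenterlinePolyline`) and projects the curves into the view.

    Returns a dict with keys ``pose_rotation``, ``pose_translation``,
    ``mean_reprojection_error_px``, ``projected_landmarks`` (68 x 2 px) and
    ``projected_curves`` (list of ``(label, (m, 2) px array)``).
    """
    if model_landmarks3d.ndim != 3 or view_landmarks2d.ndim != 2:
        raise ValueError("need 3-D model landmarks and 2-D view landmarks")
    R, t, err = estimate_pose(
        model_landmarks3d.points, view_landmarks2d.points, camera
    )
    cam_at_pose = CameraModel(
        fx=camera.fx, fy=camera.fy, cx=camera.cx, cy=camera.cy,
        rotation=R, translation=t,
    )
    projected_landmarks = project_points(model_landmarks3d.points, cam_at_pose)
    curves = []
    for poly in arterial_geometry or []:
        curves.append((poly.label, project_points(poly.points, cam_at_pose)))
    return {
        "pose_rotation": R,
        "pose_translation": t,
        "mean_reprojection_error_px": err,
        "projected_landmarks": projected_landmarks,
        "projected_curves": curves,
    }
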