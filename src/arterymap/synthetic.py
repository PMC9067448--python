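"""Seeded, ground-truthed phantoms of TOF-MRA-like head volumes.

A phantom is an ellipsoidal "head" of uniform background tissue intensity on
a dark exterior, with bright tubular arteries planted just beneath the
surface.  Each vessel has a Gaussian cross-section profile,

    I(x) = peak * exp(-d(x)^2 / (2 (radius/2)^2)),

where d is the distance to the vessel centerline — a differentiable profile
that mimics partial-volume blur and suits Hessian-based filtering better
than a hard cylinder.  The generator also places the 68 facial landmarks at
fixed parametric positions on the head surface and can render a camera view
(noisy projected landmarks plus noise-free projected artery curves), so
every pipeline stage is testable with no external data.  All randomness is
a pure function of the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .anatomy_labeling import ALL_LABELS, ArteryLabel, build_region_atlas
from .registration import CameraModel, LandmarkSet, project_points
from .scheme import ellipsoid_surface_points, landmark_directions
from .volume_io import ImageVolume, SurfaceMesh

#: Direction of the vessel arc in (azimuth, elevation) degrees for each
#: artery's course on the subject's left side (azimuth mirrored on the
#: right): labials run horizontally, the facial and temporal trunks climb.
_VESSEL_SPAN_DEG = {
    "Fa": (6.0, 14.0),
    "IL": (8.0, 2.0),
    "SL": (8.0, 2.0),
    "Ang": (4.0, 8.0),
    "LN": (4.0, 5.0),
    "DN": (3.0, 7.0),
    "STr": (3.0, 6.0),
    "SO": (5.0, 5.0),
    "ST": (5.0, 12.0),
}


@dataclass
class VesselSpec:
    """One planted artery: a labeled control-point path with radius and peak."""

    label: ArteryLabel
    path_mm: np.ndarray
    radius_mm: float = 1.0
    peak: float = 200.0

    def __post_init__(self) -> None:
        self.path_mm = np.asarray(self.path_mm, dtype=float).reshape(-1, 3)
        if self.radius_mm <= 0:
            raise ValueError("vessel radius must be positive")


@dataclass
class PhantomSpec:
    """Full description of a phantom; ``seed`` fixes all randomness."""

    shape: tuple[int, int, int] = (160, 160, 160)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    head_center_mm: tuple[float, float, float] | None = None
    head_semiaxes_mm: tuple[float, float, float] = (30.0, 33.0, 36.0)
    vessels: list[VesselSpec] = field(default_factory=list)
    background: float = 100.0
    edge_smooth_mm: float = 0.0
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"  # or "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.head_center_mm is None:
            self.head_center_mm = tuple(
                (n - 1) * s / 2 for n, s in zip(self.shape, self.spacing)
            )
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class PhantomTruth:
    """Everything planted: centerlines, landmarks, head geometry, skin mesh."""

    vessels: list[VesselSpec]
    landmarks3d: LandmarkSet
    head_center_mm: np.ndarray
    head_semiaxes_mm: np.ndarray
    skin_mesh: SurfaceMesh


def place_landmarks(
    head_center_mm, head_semiaxes_mm
) -> LandmarkSet:
    """68 landmarks at the fixed parametric positions on the head surface.

    Bilateral pairs mirror across the midsagittal (x = center) plane
    exactly, and all pairwise distances scale linearly with the head size.
    """
    pts = ellipsoid_surface_points(
        landmark_directions(),
        np.asarray(head_center_mm, float),
        np.asarray(head_semiaxes_mm, float),
    )
    return LandmarkSet(points=pts)


def _ellipsoid_mesh(center: np.ndarray, semi_axes: np.ndarray) -> SurfaceMesh:
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=3)
    verts = np.asarray(ico.vertices) * semi_axes + center
    return SurfaceMesh(vertices=verts, faces=np.asarray(ico.faces))


def default_vessel_paths(
    head_center_mm,
    head_semiaxes_mm,
    arteries: tuple[ArteryLabel, ...] = ALL_LABELS,
    depth_mm: float = 4.0,
    radius_mm: float = 1.0,
    peak: float = 200.0,
    n_points: int = 25,
) -> list[VesselSpec]:
    """Plant one vessel per requested artery, inside its atlas region.

    Each vessel is a surface-parallel arc centred on the artery's atlas
    region centroid, buried ``depth_mm`` beneath the skin, spanning a fixed
    per-artery angular course.  Construction from the same landmarks the
    atlas uses guarantees planted vessels carry their own ground-truth
    labels.
    """
    center = np.asarray(head_center_mm, float)
    axes = np.asarray(head_semiaxes_mm, float)
    atlas = build_region_atlas(place_landmarks(center, axes))
    vessels = []
    for lab in arteries:
        c = atlas.centroids[lab]
        u = (c - center) / axes
        u /= np.linalg.norm(u)
        az0 = np.arctan2(u[0], u[1])
        el0 = np.arcsin(np.clip(u[2], -1, 1))
        daz, del_ = np.deg2rad(_VESSEL_SPAN_DEG[lab.artery])
        if lab.side == "right":
            daz = -daz
        ts = np.linspace(-1.0, 1.0, n_points)
        az = az0 + ts * daz
        el = el0 + ts * del_
        dirs = np.column_stack(
            [np.cos(el) * np.sin(az), np.cos(el) * np.cos(az), np.sin(el)]
        )
        surf = center + dirs * axes
        r_local = np.linalg.norm(surf - center, axis=1)
        rho = 1.0 - depth_mm / r_local
        path = center + dirs * axes * rho[:, None]
        vessels.append(
            VesselSpec(label=lab, path_mm=path, radius_mm=radius_mm, peak=peak)
        )
    return vessels


def default_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """The standard study-condition phantom: 18 arteries, 5% Gaussian noise.

    The head gets a 1.5 mm smooth (partial-volume-like) skin edge; a hard
    indicator edge is available by setting ``edge_smooth_mm=0``.
    """
    spec = PhantomSpec(seed=seed, edge_smooth_mm=1.5)
    spec.vessels = default_vessel_paths(
        spec.head_center_mm, spec.head_semiaxes_mm
    )
    spec.noise_sigma = 0.05 * 200.0  # 5% of the vessel peak
    return replace(spec, **overrides) if overrides else spec


def _resample_path(path: np.ndarray, step: float) -> np.ndarray:
    segs = np.diff(path, axis=0)
    lens = np.linalg.norm(segs, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(lens)])
    total = cum[-1]
    if total == 0:
        return path[:1]
    s = np.arange(0.0, total + step / 2, step)
    out = np.empty((len(s), 3))
    for k in range(3):
        out[:, k] = np.interp(s, cum, path[:, k])
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, PhantomTruth]:
    """Render a phantom volume and return it with its exact ground truth.

    Voxel intensity is ``background * head_indicator`` plus each vessel's
    Gaussian profile, plus seeded noise.  Identical specs (including seed)
    produce bit-identical volumes.  A vessel whose centerline leaves the
    head raises a geometry error.
    """
    center = np.asarray(spec.head_center_mm, float)
    axes = np.asarray(spec.head_semiaxes_mm, float)
    sp = np.asarray(spec.spacing, float)

    for v in spec.vessels:
        q = ((v.path_mm - center) / axes) ** 2
        if np.any(q.sum(axis=1) > 1.0):
            raise ValueError(
                f"vessel {v.label} centerline leaves the head ellipsoid"
            )

    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(spec.shape, sp)], indexing="ij"
    )
    xyz = np.stack(grids, axis=-1)
    q = (((xyz - center) / axes) ** 2).sum(axis=-1)
    if spec.edge_smooth_mm <= 0:
        data = np.where(q <= 1.0, float(spec.background), 0.0)
    else:
        # partial-volume-like smooth skin edge: logistic profile over the
        # approximate signed distance to the ellipsoid surface
        norm = np.linalg.norm(xyz - center, axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            signed = norm * (1.0 - 1.0 / np.sqrt(np.maximum(q, 1e-12)))
        from scipy.special import expit

        data = spec.background * expit(-signed / (spec.edge_smooth_mm / 4.0))

    for v in spec.vessels:
        sigma = v.radius_mm / 2.0
        reach = 4.0 * sigma
        dense = _resample_path(v.path_mm, step=min(sp) / 4.0)
        lo = np.maximum(np.floor((dense.min(axis=0) - reach) / sp).astype(int), 0)
        hi = np.minimum(
            np.ceil((dense.max(axis=0) + reach) / sp).astype(int) + 1,
            np.asarray(spec.shape),
        )
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        box = xyz[sl].reshape(-1, 3)
        d, _ = cKDTree(dense).query(box, k=1)
        add = v.peak * np.exp(-(d**2) / (2 * sigma**2))
        data[sl] += add.reshape(xyz[sl].shape[:3])

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise_model == "gaussian":
            data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
        else:  # rician: magnitude of a complex Gaussian around the signal
            re = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
            im = rng.normal(0.0, spec.noise_sigma, size=data.shape)
            data = np.sqrt(re**2 + im**2)

    volume = ImageVolume(data=data, spacing=tuple(sp), origin=(0.0, 0.0, 0.0))
    truth = PhantomTruth(
        vessels=[
            VesselSpec(
                label=v.label,
                path_mm=_resample_path(v.path_mm, step=min(sp) / 2.0),
                radius_mm=v.radius_mm,
                peak=v.peak,
            )
            for v in spec.vessels
        ],
        landmarks3d=place_landmarks(center, axes),
        head_center_mm=center,
        head_semiaxes_mm=axes,
        skin_mesh=_ellipsoid_mesh(center, axes),
    )
    return volume, truth


def make_default_camera(
    truth: PhantomTruth, distance_mm: float = 250.0,
    fx: float = 1200.0, fy: float = 1200.0, cx: float = 400.0, cy: float = 400.0,
) -> CameraModel:
    """A frontal camera looking at the face along the -A (posterior) axis.

    Camera x runs toward the subject's left in the image (mirror view),
    camera y runs inferior (image rows grow downward), depth grows toward
    the head.
    """
    R = np.array([[-1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, -1.0, 0.0]])
    cam_center = truth.head_center_mm + np.array([0.0, distance_mm, 0.0])
    return CameraModel(
        fx=fx, fy=fy, cx=cx, cy=cy, rotation=R, translation=-R @ cam_center
    )


def render_view(
    truth: PhantomTruth,
    camera: CameraModel,
    landmark_noise_px: float = 0.0,
    seed: int = 0,
) -> tuple[LandmarkSet, list[tuple[str, np.ndarray]]]:
    """Project the phantom into a camera view.

    Returns the 68 projected landmarks with seeded Gaussian pixel noise
    added, and the artery centerlines projected noise-free as evaluation
    ground truth.  Raises a projection error if any landmark sits at or
    behind the camera plane.
    """
    lm2d = project_points(truth.landmarks3d.points, camera)
    if landmark_noise_px > 0:
        rng = np.random.default_rng(seed)
        lm2d = lm2d + rng.normal(0.0, landmark_noise_px, size=lm2d.shape)
    curves = [
        (str(v.label), project_points(v.path_mm, camera)) for v in truth.vessels
    ]
    return LandmarkSet(points=lm2d), curves
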