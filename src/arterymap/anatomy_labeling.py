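"""Assignment of extracted centerlines to the 18 named facial arteries.

Nine arteries per side are considered: facial (Fa), inferior (IL) and
superior labial (SL), angular (Ang), lateral nasal (LN), dorsal nasal (DN),
supratrochlear (STr), supraorbital (SO) and superficial temporal (ST).
Assignment uses a deterministic landmark-anchored region atlas — spherical
regions built from affine combinations of the 68 facial landmarks — rather
than expert visual comparison, and always permits "unclassified".  Region
geometry (combination weights, radius fractions) is calibration data kept in
a versioned config file (``data/atlas_regions.json``), not science.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .registration import MIDLINE_INDICES, N_LANDMARKS, LandmarkSet
from .scheme import MIRROR_MAP
from .segmentation import CenterlinePolyline

#: Artery abbreviations in fixed reporting order.
ARTERIES = ("Fa", "IL", "SL", "Ang", "LN", "DN", "STr", "SO", "ST")
SIDES = ("left", "right")

#: Long names, for report rendering.
ARTERY_NAMES = {
    "Fa": "Facial",
    "IL": "Inferior labial",
    "SL": "Superior labial",
    "Ang": "Angular",
    "LN": "Lateral nasal",
    "DN": "Dorsal nasal",
    "STr": "Supratrochlear",
    "SO": "Supraorbital",
    "ST": "Superficial temporal",
}


@dataclass(frozen=True, order=True)
class ArteryLabel:
    """One of the 18 (artery, side) combinations."""

    artery: str
    side: str

    def __post_init__(self) -> None:
        if self.artery not in ARTERIES:
            raise ValueError(f"unknown artery {self.artery!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    def __str__(self) -> str:
        return f"{self.artery}-{self.side}"


ALL_LABELS = tuple(
    ArteryLabel(a, s) for a in ARTERIES for s in SIDES
)


@dataclass
class RegionAtlas:
    """Spherical region per artery label, in the landmark mm frame."""

    centroids: dict[ArteryLabel, np.ndarray]
    radii: dict[ArteryLabel, float]
    midplane_point: np.ndarray
    midplane_normal: np.ndarray


def _load_region_config() -> dict:
    with resources.files("arterymap.data").joinpath("atlas_regions.json").open() as fh:
        return json.load(fh)


def fit_midsagittal_plane(landmarks: LandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through the nine midline landmarks.

    Returns (point on plane, unit normal).  The normal is the
    smallest-variance principal direction of the midline points, i.e. the
    left-right axis for a face.
    """
    pts = landmarks.points[list(MIDLINE_INDICES)]
    centre = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centre)
    return centre, vt[2]


def build_region_atlas(landmarks3d: LandmarkSet) -> RegionAtlas:
    """Construct the 18 artery regions from a 3-D landmark set.

    Regions are spheres whose centroids are fixed affine combinations of
    landmarks (so the construction is exactly equivariant under similarity
    transforms) and whose radii scale with the outer-interocular span.
    Left-side weights come from the config; right-side regions use the
    mirror-partner indices, so for a symmetric face the two sides mirror
    across the midsagittal plane exactly.
    """
    if landmarks3d.points.shape != (N_LANDMARKS, 3):
        raise ValueError(
            f"need {N_LANDMARKS} 3-D landmarks, got shape {landmarks3d.points.shape}"
        )
    cfg = _load_region_config()
    pts = landmarks3d.points
    i0, i1 = cfg["scale_pair"]
    scale = float(np.linalg.norm(pts[i0] - pts[i1]))
    centroids: dict[ArteryLabel, np.ndarray] = {}
    radii: dict[ArteryLabel, float] = {}
    for artery, spec in cfg["regions"].items():
        weights = {int(k): float(v) for k, v in spec["weights"].items()}
        total = sum(weights.values())
        for side in SIDES:
            idx = weights if side == "left" else {
                MIRROR_MAP[k]: v for k, v in weights.items()
            }
            c = sum(v * pts[k] for k, v in idx.items()) / total
            lab = ArteryLabel(artery, side)
            centroids[lab] = np.asarray(c)
            radii[lab] = spec["radius_frac"] * scale
    mp, mn = fit_midsagittal_plane(landmarks3d)
    return RegionAtlas(
        centroids=centroids, radii=radii, midplane_point=mp, midplane_normal=mn
    )


def label_centerlines(
    centerlines: list[CenterlinePolyline], atlas: RegionAtlas
) -> list[CenterlinePolyline]:
    """Assign each polyline the artery region containing most of its points.

    A polyline takes the label whose sphere contains the largest fraction of
    its points, provided that fraction is at least 0.5; otherwise it stays
    "unclassified".  Ties are broken by smaller distance from the polyline
    centroid to the region centroid, then by the fixed label order, so the
    result is deterministic and independent of input order.
    """
    labels = sorted(atlas.centroids, key=lambda l: (ARTERIES.index(l.artery), l.side))
    out = []
    for poly in centerlines:
        pts = poly.points
        best = None  # (-fraction, centroid_dist, order, label)
        pc = pts.mean(axis=0)
        for order, lab in enumerate(labels):
            d = np.linalg.norm(pts - atlas.centroids[lab], axis=1)
            frac = float((d <= atlas.radii[lab]).mean())
            if frac < 0.5:
                continue
            key = (-frac, float(np.linalg.norm(pc - atlas.centroids[lab])), order)
            if best is None or key < best[0]:
                best = (key, lab)
        out.append(
            CenterlinePolyline(
                points=pts,
                label=str(best[1]) if best else "unclassified",
                mean_radius_mm=poly.mean_radius_mm,
            )
        )
    return out


@dataclass
class VisualizationTally:
    """Per-artery detection counts across subjects (Table-1-style)."""

    left: dict[str, int]
    right: dict[str, int]
    n_subjects: int

    def total(self, artery: str) -> int:
        return self.left[artery] + self.right[artery]

    def percentage(self, artery: str) -> float:
        """Bilateral visualization rate, % of 2 * n_subjects, one decimal."""
        from .accuracy import round_half_up

        return round_half_up(
            100.0 * self.total(artery) / (2 * self.n_subjects), 1
        )

    @property
    def grand_total(self) -> int:
        return sum(self.left.values()) + sum(self.right.values())


def tally_visualization(
    per_subject_labels: list[set[ArteryLabel] | list[ArteryLabel]],
    n_subjects: int | None = None,
) -> VisualizationTally:
    """Count, per artery and side, the subjects in which it was detected."""
    if n_subjects is None:
        n_subjects = len(per_subject_labels)
    left = {a: 0 for a in ARTERIES}
    right = {a: 0 for a in ARTERIES}
    for i, labels in enumerate(per_subject_labels):
        labels = list(labels)
        if len(labels) != len(set(labels)):
            raise ValueError(f"subject {i} contributes a duplicate artery label")
        for lab in labels:
            (left if lab.side == "left" else right)[lab.artery] += 1
    for a in ARTERIES:
        if left[a] > n_subjects or right[a] > n_subjects:
            raise ValueError(f"count for {a} exceeds the number of subjects")
    return VisualizationTally(left=left, right=right, n_subjects=n_subjects)
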