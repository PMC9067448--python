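"""End-to-end pipeline driver with a reproducibility manifest.

Wires the stages in workflow order — vessel enhancement, thresholding, band
restriction, meshing/STL export, centerline extraction and labeling,
registration and projection, accuracy report — writing every intermediate
artifact into one run directory together with a manifest of parameter
values and content hashes, so a rerun with identical inputs is verifiably
identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import segmentation, vesselness
from .accuracy import evaluate_projection_accuracy, group_statistics
from .anatomy_labeling import build_region_atlas, label_centerlines
from .registration import CameraModel, LandmarkSet, register_model_to_view
from .volume_io import ImageVolume, write_nifti, write_stl

log = logging.getLogger("arterymap")


@dataclass
class PipelineConfig:
    """Flat, serializable knob set for one pipeline run."""

    scales_mm: tuple[float, ...] = vesselness.DEFAULT_SCALES_MM
    tau: float = vesselness.DEFAULT_TAU
    polarity: str = "bright"
    threshold: float = 0.5
    band_depth_mm: float = segmentation.DEFAULT_BAND_DEPTH_MM
    skin_offset_mm: float = 2.0
    min_component_voxels: int = segmentation.DEFAULT_MIN_COMPONENT_VOXELS
    min_branch_mm: float = 3.0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.tau <= 1:
            raise ValueError(f"tau must lie in (0, 1], got {self.tau}")
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")
        if self.band_depth_mm <= 0:
            raise ValueError("band depth must be positive")
        if not 0 <= self.skin_offset_mm < self.band_depth_mm:
            raise ValueError("skin offset must lie in [0, band depth)")
        if not self.scales_mm or any(s <= 0 for s in self.scales_mm):
            raise ValueError("scales must be a non-empty list of positive values")
        if self.min_component_voxels < 0:
            raise ValueError("min component size must be non-negative")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["scales_mm"] = tuple(d.get("scales_mm", vesselness.DEFAULT_SCALES_MM))
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    volume: ImageVolume,
    out_dir,
    model_landmarks: LandmarkSet | None = None,
    view_landmarks: LandmarkSet | None = None,
    camera: CameraModel | None = None,
    truth_marks: list | None = None,
    pixel_to_mm: float = 1.0,
) -> dict:
    """Run enhancement -> segmentation -> meshing -> labeling (-> registration).

    Registration, projection and the accuracy report run only when model
    and view landmarks plus a camera are supplied.  Returns the manifest
    dict; all artifacts live under ``out_dir``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}

    def _stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, *exc):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                log.info("stage %s: %.2fs", name, timings[name])
                return False

        return _T()

    with _stage("vesselness"):
        vmap = vesselness.multiscale_vesselness(
            volume, scales_mm=config.scales_mm, tau=config.tau,
            polarity=config.polarity,
        )
        p = out / "vesselness.nii.gz"
        write_nifti(
            ImageVolume(vmap.response.astype(np.float32), volume.spacing,
                        volume.origin, volume.axis_orientation), p)
        artifacts["vesselness"] = p.name

    with _stage("segment"):
        vessel_mask = segmentation.threshold_segment(vmap, config.threshold)
        band = segmentation.subcutaneous_band_mask(
            volume, config.band_depth_mm, config.skin_offset_mm
        )
        mask = segmentation.separate_superficial(
            vessel_mask, band, config.min_component_voxels
        )
        p = out / "mask.nii.gz"
        write_nifti(
            ImageVolume(mask.data.astype(np.uint8), volume.spacing,
                        volume.origin, volume.axis_orientation), p)
        artifacts["mask"] = p.name

    with _stage("mesh"):
        mesh = segmentation.marching_cubes_mesh(mask)
        p = out / "arteries.stl"
        write_stl(mesh, p)
        artifacts["stl"] = p.name

    with _stage("centerlines"):
        centerlines = segmentation.skeletonize_centerlines(
            mask, min_branch_mm=config.min_branch_mm
        )
        if model_landmarks is not None:
            atlas = build_region_atlas(model_landmarks)
            centerlines = label_centerlines(centerlines, atlas)
        p = out / "centerlines.json"
        with open(p, "w") as fh:
            json.dump(
                [
                    {"label": c.label, "points_mm": c.points.tolist()}
                    for c in centerlines
                ],
                fh,
            )
        artifacts["centerlines"] = p.name

    report: dict = {
        "mask_voxels": mask.count,
        "n_centerlines": len(centerlines),
        "mesh_faces": mesh.n_faces,
    }
    if model_landmarks is not None and view_landmarks is not None and camera:
        with _stage("register"):
            reg = register_model_to_view(
                model_landmarks, view_landmarks, camera, centerlines
            )
            p = out / "overlay.json"
            with open(p, "w") as fh:
                json.dump(
                    {
                        "mean_reprojection_error_px": reg[
                            "mean_reprojection_error_px"
                        ],
                        "curves": [
                            {"label": lab, "points_px": pts.tolist()}
                            for lab, pts in reg["projected_curves"]
                        ],
                    },
                    fh,
                )
            artifacts["overlay"] = p.name
            report["mean_reprojection_error_px"] = reg[
                "mean_reprojection_error_px"
            ]
        if truth_marks:
            with _stage("accuracy"):
                records = evaluate_projection_accuracy(
                    reg["projected_curves"], truth_marks, pixel_to_mm
                )
                summary = group_statistics(records)
                report["overall_mean_deviation_mm"] = summary.overall_mean_mm
                report["n_scored_arteries"] = summary.n_records

    p = out / "report.json"
    with open(p, "w") as fh:
        json.dump(report, fh, indent=2)
    artifacts["report"] = p.name

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "artifacts": {k: {"file": v, "sha256": _sha256(out / v)}
                      for k, v in artifacts.items()},
        "timings_s": timings,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
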