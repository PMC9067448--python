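"""Projection-accuracy statistics for the AR artery overlay.

The accuracy of the AR projection is summarized by per-artery millimetre
deviations between the projected artery position and the duplex-ultrasound
ground truth, recorded per patient for the 18 artery/side combinations.
This module loads such deviation tables, computes grouped statistics
(per-side and bilateral mean / max / min / sample SD), visualization-rate
tables, and the braces-excluded sensitivity recomputation for the labial
arteries, and scores synthetic end-to-end runs the same way.

Aggregation convention: the overall mean is the unweighted mean of the 18
per-side group means and the overall SD the unweighted mean of the 18 group
sample SDs (not a pooled per-record statistic); sample SDs use the n-1
denominator and groups of size <= 1 report SD 0.  Printed values are
rounded half-up (two decimals for mm, one for percentages).
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .anatomy_labeling import ARTERIES, SIDES, ArteryLabel

#: Em dash, en dash, hyphen — all read as "artery not visualized".
_MISSING_TOKENS = {"", "—", "–", "-"}


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding (0.625 -> 0.63), as printed tables use."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DeviationRecord:
    """Deviation of one artery in one patient; ``None`` = not visualized."""

    patient_id: int
    label: ArteryLabel
    deviation_mm: float | None

    def __post_init__(self) -> None:
        if self.deviation_mm is not None and self.deviation_mm < 0:
            raise ValueError("deviation must be non-negative")

    @property
    def visualized(self) -> bool:
        return self.deviation_mm is not None


@dataclass
class GroupStats:
    n_visualized: int
    mean_mm: float
    max_mm: float
    min_mm: float
    sd_mm: float


@dataclass
class AccuracySummary:
    """Grouped deviation statistics (per side, bilateral, and overall)."""

    per_side: dict[ArteryLabel, GroupStats]
    bilateral: dict[str, GroupStats]
    overall_mean_mm: float
    overall_sd_mm: float
    global_max_mm: float
    n_records: int

    def to_frame(self) -> pd.DataFrame:
        """Rows mean/max/min/SD x columns per-side then bilateral groups."""
        cols = {}
        for lab, g in self.per_side.items():
            cols[str(lab)] = [g.n_visualized, round_half_up(g.mean_mm, 2),
                              g.max_mm, g.min_mm, round_half_up(g.sd_mm, 2)]
        for artery, g in self.bilateral.items():
            cols[f"{artery}-bilateral"] = [
                g.n_visualized, round_half_up(g.mean_mm, 2),
                g.max_mm, g.min_mm, round_half_up(g.sd_mm, 2),
            ]
        cols["overall"] = [
            self.n_records, round_half_up(self.overall_mean_mm, 2),
            self.global_max_mm, 0.0, round_half_up(self.overall_sd_mm, 2),
        ]
        return pd.DataFrame(
            cols, index=["n", "mean_mm", "max_mm", "min_mm", "sd_mm"]
        )


def packaged_table_path():
    """Path-like handle to the packaged per-patient deviation fixture."""
    return resources.files("arterymap.data").joinpath("table2_deviations.csv")


def load_deviation_table(path: str | os.PathLike | None = None) -> list[DeviationRecord]:
    """Read a wide per-patient deviation CSV into records.

    The CSV has one row per patient and 18 artery columns
    (``left_Fa .. right_ST``).  Cells hold a non-negative number (mm), a
    dash (em, en or ASCII), or nothing; dashes and blanks both mean the
    artery was not visualized.  With no path the packaged study fixture is
    loaded.
    """
    if path is None:
        source = packaged_table_path().open()
    else:
        source = open(path)
    records: list[DeviationRecord] = []
    with source as fh:
        reader = csv.DictReader(fh)
        expected = [f"{s}_{a}" for s in SIDES for a in ARTERIES]
        missing = [c for c in expected if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"deviation table lacks columns: {missing}")
        for row_no, row in enumerate(reader, start=2):
            patient = int(row["patient"])
            for col in expected:
                side, artery = col.split("_")
                cell = (row[col] or "").strip()
                if cell in _MISSING_TOKENS:
                    dev = None
                else:
                    try:
                        dev = float(cell)
                    except ValueError:
                        raise ValueError(
                            f"malformed cell {cell!r} at row {row_no}, "
                            f"column {col!r}"
                        ) from None
                records.append(
                    DeviationRecord(
                        patient_id=patient,
                        label=ArteryLabel(artery, side),
                        deviation_mm=dev,
                    )
                )
    return records


def _stats(values: np.ndarray) -> GroupStats:
    n = len(values)
    if n == 0:
        return GroupStats(0, float("nan"), float("nan"), float("nan"), 0.0)
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return GroupStats(
        n_visualized=n,
        mean_mm=float(values.mean()),
        max_mm=float(values.max()),
        min_mm=float(values.min()),
        sd_mm=sd,
    )


def group_statistics(records: list[DeviationRecord]) -> AccuracySummary:
    """Per-group deviation statistics over visualized records.

    Groups are the 18 artery/side combinations plus the 9 bilateral
    arteries.  The overall mean (SD) is the unweighted mean of the non-empty
    per-side group means (sample SDs); the global maximum is taken over all
    visualized records.
    """
    if not records:
        raise ValueError("cannot summarize an empty record list")
    per_side: dict[ArteryLabel, GroupStats] = {}
    means, sds = [], []
    all_vals = []
    for artery in ARTERIES:
        for side in SIDES:
            lab = ArteryLabel(artery, side)
            vals = np.array(
                [r.deviation_mm for r in records
                 if r.label == lab and r.visualized]
            )
            g = _stats(vals)
            per_side[lab] = g
            if g.n_visualized:
                means.append(g.mean_mm)
                sds.append(g.sd_mm)
                all_vals.append(vals)
    bilateral = {
        artery: _stats(
            np.array(
                [r.deviation_mm for r in records
                 if r.label.artery == artery and r.visualized]
            )
        )
        for artery in ARTERIES
    }
    flat = np.concatenate(all_vals) if all_vals else np.array([])
    return AccuracySummary(
        per_side=per_side,
        bilateral=bilateral,
        overall_mean_mm=float(np.mean(means)) if means else float("nan"),
        overall_sd_mm=float(np.mean(sds)) if sds else float("nan"),
        global_max_mm=float(flat.max()) if flat.size else float("nan"),
        n_records=int(flat.size),
    )


def visualization_percentages(records: list[DeviationRecord]) -> pd.DataFrame:
    """Table-1-style visualization counts and bilateral percentages.

    One row per artery with left / right / total counts and the percentage
    of 2 * n_subjects (one decimal, half-up), plus a totals row.
    """
    n_subjects = len({r.patient_id for r in records})
    rows = []
    for artery in ARTERIES:
        left = sum(
            1 for r in records
            if r.label == ArteryLabel(artery, "left") and r.visualized
        )
        right = sum(
            1 for r in records
            if r.label == ArteryLabel(artery, "right") and r.visualized
        )
        total = left + right
        rows.append(
            {
                "artery": artery,
                "left": left,
                "right": right,
                "total": total,
                "percentage": round_half_up(100.0 * total / (2 * n_subjects), 1),
            }
        )
    totals = {
        "artery": "Total",
        "left": sum(r["left"] for r in rows),
        "right": sum(r["right"] for r in rows),
        "total": sum(r["total"] for r in rows),
        "percentage": round_half_up(
            100.0 * sum(r["total"] for r in rows) / (18 * n_subjects), 1
        ),
    }
    return pd.DataFrame(rows + [totals])


def recompute_excluding_braces(
    records: list[DeviationRecord], excluded_patient_count: int
) -> dict[str, float]:
    """Labial-artery sensitivity with brace-artifact patients excluded.

    Dental braces produce metal artifacts that wipe out the labial arteries
    on MRA.  Excluding those patients shrinks the denominator to
    ``2 * (n_subjects - excluded)`` while the visualized IL/SL counts are
    unchanged (the affected labial arteries are assumed to belong to the
    brace wearers).  Returns one-decimal percentages for ``IL`` and ``SL``.
    """
    n_subjects = len({r.patient_id for r in records})
    if not 0 <= excluded_patient_count < n_subjects:
        raise ValueError(
            f"excluded count {excluded_patient_count} must lie in "
            f"[0, {n_subjects})"
        )
    denom = 2 * (n_subjects - excluded_patient_count)
    if denom <= 0:
        raise ValueError("exclusion leaves an empty denominator")
    out = {}
    for artery in ("IL", "SL"):
        count = sum(
            1 for r in records if r.label.artery == artery and r.visualized
        )
        out[artery] = round_half_up(100.0 * count / denom, 1)
    return out


def evaluate_projection_accuracy(
    projected_curves: list[tuple[str, np.ndarray]],
    truth_marks: list[tuple[str, np.ndarray]],
    pixel_to_mm: float = 1.0,
    patient_id: int = 0,
) -> list[DeviationRecord]:
    """Score projected artery curves against labeled ground-truth marks.

    For each truth mark (``"<artery>-<side>"`` label + a 2-D or 3-D point)
    the deviation is the distance to the nearest point of the same-labeled
    projected curve — nearest-point distance to the polyline's segments —
    scaled by ``pixel_to_mm``.  Marks whose artery has no projected curve
    yield a not-visualized record.
    """
    if pixel_to_mm <= 0:
        raise ValueError(f"pixel_to_mm must be positive, got {pixel_to_mm}")
    if not truth_marks:
        raise ValueError("need at least one truth mark")
    curves: dict[str, list[np.ndarray]] = {}
    for label, pts in projected_curves:
        curves.setdefault(label, []).append(np.atleast_2d(np.asarray(pts, float)))
    records = []
    for label, point in truth_marks:
        artery, side = label.split("-")
        lab = ArteryLabel(artery, side)
        if label not in curves:
            records.append(DeviationRecord(patient_id, lab, None))
            continue
        point = np.asarray(point, float)
        d = min(_point_polyline_distance(point, c) for c in curves[label])
        records.append(DeviationRecord(patient_id, lab, d * pixel_to_mm))
    return records


def _point_polyline_distance(point: np.ndarray, poly: np.ndarray) -> float:
    """Euclidean distance from a point to a polyline's segments."""
    if len(poly) == 1:
        return float(np.linalg.norm(point - poly[0]))
    a, b = poly[:-1], poly[1:]
    ab = b - a
    denom = (ab**2).sum(axis=1)
    denom[denom == 0] = 1.0
    t = np.clip(((point - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.linalg.norm(proj - point, axis=1).min())
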