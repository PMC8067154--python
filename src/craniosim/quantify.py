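"""Volumetric quantification of the reconstructed skull models.

Computes, per stack: the skull-defect area (the defect margin projected
onto the sagittal plane through the defect's maximal extent), the
enclosed model volume at each contour elevation of the clinical
schedule, the volume-increasing rate relative to the regular (0 mm)
model and the defect-area group (<125 / 125–150 / ≥150 cm²).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contours import (
    ElevationSchedule,
    SliceContour,
    elevate_contour,
    extract_outline,
    mirror_fill,
    schedule_default,
)
from .mesh import SkullMesh, build_mesh, open_edges
from .phantom import SliceStack

__all__ = [
    "QuantResult",
    "defect_area",
    "enclosed_volume",
    "volume_increasing_rate",
    "assign_group",
    "run_pipeline",
]

GROUP_BOUNDS_CM2 = (125.0, 150.0)


@dataclass
class QuantResult:
    """Pipeline output for one slice stack."""

    defect_area_cm2: float
    volumes_cm3: dict[float, float]  # elevation mm -> enclosed volume
    rates_pct: dict[float, float]  # elevation mm -> volume-increasing rate
    group: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "defect_area_cm2": self.defect_area_cm2,
                    "volumes_cm3": {str(k): v for k, v in self.volumes_cm3.items()},
                    "rates_pct": {str(k): v for k, v in self.rates_pct.items()},
                    "group": self.group,
                },
                indent=1,
            )
        )
        return path

    def to_table(self) -> pd.DataFrame:
        """One row per elevation: volume and volume-increasing rate."""
        ks = sorted(self.volumes_cm3)
        return pd.DataFrame(
            {
                "elevation_mm": ks,
                "volume_cm3": [self.volumes_cm3[k] for k in ks],
                "rate_pct": [self.rates_pct[k] for k in ks],
            }
        )


def defect_area(contours: Sequence[SliceContour], slab_halfwidth: float = 0.0) -> float:
    """Skull-defect area (cm²) by sagittal projection of the margin.

    Each defective slice contributes its defect endpoints D, D′; the
    margin polygon is formed in the (anteroposterior, craniocaudal) =
    (y, z) plane — the projection onto the sagittal plane through the
    defect's maximal extent — and measured with the shoelace formula.
    ``slab_halfwidth`` (mm, typically half the slice thickness) extends
    the polygon past the first and last defective slice centre, since
    each slice stands for a full slab of removed bone.
    """
    upper: list[tuple[float, float]] = []
    lower: list[tuple[float, float]] = []
    for c in contours:
        if c.defect_endpoints is None:
            continue
        y1, y2 = c.defect_endpoints[0][1], c.defect_endpoints[1][1]
        upper.append((max(y1, y2), c.z))
        lower.append((min(y1, y2), c.z))
    if upper and slab_halfwidth > 0.0:
        upper = [(upper[0][0], upper[0][1] - slab_halfwidth), *upper,
                 (upper[-1][0], upper[-1][1] + slab_halfwidth)]
        lower = [(lower[0][0], lower[0][1] - slab_halfwidth), *lower,
                 (lower[-1][0], lower[-1][1] + slab_halfwidth)]
    pts = upper + lower[::-1]
    if len(pts) < 3:
        raise ValueError("fewer than 3 defect-margin points")
    arr = np.asarray(pts, dtype=float)
    y, z = arr[:, 0], arr[:, 1]
    area_mm2 = 0.5 * abs(float(np.sum(y * np.roll(z, -1) - np.roll(y, -1) * z)))
    return area_mm2 / 100.0


def enclosed_volume(mesh: SkullMesh) -> float:
    """Enclosed volume (cm³) of a watertight mesh by signed tetrahedra."""
    bad = open_edges(mesh.faces)
    if len(bad):
        shown = ", ".join(f"{a}-{b}" for a, b in bad[:5])
        raise ValueError(f"mesh is not watertight; open edges: {shown}"
                         + (" …" if len(bad) > 5 else ""))
    return abs(mesh.signed_volume()) / 1000.0


def volume_increasing_rate(volumes: Mapping[float, float]) -> dict[float, float]:
    """Percent volume gain over the 0 mm (regular) model per elevation."""
    if 0.0 not in volumes:
        raise ValueError("volumes must contain the 0 mm baseline")
    v0 = volumes[0.0]
    if v0 <= 0:
        raise ValueError(f"baseline volume must be positive, got {v0}")
    return {k: (v - v0) / v0 * 100.0 for k, v in volumes.items()}


def assign_group(area_cm2: float) -> int:
    """Defect-area group: 1 (<125), 2 (125 ≤ area < 150), 3 (≥150 cm²)."""
    if area_cm2 < 0:
        raise ValueError(f"area must be non-negative, got {area_cm2}")
    if area_cm2 < GROUP_BOUNDS_CM2[0]:
        return 1
    if area_cm2 < GROUP_BOUNDS_CM2[1]:
        return 2
    return 3


def run_pipeline(
    stack: SliceStack,
    schedule: ElevationSchedule | None = None,
    boundary: str = "outer",
    n_points: int | None = 256,
) -> QuantResult:
    """Full stack quantification.

    Extracts per-slice outlines, mirror-fills the defective slices,
    elevates the filled contours over the schedule, stitches each
    elevation into a watertight mesh and measures its volume.  The 0 mm
    baseline uses the same arc construction (k = 0 passes through the
    regular contour at the chord bisector) so rates are exactly 0 at 0.

    ``boundary`` picks which bone surface bounds the enclosed volume:
    "outer" (whole model, shell included — the default whole-minus-bone
    bookkeeping) or "inner" (brain cavity plus reconstructed bulge).
    """
    if schedule is None:
        schedule = schedule_default()
    sp = stack.pixel_spacing
    w = stack.images.shape[2]
    axis_x = (stack.symmetry_axis_col - (w - 1) / 2.0) * sp

    base: list[SliceContour] = []
    defective: dict[int, SliceContour] = {}
    for i in range(stack.n_slices):
        c = extract_outline(
            stack.images[i], sp, axis_x=axis_x, z=stack.z(i), boundary=boundary
        )
        if not c.closed:
            filled = mirror_fill(c)
            defective[len(base)] = filled
            base.append(filled)
        else:
            base.append(c)
    if not defective:
        raise ValueError("stack has no defective slices to quantify")

    area = defect_area(
        [base[i] for i in sorted(defective)],
        slab_halfwidth=stack.slice_thickness / 2.0,
    )

    volumes: dict[float, float] = {}
    for k in schedule:
        layers = list(base)
        for i, filled in defective.items():
            layers[i] = elevate_contour(filled, float(k))
        mesh = build_mesh(layers, n_points=n_points)
        volumes[float(k)] = enclosed_volume(mesh)

    rates = volume_increasing_rate(volumes)
    return QuantResult(
        defect_area_cm2=area,
        volumes_cm3=volumes,
        rates_pct=rates,
        group=assign_group(area),
    )
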