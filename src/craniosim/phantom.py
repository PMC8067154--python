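"""Synthetic CT-like skull phantoms.

Generates stacks of binary bone-mask slices that emulate the bone-window
CT series the reconstruction pipeline operates on: elliptical skull
annuli on a 512×512 grid (30 cm field of view, ≈0.586 mm/pixel), 1.25 mm
slice thickness, stacked inferior → superior, with an optional
unilateral craniectomy defect cut out of one lateral half as an angular
arc.  Masks are binary (bone = 1); no Hounsfield/soft-tissue simulation.

Coordinate convention: pixel centres at integer (row, col); the physical
origin is the image centre, x grows with column (subject left–right),
y grows upward (anterior); the midline symmetry axis is the vertical
line x = 0, i.e. the (sub-pixel) central column.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "DefectSpec",
    "PhantomSpec",
    "SliceStack",
    "generate_slice",
    "generate_stack",
    "write_stack",
    "read_stack",
    "ellipsoid_profile",
    "ellipsoid_phantom",
    "preset",
    "PRESETS",
    "outer_radius_at_angle",
    "defect_endpoints_analytic",
    "projected_defect_area_analytic",
]


@dataclass(frozen=True)
class DefectSpec:
    """Unilateral craniectomy defect: an angular arc removed from the annulus.

    ``arc_fn(index)`` returns the removed arc ``(start_deg, end_deg)`` in
    polar degrees about the slice centre (0° = +x = subject's right,
    counter-clockwise), or None for no defect on that slice.
    ``slice_range`` is the half-open [first, last) affected index range.
    The arc must stay strictly within one lateral half: within
    (−90°, 90°) for side "right", within (90°, 270°) for side "left".
    """

    side: str = "right"
    arc_fn: Callable[[int], tuple[float, float] | None] = lambda i: None
    slice_range: tuple[int, int] = (0, 0)

    def arc_at(self, index: int) -> tuple[float, float] | None:
        lo, hi = self.slice_range
        if not lo <= index < hi:
            return None
        arc = self.arc_fn(index)
        if arc is None:
            return None
        start, end = arc
        if end == start:  # zero angular extent removes nothing
            return None
        if end < start:
            raise ValueError(f"defect arc must have end >= start, got {arc}")
        if self.side == "right":
            if not (-90.0 < start and end < 90.0):
                raise ValueError(f"right-side arc must lie in (-90, 90), got {arc}")
        elif self.side == "left":
            if not (90.0 < start and end < 270.0):
                raise ValueError(f"left-side arc must lie in (90, 270), got {arc}")
        else:
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        return start, end


def _no_defect() -> DefectSpec:
    return DefectSpec(side="right", arc_fn=lambda i: None, slice_range=(0, 0))


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic skull slice stack.

    ``semi_axes_fn(index)`` gives the per-slice outer-ellipse semi-axes
    (a_lat, b_ap) in mm — e.g. an ellipsoidal taper toward the vertex.
    ``bone_thickness`` is the annulus thickness in mm.  ``jitter_mm``
    adds seed-deterministic Gaussian noise to the per-slice semi-axes
    (off by default).
    """

    n_slices: int
    semi_axes_fn: Callable[[int], tuple[float, float]]
    grid: tuple[int, int] = (512, 512)
    pixel_spacing: float = 300.0 / 512.0
    slice_thickness: float = 1.25
    bone_thickness: float = 5.0
    defect: DefectSpec = field(default_factory=_no_defect)
    seed: int = 0
    jitter_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("spacing and thickness must be positive")
        if self.bone_thickness <= 0:
            raise ValueError("bone_thickness must be positive")

    def semi_axes(self, index: int) -> tuple[float, float]:
        a, b = self.semi_axes_fn(index)
        if self.jitter_mm > 0.0:
            rng = np.random.default_rng([self.seed, index])
            a += float(rng.normal(0.0, self.jitter_mm))
            b += float(rng.normal(0.0, self.jitter_mm))
        return a, b


@dataclass
class SliceStack:
    """Ordered binary bone masks with physical metadata.

    ``images``: (n, H, W) uint8 array (bone = 1), inferior → superior,
    slice i at physical z = i · slice_thickness.  ``symmetry_axis_col``
    is the (sub-pixel) image column of the midline.  ``defect_arcs``
    records the removed arc per slice (or None), as generated.
    """

    images: np.ndarray
    pixel_spacing: float
    slice_thickness: float
    symmetry_axis_col: float
    defect_arcs: list[tuple[float, float] | None]

    def __post_init__(self) -> None:
        if self.images.ndim != 3:
            raise ValueError("images must be a (n, H, W) array")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("spacing must be positive")
        if not 0 <= self.symmetry_axis_col <= self.images.shape[2] - 1:
            raise ValueError("symmetry axis outside the image")

    @property
    def n_slices(self) -> int:
        return self.images.shape[0]

    def z(self, index: int) -> float:
        return index * self.slice_thickness


def _physical_grid(shape: tuple[int, int], spacing: float):
    h, w = shape
    rows, cols = np.ogrid[0:h, 0:w]
    x = (cols - (w - 1) / 2.0) * spacing
    y = ((h - 1) / 2.0 - rows) * spacing
    return x, y


def generate_slice(spec: PhantomSpec, index: int) -> np.ndarray:
    """Rasterise one bone-annulus slice (uint8, bone = 1)."""
    if not 0 <= index < spec.n_slices:
        raise ValueError(f"slice index {index} outside stack of {spec.n_slices}")
    a, b = spec.semi_axes(index)
    if a <= 0 or b <= 0:
        raise ValueError(f"degenerate semi-axes (a={a}, b={b}) on slice {index}")
    x, y = _physical_grid(spec.grid, spec.pixel_spacing)
    outer = (x / a) ** 2 + (y / b) ** 2 <= 1.0
    ai, bi = a - spec.bone_thickness, b - spec.bone_thickness
    if ai > 0 and bi > 0:
        inner = (x / ai) ** 2 + (y / bi) ** 2 <= 1.0
    else:  # solid cap near the vertex
        inner = np.zeros_like(outer)
    bone = outer & ~inner

    arc = spec.defect.arc_at(index)
    if arc is not None:
        theta = np.degrees(np.arctan2(y, x))  # (-180, 180]
        start, end = arc
        in_arc = ((theta - start) % 360.0) < (end - start)
        bone &= ~in_arc
    return bone.astype(np.uint8)


def generate_stack(spec: PhantomSpec) -> SliceStack:
    """Rasterise the whole stack; deterministic for a fixed seed."""
    images = np.stack([generate_slice(spec, i) for i in range(spec.n_slices)])
    arcs = [spec.defect.arc_at(i) for i in range(spec.n_slices)]
    return SliceStack(
        images=images,
        pixel_spacing=spec.pixel_spacing,
        slice_thickness=spec.slice_thickness,
        symmetry_axis_col=(spec.grid[1] - 1) / 2.0,
        defect_arcs=arcs,
    )


# ---------------------------------------------------------------------------
# stack I/O: one PNG per slice + a JSON metadata sidecar

def write_stack(stack: SliceStack, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i in range(stack.n_slices):
        Image.fromarray(stack.images[i] * 255).save(out / f"slice_{i:04d}.png")
    meta = {
        "n_slices": stack.n_slices,
        "grid": list(stack.images.shape[1:]),
        "spacing_mm": stack.pixel_spacing,
        "slice_thickness_mm": stack.slice_thickness,
        "symmetry_axis_col": stack.symmetry_axis_col,
        "defect_arcs": [list(a) if a is not None else None for a in stack.defect_arcs],
    }
    (out / "stack.json").write_text(json.dumps(meta, indent=1))
    return out


def read_stack(in_dir: str | Path) -> SliceStack:
    src = Path(in_dir)
    meta = json.loads((src / "stack.json").read_text())
    images = np.stack(
        [
            (np.asarray(Image.open(src / f"slice_{i:04d}.png")) > 0).astype(np.uint8)
            for i in range(meta["n_slices"])
        ]
    )
    arcs = [tuple(a) if a is not None else None for a in meta["defect_arcs"]]
    return SliceStack(
        images=images,
        pixel_spacing=meta["spacing_mm"],
        slice_thickness=meta["slice_thickness_mm"],
        symmetry_axis_col=meta["symmetry_axis_col"],
        defect_arcs=arcs,
    )


# ---------------------------------------------------------------------------
# ellipsoidal skull profile and presets

def ellipsoid_profile(
    a: float, b: float, c: float, slice_thickness: float
) -> tuple[int, Callable[[int], tuple[float, float]], Callable[[int], float]]:
    """Per-slice semi-axes of an ellipsoid sampled at slice mid-planes.

    Slice i sits at height z_i = (i + 0.5)·t − c above the ellipsoid
    base, so all slices cut the ellipsoid strictly between its poles.
    Returns (n_slices, semi_axes_fn, scale_fn).
    """
    n = int(round(2.0 * c / slice_thickness))

    def scale(i: int) -> float:
        z = (i + 0.5) * slice_thickness - c
        return math.sqrt(max(1.0 - (z / c) ** 2, 0.0))

    def axes(i: int) -> tuple[float, float]:
        s = scale(i)
        return a * s, b * s

    return n, axes, scale


def ellipsoid_phantom(
    a: float = 65.0,
    b: float = 75.0,
    c: float = 85.0,
    defect: DefectSpec | None = None,
    **kwargs,
) -> PhantomSpec:
    """Ellipsoidal skull phantom (semi-axes lateral a, anteroposterior b,
    craniocaudal c, all mm) with an optional defect."""
    thickness = kwargs.pop("slice_thickness", 1.25)
    n, axes, _ = ellipsoid_profile(a, b, c, thickness)
    return PhantomSpec(
        n_slices=n,
        semi_axes_fn=axes,
        slice_thickness=thickness,
        defect=defect if defect is not None else _no_defect(),
        **kwargs,
    )


def _z_to_index(z: float, c: float, thickness: float) -> int:
    return int(round((z + c) / thickness - 0.5))


def _symmetric_arc_defect(
    half_angle_deg: float, z_range: tuple[float, float], c: float, thickness: float
) -> DefectSpec:
    lo = _z_to_index(z_range[0], c, thickness)
    hi = _z_to_index(z_range[1], c, thickness)
    arc = (-half_angle_deg, half_angle_deg)
    return DefectSpec(side="right", arc_fn=lambda i: arc, slice_range=(lo, hi))


# Presets span the three defect-area groups (<125 / 125–150 / ≥150 cm²);
# arc extents and slice ranges were sized from the analytic projected-area
# formula (see projected_defect_area_analytic).
_PRESET_PARAMS = {
    "small-defect": dict(half_angle=60.0, z_range=(-25.0, 45.0)),   # ≈ 84 cm²
    "medium-defect": dict(half_angle=75.0, z_range=(-45.0, 58.0)),  # ≈ 137 cm²
    "large-defect": dict(half_angle=82.0, z_range=(-55.0, 65.0)),   # ≈ 161 cm²
}
PRESETS = tuple(_PRESET_PARAMS) + ("intact",)


def preset(name: str, a: float = 65.0, b: float = 75.0, c: float = 85.0, **kwargs) -> PhantomSpec:
    """Named phantom presets: 'intact' plus one per defect-area group."""
    if name == "intact":
        return ellipsoid_phantom(a, b, c, defect=None, **kwargs)
    try:
        p = _PRESET_PARAMS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}") from None
    thickness = kwargs.get("slice_thickness", 1.25)
    defect = _symmetric_arc_defect(p["half_angle"], p["z_range"], c, thickness)
    return ellipsoid_phantom(a, b, c, defect=defect, **kwargs)


# ---------------------------------------------------------------------------
# analytic ground-truth helpers (oracles for the pipeline tests)

def outer_radius_at_angle(a: float, b: float, theta_deg: float) -> float:
    """Radius of the ellipse x²/a² + y²/b² = 1 at polar angle theta."""
    th = math.radians(theta_deg)
    return a * b / math.hypot(b * math.cos(th), a * math.sin(th))


def defect_endpoints_analytic(
    spec: PhantomSpec, index: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """Exact (x, y) positions of the defect arc ends on the outer ellipse."""
    arc = spec.defect.arc_at(index)
    if arc is None:
        return None
    a, b = spec.semi_axes(index)
    pts = []
    for ang in arc:
        r = outer_radius_at_angle(a, b, ang)
        th = math.radians(ang)
        pts.append(np.array([r * math.cos(th), r * math.sin(th)]))
    return pts[0], pts[1]


def projected_defect_area_analytic(spec: PhantomSpec) -> float:
    """Sagittal-projection area of the defect margin, cm² (midpoint rule
    over slices, i.e. the same discretisation the stack itself has)."""
    total = 0.0
    for i in range(spec.n_slices):
        ends = defect_endpoints_analytic(spec, i)
        if ends is None:
            continue
        total += abs(ends[0][1] - ends[1][1]) * spec.slice_thickness
    return total / 100.0
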