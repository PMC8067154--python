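"""Elliptical skull model of decompressive craniectomy (DC).

The axial skull cross-section is idealised as the ellipse
``x²/a² + y²/b² = 1`` (all lengths in mm).  A craniectomy of extent
*d* (the "tangential diameter") is the chord perpendicular to the
x-axis at distance ``h`` from the centre, ``d = 2b·sqrt(1 − h²/a²)``.
After surgery the scalp/brain bulges outward by an elevation height
``k``; the bulged contour is modelled as the half-ellipse centred on
the chord midpoint with semi-axes ``a_h = a + k − h`` (along x) and
``b_h = b·sqrt(1 − h²/a²)`` (along y, equal to half the chord).

The newly gained cross-sectional area is

    ΔA = ∫_a^{a+k} y_h dx  +  ∫_h^a (y_h − y) dx          (first quadrant)

evaluated, exactly as in the original computerised analysis, with the
rectangle (Riemann-sum) method: left endpoints on the first integral,
right endpoints on the second.  The overall newly increased area is
``2·ΔA`` (the model is symmetric about the x-axis) and the
volume-increasing rate is ΔA divided by twice the left-endpoint
rectangle approximation of the half-ellipse area, in percent.

A closed-form ellipse-segment expression is provided as an
independent cross-check of the rectangle sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EllipseSpec",
    "TangentSection",
    "AreaResult",
    "SweepResult",
    "ScalpFormulaInput",
    "tangent_diameter",
    "elevated_half_contour",
    "delta_area_rectangle",
    "delta_area_closed_form",
    "sweep_tangent_diameters",
    "find_plateau",
    "ellipse_perimeter_approx",
    "scalp_elevation_K",
]


@dataclass(frozen=True)
class EllipseSpec:
    """Semi-axes of the idealised axial skull section.

    ``a`` lies along the defect axis (lateral, x), ``b`` along the
    chord/tangent direction (anteroposterior, y).  Defaults are the
    general adult skull size used throughout the model analysis.
    """

    a: float = 65.0
    b: float = 75.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"semi-axes must be positive, got a={self.a}, b={self.b}")

    def y(self, x: np.ndarray | float) -> np.ndarray | float:
        """Upper-half ordinate of the skull ellipse, b·sqrt(1 − x²/a²)."""
        return self.b * np.sqrt(np.clip(1.0 - np.square(x) / self.a**2, 0.0, None))


@dataclass(frozen=True)
class TangentSection:
    """Geometry of one craniectomy chord plus its elevated contour.

    h    distance from ellipse centre to the chord (mm)
    k    contour elevation height (mm)
    a_h  semi-axis of the bulge ellipse along x: a + k − h
    b_h  semi-axis along y: b·sqrt(1 − h²/a²) (half the chord)
    d    tangential diameter, 2·b_h
    """

    h: float
    k: float
    a_h: float
    b_h: float
    d: float

    @classmethod
    def from_geometry(cls, h: float, k: float, e: EllipseSpec) -> "TangentSection":
        if not 0.0 <= h <= e.a:
            raise ValueError(f"h must lie in [0, a]=[0, {e.a}], got {h}")
        if k < 0:
            raise ValueError(f"elevation k must be >= 0, got {k}")
        b_h = e.b * math.sqrt(1.0 - (h / e.a) ** 2)
        return cls(h=h, k=k, a_h=e.a + k - h, b_h=b_h, d=2.0 * b_h)


@dataclass(frozen=True)
class AreaResult:
    """Area gain of one elevated section.

    delta_A   first-quadrant area increase (mm²)
    new_area  doubled, overall newly increased area = 2·delta_A (mm²)
    rate      volume-increasing rate (% of the original total area)
    """

    delta_A: float
    new_area: float
    rate: float


@dataclass
class SweepResult:
    """Sweep of the area gain over tangential diameters at fixed elevation."""

    rows: pd.DataFrame  # columns h_mm, d_mm, new_area_mm2, rate_pct, ordered by h
    k: float
    n_grid: int
    n_rect: int


@dataclass(frozen=True)
class ScalpFormulaInput:
    """Inputs of the closed-form maximal scalp-elevation height K.

    Note the semi-axis roles here follow the scalp-arc construction:
    ``a_ap`` is the anteroposterior semi-axis (major), ``b_lat`` the
    lateral one (minor) — the reverse of :class:`EllipseSpec`.  ``X``
    is the arc length of the defect margin; ``extension`` the maximal
    extra arc length the scalp can yield (4.1 mm per the largest
    closable scalp-wound width of 41 mm, on the model's 1/10 scale
    usage).  ``pi_const`` lets the worked-example value π = 3.14 be
    reproduced exactly.
    """

    a_ap: float = 75.0
    b_lat: float = 65.0
    X: float = 224.1
    extension: float = 4.1
    pi_const: float = math.pi

    def __post_init__(self) -> None:
        if self.X <= 0:
            raise ValueError(f"arc length X must be positive, got {self.X}")
        if min(self.a_ap, self.b_lat, self.extension) <= 0:
            raise ValueError("all lengths must be positive")


def tangent_diameter(h: float, e: EllipseSpec) -> float:
    """Chord length d = 2b·sqrt(1 − h²/a²) of the craniectomy at offset h."""
    if not 0.0 <= h <= e.a:
        raise ValueError(f"h must lie in [0, a]=[0, {e.a}], got {h}")
    return 2.0 * e.b * math.sqrt(1.0 - (h / e.a) ** 2)


def elevated_half_contour(
    x: np.ndarray | float, t: TangentSection, e: EllipseSpec
) -> np.ndarray | float:
    """Ordinate y_h = b_h·sqrt(1 − (x − h)²/a_h²) of the elevated contour.

    Defined on [h, a + k]; the contour is the upper half of the bulge
    ellipse centred on the chord midpoint.
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa < t.h - 1e-12) or np.any(xa > t.h + t.a_h + 1e-12):
        raise ValueError(f"x must lie in [h, a+k]=[{t.h}, {t.h + t.a_h}]")
    val = t.b_h * np.sqrt(np.clip(1.0 - np.square(xa - t.h) / t.a_h**2, 0.0, None))
    return float(val) if np.isscalar(x) else val


def _y_h(x: np.ndarray, t: TangentSection) -> np.ndarray:
    return t.b_h * np.sqrt(np.clip(1.0 - np.square(x - t.h) / t.a_h**2, 0.0, None))


def delta_area_rectangle(t: TangentSection, e: EllipseSpec, n: int = 2000) -> AreaResult:
    """Rectangle-rule area gain for one elevated section.

    First sum: left endpoints x_i = a + i·k/n, i = 0..n−1 over [a, a+k].
    Second sum: right endpoints x_i = h + i·(a−h)/n, i = 1..n over [h, a].
    Rate denominator: 2·Σ_{i=0}^{n−1} (a/n)·y(x_i) with x_i = i·a/n
    (left-endpoint approximation of twice the quarter-ellipse area).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    a, k, h = e.a, t.k, t.h
    i = np.arange(n, dtype=float)

    x1 = a + i * (k / n)
    s1 = (k / n) * float(np.sum(_y_h(x1, t)))

    x2 = h + (i + 1.0) * ((a - h) / n)
    s2 = ((a - h) / n) * float(np.sum(_y_h(x2, t) - e.y(x2)))

    delta_A = s1 + s2

    xd = i * (a / n)
    denom = 2.0 * (a / n) * float(np.sum(e.y(xd)))
    rate = delta_A / denom * 100.0
    return AreaResult(delta_A=delta_A, new_area=2.0 * delta_A, rate=rate)


def delta_area_closed_form(t: TangentSection, e: EllipseSpec) -> float:
    """Exact first-quadrant area gain via the ellipse-segment antiderivative.

    With F(u) = (u·sqrt(1−u²) + asin u)/2,
    ΔA = a_h·b_h·F(1) − a·b·[F(1) − F(h/a)]: quarter of the bulge
    ellipse minus the original ellipse segment between x = h and x = a.
    Serves as the independent oracle for the rectangle sums.
    """

    def F(u: float) -> float:
        return (u * math.sqrt(1.0 - u * u) + math.asin(u)) / 2.0

    return t.a_h * t.b_h * F(1.0) - e.a * e.b * (F(1.0) - F(t.h / e.a))


def sweep_tangent_diameters(
    k: float, e: EllipseSpec, n_grid: int = 500, n_rect: int = 2000
) -> SweepResult:
    """Evaluate the area gain over the default craniectomy-extent grid.

    h is swept over h_i = i·a/n_grid, i = 0..n_grid−1 (h = 0 included,
    the degenerate tangent h = a excluded); each row carries the
    tangential diameter d(h_i) and the rectangle-rule area/rate.
    """
    if k <= 0:
        raise ValueError(f"elevation k must be positive, got {k}")
    if n_grid < 2:
        raise ValueError(f"n_grid must be >= 2, got {n_grid}")
    hs = np.arange(n_grid, dtype=float) * (e.a / n_grid)
    recs = []
    for h in hs:
        t = TangentSection.from_geometry(float(h), k, e)
        r = delta_area_rectangle(t, e, n_rect)
        recs.append((float(h), t.d, r.new_area, r.rate))
    rows = pd.DataFrame(recs, columns=["h_mm", "d_mm", "new_area_mm2", "rate_pct"])
    return SweepResult(rows=rows, k=k, n_grid=n_grid, n_rect=n_rect)


def find_plateau(s: SweepResult) -> tuple[float, float, float]:
    """Row of maximal newly increased area: (d*, area*, rate*).

    Ties are broken toward the larger tangential diameter (the larger
    craniectomy, i.e. the smaller h).
    """
    if s.rows.empty:
        raise ValueError("sweep is empty")
    areas = s.rows["new_area_mm2"].to_numpy()
    best = int(np.flatnonzero(areas == areas.max())[0])  # smallest h -> largest d
    row = s.rows.iloc[best]
    return float(row["d_mm"]), float(row["new_area_mm2"]), float(row["rate_pct"])


def ellipse_perimeter_approx(
    a_major: float, b_minor: float, pi_const: float = math.pi
) -> float:
    """Approximate ellipse perimeter 2π·b + 4·(a − b), a ≥ b > 0."""
    if b_minor <= 0 or a_major < b_minor:
        raise ValueError(f"need a_major >= b_minor > 0, got {a_major}, {b_minor}")
    return 2.0 * pi_const * b_minor + 4.0 * (a_major - b_minor)


def scalp_elevation_K(inp: ScalpFormulaInput) -> float:
    """Closed-form maximal scalp-elevation height K (mm).

    Stretching the defect-margin arc X by the maximal scalp extension E
    scales the approximate perimeter 2πb + 4(a − b) onto that of the
    ellipse with minor semi-axis b + K:

        (X + E)/X = [2π(b + K) + 4(a − b − K)] / [2πb + 4(a − b)]

    which solves to K = (4E·a + (2πE − 4E)·b) / (X·(2π − 4)).  With
    E = 4.1 and π = 3.14 this is the familiar (16.4a + 9.348b)/(2.28X).
    """
    pi, E = inp.pi_const, inp.extension
    num = 4.0 * E * inp.a_ap + (2.0 * pi * E - 4.0 * E) * inp.b_lat
    return num / (inp.X * (2.0 * pi - 4.0))
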