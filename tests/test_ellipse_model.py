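"""Elliptical craniectomy model: diameters, area integrals, plateau, scalp K."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import craniosim as cs
from craniosim.ellipse_model import delta_area_closed_form


@pytest.mark.parametrize(
    "h, expected, tol",
    [
        (0.0, 150.0, 1e-12),        # chord through the centre is the full axis 2b
        (65.0, 0.0, 1e-12),         # tangent at the vertex
        (18.85, 143.55, 0.01),      # clinical plateau diameter at K = 10
    ],
)
def test_tangent_diameter(ellipse, h, expected, tol):
    assert cs.tangent_diameter(h, ellipse) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize("h", [-1.0, 65.1])
def test_tangent_diameter_domain(ellipse, h):
    with pytest.raises(ValueError):
        cs.tangent_diameter(h, ellipse)


def test_elevated_half_contour_endpoints_and_value(ellipse):
    t = cs.TangentSection.from_geometry(18.85, 10.0, ellipse)
    assert cs.elevated_half_contour(t.h, t, ellipse) == pytest.approx(t.b_h)
    assert cs.elevated_half_contour(65.0 + 10.0, t, ellipse) == pytest.approx(0.0)
    # direct evaluation of the bulge-ellipse ordinate at x = 40
    expected = t.b_h * math.sqrt(1.0 - ((40.0 - 18.85) / (65.0 + 10.0 - 18.85)) ** 2)
    assert cs.elevated_half_contour(40.0, t, ellipse) == pytest.approx(expected)
    with pytest.raises(ValueError):
        cs.elevated_half_contour(t.h - 1.0, t, ellipse)
    with pytest.raises(ValueError):
        cs.elevated_half_contour(75.1, t, ellipse)


def test_tangent_section_invariants(ellipse):
    t = cs.TangentSection.from_geometry(18.85, 10.0, ellipse)
    assert t.a_h == pytest.approx(65.0 + 10.0 - 18.85)
    assert t.b_h == pytest.approx(75.0 * math.sqrt(1 - (18.85 / 65.0) ** 2))
    assert t.d == pytest.approx(2 * t.b_h)
    with pytest.raises(ValueError):
        cs.TangentSection.from_geometry(66.0, 10.0, ellipse)
    with pytest.raises(ValueError):
        cs.TangentSection.from_geometry(10.0, -1.0, ellipse)


def test_delta_area_degenerate_tangent(ellipse):
    """h = a: the chord shrinks to the vertex and no area is gained."""
    t = cs.TangentSection.from_geometry(65.0, 10.0, ellipse)
    r = cs.delta_area_rectangle(t, ellipse, 2000)
    assert r.new_area == 0.0
    assert r.rate == 0.0


def test_delta_area_clinical_plateau_values(ellipse):
    """K = 10 at the plateau chord: area ≈ 1461.63 mm², rate ≈ 9.55 %."""
    t = cs.TangentSection.from_geometry(18.85, 10.0, ellipse)
    r = cs.delta_area_rectangle(t, ellipse, 2000)
    assert r.new_area == pytest.approx(1461.63, rel=5e-3)
    assert r.rate == pytest.approx(9.55, rel=5e-3)
    assert r.new_area == pytest.approx(2 * r.delta_A)
    # the closed-form segment area agrees to 0.1 % at this operating point
    assert r.delta_A == pytest.approx(delta_area_closed_form(t, ellipse), rel=1e-3)


@pytest.mark.parametrize("h", np.linspace(0.0, 64.0, 20))
@pytest.mark.parametrize("k", [2.0, 10.0, 25.0, 40.0, 50.0])
def test_rectangle_sum_matches_closed_form(ellipse, h, k):
    """Rectangle rule vs ellipse-segment antiderivative at n = 2000.

    The left/right-endpoint sums converge ~O(1/n) with the relative
    error growing toward the h = 0 boundary (vertical tangent of the
    bulge ellipse) and toward small elevations (small ΔA); 3e-3 bounds
    the whole domain, and the published operating region (h, k ≥ 10 mm)
    sits below 1e-3.
    """
    t = cs.TangentSection.from_geometry(float(h), k, ellipse)
    exact = delta_area_closed_form(t, ellipse)
    approx = cs.delta_area_rectangle(t, ellipse, 2000).delta_A
    assert approx == pytest.approx(exact, rel=3e-3)
    if h >= 10.0 and k >= 10.0:
        assert approx == pytest.approx(exact, rel=1e-3)


@pytest.mark.parametrize("h, k", [(18.85, 10.0), (40.0, 30.0)])
def test_rectangle_sum_converges(ellipse, h, k):
    """At n = 2·10⁵ the rectangle sums agree with the closed form to 1e-5."""
    t = cs.TangentSection.from_geometry(h, k, ellipse)
    exact = delta_area_closed_form(t, ellipse)
    approx = cs.delta_area_rectangle(t, ellipse, 200_000).delta_A
    assert approx == pytest.approx(exact, rel=1e-5)


@given(
    h=st.floats(0.0, 64.0),
    k1=st.floats(0.5, 49.0),
    dk=st.floats(0.5, 20.0),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_area_monotone_in_elevation(h, k1, dk):
    e = cs.EllipseSpec()
    t1 = cs.TangentSection.from_geometry(h, k1, e)
    t2 = cs.TangentSection.from_geometry(h, k1 + dk, e)
    a1 = cs.delta_area_rectangle(t1, e, 500).new_area
    a2 = cs.delta_area_rectangle(t2, e, 500).new_area
    assert a2 > a1


def test_sweep_grid_convention(sweeps):
    """h advances in steps of a/500 = 0.13 mm; row 145 is the K=10 plateau."""
    rows = sweeps[10].rows
    assert len(rows) == 500
    assert rows["h_mm"].iloc[145] == pytest.approx(18.85)
    assert rows["d_mm"].iloc[145] == pytest.approx(143.55, abs=0.01)
    assert rows["h_mm"].is_monotonic_increasing


def test_sweep_contracts(ellipse):
    assert len(cs.sweep_tangent_diameters(10.0, ellipse, n_grid=2, n_rect=50).rows) == 2
    with pytest.raises(ValueError):
        cs.sweep_tangent_diameters(0.0, ellipse)
    with pytest.raises(ValueError):
        cs.sweep_tangent_diameters(-3.0, ellipse)


def test_find_plateau_clinical_values(sweeps):
    d10, a10, r10 = cs.find_plateau(sweeps[10])
    assert (d10, a10, r10) == (
        pytest.approx(143.55, abs=0.01),
        pytest.approx(1461.63, rel=5e-3),
        pytest.approx(9.55, rel=5e-3),
    )
    d50, a50, r50 = cs.find_plateau(sweeps[50])
    assert (d50, a50, r50) == (
        pytest.approx(147.92, abs=0.01),
        pytest.approx(6063.32, rel=5e-3),
        pytest.approx(39.58, rel=5e-3),
    )


def test_find_plateau_argmax_contract(ellipse):
    import pandas as pd

    rows = pd.DataFrame(
        {"h_mm": [0.0, 1.0, 2.0], "d_mm": [150.0, 149.0, 148.0],
         "new_area_mm2": [1.0, 2.0, 3.0], "rate_pct": [0.1, 0.2, 0.3]}
    )
    s = cs.SweepResult(rows=rows, k=10.0, n_grid=3, n_rect=10)
    assert cs.find_plateau(s)[0] == 148.0  # strictly increasing -> last row
    rows2 = rows.copy()
    rows2.loc[0, "new_area_mm2"] = 3.0  # tie -> larger diameter wins
    s2 = cs.SweepResult(rows=rows2, k=10.0, n_grid=3, n_rect=10)
    assert cs.find_plateau(s2)[0] == 150.0
    with pytest.raises(ValueError):
        cs.find_plateau(cs.SweepResult(rows=rows.iloc[:0], k=10.0, n_grid=0, n_rect=10))


def test_plateau_is_interior_single_maximum(sweeps):
    """Area vs diameter rises to one grid maximum strictly below d = 2b, then falls."""
    for k, s in sweeps.items():
        by_d = s.rows.sort_values("d_mm").reset_index(drop=True)
        areas = by_d["new_area_mm2"].to_numpy()
        i = int(np.argmax(areas))
        assert by_d["d_mm"].iloc[i] < 150.0
        assert np.all(np.diff(areas[: i + 1]) > 0)
        assert np.all(np.diff(areas[i:]) < 0)


def test_plateau_drifts_toward_full_axis(sweeps):
    ds = [cs.find_plateau(sweeps[k])[0] for k in (10, 20, 30, 40, 50)]
    assert all(b >= a for a, b in zip(ds, ds[1:]))


def test_rate_denominator_is_half_ellipse_area(ellipse):
    n = 2000
    i = np.arange(n)
    denom = 2.0 * (ellipse.a / n) * np.sum(ellipse.y(i * ellipse.a / n))
    assert denom == pytest.approx(math.pi * 65.0 * 75.0 / 2.0, rel=1e-3)


def test_ellipse_perimeter_approx():
    assert cs.ellipse_perimeter_approx(75.0, 65.0, 3.14) == pytest.approx(448.2)
    assert cs.ellipse_perimeter_approx(75.0, 65.0, 3.14) / 2 == pytest.approx(224.1)
    r = 10.0
    assert cs.ellipse_perimeter_approx(r, r) == pytest.approx(2 * math.pi * r)
    with pytest.raises(ValueError):
        cs.ellipse_perimeter_approx(60.0, 65.0)


def test_scalp_elevation_worked_example():
    inp = cs.ScalpFormulaInput(a_ap=75.0, b_lat=65.0, X=224.1, pi_const=3.14)
    assert round(cs.scalp_elevation_K(inp), 3) == 3.596


def test_scalp_elevation_inverse_in_X():
    inp = cs.ScalpFormulaInput(a_ap=75.0, b_lat=65.0, X=1e6, pi_const=3.14)
    assert cs.scalp_elevation_K(inp) == pytest.approx(0.0, abs=1e-2)
    with pytest.raises(ValueError):
        cs.ScalpFormulaInput(X=-1.0)


@given(
    a=st.floats(50.0, 110.0),
    b=st.floats(40.0, 100.0),
    X=st.floats(100.0, 400.0),
    ext=st.floats(1.0, 10.0),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_scalp_elevation_matches_root_finding_oracle(a, b, X, ext):
    """K solves (X+E)/X = perimeter(b+K)/perimeter(b) for the arc stretch."""
    pi = math.pi
    peri = lambda bb: 2 * pi * bb + 4 * (a - bb)

    def resid(K):
        return (X + ext) / X - peri(b + K) / peri(b)

    root = brentq(resid, 0.0, 200.0, xtol=1e-12)
    inp = cs.ScalpFormulaInput(a_ap=a, b_lat=b, X=X, extension=ext, pi_const=pi)
    assert cs.scalp_elevation_K(inp) == pytest.approx(root, abs=1e-9)
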