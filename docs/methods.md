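# Methods

## Elliptical craniectomy model

The axial skull section is idealised as an ellipse with semi-axes
`a` (lateral, along the defect axis; default 65 mm) and `b`
(anteroposterior; default 75 mm) — a general adult skull size. A
craniectomy of extent *d* (tangential diameter) is the chord at distance
`h ∈ [0, a]` from the centre; elevating the scalp by `k` mm replaces the
removed segment with the half-ellipse centred on the chord midpoint with
semi-axes `a_h = a + k − h` and `b_h = b·√(1 − h²/a²)`.

The elevated-contour ordinate is `y_h = b_h·√(1 − (x − h)²/a_h²)`: the
first factor is the constant `b_h`, not the original ellipse ordinate
`y(x)` — that variant would be undefined on `[a, a + k]` and does not
reproduce the model's operating points, while the constant-factor form
does (plateau at d = 143.55 mm, 1461.63 mm², 9.55 % for k = 10).

### Numerical integration

The area gain is evaluated exactly as in the original computerised
analysis, with plain rectangle sums rather than a higher-order rule,
because the published numbers are themselves rectangle sums:

* first integral `∫ₐ^{a+k} y_h dx`: left endpoints `x_i = a + i·k/n`,
  `i = 0..n−1`;
* second integral `∫ₕ^a (y_h − y) dx`: right endpoints
  `x_i = h + i·(a−h)/n`, `i = 1..n`;
* rate denominator `2·Σ (a/n)·y(i·a/n)` with left endpoints
  (≈ half-ellipse area `πab/2`, accurate to ~1e-4 at n = 2000).

Default n = 2000 per integral. The closed-form oracle uses the
antiderivative `F(u) = (u·√(1−u²) + asin u)/2`:
`ΔA = a_h·b_h·F(1) − a·b·(F(1) − F(h/a))`. Rectangle-vs-closed-form
agreement at n = 2000 is ≤1e-3 relative in the published operating
region (h, k ≥ 10 mm) but degrades toward the boundaries — worst case
~1.2e-3 at (h = 0, k = 10) and ~2.7e-3 at (h = 0, k = 2) — because the
endpoint sums converge only ~O(1/n) against the bulge ellipse's vertical
tangent. The property tests assert the measured bounds (3e-3 globally,
1e-3 interior) rather than a single uniform tolerance.

### Sweep and plateau

`sweep_tangent_diameters` evaluates the h-grid `h_i = i·a/n_grid`,
`i = 0..n_grid−1` (default 500; h = 0 included, the degenerate tangent
h = a excluded). The 0.13 mm step makes the published plateau diameters
grid-exact (143.55 = d at row 145 for k = 10). `find_plateau` returns
the row of maximal newly increased area, breaking ties toward the larger
diameter (the larger craniectomy); at the default resolution ties do not
occur in practice.

### Scalp-elevation height K

The defect-margin arc X stretches by at most E = 4.1 mm (a scalp wound
wider than 41 mm resists closure; lengths here live on the model's
mm scale). Scaling the perimeter approximation `2πb + 4(a − b)` gives
`K = (4E·a + (2πE − 4E)·b)/(X·(2π − 4))`. Two conventions deserve care:

* the K-formula semi-axes are `a_ap = 75` (anteroposterior, major) and
  `b_lat = 65` (lateral, minor) — the *reverse* of the integration
  model's roles. Both parameter sets are stored explicitly
  (`EllipseSpec` vs `ScalpFormulaInput`) and never swapped silently.
* `pi_const` defaults to exact π; the worked example (X = 224.1 mm,
  K = 3.596 mm) uses 3.14, so the constant is configurable.

Areas produced by the sweep are reported in mm² (they are
cross-sectional areas, whatever unit label conventions elsewhere may
suggest); the slice pipeline reports cm² and cm³.

## Synthetic phantoms

`phantom` rasterises elliptical bone annuli (outer ellipse minus a
concentric inner ellipse shrunk by the bone thickness, default 5 mm)
onto a 512×512 grid with a 30 cm field of view (0.586 mm/pixel) and
1.25 mm slices — the acquisition geometry of thin-slice cranial CT. The
per-slice semi-axes follow an ellipsoid profile (defaults 65/75/85 mm)
sampled at slice mid-planes; a craniectomy defect is an angular arc
removed from one lateral half over a slice range. Pixel centres sit at
integer coordinates, the physical origin is the image centre, and the
symmetry axis is the central column, so defect-free phantoms are
mirror-symmetric to the pixel.

Presets `small-defect` (~84 cm²), `medium-defect` (~137 cm²) and
`large-defect` (~161 cm²) span the three defect-area groups; their arc
extents and slice ranges were sized from the analytic projected-area
formula, not fitted to outputs. Optional Gaussian semi-axis jitter
(seed-deterministic) is off by default.

What the phantoms deliberately do **not** model: Hounsfield intensities
and soft tissue (the pipeline consumes bone-window binary masks),
non-elliptical skull shape, sutures/foramina, bilateral defects, and
partial-volume effects. Passing pipeline tests therefore demonstrate the
geometry processing is correct on clean skull-like inputs, not that
outline extraction would survive clinical segmentation noise.

## Contour reconstruction

Outlines are traced at the 0.5 iso-level (marching squares), giving
sub-pixel staircase polylines; pixel-corner outlines would alias the
mirror comparison. The outer outline is isolated per polar angle
(maximal radius about a point on the symmetry axis at the boundary's
vertical midpoint — a centroid would shift away from the defect and
smear the radial defect faces across angular bins). On a defective slice
the outline is open; the gap ends are the defect endpoints D, D′
(within 2 pixels of ground truth on phantoms).

`mirror_fill` reflects the contralateral segment between the mirror
images of D and D′ and splices it into the gap. A linear correction
pins the segment ends exactly onto D and D′ (the reconstructed boundary
must coincide with the defect boundary); the correction is at most a
pixel when the axis is placed correctly and can be disabled.

`elevate_contour` intersects the filled segment with the perpendicular
bisector of the chord DD′ (point P), pushes it outward by k to X, and
replaces the segment with the **circular arc** through D, X, D′. The
curve family of the elevated contour is a genuine design choice — no
single interpolating curve is canonical — and the circle is the simplest
curve through the three defining points; it degenerates gracefully to
the chord (two straight segments D–X, X–D′ when the points are
collinear) and at k = 0 encloses the regular contour's area within 1 %
on phantoms. Contours are stored counter-clockwise; k = 0 reproduces P
exactly on the arc.

The elevation schedule is 0–30 mm in 2 mm steps, then 35–50 mm in 5 mm
steps (20 heights).

## Mesh stitching

Adjacent layers are joined by the mapping `n = floor(m·N₁/N₀)`: lower
point m forms triangles {m, m+1, n} and {m+1, n, n+1}. The floor makes
the map monotone; degenerate (repeated-vertex) triangles are dropped.
With unequal counts the literal rule leaves uncovered quads (boundary
edges) whenever N₁ > N₀, so the full-mesh builder first resamples every
contour to a common count (arc-length uniform, default min(median, 512),
256 in the pipeline), which reduces the map to the identity and makes
the band hole-free by construction. Start points are aligned to the most
anterior point of each contour to prevent band twisting. Stack ends are
closed with centroid fans; windings are chosen for outward normals and
verified by the signed volume; watertightness (every edge in exactly two
faces) is asserted after every build. Faces touching a reconstructed
contour point carry the `reconstructed` tag, preserved through OBJ
`g` groups.

## Quantification

* **Defect area**: the per-slice defect endpoints are projected onto the
  sagittal plane (anteroposterior × craniocaudal); the margin polygon is
  measured by the shoelace formula. The polygon is extended by half a
  slice thickness past the first and last defective slice, since each
  slice stands for a full slab of removed bone; without the extension
  the area is biased low by half a slab at each end.
* **Enclosed volume**: sum of signed tetrahedra against the origin on a
  watertight mesh (the divergence theorem); non-watertight input raises
  with the offending edges named.
* **Rates**: `rate_i = (V_i − V_0)/V_0 × 100`. The 0 mm baseline uses
  the same circular-arc construction as every other elevation (k = 0
  passes through the regular contour at the bisector), so the rate at 0
  is identically zero and monotonicity follows from arc containment. The
  baseline volume therefore differs from the raw mirror-filled model by
  the (≤1 %) arc-vs-mirror discrepancy.
* **Volume boundary**: config selects the outer skull surface (whole
  model, shell included — the default whole-minus-bone bookkeeping) or
  the inner surface (brain cavity plus bulge); shell volume equals
  outer minus inner within voxel tolerance.
* **Groups**: 1 (<125 cm²), 2 (125 ≤ area < 150), 3 (≥150), left-closed
  at both boundaries.

## Problem sizes and determinism

Default analysis sizes: 500-step sweeps with n = 2000 rectangles
(sub-second); phantom pipeline at 136 slices of 512×512 with 256-point
resampled contours over the 20-step schedule (~10 s). All computations
are deterministic; the only randomness in the package is the optional
phantom jitter, seeded explicitly.

## Known limitations

* The elliptical model is two-dimensional: "volume-increasing rate" is
  an area ratio on the axial section, a proxy for the volumetric rate of
  the slice pipeline.
* Unilateral defects only; bilateral reconstruction would need a
  two-pass mirroring strategy.
* The defect endpoint detector assumes a star-convex outline about the
  symmetry-axis midpoint — true for skull sections, not for arbitrary
  shapes.
* No fitting of ellipse parameters to imagery; phantom parameters are
  inputs, not estimates.
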