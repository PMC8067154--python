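"""Slice-to-slice triangle stitching and Wavefront OBJ I/O.

Adjacent slice contours are joined with the adjacent-point mapping rule
n = floor(m · N_{L+1}/N_L): point m of the lower contour is connected to
point n of the upper one, producing two triangles per lower point.  The
rule is exact for equal point counts; for a full watertight skull mesh
the builder therefore resamples every contour to a common count first
(arc-length uniform, start point aligned to the most anterior point so
the band does not twist), closes the stack ends with centroid fans and
verifies edge-manifoldness.

Faces built from reconstructed contour points keep the tag
"reconstructed" so the artificial flap stays distinguishable from the
original bone, including through OBJ round trips (``g`` groups).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .contours import SliceContour

__all__ = [
    "SkullMesh",
    "stitch_layers",
    "close_caps",
    "build_mesh",
    "resample_contour",
    "open_edges",
    "write_obj",
    "read_obj",
]

TAG_ORIGINAL = "original"
TAG_RECONSTRUCTED = "reconstructed"


@dataclass
class SkullMesh:
    """Triangle surface mesh: vertices in mm, faces as index triples."""

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray  # (F, 3) int
    face_tags: np.ndarray  # (F,) str, original | reconstructed

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.face_tags = np.asarray(self.face_tags)
        if len(self.face_tags) != len(self.faces):
            raise ValueError("face_tags must match faces")

    def signed_volume(self) -> float:
        """Sum of signed tetrahedra against the origin (mm³)."""
        v = self.vertices
        t = v[self.faces]
        return float(np.einsum("ij,ij->", t[:, 0], np.cross(t[:, 1], t[:, 2]))) / 6.0

    def is_watertight(self) -> bool:
        return len(open_edges(self.faces)) == 0

    def euler_characteristic(self) -> int:
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        n_edges = len(np.unique(e, axis=0))
        n_verts = len(np.unique(self.faces))
        return n_verts - n_edges + len(self.faces)


def open_edges(faces: np.ndarray) -> np.ndarray:
    """Edges not shared by exactly two faces (empty for a watertight mesh)."""
    e = np.sort(np.asarray(faces)[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return uniq[counts != 2]


def stitch_layers(
    cL: np.ndarray, cL1: np.ndarray, zL: float, zL1: float
) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate the band between two closed contours.

    Returns (vertices, faces): vertices are the lower contour lifted to
    zL followed by the upper at zL1; for each lower index m with
    n = floor(m·N₁/N₀) the two faces use vertex sets {m, m+1, n} and
    {m+1, n, n+1} (indices modulo the respective counts), wound for
    outward normals with counter-clockwise input contours.  Degenerate
    (repeated-vertex) faces are dropped.
    """
    cL, cL1 = np.asarray(cL, float), np.asarray(cL1, float)
    if len(cL) < 3 or len(cL1) < 3:
        raise ValueError("contours must have at least 3 points")
    n0, n1 = len(cL), len(cL1)
    verts = np.vstack(
        [
            np.column_stack([cL, np.full(n0, float(zL))]),
            np.column_stack([cL1, np.full(n1, float(zL1))]),
        ]
    )
    m = np.arange(n0)
    n = (m * n1) // n0
    lo, lo1 = m, (m + 1) % n0
    up, up1 = n0 + (n % n1), n0 + ((n + 1) % n1)
    f1 = np.column_stack([lo, lo1, up])
    f2 = np.column_stack([lo1, up1, up])
    faces = np.vstack([f1, f2])
    keep = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    return verts, faces[keep]


def close_caps(
    vertices: np.ndarray,
    faces: np.ndarray,
    bottom: Sequence[int],
    top: Sequence[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Fan-triangulate the end contours from their centroids.

    ``bottom``/``top`` are vertex index loops (counter-clockwise seen
    from +z) of the first and last slice contour; two centroid vertices
    are appended.  The bottom fan is wound downward, the top fan upward.
    """
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces, int)
    new_faces = [faces]
    verts = [vertices]
    next_idx = len(vertices)
    for loop, downward in ((np.asarray(bottom, int), True), (np.asarray(top, int), False)):
        if len(loop) < 3:
            raise ValueError("cap contour needs at least 3 points")
        centroid = vertices[loop].mean(axis=0)
        verts.append(centroid[None])
        nxt = np.roll(loop, -1)
        if downward:
            fan = np.column_stack([np.full(len(loop), next_idx), nxt, loop])
        else:
            fan = np.column_stack([np.full(len(loop), next_idx), loop, nxt])
        new_faces.append(fan)
        next_idx += 1
    return np.vstack(verts), np.vstack(new_faces)


def resample_contour(c: SliceContour, n: int) -> SliceContour:
    """Arc-length uniform resampling of a closed contour to n points.

    The start point is aligned to the most anterior (max y) point so
    successive layers do not twist against each other; provenance is
    carried over from the enclosing source segment.
    """
    if not c.closed:
        raise ValueError("can only resample closed contours")
    pts = c.points
    start = int(np.argmax(pts[:, 1]))
    pts = np.roll(pts, -start, axis=0)
    rec = np.roll(c.reconstructed, -start)
    loop = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(loop, axis=0), axis=1)
    cum = np.r_[0.0, np.cumsum(seg)]
    total = cum[-1]
    s = np.arange(n) * (total / n)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    w = (s - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    new_pts = loop[idx] * (1 - w)[:, None] + loop[idx + 1] * w[:, None]
    rec_loop = np.r_[rec, rec[:1]]
    new_rec = rec_loop[idx] | rec_loop[idx + 1]
    return SliceContour(
        new_pts,
        closed=True,
        axis_x=c.axis_x,
        reconstructed=new_rec,
        defect_endpoints=c.defect_endpoints,
        z=c.z,
    )


def build_mesh(
    contours: Sequence[SliceContour],
    slice_thickness: float | None = None,
    n_points: int | None = None,
) -> SkullMesh:
    """Stitch an ordered stack of closed contours into a watertight mesh.

    Contours are resampled to a common point count (median of the input
    counts unless ``n_points`` is given), stitched layer by layer and
    capped at both ends.  Faces touching a reconstructed contour point
    are tagged reconstructed.  Raises if the result is not watertight.
    """
    if len(contours) < 1:
        raise ValueError("need at least one contour")
    if n_points is None:
        n_points = int(np.median([len(c.points) for c in contours]))
        n_points = max(16, min(n_points, 512))
    rs = [resample_contour(c, n_points) for c in contours]
    zs = [
        c.z if slice_thickness is None else i * slice_thickness
        for i, c in enumerate(rs)
    ]
    if len(rs) == 1:  # minimal stack: one band of zero height is meaningless,
        # extrude the single contour over one slice thickness
        t = slice_thickness if slice_thickness is not None else 1.0
        rs = [rs[0], rs[0]]
        zs = [zs[0], zs[0] + t]

    n = n_points
    verts = np.vstack(
        [np.column_stack([c.points, np.full(n, z)]) for c, z in zip(rs, zs)]
    )
    vert_rec = np.concatenate([c.reconstructed for c in rs])
    faces_list, tags_list = [], []
    for layer in range(len(rs) - 1):
        _, f = stitch_layers(rs[layer].points, rs[layer + 1].points, zs[layer], zs[layer + 1])
        f = f + layer * n  # stitch indexes its own two layers from 0
        faces_list.append(f)
    faces = np.vstack(faces_list)
    verts, faces = close_caps(
        verts, faces, bottom=np.arange(n), top=np.arange(n) + (len(rs) - 1) * n
    )
    vert_rec = np.r_[vert_rec, False, False]
    tags = np.where(vert_rec[faces].any(axis=1), TAG_RECONSTRUCTED, TAG_ORIGINAL)
    mesh = SkullMesh(verts, faces, tags)
    if mesh.signed_volume() < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
    bad = open_edges(mesh.faces)
    if len(bad):
        raise ValueError(f"stitched mesh is not watertight: {len(bad)} open edges")
    return mesh


# ---------------------------------------------------------------------------
# Wavefront OBJ

def write_obj(mesh: SkullMesh, path: str | Path) -> Path:
    path = Path(path)
    lines = ["# craniosim skull mesh"]
    for v in mesh.vertices:
        lines.append(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
    for tag in (TAG_ORIGINAL, TAG_RECONSTRUCTED):
        sel = mesh.faces[mesh.face_tags == tag]
        if len(sel) == 0:
            continue
        lines.append(f"g {tag}")
        for f in sel + 1:  # OBJ is 1-based
            lines.append(f"f {f[0]} {f[1]} {f[2]}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_obj(path: str | Path) -> SkullMesh:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    tags: list[str] = []
    group = TAG_ORIGINAL
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        tokens = raw.split()
        if not tokens or tokens[0].startswith("#"):
            continue
        kind = tokens[0]
        try:
            if kind == "v":
                verts.append([float(t) for t in tokens[1:4]])
            elif kind == "g":
                group = tokens[1] if len(tokens) > 1 else TAG_ORIGINAL
            elif kind == "f":
                idx = [int(t.split("/")[0]) - 1 for t in tokens[1:]]
                if len(idx) != 3:
                    raise ValueError("only triangle faces are supported")
                faces.append(idx)
                tags.append(group)
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed OBJ at line {ln}: {raw!r} ({exc})") from None
    return SkullMesh(np.array(verts), np.array(faces, int), np.array(tags))
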