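"""Triangulation of cell interiors and periodic remeshing.

Each cell's in-plane wall is meshed with a conforming triangulation whose
boundary edges subdivide (never cross) the cell's polygon edges. Quality is
controlled by a (min_angle [deg], max_area [μm²]) pair: the mesher derives a
target spacing h = sqrt(2·max_area), subdivides boundary edges longer than h
(a tissue-level pass, so shared edges stay conforming between neighbors) and
seeds interior Steiner points on a triangular lattice of spacing h kept a
margin away from the boundary; a Delaunay triangulation of boundary plus
interior points then covers the polygon. If the lattice construction fails
to tile a (non-convex) polygon exactly, the mesher falls back to a
constrained Delaunay triangulation of the polygon vertices alone.

Remeshing regenerates each cell's triangulation in its *current*
configuration; reference positions of new vertices are assigned by
barycentric interpolation from the old elements, which is exact for affine
deformation fields, so remeshing is invisible to the mechanics up to
interpolation error.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon

from .tissue import (
    Tissue,
    TriElement,
    TissueError,
    edge_key,
    polygon_signed_area,
)

__all__ = [
    "aspect_ratio",
    "triangulate_cell",
    "subdivide_long_edges",
    "triangulate_tissue",
    "remesh_tissue",
    "barycentric_interpolate",
]

#: relative tolerance on triangulation coverage of the polygon area
_COVER_RTOL = 1e-9
#: how far (μm) outside every old element a remeshed point may fall before
#: a warning is emitted and the point is snapped to the nearest element
_SNAP_WARN_TOL = 1e-6


def aspect_ratio(pts) -> float:
    """Longest edge over twice the inradius: ≥ √3, = √3 iff equilateral.

    A zero-area triangle reports infinity.
    """
    pts = np.asarray(pts, dtype=float).reshape(3, 2)
    e = np.linalg.norm(pts - np.roll(pts, -1, axis=0), axis=1)
    area = abs(polygon_signed_area(pts))
    if area <= 0:
        return float("inf")
    inradius = area / (0.5 * e.sum())
    return float(e.max() / (2.0 * inradius))


def _interior_lattice(poly: Polygon, h: float, margin: float) -> np.ndarray:
    """Deterministic triangular lattice of points inside ``poly``, at least
    ``margin`` away from its boundary."""
    minx, miny, maxx, maxy = poly.bounds
    dy = h * math.sqrt(3.0) / 2.0
    pts = []
    row = 0
    y = miny + dy
    while y < maxy - 1e-12:
        off = 0.5 * h if row % 2 else 0.0
        xs = np.arange(minx + off + 0.5 * h, maxx, h)
        pts.extend((x, y) for x in xs)
        row += 1
        y = miny + (row + 1) * dy
    if not pts:
        return np.empty((0, 2))
    pts = np.asarray(pts)
    inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
    pts = pts[inside]
    if len(pts) == 0:
        return pts
    dist = shapely.distance(poly.exterior, shapely.points(pts))
    return pts[dist >= margin]


def _orient_ccw(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = points[tris]
    cross = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
             - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    flip = cross < 0
    tris = tris.copy()
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return tris


def _cdt_fallback(pts: np.ndarray, poly: Polygon) -> np.ndarray:
    """Constrained Delaunay triangulation of the polygon's own vertices."""
    tree = cKDTree(pts)
    tris = []
    for geom in shapely.get_parts(shapely.constrained_delaunay_triangles(poly)):
        coords = np.asarray(geom.exterior.coords)[:3]
        d, idx = tree.query(coords)
        if np.any(d > 1e-9 * (1 + np.abs(pts).max())):
            raise TissueError("constrained triangulation introduced unknown vertices")
        tris.append(idx)
    return _orient_ccw(pts, np.asarray(tris, dtype=int))


def triangulate_cell(polygon, quality: Tuple[float, float] = (20.0, 250.0)):
    """Triangulate a simple polygon.

    Parameters
    ----------
    polygon : (n, 2) array of anticlockwise boundary points (already
        refined: boundary edges are not subdivided here).
    quality : (min_angle [deg], max_area [μm²]). max_area sets the interior
        point spacing; min_angle sets the margin keeping Steiner points off
        the boundary (larger angles push points further in).

    Returns
    -------
    points : (N, 2) array; the first n rows are the input boundary points,
        the remainder are interior Steiner points.
    triangles : (M, 3) int array of anticlockwise triangles indexing
        ``points``, exactly covering the polygon.
    """
    pts = np.asarray(polygon, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise TissueError("polygon must be an (n>=3, 2) array")
    area = polygon_signed_area(pts)
    if area <= 0:
        raise TissueError("polygon must be anticlockwise with positive area")
    poly = Polygon(pts)
    if not poly.is_valid:
        raise TissueError("polygon is degenerate or self-intersecting")
    min_angle, max_area = quality
    h = math.sqrt(2.0 * max_area)
    margin = h * max(0.3, math.sin(math.radians(min_angle)))
    interior = _interior_lattice(poly, h, margin)
    allpts = np.vstack([pts, interior]) if len(interior) else pts

    if len(allpts) == 3:
        return allpts, np.array([[0, 1, 2]])
    tri = Delaunay(allpts)
    cand = tri.simplices
    p = allpts[cand]
    areas = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    cent = p.mean(axis=1)
    keep = (areas > 1e-10) & shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
    kept = cand[keep]
    if abs(areas[keep].sum() - poly.area) <= _COVER_RTOL * poly.area and len(kept):
        order = np.lexsort((kept[:, 2], kept[:, 1], kept[:, 0]))
        return allpts, _orient_ccw(allpts, kept[order])
    # non-convex corner case: drop Steiner points, use the exact CDT
    return pts, _cdt_fallback(pts, poly)


def subdivide_long_edges(tissue: Tissue, max_len: float) -> set:
    """Split every cell-boundary edge longer than ``max_len`` into equal
    sub-edges (shared edges split once, consistently for both neighbors;
    wall segments inherit rest length proportionally). Returns the ids of
    cells whose triangulation became stale."""
    affected = set()
    for key, cids in sorted(tissue.edge_cells().items()):
        length = tissue.edge_length(key)
        n = int(math.ceil(length / max_len - 1e-9))
        if n >= 2:
            tissue.subdivide_edge(key, [k / n for k in range(1, n)])
            affected.update(cids)
    return affected


def barycentric_interpolate(points: np.ndarray,
                            tri_cur: np.ndarray,
                            tri_ref: np.ndarray,
                            warn_label: str = "") -> np.ndarray:
    """Map ``points`` (in the current configuration) to reference positions
    by barycentric interpolation over old elements.

    ``tri_cur``/``tri_ref`` are (M, 3, 2) current and reference corner
    positions. Each point uses the element containing it; a point outside
    every element by more than a tolerance is snapped to the nearest one
    (with a warning), which keeps remeshing robust to roundoff.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(tri_cur) == 0:
        return points.copy()
    a, b, c = tri_cur[:, 0], tri_cur[:, 1], tri_cur[:, 2]
    T = np.stack([b - a, c - a], axis=-1)           # (M,2,2)
    Tinv = np.linalg.inv(T)
    d = points[:, None, :] - a[None, :, :]          # (P,M,2)
    uv = np.einsum("mij,pmj->pmi", Tinv, d)
    w = np.concatenate([1.0 - uv.sum(-1, keepdims=True), uv], axis=-1)  # (P,M,3)
    score = w.min(axis=-1)                          # (P,M)
    best = score.argmax(axis=1)
    wbest = w[np.arange(len(points)), best]
    worst = score[np.arange(len(points)), best]
    scale = np.sqrt(np.abs(polygon_signed_area(tri_cur[0])) + 1e-300)
    if np.any(worst < -_SNAP_WARN_TOL / max(scale, 1e-12)):
        warnings.warn(
            f"remesh point-location: {int(np.sum(worst < -_SNAP_WARN_TOL))} point(s) "
            f"outside all old elements{(' in ' + warn_label) if warn_label else ''}; "
            "snapped to nearest element")
    wbest = np.clip(wbest, 0.0, None)
    wbest /= wbest.sum(axis=1, keepdims=True)
    return np.einsum("pk,pki->pi", wbest, tri_ref[best])


def _retriangulate_cell(tissue: Tissue, cid: int,
                        quality: Tuple[float, float]) -> None:
    cell = tissue.cells[cid]
    old_cur = (np.array([tissue.positions(el.vids) for el in cell.elements])
               if cell.elements else np.empty((0, 3, 2)))
    old_ref = (np.array([el.X for el in cell.elements])
               if cell.elements else np.empty((0, 3, 2)))
    tissue.drop_cell_interior(cid)
    cell.elements = []
    pts = tissue.positions(cell.boundary)
    points, tris = triangulate_cell(pts, quality)
    n_b = len(cell.boundary)
    new_ids = list(cell.boundary)
    if len(points) > n_b:
        steiner = points[n_b:]
        if len(old_cur):
            refs = barycentric_interpolate(steiner, old_cur, old_ref,
                                           warn_label=f"cell {cid}")
        else:
            refs = steiner.copy()
        for p, X in zip(steiner, refs):
            vid = tissue.new_vertex(p, fixed=False)
            cell.interior.add(vid)
            cell.ref_coords[vid] = np.asarray(X, dtype=float)
            new_ids.append(vid)
    n_reset = 0
    for t in tris:
        vids = tuple(new_ids[k] for k in t)
        X = np.array([cell.ref_coords[v] for v in vids])
        # under strongly non-affine deformation the interpolated reference
        # corners of a new triangle can be inverted or collinear (e.g.
        # three points on an originally straight, now bulged wall) even
        # though the old piecewise-linear map is orientation-preserving;
        # reset such an element's reference to its current shape (local
        # loss of fiber advection history only)
        cur = tissue.positions(vids)
        if polygon_signed_area(X) <= 1e-6 * max(polygon_signed_area(cur), 1e-12):
            X = cur
            n_reset += 1
        cell.elements.append(TriElement(vids=vids, X=X))
    if n_reset:
        warnings.warn(f"cell {cid}: reset reference of {n_reset} element(s) "
                      "with inverted interpolated reference")


def triangulate_tissue(tissue: Tissue,
                       quality: Tuple[float, float] = (20.0, 250.0),
                       subdivide_boundary: bool = True,
                       cells: Optional[Iterable[int]] = None) -> Tissue:
    """(Re)build the in-plane triangulation of the given cells (default:
    all). When ``subdivide_boundary``, cell edges longer than the target
    spacing are first split tissue-wide so the mesh conforms across shared
    walls."""
    if subdivide_boundary:
        h = math.sqrt(2.0 * quality[1])
        stale = subdivide_long_edges(tissue, h)
        if cells is not None:
            cells = set(cells) | stale
    todo = sorted(tissue.cells) if cells is None else sorted(set(cells))
    for cid in todo:
        _retriangulate_cell(tissue, cid, quality)
    return tissue


def remesh_tissue(tissue: Tissue,
                  quality: Tuple[float, float] = (20.0, 250.0),
                  subdivide_boundary: bool = True) -> Tissue:
    """Regenerate every cell's triangulation in its current configuration.

    Cell polygons (up to collinear subdivision points), concentrations and
    timers are untouched; new vertices get reference positions by
    barycentric interpolation and fiber directions stay the per-cell
    constants, so for affine deformation the mechanics after remeshing
    matches the unremeshed state exactly.

    By default boundary edges that have stretched beyond the target spacing
    are re-subdivided (otherwise strip-shaped cells would keep their
    elongated boundary triangles and remeshing would not restore element
    quality). Splitting a straight edge's wall segment into sub-segments
    with proportional rest lengths leaves all assembled forces unchanged,
    so this is mechanically neutral at the instant of remeshing.
    """
    return triangulate_tissue(tissue, quality, subdivide_boundary=subdivide_boundary)
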