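"""Tissue data model, topology validation, synthetic-root generation and I/O.

A :class:`Tissue` is the single source of truth for geometry: vertices with
positions (μm), polygonal cells listed anticlockwise, out-of-plane wall
segments per (cell, edge) incidence, and per-cell triangulations of the
in-plane wall (elements, with reference coordinates for the deformation
gradient). Adjacent cells share edge objects — the vertex/edge sharing is
what enforces symplastic growth.

Edges are identified by the canonical (min id, max id) pair of their
endpoints. Interior edges carry two wall segments (one per adjacent cell);
edges on the organ boundary carry one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .config import SimConfig
from .constitutive import InPlaneWallMaterial

__all__ = [
    "TissueError",
    "Vertex",
    "Cell",
    "WallSegment",
    "TriElement",
    "Tissue",
    "edge_key",
    "edge_class",
    "classify_edges",
    "cell_area",
    "cell_centroid",
    "polygon_signed_area",
    "build_synthetic_root",
    "validate_topology",
    "read_tissue",
    "write_tissue",
]

EdgeKey = Tuple[int, int]

#: snapping tolerance for near-coincident cross-wall positions in adjacent
#: files of the synthetic root [μm]
_SNAP_TOL = 1.0
#: tolerance for flagging max-x vertices as fixed [μm]
_FIXED_TOL = 1.0e-6


class TissueError(ValueError):
    """Topology or schema violation, with a message naming the location."""


def edge_key(i: int, j: int) -> EdgeKey:
    if i == j:
        raise TissueError(f"degenerate edge ({i}, {j}): endpoints must be distinct")
    return (i, j) if i < j else (j, i)


@dataclass
class Vertex:
    pos: np.ndarray
    fixed: bool = False

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float).reshape(2)
        if not np.all(np.isfinite(self.pos)):
            raise TissueError("vertex position must be finite")


@dataclass
class WallSegment:
    """One cell's view of one out-of-plane wall edge.

    ``mu`` [MPa μm hr], ``tau`` [MPa μm], ``eps_star`` [hr⁻¹],
    ``lam`` [MPa μm], ``l0`` rest length [μm].
    """

    cell: int
    key: EdgeKey
    wall_class: str  # "axial" or "cross"
    mu: float
    tau: float
    eps_star: float
    lam: float
    l0: float

    def __post_init__(self):
        for name in ("mu", "tau", "eps_star", "lam", "l0"):
            if getattr(self, name) < 0:
                raise TissueError(f"wall segment {self.cell}/{self.key}: {name} < 0")


@dataclass
class TriElement:
    """One triangular patch of in-plane wall: vertex ids (anticlockwise) and
    their positions in the reference configuration."""

    vids: Tuple[int, int, int]
    X: np.ndarray  # (3, 2) reference positions

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float).reshape(3, 2)


@dataclass
class Cell:
    """Polygonal cell: anticlockwise boundary, turgor pressure [MPa], tissue
    type, inhibitor concentration b [nM], division timer, in-plane material
    and reference fiber directions, plus the cell's triangulation."""

    boundary: List[int]
    pressure: float = 0.3
    cell_type: str = "generic"
    b: float = 0.0
    timer: float = 0.0
    material: InPlaneWallMaterial = field(default_factory=InPlaneWallMaterial)
    file_index: Optional[int] = None
    segments: Dict[EdgeKey, WallSegment] = field(default_factory=dict)
    ref_coords: Dict[int, np.ndarray] = field(default_factory=dict)
    elements: List[TriElement] = field(default_factory=list)
    interior: Set[int] = field(default_factory=set)

    def boundary_edges(self) -> List[Tuple[int, int]]:
        """Directed boundary edges (i -> j) in anticlockwise order."""
        b = self.boundary
        return [(b[k], b[(k + 1) % len(b)]) for k in range(len(b))]


def polygon_signed_area(pts: np.ndarray) -> float:
    """Shoelace signed area; positive for anticlockwise polygons."""
    pts = np.asarray(pts, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _cell_pts(cell: Cell, vertices: Dict[int, Vertex]) -> np.ndarray:
    return np.array([vertices[v].pos for v in cell.boundary])


def _check_simple_ccw(pts: np.ndarray, where: str) -> Polygon:
    if len(pts) < 3:
        raise TissueError(f"{where}: polygon needs at least 3 vertices")
    poly = Polygon(pts)
    if not poly.is_valid:
        raise TissueError(f"{where}: polygon is self-intersecting or degenerate")
    if polygon_signed_area(pts) <= 0:
        raise TissueError(f"{where}: boundary must be anticlockwise (signed area > 0)")
    return poly


def cell_area(cell: Cell, vertices: Dict[int, Vertex]) -> float:
    """Shoelace area [μm²] of a simple anticlockwise cell polygon."""
    pts = _cell_pts(cell, vertices)
    _check_simple_ccw(pts, "cell")
    return polygon_signed_area(pts)


def cell_centroid(cell: Cell, vertices: Dict[int, Vertex]) -> np.ndarray:
    """Area-weighted centroid of the cell polygon [μm]."""
    pts = _cell_pts(cell, vertices)
    _check_simple_ccw(pts, "cell")
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def edge_class(d: np.ndarray, threshold: float = math.pi / 4) -> str:
    """Classify an edge direction as "axial" or "cross".

    Axial iff the absolute angle to the x-axis is strictly below the
    threshold; the boundary case (exactly at the threshold, e.g. π/4) is
    assigned to "cross" so the rule is deterministic.
    """
    d = np.asarray(d, dtype=float)
    n = np.hypot(d[0], d[1])
    if n == 0:
        raise TissueError("zero-length edge cannot be classified")
    ang = math.atan2(abs(d[1]), abs(d[0]))
    return "axial" if ang < threshold else "cross"


class Tissue:
    """Shared vertex/edge/cell topology plus all mechanical state."""

    def __init__(self, wall_defaults: Optional[dict] = None):
        self.vertices: Dict[int, Vertex] = {}
        self.cells: Dict[int, Cell] = {}
        # per-class default segment parameters for newly created walls
        self.wall_defaults: dict = wall_defaults or _wall_defaults_from_config(SimConfig())
        self._next_vid = 0
        self._next_cid = 0

    # -- construction -----------------------------------------------------
    def new_vertex(self, pos, fixed: bool = False) -> int:
        vid = self._next_vid
        self._next_vid += 1
        self.vertices[vid] = Vertex(np.asarray(pos, dtype=float), fixed)
        return vid

    def new_cell(self, cell: Cell) -> int:
        cid = self._next_cid
        self._next_cid += 1
        self.cells[cid] = cell
        return cid

    def make_segment(self, cid: int, key: EdgeKey, l0: float,
                     wall_class: Optional[str] = None,
                     overrides: Optional[dict] = None) -> WallSegment:
        """Create a segment for (cell, edge) from the per-class defaults."""
        if wall_class is None:
            d = self.vertices[key[1]].pos - self.vertices[key[0]].pos
            wall_class = edge_class(d)
        params = dict(self.wall_defaults[wall_class])
        if overrides:
            params.update({k: v for k, v in overrides.items() if k in params})
        return WallSegment(cell=cid, key=key, wall_class=wall_class, l0=l0, **params)

    # -- topology queries --------------------------------------------------
    def positions(self, vids: Iterable[int]) -> np.ndarray:
        return np.array([self.vertices[v].pos for v in vids])

    def edge_cells(self) -> Dict[EdgeKey, List[int]]:
        """Map from each edge to the (1 or 2) cells incident on it."""
        out: Dict[EdgeKey, List[int]] = {}
        for cid in sorted(self.cells):
            for i, j in self.cells[cid].boundary_edges():
                out.setdefault(edge_key(i, j), []).append(cid)
        return out

    def boundary_edge_keys(self) -> Set[EdgeKey]:
        return {k for k, cs in self.edge_cells().items() if len(cs) == 1}

    @property
    def interior_vertices(self) -> Set[int]:
        out: Set[int] = set()
        for cell in self.cells.values():
            out |= cell.interior
        return out

    def edge_length(self, key: EdgeKey) -> float:
        return float(np.linalg.norm(self.vertices[key[1]].pos - self.vertices[key[0]].pos))

    def cell_polygon(self, cid: int) -> Polygon:
        return Polygon(_cell_pts(self.cells[cid], self.vertices))

    def organ_polygon(self) -> Polygon:
        geom = unary_union([self.cell_polygon(c) for c in sorted(self.cells)])
        if geom.geom_type != "Polygon":
            raise TissueError("organ is not a single connected polygon")
        return geom

    # -- topology edits ----------------------------------------------------
    def subdivide_edge(self, key: EdgeKey, fractions: Iterable[float]) -> List[int]:
        """Insert vertices on edge ``key`` at the given fractions (0..1 from
        the low-id endpoint), for every incident cell.

        Boundary lists are updated, each incident cell's wall segment is
        split with rest length distributed proportionally to the current
        sub-lengths, and per-cell reference coordinates are interpolated
        linearly along the edge. The affected cells' triangulations become
        stale and must be rebuilt by the caller.
        """
        i, j = key
        fr = sorted(float(f) for f in fractions)
        if not fr:
            return []
        if fr[0] <= 0 or fr[-1] >= 1:
            raise TissueError(f"edge {key}: subdivision fractions must be in (0, 1)")
        pi_, pj_ = self.vertices[i].pos, self.vertices[j].pos
        both_fixed = self.vertices[i].fixed and self.vertices[j].fixed
        new_vids = [self.new_vertex(pi_ + f * (pj_ - pi_), fixed=both_fixed) for f in fr]
        cut = [0.0] + fr + [1.0]
        sub_fracs = np.diff(cut)  # relative length of each sub-edge
        incident = [cid for cid, cs in ((c, self.cells[c]) for c in sorted(self.cells))
                    if key in {edge_key(a, b) for a, b in cs.boundary_edges()}]
        if not incident:
            raise TissueError(f"edge {key} not found in any cell")
        for cid in incident:
            cell = self.cells[cid]
            seg = cell.segments.pop(key, None)
            edges = cell.boundary_edges()
            forward = (i, j) in edges
            chain = new_vids if forward else list(reversed(new_vids))
            first, second = (i, j) if forward else (j, i)
            pos = cell.boundary.index(first)
            # guard against (first, second) appearing via the wrap-around only
            nxt = cell.boundary[(pos + 1) % len(cell.boundary)]
            if nxt != second:
                pos = next(k for k in range(len(cell.boundary))
                           if cell.boundary[k] == first
                           and cell.boundary[(k + 1) % len(cell.boundary)] == second)
            cell.boundary[pos + 1:pos + 1] = chain
            # reference coordinates: linear along the (straight) edge image
            Xi, Xj = cell.ref_coords[i], cell.ref_coords[j]
            for f, vid in zip(fr, new_vids):
                cell.ref_coords[vid] = (1 - f) * Xi + f * Xj
            if seg is not None:
                ids = [i] + new_vids + [j]
                for k in range(len(ids) - 1):
                    sk = edge_key(ids[k], ids[k + 1])
                    sub = WallSegment(cell=cid, key=sk, wall_class=seg.wall_class,
                                      mu=seg.mu, tau=seg.tau, eps_star=seg.eps_star,
                                      lam=seg.lam, l0=seg.l0 * sub_fracs[k])
                    cell.segments[sk] = sub
        return new_vids

    def drop_cell_interior(self, cid: int) -> None:
        """Remove a cell's interior (Steiner) vertices from the tissue."""
        cell = self.cells[cid]
        for vid in cell.interior:
            self.vertices.pop(vid, None)
            cell.ref_coords.pop(vid, None)
        cell.interior = set()

    def remove_cell(self, cid: int) -> None:
        self.drop_cell_interior(cid)
        del self.cells[cid]


def _wall_defaults_from_config(config: SimConfig) -> dict:
    return {
        "axial": {"mu": config.mu_axial, "tau": config.tau_axial,
                  "eps_star": config.eps_star_axial, "lam": config.lam_axial},
        "cross": {"mu": config.mu_cross, "tau": config.tau_cross,
                  "eps_star": config.eps_star_cross, "lam": config.lam_cross},
    }


def classify_edges(tissue: Tissue, axis_angle_threshold: float = math.pi / 4) -> Tissue:
    """(Re)label every wall segment as axial or cross from its current
    geometry: axial iff the edge is strictly within the threshold angle of
    the x-axis (the organ's long axis)."""
    for cid in sorted(tissue.cells):
        cell = tissue.cells[cid]
        for key, seg in cell.segments.items():
            d = tissue.vertices[key[1]].pos - tissue.vertices[key[0]].pos
            seg.wall_class = edge_class(d, axis_angle_threshold)
    return tissue


# --------------------------------------------------------------------------
# synthetic root generation
# --------------------------------------------------------------------------

def _file_cuts(rng: np.random.Generator, total: float, lmin: float) -> List[float]:
    """Cross-wall x-positions of one file, rootward (x=0) to shootward.

    Successive cell lengths are drawn U[lmin, 2 lmin]; the last cell is
    truncated so the file spans exactly ``total``. A truncated sliver
    shorter than 0.5 μm is merged into the previous cell.
    """
    cuts = [0.0]
    x = 0.0
    while True:
        x += rng.uniform(lmin, 2.0 * lmin)
        if x >= total - 1e-9:
            cuts.append(total)
            break
        cuts.append(x)
    if len(cuts) >= 3 and cuts[-1] - cuts[-2] < 0.5:
        del cuts[-2]
    return cuts


def build_synthetic_root(
    n_files: int = 5,
    file_height: float = 20.0,
    total_length: float = 2000.0,
    min_cell_length: float = 50.0,
    seed: int = 0,
    config: Optional[SimConfig] = None,
) -> Tissue:
    """Generate the rectangular multi-file "root" used for the synthetic
    experiments.

    Files are stacked in y; within each file, cross walls are placed
    independently (staggered between files), with cell lengths drawn from
    U[min_cell_length, 2·min_cell_length] starting at the rootward (min-x)
    end and the last cell truncated to fit. Vertices on the shootward
    (max-x) boundary are flagged fixed. Cross-wall positions in adjacent
    files closer than 1 μm are snapped together to avoid sliver edges on
    the shared interface.

    ``config`` supplies material parameters, fiber angle, per-file
    overrides, file heights and QC labelling; geometry arguments passed
    explicitly win over the config's geometry block.
    """
    if config is None:
        config = SimConfig()
    if n_files < 1:
        raise TissueError("n_files must be >= 1")
    if min(file_height, total_length, min_cell_length) <= 0:
        raise TissueError("all lengths must be positive")
    if total_length < min_cell_length:
        raise TissueError("total_length must be at least min_cell_length")

    heights = (config.geometry.heights()
               if config.geometry.file_heights is not None
               and len(config.geometry.heights()) == n_files
               else [file_height] * n_files)
    rng = np.random.default_rng(seed)

    # cross-wall positions per file, snapped across adjacent files
    file_cuts: List[List[float]] = []
    for f in range(n_files):
        cuts = _file_cuts(rng, total_length, min_cell_length)
        if f > 0:
            prev = file_cuts[f - 1]
            snapped = []
            for c in cuts[1:-1]:
                near = min(prev, key=lambda p: abs(p - c))
                snapped.append(near if abs(near - c) < _SNAP_TOL else c)
            cuts = [0.0] + sorted(set(snapped)) + [total_length]
        file_cuts.append(cuts)

    tissue = Tissue(wall_defaults=_wall_defaults_from_config(config))

    # vertices on each horizontal interface y_k: union of the adjacent
    # files' cut positions
    ys = np.concatenate([[0.0], np.cumsum(heights)])
    line_vids: List[Dict[float, int]] = []
    for k in range(n_files + 1):
        xs: Set[float] = set()
        if k > 0:
            xs |= set(file_cuts[k - 1])
        if k < n_files:
            xs |= set(file_cuts[k])
        vids = {}
        for x in sorted(xs):
            fixed = abs(x - total_length) < _FIXED_TOL
            vids[x] = tissue.new_vertex((x, ys[k]), fixed=fixed)
        line_vids.append(vids)

    alpha = config.fiber_angle
    A1 = np.array([math.sin(alpha), math.cos(alpha)])
    A2 = np.array([-math.sin(alpha), math.cos(alpha)])

    for f in range(n_files):
        override = config.file_overrides.get(f, {})
        mat_kwargs = dict(mu1=config.mu1, mu2=config.mu2, mu3=config.mu3,
                          tau_w=config.tau_w, eps_star=config.eps_star)
        for k in mat_kwargs:
            if k in override:
                mat_kwargs[k] = override[k]
        seg_override = {}
        for k, v in override.items():
            if k.endswith("_axial"):
                seg_override.setdefault("axial", {})[k[:-len("_axial")]] = v
            elif k.endswith("_cross"):
                seg_override.setdefault("cross", {})[k[:-len("_cross")]] = v
        cuts = file_cuts[f]
        bot, top = line_vids[f], line_vids[f + 1]
        bot_xs, top_xs = sorted(bot), sorted(top)
        for xa, xb in zip(cuts[:-1], cuts[1:]):
            bottom = [bot[x] for x in bot_xs if xa <= x <= xb]
            topr = [top[x] for x in top_xs if xa <= x <= xb][::-1]
            boundary = bottom + topr
            cell = Cell(
                boundary=boundary,
                pressure=config.pressure,
                cell_type="QC" if (config.geometry.qc_at_tip and xa == 0.0) else "generic",
                b=0.0,
                timer=float(rng.uniform(0.0, 1.0)),
                material=InPlaneWallMaterial(A1=A1.copy(), A2=A2.copy(), **mat_kwargs),
                file_index=f,
            )
            cid = tissue.new_cell(cell)
            for vid in boundary:
                cell.ref_coords[vid] = tissue.vertices[vid].pos.copy()
            for i, j in cell.boundary_edges():
                key = edge_key(i, j)
                wclass = edge_class(tissue.vertices[j].pos - tissue.vertices[i].pos)
                ov = seg_override.get(wclass)
                cell.segments[key] = tissue.make_segment(
                    cid, key, l0=tissue.edge_length(key), wall_class=wclass, overrides=ov)
    validate_topology(tissue)
    return tissue


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def validate_topology(tissue: Tissue, check_elements: bool = True,
                      area_rtol: float = 1e-6) -> None:
    """Check the structural invariants of a tissue; raise TissueError naming
    the offending entity on the first violation found.

    ``area_rtol`` bounds the relative mismatch between the summed cell
    areas and the organ outline area. The model has no cell-cell contact
    mechanics, so extreme wall-rounding regimes can produce slight
    physical overlap of bulged boundaries; callers simulating such regimes
    may pass a looser tolerance (the mismatch is then reported as a
    warning above the strict default).
    """
    if not tissue.cells:
        raise TissueError("tissue has no cells")
    for vid, v in tissue.vertices.items():
        if not np.all(np.isfinite(v.pos)):
            raise TissueError(f"vertex {vid}: non-finite position")
    polys = []
    for cid in sorted(tissue.cells):
        cell = tissue.cells[cid]
        if len(set(cell.boundary)) != len(cell.boundary):
            raise TissueError(f"cell {cid}: repeated vertex in boundary")
        for vid in cell.boundary:
            if vid not in tissue.vertices:
                raise TissueError(f"cell {cid}: references missing vertex {vid}")
        pts = _cell_pts(cell, tissue.vertices)
        polys.append(_check_simple_ccw(pts, f"cell {cid}"))
    ec = tissue.edge_cells()
    for key, cids in ec.items():
        if len(cids) > 2:
            raise TissueError(f"edge {key}: shared by more than two cells {cids}")
        for vid in key:
            if vid not in tissue.vertices:
                raise TissueError(f"edge {key}: missing vertex {vid}")
    for cid in sorted(tissue.cells):
        cell = tissue.cells[cid]
        keys = {edge_key(i, j) for i, j in cell.boundary_edges()}
        if set(cell.segments) != keys:
            missing = keys - set(cell.segments)
            extra = set(cell.segments) - keys
            raise TissueError(
                f"cell {cid}: wall segments do not match boundary edges "
                f"(missing {sorted(missing)}, extra {sorted(extra)})")
    # no gaps/overlaps: cell areas must tile the organ outline
    total = sum(polygon_signed_area(_cell_pts(tissue.cells[c], tissue.vertices))
                for c in tissue.cells)
    outline = unary_union(polys)
    mismatch = abs(total - outline.area) / max(outline.area, 1.0)
    if mismatch > area_rtol:
        raise TissueError(
            f"cells do not tile the organ: sum of areas {total:.6f} != outline {outline.area:.6f}")
    if mismatch > 1e-6:
        import warnings

        warnings.warn(f"cell areas and organ outline differ by {mismatch:.2e} "
                      "relative (bulged boundaries overlapping slightly)")
    boundary_vids = {v for c in tissue.cells.values() for v in c.boundary}
    for cid in sorted(tissue.cells):
        cell = tissue.cells[cid]
        for vid in cell.interior:
            if vid in boundary_vids:
                raise TissueError(f"cell {cid}: interior vertex {vid} lies on a cell boundary")
            if vid not in tissue.vertices:
                raise TissueError(f"cell {cid}: interior vertex {vid} missing")
        if check_elements and cell.elements:
            area = 0.0
            for el in cell.elements:
                for vid in el.vids:
                    if vid not in tissue.vertices:
                        raise TissueError(f"cell {cid}: element references missing vertex {vid}")
                    if vid not in cell.ref_coords:
                        raise TissueError(f"cell {cid}: vertex {vid} has no reference coordinates")
                area += polygon_signed_area(tissue.positions(el.vids))
            carea = polygon_signed_area(_cell_pts(cell, tissue.vertices))
            if abs(area - carea) > 1e-8 * max(carea, 1.0):
                raise TissueError(
                    f"cell {cid}: element areas {area:.9f} do not tile the cell {carea:.9f}")


# --------------------------------------------------------------------------
# JSON I/O
# --------------------------------------------------------------------------

SCHEMA_VERSION = 1


def write_tissue(tissue: Tissue, path) -> None:
    """Serialize a tissue (including segments, triangulation and reference
    coordinates) to the versioned tissue-JSON schema."""
    doc = {
        "version": SCHEMA_VERSION,
        "wall_defaults": tissue.wall_defaults,
        "vertices": [
            {"id": vid, "x": float(v.pos[0]), "y": float(v.pos[1]), "fixed": bool(v.fixed)}
            for vid, v in sorted(tissue.vertices.items())
        ],
        "cells": [],
    }
    for cid in sorted(tissue.cells):
        cell = tissue.cells[cid]
        m = cell.material
        doc["cells"].append({
            "id": cid,
            "vertex_ids": list(cell.boundary),
            "type": cell.cell_type,
            "pressure": cell.pressure,
            "b": cell.b,
            "t_timer": cell.timer,
            "file_index": cell.file_index,
            "material": {"mu1": m.mu1, "mu2": m.mu2, "mu3": m.mu3,
                         "tau_w": m.tau_w, "eps_star": m.eps_star},
            "fibers": [m.A1.tolist(), m.A2.tolist()],
            "segments": [
                {"v1": k[0], "v2": k[1], "wall_class": s.wall_class, "mu": s.mu,
                 "tau": s.tau, "eps_star": s.eps_star, "lam": s.lam, "l0": s.l0}
                for k, s in sorted(cell.segments.items())
            ],
            "interior": sorted(cell.interior),
            "ref_coords": {str(v): X.tolist() for v, X in sorted(cell.ref_coords.items())},
            "elements": [{"vids": list(el.vids), "X": el.X.tolist()} for el in cell.elements],
        })
    Path(path).write_text(json.dumps(doc))


def read_tissue(path) -> Tissue:
    """Load and validate a tissue from the tissue-JSON schema."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise TissueError(f"{path}: not valid JSON ({exc})") from exc
    if doc.get("version") != SCHEMA_VERSION:
        raise TissueError(f"{path}: unsupported schema version {doc.get('version')!r}")
    for section in ("vertices", "cells"):
        if section not in doc or not isinstance(doc[section], list):
            raise TissueError(f"{path}: missing '{section}' list")
    if not doc["cells"]:
        raise TissueError(f"{path}: empty cell list")
    tissue = Tissue(wall_defaults=doc.get("wall_defaults"))
    for rec in doc["vertices"]:
        vid = int(rec["id"])
        if vid in tissue.vertices:
            raise TissueError(f"{path}: duplicate vertex id {vid}")
        tissue.vertices[vid] = Vertex(np.array([rec["x"], rec["y"]]), bool(rec.get("fixed", False)))
    tissue._next_vid = max(tissue.vertices, default=-1) + 1
    for rec in doc["cells"]:
        cid = int(rec["id"])
        if cid in tissue.cells:
            raise TissueError(f"{path}: duplicate cell id {cid}")
        boundary = [int(v) for v in rec["vertex_ids"]]
        for vid in boundary:
            if vid not in tissue.vertices:
                raise TissueError(f"{path}: cell {cid} references missing vertex {vid}")
        mat = rec.get("material", {})
        fibers = rec.get("fibers")
        fib_kwargs = {}
        if fibers is not None:
            fib_kwargs = {"A1": np.asarray(fibers[0], float), "A2": np.asarray(fibers[1], float)}
        cell = Cell(
            boundary=boundary,
            pressure=float(rec.get("pressure", 0.3)),
            cell_type=rec.get("type", "generic"),
            b=float(rec.get("b", 0.0)),
            timer=float(rec.get("t_timer", 0.0)),
            material=InPlaneWallMaterial(**mat, **fib_kwargs),
            file_index=rec.get("file_index"),
        )
        tissue.cells[cid] = cell
        boundary_keys = {edge_key(i, j) for i, j in cell.boundary_edges()}
        for srec in rec.get("segments", []):
            key = edge_key(int(srec["v1"]), int(srec["v2"]))
            if key not in boundary_keys:
                raise TissueError(f"{path}: cell {cid} segment {key} is not a boundary edge")
            cell.segments[key] = WallSegment(
                cell=cid, key=key, wall_class=srec["wall_class"], mu=float(srec["mu"]),
                tau=float(srec["tau"]), eps_star=float(srec["eps_star"]),
                lam=float(srec["lam"]), l0=float(srec["l0"]))
        if not cell.segments:  # build from defaults if the file omits them
            for i, j in cell.boundary_edges():
                key = edge_key(i, j)
                cell.segments[key] = tissue.make_segment(cid, key, l0=tissue.edge_length(key))
        cell.interior = {int(v) for v in rec.get("interior", [])}
        for v, X in rec.get("ref_coords", {}).items():
            cell.ref_coords[int(v)] = np.asarray(X, dtype=float)
        for vid in boundary:
            cell.ref_coords.setdefault(vid, tissue.vertices[vid].pos.copy())
        for erec in rec.get("elements", []):
            vids = tuple(int(v) for v in erec["vids"])
            for vid in vids:
                if vid not in tissue.vertices:
                    raise TissueError(f"{path}: cell {cid} element references missing vertex {vid}")
            cell.elements.append(TriElement(vids=vids, X=np.asarray(erec["X"], float)))
    tissue._next_cid = max(tissue.cells, default=-1) + 1
    validate_topology(tissue)
    return tissue
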