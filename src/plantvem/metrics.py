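"""Organ-scale readouts and calibration helpers.

The organ midline is traced by marching cross-section centroids from the
pinned (shootward) end toward the free tip: starting at the midpoint of the
fixed end, repeatedly step a half cell-height along the current direction,
cut the organ polygon with a transverse line, and take the midpoint of the
cross-section; the tip angle θ is the angle the final midline segment makes
with the organ's original (−x) growth direction, positive for upward
bending. This stays accurate for strongly bent organs (a quarter-circle
strip reads θ ≈ π/2).

The calibration relations come from the force balance of an isolated
rectangular cell of width H with transverse fibers and no yield:
H p = (2 μ1 H + 4 μ_axial) ε̇, split so the in-plane and axial walls resist
equally: μ1 = p/(4 ε̇), μ_axial = H p/(8 ε̇).
"""

from __future__ import annotations

import math
from typing import Dict, Tuple

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from .mechanics import MechanicalSystem
from .tissue import Tissue, TissueError

__all__ = [
    "organ_midline_and_tip",
    "mean_fiber_angle",
    "cell_expansion_rates",
    "calibrate_viscosities",
]


def _anchor_vertices(tissue: Tissue):
    fixed = [vid for vid, v in tissue.vertices.items() if v.fixed]
    if fixed:
        return fixed
    xmax = max(v.pos[0] for v in tissue.vertices.values())
    return [vid for vid, v in tissue.vertices.items() if abs(v.pos[0] - xmax) < 1e-6]


def _cross_section_midpoint(poly: Polygon, point: np.ndarray, direction: np.ndarray,
                            span: float):
    """Midpoint and length of the cross-section through ``point`` normal to
    ``direction``; None if the cut misses the polygon near the point."""
    n = np.array([-direction[1], direction[0]])
    line = LineString([point - span * n, point + span * n])
    cut = line.intersection(poly)
    if cut.is_empty:
        return None
    parts = getattr(cut, "geoms", [cut])
    best, best_d = None, math.inf
    p = Point(point)
    for part in parts:
        if part.geom_type != "LineString" or part.length == 0:
            continue
        d = part.distance(p)
        if d < best_d:
            best, best_d = part, d
    if best is None or best_d > 1e-6 * max(span, 1.0):
        return None
    mid = best.interpolate(0.5, normalized=True)
    return np.array([mid.x, mid.y]), best.length


def organ_midline_and_tip(tissue: Tissue) -> Tuple[np.ndarray, float, float]:
    """Midline polyline, its length L [μm], and the tip angle θ [rad].

    θ is measured at the free (rootward) end: the angle between the last
    midline segment and the organ's −x growth direction, positive when the
    tip points upward (+y). A straight organ along x reads θ = 0.
    """
    poly = tissue.organ_polygon()
    anchors = _anchor_vertices(tissue)
    if not anchors:
        raise TissueError("no pinned end found to anchor the midline")
    apos = np.array([tissue.vertices[v].pos for v in anchors])
    m0 = apos.mean(axis=0)
    cap = float(np.linalg.norm(apos.max(axis=0) - apos.min(axis=0)))
    minx, miny, maxx, maxy = poly.bounds
    span = 4.0 * math.hypot(maxx - minx, maxy - miny)
    step = max(cap / 2.0, 1e-3)

    centroid = np.array([poly.centroid.x, poly.centroid.y])
    d = centroid - m0
    nrm = np.linalg.norm(d)
    d = np.array([-1.0, 0.0]) if nrm == 0 else d / nrm
    pts = [m0]
    max_steps = int(20 * (poly.length / step + 10))
    for _ in range(max_steps):
        advanced = False
        for frac in (1.0, 0.5, 0.25, 0.125):
            cand = pts[-1] + frac * step * d
            if not poly.contains(Point(cand)):
                continue
            sec = _cross_section_midpoint(poly, cand, d, span)
            if sec is None:
                continue
            mid, _ = sec
            new_d = mid - pts[-1]
            n = np.linalg.norm(new_d)
            # reject stalls and near-reversals (cross-section mis-picks)
            if n < 0.05 * frac * step or (new_d / n) @ d < 0.5:
                continue
            pts.append(mid)
            d = new_d / n
            advanced = True
            break
        if not advanced:
            break
    # extend along the current direction to the organ boundary (the free
    # tip face); only accept a forward intersection
    ray = LineString([pts[-1], pts[-1] + 3.0 * step * d])
    hit = ray.intersection(poly.exterior)
    if not hit.is_empty:
        cands = []
        for g in getattr(hit, "geoms", [hit]):
            coords = [np.asarray(c) for c in getattr(g, "coords", [])]
            cands.extend(coords)
        forward = [c for c in cands if (c - pts[-1]) @ d > 0]
        if forward:
            pts.append(min(forward, key=lambda c: np.linalg.norm(c - pts[-1])))
    polyline = np.array(pts)
    if len(polyline) < 2:
        raise TissueError("midline needs at least 2 stations")
    L = float(np.sum(np.linalg.norm(np.diff(polyline, axis=0), axis=1)))
    # tip direction: chord ending at the tip spanning at least one step
    # (robust to a short boundary-extension stub, short enough not to lag
    # the tangent on a bent organ)
    k = len(polyline) - 2
    for k in range(len(polyline) - 2, -1, -1):
        if np.linalg.norm(polyline[-1] - polyline[k]) >= 0.8 * step:
            break
    tip = polyline[-1] - polyline[k]
    theta = math.atan2(tip[1], -tip[0])
    return polyline, L, theta


def mean_fiber_angle(tissue: Tissue) -> float:
    """Area-weighted mean angle φ ∈ [0, π/2] between the current
    microfibril directions (both families) and the y-axis."""
    system = MechanicalSystem(tissue)
    if not len(system.tri):
        return 0.0
    a1, a2, areas = system.current_fibers()
    angles = np.concatenate([
        np.arccos(np.clip(np.abs(a1[:, 1]), 0.0, 1.0)),
        np.arccos(np.clip(np.abs(a2[:, 1]), 0.0, 1.0)),
    ])
    w = np.concatenate([areas, areas])
    return float(np.sum(angles * w) / np.sum(w))


def cell_expansion_rates(tissue: Tissue,
                         velocities: Dict[int, np.ndarray]) -> Dict[int, float]:
    """Relative area growth rate (dA/dt)/A [hr⁻¹] per cell, from the
    time-derivative of the shoelace formula over the boundary vertices."""
    rates = {}
    for cid in sorted(tissue.cells):
        cell = tissue.cells[cid]
        x = tissue.positions(cell.boundary)
        v = np.array([velocities.get(vid, np.zeros(2)) for vid in cell.boundary])
        xn = np.roll(x, -1, axis=0)
        vn = np.roll(v, -1, axis=0)
        area = 0.5 * np.sum(x[:, 0] * xn[:, 1] - xn[:, 0] * x[:, 1])
        dadt = 0.5 * np.sum(v[:, 0] * xn[:, 1] + x[:, 0] * vn[:, 1]
                            - vn[:, 0] * x[:, 1] - xn[:, 0] * v[:, 1])
        rates[cid] = float(dadt / area)
    return rates


def calibrate_viscosities(H: float, p: float, eps_target: float) -> Tuple[float, float]:
    """Viscosities giving an isolated cell of width H [μm] under pressure
    p [MPa] a steady elongation rate eps_target [hr⁻¹], with in-plane and
    axial walls contributing equally:

        μ1 = p/(4 ε̇)  [MPa hr],   μ_axial = H p/(8 ε̇)  [MPa μm hr]

    The pair inverts the balance H p = (2 μ1 H + 4 μ_axial) ε̇ exactly.
    """
    if eps_target <= 0:
        raise ValueError("target strain rate must be positive")
    return p / (4.0 * eps_target), H * p / (8.0 * eps_target)
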