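"""Growth-inhibitor transport, yield-stress modulation and cell division.

The inhibitor is produced in quiescent-center (QC) cells, diffuses between
adjacent cells through their shared walls (permeability P_b, flux
proportional to the shared wall length), and decays at rate λ_b:

    db_m/dt = (1/A_m) Σ_n P_b S_{m,n} (b_n − b_m) − λ_b b_m + α_m

with α_m = α_b in QC cells and 0 elsewhere. The concentration modulates
wall yield stresses through a Hill function of b_m/k_b, so walls near the
QC stay stiff and walls further along the axis yield and elongate.

Cells divide perpendicular to the direction of maximum strain rate: the
area-weighted mean rate-of-strain tensor over the cell's elements is
diagonalized, and the new wall passes through the cell centroid normal to
the dominant eigenvector. Division timing uses a per-cell timer advancing
at rate β; a cell divides once its timer exceeds 1, provided its inhibitor
concentration exceeds k_b (the meristem proxy).
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .config import DivisionConfig, RegulationConfig
from .meshing import _retriangulate_cell
from .tissue import (
    Cell,
    Tissue,
    TissueError,
    cell_area,
    cell_centroid,
    edge_key,
    polygon_signed_area,
)

__all__ = [
    "shared_wall_lengths",
    "inhibitor_rhs",
    "step_inhibitor",
    "update_yield_stresses",
    "division_direction",
    "split_cell",
    "attempt_divisions",
]

#: a division wall passing within this distance [μm] of an existing vertex
#: reuses that vertex instead of creating a near-duplicate
_VERTEX_SNAP = 1.0e-3


def shared_wall_lengths(tissue: Tissue) -> Dict[Tuple[int, int], float]:
    """Total shared-wall length S_{m,n} [μm] per adjacent cell pair (m < n)."""
    out: Dict[Tuple[int, int], float] = {}
    for key, cids in tissue.edge_cells().items():
        if len(cids) == 2:
            pair = (min(cids), max(cids))
            out[pair] = out.get(pair, 0.0) + tissue.edge_length(key)
    return out


def _areas(tissue: Tissue) -> Dict[int, float]:
    areas = {}
    for cid in sorted(tissue.cells):
        a = cell_area(tissue.cells[cid], tissue.vertices)
        if a <= 0:
            raise TissueError(f"cell {cid}: non-positive area {a}")
        areas[cid] = a
    return areas


def inhibitor_rhs(tissue: Tissue, params: RegulationConfig) -> Dict[int, float]:
    """Instantaneous db_m/dt [nM hr⁻¹] per cell."""
    areas = _areas(tissue)
    rates = {}
    S = shared_wall_lengths(tissue)
    for cid in sorted(tissue.cells):
        cell = tissue.cells[cid]
        alpha = params.alpha_b if cell.cell_type == "QC" else 0.0
        rates[cid] = -params.lambda_b * cell.b + alpha
    for (m, n), s in S.items():
        flux = params.P_b * s * (tissue.cells[n].b - tissue.cells[m].b)
        rates[m] += flux / areas[m]
        rates[n] -= flux / areas[n]
    return rates


def step_inhibitor(tissue: Tissue, dt: float,
                   params: RegulationConfig) -> Tissue:
    """Advance the inhibitor ODE system by one implicit-Euler step with the
    geometry frozen. The system matrix is an M-matrix, so concentrations
    stay non-negative."""
    cids = sorted(tissue.cells)
    idx = {cid: k for k, cid in enumerate(cids)}
    n = len(cids)
    areas = _areas(tissue)
    b = np.array([tissue.cells[c].b for c in cids])
    alpha = np.array([params.alpha_b if tissue.cells[c].cell_type == "QC" else 0.0
                      for c in cids])
    rows, cols, vals = [], [], []
    diag = np.full(n, -params.lambda_b)
    for (m, nn), s in sorted(shared_wall_lengths(tissue).items()):
        km, kn = idx[m], idx[nn]
        cm = params.P_b * s / areas[m]
        cn = params.P_b * s / areas[nn]
        rows += [km, kn]
        cols += [kn, km]
        vals += [cm, cn]
        diag[km] -= cm
        diag[kn] -= cn
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    K = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    A = sp.eye(n, format="csr") - dt * K
    b_new = spsolve(A.tocsc(), b + dt * alpha) if n > 1 else \
        np.atleast_1d((b + dt * alpha) / A.toarray()[0, 0])
    for cid, val in zip(cids, b_new):
        tissue.cells[cid].b = float(max(val, 0.0))
    return tissue


def update_yield_stresses(tissue: Tissue, params: RegulationConfig) -> Tissue:
    """Set τ_w = τ_w0 (1 + (b/k_b)^n) for each cell's in-plane wall and
    τ = τ_axial0 (1 + (b/k_b)^n) for its axial wall segments; cross-wall
    yield stresses are untouched."""
    if params.k_b <= 0:
        raise TissueError("k_b must be positive")
    for cid in sorted(tissue.cells):
        cell = tissue.cells[cid]
        factor = 1.0 + (cell.b / params.k_b) ** params.n_b
        cell.material.tau_w = params.tau_w0 * factor
        for seg in cell.segments.values():
            if seg.wall_class == "axial":
                seg.tau = params.tau_axial0 * factor
    return tissue


# --------------------------------------------------------------------------
# division
# --------------------------------------------------------------------------

def _polygon_principal_axis(pts: np.ndarray) -> np.ndarray:
    """Unit direction of the polygon's longest principal geometric axis
    (eigenvector of the area-moment covariance)."""
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    sxx = np.sum((x * x + x * xn + xn * xn) * cross) / 12.0
    syy = np.sum((y * y + y * yn + yn * yn) * cross) / 12.0
    sxy = np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross) / 24.0
    C = np.array([[sxx / a - cx * cx, sxy / a - cx * cy],
                  [sxy / a - cx * cy, syy / a - cy * cy]])
    w, V = np.linalg.eigh(C)
    return _canonical(V[:, int(np.argmax(w))])


def _canonical(d: np.ndarray) -> np.ndarray:
    d = d / np.linalg.norm(d)
    if d[0] < 0 or (abs(d[0]) < 1e-12 and d[1] < 0):
        d = -d
    return d


def division_direction(tissue: Tissue, cid: int,
                       velocities: Dict[int, np.ndarray]) -> np.ndarray:
    """Direction of maximum strain rate of a cell (unit vector): the
    dominant eigenvector of the area-weighted mean rate-of-strain tensor
    over the cell's elements. The division wall is normal to this
    direction. Degenerate (isotropic or zero) strain rate falls back to
    the cell's longest principal geometric axis."""
    cell = tissue.cells[cid]
    if not cell.elements:
        raise TissueError(f"cell {cid}: no elements; triangulate before division")
    Esum = np.zeros((2, 2))
    wsum = 0.0
    for el in cell.elements:
        x = tissue.positions(el.vids)
        v = np.array([velocities.get(vid, np.zeros(2)) for vid in el.vids])
        F2 = np.stack([x[1] - x[0], x[2] - x[0]], axis=-1)
        det = float(np.linalg.det(F2))
        if det <= 0:
            continue
        Vg = np.stack([v[1] - v[0], v[2] - v[0]], axis=-1)
        grad_v = Vg @ np.linalg.inv(F2)
        E = 0.5 * (grad_v + grad_v.T)
        area = det / 2.0
        Esum += area * E
        wsum += area
    Emean = Esum / max(wsum, 1e-300)
    w, V = np.linalg.eigh(Emean)
    scale = max(np.abs(w).max(), 1e-300)
    if np.abs(w).max() < 1e-12 or (w[1] - w[0]) < 1e-9 * scale:
        return _polygon_principal_axis(tissue.positions(cell.boundary))
    return _canonical(V[:, 1])


def _line_polygon_crossings(tissue: Tissue, cell: Cell, c: np.ndarray,
                            w: np.ndarray) -> List[Tuple[float, int, float]]:
    """Crossings (s, edge_position, u) of the line c + s·w with the cell
    boundary; u is the position along the directed edge in [0, 1)."""
    out = []
    edges = cell.boundary_edges()
    for k, (i, j) in enumerate(edges):
        a = tissue.vertices[i].pos
        b = tissue.vertices[j].pos
        e = b - a
        det = w[0] * (-e[1]) - (-e[0]) * w[1]
        if abs(det) < 1e-14 * max(1.0, np.linalg.norm(e)):
            continue
        rhs = a - c
        s = (rhs[0] * (-e[1]) - (-e[0]) * rhs[1]) / det
        u = (w[0] * rhs[1] - w[1] * rhs[0]) / det
        if -1e-12 <= u < 1.0 - 1e-12:
            out.append((s, k, min(max(u, 0.0), 1.0)))
    return out


def split_cell(tissue: Tissue, cid: int, growth_dir: np.ndarray,
               quality: Tuple[float, float] = (20.0, 250.0)) -> Tuple[int, int]:
    """Divide a cell by a straight wall through its centroid perpendicular
    to ``growth_dir``.

    Two boundary edges are subdivided at the intersection points (reusing
    an existing vertex if the wall passes within 10⁻³ μm of it); neighbor
    polygons sharing those edges gain the vertex and are retriangulated.
    Both daughters inherit the parent's pressure, tissue type, material,
    fiber directions and inhibitor concentration; timers reset to 0. The
    new wall carries one wall segment per daughter with the tissue's
    per-class default parameters and rest length equal to its current
    length. Returns the two daughter cell ids.
    """
    cell = tissue.cells[cid]
    c = cell_centroid(cell, tissue.vertices)
    g = np.asarray(growth_dir, dtype=float)
    g = g / np.linalg.norm(g)
    wall_dir = np.array([-g[1], g[0]])
    crossings = _line_polygon_crossings(tissue, cell, c, wall_dir)
    neg = [cr for cr in crossings if cr[0] < 0]
    pos = [cr for cr in crossings if cr[0] > 0]
    if not neg or not pos:
        raise TissueError(f"cell {cid}: division line does not cross the boundary twice")
    picks = [max(neg, key=lambda cr: cr[0]), min(pos, key=lambda cr: cr[0])]

    # resolve edge indices to vertex-id pairs before any subdivision
    # mutates the boundary list
    edges0 = cell.boundary_edges()
    picks = [(edges0[k][0], edges0[k][1], u) for _, k, u in picks]
    wall_vids = []
    affected_neighbors = set()
    for i, j, u in picks:
        a = tissue.vertices[i].pos
        b = tissue.vertices[j].pos
        elen = float(np.linalg.norm(b - a))
        if u * elen < _VERTEX_SNAP:
            wall_vids.append(i)
            continue
        if (1.0 - u) * elen < _VERTEX_SNAP:
            wall_vids.append(j)
            continue
        key = edge_key(i, j)
        frac = u if key == (i, j) else 1.0 - u
        incident_before = tissue.edge_cells()[key]
        new = tissue.subdivide_edge(key, [frac])
        wall_vids.append(new[0])
        affected_neighbors.update(set(incident_before) - {cid})
    p_vid, q_vid = wall_vids
    if p_vid == q_vid:
        raise TissueError(f"cell {cid}: degenerate division (wall endpoints coincide)")

    boundary = cell.boundary
    ip = boundary.index(p_vid)
    iq = boundary.index(q_vid)
    if ip < iq:
        chain_a = boundary[ip:iq + 1]
        chain_b = boundary[iq:] + boundary[:ip + 1]
    else:
        chain_a = boundary[ip:] + boundary[:iq + 1]
        chain_b = boundary[iq:ip + 1]
    if len(chain_a) < 3 or len(chain_b) < 3:
        raise TissueError(f"cell {cid}: division chains too short")

    old_elements = list(cell.elements)
    daughters = []
    for chain in (chain_a, chain_b):
        mat = cell.material
        from .constitutive import InPlaneWallMaterial

        d = Cell(
            boundary=list(chain),
            pressure=cell.pressure,
            cell_type=cell.cell_type,
            b=cell.b,
            timer=0.0,
            material=InPlaneWallMaterial(
                mu1=mat.mu1, mu2=mat.mu2, mu3=mat.mu3, tau_w=mat.tau_w,
                eps_star=mat.eps_star, A1=mat.A1.copy(), A2=mat.A2.copy()),
            file_index=cell.file_index,
        )
        did = tissue.new_cell(d)
        for vid in chain:
            d.ref_coords[vid] = cell.ref_coords[vid].copy()
        for i, j in d.boundary_edges():
            key = edge_key(i, j)
            if key == edge_key(p_vid, q_vid):
                d.segments[key] = tissue.make_segment(did, key, l0=tissue.edge_length(key))
            else:
                src = cell.segments[key]
                d.segments[key] = tissue.make_segment(
                    did, key, l0=src.l0, wall_class=src.wall_class,
                    overrides={"mu": src.mu, "tau": src.tau,
                               "eps_star": src.eps_star, "lam": src.lam})
        # interpolate from the parent's old mesh when the daughters are meshed
        d.elements = old_elements
        daughters.append(did)

    for did in daughters:
        _retriangulate_cell(tissue, did, quality)
    for nid in affected_neighbors:
        _retriangulate_cell(tissue, nid, quality)
    cell.elements = []  # parent's interior vertices removed with the cell
    tissue.remove_cell(cid)
    return daughters[0], daughters[1]


def attempt_divisions(tissue: Tissue, dt: float, rng,
                      division: DivisionConfig,
                      regulation: RegulationConfig,
                      velocities: Optional[Dict[int, np.ndarray]] = None,
                      quality: Tuple[float, float] = (20.0, 250.0)) -> List[dict]:
    """Advance division timers by β·dt for every cell, then split each
    eligible cell (timer > 1 and, when required, b > k_b) through its
    centroid perpendicular to the maximum-strain-rate direction. At most
    one division per cell per timestep; eligible cells divide in
    deterministic cell-id order. Returns the division events."""
    velocities = velocities or {}
    for cid in sorted(tissue.cells):
        tissue.cells[cid].timer += division.beta * dt
    eligible = [cid for cid in sorted(tissue.cells)
                if tissue.cells[cid].timer > 1.0
                and (not division.require_inhibitor
                     or tissue.cells[cid].b > regulation.k_b)]
    events = []
    for cid in eligible:
        if cid not in tissue.cells:
            continue
        g = division_direction(tissue, cid, velocities)
        d1, d2 = split_cell(tissue, cid, g, quality=quality)
        events.append({"parent": cid, "daughters": [d1, d2],
                       "direction": [float(g[0]), float(g[1])]})
    return events
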