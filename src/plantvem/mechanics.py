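"""Element kinematics and vertex-force assembly.

The tissue's mechanical state is the position of every vertex; inertia is
negligible at cell scale, so at each instant the total force on each free
vertex vanishes. Three contributions are assembled:

* turgor pressure: each anticlockwise boundary edge (i → j) of a cell with
  pressure p contributes (p/2) R(x_j − x_i) to both endpoints, where R is
  rotation by −π/2 (the outward normal times the edge length);
* in-plane wall elements: the viscous stress σ = σ_y + σ_a (no elastic
  part) is evaluated from the rate-of-strain tensor of each linear triangle
  and converted to edge tractions f_pq = −σ n_pq |x_q − x_p|, distributed
  half-and-half to the edge endpoints;
* out-of-plane wall segments: the tensile stress resultant of each segment
  pulls its two endpoints together along the edge.

The residual is a function of the vertex velocities v (through the
rate-of-strain) and, for implicit time stepping, of the end-of-step
positions x = x0 + Δt v. Rows of pinned (fixed) vertices are replaced by
the constraint v = 0.

:class:`MechanicalSystem` compiles a tissue into flat arrays so the
residual, its sparsity pattern, and per-element strain-rate queries are all
vectorized; the module-level functions give the same physics pointwise for
a single element, cell or segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from . import constitutive as cst
from .constitutive import InPlaneWallMaterial
from .tissue import Cell, Tissue, TriElement, TissueError, WallSegment, edge_key

__all__ = [
    "rotate_minus_90",
    "shape_gradients",
    "Kinematics",
    "element_kinematics",
    "element_vertex_forces",
    "pressure_vertex_forces",
    "wall_segment_vertex_forces",
    "MechanicalSystem",
    "assemble_residual",
]

#: current triangle areas below this [μm²] are rejected as degenerate
_DEGENERATE_AREA = 1.0e-12


def rotate_minus_90(d: np.ndarray) -> np.ndarray:
    """R(x) = x × k: in-plane rotation by −π/2 (outward normal direction of
    an anticlockwise-traversed edge, scaled by its length)."""
    d = np.asarray(d, dtype=float)
    return np.stack([d[..., 1], -d[..., 0]], axis=-1)


def shape_gradients() -> np.ndarray:
    """Gradients N_{I,B} of the linear shape functions N1 = 1−ξ1−ξ2,
    N2 = ξ1, N3 = ξ2 on the unit triangle: rows (−1,−1), (1,0), (0,1)."""
    return np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])


@dataclass
class Kinematics:
    """Deformation and rate-of-strain state of one triangular element."""

    F1: np.ndarray       # reference map gradient (2,2)
    F2: np.ndarray       # current map gradient (2,2)
    F: np.ndarray        # deformation gradient F2 F1⁻¹
    a1: np.ndarray       # current fiber directions (unit)
    a2: np.ndarray
    grad_v: np.ndarray   # spatial velocity gradient (2,2)
    E: np.ndarray        # rate of strain (symmetric 2,2)


def _as_tri_arrays(element: TriElement, mapping) -> np.ndarray:
    if isinstance(mapping, Mapping):
        return np.array([np.asarray(mapping[v], dtype=float) for v in element.vids])
    arr = np.asarray(mapping, dtype=float)
    if arr.shape != (3, 2):
        raise ValueError("expected a (3, 2) array or a mapping keyed by vertex id")
    return arr


def element_kinematics(element: TriElement, current_positions, velocities,
                       A1=None, A2=None) -> Kinematics:
    """Kinematic quantities of one element.

    ``current_positions``/``velocities`` are (3, 2) arrays in vertex order,
    or mappings from vertex id. ``A1``/``A2`` are the reference fiber
    directions (default transverse, along y).
    """
    x = _as_tri_arrays(element, current_positions)
    v = _as_tri_arrays(element, velocities)
    X = element.X
    F1 = np.stack([X[1] - X[0], X[2] - X[0]], axis=-1)
    F2 = np.stack([x[1] - x[0], x[2] - x[0]], axis=-1)
    det1 = float(np.linalg.det(F1))
    det2 = float(np.linalg.det(F2))
    if det1 <= 0:
        raise TissueError(f"element {element.vids}: reference triangle not positively oriented")
    if det2 / 2.0 < _DEGENERATE_AREA:
        raise TissueError(f"element {element.vids}: degenerate current triangle "
                          f"(area {det2 / 2.0:.3e} μm²)")
    F = F2 @ np.linalg.inv(F1)
    A1 = np.array([0.0, 1.0]) if A1 is None else np.asarray(A1, dtype=float)
    A2 = np.array([0.0, 1.0]) if A2 is None else np.asarray(A2, dtype=float)
    a1 = F @ A1
    a2 = F @ A2
    a1 = a1 / np.linalg.norm(a1)
    a2 = a2 / np.linalg.norm(a2)
    Vg = np.stack([v[1] - v[0], v[2] - v[0]], axis=-1)
    grad_v = Vg @ np.linalg.inv(F2)
    E = 0.5 * (grad_v + grad_v.T)
    return Kinematics(F1=F1, F2=F2, F=F, a1=a1, a2=a2, grad_v=grad_v, E=E)


def element_vertex_forces(element: TriElement, kin: Kinematics,
                          material: InPlaneWallMaterial,
                          current_positions=None) -> np.ndarray:
    """Forces (3, 2) [MPa μm] on the element's three vertices from the
    in-plane viscous stress (no elastic part)."""
    sigma = (cst.stress_isotropic_viscous(kin.E, material)
             + cst.stress_anisotropic(kin.E, kin.a1, kin.a2, material.mu2, material.mu3))
    if current_positions is None:
        # reconstruct from F2 (edge vectors are all the traction needs)
        x1 = np.zeros(2)
        x2 = kin.F2[:, 0]
        x3 = kin.F2[:, 1]
    else:
        x1, x2, x3 = _as_tri_arrays(element, current_positions)
    f12 = -sigma @ rotate_minus_90(x2 - x1)
    f23 = -sigma @ rotate_minus_90(x3 - x2)
    f31 = -sigma @ rotate_minus_90(x1 - x3)
    return np.array([0.5 * (f12 + f31), 0.5 * (f23 + f12), 0.5 * (f31 + f23)])


def pressure_vertex_forces(cell: Cell, vertices) -> Dict[int, np.ndarray]:
    """Turgor forces on the cell's boundary vertices: each anticlockwise
    edge (i → j) contributes (p/2) R(x_j − x_i) to both endpoints. Interior
    (Steiner) vertices receive no pressure force."""
    pos = {v: (vertices[v].pos if hasattr(vertices[v], "pos") else np.asarray(vertices[v]))
           for v in cell.boundary}
    pts = np.array([pos[v] for v in cell.boundary])
    from .tissue import polygon_signed_area
    if polygon_signed_area(pts) <= 0:
        raise TissueError("pressure forces require an anticlockwise boundary")
    forces = {v: np.zeros(2) for v in cell.boundary}
    half_p = 0.5 * cell.pressure
    for i, j in cell.boundary_edges():
        f = half_p * rotate_minus_90(pos[j] - pos[i])
        forces[i] = forces[i] + f
        forces[j] = forces[j] + f
    return forces


def wall_segment_vertex_forces(segment: WallSegment, x_i, x_j, v_i, v_j
                               ) -> Tuple[np.ndarray, np.ndarray]:
    """Forces on the two endpoints of an out-of-plane wall segment:
    +σ (x_j − x_i)/l on vertex i and the negative on vertex j, so positive
    (tensile) stress pulls the endpoints together."""
    x_i, x_j = np.asarray(x_i, float), np.asarray(x_j, float)
    v_i, v_j = np.asarray(v_i, float), np.asarray(v_j, float)
    d = x_j - x_i
    l = float(np.linalg.norm(d))
    if l <= 1e-12:
        raise TissueError(f"wall segment {segment.key}: coincident endpoints")
    eps_e = float(d @ (v_j - v_i)) / l**2
    sigma = cst.wall_segment_stress(eps_e, l, segment)
    f = sigma * d / l
    return f, -f


# --------------------------------------------------------------------------
# compiled assembly
# --------------------------------------------------------------------------

class MechanicalSystem:
    """Flat-array view of a tissue for vectorized residual evaluation.

    The DOF vector stacks (vx, vy) for every vertex in sorted-id order.
    ``x0`` holds the configuration about which the residual is evaluated;
    with a timestep dt the residual is evaluated at x = x0 + dt·v (backward
    Euler), with dt = 0 it is the instantaneous force balance at x0.
    """

    def __init__(self, tissue: Tissue):
        self.tissue = tissue
        self.vids = sorted(tissue.vertices)
        self.index = {vid: k for k, vid in enumerate(self.vids)}
        self.n = len(self.vids)
        self.x0 = np.array([tissue.vertices[v].pos for v in self.vids])
        self.fixed = np.array([tissue.vertices[v].fixed for v in self.vids])

        tri, Xref, elcell = [], [], []
        mu1, mu2, mu3, tau_w, eps_star = [], [], [], [], []
        A1, A2 = [], []
        self.cell_ids = sorted(tissue.cells)
        self.cell_index = {cid: k for k, cid in enumerate(self.cell_ids)}
        for cid in self.cell_ids:
            cell = tissue.cells[cid]
            m = cell.material
            for el in cell.elements:
                tri.append([self.index[v] for v in el.vids])
                Xref.append(el.X)
                elcell.append(self.cell_index[cid])
                mu1.append(m.mu1); mu2.append(m.mu2); mu3.append(m.mu3)
                tau_w.append(m.tau_w); eps_star.append(m.eps_star)
                A1.append(m.A1); A2.append(m.A2)
        self.tri = np.asarray(tri, dtype=int).reshape(-1, 3)
        self.Xref = np.asarray(Xref, dtype=float).reshape(-1, 3, 2)
        self.el_cell = np.asarray(elcell, dtype=int)
        self.mu1 = np.asarray(mu1); self.mu2 = np.asarray(mu2); self.mu3 = np.asarray(mu3)
        self.tau_w = np.asarray(tau_w); self.eps_star = np.asarray(eps_star)
        self.A1 = np.asarray(A1, dtype=float).reshape(-1, 2)
        self.A2 = np.asarray(A2, dtype=float).reshape(-1, 2)
        if len(self.tri):
            F1 = np.stack([self.Xref[:, 1] - self.Xref[:, 0],
                           self.Xref[:, 2] - self.Xref[:, 0]], axis=-1)
            det1 = F1[:, 0, 0] * F1[:, 1, 1] - F1[:, 0, 1] * F1[:, 1, 0]
            if np.any(det1 <= 0):
                bad = int(np.argmin(det1))
                raise TissueError(
                    f"element {tuple(self.vids[k] for k in self.tri[bad])}: "
                    "reference triangle not positively oriented")
            self.invF1 = _inv2(F1, det1)
        else:
            self.invF1 = np.empty((0, 2, 2))

        si, sj = [], []
        smu, stau, seps, slam, sl0 = [], [], [], [], []
        self._seg_refs = []
        for cid in self.cell_ids:
            cell = tissue.cells[cid]
            for key in sorted(cell.segments):
                s = cell.segments[key]
                si.append(self.index[key[0]]); sj.append(self.index[key[1]])
                smu.append(s.mu); stau.append(s.tau); seps.append(s.eps_star)
                slam.append(s.lam); sl0.append(s.l0)
                self._seg_refs.append(s)
        self.seg_i = np.asarray(si, dtype=int); self.seg_j = np.asarray(sj, dtype=int)
        self.seg_mu = np.asarray(smu); self.seg_tau = np.asarray(stau)
        self.seg_eps = np.asarray(seps); self.seg_lam = np.asarray(slam)
        self.seg_l0 = np.asarray(sl0)

        pi_, pj_, ph = [], [], []
        for cid in self.cell_ids:
            cell = tissue.cells[cid]
            for i, j in cell.boundary_edges():
                pi_.append(self.index[i]); pj_.append(self.index[j])
                ph.append(0.5 * cell.pressure)
        self.pres_i = np.asarray(pi_, dtype=int)
        self.pres_j = np.asarray(pj_, dtype=int)
        self.pres_half = np.asarray(ph)

        self._pattern: Optional[sp.csr_matrix] = None

    # -- updates ----------------------------------------------------------
    def sync_from_tissue(self) -> None:
        """Refresh positions and material parameters (same topology)."""
        self.x0 = np.array([self.tissue.vertices[v].pos for v in self.vids])
        k = 0
        for cid in self.cell_ids:
            cell = self.tissue.cells[cid]
            m = cell.material
            n_el = len(cell.elements)
            self.tau_w[k:k + n_el] = m.tau_w
            self.mu1[k:k + n_el] = m.mu1
            k += n_el
        for idx, s in enumerate(self._seg_refs):
            self.seg_tau[idx] = s.tau
            self.seg_mu[idx] = s.mu

    def write_positions(self, x: np.ndarray) -> None:
        self.x0 = np.asarray(x, dtype=float).reshape(self.n, 2)
        for k, vid in enumerate(self.vids):
            self.tissue.vertices[vid].pos = self.x0[k].copy()

    def velocity_dict(self, v: np.ndarray) -> Dict[int, np.ndarray]:
        vv = np.asarray(v, dtype=float).reshape(self.n, 2)
        return {vid: vv[k].copy() for k, vid in enumerate(self.vids)}

    # -- evaluation -------------------------------------------------------
    def _kinematics(self, x: np.ndarray, vv: np.ndarray):
        x1, x2, x3 = x[self.tri[:, 0]], x[self.tri[:, 1]], x[self.tri[:, 2]]
        F2 = np.stack([x2 - x1, x3 - x1], axis=-1)
        det2 = F2[:, 0, 0] * F2[:, 1, 1] - F2[:, 0, 1] * F2[:, 1, 0]
        if np.any(det2 / 2.0 < _DEGENERATE_AREA):
            bad = int(np.argmin(det2))
            raise TissueError(
                f"element {tuple(self.vids[k] for k in self.tri[bad])}: "
                f"degenerate current triangle (area {det2[bad] / 2.0:.3e} μm²)")
        invF2 = _inv2(F2, det2)
        v1, v2, v3 = vv[self.tri[:, 0]], vv[self.tri[:, 1]], vv[self.tri[:, 2]]
        Vg = np.stack([v2 - v1, v3 - v1], axis=-1)
        grad_v = Vg @ invF2
        E = 0.5 * (grad_v + np.swapaxes(grad_v, -1, -2))
        return x1, x2, x3, F2, det2, invF2, E

    def _stress(self, F2, E):
        eps = np.sqrt(np.sum(E * E, axis=(-2, -1)))
        mu_eff = self.mu1 + cst.papanastasiou_viscosity(eps, self.tau_w, self.eps_star)
        sigma = 2.0 * mu_eff[:, None, None] * E
        F = F2 @ self.invF1
        for A, in ((self.A1,), (self.A2,)):
            a = np.einsum("eij,ej->ei", F, A)
            a /= np.linalg.norm(a, axis=-1, keepdims=True)
            Ea = np.einsum("eij,ej->ei", E, a)
            aEa = np.einsum("ei,ei->e", a, Ea)
            sigma += self.mu2[:, None, None] * aEa[:, None, None] * (a[:, :, None] * a[:, None, :])
            sigma += self.mu3[:, None, None] * (a[:, :, None] * Ea[:, None, :]
                                                + Ea[:, :, None] * a[:, None, :])
        return sigma

    def residual(self, v: np.ndarray, dt: float = 0.0) -> np.ndarray:
        """Total force on each vertex [MPa μm], evaluated at x = x0 + dt·v;
        rows of fixed vertices hold the constraint value v."""
        v = np.asarray(v, dtype=float)
        if v.size != 2 * self.n:
            raise TissueError(f"velocity vector has size {v.size}, expected {2 * self.n}")
        vv = v.reshape(self.n, 2).copy()
        vfix = vv[self.fixed].copy()
        vv[self.fixed] = 0.0
        x = self.x0 + dt * vv
        f = np.zeros((self.n, 2))

        if len(self.tri):
            x1, x2, x3, F2, det2, invF2, E = self._kinematics(x, vv)
            sigma = self._stress(F2, E)
            r12 = np.stack([(x2 - x1)[:, 1], -(x2 - x1)[:, 0]], axis=-1)
            r23 = np.stack([(x3 - x2)[:, 1], -(x3 - x2)[:, 0]], axis=-1)
            r31 = np.stack([(x1 - x3)[:, 1], -(x1 - x3)[:, 0]], axis=-1)
            f12 = -np.einsum("eij,ej->ei", sigma, r12)
            f23 = -np.einsum("eij,ej->ei", sigma, r23)
            f31 = -np.einsum("eij,ej->ei", sigma, r31)
            np.add.at(f, self.tri[:, 0], 0.5 * (f12 + f31))
            np.add.at(f, self.tri[:, 1], 0.5 * (f23 + f12))
            np.add.at(f, self.tri[:, 2], 0.5 * (f31 + f23))

        if len(self.seg_i):
            d = x[self.seg_j] - x[self.seg_i]
            l = np.linalg.norm(d, axis=-1)
            if np.any(l <= 1e-12):
                bad = int(np.argmin(l))
                raise TissueError(
                    f"wall segment {self._seg_refs[bad].key}: coincident endpoints")
            eps_e = np.einsum("si,si->s", d, vv[self.seg_j] - vv[self.seg_i]) / l**2
            yield_term = cst.papanastasiou_viscosity(np.abs(eps_e), self.seg_tau, self.seg_eps)
            sig = (2.0 * (self.seg_mu * eps_e + yield_term * eps_e)
                   + self.seg_lam * (l / self.seg_l0 - 1.0))
            fseg = (sig / l)[:, None] * d
            np.add.at(f, self.seg_i, fseg)
            np.add.at(f, self.seg_j, -fseg)

        if len(self.pres_i):
            d = x[self.pres_j] - x[self.pres_i]
            fp = self.pres_half[:, None] * np.stack([d[:, 1], -d[:, 0]], axis=-1)
            np.add.at(f, self.pres_i, fp)
            np.add.at(f, self.pres_j, fp)

        f[self.fixed] = vfix
        return f.ravel()

    def element_strain_state(self, v: np.ndarray, dt: float = 0.0):
        """Per-element rate-of-strain tensors and current areas for the
        velocity field ``v`` (used by division-plane choice and metrics)."""
        vv = np.asarray(v, dtype=float).reshape(self.n, 2).copy()
        vv[self.fixed] = 0.0
        x = self.x0 + dt * vv
        if not len(self.tri):
            return np.empty((0, 2, 2)), np.empty(0), self.el_cell
        _, _, _, _, det2, _, E = self._kinematics(x, vv)
        return E, det2 / 2.0, self.el_cell

    def current_fibers(self):
        """Current fiber directions (a1, a2) and areas per element."""
        x = self.x0
        x1, x2, x3 = x[self.tri[:, 0]], x[self.tri[:, 1]], x[self.tri[:, 2]]
        F2 = np.stack([x2 - x1, x3 - x1], axis=-1)
        det2 = F2[:, 0, 0] * F2[:, 1, 1] - F2[:, 0, 1] * F2[:, 1, 0]
        F = F2 @ self.invF1
        out = []
        for A in (self.A1, self.A2):
            a = np.einsum("eij,ej->ei", F, A)
            a /= np.linalg.norm(a, axis=-1, keepdims=True)
            out.append(a)
        return out[0], out[1], det2 / 2.0

    # -- sparsity ----------------------------------------------------------
    def sparsity(self) -> sp.csr_matrix:
        """Boolean Jacobian pattern: vertex pairs coupled through a shared
        element, wall segment or pressure edge; fixed DOFs couple only to
        themselves."""
        if self._pattern is not None:
            return self._pattern
        pairs = set()
        for t in self.tri:
            for a in t:
                for b in t:
                    pairs.add((int(a), int(b)))
        for i, j in zip(self.seg_i, self.seg_j):
            pairs.update({(int(i), int(i)), (int(i), int(j)),
                          (int(j), int(i)), (int(j), int(j))})
        for i, j in zip(self.pres_i, self.pres_j):
            pairs.update({(int(i), int(i)), (int(i), int(j)),
                          (int(j), int(i)), (int(j), int(j))})
        for k in range(self.n):
            pairs.add((k, k))
        rows, cols = [], []
        for a, b in pairs:
            if self.fixed[a]:
                continue  # handled by the diagonal below
            if self.fixed[b]:
                continue  # forces do not depend on pinned velocities
            for da in (0, 1):
                for db in (0, 1):
                    rows.append(2 * a + da)
                    cols.append(2 * b + db)
        fixed_dofs = np.flatnonzero(np.repeat(self.fixed, 2))
        rows.extend(fixed_dofs)
        cols.extend(fixed_dofs)
        data = np.ones(len(rows), dtype=bool)
        self._pattern = sp.csr_matrix(
            (data, (rows, cols)), shape=(2 * self.n, 2 * self.n))
        self._pattern.sum_duplicates()
        return self._pattern


def _inv2(M: np.ndarray, det: np.ndarray) -> np.ndarray:
    """Inverse of a stack of 2×2 matrices with known determinants."""
    inv = np.empty_like(M)
    inv[:, 0, 0] = M[:, 1, 1]
    inv[:, 0, 1] = -M[:, 0, 1]
    inv[:, 1, 0] = -M[:, 1, 0]
    inv[:, 1, 1] = M[:, 0, 0]
    return inv / det[:, None, None]


def assemble_residual(tissue: Tissue, velocity_vector: np.ndarray,
                      dt: float = 0.0) -> np.ndarray:
    """Assembled force residual for a velocity vector ordered by sorted
    vertex id ((vx, vy) interleaved); see :class:`MechanicalSystem`."""
    return MechanicalSystem(tissue).residual(np.asarray(velocity_vector, float), dt)
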