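"""Element kinematics, vertex forces and global force assembly."""

import numpy as np
import pytest

from plantvem.constitutive import InPlaneWallMaterial
from plantvem.mechanics import (
    MechanicalSystem,
    assemble_residual,
    element_kinematics,
    element_vertex_forces,
    pressure_vertex_forces,
    shape_gradients,
    wall_segment_vertex_forces,
)
from plantvem.tissue import (
    Cell,
    Tissue,
    TriElement,
    TissueError,
    WallSegment,
    edge_key,
)


class TestShapeGradients:
    def test_rows_and_partition_of_unity(self):
        N = shape_gradients()
        assert np.array_equal(N, [[-1, -1], [1, 0], [0, 1]])
        assert np.allclose(N.sum(axis=0), 0)

    def test_barycentric_midpoint_interpolation(self):
        # N at xi=(1/3,1/3) weights each vertex equally
        xi = np.array([1 / 3, 1 / 3])
        vals = np.array([1 - xi.sum(), xi[0], xi[1]])
        pts = np.array([(0.0, 0.0), (3.0, 0.0), (0.0, 3.0)])
        assert np.allclose(vals @ pts, pts.mean(axis=0))


class TestElementKinematics:
    def _el(self, X):
        return TriElement(vids=(0, 1, 2), X=np.asarray(X, float))

    def test_identity_state(self):
        X = [(0, 0), (1, 0), (0, 1)]
        kin = element_kinematics(self._el(X), np.array(X, float), np.zeros((3, 2)),
                                 A1=(0, 1), A2=(0, 1))
        assert np.allclose(kin.F, np.eye(2))
        assert np.allclose(kin.a1, [0, 1])
        assert np.allclose(kin.E, 0)

    def test_hand_stretch(self):
        X = [(0, 0), (1, 0), (0, 1)]
        x = np.array([(0, 0), (2, 0), (0, 1)], float)
        A = np.array([1, 1]) / np.sqrt(2)
        kin = element_kinematics(self._el(X), x, np.zeros((3, 2)), A1=A, A2=A)
        assert np.allclose(kin.F, np.diag([2, 1]))
        assert np.allclose(kin.a1, np.array([2, 1]) / np.sqrt(5))

    def test_rigid_rotation_velocity_gives_zero_strain_rate(self):
        X = [(0, 0), (1, 0), (0, 1)]
        x = np.array(X, float)
        omega = 0.7
        v = omega * np.stack([-x[:, 1], x[:, 0]], axis=1)
        kin = element_kinematics(self._el(X), x, v)
        assert np.allclose(kin.E, 0, atol=1e-14)
        assert np.allclose(kin.grad_v, omega * np.array([[0, -1], [1, 0]]))

    def test_degenerate_current_triangle_rejected(self):
        X = [(0, 0), (1, 0), (0, 1)]
        x = np.array([(0, 0), (1, 0), (2, 0)], float)
        with pytest.raises(TissueError, match="degenerate"):
            element_kinematics(self._el(X), x, np.zeros((3, 2)))


class TestElementForces:
    def test_zero_stress_zero_forces(self):
        X = [(0, 0), (1, 0), (0, 1)]
        el = TriElement(vids=(0, 1, 2), X=np.array(X, float))
        kin = element_kinematics(el, np.array(X, float), np.zeros((3, 2)))
        m = InPlaneWallMaterial(mu1=0.15, mu2=20.0)
        f = element_vertex_forces(el, kin, m, np.array(X, float))
        assert np.allclose(f, 0)

    def test_uniform_stress_forces_sum_to_zero(self):
        X = np.array([(0, 0), (2, 0.3), (0.5, 1.5)])
        el = TriElement(vids=(0, 1, 2), X=X)
        v = np.array([(0.0, 0.0), (1.0, 0.2), (0.1, -0.4)])
        kin = element_kinematics(el, X, v)
        m = InPlaneWallMaterial(mu1=0.15, mu2=20.0, mu3=1.0)
        f = element_vertex_forces(el, kin, m, X)
        assert np.allclose(f.sum(axis=0), 0, atol=1e-12)

    def test_unit_triangle_hand_values(self):
        """sigma = diag(1, 0) on the unit triangle gives
        f1 = (0.5, 0), f2 = (-0.5, 0), f3 = (0, 0)."""
        # choose a velocity field so that 2 mu1 E = diag(1, 0): E = diag(rate,0)
        X = np.array([(0.0, 0.0), (1.0, 0.0), (0.0, 1.0)])
        el = TriElement(vids=(0, 1, 2), X=X)
        mu1, rate = 0.25, 2.0  # 2*0.25*2 = 1
        v = rate * np.stack([X[:, 0], np.zeros(3)], axis=1)
        kin = element_kinematics(el, X, v)
        m = InPlaneWallMaterial(mu1=mu1, mu2=0.0, mu3=0.0, tau_w=0.0)
        f = element_vertex_forces(el, kin, m, X)
        assert np.allclose(f, [(0.5, 0), (-0.5, 0), (0, 0)], atol=1e-12)


class TestPressureForces:
    def _square_cell(self, pressure):
        t = Tissue()
        vids = [t.new_vertex(p) for p in [(0, 0), (20, 0), (20, 20), (0, 20)]]
        return Cell(boundary=vids, pressure=pressure), t

    def test_closed_polygon_forces_sum_to_zero(self):
        cell, t = self._square_cell(0.3)
        f = pressure_vertex_forces(cell, t.vertices)
        assert np.allclose(sum(f.values()), 0, atol=1e-12)

    def test_hand_value_on_vertical_edge(self):
        """p = 0.3 MPa: the anticlockwise-traversed edge (0,0)->(0,20)
        contributes (3, 0) MPa μm to each endpoint, directed outward (the
        cell lies on the -x side of that edge)."""
        t = Tissue()
        vids = [t.new_vertex(p) for p in [(0, 0), (0, 20), (-30, 20), (-30, 0)]]
        cell = Cell(boundary=vids, pressure=0.3)
        f = pressure_vertex_forces(cell, t.vertices)
        # vertex (0,0): (3,0) from the vertical edge + (0,-4.5) from the
        # bottom edge; vertex (0,20): (3,0) + (0,4.5) from the top edge
        assert np.allclose(f[vids[0]], [3.0, -4.5])
        assert np.allclose(f[vids[1]], [3.0, 4.5])

    def test_zero_pressure(self):
        cell, t = self._square_cell(0.0)
        f = pressure_vertex_forces(cell, t.vertices)
        assert all(np.allclose(v, 0) for v in f.values())

    def test_clockwise_rejected(self):
        t = Tissue()
        vids = [t.new_vertex(p) for p in [(0, 0), (0, 20), (20, 20), (20, 0)]]
        cell = Cell(boundary=vids, pressure=0.3)
        with pytest.raises(TissueError):
            pressure_vertex_forces(cell, t.vertices)


class TestWallSegmentForces:
    def _seg(self, **kw):
        params = dict(cell=0, key=(0, 1), wall_class="axial", mu=1.5, tau=0.0,
                      eps_star=0.05, lam=0.0, l0=10.0)
        params.update(kw)
        return WallSegment(**params)

    def test_zero_state_zero_force(self):
        f_i, f_j = wall_segment_vertex_forces(
            self._seg(), (0, 0), (10, 0), (0, 0), (0, 0))
        assert np.allclose(f_i, 0) and np.allclose(f_j, 0)

    def test_action_reaction(self):
        f_i, f_j = wall_segment_vertex_forces(
            self._seg(lam=100.0, l0=8.0), (0, 0), (10, 0), (-1, 0), (2, 0.5))
        assert np.allclose(f_i + f_j, 0)

    def test_stretching_edge_pulls_endpoints_together(self):
        # edge elongating: tension > 0, force on i points toward j
        f_i, f_j = wall_segment_vertex_forces(
            self._seg(), (0, 0), (10, 0), (0, 0), (5, 0))
        assert f_i[0] > 0 and f_j[0] < 0

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(TissueError):
            wall_segment_vertex_forces(self._seg(), (1, 1), (1, 1), (0, 0), (0, 0))


class TestAssembly:
    def test_unloaded_single_cell_in_equilibrium(self):
        from plantvem.config import GeometryConfig, MeshConfig, SimConfig
        from plantvem.meshing import triangulate_tissue
        from plantvem.tissue import build_synthetic_root

        cfg = SimConfig(pressure=0.0)
        cfg.geometry = GeometryConfig(n_files=1, total_length=100.0,
                                      min_cell_length=100.0)
        t = build_synthetic_root(1, 20.0, 100.0, 100.0, seed=0, config=cfg)
        triangulate_tissue(t, (20.0, 100.0))
        r = assemble_residual(t, np.zeros(2 * len(t.vertices)))
        assert np.linalg.norm(r, np.inf) < 1e-12

    def test_net_force_and_torque_vanish_without_pins(self, small_meshed_tissue):
        t = small_meshed_tissue
        for v in t.vertices.values():
            v.fixed = False
        sysm = MechanicalSystem(t)
        rng = np.random.default_rng(1)
        v = rng.normal(0, 3.0, 2 * sysm.n)
        r = sysm.residual(v, dt=0.0).reshape(-1, 2)
        assert np.allclose(r.sum(axis=0), 0, atol=1e-9)
        torque = np.sum(sysm.x0[:, 0] * r[:, 1] - sysm.x0[:, 1] * r[:, 0])
        assert abs(torque) < 1e-7

    def test_rigid_motions_produce_no_viscous_force(self, small_meshed_tissue):
        """Translation and rotation velocity fields are force-free when
        pressure is off and elastic springs are at rest."""
        t = small_meshed_tissue
        for cell in t.cells.values():
            cell.pressure = 0.0
            cell.material.tau_w = 0.1  # include the yield term
            for seg in cell.segments.values():
                seg.lam = 0.0
                seg.tau = 0.05
        for v in t.vertices.values():
            v.fixed = False
        sysm = MechanicalSystem(t)
        # translation
        v_trans = np.tile([3.0, -2.0], sysm.n)
        r = sysm.residual(v_trans, dt=0.0)
        assert np.linalg.norm(r, np.inf) < 1e-10
        # rotation about an arbitrary point
        omega, c = 0.4, np.array([30.0, -10.0])
        rel = sysm.x0 - c
        v_rot = (omega * np.stack([-rel[:, 1], rel[:, 0]], axis=1)).ravel()
        r = sysm.residual(v_rot, dt=0.0)
        assert np.linalg.norm(r, np.inf) < 1e-9

    def test_residual_directional_derivative_consistent(self, small_meshed_tissue):
        sysm = MechanicalSystem(small_meshed_tissue)
        rng = np.random.default_rng(2)
        v = rng.normal(0, 2.0, 2 * sysm.n)
        d = rng.normal(0, 1.0, 2 * sysm.n)
        dt = 0.1
        r0 = sysm.residual(v, dt)
        errs = []
        for h in (1e-3, 1e-4, 1e-5):
            fd = (sysm.residual(v + h * d, dt) - r0) / h
            errs.append(fd)
        # FD directional derivatives converge: successive estimates agree to O(h)
        assert np.linalg.norm(errs[1] - errs[2], np.inf) < \
            0.2 * np.linalg.norm(errs[0] - errs[2], np.inf) + 1e-9

    def test_size_mismatch_rejected(self, small_meshed_tissue):
        with pytest.raises(TissueError):
            assemble_residual(small_meshed_tissue, np.zeros(3))

    def test_interior_vertices_carry_no_pressure_or_segment_forces(
            self, small_meshed_tissue):
        sysm = MechanicalSystem(small_meshed_tissue)
        interior = small_meshed_tissue.interior_vertices
        for k in np.concatenate([sysm.pres_i, sysm.pres_j,
                                 sysm.seg_i, sysm.seg_j]):
            assert sysm.vids[k] not in interior
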