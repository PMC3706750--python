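"""Growth-inhibitor transport, yield modulation and cell division."""

import numpy as np
import pytest

from plantvem.config import (
    DivisionConfig,
    GeometryConfig,
    MeshConfig,
    RegulationConfig,
    SimConfig,
)
from plantvem.meshing import triangulate_tissue
from plantvem.regulation import (
    attempt_divisions,
    division_direction,
    inhibitor_rhs,
    split_cell,
    step_inhibitor,
    update_yield_stresses,
)
from plantvem.tissue import (
    TissueError,
    build_synthetic_root,
    cell_area,
    validate_topology,
)
from conftest import rot


def _chain_tissue(n_cells, qc_first=True, length=50.0, seed=0):
    """A single file of cells; optionally the rootward cell is QC."""
    cfg = SimConfig(geometry=GeometryConfig(
        n_files=1, total_length=length * n_cells, min_cell_length=length,
        qc_at_tip=qc_first))
    t = build_synthetic_root(1, 20.0, length * n_cells, length, seed=seed,
                             config=cfg)
    return t


class TestInhibitorTransport:
    def test_uniform_state_is_steady_without_sources(self):
        t = _chain_tissue(4, qc_first=False)
        for c in t.cells.values():
            c.b = 2.5
        params = RegulationConfig(alpha_b=0.0, lambda_b=0.0)
        rates = inhibitor_rhs(t, params)
        assert all(abs(r) < 1e-12 for r in rates.values())

    def test_isolated_qc_cell_steady_state(self):
        # fixed point b = alpha_b / lambda_b = 2/16 = 0.125 nM
        t = _chain_tissue(1, qc_first=True)
        params = RegulationConfig()
        for _ in range(4000):
            step_inhibitor(t, 0.01, params)
        b = next(iter(t.cells.values())).b
        assert b == pytest.approx(0.125, rel=1e-6)

    def test_pairwise_flux_conserves_total_amount(self):
        t = _chain_tissue(2, qc_first=False)
        cids = sorted(t.cells)
        t.cells[cids[0]].b = 1.0
        t.cells[cids[1]].b = 0.2
        params = RegulationConfig(alpha_b=0.0, lambda_b=0.0)
        rates = inhibitor_rhs(t, params)
        areas = {c: cell_area(t.cells[c], t.vertices) for c in cids}
        total_rate = sum(areas[c] * rates[c] for c in cids)
        # flux scale is P_b S b ~ 4e4, so 1e-9 is roundoff-level
        assert total_rate == pytest.approx(0.0, abs=1e-9)

    def test_implicit_step_conserves_mass_without_decay(self):
        t = _chain_tissue(5, qc_first=False, seed=3)
        rng = np.random.default_rng(0)
        for c in t.cells.values():
            c.b = float(rng.uniform(0, 1))
        params = RegulationConfig(alpha_b=0.0, lambda_b=0.0)
        areas = {c: cell_area(t.cells[c], t.vertices) for c in t.cells}
        m0 = sum(areas[c] * t.cells[c].b for c in t.cells)
        for _ in range(50):
            step_inhibitor(t, 0.1, params)
        m1 = sum(areas[c] * t.cells[c].b for c in t.cells)
        assert m1 == pytest.approx(m0, rel=1e-9)

    def test_decay_makes_total_amount_monotone(self):
        t = _chain_tissue(4, qc_first=False, seed=1)
        for c in t.cells.values():
            c.b = 1.0
        params = RegulationConfig(alpha_b=0.0, lambda_b=2.0)
        areas = {c: cell_area(t.cells[c], t.vertices) for c in t.cells}
        prev = sum(areas[c] * t.cells[c].b for c in t.cells)
        for _ in range(20):
            step_inhibitor(t, 0.1, params)
            cur = sum(areas[c] * t.cells[c].b for c in t.cells)
            assert cur < prev
            prev = cur

    def test_source_chain_has_monotone_decreasing_profile(self):
        """Steady state of a 1-D chain with a QC source at the rootward end:
        concentration decreases monotonically along the chain (screened
        diffusion), matching a direct linear solve."""
        t = _chain_tissue(6, qc_first=True, seed=2)
        params = RegulationConfig()
        for _ in range(3000):
            step_inhibitor(t, 0.05, params)
        # order cells along x
        cids = sorted(t.cells, key=lambda c: min(
            t.vertices[v].pos[0] for v in t.cells[c].boundary))
        profile = [t.cells[c].b for c in cids]
        assert all(a > b for a, b in zip(profile, profile[1:]))
        # direct steady solve of the same linear system
        from plantvem.regulation import shared_wall_lengths
        areas = {c: cell_area(t.cells[c], t.vertices) for c in t.cells}
        idx = {c: k for k, c in enumerate(sorted(t.cells))}
        n = len(idx)
        K = np.zeros((n, n))
        alpha = np.zeros(n)
        for c in t.cells:
            K[idx[c], idx[c]] -= params.lambda_b
            if t.cells[c].cell_type == "QC":
                alpha[idx[c]] = params.alpha_b
        for (m, nn), s in shared_wall_lengths(t).items():
            K[idx[m], idx[nn]] += params.P_b * s / areas[m]
            K[idx[m], idx[m]] -= params.P_b * s / areas[m]
            K[idx[nn], idx[m]] += params.P_b * s / areas[nn]
            K[idx[nn], idx[nn]] -= params.P_b * s / areas[nn]
        b_direct = np.linalg.solve(-K, alpha)
        for c in t.cells:
            assert t.cells[c].b == pytest.approx(b_direct[idx[c]], rel=1e-6)

    def test_small_step_matches_explicit_euler(self):
        t = _chain_tissue(3, qc_first=True, seed=4)
        for c, cell in t.cells.items():
            cell.b = 0.01 * (c + 1)
        params = RegulationConfig()
        rates = inhibitor_rhs(t, params)
        b0 = {c: t.cells[c].b for c in t.cells}
        dt = 1e-7
        step_inhibitor(t, dt, params)
        for c in t.cells:
            explicit = b0[c] + dt * rates[c]
            # implicit and explicit Euler differ at O(dt^2 K^2 b) ~ 1e-12
            assert t.cells[c].b == pytest.approx(explicit, abs=1e-10)


class TestYieldModulation:
    def test_basal_when_no_inhibitor(self):
        t = _chain_tissue(2, qc_first=False)
        params = RegulationConfig(tau_w0=0.1, tau_axial0=0.1)
        update_yield_stresses(t, params)
        for c in t.cells.values():
            assert c.material.tau_w == pytest.approx(0.1)

    def test_half_saturation_doubles_yield(self):
        t = _chain_tissue(1)
        params = RegulationConfig(tau_w0=0.1, tau_axial0=0.2, k_b=1e-5, n_b=3)
        for c in t.cells.values():
            c.b = params.k_b
        update_yield_stresses(t, params)
        for c in t.cells.values():
            assert c.material.tau_w == pytest.approx(0.2)
            for seg in c.segments.values():
                if seg.wall_class == "axial":
                    assert seg.tau == pytest.approx(0.4)
                else:
                    assert seg.tau == pytest.approx(0.0)  # cross untouched

    def test_hill_asymptotics(self):
        t = _chain_tissue(1)
        params = RegulationConfig(tau_w0=0.1, k_b=1e-5, n_b=2)
        for c in t.cells.values():
            c.b = 1000 * params.k_b
        update_yield_stresses(t, params)
        for c in t.cells.values():
            assert c.material.tau_w == pytest.approx(0.1 * 1000**2, rel=1e-4)

    def test_zero_half_saturation_rejected(self):
        t = _chain_tissue(1)
        with pytest.raises(TissueError):
            update_yield_stresses(t, RegulationConfig(k_b=0.0))


class TestDivisionDirection:
    def test_axial_strain_gives_axial_direction(self, single_cell_tissue):
        t = single_cell_tissue
        vels = {vid: np.array([0.5 * t.vertices[vid].pos[0], 0.0])
                for vid in t.vertices}
        cid = next(iter(t.cells))
        g = division_direction(t, cid, vels)
        assert abs(g @ np.array([1.0, 0.0])) == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_strain_falls_back_to_long_axis(self, single_cell_tissue):
        t = single_cell_tissue
        vels = {vid: 0.3 * t.vertices[vid].pos for vid in t.vertices}
        cid = next(iter(t.cells))
        g = division_direction(t, cid, vels)
        # 100x20 cell: longest principal axis is x
        assert abs(g @ np.array([1.0, 0.0])) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_equivariance(self, single_cell_tissue):
        import copy

        t = single_cell_tissue
        cid = next(iter(t.cells))
        vels = {vid: np.array([0.4 * t.vertices[vid].pos[0],
                               -0.1 * t.vertices[vid].pos[1]])
                for vid in t.vertices}
        g = division_direction(t, cid, vels)
        Q = rot(0.7)
        t2 = copy.deepcopy(t)
        for vid, v in t2.vertices.items():
            v.pos = Q @ v.pos
        for cell in t2.cells.values():
            for el in cell.elements:
                el.X = el.X @ Q.T
        vels2 = {vid: Q @ vels[vid] for vid in vels}
        g2 = division_direction(t2, cid, vels2)
        assert min(np.linalg.norm(g2 - Q @ g), np.linalg.norm(g2 + Q @ g)) < 1e-9


class TestSplitAndDivisions:
    def test_rectangle_splits_into_halves(self, single_cell_tissue):
        t = single_cell_tissue
        cid = next(iter(t.cells))
        parent_area = cell_area(t.cells[cid], t.vertices)
        d1, d2 = split_cell(t, cid, np.array([1.0, 0.0]), quality=(20.0, 50.0))
        validate_topology(t)
        a1 = cell_area(t.cells[d1], t.vertices)
        a2 = cell_area(t.cells[d2], t.vertices)
        assert a1 + a2 == pytest.approx(parent_area, rel=1e-9)
        # centroid at (50, 10), wall along y: two 50x20 rectangles
        assert a1 == pytest.approx(1000.0, rel=1e-6)
        assert a2 == pytest.approx(1000.0, rel=1e-6)
        assert t.cells[d1].timer == 0.0 and t.cells[d2].timer == 0.0

    def test_timer_below_threshold_no_division(self, single_cell_tissue):
        t = single_cell_tissue
        for c in t.cells.values():
            c.timer = 0.5
            c.b = 1.0
        events = attempt_divisions(
            t, 0.1, None, DivisionConfig(enabled=True, beta=0.1),
            RegulationConfig(), velocities={}, quality=(20.0, 50.0))
        assert events == []
        assert len(t.cells) == 1

    def test_division_requires_inhibitor_above_threshold(self, single_cell_tissue):
        t = single_cell_tissue
        for c in t.cells.values():
            c.timer = 1.5
            c.b = 0.0
        events = attempt_divisions(
            t, 0.1, None, DivisionConfig(enabled=True), RegulationConfig(),
            velocities={}, quality=(20.0, 50.0))
        assert events == []

    def test_division_resets_timers_and_conserves_area(self, small_meshed_tissue):
        t = small_meshed_tissue
        total0 = t.organ_polygon().area
        cids = sorted(t.cells)
        target = cids[0]
        for c in t.cells.values():
            c.timer = 0.0
        t.cells[target].timer = 1.2
        t.cells[target].b = 1.0
        events = attempt_divisions(
            t, 0.1, None, DivisionConfig(enabled=True), RegulationConfig(),
            velocities={}, quality=(20.0, 250.0))
        assert len(events) == 1
        validate_topology(t)
        assert t.organ_polygon().area == pytest.approx(total0, rel=1e-9)
        for d in events[0]["daughters"]:
            assert t.cells[d].timer == 0.0
            assert t.cells[d].b == 1.0

    def test_long_run_division_rate_approaches_beta(self):
        """In the meristem proxy (b > k_b) the per-cell division rate tends
        to beta; cells with b <= k_b never divide."""
        t = _chain_tissue(3, qc_first=False, seed=5)
        triangulate_tissue(t, (20.0, 250.0))
        beta, dt = 0.5, 0.1
        reg = RegulationConfig()
        for c in t.cells.values():
            c.b = 1.0  # well above k_b
        n_divisions = 0
        T = 12.0
        steps = int(T / dt)
        for _ in range(steps):
            ev = attempt_divisions(t, dt, None,
                                   DivisionConfig(enabled=True, beta=beta),
                                   reg, velocities={}, quality=(20.0, 250.0))
            n_divisions += len(ev)
            for e in ev:
                for d in e["daughters"]:
                    t.cells[d].b = 1.0
        # each cell waits 1/beta between divisions, so the population
        # doubles every 1/beta: the realized per-cell division rate
        # ln(N/N0)/(T ln 2) tends to beta
        realized = np.log(len(t.cells) / 3) / (T * np.log(2))
        assert realized == pytest.approx(beta, rel=0.2)
        # and with b below threshold nothing divides
        t2 = _chain_tissue(2, qc_first=False, seed=6)
        triangulate_tissue(t2, (20.0, 250.0))
        for c in t2.cells.values():
            c.b = 0.0
        for _ in range(100):
            ev = attempt_divisions(t2, dt, None,
                                   DivisionConfig(enabled=True, beta=beta),
                                   reg, velocities={}, quality=(20.0, 250.0))
            assert ev == []
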