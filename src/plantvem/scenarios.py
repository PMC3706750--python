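"""Preset configurations for the standard synthetic-geometry experiments.

All presets default to a reduced-scale organ (1000 μm, 5 files, 250 μm²
triangles) so a full scenario runs in seconds-to-minutes on one CPU while
preserving the qualitative organ-scale behavior; pass ``full_scale=True``
for the 2000 μm organ with the fine default mesh.
"""

from __future__ import annotations

from .config import GeometryConfig, MeshConfig, SimConfig, SolverConfig

__all__ = [
    "single_cell",
    "anisotropic_organ",
    "isotropic_floppy_organ",
    "bending_soft_top_file",
    "tilted_fibers_organ",
    "thin_bottom_file",
]

_REDUCED_LENGTH = 1000.0
_REDUCED_AREA = 250.0


def _base(seed: int, t_end: float, full_scale: bool, remesh_every: int = 5) -> SimConfig:
    cfg = SimConfig(seed=seed)
    if not full_scale:
        cfg.geometry = GeometryConfig(total_length=_REDUCED_LENGTH)
        cfg.mesh = MeshConfig(max_area=_REDUCED_AREA, remesh_every=remesh_every)
    else:
        cfg.mesh.remesh_every = remesh_every
    cfg.solver = SolverConfig(t_end=t_end)
    return cfg


def single_cell(seed: int = 0) -> SimConfig:
    """One isolated 100×20 μm cell with transverse fibers and default
    parameters: the analytic steady elongation rate is
    H p / (2 μ1 H + 4 μ_axial) = 0.5 hr⁻¹."""
    cfg = SimConfig(seed=seed)
    cfg.geometry = GeometryConfig(n_files=1, file_height=20.0,
                                  total_length=100.0, min_cell_length=100.0)
    cfg.mesh = MeshConfig(max_area=50.0, remesh_every=5)
    cfg.solver = SolverConfig(t_end=1.0)
    return cfg


def anisotropic_organ(seed: int = 0, t_end: float = 1.0,
                      full_scale: bool = False) -> SimConfig:
    """Default wall rheology: strong fiber viscosity keeps cells
    rectangular while the organ elongates axially."""
    return _base(seed, t_end, full_scale)


def isotropic_floppy_organ(seed: int = 0, t_end: float = 1.0,
                           full_scale: bool = False) -> SimConfig:
    """Nearly inviscid in-plane walls (μ1 = 0.002 MPa hr, μ2 = μ3 = 0) with
    stiffer axial walls (μ_axial = 10 MPa μm hr): cells bulge and round."""
    cfg = _base(seed, t_end, full_scale)
    cfg.mu1 = 0.002
    cfg.mu2 = 0.0
    cfg.mu3 = 0.0
    cfg.mu_axial = 10.0
    return cfg


def bending_soft_top_file(seed: int = 0, t_end: float = 2.0,
                          full_scale: bool = False,
                          remesh_every: int = 5) -> SimConfig:
    """Top file slightly more extensible (μ1 = 0.13 vs 0.15 MPa hr): the
    organ bends upward; remeshing keeps the tip angle accelerating."""
    cfg = _base(seed, t_end, full_scale, remesh_every=remesh_every)
    if not full_scale:
        # bending needs interior mesh structure inside the 20 μm files
        cfg.mesh.max_area = 100.0
    cfg.file_overrides = {cfg.geometry.n_files - 1: {"mu1": 0.13}}
    return cfg


def tilted_fibers_organ(seed: int = 0, fiber_angle: float = 0.2,
                        t_end: float = 3.0, full_scale: bool = False) -> SimConfig:
    """Fiber families at ±fiber_angle rad to the y-axis: reorientation
    toward the axis progressively slows elongation (fiber_angle = 0 gives
    near-exponential growth)."""
    cfg = _base(seed, t_end, full_scale)
    cfg.fiber_angle = fiber_angle
    return cfg


def thin_bottom_file(seed: int = 0, t_end: float = 2.0, thin: bool = True,
                     full_scale: bool = False) -> SimConfig:
    """Bottom file 18 μm (vs 20 μm) with μ_axial = 0.5 MPa μm hr and
    μ1 = 0.2 MPa hr: the geometric asymmetry alone bends the organ;
    thin=False gives the uniform-geometry baseline."""
    cfg = _base(seed, t_end, full_scale)
    if not full_scale:
        cfg.mesh.max_area = 100.0
    cfg.mu_axial = 0.5
    cfg.mu1 = 0.2
    if thin:
        heights = [18.0] + [20.0] * (cfg.geometry.n_files - 1)
        cfg.geometry.file_heights = heights
    return cfg
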