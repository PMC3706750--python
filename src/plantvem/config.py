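"""Simulation configuration.

All quantities use the unit system of the model throughout: lengths in μm,
time in hr, stresses in MPa (in-plane stress resultants in MPa, out-of-plane
wall stress resultants in MPa μm). There is no internal nondimensionalization.

Defaults are the standard operating point for Arabidopsis root
simulations: turgor pressure 0.3 MPa, in-plane isotropic viscosity
0.15 MPa hr, fiber extensional viscosity 20 MPa hr, axial wall viscosity
1.5 MPa μm hr, cross-wall spring constant 100 MPa μm, and so on. Yield
stresses default to zero (the linear law used for the synthetic-geometry
experiments); the regulated, non-linear law activates them through the
growth-inhibitor model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class GeometryConfig:
    """Synthetic rectangular-root geometry.

    ``file_heights`` overrides ``file_height`` per file (index 0 is the
    bottom file); used e.g. to make the bottom file slightly thinner.
    """

    n_files: int = 5
    file_height: float = 20.0          # μm (L_y)
    file_heights: Optional[list] = None
    total_length: float = 2000.0       # μm (L_x,tot)
    min_cell_length: float = 50.0      # μm (L_x); cell lengths ~ U[L_x, 2 L_x]
    qc_at_tip: bool = False            # label rootward-most cells as QC

    def heights(self) -> list:
        if self.file_heights is not None:
            if len(self.file_heights) != self.n_files:
                raise ValueError("file_heights must have n_files entries")
            return [float(h) for h in self.file_heights]
        return [float(self.file_height)] * self.n_files


@dataclass
class MeshConfig:
    """Triangulation quality for in-plane walls.

    ``max_area`` bounds triangle areas [μm²]; the mesher derives its target
    point spacing h = sqrt(2 max_area) from it, subdividing boundary edges
    longer than h and seeding interior (Steiner) points on a lattice of that
    spacing. ``min_angle`` [degrees] sets the margin used to keep interior
    points away from the boundary so Delaunay triangles stay well shaped.
    ``remesh_every`` regenerates the triangulation every k timesteps
    (0 disables periodic remeshing). ``refine_factor`` divides max_area
    (10 reproduces the "refine" strategy).
    """

    max_area: float = 60.0
    min_angle: float = 20.0
    remesh_every: int = 5
    refine_factor: float = 1.0

    def effective_max_area(self) -> float:
        return self.max_area / self.refine_factor


@dataclass
class RegulationConfig:
    """Growth-inhibitor transport and yield-stress modulation."""

    enabled: bool = False
    P_b: float = 2.0e3        # wall permeability [μm hr⁻¹]
    lambda_b: float = 16.0    # decay rate [hr⁻¹]
    alpha_b: float = 2.0      # production rate in QC cells [nM hr⁻¹]
    k_b: float = 1.0e-5       # half-saturation concentration [nM]
    n_b: float = 2.0          # Hill exponent
    tau_w0: float = 0.1       # basal in-plane yield stress [MPa]
    tau_axial0: float = 0.1   # basal axial wall yield stress [MPa μm]


@dataclass
class DivisionConfig:
    """Cell division timing: timers advance at rate beta and a cell divides
    once its timer exceeds 1, provided (when ``require_inhibitor``) its
    growth-inhibitor concentration exceeds the half-saturation k_b."""

    enabled: bool = False
    beta: float = 0.1             # timer rate [hr⁻¹]
    require_inhibitor: bool = True


@dataclass
class SolverConfig:
    dt: float = 0.1               # timestep [hr]
    t_end: float = 2.0            # [hr]
    newton_tol: float = 1.0e-8    # absolute residual norm [MPa μm]
    # relative velocity-increment tolerance: converged when
    # ||dv|| < newton_dv_tol (1 + ||v||)  [dimensionless]
    newton_dv_tol: float = 1.0e-3
    newton_accept_tol: float = 1.0e-3  # fallback residual norm [MPa μm]
    max_newton_iters: int = 30
    fd_step: float = 1.0e-6       # relative FD perturbation
    max_step_halvings: int = 12


@dataclass
class SimConfig:
    """Everything needed to reproduce a run: geometry, material parameters,
    regulation, division, meshing and numerics, plus the seed."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    mesh: MeshConfig = field(default_factory=MeshConfig)
    regulation: RegulationConfig = field(default_factory=RegulationConfig)
    division: DivisionConfig = field(default_factory=DivisionConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)

    # turgor
    pressure: float = 0.3         # MPa, uniform in all cells

    # in-plane wall material
    mu1: float = 0.15             # isotropic viscosity [MPa hr]
    mu2: float = 20.0             # fiber extensional viscosity [MPa hr]
    mu3: float = 0.0              # fiber shear viscosity [MPa hr]
    tau_w: float = 0.0            # yield stress [MPa] (0 = linear law)
    eps_star: float = 0.05        # yield strain rate [hr⁻¹]
    fiber_angle: float = 0.0      # fiber families at ±angle [rad] from the y-axis

    # axial out-of-plane walls
    mu_axial: float = 1.5         # [MPa μm hr]
    tau_axial: float = 0.0        # [MPa μm]
    eps_star_axial: float = 0.05  # [hr⁻¹]
    lam_axial: float = 0.0        # [MPa μm]

    # cross out-of-plane walls
    mu_cross: float = 0.05        # [MPa μm hr]
    tau_cross: float = 0.0        # [MPa μm]
    eps_star_cross: float = 0.05  # [hr⁻¹]
    lam_cross: float = 100.0      # [MPa μm]

    # per-file overrides, e.g. {4: {"mu1": 0.13}} to soften the top file
    file_overrides: dict = field(default_factory=dict)

    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        kwargs = {}
        for name, sub in (
            ("geometry", GeometryConfig),
            ("mesh", MeshConfig),
            ("regulation", RegulationConfig),
            ("division", DivisionConfig),
            ("solver", SolverConfig),
        ):
            if name in d:
                kwargs[name] = sub(**d.pop(name))
        if "file_overrides" in d:
            kwargs["file_overrides"] = {
                int(k): dict(v) for k, v in d.pop("file_overrides").items()
            }
        kwargs.update(d)
        return cls(**kwargs)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
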