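"""Pointwise stress laws for cell walls.

In-plane walls carry a 2×2 Cauchy stress resultant σ = σ_y + σ_a:

* σ_y = 2 μ_eff(ε) E is a non-linear isotropic viscous term with a
  Papanastasiou-regularized yield contribution,
  μ_eff = μ1 + (τ_w/ε)(1 − exp(−ε/ε*)), where ε = |E| is the Frobenius
  magnitude of the rate-of-strain tensor. The regularization is smooth at
  ε = 0 with μ_eff(0) = μ1 + τ_w/ε*: the wall is effectively stiff below
  the yield strain rate ε* and flows with viscosity ≈ μ1 (plus a constant
  plastic stress 2 τ_w E/ε) far above it.
* σ_a adds the resistance of two cellulose microfibril families a_1, a_2:
  extensional viscosity μ2 along each family and shear viscosity μ3 for
  shearing parallel to it.

Out-of-plane wall segments (axial and cross walls) carry a single tensile
stress resultant along the edge, with the same regularized viscous law in
the edge strain rate plus a linear spring on the relative extension from
the rest length.

All functions broadcast over leading axes so the assembly code can evaluate
them for every element or segment at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InPlaneWallMaterial",
    "papanastasiou_viscosity",
    "effective_isotropic_viscosity",
    "stress_isotropic_viscous",
    "stress_anisotropic",
    "wall_segment_stress",
    "wall_stress_scalar",
]

#: below this multiple of eps_star the series expansion of the
#: regularization is used instead of the (0/0) closed form
_SERIES_THRESHOLD = 1.0e-8


@dataclass
class InPlaneWallMaterial:
    """Material parameters of in-plane wall elements.

    Viscosities in MPa hr, yield stress in MPa, yield strain rate in hr⁻¹.
    ``A1``/``A2`` are the unit microfibril directions in the reference
    configuration (stored separately even when the two families coincide).
    """

    mu1: float = 0.15
    mu2: float = 20.0
    mu3: float = 0.0
    tau_w: float = 0.0
    eps_star: float = 0.05
    A1: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))
    A2: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))

    def __post_init__(self):
        self.A1 = np.asarray(self.A1, dtype=float)
        self.A2 = np.asarray(self.A2, dtype=float)
        for name in ("mu1", "mu2", "mu3", "tau_w", "eps_star"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for a in (self.A1, self.A2):
            if not np.isclose(np.linalg.norm(a), 1.0, atol=1e-9):
                raise ValueError("fiber directions must be unit vectors")


def papanastasiou_viscosity(eps, tau, eps_star):
    """Regularized yield term (τ/ε)(1 − exp(−ε/ε*)).

    Smooth at ε = 0 where it equals τ/ε*; for ε ≪ ε* the series
    τ/ε* (1 − ε/(2ε*)) is used to avoid cancellation. Broadcasts.
    """
    eps = np.asarray(eps, dtype=float)
    tau = np.asarray(tau, dtype=float)
    eps_star = np.asarray(eps_star, dtype=float)
    if np.any(eps < 0):
        raise ValueError("strain-rate magnitude must be non-negative")
    if np.any((tau > 0) & (eps_star <= 0)):
        raise ValueError("eps_star must be positive where tau > 0")
    safe_star = np.where(eps_star > 0, eps_star, 1.0)
    small = eps < _SERIES_THRESHOLD * safe_star
    safe_eps = np.where(small, safe_star, eps)
    closed = tau / safe_eps * -np.expm1(-safe_eps / safe_star)
    series = tau / safe_star * (1.0 - 0.5 * eps / safe_star)
    out = np.where(small, series, closed)
    out = np.where(tau == 0, 0.0, out)
    return out if out.shape else float(out)


def effective_isotropic_viscosity(eps, mu1, tau_w, eps_star):
    """μ_eff(ε) = μ1 + (τ_w/ε)(1 − exp(−ε/ε*))  [MPa hr].

    Continuous and monotone non-increasing in ε; μ_eff(0) = μ1 + τ_w/ε*.
    """
    return mu1 + papanastasiou_viscosity(eps, tau_w, eps_star)


def _check_symmetric(E):
    E = np.asarray(E, dtype=float)
    if E.shape[-2:] != (2, 2):
        raise ValueError("rate-of-strain tensor must be 2x2")
    if not np.allclose(E, np.swapaxes(E, -1, -2), atol=1e-10 * (1 + np.abs(E).max())):
        raise ValueError("rate-of-strain tensor must be symmetric")
    return E


def strain_rate_magnitude(E):
    """Frobenius magnitude ε = sqrt(Σ_ij E_ij²); zero iff E is zero."""
    E = np.asarray(E, dtype=float)
    return np.sqrt(np.sum(E * E, axis=(-2, -1)))


def stress_isotropic_viscous(E, material: InPlaneWallMaterial):
    """σ_y = 2 μ_eff(|E|) E  [MPa]. Symmetric, zero iff E is zero."""
    E = _check_symmetric(E)
    eps = strain_rate_magnitude(E)
    mu = effective_isotropic_viscosity(eps, material.mu1, material.tau_w, material.eps_star)
    return 2.0 * np.asarray(mu)[..., None, None] * E


def stress_anisotropic(E, a1, a2, mu2, mu3):
    """Microfibril stress σ_a = Σ_k μ2 (a_k·E a_k) a_k⊗a_k
    + μ3 (a_k ⊗ E a_k + E a_k ⊗ a_k)  [MPa].

    ``a1``/``a2`` are unit fiber directions in the *current* configuration.
    """
    E = _check_symmetric(E)
    sigma = np.zeros_like(E)
    for a in (a1, a2):
        a = np.asarray(a, dtype=float)
        norms = np.linalg.norm(a, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("fiber directions must be unit vectors")
        Ea = np.einsum("...ij,...j->...i", E, a)
        aEa = np.einsum("...i,...i->...", a, Ea)
        outer_aa = a[..., :, None] * a[..., None, :]
        cross = a[..., :, None] * Ea[..., None, :] + Ea[..., :, None] * a[..., None, :]
        sigma = sigma + np.asarray(mu2)[..., None, None] * aEa[..., None, None] * outer_aa
        sigma = sigma + np.asarray(mu3)[..., None, None] * cross
    return sigma


def wall_stress_scalar(eps_e, l_e, mu, tau, eps_star, lam, l0):
    """Tensile stress resultant of an out-of-plane wall segment [MPa μm].

    σ = 2[μ + (τ/ε_e)(1 − exp(−ε_e/ε*))] ε_e + λ (l_e/l0 − 1)

    The regularization uses |ε_e| with the sign restored, so compressive
    transients are handled smoothly. Positive σ is tension. Broadcasts.
    """
    eps_e = np.asarray(eps_e, dtype=float)
    l_e = np.asarray(l_e, dtype=float)
    l0 = np.asarray(l0, dtype=float)
    if np.any(l0 <= 0):
        raise ValueError("rest length must be positive")
    if np.any(l_e <= 0):
        raise ValueError("edge length must be positive")
    visc = 2.0 * (mu + papanastasiou_viscosity(np.abs(eps_e), tau, eps_star)) * eps_e
    elastic = lam * (l_e / l0 - 1.0)
    out = visc + elastic
    return out if np.asarray(out).shape else float(out)


def wall_segment_stress(eps_e, l_e, segment):
    """Stress resultant of a :class:`~plantvem.tissue.WallSegment` [MPa μm]."""
    return wall_stress_scalar(
        eps_e, l_e, segment.mu, segment.tau, segment.eps_star, segment.lam, segment.l0
    )
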