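"""Constitutive models: shear-thinning blood rheology and leaflet hyperelasticity.

Blood is modelled as an incompressible Bird–Carreau fluid,

    mu(gdot) = mu_inf + (mu_0 - mu_inf) * [1 + (lam * gdot)^2]^((n-1)/2),

which interpolates between a low-shear plateau ``mu_0`` and a high-shear
plateau ``mu_inf`` with power-law index ``n`` and time constant ``lam``.
The default constants are the standard whole-blood fit used in valve
haemodynamics (mu_inf = 3.5 mPa.s, mu_0 = 56 mPa.s, n = 0.3568,
lam = 3.313 s) with density 1060 kg/m^3.

Pericardial leaflet tissue is modelled as an incompressible, isotropic,
second-order Ogden solid with strain-energy density

    Psi = sum_i (2 mu_i / alpha_i^2) (lb1^a_i + lb2^a_i + lb3^a_i - 3),

written in modified (isochoric) principal stretches. Defaults are the
glutaraldehyde-treated bovine-pericardium fit (mu_1 = 19.58 kPa,
alpha_1 = 67.74, mu_2 = 260.56 kPa, alpha_2 = 27.47) with density
1100 kg/m^3. A Rayleigh mass-damping coefficient is stored for
completeness; it only matters inside a dynamic finite-element solve and is
never used in any computation here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CarreauParams",
    "OgdenParams",
    "carreau_viscosity",
    "ogden_energy",
    "ogden_uniaxial_stress",
]


@dataclass(frozen=True)
class CarreauParams:
    """Bird–Carreau parameters. Viscosities in Pa·s, ``lam`` in s."""

    mu_inf: float = 0.0035
    mu_0: float = 0.056
    n: float = 0.3568
    lam: float = 3.313
    rho_f: float = 1060.0  # kg/m^3

    def __post_init__(self) -> None:
        if not self.mu_0 > self.mu_inf > 0:
            raise ValueError("require mu_0 > mu_inf > 0")
        if not 0 < self.n < 1:
            raise ValueError("power-law index n must lie in (0, 1)")
        if not self.lam > 0:
            raise ValueError("time constant lam must be positive")


@dataclass(frozen=True)
class OgdenParams:
    """Ogden series terms ``(mu_i [kPa], alpha_i)``; density in kg/m^3."""

    terms: tuple[tuple[float, float], ...] = ((19.58, 67.74), (260.56, 27.47))
    density: float = 1100.0
    rayleigh_alpha: float = 200.0  # 1/s, informational only

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("at least one Ogden term required")
        if any(mu <= 0 for mu, _ in self.terms):
            raise ValueError("all mu_i must be positive")

    @property
    def order(self) -> int:
        return len(self.terms)


def carreau_viscosity(p: CarreauParams, gamma_dot: float | np.ndarray) -> float | np.ndarray:
    """Apparent viscosity in Pa·s at shear rate ``gamma_dot`` (1/s, >= 0)."""
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    mu = p.mu_inf + (p.mu_0 - p.mu_inf) * (1.0 + (p.lam * g) ** 2) ** ((p.n - 1.0) / 2.0)
    return float(mu) if np.isscalar(gamma_dot) else mu


def ogden_energy(p: OgdenParams, stretches: tuple[float, float, float]) -> float:
    """Strain-energy density (kPa) at the given modified principal stretches.

    The caller is responsible for supplying an isochoric triple
    (l1*l2*l3 = 1) when modelling incompressible tissue; the formula itself
    evaluates at any positive stretches.
    """
    l1, l2, l3 = (float(s) for s in stretches)
    if min(l1, l2, l3) <= 0:
        raise ValueError("principal stretches must be positive")
    psi = 0.0
    for mu, alpha in p.terms:
        psi += (2.0 * mu / alpha**2) * (l1**alpha + l2**alpha + l3**alpha - 3.0)
    return psi


def ogden_uniaxial_stress(p: OgdenParams, lam: float) -> float:
    """Uniaxial Cauchy stress (kPa) on the incompressible path.

    For uniaxial stretch ``lam`` with lateral stretches ``lam**-0.5`` and the
    lateral stress eliminated by incompressibility:

        sigma = sum_i (2 mu_i / alpha_i) (lam^alpha_i - lam^(-alpha_i/2)).

    Zero at the reference state and shares the sign of ``lam - 1``.
    """
    if lam <= 0:
        raise ValueError("stretch must be positive")
    sigma = 0.0
    for mu, alpha in p.terms:
        sigma += (2.0 * mu / alpha) * (lam**alpha - lam ** (-alpha / 2.0))
    return sigma
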