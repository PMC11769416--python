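"""Plasma-interstitial solute exchange by the two-pore formalism, plus the
liver-specific generic permeability pathway.

All exchange operations return amount fluxes in nmol/h (positive = net
vascular -> interstitial) so they compose uniformly in the whole-body
balance; concentration-derivative forms are obtained at the call site by
dividing by the receiving compartment volume.

Hindered transport closure (classic cylindrical-pore theory, with
lambda = r_solute / r_pore):

    partition           Phi(lambda)  = (1 - lambda)^2
    diffusive hindrance H_d(lambda)  = Phi * (1 - 2.104 lambda + 2.09 lambda^3
                                              - 0.95 lambda^5)      [Renkin]
    convective fraction W(lambda)    = Phi * (2 - Phi) * (1 - lambda^2 / 3)
    reflection          sigma        = 1 - W                         [Curry]

For lambda >= 1 the pore excludes the solute completely: PS = 0, sigma = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .physiology import OrganPhysiology

__all__ = [
    "SoluteProperties",
    "PoreExchangeTerms",
    "stokes_einstein_diffusivity",
    "hindrance_factors",
    "pore_exchange_terms",
    "peclet_factor",
    "two_pore_flux",
    "liver_permeability_flux",
]

# Stokes-Einstein at 37 degC in water: D = kB*T / (6 pi eta r)
_KB = 1.380649e-23  # J/K
_T_BODY = 310.15  # K
_ETA_WATER_37C = 6.9e-4  # Pa s


def stokes_einstein_diffusivity(solute_radius_nm: float) -> float:
    """Free aqueous diffusion coefficient (cm^2/s) of a sphere at 37 degC."""
    if solute_radius_nm <= 0:
        raise ValueError("solute radius must be positive")
    r_m = solute_radius_nm * 1e-9
    d_m2_s = _KB * _T_BODY / (6.0 * math.pi * _ETA_WATER_37C * r_m)
    return d_m2_s * 1e4  # m^2/s -> cm^2/s


@dataclass
class SoluteProperties:
    """Size/diffusivity description of the extravasating solute."""

    molecular_weight: float  # g/mol
    solute_radius: float  # nm
    D_free: Optional[float] = None  # cm^2/s; Stokes-Einstein estimate if None

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0 or self.solute_radius <= 0:
            raise ValueError("molecular weight and solute radius must be positive")
        if self.D_free is None:
            self.D_free = stokes_einstein_diffusivity(self.solute_radius)
        if self.D_free <= 0:
            raise ValueError("D_free must be positive")


@dataclass
class PoreExchangeTerms:
    """Precomputed per-organ exchange coefficients for both pore classes."""

    PS_S: float  # L/h
    PS_L: float  # L/h
    Pe_S: float  # dimensionless
    Pe_L: float  # dimensionless
    sigma_S: float
    sigma_L: float


def hindrance_factors(lam: float) -> tuple[float, float]:
    """Return (diffusive hindrance H_d, reflection coefficient sigma).

    ``lam`` is the solute-to-pore radius ratio. Full steric exclusion
    (lam >= 1) gives (0, 1).
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if lam >= 1.0:
        return 0.0, 1.0
    phi = (1.0 - lam) ** 2
    h_d = phi * (1.0 - 2.104 * lam + 2.09 * lam**3 - 0.95 * lam**5)
    h_d = max(h_d, 0.0)
    w = phi * (2.0 - phi) * (1.0 - lam**2 / 3.0)
    sigma = min(max(1.0 - w, 0.0), 1.0)
    return h_d, sigma


def peclet_factor(pe: float) -> float:
    """Pe / (exp(Pe) - 1), with the analytic limit 1 at Pe = 0."""
    if pe == 0.0:
        return 1.0
    if pe > 700.0:  # exp overflow guard; factor is numerically 0 here
        return 0.0
    return pe / math.expm1(pe)


def pore_exchange_terms(organ: OrganPhysiology, solute: SoluteProperties) -> PoreExchangeTerms:
    """Compute PS, sigma and Pe for the small and large pore class of one organ.

    PS per pore class = H_d(lambda) * D_free * (A0/dx) * area fraction of the
    class, converted to L/h. Pe = J * (1 - sigma) / PS.
    """
    d_cm2_h = solute.D_free * 3600.0

    out = {}
    for cls, r_pore, a_frac, j_flow in (
        ("S", organ.r_S, 1.0 - organ.A0_frac_L, organ.J_S),
        ("L", organ.r_L, organ.A0_frac_L, organ.J_L),
    ):
        lam = solute.solute_radius / r_pore
        h_d, sigma = hindrance_factors(lam)
        ps = h_d * d_cm2_h * organ.A0_dx * a_frac / 1000.0  # cm^3/h -> L/h
        if ps > 0.0:
            pe = j_flow * (1.0 - sigma) / ps
        else:
            pe = math.inf if j_flow * (1.0 - sigma) > 0 else 0.0
        out[cls] = (ps, pe, sigma)

    return PoreExchangeTerms(
        PS_S=out["S"][0],
        PS_L=out["L"][0],
        Pe_S=out["S"][1],
        Pe_L=out["L"][1],
        sigma_S=out["S"][2],
        sigma_L=out["L"][2],
    )


def two_pore_flux(
    C_v: float,
    C_i: float,
    terms: PoreExchangeTerms,
    J_L: float,
    J_S: float,
    fu: float,
    K_iv: float,
) -> float:
    """Net transcapillary solute flux (nmol/h), two-pore formalism.

    flux = fu * sum over pore classes of
           [ J (1 - sigma) C_v  +  PS (C_v - C_i / K_iv) Pe / (e^Pe - 1) ]

    positive = net vascular -> interstitial.
    """
    if C_v < 0 or C_i < 0:
        raise ValueError("concentrations must be nonnegative")
    if not 0.0 <= fu <= 1.0:
        raise ValueError("fu must be in [0, 1]")
    if K_iv <= 0:
        raise ValueError("K_iv must be positive")
    gradient = C_v - C_i / K_iv
    flux = 0.0
    for j_flow, ps, pe, sigma in (
        (J_L, terms.PS_L, terms.Pe_L, terms.sigma_L),
        (J_S, terms.PS_S, terms.Pe_S, terms.sigma_S),
    ):
        convective = j_flow * (1.0 - sigma) * C_v
        diffusive = ps * gradient * peclet_factor(pe) if ps > 0.0 else 0.0
        flux += convective + diffusive
    return fu * flux


def liver_permeability_flux(
    C_pls: float,
    C_int: float,
    P_liver: float,
    SA_liver: float,
    fu: float,
    Kp: float,
) -> float:
    """Additional liver extravasation flux (nmol/h).

    flux = fu * P_liver * SA_liver * (C_pls - C_int / Kp), with P_liver in
    cm/min and SA_liver in cm^2 so that P*SA is a volume clearance of
    P*SA cm^3/min = 0.06 * P * SA L/h. This pathway is added on top of the
    liver two-pore flux, not replacing it.
    """
    if C_pls < 0 or C_int < 0:
        raise ValueError("concentrations must be nonnegative")
    if P_liver < 0 or SA_liver <= 0:
        raise ValueError("P_liver must be nonnegative and SA_liver positive")
    clearance_L_h = P_liver * SA_liver * 0.06  # cm^3/min -> L/h
    return fu * clearance_L_h * (C_pls - C_int / Kp)
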