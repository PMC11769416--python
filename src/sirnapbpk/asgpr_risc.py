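"""Liver-specific target-mediated drug disposition and RISC formation.

Receptor-mediated uptake chain: free receptor on the hepatocyte surface binds
free drug in the liver interstitial space (k_on / k_off); the complex is
internalized (k_int) into the endosome, where the sugar-receptor bond is
cleaved (k_cle) releasing free receptor (recycled at k_rec or degraded at
k_deg_R) and free endosomal siRNA. Endosomal siRNA exits at the
compound-specific rate k_endosome: a fraction f_escape reaches the cytoplasm,
the rest is degraded. Cytoplasmic antisense strand degrades at k_deg_C or
loads into Ago2 to form active RISC, which turns over at k_DR (the protein is
regenerated, the antisense strand is degraded, keeping the Ago2 pool fixed).

All concentrations are on an nmol/L basis; table values quoted in umol/L are
converted at construction. The derivative operations here are written on a
single shared-volume concentration basis; the whole-body assembler performs
the amount/volume bookkeeping across sub-compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

__all__ = [
    "ASGPRParameters",
    "RISCParameters",
    "TMDDDerivatives",
    "RISCDerivatives",
    "receptor_initial_state",
    "tmdd_derivatives",
    "risc_derivatives",
]

UMOL_PER_L_TO_NMOL_PER_L = 1000.0


@dataclass
class ASGPRParameters:
    """Receptor-system rate constants (nmol/L concentration basis).

    Defaults are the mouse estimates of the underlying liver-uptake model:
    R_tot 5.23 umol/L, k_on 0.53 L/nmol/h, k_off 1.53 1/h, surface receptor
    degradation k_deg 1.52 1/h, endosomal receptor degradation k_deg_R
    1.53 1/h, internalization k_int 5.14 1/h, endosomal cleavage k_cle
    1.32 1/h, receptor recycling k_rec 13.8 1/h, cytoplasmic siRNA
    degradation k_deg_C 0.10 1/h, endosomal escape fraction 1%.
    """

    R_tot: float = 5.23 * UMOL_PER_L_TO_NMOL_PER_L  # nmol/L
    k_on: float = 0.53  # L/nmol/h
    k_off: float = 1.53  # 1/h
    k_deg: float = 1.52  # 1/h, surface receptor
    k_deg_R: float = 1.53  # 1/h, endosomal receptor
    k_int: float = 5.14  # 1/h
    k_cle: float = 1.32  # 1/h
    k_rec: float = 13.8  # 1/h
    k_deg_C: float = 0.10  # 1/h
    f_escape: float = 0.01  # fraction
    k_syn: float = field(default=None)  # nmol/L/h; R_tot * k_deg if omitted

    def __post_init__(self) -> None:
        if self.k_syn is None:
            self.k_syn = self.R_tot * self.k_deg
        for name in ("R_tot", "k_on", "k_off", "k_deg", "k_deg_R", "k_int",
                     "k_cle", "k_rec", "k_deg_C", "k_syn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.f_escape <= 1.0:
            raise ValueError("f_escape must be in [0, 1]")


@dataclass
class RISCParameters:
    """Ago2/RISC pool kinetics (nmol/L basis).

    RISC_tot 0.0003 umol/L; antisense-Ago2 dissociation 1e-7 1/h; loaded-RISC
    turnover k_DR 0.0033 1/h. The association rate kon_RISC is
    compound-specific (default 0.00027 L/nmol/h).
    """

    RISC_tot: float = 0.0003 * UMOL_PER_L_TO_NMOL_PER_L  # nmol/L
    kon_RISC: float = 0.00027  # L/nmol/h
    koff_RISC: float = 1e-7  # 1/h
    k_DR: float = 0.0033  # 1/h

    def __post_init__(self) -> None:
        for name in ("RISC_tot", "kon_RISC", "koff_RISC", "k_DR"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


class TMDDDerivatives(NamedTuple):
    dD_free: float  # binding contribution only; transport added elsewhere
    dA_free: float
    dDA: float
    dDA_endosome: float
    dA_endosome: float
    dD_endosome: float
    dD_cytoplasm: float  # escape + degradation; RISC loading added elsewhere
    degraded_flux: float  # rate of drug loss to the degraded sink


class RISCDerivatives(NamedTuple):
    dD_cytoplasm: float
    dC_RISC: float
    degraded_flux: float  # antisense destroyed on loaded-RISC turnover


def receptor_initial_state(asgpr: ASGPRParameters) -> tuple[float, float]:
    """Drug-free receptor steady state: (A_free0, A_endosome0) in nmol/L."""
    if asgpr.k_deg == 0.0:
        if asgpr.k_syn > 0.0:
            raise ValueError("no receptor steady state: k_deg = 0 with k_syn > 0")
        return 0.0, 0.0
    return asgpr.k_syn / asgpr.k_deg, 0.0


def tmdd_derivatives(
    D_free: float,
    A_free: float,
    DA: float,
    A_endosome: float,
    D_endosome: float,
    D_cytoplasm: float,
    asgpr: ASGPRParameters,
    k_endosome: float,
    DA_endosome: float = 0.0,
) -> TMDDDerivatives:
    """Concentration derivatives (nmol/L/h) of the liver TMDD chain.

    ``k_endosome`` is the compound-specific endosomal degradation/escape rate.
    ``DA_endosome`` is the internalized, not-yet-cleaved complex.
    """
    for name, value in (
        ("D_free", D_free), ("A_free", A_free), ("DA", DA),
        ("A_endosome", A_endosome), ("D_endosome", D_endosome),
        ("D_cytoplasm", D_cytoplasm), ("DA_endosome", DA_endosome),
    ):
        if value < 0:
            raise ValueError(f"{name} must be nonnegative, got {value}")
    if k_endosome < 0:
        raise ValueError("k_endosome must be nonnegative")

    bind = asgpr.k_on * D_free * A_free
    dA_free = (asgpr.k_syn - asgpr.k_deg * A_free - bind + asgpr.k_off * DA
               + asgpr.k_rec * A_endosome)
    dD_free = -bind + asgpr.k_off * DA
    dDA = bind - asgpr.k_off * DA - asgpr.k_int * DA
    dDA_endosome = asgpr.k_int * DA - asgpr.k_cle * DA_endosome
    dA_endosome = (asgpr.k_cle * DA_endosome
                   - (asgpr.k_rec + asgpr.k_deg_R) * A_endosome)
    exit_flux = k_endosome * D_endosome
    dD_endosome = asgpr.k_cle * DA_endosome - exit_flux
    dD_cytoplasm = asgpr.f_escape * exit_flux - asgpr.k_deg_C * D_cytoplasm
    degraded = (1.0 - asgpr.f_escape) * exit_flux + asgpr.k_deg_C * D_cytoplasm
    return TMDDDerivatives(dD_free, dA_free, dDA, dDA_endosome, dA_endosome,
                           dD_endosome, dD_cytoplasm, degraded)


def risc_derivatives(
    D_cytoplasm: float,
    C_RISC: float,
    risc: RISCParameters,
) -> RISCDerivatives:
    """Concentration derivatives (nmol/L/h) of RISC loading and turnover."""
    if D_cytoplasm < 0:
        raise ValueError("D_cytoplasm must be nonnegative")
    if not 0.0 <= C_RISC <= risc.RISC_tot * (1.0 + 1e-9):
        raise ValueError(
            f"C_RISC must be in [0, RISC_tot={risc.RISC_tot}], got {C_RISC}"
        )
    bind = risc.kon_RISC * D_cytoplasm * (risc.RISC_tot - C_RISC)
    dC_RISC = bind - (risc.koff_RISC + risc.k_DR) * C_RISC
    dD_cytoplasm = -bind + risc.koff_RISC * C_RISC
    return RISCDerivatives(dD_cytoplasm, dC_RISC, risc.k_DR * C_RISC)
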