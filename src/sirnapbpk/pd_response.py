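"""Indirect-response pharmacodynamics: mRNA silencing and protein knockdown.

Both response variables are expressed as percent of their pre-dose baseline
(fixed at 100%). Loaded RISC stimulates mRNA degradation through a saturable
term; protein production tracks the mRNA level raised to an empirical power.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PDParameters",
    "baseline_synthesis",
    "mrna_derivative",
    "protein_derivative",
    "steady_state_response",
]


@dataclass
class PDParameters:
    """Compound-specific pharmacodynamic constants."""

    Smax: float  # maximum stimulation of mRNA degradation (dimensionless)
    SC50: float  # loaded RISC at half-maximal stimulation, nmol/L
    gamma: float  # power coefficient for protein knockdown
    k_deg_mRNA: float = 0.06  # 1/h
    k_deg_protein: float = 0.05  # 1/h
    mRNA0: float = 100.0  # percent
    Protein0: float = 100.0  # percent

    def __post_init__(self) -> None:
        if self.Smax < 0:
            raise ValueError("Smax must be nonnegative")
        if self.SC50 <= 0:
            raise ValueError("SC50 must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.k_deg_mRNA < 0 or self.k_deg_protein < 0:
            raise ValueError("degradation rate constants must be nonnegative")
        if self.mRNA0 != 100.0 or self.Protein0 != 100.0:
            raise ValueError("baselines are fixed at 100%")


def baseline_synthesis(k_deg: float, baseline: float = 100.0) -> float:
    """Zero-order synthesis rate (%/h) holding a turnover pool at baseline."""
    if k_deg < 0:
        raise ValueError("k_deg must be nonnegative")
    return k_deg * baseline


def mrna_derivative(mRNA: float, C_RISC: float, pd: PDParameters) -> float:
    """d(mRNA)/dt in %/h: fixed synthesis, RISC-stimulated degradation."""
    if mRNA < 0 or C_RISC < 0:
        raise ValueError("mRNA and C_RISC must be nonnegative")
    stimulation = 1.0 + pd.Smax * C_RISC / (pd.SC50 + C_RISC)
    return pd.k_deg_mRNA * pd.mRNA0 - stimulation * pd.k_deg_mRNA * mRNA


def protein_derivative(Protein: float, mRNA: float, pd: PDParameters) -> float:
    """d(Protein)/dt in %/h: production scales with (mRNA/baseline)^gamma."""
    if Protein < 0 or mRNA < 0:
        raise ValueError("Protein and mRNA must be nonnegative")
    production = pd.Protein0 * (mRNA / pd.mRNA0) ** pd.gamma
    return pd.k_deg_protein * (production - Protein)


def steady_state_response(C_RISC: float, pd: PDParameters) -> tuple[float, float]:
    """Closed-form (mRNA_ss, Protein_ss) in % under clamped loaded RISC."""
    if C_RISC < 0:
        raise ValueError("C_RISC must be nonnegative")
    stimulation = 1.0 + pd.Smax * C_RISC / (pd.SC50 + C_RISC)
    mrna_ss = pd.mRNA0 / stimulation
    protein_ss = pd.Protein0 * (mrna_ss / pd.mRNA0) ** pd.gamma
    return mrna_ss, protein_ss
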