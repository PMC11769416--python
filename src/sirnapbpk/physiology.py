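"""Mouse whole-body physiology: organ volumes, plasma and lymph flows,
capillary surface areas and pore geometry.

The bundled table describes a reference 0.025 kg mouse. Volumes, flows,
surface areas and the glomerular filtration rate scale linearly with body
weight; dimensionless fractions and pore radii do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional

__all__ = [
    "OrganPhysiology",
    "PhysiologyTable",
    "UnsupportedSpeciesError",
    "load_physiology",
    "validate_physiology",
    "REQUIRED_ORGANS",
    "SPLANCHNIC_ORGANS",
]

#: The 15 individually represented tissue compartments.
REQUIRED_ORGANS = (
    "lung",
    "heart",
    "brain",
    "muscle",
    "bone",
    "skin",
    "fat",
    "stomach",
    "small_intestine",
    "large_intestine",
    "spleen",
    "pancreas",
    "liver",
    "kidney",
    "gonads",
)

#: Organs whose venous outflow drains through the portal vein into the liver.
SPLANCHNIC_ORGANS = ("stomach", "small_intestine", "large_intestine", "spleen", "pancreas")


class UnsupportedSpeciesError(ValueError):
    """Raised when a physiology is requested for a species not bundled."""


@dataclass
class OrganPhysiology:
    """Per-organ physiological constants for the circulation/exchange model."""

    name: str
    V_vas: float  # vascular (plasma) sub-compartment volume, L
    V_int: float  # interstitial volume, L
    V_endo: float  # endothelial endosomal volume, L
    V_cell: float  # intracellular volume, L
    Q_plasma: float  # plasma inflow, L/h (liver: hepatic artery only)
    J_lymph: float  # total transcapillary/lymph fluid flow, L/h
    SA_cap: float  # capillary surface area, cm^2
    A0_dx: float  # total pore cross-section area / membrane thickness, cm
    A0_frac_L: float  # fraction of pore cross-section area in large pores
    alpha_L: float  # fraction of lymph fluid flow through large pores
    r_S: float  # small pore radius, nm
    r_L: float  # large pore radius, nm

    @property
    def J_L(self) -> float:
        """Large-pore fluid flow, L/h."""
        return self.alpha_L * self.J_lymph

    @property
    def J_S(self) -> float:
        """Small-pore fluid flow, L/h."""
        return (1.0 - self.alpha_L) * self.J_lymph

    @property
    def V_total(self) -> float:
        return self.V_vas + self.V_int + self.V_endo + self.V_cell


@dataclass
class PhysiologyTable:
    """Whole-body physiological parameter set for one animal."""

    organs: Dict[str, OrganPhysiology]
    body_weight: float  # kg
    GFR: float  # L/h
    hematocrit: float  # fraction
    V_venous: float  # venous plasma pool, L
    V_arterial: float  # arterial plasma pool, L
    species: str = "mouse"
    reference_weight: float = 0.025  # kg of the bundled table

    def __getitem__(self, organ: str) -> OrganPhysiology:
        return self.organs[organ]

    @property
    def cardiac_output_plasma(self) -> float:
        """Plasma cardiac output = lung inflow, L/h."""
        return self.organs["lung"].Q_plasma

    def liver_plasma_inflow(self) -> float:
        """Hepatic artery plus portal (splanchnic venous) plasma inflow, L/h."""
        liver = self.organs["liver"]
        portal = sum(
            self.organs[o].Q_plasma - self.organs[o].J_lymph for o in SPLANCHNIC_ORGANS
        )
        return liver.Q_plasma + portal


def _data_path() -> Path:
    return Path(str(resources.files("sirnapbpk").joinpath("data/mouse_physiology.tsv")))


def _parse_table(path: Path) -> tuple[dict, List[dict]]:
    meta: dict = {}
    header: Optional[List[str]] = None
    rows: List[dict] = []
    for line in path.read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key = key.strip()
                val = val.strip()
                if key and " " not in key:
                    meta[key] = val
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            continue
        rows.append(dict(zip(header, parts)))
    if header is None:
        raise ValueError(f"no table header found in {path}")
    return meta, rows


def load_physiology(
    species: str = "mouse",
    body_weight: Optional[float] = None,
    path: Optional[str | Path] = None,
) -> PhysiologyTable:
    """Load the bundled (or user-supplied) physiology table.

    Parameters
    ----------
    species:
        Only ``"mouse"`` is supported.
    body_weight:
        Animal body weight in kg. Volumes, flows, surface areas and GFR are
        scaled linearly relative to the table's reference weight. Defaults to
        the reference weight itself.
    path:
        Optional override path to a tab-delimited physiology file using the
        bundled schema.
    """
    if species != "mouse":
        raise UnsupportedSpeciesError(
            f"unsupported species {species!r}: only 'mouse' physiology is bundled"
        )
    file = Path(path) if path is not None else _data_path()
    meta, rows = _parse_table(file)

    ref_weight = float(meta["body_weight_ref_kg"])
    if body_weight is None:
        body_weight = ref_weight
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    f = body_weight / ref_weight

    r_S = float(meta["r_small_nm"])
    r_L = float(meta["r_large_nm"])

    organs: Dict[str, OrganPhysiology] = {}
    for row in rows:
        V_total = float(row["V_total_mL"]) * 1e-3  # mL -> L
        f_vas = float(row["f_vascular"])
        f_int = float(row["f_interstitial"])
        f_endo = float(row["f_endosomal"])
        Q = float(row["Q_plasma_L_per_h"])
        organs[row["organ"]] = OrganPhysiology(
            name=row["organ"],
            V_vas=f * V_total * f_vas,
            V_int=f * V_total * f_int,
            V_endo=f * V_total * f_endo,
            V_cell=f * V_total * (1.0 - f_vas - f_int - f_endo),
            Q_plasma=f * Q,
            J_lymph=f * float(row["lymph_frac"]) * Q,
            SA_cap=f * float(row["SA_cap_cm2"]),
            A0_dx=f * float(row["A0_dx_cm"]),
            A0_frac_L=float(row["A0_frac_large"]),
            alpha_L=float(row["alpha_large"]),
            r_S=r_S,
            r_L=r_L,
        )

    return PhysiologyTable(
        organs=organs,
        body_weight=body_weight,
        GFR=f * float(meta["GFR_L_per_h"]),
        hematocrit=float(meta["hematocrit"]),
        V_venous=f * float(meta["V_venous_plasma_L"]),
        V_arterial=f * float(meta["V_arterial_plasma_L"]),
        species=species,
        reference_weight=ref_weight,
    )


def validate_physiology(table: PhysiologyTable) -> List[str]:
    """Return a list of violated invariants (empty for a valid table)."""
    violations: List[str] = []

    for organ in REQUIRED_ORGANS:
        if organ not in table.organs:
            violations.append(f"missing required organ: {organ}")

    for name, o in table.organs.items():
        for field_name in ("V_vas", "V_int", "V_endo", "V_cell", "Q_plasma", "SA_cap", "A0_dx"):
            value = getattr(o, field_name)
            if not value > 0:
                violations.append(f"{name}.{field_name} must be strictly positive, got {value}")
        if o.J_lymph < 0:
            violations.append(f"{name}.J_lymph must be nonnegative, got {o.J_lymph}")
        if o.J_lymph > o.Q_plasma:
            violations.append(f"{name}: J_lymph ({o.J_lymph}) exceeds Q_plasma ({o.Q_plasma})")
        if not 0.0 <= o.A0_frac_L <= 1.0:
            violations.append(f"{name}.A0_frac_L must be in [0, 1], got {o.A0_frac_L}")
        if not 0.0 <= o.alpha_L <= 1.0:
            violations.append(f"{name}.alpha_L must be in [0, 1], got {o.alpha_L}")
        if not o.r_S < o.r_L:
            violations.append(f"{name}: r_S ({o.r_S}) must be smaller than r_L ({o.r_L})")

    if not table.body_weight > 0:
        violations.append(f"body_weight must be positive, got {table.body_weight}")
    if not table.GFR > 0:
        violations.append(f"GFR must be positive, got {table.GFR}")
    if not 0.0 < table.hematocrit < 1.0:
        violations.append(f"hematocrit must be in (0, 1), got {table.hematocrit}")
    for field_name in ("V_venous", "V_arterial"):
        if not getattr(table, field_name) > 0:
            violations.append(f"{field_name} must be positive")

    # Circulation consistency: non-lung organ inflows must sum to cardiac
    # plasma output within 1%.
    if "lung" in table.organs:
        co = table.cardiac_output_plasma
        total = sum(o.Q_plasma for n, o in table.organs.items() if n != "lung")
        if co > 0 and abs(total - co) / co > 0.01:
            violations.append(
                f"sum of organ plasma flows ({total:.5f} L/h) deviates from "
                f"cardiac plasma output ({co:.5f} L/h) by more than 1%"
            )

    return violations


def scale_table(table: PhysiologyTable, factor: float) -> PhysiologyTable:
    """Return a copy with all extensive quantities multiplied by ``factor``."""
    organs = {
        name: replace(
            o,
            V_vas=o.V_vas * factor,
            V_int=o.V_int * factor,
            V_endo=o.V_endo * factor,
            V_cell=o.V_cell * factor,
            Q_plasma=o.Q_plasma * factor,
            J_lymph=o.J_lymph * factor,
            SA_cap=o.SA_cap * factor,
            A0_dx=o.A0_dx * factor,
        )
        for name, o in table.organs.items()
    }
    return replace(
        table,
        organs=organs,
        body_weight=table.body_weight * factor,
        GFR=table.GFR * factor,
        V_venous=table.V_venous * factor,
        V_arterial=table.V_arterial * factor,
    )
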