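"""Whole-body ODE assembly and integration.

Internal unit discipline: amounts in nmol, volumes in L, concentrations in
nmol/L, time in hours. Per-minute rate constants are converted (x60) at
assembly; receptor/RISC pool sizes quoted in umol/L are converted to nmol/L
at parameter construction.

State layout (one labeled amount per entry, all nmol except the two percent
PD states):

    depot                          subcutaneous depot
    venous, arterial               central plasma pools
    <organ>:vas, <organ>:int       per-organ vascular / interstitial drug
    <organ>:endo                   endothelial-endosomal drug (non-liver)
    liver:A_free, liver:DA, liver:DA_endo, liver:A_endo
                                   receptor species / receptor-drug complex
    liver:D_endo, liver:D_cyt, liver:C_RISC
                                   endosomal, cytoplasmic and RISC-loaded drug
    mRNA, protein                  percent-of-baseline PD states
    urine, degraded                cumulative elimination sinks

Everything except the receptor-binding, RISC-loading and PD terms is linear,
so the right-hand side is y' = A y + b + n(y) with a precomputed dense A.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .asgpr_risc import ASGPRParameters, RISCParameters, receptor_initial_state
from .extravasation import SoluteProperties, liver_permeability_flux, pore_exchange_terms, two_pore_flux
from .pd_response import PDParameters
from .physiology import PhysiologyTable, REQUIRED_ORGANS, SPLANCHNIC_ORGANS, load_physiology

__all__ = [
    "CompoundParameters",
    "GlobalDispositionParameters",
    "DoseEvent",
    "SimulationResult",
    "PBPKModel",
    "AssemblyError",
    "assemble_model",
    "apply_dose",
    "simulate",
    "total_drug_amount",
    "apply_overrides",
    "OBSERVABLE_UNITS",
]

MIN_TO_H = 60.0


class AssemblyError(ValueError):
    """Raised when the whole-body system cannot be assembled."""


@dataclass
class CompoundParameters:
    """Compound-specific PK constants.

    ``F_by_dose`` optionally overrides the bioavailability for specific
    SC doses (mg/kg), matched exactly.
    """

    name: str
    k_endosome: float  # 1/h, endosomal degradation/escape rate
    kon_RISC: float = 0.00027  # L/nmol/h
    molecular_weight: float = 16000.0  # g/mol
    solute_radius: float = 1.0  # nm
    fu: float = 1.0
    Kp: float = 0.94
    ka: float = 0.84  # 1/h
    F: float = 1.0  # SC bioavailability fraction
    F_by_dose: Dict[float, float] = field(default_factory=dict)
    stabilization: str = "ESC"
    pd: Optional[PDParameters] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fu <= 1.0:
            raise ValueError("fu must be in [0, 1]")
        if not 0.0 <= self.F <= 1.0:
            raise ValueError("F must be in [0, 1]")
        for name in ("k_endosome", "kon_RISC", "ka", "Kp",
                     "molecular_weight", "solute_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def bioavailability(self, dose_mg_kg: float) -> float:
        return self.F_by_dose.get(dose_mg_kg, self.F)


@dataclass
class GlobalDispositionParameters:
    """Global disposition constants (table units: per-minute rates, umol/L
    ribonuclease pools); converted to the hour basis at assembly."""

    k_uptake: float = 20.87  # 1/min, endosomal uptake, remaining tissues
    k_recycling: float = 0.000077  # 1/min
    k_kid_uptake: float = 68.2  # 1/min, kidney
    k_kid_recycling: float = 0.00039  # 1/min
    k_RNase: float = 0.00012  # L/umol/h (bimolecular, see note below)
    RNase_kidney: float = 1.17  # umol/L
    RNase_remaining: float = 0.17  # umol/L
    P_liver: float = 0.02  # cm/min

    # NOTE: the combining rule for the ribonuclease reaction is a documented
    # reconstruction: a pseudo-first-order rate k_RNase * [RNase_tissue] is
    # applied to plasma and to the interstitial + endosomal drug of every
    # organ except the liver (kidney uses its own RNase pool).

    def __post_init__(self) -> None:
        for name in ("k_uptake", "k_recycling", "k_kid_uptake", "k_kid_recycling",
                     "k_RNase", "RNase_kidney", "RNase_remaining", "P_liver"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class DoseEvent:
    time: float  # h
    route: str  # "IV" | "SC"
    dose: float  # mg/kg
    body_weight: float = 0.025  # kg

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be nonnegative")
        if self.time < 0:
            raise ValueError("dose time must be nonnegative")
        route = self.route.upper()
        if route not in ("IV", "SC"):
            raise ValueError(f"unknown route {self.route!r} (expected IV or SC)")
        self.route = route

    def amount_nmol(self, molecular_weight: float) -> float:
        """Administered amount in nmol (pre-bioavailability)."""
        return self.dose * self.body_weight * 1e6 / molecular_weight


OBSERVABLE_UNITS = {
    "plasma": "nmol/L",
    "plasma_ng_mL": "ng/mL",
    "liver": "nmol/L",
    "kidney": "nmol/L",
    "RISC": "nmol/L",
    "mRNA": "%",
    "protein": "%",
}


@dataclass
class SimulationResult:
    """Time grid plus labeled state trajectories and derived observables."""

    t: np.ndarray  # h
    states: np.ndarray  # (n_states, n_t)
    state_names: List[str]
    observables: Dict[str, np.ndarray]
    units: Dict[str, str]
    compound: str = ""

    def state(self, name: str) -> np.ndarray:
        return self.states[self.state_names.index(name)]

    def to_tidy_frame(self):
        """Tidy (time, observable, value, unit) table of the observables."""
        import pandas as pd

        rows = []
        for name, values in self.observables.items():
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": self.t,
                        "observable": name,
                        "value": values,
                        "unit": self.units[name],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


class PBPKModel:
    """Assembled whole-body system: y' = A y + b + n(y)."""

    def __init__(
        self,
        compound: CompoundParameters,
        globals_: GlobalDispositionParameters,
        physiology: PhysiologyTable,
        asgpr: ASGPRParameters,
        risc: RISCParameters,
    ):
        self.compound = compound
        self.globals = globals_
        self.physiology = physiology
        self.asgpr = asgpr
        self.risc = risc
        if compound.pd is None:
            raise AssemblyError("compound has no PD parameter block attached")
        self.pd: PDParameters = compound.pd

        missing = [o for o in REQUIRED_ORGANS if o not in physiology.organs]
        if missing:
            raise AssemblyError(f"physiology table missing organs: {missing}")

        self._build_layout()
        self._build_system()

    # -- layout ---------------------------------------------------------
    def _build_layout(self) -> None:
        names: List[str] = ["depot", "venous", "arterial"]
        for organ in REQUIRED_ORGANS:
            names.append(f"{organ}:vas")
            names.append(f"{organ}:int")
            if organ != "liver":
                names.append(f"{organ}:endo")
        names += [
            "liver:A_free",
            "liver:DA",
            "liver:DA_endo",
            "liver:A_endo",
            "liver:D_endo",
            "liver:D_cyt",
            "liver:C_RISC",
            "mRNA",
            "protein",
            "urine",
            "degraded",
        ]
        self.state_names = names
        self.index = {n: i for i, n in enumerate(names)}
        self.n_states = len(names)

        receptor_only = {"liver:A_free", "liver:A_endo"}
        non_drug = receptor_only | {"mRNA", "protein"}
        self.drug_mask = np.array([n not in non_drug for n in names])
        # Drug still resident in the body (excludes sinks and depot).
        self.in_body_mask = self.drug_mask.copy()
        for n in ("urine", "degraded", "depot"):
            self.in_body_mask[self.index[n]] = False

    # -- assembly -------------------------------------------------------
    def _build_system(self) -> None:
        c, g, phys = self.compound, self.globals, self.physiology
        idx = self.index
        n = self.n_states
        A = np.zeros((n, n))
        b = np.zeros(n)

        def transfer(src: str, dst: str, rate: float) -> None:
            """First-order amount transfer src -> dst at `rate` (1/h)."""
            if rate < 0:
                raise AssemblyError(f"negative rate for {src} -> {dst}")
            A[idx[src], idx[src]] -= rate
            A[idx[dst], idx[src]] += rate

        solute = SoluteProperties(c.molecular_weight, c.solute_radius)

        # --- SC absorption
        transfer("depot", "venous", c.ka)

        # --- circulation
        co = phys.cardiac_output_plasma
        lung = phys["lung"]
        transfer("venous", "lung:vas", co / phys.V_venous)
        transfer("lung:vas", "arterial", (co - lung.J_lymph) / lung.V_vas)
        liver_inflow = phys["liver"].Q_plasma
        for organ in REQUIRED_ORGANS:
            if organ == "lung":
                continue
            o = phys[organ]
            transfer("arterial", f"{organ}:vas", o.Q_plasma / phys.V_arterial)
            if organ in SPLANCHNIC_ORGANS:
                out = o.Q_plasma - o.J_lymph
                transfer(f"{organ}:vas", "liver:vas", out / o.V_vas)
                liver_inflow += out
            elif organ != "liver":
                transfer(f"{organ}:vas", "venous", (o.Q_plasma - o.J_lymph) / o.V_vas)
        liver = phys["liver"]
        transfer("liver:vas", "venous", (liver_inflow - liver.J_lymph) / liver.V_vas)

        # --- two-pore extravasation + lymph return, every organ
        self.pore_terms = {}
        for organ in REQUIRED_ORGANS:
            o = phys[organ]
            terms = pore_exchange_terms(o, solute)
            self.pore_terms[organ] = terms
            pf_sum = 0.0
            conv = 0.0
            for j_flow, ps, pe, sigma in (
                (o.J_L, terms.PS_L, terms.Pe_L, terms.sigma_L),
                (o.J_S, terms.PS_S, terms.Pe_S, terms.sigma_S),
            ):
                conv += j_flow * (1.0 - sigma)
                if ps > 0.0:
                    pf_sum += ps * pe / np.expm1(pe) if pe != 0.0 else ps
            # vascular -> interstitial: fu * (conv + PS*Pf) * C_v
            transfer(f"{organ}:vas", f"{organ}:int", c.fu * (conv + pf_sum) / o.V_vas)
            # interstitial -> vascular: fu * PS*Pf / Kp * C_i
            transfer(f"{organ}:int", f"{organ}:vas", c.fu * pf_sum / (c.Kp * o.V_int))
            # lymph drains interstitial fluid back to venous plasma
            transfer(f"{organ}:int", "venous", o.J_lymph / o.V_int)

        # --- liver-specific permeability pathway (added, not replacing)
        clearance = c.fu * g.P_liver * liver.SA_cap * 0.06  # L/h
        transfer("liver:vas", "liver:int", clearance / liver.V_vas)
        transfer("liver:int", "liver:vas", clearance / (c.Kp * liver.V_int))

        # --- unspecific endosomal trafficking (non-liver organs)
        for organ in REQUIRED_ORGANS:
            if organ == "liver":
                continue
            if organ == "kidney":
                k_up, k_rec = g.k_kid_uptake * MIN_TO_H, g.k_kid_recycling * MIN_TO_H
            else:
                k_up, k_rec = g.k_uptake * MIN_TO_H, g.k_recycling * MIN_TO_H
            transfer(f"{organ}:int", f"{organ}:endo", k_up)
            transfer(f"{organ}:endo", f"{organ}:int", k_rec)

        # --- ribonuclease degradation (plasma + all organs except liver)
        k_plasma = g.k_RNase * g.RNase_remaining
        for name in ("venous", "arterial"):
            transfer(name, "degraded", k_plasma)
        for organ in REQUIRED_ORGANS:
            if organ == "liver":
                continue
            rnase = g.RNase_kidney if organ == "kidney" else g.RNase_remaining
            k_tissue = g.k_RNase * rnase
            transfer(f"{organ}:vas", "degraded", k_plasma)
            transfer(f"{organ}:int", "degraded", k_tissue)
            transfer(f"{organ}:endo", "degraded", k_tissue)

        # --- renal filtration of unbound drug
        kidney = phys["kidney"]
        transfer("kidney:vas", "urine", c.fu * phys.GFR / kidney.V_vas)

        # --- liver TMDD linear terms (binding is nonlinear, added in rhs)
        a = self.asgpr
        transfer("liver:DA", "liver:DA_endo", a.k_int)
        # k_off returns complex to free drug + free receptor
        A[idx["liver:DA"], idx["liver:DA"]] -= a.k_off
        A[idx["liver:int"], idx["liver:DA"]] += a.k_off
        A[idx["liver:A_free"], idx["liver:DA"]] += a.k_off
        # cleavage splits the endosomal complex into receptor + siRNA
        A[idx["liver:DA_endo"], idx["liver:DA_endo"]] -= a.k_cle
        A[idx["liver:A_endo"], idx["liver:DA_endo"]] += a.k_cle
        A[idx["liver:D_endo"], idx["liver:DA_endo"]] += a.k_cle
        transfer("liver:A_endo", "liver:A_free", a.k_rec)
        A[idx["liver:A_endo"], idx["liver:A_endo"]] -= a.k_deg_R  # receptor leaves
        A[idx["liver:A_free"], idx["liver:A_free"]] -= a.k_deg
        b[idx["liver:A_free"]] = a.k_syn * liver.V_int  # nmol/h
        # endosomal exit: escape fraction to cytoplasm, rest degraded
        A[idx["liver:D_endo"], idx["liver:D_endo"]] -= c.k_endosome
        A[idx["liver:D_cyt"], idx["liver:D_endo"]] += a.f_escape * c.k_endosome
        A[idx["degraded"], idx["liver:D_endo"]] += (1.0 - a.f_escape) * c.k_endosome
        transfer("liver:D_cyt", "degraded", a.k_deg_C)
        # RISC linear terms
        r = self.risc
        transfer("liver:C_RISC", "liver:D_cyt", r.koff_RISC)
        transfer("liver:C_RISC", "degraded", r.k_DR)

        self.A = A
        self.b = b

        # reference volume for cytosolic / loaded-RISC concentrations:
        # total liver tissue volume (tissue density 1 g/mL)
        self.V_liver_ref = liver.V_total
        self.RISC_tot_amount = r.RISC_tot * self.V_liver_ref  # nmol
        self._i_dint = idx["liver:int"]
        self._i_afree = idx["liver:A_free"]
        self._i_da = idx["liver:DA"]
        self._i_dcyt = idx["liver:D_cyt"]
        self._i_crisc = idx["liver:C_RISC"]
        self._i_mrna = idx["mRNA"]
        self._i_prot = idx["protein"]
        self._V_int_liver = liver.V_int

    # -- dynamics -------------------------------------------------------
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = self.A @ y + self.b
        a, r, pd = self.asgpr, self.risc, self.pd

        # receptor binding in the liver interstitial space
        bind = a.k_on * max(y[self._i_dint], 0.0) * max(y[self._i_afree], 0.0) / self._V_int_liver
        dy[self._i_dint] -= bind
        dy[self._i_afree] -= bind
        dy[self._i_da] += bind

        # RISC loading (free Ago2 pool = RISC_tot_amount - loaded)
        free_ago2 = max(self.RISC_tot_amount - y[self._i_crisc], 0.0)
        load = r.kon_RISC * max(y[self._i_dcyt], 0.0) * free_ago2 / self.V_liver_ref
        dy[self._i_dcyt] -= load
        dy[self._i_crisc] += load

        # PD block
        c_risc = max(y[self._i_crisc], 0.0) / self.V_liver_ref
        mrna = max(y[self._i_mrna], 0.0)
        protein = max(y[self._i_prot], 0.0)
        stim = 1.0 + pd.Smax * c_risc / (pd.SC50 + c_risc)
        dy[self._i_mrna] = pd.k_deg_mRNA * pd.mRNA0 - stim * pd.k_deg_mRNA * mrna
        dy[self._i_prot] = pd.k_deg_protein * (
            pd.Protein0 * (mrna / pd.mRNA0) ** pd.gamma - protein
        )
        return dy

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        J = self.A.copy()
        a, r, pd = self.asgpr, self.risc, self.pd
        d_free = max(y[self._i_dint], 0.0)
        a_free = max(y[self._i_afree], 0.0)
        kb = a.k_on / self._V_int_liver
        for i, dval in ((self._i_dint, -1.0), (self._i_afree, -1.0), (self._i_da, 1.0)):
            J[i, self._i_dint] += dval * kb * a_free
            J[i, self._i_afree] += dval * kb * d_free
        free_ago2 = max(self.RISC_tot_amount - y[self._i_crisc], 0.0)
        d_cyt = max(y[self._i_dcyt], 0.0)
        kl = r.kon_RISC / self.V_liver_ref
        for i, dval in ((self._i_dcyt, -1.0), (self._i_crisc, 1.0)):
            J[i, self._i_dcyt] += dval * kl * free_ago2
            J[i, self._i_crisc] += dval * kl * (-d_cyt)
        c_risc = max(y[self._i_crisc], 0.0) / self.V_liver_ref
        mrna = max(y[self._i_mrna], 0.0)
        stim = 1.0 + pd.Smax * c_risc / (pd.SC50 + c_risc)
        J[self._i_mrna, :] = 0.0
        J[self._i_mrna, self._i_mrna] = -stim * pd.k_deg_mRNA
        J[self._i_mrna, self._i_crisc] = (
            -pd.k_deg_mRNA * mrna * pd.Smax * pd.SC50
            / (pd.SC50 + c_risc) ** 2 / self.V_liver_ref
        )
        J[self._i_prot, :] = 0.0
        J[self._i_prot, self._i_prot] = -pd.k_deg_protein
        if pd.gamma == 0.0 or (mrna <= 0.0 and pd.gamma < 1.0):
            dprod = 0.0
        else:
            dprod = pd.k_deg_protein * pd.gamma * (mrna / pd.mRNA0) ** (pd.gamma - 1.0)
        J[self._i_prot, self._i_mrna] = dprod
        return J

    # -- state helpers --------------------------------------------------
    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(self.n_states)
        a_free0, a_endo0 = receptor_initial_state(self.asgpr)
        y0[self._i_afree] = a_free0 * self._V_int_liver
        y0[self.index["liver:A_endo"]] = a_endo0 * self._V_int_liver
        y0[self._i_mrna] = self.pd.mRNA0
        y0[self._i_prot] = self.pd.Protein0
        return y0

    def observables(self, y: np.ndarray) -> Dict[str, float]:
        idx, phys = self.index, self.physiology
        plasma = y[idx["venous"]] / phys.V_venous
        liver_states = ["liver:vas", "liver:int", "liver:DA", "liver:DA_endo",
                        "liver:D_endo", "liver:D_cyt", "liver:C_RISC"]
        liver_amt = sum(y[idx[s]] for s in liver_states)
        kidney_amt = y[idx["kidney:vas"]] + y[idx["kidney:int"]] + y[idx["kidney:endo"]]
        return {
            "plasma": plasma,
            "plasma_ng_mL": plasma * self.compound.molecular_weight * 1e-3,
            "liver": liver_amt / phys["liver"].V_total,
            "kidney": kidney_amt / phys["kidney"].V_total,
            "RISC": y[idx["liver:C_RISC"]] / self.V_liver_ref,
            "mRNA": y[idx["mRNA"]],
            "protein": y[idx["protein"]],
        }


def assemble_model(
    compound: CompoundParameters,
    globals_: Optional[GlobalDispositionParameters] = None,
    physiology: Optional[PhysiologyTable] = None,
    asgpr: Optional[ASGPRParameters] = None,
    risc: Optional[RISCParameters] = None,
) -> PBPKModel:
    """Assemble the whole-body ODE system for one compound.

    Missing parameter blocks default to the bundled global estimates; the
    compound's ``kon_RISC`` overrides the RISC block's association rate.
    """
    globals_ = globals_ if globals_ is not None else GlobalDispositionParameters()
    physiology = physiology if physiology is not None else load_physiology()
    asgpr = asgpr if asgpr is not None else ASGPRParameters()
    if risc is None:
        risc = RISCParameters(kon_RISC=compound.kon_RISC)
    return PBPKModel(compound, globals_, physiology, asgpr, risc)


def apply_dose(model: PBPKModel, state: np.ndarray, event: DoseEvent) -> np.ndarray:
    """Return a copy of ``state`` with the dose added (IV: venous plasma;
    SC: depot, booked net of pre-systemic loss, i.e. times F)."""
    out = state.copy()
    amount = event.amount_nmol(model.compound.molecular_weight)
    if event.route == "IV":
        out[model.index["venous"]] += amount
    else:
        out[model.index["depot"]] += model.compound.bioavailability(event.dose) * amount
    return out


def total_drug_amount(model: PBPKModel, state: np.ndarray) -> float:
    """Sum of all siRNA-bearing amounts (nmol), sinks and depot included."""
    return float(np.asarray(state)[model.drug_mask].sum())


class SolverError(RuntimeError):
    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last accepted time: {last_time} h)")
        self.last_time = last_time


def simulate(
    model: PBPKModel,
    doses: Sequence[DoseEvent],
    t_grid: np.ndarray,
    state0: Optional[np.ndarray] = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the system over ``t_grid`` with event restarts at dose times."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    t0, t_end = t_grid[0], t_grid[-1]
    for d in doses:
        if d.time > t_end:
            raise ValueError(f"dose at t={d.time} h outside simulation span")

    y = model.initial_state() if state0 is None else np.array(state0, dtype=float)
    doses = sorted(doses, key=lambda d: d.time)
    for d in doses:
        if d.time <= t0:
            y = apply_dose(model, y, d)
    event_times = sorted({d.time for d in doses if t0 < d.time <= t_end})

    segments = [t0] + event_times + [t_end]
    ts: List[np.ndarray] = []
    ys: List[np.ndarray] = []
    for seg_start, seg_end in zip(segments[:-1], segments[1:]):
        mask = (t_grid > seg_start) & (t_grid <= seg_end)
        t_eval = np.concatenate(([seg_start], t_grid[mask]))
        t_eval = np.unique(np.append(t_eval, seg_end))
        sol = solve_ivp(
            model.rhs,
            (seg_start, seg_end),
            y,
            method=method,
            t_eval=t_eval,
            jac=model.jac,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SolverError(f"integration failed: {sol.message}",
                              sol.t[-1] if len(sol.t) else seg_start)
        keep = np.isin(sol.t, t_grid)
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep])
        y = sol.y[:, -1].copy()
        for d in doses:
            if d.time == seg_end:
                y = apply_dose(model, y, d)

    # include t0 state (post any t<=t0 doses)
    if t_grid[0] == t0:
        y_start = model.initial_state() if state0 is None else np.array(state0, dtype=float)
        for d in doses:
            if d.time <= t0:
                y_start = apply_dose(model, y_start, d)
        ts.insert(0, np.array([t0]))
        ys.insert(0, y_start[:, None])

    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    # deduplicate (segment boundaries may coincide with grid points)
    _, unique_idx = np.unique(t_all, return_index=True)
    t_all = t_all[unique_idx]
    y_all = y_all[:, unique_idx]

    obs_names = list(OBSERVABLE_UNITS)
    obs = {name: np.empty(len(t_all)) for name in obs_names}
    for j in range(len(t_all)):
        values = model.observables(y_all[:, j])
        for name in obs_names:
            obs[name][j] = values[name]

    return SimulationResult(
        t=t_all,
        states=y_all,
        state_names=model.state_names,
        observables=obs,
        units=dict(OBSERVABLE_UNITS),
        compound=model.compound.name,
    )


# ---------------------------------------------------------------------------
# named parameter overrides (used by sensitivity analysis and fitting)

_OVERRIDE_TARGETS = {
    "compound": ("fu", "Kp", "ka", "F", "k_endosome", "kon_RISC",
                 "molecular_weight", "solute_radius"),
    "globals": ("k_uptake", "k_recycling", "k_kid_uptake", "k_kid_recycling",
                "k_RNase", "RNase_kidney", "RNase_remaining", "P_liver"),
    "asgpr": ("R_tot", "k_on", "k_off", "k_deg", "k_deg_R", "k_int", "k_cle",
              "k_rec", "k_deg_C", "f_escape", "k_syn"),
    "risc": ("RISC_tot", "koff_RISC", "k_DR"),
    "pd": ("Smax", "SC50", "gamma", "k_deg_mRNA", "k_deg_protein"),
    "physiology": ("GFR",),
}


def apply_overrides(
    compound: CompoundParameters,
    globals_: GlobalDispositionParameters,
    physiology: PhysiologyTable,
    asgpr: ASGPRParameters,
    risc: RISCParameters,
    overrides: Dict[str, float],
):
    """Return copies of the parameter blocks with named values replaced.

    Names are resolved in the order compound, globals, asgpr, risc, pd,
    physiology. Overriding ``R_tot`` or ``k_deg`` recomputes ``k_syn``
    unless ``k_syn`` itself is also overridden.
    """
    comp_kw, glob_kw, asg_kw, risc_kw, pd_kw, phys_kw = {}, {}, {}, {}, {}, {}
    for name, value in overrides.items():
        if name in _OVERRIDE_TARGETS["compound"]:
            comp_kw[name] = value
        elif name in _OVERRIDE_TARGETS["globals"]:
            glob_kw[name] = value
        elif name in _OVERRIDE_TARGETS["asgpr"]:
            asg_kw[name] = value
        elif name in _OVERRIDE_TARGETS["risc"]:
            risc_kw[name] = value
        elif name in _OVERRIDE_TARGETS["pd"]:
            pd_kw[name] = value
        elif name in _OVERRIDE_TARGETS["physiology"]:
            phys_kw[name] = value
        else:
            raise KeyError(f"unknown parameter name: {name!r}")

    if ("R_tot" in asg_kw or "k_deg" in asg_kw) and "k_syn" not in asg_kw:
        r_tot = asg_kw.get("R_tot", asgpr.R_tot)
        k_deg = asg_kw.get("k_deg", asgpr.k_deg)
        asg_kw["k_syn"] = r_tot * k_deg

    new_pd = replace(compound.pd, **pd_kw) if pd_kw else compound.pd
    new_comp = replace(compound, pd=new_pd, **comp_kw)
    new_glob = replace(globals_, **glob_kw) if glob_kw else globals_
    new_asg = replace(asgpr, **asg_kw) if asg_kw else asgpr
    new_risc = replace(risc, **risc_kw) if risc_kw else risc
    if "kon_RISC" in comp_kw:
        new_risc = replace(new_risc, kon_RISC=comp_kw["kon_RISC"])
    new_phys = replace(physiology, **phys_kw) if phys_kw else physiology
    return new_comp, new_glob, new_phys, new_asg, new_risc
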