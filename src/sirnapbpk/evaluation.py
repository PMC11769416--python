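"""Quantitative model-assessment toolkit.

Exposure (trapezoid AUC over a window), terminal half-life by log-linear
regression, geometric fold-error metrics (AFE/AAFE) with the 2-fold adequacy
rule, normalized local sensitivity coefficients with the WHO magnitude
classes, and bounded least-squares parameter estimation against observation
sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ObservationSet",
    "SensitivityRecord",
    "FitResult",
    "auc_trapezoid",
    "terminal_half_life",
    "fold_error_metrics",
    "local_sensitivity",
    "classify_sensitivity",
    "fit_parameters",
    "UndefinedHalfLifeError",
]

# concentration-type measurements are fit on the log scale; percent
# observables on the linear scale
CONCENTRATION_MEASUREMENTS = ("plasma", "liver", "kidney", "RISC")
PERCENT_MEASUREMENTS = ("mRNA", "protein")


@dataclass
class ObservationSet:
    """One time series of observations for one compound and measurement."""

    compound: str
    measurement: str  # plasma | liver | kidney | RISC | mRNA | protein
    route: str
    dose_mg_kg: float
    times: np.ndarray  # h
    values: np.ndarray
    unit: str = "nmol/L"
    provenance: str = "user"  # synthetic | user

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have matching shapes")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("observation values must be nonnegative")

    @property
    def label(self) -> str:
        return f"{self.compound}:{self.measurement}:{self.route}:{self.dose_mg_kg}"


class UndefinedHalfLifeError(ValueError):
    """Raised when the terminal phase does not decay."""


def auc_trapezoid(
    times: Sequence[float],
    values: Sequence[float],
    t0: Optional[float] = None,
    t1: Optional[float] = None,
) -> float:
    """Linear-trapezoid AUC on [t0, t1] with interpolated window edges."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing with >= 2 points")
    t0 = t[0] if t0 is None else float(t0)
    t1 = t[-1] if t1 is None else float(t1)
    if not (t[0] <= t0 < t1 <= t[-1]):
        raise ValueError(f"window [{t0}, {t1}] outside series span [{t[0]}, {t[-1]}]")
    inside = (t > t0) & (t < t1)
    tw = np.concatenate(([t0], t[inside], [t1]))
    vw = np.concatenate(([np.interp(t0, t, v)], v[inside], [np.interp(t1, t, v)]))
    if len(tw) < 2:
        raise ValueError("fewer than 2 points in AUC window")
    return float(np.trapezoid(vw, tw))


def terminal_half_life(
    times: Sequence[float],
    values: Sequence[float],
    tail_fraction: float = 0.33,
) -> float:
    """Terminal half-life (h) from log-linear regression on the tail.

    The tail window is the last ``tail_fraction`` of the time span; at least
    3 strictly positive points are required, and the fitted slope must be
    negative (decaying tail).
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if not 0.0 < tail_fraction <= 1.0:
        raise ValueError("tail_fraction must be in (0, 1]")
    cutoff = t[-1] - tail_fraction * (t[-1] - t[0])
    mask = (t >= cutoff) & (v > 0)
    if mask.sum() < 3:
        raise UndefinedHalfLifeError("fewer than 3 positive points in the tail window")
    slope, _ = np.polyfit(t[mask], np.log(v[mask]), 1)
    if slope >= 0:
        raise UndefinedHalfLifeError(f"non-decaying terminal phase (slope={slope:.3g})")
    return float(math.log(2.0) / -slope)


def observed_phase_half_life(
    times: Sequence[float],
    values: Sequence[float],
    floor_fraction: float = 0.01,
    tail_fraction: float = 1.0,
) -> float:
    """Half-life of the post-peak decay phase above a quantification floor.

    Restricts the log-linear regression to points after the peak whose value
    is at least ``floor_fraction`` of the peak, mimicking assay-limited
    sampling; the deep redistribution tail below the floor is excluded.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    i_max = int(np.argmax(v))
    mask = (np.arange(len(v)) > i_max) & (v >= floor_fraction * v[i_max])
    if mask.sum() < 3:
        raise UndefinedHalfLifeError("fewer than 3 points in the decay phase")
    return terminal_half_life(t[mask], v[mask], tail_fraction=tail_fraction)


def fold_error_metrics(ratios: Sequence[float]) -> Tuple[float, float]:
    """(AFE, AAFE) of simulated/observed exposure ratios.

    AFE is the geometric mean of the ratios; AAFE = 10^(mean |log10 ratio|).
    Adequate performance: 0.5 <= AFE <= 2 and AAFE <= 2.
    """
    r = np.asarray(ratios, dtype=float)
    if len(r) == 0:
        raise ValueError("empty ratio list")
    if np.any(r <= 0):
        raise ValueError("all ratios must be strictly positive")
    logs = np.log10(r)
    return float(10.0 ** logs.mean()), float(10.0 ** np.abs(logs).mean())


def is_adequate(afe: float, aafe: float) -> bool:
    """The 2-fold adequacy rule applied to (AFE, AAFE)."""
    return 0.5 <= afe <= 2.0 and aafe <= 2.0


def classify_sensitivity(S: float) -> str:
    """WHO magnitude class of a sensitivity coefficient."""
    if not np.isfinite(S):
        raise ValueError("sensitivity coefficient must be finite")
    a = abs(S)
    if a >= 0.5:
        return "high"
    if a >= 0.2:
        return "medium"
    if a >= 0.1:
        return "low"
    return "insignificant"


@dataclass
class SensitivityRecord:
    parameter: str
    S: float
    klass: str
    output: str
    window: Tuple[float, float]
    perturbation: float
    auc_base: float
    auc_perturbed: float

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "S": self.S,
            "class": self.klass,
            "output": self.output,
            "window_h": list(self.window),
            "perturbation": self.perturbation,
            "auc_base": self.auc_base,
            "auc_perturbed": self.auc_perturbed,
        }


def local_sensitivity(
    run: Callable[[Dict[str, float]], "object"],
    parameter: str,
    value: float,
    perturbation: float = 0.10,
    output: str = "plasma",
    window: Tuple[float, float] = (0.0, 1000.0),
    scheme: str = "forward",
    baseline=None,
) -> SensitivityRecord:
    """Normalized local sensitivity of AUC(output, window) to one parameter.

    ``run`` maps a parameter-override dict to a simulation result exposing
    ``.t`` and ``.observables``. S = (dAUC/dp) * (p / AUC) with a relative
    step of ``perturbation`` (one-sided forward difference by default,
    ``scheme="central"`` for central differences).
    """
    if value == 0.0:
        raise ValueError(
            f"parameter {parameter!r} has value 0: relative perturbation undefined"
        )

    def _auc(result) -> float:
        return auc_trapezoid(result.t, result.observables[output], *window)

    base = baseline if baseline is not None else run({})
    auc0 = _auc(base)
    if auc0 <= 0:
        raise ValueError(f"baseline AUC of {output!r} is not positive")

    up = run({parameter: value * (1.0 + perturbation)})
    auc_up = _auc(up)
    if scheme == "forward":
        s = (auc_up - auc0) / (perturbation * auc0)
    elif scheme == "central":
        down = run({parameter: value * (1.0 - perturbation)})
        s = (auc_up - _auc(down)) / (2.0 * perturbation * auc0)
    else:
        raise ValueError(f"unknown difference scheme {scheme!r}")

    return SensitivityRecord(
        parameter=parameter,
        S=float(s),
        klass=classify_sensitivity(s),
        output=output,
        window=window,
        perturbation=perturbation,
        auc_base=auc0,
        auc_perturbed=auc_up,
    )


@dataclass
class FitResult:
    estimates: Dict[str, float]
    bounds: Dict[str, Tuple[float, float]]
    objective: float
    auc_ratios: Dict[str, float]
    AFE: float
    AAFE: float
    success: bool
    message: str
    n_evaluations: int

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "objective": self.objective,
            "auc_ratios": self.auc_ratios,
            "AFE": self.AFE,
            "AAFE": self.AAFE,
            "success": self.success,
            "message": self.message,
            "n_evaluations": self.n_evaluations,
        }


class FitError(RuntimeError):
    pass


_LOG_FLOOR = 1e-12


def fit_parameters(
    predict: Callable[[Dict[str, float], ObservationSet], np.ndarray],
    observations: Sequence[ObservationSet],
    free: Dict[str, Tuple[float, float, float]],
    log_scale_parameters: bool = True,
    xtol: float = 1e-10,
    ftol: float = 1e-10,
    diff_step: float = 1e-3,
    max_nfev: Optional[int] = None,
) -> FitResult:
    """Bounded nonlinear least squares against observation sets.

    Parameters
    ----------
    predict:
        ``predict(params, obs)`` returns model predictions at ``obs.times``
        in the observation's units.
    observations:
        One or more series. Concentration-type measurements contribute
        log-scale residuals; percent observables contribute linear residuals
        (scaled by the 100% baseline).
    free:
        Mapping name -> (initial, lower, upper). Positive-bounded parameters
        are searched in log space when ``log_scale_parameters`` is set.
    """
    if not observations:
        raise ValueError("at least one observation series is required")
    if not free:
        raise ValueError("at least one free parameter is required")

    names = list(free)
    x0 = np.array([free[n][0] for n in names], dtype=float)
    lo = np.array([free[n][1] for n in names], dtype=float)
    hi = np.array([free[n][2] for n in names], dtype=float)
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("initial values must lie within bounds")

    use_log = log_scale_parameters and np.all(lo > 0)

    def pack(x: np.ndarray) -> np.ndarray:
        return np.log(x) if use_log else x

    def unpack(z: np.ndarray) -> np.ndarray:
        return np.exp(z) if use_log else z

    def residuals(z: np.ndarray) -> np.ndarray:
        params = dict(zip(names, unpack(z)))
        res: List[np.ndarray] = []
        for obs in observations:
            pred = np.asarray(predict(params, obs), dtype=float)
            if obs.measurement in PERCENT_MEASUREMENTS:
                res.append((pred - obs.values) / 100.0)
            else:
                pred = np.clip(pred, _LOG_FLOOR, None)
                vals = np.clip(obs.values, _LOG_FLOOR, None)
                res.append(np.log(pred) - np.log(vals))
        return np.concatenate(res)

    try:
        sol = least_squares(
            residuals,
            pack(x0),
            bounds=(pack(lo), pack(hi)),
            xtol=xtol,
            ftol=ftol,
            diff_step=diff_step,  # larger than the ODE solver noise floor
            max_nfev=max_nfev,
        )
    except Exception as exc:  # pragma: no cover - optimizer internals
        raise FitError(f"least-squares optimization failed: {exc}") from exc
    if not sol.success:
        raise FitError(f"no convergence: {sol.message}")

    estimates = dict(zip(names, unpack(sol.x)))

    ratios: Dict[str, float] = {}
    for obs in observations:
        if len(obs.times) < 2:
            continue
        pred = np.asarray(predict(estimates, obs), dtype=float)
        auc_obs = auc_trapezoid(obs.times, obs.values)
        auc_sim = auc_trapezoid(obs.times, pred)
        if auc_obs > 0 and auc_sim > 0:
            ratios[obs.label] = auc_sim / auc_obs
    if ratios:
        afe, aafe = fold_error_metrics(list(ratios.values()))
    else:
        afe = aafe = float("nan")

    return FitResult(
        estimates=estimates,
        bounds={n: (free[n][1], free[n][2]) for n in names},
        objective=float(2.0 * sol.cost),
        auc_ratios=ratios,
        AFE=afe,
        AAFE=aafe,
        success=bool(sol.success),
        message=str(sol.message),
        n_evaluations=int(sol.nfev),
    )
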