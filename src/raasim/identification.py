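"""Parameter identification: simplex minimisation of an RMS error for the
hormone-cascade parameters against steady-state targets, and seeded random
search (Monte Carlo) for the drug absorption parameters against
concentration-time data.

The objective is a root-mean-square of *relative* residuals by default:
the steady-state targets span six orders of magnitude (0.60 down to
3.62e-7 umol/L), so an absolute RMS would see nothing but angiotensinogen.
Rate constants and concentrations are searched in log10 space within
multiplicative bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .drug import AbsorptionParams, DoseEvent
from .errors import ConfigurationError, ConvergenceError, DomainError, SolverError
from .kinetics import HORMONES, OPTIMIZED_PARAMETERS, RAASParameters
from .physiology import SubjectParams, build_reference_body
from .simulator import (RAASSystem, SimOptions, assemble_system,
                        fast_steady_state, simulate)

logger = logging.getLogger("raasim.identification")

__all__ = [
    "FreeParameter",
    "FitTarget",
    "FitProblem",
    "FitResult",
    "rms_error",
    "fit_simplex",
    "fit_monte_carlo",
    "make_raas_fit_problem",
    "raas_steady_state_predictor",
    "make_absorption_fit_problem",
    "absorption_curve_predictor",
]

_FAILURE_ERROR = 1e6


@dataclass(frozen=True)
class FreeParameter:
    """One searched parameter with bounds and search-space scaling."""

    name: str
    initial: float
    lower: float
    upper: float
    log_scale: bool = True

    def __post_init__(self):
        if not self.lower <= self.initial <= self.upper:
            raise DomainError(
                f"{self.name}: bounds [{self.lower}, {self.upper}] must "
                f"bracket the initial value {self.initial}")
        if self.log_scale and self.lower <= 0:
            raise DomainError(f"{self.name}: log-scale requires lower bound > 0")


@dataclass(frozen=True)
class FitTarget:
    """One fitted observable with its reference value and weight."""

    observable: str
    value: float
    weight: float = 1.0

    def __post_init__(self):
        if self.weight <= 0:
            raise DomainError("target weights must be > 0")


@dataclass
class FitProblem:
    free_parameters: list[FreeParameter]
    targets: list[FitTarget]
    max_evaluations: int = 5000
    seed: int | None = None
    residual_mode: str = "relative"   # or "absolute"

    def __post_init__(self):
        if not self.targets:
            raise DomainError("a fit problem needs at least one target")

    @property
    def observed(self) -> np.ndarray:
        return np.array([t.value for t in self.targets])

    @property
    def weights(self) -> np.ndarray:
        return np.array([t.weight for t in self.targets])


@dataclass
class FitResult:
    parameters: dict[str, float]
    error: float
    initial_error: float
    n_evaluations: int
    converged: bool
    simplex_spread: float | None = None
    best_error_history: list[float] = field(default_factory=list)


def rms_error(predicted, observed, weights=None, mode: str = "relative") -> float:
    """Root-mean-square error, relative residuals by default:

        sqrt(mean(w * ((pred - obs) / obs)^2))

    ``mode="absolute"`` drops the division; required when any observed
    value is zero.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size == 0:
        raise DomainError("predicted and observed must share a nonzero shape")
    w = np.ones_like(observed) if weights is None else np.asarray(weights, float)
    if w.shape != observed.shape:
        raise DomainError("weights must match the observation vector")
    if mode == "relative":
        if np.any(observed == 0):
            raise DomainError(
                "observed contains 0; use mode='absolute' for these targets")
        resid = (predicted - observed) / observed
    elif mode == "absolute":
        resid = predicted - observed
    else:
        raise DomainError(f"unknown residual mode {mode!r}")
    return float(np.sqrt(np.mean(w * resid ** 2)))


# ---------------------------------------------------------------------------
# search-space transforms
# ---------------------------------------------------------------------------

def _to_search(problem: FitProblem, values: np.ndarray) -> np.ndarray:
    return np.array([np.log10(v) if fp.log_scale else v
                     for fp, v in zip(problem.free_parameters, values)])


def _from_search(problem: FitProblem, z: np.ndarray) -> np.ndarray:
    return np.array([10.0 ** x if fp.log_scale else x
                     for fp, x in zip(problem.free_parameters, z)])


def _bounds_search(problem: FitProblem) -> tuple[np.ndarray, np.ndarray]:
    lo = _to_search(problem, np.array([fp.lower for fp in problem.free_parameters]))
    hi = _to_search(problem, np.array([fp.upper for fp in problem.free_parameters]))
    return lo, hi


def _make_objective(problem: FitProblem,
                    model: Callable[[Mapping[str, float]], np.ndarray]):
    lo, hi = _bounds_search(problem)
    names = [fp.name for fp in problem.free_parameters]
    counter = {"n": 0}

    def objective(z: np.ndarray) -> float:
        counter["n"] += 1
        z_clipped = np.clip(z, lo, hi)
        penalty = float(np.sum((z - z_clipped) ** 2))
        values = _from_search(problem, z_clipped)
        try:
            predicted = model(dict(zip(names, values)))
        except (ConvergenceError, SolverError, DomainError, FloatingPointError):
            return _FAILURE_ERROR + penalty
        if not np.all(np.isfinite(predicted)):
            return _FAILURE_ERROR + penalty
        err = rms_error(predicted, problem.observed, problem.weights,
                        mode=problem.residual_mode)
        return err + penalty

    return objective, counter


# ---------------------------------------------------------------------------
# simplex (Nelder-Mead) identification
# ---------------------------------------------------------------------------

def fit_simplex(problem: FitProblem,
                model: Callable[[Mapping[str, float]], np.ndarray],
                *, initial_step: float = 0.5, xatol: float = 1e-6,
                fatol: float = 1e-10, n_restarts: int = 4) -> FitResult:
    """Nelder-Mead simplex minimisation of the RMS objective.

    The search runs in log10 space for log-scaled parameters with a custom
    initial simplex (``initial_step`` per coordinate — wide enough to
    travel several orders of magnitude), and restarts at the incumbent
    best with a shrinking step until the evaluation budget is spent or the
    simplex collapses.  The returned error never exceeds the initial one.
    """
    objective, counter = _make_objective(problem, model)
    names = [fp.name for fp in problem.free_parameters]
    z0 = _to_search(problem, np.array([fp.initial for fp in problem.free_parameters]))

    initial_error = objective(z0)
    best_z, best_err = z0.copy(), initial_error
    history = [initial_error]
    spread = None
    converged = False
    step = initial_step

    for attempt in range(n_restarts + 1):
        budget = problem.max_evaluations - counter["n"]
        if budget <= len(z0) + 1:
            break
        simplex = np.vstack([best_z] + [best_z + step * e
                                        for e in np.eye(len(z0))])
        res = minimize(objective, best_z, method="Nelder-Mead",
                       options={"initial_simplex": simplex, "maxfev": budget,
                                "xatol": xatol, "fatol": fatol,
                                "adaptive": len(z0) > 4})
        spread = float(np.max(np.abs(res.final_simplex[0] - res.final_simplex[0][0])))
        if res.fun < best_err:
            best_err, best_z = float(res.fun), res.x.copy()
        history.append(best_err)
        logger.info("simplex restart %d: error %.4e after %d evaluations",
                    attempt, best_err, counter["n"])
        improved = len(history) < 2 or history[-2] - history[-1] > fatol
        if res.status == 0 and not improved:
            converged = True
            break
        step *= 0.3

    lo, hi = _bounds_search(problem)
    values = _from_search(problem, np.clip(best_z, lo, hi))
    return FitResult(
        parameters=dict(zip(names, values)),
        error=min(best_err, initial_error),
        initial_error=initial_error,
        n_evaluations=counter["n"],
        converged=converged,
        simplex_spread=spread,
        best_error_history=history,
    )


# ---------------------------------------------------------------------------
# Monte Carlo (random search) identification
# ---------------------------------------------------------------------------

def fit_monte_carlo(problem: FitProblem,
                    model: Callable[[Mapping[str, float]], np.ndarray]) -> FitResult:
    """Uniform (or log-uniform) random search within bounds; returns the
    best of ``max_evaluations`` draws.  Deterministic for a fixed seed."""
    if problem.seed is None:
        raise ConfigurationError("Monte Carlo identification requires a seed")
    for fp in problem.free_parameters:
        if not (np.isfinite(fp.lower) and np.isfinite(fp.upper)):
            raise ConfigurationError(f"{fp.name}: Monte Carlo needs finite bounds")
    objective, counter = _make_objective(problem, model)
    names = [fp.name for fp in problem.free_parameters]
    lo, hi = _bounds_search(problem)
    rng = np.random.default_rng(problem.seed)

    z0 = _to_search(problem, np.array([fp.initial for fp in problem.free_parameters]))
    best_z, best_err = z0.copy(), objective(z0)
    initial_error = best_err
    history = [best_err]
    draws = rng.uniform(lo, hi, size=(max(problem.max_evaluations - 1, 0), len(lo)))
    for i, z in enumerate(draws):
        err = objective(z)
        if err < best_err:
            best_err, best_z = err, z.copy()
            logger.info("monte carlo draw %d: error %.4e", i + 1, best_err)
        history.append(best_err)

    values = _from_search(problem, best_z)
    return FitResult(
        parameters=dict(zip(names, values)),
        error=float(best_err),
        initial_error=float(initial_error),
        n_evaluations=counter["n"],
        converged=True,
        best_error_history=history,
    )


# ---------------------------------------------------------------------------
# canonical fit problems
# ---------------------------------------------------------------------------

def make_raas_fit_problem(
    base: RAASParameters,
    free: Sequence[str] = OPTIMIZED_PARAMETERS,
    bound_factor: float = 100.0,
    max_evaluations: int = 5000,
    targets: Mapping[str, float] | None = None,
) -> FitProblem:
    """The cascade identification problem: the Table-style 'optimized'
    parameters free within x(1/bound_factor)-x(bound_factor) of their
    initial values, targeting the printed venous steady-state
    concentrations."""
    tvals = dict(targets) if targets is not None else base.reference_concentrations()
    fps = [FreeParameter(name=path, initial=base.get(path),
                         lower=base.get(path) / bound_factor,
                         upper=base.get(path) * bound_factor, log_scale=True)
           for path in free]
    return FitProblem(
        free_parameters=fps,
        targets=[FitTarget(observable=sp, value=tvals[sp]) for sp in tvals],
        max_evaluations=max_evaluations,
    )


def raas_steady_state_predictor(
    base: RAASParameters,
    subject: SubjectParams | None = None,
    options: SimOptions | None = None,
    observables: Sequence[str] = HORMONES,
) -> Callable[[Mapping[str, float]], np.ndarray]:
    """Model callable mapping parameter overrides to the venous
    steady-state concentrations of the requested hormones.  Successive
    calls warm-start the steady-state solve from the previous solution."""
    body = build_reference_body(subject)
    cache: dict[str, np.ndarray | None] = {"y": None}

    def predict(values: Mapping[str, float]) -> np.ndarray:
        params = base.with_overrides(values)
        system = assemble_system(body, params, options=options)
        state = fast_steady_state(system, y_guess=cache["y"])
        cache["y"] = state.y.copy()
        return np.array([state.venous_concentration(sp) for sp in observables])

    return predict


def make_absorption_fit_problem(
    observed_ena: np.ndarray,
    observed_enaat: np.ndarray,
    seed: int,
    max_evaluations: int = 2000,
    ka_bounds: tuple[float, float] = (0.005, 0.1),
    f_abs_bounds: tuple[float, float] = (0.2, 1.0),
) -> tuple[FitProblem, np.ndarray]:
    """Random-search problem for the oral absorption parameters (ka,
    f_abs) against a sampled concentration-time curve (quantifiable
    samples only).  Returns the problem plus the stacked observation
    vector the predictor must match (Ena then Enaat)."""
    observed = np.concatenate([observed_ena, observed_enaat])
    if np.any(observed <= 0):
        raise DomainError("observed concentrations must be > 0 for relative RMS")
    problem = FitProblem(
        free_parameters=[
            FreeParameter("ka", initial=float(np.sqrt(np.prod(ka_bounds))),
                          lower=ka_bounds[0], upper=ka_bounds[1], log_scale=True),
            FreeParameter("f_abs", initial=float(np.mean(f_abs_bounds)),
                          lower=f_abs_bounds[0], upper=f_abs_bounds[1],
                          log_scale=False),
        ],
        targets=[FitTarget(f"conc_{i}", float(v)) for i, v in enumerate(observed)],
        max_evaluations=max_evaluations,
        seed=seed,
    )
    return problem, observed


def absorption_curve_predictor(
    subject: SubjectParams | None = None,
    times_ena: np.ndarray | None = None,
    times_enaat: np.ndarray | None = None,
    dose_mg: float | None = None,
    options: SimOptions | None = None,
) -> Callable[[Mapping[str, float]], np.ndarray]:
    """Model callable mapping (ka, f_abs) to stacked venous Ena/Enaat
    concentrations at the per-species sampling times after one oral dose
    at t = 0.

    The hormone cascade is frozen (the drug PK does not depend on it), and
    the search stage runs the integrator at relaxed tolerances — ample for
    concentration predictions fitted against noisy data.
    """
    subject = subject or SubjectParams()
    times_ena = np.asarray(times_ena if times_ena is not None
                           else DEFAULT_PK_TIMES_MIN, float)
    times_enaat = np.asarray(times_enaat if times_enaat is not None
                             else DEFAULT_PK_TIMES_MIN, float)
    dose = dose_mg if dose_mg is not None else subject.dose_mg
    opts = options or SimOptions(dynamic_raas=False, rtol=1e-6, atol=1e-10,
                                 check_negative=False)
    from .kinetics import load_raas_parameters
    from .simulator import drug_only_curves
    from .units import mg_to_umol
    body = build_reference_body(subject)
    system = assemble_system(body, load_raas_parameters(), options=opts)
    union = np.unique(np.concatenate([times_ena, times_enaat]))
    dose_umol = mg_to_umol(dose, system.drug.ena.molecular_weight)

    def predict(values: Mapping[str, float]) -> np.ndarray:
        system.drug.absorption = AbsorptionParams(
            ka=float(values["ka"]), f_abs=float(values["f_abs"]))
        ena_u, enaat_u = drug_only_curves(system, dose_umol, union)
        ena = ena_u[np.searchsorted(union, times_ena)]
        enaat = enaat_u[np.searchsorted(union, times_enaat)]
        return np.concatenate([ena, enaat])

    return predict


#: Clinical-like sampling times (min) spanning 0.25-48 h post dose.
DEFAULT_PK_TIMES_MIN = np.array(
    [15, 30, 45, 60, 90, 120, 180, 240, 360, 480, 720, 1080, 1440, 2160, 2880],
    dtype=float)
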