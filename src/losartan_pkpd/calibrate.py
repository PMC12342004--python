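"""Model calibration by stochastic ranking evolutionary strategy (SRES) and
practical-identifiability profiling.

The objective is the plain sum of squared distances between observed and
model-predicted concentrations, pooled over datasets and analytes; optional
inequality constraints enter through a quadratic penalty (for generic use)
or through SRES's stochastic ranking (during evolution).

SRES is a (mu, lambda) evolution strategy with log-normal self-adaptive
step sizes.  Selection ranks the offspring with a stochastic bubble sort:
when two adjacent individuals are compared, the objective decides with
probability ``pf`` (or always, if neither violates the constraints), and
the constraint violation decides otherwise.  This lets the population drift
through infeasible regions while still converging to feasible optima.

Identifiability is assessed by fix-and-refit profiling: a parameter is
pinned to a grid of values around the optimum, all remaining parameters are
re-optimized at each grid point, and the profile of re-optimized objectives
is compared against a threshold (default: 5% above the optimal objective).
A parameter is *identifiable* if the profile crosses the threshold on both
sides of the optimum, *partially identifiable* if on one side only, and
*unidentifiable* otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .genotype import km_for_genotype
from .model import DoseRegimen, PKParameters, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "FitProblem",
    "FitResult",
    "SRESSettings",
    "IdentifiabilityProfile",
    "objective",
    "sres_minimize",
    "sres_optimize",
    "profile_parameter",
    "stochastic_rank",
    "SENTINEL_OBJECTIVE",
]

#: Large finite objective returned when the simulation fails at a parameter
#: vector, so the optimizer can continue past pathological regions.
SENTINEL_OBJECTIVE = 1e12


@dataclass
class Dataset:
    """Observed concentration-time points for one genotype and analyte."""

    genotype: str
    analyte: str  # "losartan" or "e3174"
    times: np.ndarray
    conc: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.shape != self.conc.shape:
            raise ValueError("times and conc must have equal length")


@dataclass
class FitProblem:
    """Least-squares fitting problem over the PK model.

    ``free`` maps parameter names to ``(lower, upper)`` bounds.  Names are
    shared parameter names (``a``, ``k_a`` ...), a global ``k_m``, or a
    per-genotype rate written ``k_m[*1/*1]``.  ``fixed`` overrides base
    values; any parameter not free, not fixed, defaults to ``base``
    (genotype ``k_m`` defaults to the genotype table).
    ``constraints`` are callables g(params_dict) that are feasible when
    <= 0.

    ``model`` optionally replaces the PK simulator with an arbitrary
    prediction function ``model(values, dataset) -> conc`` (``values`` is
    the merged base/fixed/free dict); used for non-PK fitting problems
    such as the toy models in identifiability checks.
    """

    datasets: list[Dataset]
    free: dict[str, tuple[float, float]]
    base: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    regimen: DoseRegimen | None = None
    t_end: float = 24.0
    constraints: list[Callable[[dict], float]] = field(default_factory=list)
    penalty_weight: float = 1e3
    rtol: float = 1e-6
    atol: float = 1e-8
    model: Callable | None = None

    def __post_init__(self):
        for name, (lo, hi) in self.free.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite with lower < upper")
        horizon = self.t_end
        for ds in self.datasets:
            if np.any(ds.times < 0) or np.any(ds.times > horizon):
                raise ValueError("observation times must lie within [0, t_end]")
        if self.regimen is None:
            self.regimen = DoseRegimen.single_oral(50.0)

    @property
    def names(self) -> list[str]:
        return list(self.free)

    def bounds_array(self):
        return np.array([self.free[n] for n in self.names], dtype=float)

    def params_for(self, theta: Sequence[float], genotype: str) -> PKParameters:
        """Assemble PKParameters for one genotype from a free-parameter vector."""
        values = dict(self.base)
        values.setdefault("k_m", km_for_genotype(genotype))
        values.update(self.fixed)
        free_vals = dict(zip(self.names, theta))
        per_g = f"k_m[{genotype}]"
        for name, v in free_vals.items():
            if name == per_g:
                values["k_m"] = v
            elif name.startswith("k_m["):
                continue
            else:
                values[name] = v
        return PKParameters(**values)

    def param_dict(self, theta: Sequence[float]) -> dict:
        return dict(zip(self.names, theta))


def _ssq_and_violation(theta, problem: FitProblem):
    """Pooled sum of squares and total constraint violation at ``theta``."""
    ssq = 0.0
    if problem.model is not None:
        values = dict(problem.base)
        values.update(problem.fixed)
        values.update(problem.param_dict(theta))
        try:
            for ds in problem.datasets:
                pred = np.asarray(problem.model(values, ds), dtype=float)
                ssq += float(np.sum((ds.conc - pred) ** 2))
        except Exception as exc:
            logger.warning("model evaluation failed at %s: %s",
                           problem.param_dict(theta), exc)
            return SENTINEL_OBJECTIVE, 0.0
        viol = 0.0
        pd = problem.param_dict(theta)
        for g in problem.constraints:
            viol += max(0.0, float(g(pd))) ** 2
        return ssq, viol
    cache = {}
    for ds in problem.datasets:
        key = ds.genotype
        if key not in cache:
            t_eval = np.unique(np.concatenate([d.times for d in problem.datasets
                                               if d.genotype == ds.genotype]))
            try:
                p = problem.params_for(theta, ds.genotype)
                cache[key] = simulate(p, problem.regimen, t_end=problem.t_end,
                                      t_eval=t_eval, rtol=problem.rtol, atol=problem.atol)
            except Exception as exc:  # sentinel, not an exception: keep optimizing
                logger.warning("simulation failed at %s: %s", problem.param_dict(theta), exc)
                cache[key] = None
        res = cache[key]
        if res is None:
            return SENTINEL_OBJECTIVE, 0.0
        model_c = res.Cp if ds.analyte == "losartan" else res.Cm
        pred = np.interp(ds.times, res.t, model_c)
        ssq += float(np.sum((ds.conc - pred) ** 2))
    viol = 0.0
    pd = problem.param_dict(theta)
    for g in problem.constraints:
        viol += max(0.0, float(g(pd))) ** 2
    return ssq, viol


def objective(theta, problem: FitProblem) -> float:
    """Scalar objective: SSQ plus quadratic penalty for violated constraints."""
    ssq, viol = _ssq_and_violation(theta, problem)
    return ssq + problem.penalty_weight * viol


@dataclass
class SRESSettings:
    lam: int = 140          # offspring per generation
    mu: int = 20            # parents
    generations: int = 500
    pf: float = 0.45        # probability of objective-based comparison
    seed: int | None = None
    init_center: np.ndarray | None = None   # warm-start population center
    init_spread: float = 0.25               # fraction of bounds width around center

    def __post_init__(self):
        if not (self.lam > self.mu >= 1):
            raise ValueError("need lambda > mu >= 1")
        if self.generations < 1:
            raise ValueError("need generations >= 1")
        if not (0.0 <= self.pf <= 1.0):
            raise ValueError("pf must be in [0, 1]")


@dataclass
class FitResult:
    x: np.ndarray
    fun: float
    violation: float
    n_eval: int
    trace: list
    seed: int | None
    feasible: bool
    names: list[str] | None = None

    def as_dict(self) -> dict:
        d = {"objective": self.fun, "violation": self.violation,
             "n_eval": self.n_eval, "seed": self.seed, "feasible": self.feasible}
        if self.names:
            d["parameters"] = dict(zip(self.names, map(float, self.x)))
        else:
            d["parameters"] = list(map(float, self.x))
        return d


def stochastic_rank(f: np.ndarray, phi: np.ndarray, pf: float, rng) -> np.ndarray:
    """Stochastic-ranking bubble sort; returns an index ordering.

    With ``pf = 0`` the ranking is feasibility-first; with no violations it
    is a pure objective sort.
    """
    n = len(f)
    idx = np.arange(n)
    for _ in range(n):
        swapped = False
        for j in range(n - 1):
            i1, i2 = idx[j], idx[j + 1]
            both_feasible = phi[i1] == 0 and phi[i2] == 0
            if both_feasible or rng.random() < pf:
                out_of_order = f[i1] > f[i2]
            else:
                out_of_order = phi[i1] > phi[i2]
            if out_of_order:
                idx[j], idx[j + 1] = i2, i1
                swapped = True
        if not swapped:
            break
    return idx


def sres_minimize(fun, bounds, settings: SRESSettings = SRESSettings()) -> FitResult:
    """Minimize ``fun`` over box ``bounds`` with SRES.

    ``fun(x)`` returns either a scalar objective (unconstrained) or an
    ``(objective, violation)`` pair with violation >= 0 and 0 = feasible.
    Fully reproducible under a fixed ``settings.seed``.
    """
    bounds = np.asarray(bounds, dtype=float)
    n = bounds.shape[0]
    lb, ub = bounds[:, 0], bounds[:, 1]
    rng = np.random.default_rng(settings.seed)
    lam, mu = settings.lam, settings.mu
    tau = 1.0 / math.sqrt(2.0 * math.sqrt(n))
    tau_prime = 1.0 / math.sqrt(2.0 * n)

    def evaluate(x):
        out = fun(x)
        if isinstance(out, tuple):
            f, phi = out
        else:
            f, phi = out, 0.0
        return float(f), float(phi)

    # initial population
    if settings.init_center is not None:
        center = np.clip(np.asarray(settings.init_center, float), lb, ub)
        half = settings.init_spread * (ub - lb) / 2.0
        pop = rng.uniform(np.clip(center - half, lb, ub), np.clip(center + half, lb, ub),
                          size=(mu, n))
        pop[0] = center
    else:
        pop = rng.uniform(lb, ub, size=(mu, n))
    sigma = np.full((mu, n), 1.0) * (ub - lb) / math.sqrt(n)
    if settings.init_center is not None:
        sigma *= settings.init_spread

    n_eval = 0
    best_x, best_f, best_phi = None, np.inf, np.inf
    best_infeas_x, best_infeas_f, best_infeas_phi = None, np.inf, np.inf
    trace = []

    parent_f = np.empty(mu)
    parent_phi = np.empty(mu)
    for i in range(mu):
        parent_f[i], parent_phi[i] = evaluate(pop[i])
        n_eval += 1

    for gen in range(settings.generations):
        child = np.empty((lam, n))
        child_sigma = np.empty((lam, n))
        child_f = np.empty(lam)
        child_phi = np.empty(lam)
        for j in range(lam):
            h = j % mu
            s = sigma[h] * np.exp(tau_prime * rng.standard_normal()
                                  + tau * rng.standard_normal(n))
            s = np.minimum(s, ub - lb)
            x = pop[h] + s * rng.standard_normal(n)
            x = np.clip(x, lb, ub)
            child[j], child_sigma[j] = x, s
            child_f[j], child_phi[j] = evaluate(x)
            n_eval += 1

        order = stochastic_rank(child_f, child_phi, settings.pf, rng)
        sel = order[:mu]
        pop, sigma = child[sel].copy(), child_sigma[sel].copy()
        parent_f, parent_phi = child_f[sel].copy(), child_phi[sel].copy()

        feas = child_phi == 0
        if feas.any():
            j = np.flatnonzero(feas)[np.argmin(child_f[feas])]
            if child_f[j] < best_f:
                best_x, best_f, best_phi = child[j].copy(), child_f[j], child_phi[j]
        j = int(np.lexsort((child_f, child_phi))[0])
        if (child_phi[j], child_f[j]) < (best_infeas_phi, best_infeas_f):
            best_infeas_x = child[j].copy()
            best_infeas_f, best_infeas_phi = child_f[j], child_phi[j]
        trace.append((gen, best_f if best_x is not None else math.nan,
                      float(child_phi.min())))

    if best_x is None:  # no feasible individual found in any generation
        logger.warning("SRES found no feasible individual; returning best-penalty point")
        return FitResult(x=best_infeas_x, fun=best_infeas_f, violation=best_infeas_phi,
                         n_eval=n_eval, trace=trace, seed=settings.seed, feasible=False)
    return FitResult(x=best_x, fun=best_f, violation=0.0, n_eval=n_eval,
                     trace=trace, seed=settings.seed, feasible=True)


def sres_optimize(problem: FitProblem, settings: SRESSettings = SRESSettings()) -> FitResult:
    """SRES fit of a :class:`FitProblem`; returns the best feasible vector."""

    def fun(theta):
        return _ssq_and_violation(theta, problem)

    result = sres_minimize(fun, problem.bounds_array(), settings)
    result.names = problem.names
    return result


@dataclass
class IdentifiabilityProfile:
    """Fix-and-refit profile of one parameter.

    ``values``/``objectives`` are the scanned grid and re-optimized
    objectives (NaN where the refit failed); classification is one of
    ``identifiable``, ``partially identifiable``, ``unidentifiable``.
    """

    name: str
    values: np.ndarray
    objectives: np.ndarray
    classification: str
    threshold: float
    opt_value: float
    opt_objective: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"fixed_value": self.values, "objective": self.objectives,
                             "parameter": self.name})


def default_profile_factors(n_points: int = 15, span: float = 4.0) -> np.ndarray:
    """Multiplicative grid around the optimum: log-spaced in [1/span, span]."""
    return np.geomspace(1.0 / span, span, n_points)


def profile_parameter(problem: FitProblem, optimum: FitResult, name: str,
                      factors: np.ndarray | None = None,
                      settings: SRESSettings | None = None,
                      threshold_factor: float = 1.05,
                      threshold_floor: float = 1e-12) -> IdentifiabilityProfile:
    """Profile one free parameter of ``problem`` around ``optimum``.

    At each grid value the parameter is fixed and the remaining free
    parameters are re-optimized with a reduced-budget, warm-started SRES.
    The threshold is ``max(threshold_factor * optimum.fun, threshold_floor)``
    (the floor only matters for an exactly-zero optimum, e.g. noiseless
    synthetic data).
    """
    if name not in problem.free:
        raise KeyError(f"{name!r} is not a free parameter of the problem")
    if factors is None:
        factors = default_profile_factors()
    factors = np.asarray(factors, dtype=float)
    if settings is None:
        settings = SRESSettings(lam=20, mu=4, generations=100, pf=0.45, seed=0)

    names = problem.names
    i_name = names.index(name)
    opt_theta = np.asarray(optimum.x, dtype=float)
    opt_value = float(opt_theta[i_name])
    threshold = max(threshold_factor * optimum.fun, threshold_floor)

    reduced_free = {n: b for n, b in problem.free.items() if n != name}
    center = np.array([opt_theta[names.index(n)] for n in reduced_free])

    values = opt_value * factors
    objectives = np.full(len(values), np.nan)
    for k, v in enumerate(values):
        sub = FitProblem(datasets=problem.datasets, free=reduced_free,
                         base=problem.base, fixed={**problem.fixed, name: float(v)},
                         regimen=problem.regimen, t_end=problem.t_end,
                         constraints=problem.constraints,
                         penalty_weight=problem.penalty_weight,
                         rtol=problem.rtol, atol=problem.atol, model=problem.model)
        sub_settings = SRESSettings(
            lam=settings.lam, mu=settings.mu, generations=settings.generations,
            pf=settings.pf, seed=None if settings.seed is None else settings.seed + k,
            init_center=center, init_spread=settings.init_spread)
        try:
            refit = sres_optimize(sub, sub_settings)
            if refit.feasible and refit.fun < SENTINEL_OBJECTIVE:
                objectives[k] = refit.fun
            else:
                logger.warning("profile refit infeasible at %s=%g", name, v)
        except Exception as exc:
            logger.warning("profile refit failed at %s=%g: %s", name, v, exc)

    below = values < opt_value
    above = values > opt_value
    ok = np.isfinite(objectives)
    crossed_low = bool(np.any(objectives[below & ok] > threshold))
    crossed_high = bool(np.any(objectives[above & ok] > threshold))
    if crossed_low and crossed_high:
        classification = "identifiable"
    elif crossed_low or crossed_high:
        classification = "partially identifiable"
    else:
        classification = "unidentifiable"
    return IdentifiabilityProfile(name=name, values=values, objectives=objectives,
                                  classification=classification, threshold=threshold,
                                  opt_value=opt_value, opt_objective=optimum.fun)
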