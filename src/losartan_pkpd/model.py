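"""Four-compartment delay-differential model of losartan and E-3174 disposition.

The model tracks losartan through stomach, small intestine, central and
peripheral compartments after oral dosing, and its active carboxylic-acid
metabolite E-3174 in a metabolite central compartment.  Gastric emptying is
modulated by a sinusoidal pyloric-flux term (mimicking open/close cycles of
the pyloric valve during the migrating motor complex); hepatic conversion of
losartan to E-3174 (CYP2C9-mediated) is first order with rate ``k_m`` and a
transit delay ``T``: drug converted at time ``t`` appears as metabolite at
``t + T``.

All reactions are first order, so the system is linear in dose.  The delayed
metabolite state does not feed back on the parent states, which lets the
delay equation be integrated exactly as a cascade: the parent subsystem is
solved first with dense output, and the metabolite equation is then driven
by the interpolated, delayed parent history (a method-of-steps scheme in
which every step can use the already-completed parent solution).

State ordering used throughout: ``[A_s, A_i, A_c, A_per, A_m, AUC_p, AUC_m]``
(amounts in nmol, running AUCs in nmol*h/L).
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PKParameters",
    "DoseRegimen",
    "SimulationResult",
    "InvalidParameterError",
    "IntegrationError",
    "IntegrityError",
    "pyloric_rate",
    "model_rhs",
    "simulate",
    "LOSARTAN_POTASSIUM_G_PER_MOL",
    "dose_mg_to_nmol",
    "STATE_NAMES",
]

STATE_NAMES = ("A_s", "A_i", "A_c", "A_per", "A_m", "AUC_p", "AUC_m")

#: Molar mass of losartan potassium (the salt actually dosed), g/mol.
LOSARTAN_POTASSIUM_G_PER_MOL = 461.0


class InvalidParameterError(ValueError):
    """A model parameter violates its positivity/sign constraint."""


class IntegrationError(RuntimeError):
    """The ODE/DDE solver failed; carries the failing time when known."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class IntegrityError(RuntimeError):
    """A physical invariant (e.g. non-negative amounts) was violated."""


def dose_mg_to_nmol(dose_mg: float, salt_molar_mass_g_per_mol: float = LOSARTAN_POTASSIUM_G_PER_MOL) -> float:
    """Convert an oral dose in mg of salt to nmol of drug."""
    if dose_mg < 0 or salt_molar_mass_g_per_mol <= 0:
        raise InvalidParameterError("dose must be >= 0 and molar mass > 0")
    return dose_mg * 1e6 / salt_molar_mass_g_per_mol


@dataclass(frozen=True)
class PKParameters:
    """Model constants.

    Attributes
    ----------
    a : float
        Pyloric-flux amplitude (1/h); peak stomach-emptying rate.
    b : float
        Pyloric-flux angular frequency (rad/h); 2*pi/b is the migrating
        motor complex period (b = 3.95 gives ~95 min).
    k_a : float
        Small-intestine -> central absorption rate constant (1/h).
    k_m : float
        Losartan -> E-3174 conversion rate constant (1/h); proxies CYP2C9
        catalytic activity and is the genotype-specific parameter.
    T : float
        Conversion transit delay (h).
    CL_p, CL_m : float
        Apparent clearances of losartan and E-3174 (L/h).
    Q : float
        Apparent inter-compartmental clearance of losartan (L/h).
    Vp1, Vp2, Vm : float
        Apparent volumes: losartan central, losartan peripheral, E-3174
        central (L).  "Apparent" because oral bioavailability is absorbed
        into volumes and clearances; there is no explicit F.
    """

    a: float
    b: float
    k_a: float
    k_m: float
    T: float
    CL_p: float
    CL_m: float
    Q: float
    Vp1: float
    Vp2: float
    Vm: float

    def __post_init__(self):
        strictly_positive = {
            "a": self.a, "b": self.b, "k_a": self.k_a, "Vp1": self.Vp1,
            "Vp2": self.Vp2, "Vm": self.Vm,
        }
        for name, value in strictly_positive.items():
            if not (value > 0) or not math.isfinite(value):
                raise InvalidParameterError(f"{name} must be strictly positive, got {value!r}")
        # rates/clearances may be zero: k_m = 0 is the no-conversion limit and
        # zero clearances give the closed (mass-conserving) system
        non_negative = {"k_m": self.k_m, "T": self.T, "CL_p": self.CL_p,
                        "CL_m": self.CL_m, "Q": self.Q}
        for name, value in non_negative.items():
            if value < 0 or not math.isfinite(value):
                raise InvalidParameterError(f"{name} must be >= 0, got {value!r}")

    def replace(self, **changes) -> "PKParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "PKParameters":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class DoseRegimen:
    """Oral dosing schedule: instantaneous deposits into the stomach.

    ``events`` is a sequence of ``(time_h, amount_nmol)`` pairs with
    non-negative, strictly increasing times and non-negative amounts (a
    zero amount is the null-input limit).  ``into`` selects the deposit
    compartment: ``"stomach"`` (oral dosing, default) or ``"intestine"``
    (bypasses gastric emptying; useful for degenerate-limit checks).
    """

    events: tuple[tuple[float, float], ...]
    label: str = ""
    into: str = "stomach"

    def __post_init__(self):
        events = tuple((float(t), float(amt)) for t, amt in self.events)
        object.__setattr__(self, "events", events)
        times = [t for t, _ in events]
        if any(t < 0 for t in times):
            raise InvalidParameterError("dose times must be non-negative")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise InvalidParameterError("dose times must be strictly increasing")
        if any(amt < 0 for _, amt in events):
            raise InvalidParameterError("dose amounts must be non-negative")
        if self.into not in ("stomach", "intestine"):
            raise InvalidParameterError(f"unknown dose compartment {self.into!r}")

    @classmethod
    def single_oral(cls, dose_mg: float = 50.0, time_h: float = 0.0,
                    salt_molar_mass_g_per_mol: float = LOSARTAN_POTASSIUM_G_PER_MOL,
                    label: str | None = None) -> "DoseRegimen":
        """Single oral dose given in mg of losartan potassium."""
        amount = dose_mg_to_nmol(dose_mg, salt_molar_mass_g_per_mol)
        return cls(events=((time_h, amount),),
                   label=label if label is not None else f"{dose_mg:g} mg single oral dose")

    @property
    def total_amount(self) -> float:
        return sum(amt for _, amt in self.events)

    def first_dose_time(self) -> float:
        return self.events[0][0] if self.events else 0.0


@dataclass
class SimulationResult:
    """Dense simulation output.

    ``states`` has shape ``(len(t), 7)`` in :data:`STATE_NAMES` order.
    ``Cp = A_c / Vp1`` and ``Cm = A_m / Vm`` pointwise (nM).
    """

    t: np.ndarray
    Cp: np.ndarray
    Cm: np.ndarray
    states: np.ndarray
    params: PKParameters
    regimen: DoseRegimen
    #: callable t -> A_c(t) from the dense parent solution (0 before dosing)
    parent_history: Callable[[float], float] | None = field(default=None, repr=False)

    def state(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def auc_p(self) -> float:
        return float(self.states[-1, 5])

    @property
    def auc_m(self) -> float:
        return float(self.states[-1, 6])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_h": self.t,
            "Cp_nM": self.Cp,
            "Cm_nM": self.Cm,
            "AUCp": self.states[:, 5],
            "AUCm": self.states[:, 6],
        })


def pyloric_rate(t, a: float, b: float):
    """Instantaneous stomach -> small-intestine transfer rate (1/h).

    ``rate(t) = a * (1 + sin(b*t)) / 2``: non-negative, bounded by ``a``,
    periodic with period ``2*pi/b`` and time-average ``a/2``.  The valve is
    fully closed when ``sin(b*t) = -1``.
    """
    if not (a > 0) or not (b > 0):
        raise InvalidParameterError("pyloric amplitude a and frequency b must be positive")
    return a * (1.0 + np.sin(b * np.asarray(t, dtype=float))) / 2.0


def model_rhs(t: float, state: Sequence[float], delayed_A_c: float, params: PKParameters) -> np.ndarray:
    """Time derivative of the full 7-component state.

    ``delayed_A_c`` is ``A_c(t - T)`` (zero for arguments before the first
    dose).  The seven first-order reactions: (1) stomach emptying through the
    pyloric valve, (2) intestinal absorption, (3) conversion of losartan to
    E-3174 (delayed appearance), (4) losartan clearance, (5)/(6)
    central<->peripheral distribution, (7) E-3174 clearance; plus the two
    AUC bookkeeping equations dAUC_p/dt = Cp, dAUC_m/dt = Cm.
    """
    p = params
    A_s, A_i, A_c, A_per, A_m = state[0], state[1], state[2], state[3], state[4]
    rate = p.a * (1.0 + math.sin(p.b * t)) / 2.0
    dA_s = -rate * A_s
    dA_i = rate * A_s - p.k_a * A_i
    dA_c = (p.k_a * A_i - p.k_m * A_c - (p.CL_p / p.Vp1) * A_c
            - (p.Q / p.Vp1) * A_c + (p.Q / p.Vp2) * A_per)
    dA_per = (p.Q / p.Vp1) * A_c - (p.Q / p.Vp2) * A_per
    dA_m = p.k_m * delayed_A_c - (p.CL_m / p.Vm) * A_m
    dAUC_p = A_c / p.Vp1
    dAUC_m = A_m / p.Vm
    return np.array([dA_s, dA_i, dA_c, dA_per, dA_m, dAUC_p, dAUC_m])


class _ParentHistory:
    """Piecewise dense solution of the parent (losartan) subsystem.

    Evaluates A_c(t); returns 0.0 for times at or before the first dose.
    """

    def __init__(self, segments, t0: float):
        # segments: list of (t_start, t_end, OdeSolution over 5-dim parent state)
        self.segments = segments
        self.starts = [s[0] for s in segments]
        self.t0 = t0

    def __call__(self, t: float) -> float:
        if t <= self.t0:
            return 0.0
        i = bisect.bisect_right(self.starts, t) - 1
        i = min(max(i, 0), len(self.segments) - 1)
        t_start, t_end, sol = self.segments[i]
        return float(sol(min(max(t, t_start), t_end))[2])


def _integrate_segments(rhs, y0, breakpoints, jumps, rtol, atol, method):
    """Integrate ``rhs`` across ``breakpoints``, applying state ``jumps``
    (dict time -> additive state vector) at segment starts.  Returns the
    list of (t_start, t_end, dense solution) segments and the final state."""
    segments = []
    y = np.array(y0, dtype=float)
    for t_start, t_end in zip(breakpoints[:-1], breakpoints[1:]):
        if t_start in jumps:
            y = y + jumps[t_start]
        sol = solve_ivp(rhs, (t_start, t_end), y, method=method,
                        dense_output=True, rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"solver failed in [{t_start}, {t_end}]: {sol.message}", t_fail=float(sol.t[-1]))
        segments.append((t_start, t_end, sol.sol))
        y = sol.y[:, -1]
    return segments, y


def _eval_segments(segments, t_grid, dim):
    """Evaluate a list of dense segments on a grid.  A grid point equal to a
    segment start (a dose time) takes the post-dose value."""
    out = np.empty((len(t_grid), dim))
    starts = [s[0] for s in segments]
    seg_idx = np.clip(np.searchsorted(starts, t_grid, side="right") - 1,
                      0, len(segments) - 1)
    for i, (t_start, t_end, sol) in enumerate(segments):
        mask = seg_idx == i
        if mask.any():
            ts = np.clip(t_grid[mask], t_start, t_end)
            out[mask] = sol(ts).T
    return out


def simulate(params: PKParameters, regimen: DoseRegimen, t_end: float = 24.0,
             n_out: int = 2401, t_eval: np.ndarray | None = None,
             rtol: float = 1e-8, atol: float = 1e-10,
             method: str = "LSODA") -> SimulationResult:
    """Simulate the model from t = 0 to ``t_end``.

    The parent (losartan) subsystem is integrated first with dense output,
    restarting at every dose event (instantaneous addition to the stomach
    amount).  The metabolite equation, whose formation term reads the parent
    history at ``t - T``, is then integrated against that interpolated
    history; this is exact for this model because the metabolite does not
    feed back on the parent.

    Parameters
    ----------
    t_eval : array, optional
        Explicit output times; overrides the uniform ``n_out``-point grid.

    Returns
    -------
    SimulationResult
        Dense trajectory with concentrations and running AUCs.
    """
    if not regimen.events:
        raise InvalidParameterError("regimen must contain at least one dose event")
    if t_end <= regimen.events[-1][0]:
        raise InvalidParameterError("t_end must exceed the last dose time")
    if t_eval is None:
        if n_out < 2:
            raise InvalidParameterError("n_out must be >= 2")
        t_grid = np.linspace(0.0, t_end, int(n_out))
    else:
        t_grid = np.asarray(t_eval, dtype=float)
        if t_grid.ndim != 1 or np.any(np.diff(t_grid) < 0) or t_grid[0] < 0 or t_grid[-1] > t_end:
            raise InvalidParameterError("t_eval must be non-decreasing within [0, t_end]")

    p = params
    dose_times = [t for t, _ in regimen.events]
    dose_idx = 0 if regimen.into == "stomach" else 1
    jumps = {}
    for t, amt in regimen.events:
        vec = np.zeros(5)
        vec[dose_idx] = amt
        jumps[t] = vec

    # --- stage 1: parent subsystem [A_s, A_i, A_c, A_per, AUC_p] ---
    def parent_rhs(t, y):
        full = model_rhs(t, (y[0], y[1], y[2], y[3], 0.0), 0.0, p)
        return full[[0, 1, 2, 3, 5]]

    bp = np.unique(np.concatenate(([0.0], dose_times, [t_end])))
    bp = bp[(bp >= 0.0) & (bp <= t_end)]
    parent_jumps = {t: jumps[t] for t in jumps}
    parent_segments, _ = _integrate_segments(parent_rhs, np.zeros(5), list(bp),
                                             parent_jumps, rtol, atol, method)
    history = _ParentHistory(parent_segments, t0=dose_times[0])

    # --- stage 2: metabolite [A_m, AUC_m], driven by delayed parent history ---
    ke_m = p.CL_m / p.Vm

    def metabolite_rhs(t, y):
        dA_m = p.k_m * history(t - p.T) - ke_m * y[0]
        return np.array([dA_m, y[0] / p.Vm])

    # break where the forcing has kinks: dose times shifted by the delay
    met_bp = np.unique(np.concatenate(([0.0], bp, np.asarray(dose_times) + p.T, [t_end])))
    met_bp = met_bp[(met_bp >= 0.0) & (met_bp <= t_end)]
    met_segments, _ = _integrate_segments(metabolite_rhs, np.zeros(2), list(met_bp),
                                          {}, rtol, atol, method)

    parent_states = _eval_segments(parent_segments, t_grid, 5)
    met_states = _eval_segments(met_segments, t_grid, 2)

    states = np.column_stack([
        parent_states[:, 0:4], met_states[:, 0:1], parent_states[:, 4:5], met_states[:, 1:2],
    ])

    amounts = states[:, :5]
    scale = max(regimen.total_amount, 1.0)
    if amounts.min() < -1e-6 * scale:
        raise IntegrityError(
            f"negative compartment amount beyond tolerance: min {amounts.min():.3e} nmol")
    # clip solver-level negative dust
    states[:, :5] = np.clip(amounts, 0.0, None)

    Cp = states[:, 2] / p.Vp1
    Cm = states[:, 4] / p.Vm
    return SimulationResult(t=t_grid, Cp=Cp, Cm=Cm, states=states,
                            params=params, regimen=regimen, parent_history=history)
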