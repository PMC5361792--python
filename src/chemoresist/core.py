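"""Conjoint normal–tumor chemotherapy dynamics with intrinsic and drug-induced resistance.

This module implements a deterministic compartment model of a growing tumor
under chemotherapy, in which the tumor consists of up to three sub-populations
sharing one logistic niche with the surrounding normal tissue:

* ``T``   — wild (drug-responsive) tumor cells,
* ``T_M`` — mutated tumor cells: still drug-responsive, but carrying a gene
  that converts them to resistant cells when they interact with the drug,
* ``T_R`` — drug-resistant tumor cells, untouched by the first drug and
  targetable only by a second drug in combination therapy,
* ``N``   — normal cells, coupled to the total tumor burden through a
  critical-size interaction term.

Two model variants are provided.  The *intrinsic* variant has no mutated
compartment: wild cells convert directly to resistant cells at a constant
per-capita rate ``tau``.  The *extended* variant adds the mutated compartment,
a wild→mutated transition ``tau2``, a wild→resistant transition ``tau1`` and a
drug-driven mutated→resistant conversion ``tau_MR * (1 - exp(-M*C))``.

Drug action on every susceptible compartment is a saturating kill term
``a * (1 - exp(-M*C(t)))`` where ``a`` is the compartment's induced death rate
(day^-1), ``M`` the drug efficiency coefficient (m^2/mg) and ``C(t)`` the
concentration at the tumor site (mg/m^2), either constant or decaying
exponentially after a therapy start time.

The module is organised in the order a simulation runs: domain types, dosing
profiles and gates, model right-hand sides, the integration engine, trajectory
analytics (detectability / extinction / dominance), the four bundled treatment
scenarios with initial-condition calibration, and file I/O (config, tables,
plots).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

logger = logging.getLogger("chemoresist")

__all__ = [
    "PopulationState",
    "ModelParams",
    "DrugSchedule",
    "GateTimes",
    "ScenarioSpec",
    "ScenarioResult",
    "Trajectory",
    "AnalyticsReport",
    "IntegrationError",
    "CalibrationError",
    "ConfigError",
    "kill_rate",
    "coupling_term",
    "rhs_intrinsic",
    "rhs_extended",
    "concentration",
    "gate",
    "integrate",
    "first_crossing_time",
    "extinction_time",
    "dominant_population",
    "analyze",
    "preset",
    "PRESET_NAMES",
    "run_scenario",
    "calibrate_initial_conditions",
    "load_scenario_config",
    "save_scenario_config",
    "write_trajectory",
    "read_trajectory",
    "plot_scenario",
]

#: Output grid spacing in days.  Fine enough that interpolated event times are
#: stable well below the one-day precision at which detection times are quoted.
GRID_STEP = 0.5

#: Default solver tolerances (relative; absolute in cells).
RTOL = 1e-8
ATOL = 1e-6

#: Tumor burden treated as clinically detectable (cells).
DETECTION_THRESHOLD = 2e5

#: A population below this count for the rest of the horizon has died out.
EXTINCTION_EPS = 1.0

#: Column order used everywhere a trajectory is laid out as a table.
POPULATIONS = ("N", "T", "T_R", "T_M")

#: Tumor compartments, in dominance tie-break priority order.
TUMOR_POPULATIONS = ("T", "T_M", "T_R")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


def _require_nonneg(name: str, value: float) -> None:
    _require_finite(name, value)
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")


def _require_positive(name: str, value: float) -> None:
    _require_finite(name, value)
    if value <= 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class PopulationState:
    """Instantaneous cell counts of the four compartments (cells).

    ``T_M`` stays fixed at 0 in the intrinsic model, which has no mutated
    compartment.
    """

    N: float
    T: float
    T_R: float = 0.0
    T_M: float = 0.0

    def __post_init__(self) -> None:
        for name in ("N", "T", "T_R", "T_M"):
            _require_nonneg(name, getattr(self, name))

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in POPULATIONS}


@dataclass(frozen=True)
class ModelParams:
    """Growth, coupling and transition parameters shared by both model variants.

    Rates are per day, capacities and the critical tumor size ``T_star`` in
    cells.  ``tau`` is the single mutation rate of the intrinsic model;
    ``tau1``/``tau2`` are the wild→resistant and wild→mutated transition rates
    of the extended model and ``tau_MR`` its drug-driven mutated→resistant
    conversion rate.
    """

    r_N: float = 0.5
    r_T: float = 0.25
    r_R: float = 0.25
    r_M: float = 0.25
    K_N: float = 1e6
    K_T: float = 1e6
    K_R: float = 1e6
    K_M: float = 1e6
    kappa: float = 0.0124
    T_star: float = 3e5
    tau: float = 0.0
    tau1: float = 0.0
    tau2: float = 0.0
    tau_MR: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_N", "r_T", "r_R", "r_M", "kappa", "tau", "tau1", "tau2", "tau_MR"):
            _require_nonneg(name, getattr(self, name))
        for name in ("K_N", "K_T", "K_R", "K_M", "T_star"):
            _require_positive(name, getattr(self, name))


@dataclass(frozen=True)
class DrugSchedule:
    """One drug's concentration-vs-time rule plus its kill coefficients.

    The concentration is 0 before ``t_start`` and afterwards either constant at
    ``C0`` (``decay_rate == 0``) or decaying exponentially.  By default the
    decay clock is absolute simulation time (``C0 * exp(-decay_rate * t)``);
    set ``decay_from_start`` to measure the decay from ``t_start`` instead.

    ``kill_*`` are the induced per-capita death coefficients ``a_i`` (day^-1)
    this drug applies to each compartment; coefficients for compartments a drug
    does not touch are simply 0.
    """

    C0: float
    t_start: float = 0.0
    decay_rate: float = 0.0
    M: float = 1.0
    kill_N: float = 0.0
    kill_T: float = 0.0
    kill_TM: float = 0.0
    kill_TR: float = 0.0
    decay_from_start: bool = False

    def __post_init__(self) -> None:
        for name in ("C0", "t_start", "decay_rate", "M", "kill_N", "kill_T", "kill_TM", "kill_TR"):
            _require_nonneg(name, getattr(self, name))


@dataclass(frozen=True)
class GateTimes:
    """On-times (days) of the extended model's transition terms.

    Each gated term is absent before its on-time and fully active from it
    (hard 0/1 switch, closed on the left).
    """

    t_tau2_on: float = 0.0
    t_conv_on: float = 0.0
    t_tau1_on: float = 0.0

    def __post_init__(self) -> None:
        for name in ("t_tau2_on", "t_conv_on", "t_tau1_on"):
            _require_nonneg(name, getattr(self, name))


# ---------------------------------------------------------------------------
# Dosing: concentration profiles and gates
# ---------------------------------------------------------------------------


def concentration(t: float, sched: DrugSchedule) -> float:
    """Drug concentration at the tumor site at time ``t`` (mg/m^2).

    0 before ``sched.t_start``; afterwards the plateau ``C0`` or the
    exponential decay ``C0 * exp(-decay_rate * clock)`` where the clock is the
    absolute time ``t`` (default) or ``t - t_start`` when
    ``sched.decay_from_start`` is set.
    """
    _require_nonneg("t", t)
    if t < sched.t_start:
        return 0.0
    if sched.decay_rate == 0.0:
        return sched.C0
    clock = t - sched.t_start if sched.decay_from_start else t
    return sched.C0 * math.exp(-sched.decay_rate * clock)


def gate(t: float, t_on: float) -> float:
    """Hard switch: 1.0 once ``t`` has reached ``t_on``, else 0.0."""
    _require_nonneg("t", t)
    _require_nonneg("t_on", t_on)
    return 1.0 if t >= t_on else 0.0


# ---------------------------------------------------------------------------
# Model right-hand sides
# ---------------------------------------------------------------------------

ConcFn = Callable[[float, DrugSchedule], float]


def kill_rate(a: float, M: float, C: float) -> float:
    """Saturating chemotherapy-induced death rate ``a * (1 - exp(-M*C))``.

    ``a`` (day^-1) is the compartment's induced death coefficient, ``M``
    (m^2/mg) the drug efficiency coefficient and ``C`` (mg/m^2) the current
    concentration.  The result rises monotonically from 0 (no drug) and
    saturates at ``a`` for large ``M*C``.
    """
    _require_nonneg("a", a)
    _require_nonneg("M", M)
    _require_nonneg("C", C)
    return a * -math.expm1(-M * C)


def coupling_term(T_total: float, kappa: float, T_star: float) -> float:
    """Tumor→normal interaction term ``kappa * T_total * (1 - T_total/T_star)``.

    Positive (stimulatory) below the critical tumor size ``T_star`` and
    negative above it: large tumors suppress normal cells.
    """
    _require_nonneg("T_total", T_total)
    _require_nonneg("kappa", kappa)
    _require_positive("T_star", T_star)
    return kappa * T_total * (1.0 - T_total / T_star)


def _unpack(state, n: int):
    """Accept a PopulationState or a plain sequence of compartment counts."""
    if isinstance(state, PopulationState):
        if n == 3:
            if state.T_M != 0.0:
                raise ValueError("intrinsic model has no mutated compartment; T_M must be 0")
            return state.T, state.T_R, state.N
        return state.T, state.T_R, state.T_M, state.N
    vals = tuple(float(v) for v in state)
    if len(vals) != n:
        raise ValueError(f"expected {n} compartment values, got {len(vals)}")
    return vals


def rhs_intrinsic(
    t: float,
    state,
    params: ModelParams,
    drug: DrugSchedule,
    conc_at: Optional[ConcFn] = None,
) -> tuple:
    """Time derivatives ``(dT, dT_R, dN)`` of the intrinsic-resistance model.

    Wild tumor cells grow logistically against the shared burden ``T + T_R``,
    lose cells to the resistant compartment at rate ``tau`` and to the drug at
    ``kill_rate(a_T, M, C(t))``; resistant cells receive the mutation flux and
    grow logistically; normal cells grow logistically, feel the tumor through
    the critical-size coupling and are killed by the drug at rate ``a_N``.

    ``state`` may be a :class:`PopulationState` (with ``T_M == 0``) or a plain
    ``(T, T_R, N)`` triple, which is what the integration engine passes.
    """
    T, T_R, N = _unpack(state, 3)
    C = (conc_at or concentration)(t, drug)
    burden = T + T_R
    dT = params.r_T * T * (1.0 - burden / params.K_T) - params.tau * T - kill_rate(drug.kill_T, drug.M, C) * T
    dT_R = params.r_R * T_R * (1.0 - burden / params.K_R) + params.tau * T
    dN = (
        params.r_N * N * (1.0 - N / params.K_N)
        + coupling_term(burden, params.kappa, params.T_star)
        - kill_rate(drug.kill_N, drug.M, C) * N
    )
    return dT, dT_R, dN


def rhs_extended(
    t: float,
    state,
    params: ModelParams,
    drug1: DrugSchedule,
    drug2: Optional[DrugSchedule],
    gates: GateTimes,
    conc_at: Optional[ConcFn] = None,
) -> tuple:
    """Time derivatives ``(dT, dT_R, dT_M, dN)`` of the extended model.

    On top of the intrinsic structure, wild cells also feed a mutated
    compartment (rate ``tau2``, gated at ``gates.t_tau2_on``), and mutated
    cells are partially killed by drug 1 (coefficient ``kill_TM``) and
    partially converted to resistant cells at the drug-driven rate
    ``tau_MR * (1 - exp(-M*C1))`` once the conversion gate is open.  A second
    drug, effective only on resistant cells (coefficient ``kill_TR``), models
    combination therapy; pass ``drug2=None`` for monotherapy.

    All three tumor compartments share one logistic burden ``T + T_R + T_M``.
    ``state`` may be a :class:`PopulationState` or a plain
    ``(T, T_R, T_M, N)`` tuple.
    """
    T, T_R, T_M, N = _unpack(state, 4)
    conc = conc_at or concentration
    C1 = conc(t, drug1)
    C2 = conc(t, drug2) if drug2 is not None else 0.0
    burden = T + T_R + T_M

    g1 = gate(t, gates.t_tau1_on)
    g2 = gate(t, gates.t_tau2_on)
    gc = gate(t, gates.t_conv_on)
    response1 = -math.expm1(-drug1.M * C1)  # 1 - exp(-M*C1), shared by kill and conversion
    conversion = gc * params.tau_MR * response1 * T_M

    dT = (
        params.r_T * T * (1.0 - burden / params.K_T)
        - g1 * params.tau1 * T
        - g2 * params.tau2 * T
        - drug1.kill_T * response1 * T
    )
    dT_R = (
        params.r_R * T_R * (1.0 - burden / params.K_R)
        + g1 * params.tau1 * T
        + conversion
        - (kill_rate(drug2.kill_TR, drug2.M, C2) if drug2 is not None else 0.0) * T_R
    )
    dT_M = (
        params.r_M * T_M * (1.0 - burden / params.K_M)
        + g2 * params.tau2 * T
        - drug1.kill_TM * response1 * T_M
        - conversion
    )
    dN = (
        params.r_N * N * (1.0 - N / params.K_N)
        + coupling_term(burden, params.kappa, params.T_star)
        - drug1.kill_N * response1 * N
    )
    return dT, dT_R, dT_M, dN


# ---------------------------------------------------------------------------
# Scenario specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """A complete runnable experiment: model variant, parameters, schedules,
    gates, initial conditions, horizon and analytics thresholds."""

    name: str
    model: str  # "intrinsic" | "extended"
    params: ModelParams
    drug1: DrugSchedule
    drug2: Optional[DrugSchedule] = None
    gates: GateTimes = field(default_factory=GateTimes)
    initial_state: PopulationState = field(default_factory=lambda: PopulationState(N=1e6, T=1e4))
    horizon: float = 500.0
    detection_threshold: float = DETECTION_THRESHOLD
    extinction_eps: float = EXTINCTION_EPS

    def __post_init__(self) -> None:
        if self.model not in ("intrinsic", "extended"):
            raise ValueError(f"model must be 'intrinsic' or 'extended', got {self.model!r}")
        _require_positive("horizon", self.horizon)
        _require_positive("detection_threshold", self.detection_threshold)
        _require_positive("extinction_eps", self.extinction_eps)
        if max(self._event_times()) >= self.horizon:
            raise ValueError("horizon must exceed every therapy start and gate time")

    def _event_times(self) -> list:
        """Times at which the right-hand side is discontinuous."""
        times = [self.drug1.t_start]
        if self.drug2 is not None:
            times.append(self.drug2.t_start)
        if self.model == "extended":
            times += [self.gates.t_tau1_on, self.gates.t_tau2_on, self.gates.t_conv_on]
        return times


# ---------------------------------------------------------------------------
# Integration engine
# ---------------------------------------------------------------------------


class IntegrationError(RuntimeError):
    """Solver failure; ``last_time`` holds the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


@dataclass(eq=False)
class Trajectory:
    """A dense simulated trajectory.

    ``values`` has one row per grid time and columns in :data:`POPULATIONS`
    order (``N, T, T_R, T_M``), clamped to be non-negative.  ``meta`` records
    the scenario name, solver settings and the per-population minimum seen
    before clamping.
    """

    times: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times.size, len(POPULATIONS)):
            raise ValueError("values must have shape (len(times), 4)")
        if self.times.size:
            if self.times[0] < 0:
                raise ValueError("times must start at a non-negative time")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")

    def population(self, label: str) -> np.ndarray:
        if label not in POPULATIONS:
            raise KeyError(f"unknown population {label!r}; expected one of {POPULATIONS}")
        return self.values[:, POPULATIONS.index(label)]

    def state_at(self, index: int) -> PopulationState:
        row = self.values[index]
        return PopulationState(**{name: float(row[i]) for i, name in enumerate(POPULATIONS)})

    @property
    def final_state(self) -> PopulationState:
        return self.state_at(-1)


def _output_grid(horizon: float, step: float) -> np.ndarray:
    n = int(math.floor(horizon / step + 1e-9))
    grid = step * np.arange(n + 1)
    if grid[-1] < horizon - 1e-9 * max(1.0, horizon):
        grid = np.append(grid, horizon)
    return grid


def integrate(
    spec: ScenarioSpec,
    model: Optional[str] = None,
    *,
    rtol: float = RTOL,
    atol: float = ATOL,
    grid_step: float = GRID_STEP,
) -> Trajectory:
    """Integrate a scenario over its horizon and return the dense trajectory.

    The adaptive solver (LSODA) is restarted at every discontinuity time —
    therapy starts and gate on-times — so it never steps across a jump in the
    right-hand side.  Output is sampled on a ``grid_step``-day grid; tiny
    negative solver noise is clamped to zero at output only (the state handed
    back to the solver between segments is untouched).
    """
    model = model or spec.model
    params, d1, d2, gates = spec.params, spec.drug1, spec.drug2, spec.gates

    if model == "intrinsic":
        if spec.initial_state.T_M != 0.0:
            raise ValueError("intrinsic model requires T_M(0) = 0")

        def f(t, y):
            dT, dTR, dN = rhs_intrinsic(t, (y[0], y[1], y[3]), params, d1)
            return (dT, dTR, 0.0, dN)

    elif model == "extended":

        def f(t, y):
            return rhs_extended(t, (y[0], y[1], y[2], y[3]), params, d1, d2, gates)

    else:
        raise ValueError(f"unknown model {model!r}")

    grid = _output_grid(spec.horizon, grid_step)
    breaks = sorted({0.0, spec.horizon} | {t for t in spec._event_times() if 0.0 < t < spec.horizon})

    s0 = spec.initial_state
    y = np.array([s0.T, s0.T_R, s0.T_M, s0.N], dtype=float)
    out_t = [0.0]
    out_y = [y.copy()]
    n_steps = 0
    for a, b in zip(breaks[:-1], breaks[1:]):
        t_eval = grid[(grid > a + 1e-12) & (grid <= b + 1e-12)]
        appended_end = t_eval.size == 0 or t_eval[-1] < b - 1e-12
        if appended_end:
            t_eval = np.append(t_eval, b)
        sol = solve_ivp(f, (a, b), y, method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval)
        if not sol.success:
            last = float(sol.t[-1]) if sol.t.size else a
            raise IntegrationError(f"solver failed in segment [{a}, {b}]: {sol.message}", last)
        if not np.all(np.isfinite(sol.y)):
            raise IntegrationError(f"non-finite state in segment [{a}, {b}]", a)
        n_steps += sol.t.size
        keep = sol.y[:, :-1] if appended_end else sol.y
        keep_t = sol.t[:-1] if appended_end else sol.t
        out_t.extend(keep_t.tolist())
        out_y.extend(keep.T)
        y = sol.y[:, -1]
        logger.debug("segment [%g, %g]: %d output points, end state %s", a, b, keep_t.size, y)

    raw = np.vstack(out_y)  # columns T, T_R, T_M, N
    # reorder to POPULATIONS = (N, T, T_R, T_M)
    raw = raw[:, [3, 0, 1, 2]]
    mins = {name: float(raw[:, i].min()) for i, name in enumerate(POPULATIONS)}
    traj = Trajectory(
        times=np.array(out_t),
        values=np.maximum(raw, 0.0),
        meta={
            "scenario": spec.name,
            "model": model,
            "rtol": rtol,
            "atol": atol,
            "grid_step": grid_step,
            "min_before_clamp": mins,
        },
    )
    logger.info(
        "integrated scenario %r (%s model) over %g days: %d grid points, rtol=%g atol=%g",
        spec.name, model, spec.horizon, traj.times.size, rtol, atol,
    )
    return traj


# ---------------------------------------------------------------------------
# Trajectory analytics
# ---------------------------------------------------------------------------


def first_crossing_time(traj: Trajectory, population: str, threshold: float) -> Optional[float]:
    """Earliest time the population rises to ``threshold`` cells, or None.

    Located by linear interpolation between the bracketing grid points; if the
    population already meets the threshold at the first grid point, that time
    is returned.
    """
    _require_positive("threshold", threshold)
    v = traj.population(population)
    above = np.nonzero(v >= threshold)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0:
        return float(traj.times[0])
    lo, hi = v[i - 1], v[i]
    if hi == lo:
        return float(traj.times[i])
    frac = (threshold - lo) / (hi - lo)
    return float(traj.times[i - 1] + frac * (traj.times[i] - traj.times[i - 1]))


def extinction_time(traj: Trajectory, population: str, eps: float = EXTINCTION_EPS) -> Optional[float]:
    """Earliest time after which the population stays below ``eps`` cells.

    None if the population is still at or above ``eps`` at the end of the
    horizon; the start time if it never reached ``eps`` at all.
    """
    _require_positive("eps", eps)
    v = traj.population(population)
    if v.size == 0:
        return None
    if v[-1] >= eps:
        return None
    at_or_above = np.nonzero(v >= eps)[0]
    if at_or_above.size == 0:
        return float(traj.times[0])
    i = int(at_or_above[-1])  # v[i] >= eps > v[i+1]
    frac = (v[i] - eps) / (v[i] - v[i + 1])
    return float(traj.times[i] + frac * (traj.times[i + 1] - traj.times[i]))


def dominant_population(traj: Trajectory, t: float) -> Optional[str]:
    """Label of the largest tumor compartment at the grid point nearest ``t``.

    Normal cells are excluded.  Ties are broken in the fixed priority order
    ``T`` > ``T_M`` > ``T_R``.  Returns None when all tumor compartments are
    empty.  ``t`` must lie inside the simulated horizon.
    """
    if traj.times.size == 0 or t < traj.times[0] or t > traj.times[-1]:
        raise ValueError(f"t={t} outside simulated horizon [{traj.times[0] if traj.times.size else 0}, "
                         f"{traj.times[-1] if traj.times.size else 0}]")
    idx = int(np.argmin(np.abs(traj.times - t)))
    best, best_v = None, 0.0
    for label in TUMOR_POPULATIONS:
        v = traj.population(label)[idx]
        if v > best_v:
            best, best_v = label, v
    return best


@dataclass(frozen=True)
class AnalyticsReport:
    """Per-population detection and extinction times, the dominant tumor
    compartment at the horizon, and the final state."""

    detection_times: Mapping[str, Optional[float]]
    extinction_times: Mapping[str, Optional[float]]
    dominant: Optional[str]
    final_state: PopulationState


def analyze(traj: Trajectory, threshold: float = DETECTION_THRESHOLD, eps: float = EXTINCTION_EPS) -> AnalyticsReport:
    """Bundle detection, extinction and dominance analytics for a trajectory."""
    report = AnalyticsReport(
        detection_times={p: first_crossing_time(traj, p, threshold) for p in POPULATIONS},
        extinction_times={p: extinction_time(traj, p, eps) for p in POPULATIONS},
        dominant=dominant_population(traj, float(traj.times[-1])) if traj.times.size else None,
        final_state=traj.final_state if traj.times.size else PopulationState(0, 0),
    )
    logger.info(
        "analytics: detection %s; extinction %s; dominant at horizon: %s",
        {k: v for k, v in report.detection_times.items() if v is not None},
        {k: v for k, v in report.extinction_times.items() if v is not None},
        report.dominant,
    )
    return report


# ---------------------------------------------------------------------------
# Treatment scenarios and initial-condition calibration
# ---------------------------------------------------------------------------

PRESET_NAMES = ("a", "b", "c", "d")

# Shared settings of all four bundled treatment scenarios: equal carrying
# capacities of 1e6 cells, tumor growth 0.25/day, normal growth 0.5/day,
# critical tumor size 3e5 cells, drug efficiency M = 1 m^2/mg, first drug at
# 0.2 mg/m^2 from day 50 with induced death 0.15/day on wild and mutated
# cells, wild→mutated mutation 1e-3/day from day 0 and drug-driven
# mutated→resistant conversion 1e-4/day.
_SHARED = dict(
    r_N=0.5, r_T=0.25, r_R=0.25, r_M=0.25,
    K_N=1e6, K_T=1e6, K_R=1e6, K_M=1e6,
    kappa=0.0124, T_star=3e5,
    tau=0.0, tau2=1e-3, tau_MR=1e-4,
)


def _drug1(decay_rate: float) -> DrugSchedule:
    return DrugSchedule(
        C0=0.2, t_start=50.0, decay_rate=decay_rate, M=1.0,
        kill_N=0.15, kill_T=0.15, kill_TM=0.15, kill_TR=0.0,
    )


def preset(name: str) -> ScenarioSpec:
    """One of the four bundled treatment scenarios.

    * ``"a"`` — constant drug (0.2 mg/m^2 from day 50), mutated→resistant
      conversion from day 50, drug-induced resistance only.
    * ``"b"`` — as (a) but the conversion only becomes possible at day 150.
    * ``"c"`` — decaying drug ``0.2*exp(-0.001 t)`` from day 50, conversion
      from day 50.
    * ``"d"`` — decaying first drug as in (c), plus intrinsic resistance
      (``tau1 = 1e-4``/day) and a second, constant drug (0.6 mg/m^2 from day
      50, death rate 0.15/day) that targets resistant cells.

    Initial conditions default to ``T(0) = 1e4`` wild cells (the free variable
    of :func:`calibrate_initial_conditions`), no resistant or mutated cells,
    and normal tissue at its carrying capacity.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}")
    drug2 = None
    tau1 = 0.0
    conv_on = 50.0
    if name in ("a", "b"):
        drug1 = _drug1(decay_rate=0.0)
        if name == "b":
            conv_on = 150.0
    else:
        drug1 = _drug1(decay_rate=1e-3)
        if name == "d":
            tau1 = 1e-4
            drug2 = DrugSchedule(C0=0.6, t_start=50.0, decay_rate=0.0, M=1.0, kill_TR=0.15)
    return ScenarioSpec(
        name=name,
        model="extended",
        params=ModelParams(tau1=tau1, **_SHARED),
        drug1=drug1,
        drug2=drug2,
        gates=GateTimes(t_tau2_on=0.0, t_conv_on=conv_on, t_tau1_on=0.0),
        initial_state=PopulationState(N=1e6, T=1e4, T_R=0.0, T_M=0.0),
        horizon=500.0,
        detection_threshold=DETECTION_THRESHOLD,
        extinction_eps=EXTINCTION_EPS,
    )


@dataclass(eq=False)
class ScenarioResult:
    """A scenario, its simulated trajectory and the derived analytics."""

    spec: ScenarioSpec
    trajectory: Trajectory
    report: AnalyticsReport


def run_scenario(spec: ScenarioSpec, *, rtol: float = RTOL, atol: float = ATOL) -> ScenarioResult:
    """Integrate a scenario to its horizon and attach trajectory analytics."""
    traj = integrate(spec, rtol=rtol, atol=atol)
    report = analyze(traj, spec.detection_threshold, spec.extinction_eps)
    return ScenarioResult(spec=spec, trajectory=traj, report=report)


class CalibrationError(RuntimeError):
    """Initial-condition calibration could not bracket the target."""


def calibrate_initial_conditions(
    target_detection_time: float,
    spec: ScenarioSpec,
    free_variable: str = "T0",
    bracket: Optional[tuple] = None,
    *,
    tol_days: float = 0.5,
    max_iter: int = 80,
) -> PopulationState:
    """Find the initial wild-cell count for which resistant cells become
    detectable at a target time.

    Performs monotone bisection on ``T(0)`` over ``bracket`` (default
    ``(1, K_T)``) so that ``first_crossing_time(T_R, detection_threshold)``
    matches ``target_detection_time`` to within ``tol_days``; all other initial
    populations are held at the scenario's values.  Raises
    :class:`CalibrationError` when the residual has no sign change over the
    bracket (no feasible ``T(0)``) and no endpoint already meets the target.
    """
    if free_variable != "T0":
        raise ValueError(f"unsupported free variable {free_variable!r}; only 'T0' is calibratable")
    _require_positive("target_detection_time", target_detection_time)
    lo, hi = bracket if bracket is not None else (1.0, spec.params.K_T)
    if not (0 <= lo < hi):
        raise ValueError(f"invalid bracket ({lo}, {hi})")

    def residual(T0: float) -> float:
        state = replace(spec.initial_state, T=T0)
        traj = integrate(replace(spec, initial_state=state))
        det = first_crossing_time(traj, "T_R", spec.detection_threshold)
        if det is None:
            # never detectable: treat as "later than any target"
            return math.inf
        return det - target_detection_time

    f_lo, f_hi = residual(lo), residual(hi)
    logger.info("calibration residuals at bracket: f(%g)=%g, f(%g)=%g", lo, f_lo, hi, f_hi)
    for T0, f_val in ((lo, f_lo), (hi, f_hi)):
        if abs(f_val) <= tol_days:
            return replace(spec.initial_state, T=T0)
    if not (min(f_lo, f_hi) < 0 < max(f_lo, f_hi)):
        raise CalibrationError(
            f"no sign change over bracket ({lo:g}, {hi:g}): residuals "
            f"{f_lo:+.3g} and {f_hi:+.3g} days; the detection time cannot reach "
            f"{target_detection_time:g} days by varying T(0) alone"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = residual(mid)
        if abs(f_mid) <= tol_days:
            logger.info("calibration converged: T0=%g (residual %.3g days)", mid, f_mid)
            return replace(spec.initial_state, T=mid)
        if (f_lo < 0) == (f_mid < 0):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
        if hi - lo <= 1e-9 * max(1.0, hi):
            break
    raise CalibrationError(
        f"bisection did not reach the target within {tol_days} days "
        f"(final bracket ({lo:g}, {hi:g}))"
    )


# ---------------------------------------------------------------------------
# File I/O: scenario configs, trajectory tables, plots
# ---------------------------------------------------------------------------


class ConfigError(ValueError):
    """Malformed or invalid scenario configuration."""


_GROWTH_KEYS = ("r_N", "r_T", "r_R", "r_M", "K_N", "K_T", "K_R", "K_M", "kappa", "T_star")
_TRANSITION_KEYS = ("tau", "tau1", "tau2", "tau_MR", "t_tau1_on", "t_tau2_on", "t_conv_on")
_DRUG1_KEYS = ("C0", "decay_rate", "t_start", "M", "a_N", "a_T", "a_TM", "decay_from_start")
_DRUG2_KEYS = ("C0", "decay_rate", "t_start", "a_TR")
_STATE_KEYS = ("N", "T", "T_R", "T_M")
_THRESHOLD_KEYS = ("detection", "extinction_eps")
_TOP_KEYS = ("preset", "name", "model", "growth", "transitions", "drug1", "drug2",
             "initial_state", "horizon", "thresholds")


def _spec_to_dict(spec: ScenarioSpec) -> dict:
    p, d1 = spec.params, spec.drug1
    doc = {
        "name": spec.name,
        "model": spec.model,
        "growth": {k: getattr(p, k) for k in _GROWTH_KEYS},
        "transitions": {
            "tau": p.tau, "tau1": p.tau1, "tau2": p.tau2, "tau_MR": p.tau_MR,
            "t_tau1_on": spec.gates.t_tau1_on,
            "t_tau2_on": spec.gates.t_tau2_on,
            "t_conv_on": spec.gates.t_conv_on,
        },
        "drug1": {
            "C0": d1.C0, "decay_rate": d1.decay_rate, "t_start": d1.t_start, "M": d1.M,
            "a_N": d1.kill_N, "a_T": d1.kill_T, "a_TM": d1.kill_TM,
            "decay_from_start": d1.decay_from_start,
        },
        "initial_state": spec.initial_state.as_dict(),
        "horizon": spec.horizon,
        "thresholds": {"detection": spec.detection_threshold, "extinction_eps": spec.extinction_eps},
    }
    if spec.drug2 is not None:
        d2 = spec.drug2
        doc["drug2"] = {"C0": d2.C0, "decay_rate": d2.decay_rate, "t_start": d2.t_start, "a_TR": d2.kill_TR}
    return doc


def _check_keys(section: str, given: Mapping, allowed: Sequence[str]) -> None:
    for key in given:
        if key not in allowed:
            where = f"{section}.{key}" if section else key
            raise ConfigError(f"unknown key {where!r}")


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def _num(section: str, doc: Mapping, key: str) -> float:
    if key not in doc:
        raise ConfigError(f"missing key {section + '.' if section else ''}{key!r}")
    value = doc[key]
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"key {section + '.' if section else ''}{key!r} must be a number, got {value!r}")
    return float(value)


def _dict_to_spec(doc: Mapping) -> ScenarioSpec:
    _check_keys("", doc, _TOP_KEYS)
    if "preset" in doc:
        base = _spec_to_dict(preset(doc["preset"]))
        doc = _merge(base, {k: v for k, v in doc.items() if k != "preset"})
    for section, keys in (("growth", _GROWTH_KEYS), ("transitions", _TRANSITION_KEYS),
                          ("drug1", _DRUG1_KEYS), ("initial_state", _STATE_KEYS),
                          ("thresholds", _THRESHOLD_KEYS)):
        if section not in doc:
            raise ConfigError(f"missing section {section!r}")
        if not isinstance(doc[section], Mapping):
            raise ConfigError(f"section {section!r} must be a mapping")
        _check_keys(section, doc[section], keys)

    g, tr, d1 = doc["growth"], doc["transitions"], doc["drug1"]
    try:
        params = ModelParams(
            **{k: _num("growth", g, k) for k in _GROWTH_KEYS},
            **{k: _num("transitions", tr, k) for k in ("tau", "tau1", "tau2", "tau_MR")},
        )
        gates = GateTimes(**{k: _num("transitions", tr, k) for k in ("t_tau2_on", "t_conv_on", "t_tau1_on")})
        drug1 = DrugSchedule(
            C0=_num("drug1", d1, "C0"), decay_rate=_num("drug1", d1, "decay_rate"),
            t_start=_num("drug1", d1, "t_start"), M=_num("drug1", d1, "M"),
            kill_N=_num("drug1", d1, "a_N"), kill_T=_num("drug1", d1, "a_T"),
            kill_TM=_num("drug1", d1, "a_TM"), kill_TR=0.0,
            decay_from_start=bool(d1.get("decay_from_start", False)),
        )
        drug2 = None
        if "drug2" in doc and doc["drug2"] is not None:
            d2 = doc["drug2"]
            if not isinstance(d2, Mapping):
                raise ConfigError("section 'drug2' must be a mapping")
            _check_keys("drug2", d2, _DRUG2_KEYS)
            drug2 = DrugSchedule(
                C0=_num("drug2", d2, "C0"), decay_rate=_num("drug2", d2, "decay_rate"),
                t_start=_num("drug2", d2, "t_start"), M=drug1.M,
                kill_TR=_num("drug2", d2, "a_TR"),
            )
        state = PopulationState(**{k: _num("initial_state", doc["initial_state"], k) for k in _STATE_KEYS})
        th = doc["thresholds"]
        return ScenarioSpec(
            name=str(doc.get("name", "custom")),
            model=str(doc.get("model", "extended")),
            params=params, drug1=drug1, drug2=drug2, gates=gates,
            initial_state=state,
            horizon=_num("", doc, "horizon"),
            detection_threshold=_num("thresholds", th, "detection"),
            extinction_eps=_num("thresholds", th, "extinction_eps"),
        )
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_scenario_config(path) -> ScenarioSpec:
    """Read a YAML scenario configuration and return the validated spec.

    The document mirrors :class:`ScenarioSpec` field-for-field; when a
    ``preset`` key is given, missing keys are filled from that preset and any
    other keys act as overrides.  Unknown keys and invariant violations raise
    :class:`ConfigError` naming the offending key.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"config {path} must contain a mapping at top level")
    return _dict_to_spec(doc)


def save_scenario_config(spec: ScenarioSpec, path) -> None:
    """Write a scenario spec as a YAML document (lossless round-trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_spec_to_dict(spec), fh, sort_keys=False)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as a CSV table ``time,N,T,T_R,T_M`` (full precision)."""
    frame = pd.DataFrame({"time": traj.times})
    for label in POPULATIONS:
        frame[label] = traj.population(label)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    """Read a trajectory table previously written by :func:`write_trajectory`."""
    frame = pd.read_csv(path, float_precision="round_trip")
    expected = ["time", *POPULATIONS]
    if list(frame.columns) != expected:
        raise ValueError(f"trajectory table must have columns {expected}, got {list(frame.columns)}")
    return Trajectory(
        times=frame["time"].to_numpy(float),
        values=frame[list(POPULATIONS)].to_numpy(float),
        meta={"source": str(path)},
    )


#: Curve colors: normal black, wild orange, mutated blue, resistant red.
PLOT_COLORS = {"N": "black", "T": "tab:orange", "T_M": "tab:blue", "T_R": "tab:red"}
_PLOT_LABELS = {
    "N": "normal (N)",
    "T": "wild tumor (T)",
    "T_M": "mutated tumor (T_M)",
    "T_R": "drug-resistant tumor (T_R)",
}


def plot_scenario(result: ScenarioResult, path) -> None:
    """Render a single panel with all four population curves and the
    detectability threshold as a horizontal reference line."""
    import matplotlib.pyplot as plt

    traj = result.trajectory
    if traj.times.size == 0:
        raise ValueError("cannot plot an empty trajectory")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label in ("N", "T", "T_M", "T_R"):
        ax.plot(traj.times, traj.population(label), color=PLOT_COLORS[label], label=_PLOT_LABELS[label])
    ax.axhline(result.spec.detection_threshold, color="grey", linestyle="--", linewidth=1,
               label="detectability threshold")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("cells")
    ax.set_title(f"scenario {result.spec.name!r}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
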