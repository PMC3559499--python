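"""Four-compartment first-order kinetics of strand-break repair.

The ~172 kb circular minichromosome is tracked through four molecular forms:

* ``S``    — supercoiled (intact closed-circular) molecules,
* ``L``    — full-length linear molecules carrying a double-strand break (DSB)
  and no single-strand breaks (SSBs),
* ``LSSB`` — linear molecules that also carry SSBs,
* ``CSSB`` — relaxed (nicked) circular molecules carrying SSBs only.

Transfers between compartments are first order, with per-hour rate constants

* ``k_sd`` — repair of all SSBs in an LSSB molecule (LSSB -> L),
* ``k_ds`` — repair of the DSB in an LSSB molecule (LSSB -> CSSB),
* ``k_d``  — repair of the DSB in an L molecule (L -> S),
* ``k_s``  — repair of all SSBs in a CSSB molecule (CSSB -> S).

Each rate is the fraction of molecules transferred between compartments per
hour, not a per-break rate: a single first-order step moves a molecule with
*all* of its SSBs repaired.

DSB repair can be pharmacologically arrested (DNA-PKcs inhibitors); this is
the binary switch ``s_inh`` (0 = arrested), which zeroes both DSB-repair
rates ``k_d`` and ``k_ds``.  Partial slowing of DSB repair (homologous
recombination impairment) is a multiplier ``hr_factor`` in (0, 1] on the same
two rates.  With effective rates kd* = k_d*hr_factor*s_inh and
kds* = k_ds*hr_factor*s_inh, the governing equations are::

    dS/dt    =  kd*.L + k_s.CSSB
    dL/dt    =  k_sd.LSSB - kd*.L
    dLSSB/dt = -(k_sd + kds*).LSSB
    dCSSB/dt =  kds*.LSSB - k_s.CSSB

The system is linear with constant coefficients and lower-triangular
structure, so it admits an explicit exponential-cascade solution; a numerical
integrator is also provided and the two are required to agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import ValidationError

__all__ = [
    "RateConstants",
    "Scenario",
    "CONTROL",
    "DSB_ARREST",
    "CompartmentState",
    "Trajectory",
    "Observables",
    "COMPARTMENTS",
    "OBSERVABLE_NAMES",
    "derivatives",
    "solve",
    "observe",
    "half_time",
    "per_break_repair_time",
    "extrapolate",
]

#: Compartment order used for all array representations.
COMPARTMENTS = ("S", "L", "LSSB", "CSSB")

#: The two quantities quantitated on the pulsed-field gel.
OBSERVABLE_NAMES = ("linear_total", "supercoiled")

_CONSERVATION_TOL = 1e-9


def _require_finite_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0.0:
        raise ValidationError(f"{name} must be finite and >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class RateConstants:
    """Per-hour transfer rates between the four compartments.

    Parameters
    ----------
    k_s, k_sd, k_d, k_ds : float
        Nonnegative first-order rate constants (per hour).
    tied : bool
        If True, enforce the tied-rate constraint ``k_s == k_sd`` and
        ``k_d == k_ds`` (SSB repair proceeds at one rate whether or not the
        molecule is linear, and likewise for DSB repair).
    """

    k_s: float
    k_sd: float
    k_d: float
    k_ds: float
    tied: bool = False

    def __post_init__(self) -> None:
        for name in ("k_s", "k_sd", "k_d", "k_ds"):
            object.__setattr__(
                self, name, _require_finite_nonneg(name, getattr(self, name))
            )
        if self.tied and (self.k_s != self.k_sd or self.k_d != self.k_ds):
            raise ValidationError(
                "tied rates require k_s == k_sd and k_d == k_ds; got "
                f"k_s={self.k_s}, k_sd={self.k_sd}, k_d={self.k_d}, k_ds={self.k_ds}"
            )

    @classmethod
    def tied_rates(cls, k_s: float, k_d: float) -> "RateConstants":
        """Build a tied rate set from the two free constants."""
        return cls(k_s=k_s, k_sd=k_s, k_d=k_d, k_ds=k_d, tied=True)

    def as_dict(self) -> dict[str, float]:
        return {
            "k_s": self.k_s,
            "k_sd": self.k_sd,
            "k_d": self.k_d,
            "k_ds": self.k_ds,
        }


@dataclass(frozen=True)
class Scenario:
    """An experimental condition expressed as a modification of DSB repair.

    ``s_inh`` is 1 under normal repair and 0 when DSB repair is arrested
    (DNA-PKcs inhibition); ``hr_factor`` in (0, 1] scales DSB-repair rates to
    model partial homologous-recombination impairment.
    """

    name: str
    s_inh: int = 1
    hr_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.s_inh not in (0, 1):
            raise ValidationError(f"s_inh must be 0 or 1, got {self.s_inh!r}")
        hf = float(self.hr_factor)
        if not math.isfinite(hf) or not 0.0 < hf <= 1.0:
            raise ValidationError(f"hr_factor must be in (0, 1], got {self.hr_factor!r}")
        object.__setattr__(self, "hr_factor", hf)


CONTROL = Scenario("control", s_inh=1, hr_factor=1.0)
DSB_ARREST = Scenario("NU7441", s_inh=0, hr_factor=1.0)


@dataclass(frozen=True)
class CompartmentState:
    """Fractions of total minichromosome molecules in each form.

    Fractions must be in [0, 1] and sum to 1 within 1e-9.
    """

    S: float = 0.0
    L: float = 0.0
    LSSB: float = 0.0
    CSSB: float = 0.0

    def __post_init__(self) -> None:
        total = 0.0
        for name in COMPARTMENTS:
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < -1e-12 or v > 1.0 + 1e-12:
                raise ValidationError(f"fraction {name} must be in [0, 1], got {v!r}")
            object.__setattr__(self, name, v)
            total += v
        if abs(total - 1.0) > _CONSERVATION_TOL:
            raise ValidationError(
                f"compartment fractions must sum to 1 (got {total!r})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.L, self.LSSB, self.CSSB], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "CompartmentState":
        x = np.asarray(x, dtype=float)
        if x.shape != (4,):
            raise ValidationError(f"state array must have shape (4,), got {x.shape}")
        return cls(S=x[0], L=x[1], LSSB=x[2], CSSB=x[3])

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in COMPARTMENTS}


@dataclass(frozen=True)
class Trajectory:
    """Compartment fractions on a grid of times (hours).

    ``states`` has shape (n_times, 4) in :data:`COMPARTMENTS` order; mass is
    conserved at every time.
    """

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        if times.ndim != 1 or times.size == 0:
            raise ValidationError("times must be a nonempty 1-D array")
        if np.any(times < 0) or np.any(np.diff(times) <= 0):
            raise ValidationError("times must be nonnegative and strictly increasing")
        if states.shape != (times.size, 4):
            raise ValidationError(
                f"states must have shape ({times.size}, 4), got {states.shape}"
            )
        if np.max(np.abs(states.sum(axis=1) - 1.0)) > _CONSERVATION_TOL:
            raise ValidationError("mass not conserved along trajectory")
        if states.min() < -1e-9 or states.max() > 1.0 + 1e-9:
            raise ValidationError("compartment fractions out of [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)

    def __getattr__(self, name: str) -> np.ndarray:
        if name in COMPARTMENTS:
            return self.states[:, COMPARTMENTS.index(name)]
        raise AttributeError(name)

    def state_at(self, i: int) -> CompartmentState:
        return CompartmentState.from_array(np.clip(self.states[i], 0.0, 1.0))


@dataclass(frozen=True)
class Observables:
    """The two gel-quantitated signals: total linear (L + LSSB) and supercoiled (S)."""

    times: np.ndarray
    linear_total: np.ndarray
    supercoiled: np.ndarray

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.times,
                "linear_total": self.linear_total,
                "supercoiled": self.supercoiled,
            }
        )


def effective_rates(rates: RateConstants, scenario: Scenario) -> tuple[float, float, float, float]:
    """Return (k_s, k_sd, kd*, kds*) with the scenario applied to DSB repair."""
    f = scenario.hr_factor * scenario.s_inh
    return rates.k_s, rates.k_sd, rates.k_d * f, rates.k_ds * f


def derivatives(
    state: CompartmentState, rates: RateConstants, scenario: Scenario = CONTROL
) -> np.ndarray:
    """Time derivatives (per hour) of (S, L, LSSB, CSSB).

    The returned vector sums to zero: molecules are only transferred between
    compartments, never created or destroyed.
    """
    if not isinstance(state, CompartmentState):
        state = CompartmentState.from_array(np.asarray(state, dtype=float))
    k_s, k_sd, kd_eff, kds_eff = effective_rates(rates, scenario)
    dS = kd_eff * state.L + k_s * state.CSSB
    dL = k_sd * state.LSSB - kd_eff * state.L
    dLSSB = -(k_sd + kds_eff) * state.LSSB
    dCSSB = kds_eff * state.LSSB - k_s * state.CSSB
    return np.array([dS, dL, dLSSB, dCSSB])


def rate_matrix(rates: RateConstants, scenario: Scenario = CONTROL) -> np.ndarray:
    """The 4x4 generator matrix A with d(state)/dt = A @ state."""
    k_s, k_sd, kd_eff, kds_eff = effective_rates(rates, scenario)
    return np.array(
        [
            [0.0, kd_eff, 0.0, k_s],
            [0.0, -kd_eff, k_sd, 0.0],
            [0.0, 0.0, -(k_sd + kds_eff), 0.0],
            [0.0, 0.0, kds_eff, -k_s],
        ]
    )


def _dd_exp(x: float, y: float, t: np.ndarray) -> np.ndarray:
    """Stable divided difference (exp(-x t) - exp(-y t)) / (y - x).

    Tends to t*exp(-x t) as y -> x; evaluated via expm1 to avoid cancellation.
    """
    d = y - x
    if abs(d) < 1e-12 * max(1.0, abs(x), abs(y)):
        return t * np.exp(-x * t)
    return np.exp(-x * t) * (-np.expm1(-d * t)) / d


def _solve_analytic(
    rates: RateConstants, scenario: Scenario, init: CompartmentState, times: np.ndarray
) -> np.ndarray:
    k_s, k_sd, kd_eff, kds_eff = effective_rates(rates, scenario)
    a = k_sd + kds_eff  # total exit rate of LSSB
    t = times
    lssb0, l0, c0 = init.LSSB, init.L, init.CSSB

    lssb = lssb0 * np.exp(-a * t)
    lin = l0 * np.exp(-kd_eff * t) + k_sd * lssb0 * _dd_exp(kd_eff, a, t)
    cssb = c0 * np.exp(-k_s * t) + kds_eff * lssb0 * _dd_exp(k_s, a, t)
    s = 1.0 - lin - lssb - cssb  # S absorbs: conservation is exact
    return np.column_stack([s, lin, lssb, cssb])


def _solve_numeric(
    rates: RateConstants, scenario: Scenario, init: CompartmentState, times: np.ndarray
) -> np.ndarray:
    A = rate_matrix(rates, scenario)
    sol = solve_ivp(
        lambda _, y: A @ y,
        (0.0, float(times[-1])) if times[-1] > 0 else (0.0, 1e-6),
        init.as_array(),
        t_eval=times,
        method="DOP853",
        rtol=1e-9,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover - linear system should never fail
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    states = sol.y.T
    # renormalise roundoff so conservation holds at the tested 1e-9
    states = np.clip(states, 0.0, None)
    return states / states.sum(axis=1, keepdims=True)


def solve(
    rates: RateConstants,
    scenario: Scenario,
    init: CompartmentState,
    times,
    method: str = "analytic",
) -> Trajectory:
    """Solve the compartment system at the requested times (hours).

    Parameters
    ----------
    method : {"analytic", "numeric"}
        "analytic" evaluates the exact exponential-cascade solution;
        "numeric" integrates the ODEs with an adaptive Runge-Kutta scheme
        (rtol 1e-9, atol 1e-12).  The two agree to better than 1e-8.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size == 0:
        raise ValidationError("times must be nonempty")
    if np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValidationError("times must be sorted, strictly increasing and >= 0")
    if not isinstance(init, CompartmentState):
        init = CompartmentState.from_array(np.asarray(init, dtype=float))

    # solve from t=0 so that solve(..., times=[t0]) with t0 > 0 is correct
    if times[0] == 0.0:
        grid = times
        drop_first = False
    else:
        grid = np.concatenate([[0.0], times])
        drop_first = True

    if method == "analytic":
        states = _solve_analytic(rates, scenario, init, grid)
    elif method == "numeric":
        states = _solve_numeric(rates, scenario, init, grid)
    else:
        raise ValidationError(f"unknown method {method!r}")

    if not drop_first:
        states[0] = init.as_array()  # exact at t=0
    else:
        states = states[1:]
    states = np.clip(states, 0.0, 1.0)
    return Trajectory(times=times, states=states)


def observe(traj: Trajectory) -> Observables:
    """Project a trajectory onto the two gel-quantitated bands.

    LSSB co-migrates with L on the pulsed-field gel, so the linear band
    reports L + LSSB; the supercoiled band reports S.  Nicked circles (CSSB)
    are not quantitated.
    """
    return Observables(
        times=traj.times,
        linear_total=traj.L + traj.LSSB,
        supercoiled=traj.S,
    )


def half_time(k: float) -> float:
    """Half-time ln(2)/k in minutes for a first-order transfer with rate k per hour."""
    k = float(k)
    if not math.isfinite(k) or k <= 0:
        raise ValidationError(f"rate must be > 0 for a half-time, got {k!r}")
    return math.log(2.0) / k * 60.0


def per_break_repair_time(total_minutes: float, n_breaks: float) -> float:
    """Average minutes to repair one break, given the time to repair them all.

    With ``n_breaks`` single-strand breaks per molecule repaired in
    ``total_minutes``, the mean time per break is simply the ratio.
    """
    total_minutes = float(total_minutes)
    n_breaks = float(n_breaks)
    if total_minutes <= 0 or n_breaks <= 0:
        raise ValidationError("total_minutes and n_breaks must be > 0")
    return total_minutes / n_breaks


def extrapolate(
    rates: RateConstants,
    scenario: Scenario,
    init: CompartmentState,
    horizon: float,
    n_points: int = 401,
) -> Trajectory:
    """Solve on a dense grid from 0 to ``horizon`` hours (default 401 points)."""
    horizon = float(horizon)
    if horizon <= 0:
        raise ValidationError(f"horizon must be > 0, got {horizon!r}")
    times = np.linspace(0.0, horizon, int(n_points))
    return solve(rates, scenario, init, times)
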