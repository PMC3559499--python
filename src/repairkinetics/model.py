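"""Joint least-squares fitting of the repair model to band time courses.

Follows the Model/Results idiom: :class:`StrandBreakRepairModel` is built
from a measurement table plus a condition->scenario mapping, its
:meth:`~StrandBreakRepairModel.fit` runs a seeded multistart bounded
least-squares optimisation and returns a :class:`RepairResults` carrying the
estimates, the multistart trace, identifiability flags, bootstrap confidence
intervals and a ``summary()`` table.

Parameterisation
----------------
Rates enter the optimiser on the log scale (positivity by construction);
the shared initial state enters through a stick-breaking map from the unit
box [0, 1]^3 onto the 3-simplex (LSSB first, then L, then CSSB, with S the
remainder), which reaches the simplex boundary at finite parameter values.
The tied model shares one parameter for k_s = k_sd and one for k_d = k_ds.

Residuals are value - model prediction, one per replicate row (replicates
are not averaged); the objective is their sum of squares, pooled over all
conditions with rates and (by default) the initial state shared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.optimize import least_squares

from .data import MeasurementTable
from .exceptions import UnderdeterminedError, ValidationError
from .kinetics import (
    COMPARTMENTS,
    CompartmentState,
    Observables,
    RateConstants,
    Scenario,
    Trajectory,
    extrapolate,
    half_time,
    observe,
    solve,
)

__all__ = [
    "StrandBreakRepairModel",
    "RepairResults",
    "IdentifiabilityReport",
    "EndpointComparison",
    "compare_at_endpoint",
]

_LOG_RATE_BOUNDS = (math.log(1e-4), math.log(50.0))
_START_LOG_RANGE = (math.log(0.01), math.log(10.0))

# near-optimal band for multistart dispersion: relative width plus an
# absolute floor so a near-zero optimal SSR still admits converged starts
_BAND_REL = 0.01
_BAND_ABS = 1e-12
_SPREAD_THRESHOLD = 0.25


def _simplex_from_u(u: np.ndarray) -> np.ndarray:
    """Stick-breaking map [0,1]^3 -> (S, L, LSSB, CSSB) on the simplex."""
    u1, u2, u3 = u
    lssb = u1
    l = (1.0 - u1) * u2
    cssb = (1.0 - u1) * (1.0 - u2) * u3
    s = 1.0 - lssb - l - cssb
    return np.array([max(s, 0.0), l, lssb, cssb])


def _u_from_simplex(state: CompartmentState) -> np.ndarray:
    """Inverse stick-breaking; flat directions default to 0.5."""
    u1 = state.LSSB
    rem1 = 1.0 - u1
    u2 = state.L / rem1 if rem1 > 1e-12 else 0.5
    rem2 = rem1 * (1.0 - u2)
    u3 = state.CSSB / rem2 if rem2 > 1e-12 else 0.5
    return np.clip([u1, u2, u3], 0.0, 1.0)


class StrandBreakRepairModel:
    """Four-compartment repair model bound to a measurement table.

    Parameters
    ----------
    data : MeasurementTable or pandas.DataFrame
        Long-format replicate table with columns
        condition, time_h, replicate, observable, value.
    scenarios : mapping of condition name -> Scenario, optional
        Defaults resolve condition labels through the inhibitor registry
        ("control", "NU7441", ...).
    tie_rates : bool
        Share one rate for SSB repair (k_s = k_sd) and one for DSB repair
        (k_d = k_ds).  Default True; the untied model with four free rates
        is practically non-identifiable on two-band data.
    share_init : bool
        Fit a single initial state common to all conditions (both arms come
        from the same irradiated population).  If False, one initial state
        per condition.
    weight_column : str, optional
        Name of a column of positive weights; residuals are multiplied by
        sqrt(weight) (e.g. 1/SEM^2 weighting).
    """

    def __init__(
        self,
        data,
        scenarios: dict[str, Scenario] | None = None,
        tie_rates: bool = True,
        share_init: bool = True,
        weight_column: str | None = None,
    ):
        if isinstance(data, pd.DataFrame):
            data = MeasurementTable.from_dataframe(data)
        if not isinstance(data, MeasurementTable):
            raise ValidationError("data must be a MeasurementTable or DataFrame")
        self.data = data
        self.tie_rates = bool(tie_rates)
        self.share_init = bool(share_init)
        self.conditions = list(data.conditions)

        if scenarios is None:
            from .synthetic import scenario_for_condition

            scenarios = {c: scenario_for_condition(c) for c in self.conditions}
        missing = [c for c in self.conditions if c not in scenarios]
        if missing:
            raise ValidationError(
                f"no scenario defined for condition(s): {', '.join(map(str, missing))}"
            )
        self.scenarios = {c: scenarios[c] for c in self.conditions}

        if len(data.times) < 2:
            raise UnderdeterminedError(
                "data must cover at least two distinct times to constrain rates"
            )

        frame = data.frame
        if weight_column is not None:
            if weight_column not in frame.columns:
                raise ValidationError(f"weight column {weight_column!r} not found")
            w = frame[weight_column].to_numpy(dtype=float)
            if np.any(~np.isfinite(w)) or np.any(w <= 0):
                raise ValidationError("weights must be finite and > 0")
            self._sqrt_w = np.sqrt(w)
        else:
            self._sqrt_w = None

        # per-condition design: unique times plus row -> (time, observable) maps
        self._design = []
        obs_index = {"linear_total": 0, "supercoiled": 1}
        for cond in self.conditions:
            sub = frame[frame["condition"] == cond]
            times = np.sort(sub["time_h"].unique())
            t_pos = {t: i for i, t in enumerate(times)}
            rows = sub.index.to_numpy()
            self._design.append(
                {
                    "condition": cond,
                    "scenario": self.scenarios[cond],
                    "times": times,
                    "t_idx": sub["time_h"].map(t_pos).to_numpy(),
                    "o_idx": sub["observable"].map(obs_index).to_numpy(),
                    "values": sub["value"].to_numpy(dtype=float),
                    "rows": rows,
                }
            )
        self.nobs = len(frame)

    # -- parameter vector layout ----------------------------------------------

    @property
    def rate_param_names(self) -> list[str]:
        return ["k_s", "k_d"] if self.tie_rates else ["k_s", "k_sd", "k_d", "k_ds"]

    @property
    def init_param_names(self) -> list[str]:
        names = []
        groups = ["shared"] if self.share_init else self.conditions
        for g in groups:
            suffix = "" if self.share_init else f"[{g}]"
            names += [f"{c}0{suffix}" for c in COMPARTMENTS]
        return names

    @property
    def n_rate_params(self) -> int:
        return 2 if self.tie_rates else 4

    @property
    def n_init_groups(self) -> int:
        return 1 if self.share_init else len(self.conditions)

    @property
    def nparams(self) -> int:
        # optimiser dimension: log-rates + 3 stick-breaking coords per group
        return self.n_rate_params + 3 * self.n_init_groups

    def _unpack(self, x: np.ndarray) -> tuple[RateConstants, list[CompartmentState]]:
        k = np.exp(x[: self.n_rate_params])
        if self.tie_rates:
            rates = RateConstants(k_s=k[0], k_sd=k[0], k_d=k[1], k_ds=k[1], tied=True)
        else:
            rates = RateConstants(k_s=k[0], k_sd=k[1], k_d=k[2], k_ds=k[3])
        inits = []
        for g in range(self.n_init_groups):
            u = x[self.n_rate_params + 3 * g : self.n_rate_params + 3 * (g + 1)]
            inits.append(CompartmentState.from_array(_simplex_from_u(u)))
        return rates, inits

    def _pack(self, rates: RateConstants, inits: list[CompartmentState]) -> np.ndarray:
        if self.tie_rates:
            logk = np.log([max(rates.k_s, 1e-4), max(rates.k_d, 1e-4)])
        else:
            logk = np.log(
                np.maximum([rates.k_s, rates.k_sd, rates.k_d, rates.k_ds], 1e-4)
            )
        us = [_u_from_simplex(init) for init in inits]
        return np.concatenate([logk] + us)

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = [_LOG_RATE_BOUNDS[0]] * self.n_rate_params + [0.0] * (3 * self.n_init_groups)
        hi = [_LOG_RATE_BOUNDS[1]] * self.n_rate_params + [1.0] * (3 * self.n_init_groups)
        return np.array(lo), np.array(hi)

    # -- objective -------------------------------------------------------------

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        rates, inits = self._unpack(x)
        out = np.empty(self.nobs)
        pos = 0
        for g, d in enumerate(self._design):
            init = inits[0] if self.share_init else inits[g]
            traj = solve(rates, d["scenario"], init, d["times"])
            obs = observe(traj)
            pred = np.column_stack([obs.linear_total, obs.supercoiled])
            r = d["values"] - pred[d["t_idx"], d["o_idx"]]
            out[pos : pos + r.size] = r
            pos += r.size
        if self._sqrt_w is not None:
            row_order = np.concatenate([d["rows"] for d in self._design])
            out = out * self._sqrt_w[row_order]
        return out

    def ssr(self, rates: RateConstants, inits) -> float:
        """Sum of squared residuals at explicit parameter values."""
        if isinstance(inits, CompartmentState):
            inits = [inits]
        x = self._pack(rates, list(inits))
        r = self._residuals(x)
        return float(r @ r)

    # -- fitting ---------------------------------------------------------------

    def _random_start(self, rng: np.random.Generator) -> np.ndarray:
        logk = rng.uniform(*_START_LOG_RANGE, size=self.n_rate_params)
        u = rng.uniform(0.0, 1.0, size=3 * self.n_init_groups)
        return np.concatenate([logk, u])

    def _minimise(self, x0: np.ndarray, tol: float = 1e-14) -> tuple[float, np.ndarray]:
        res = least_squares(
            self._residuals,
            x0,
            bounds=self._bounds(),
            method="trf",
            xtol=tol,
            ftol=tol,
            gtol=1e-12,
        )
        return float(2.0 * res.cost), res.x

    def fit(
        self,
        n_starts: int = 100,
        seed: int | None = None,
        x0: np.ndarray | None = None,
    ) -> "RepairResults":
        """Multistart bounded least squares; returns the best start.

        ``n_starts`` uniform random starts are drawn from ``seed`` (log-rates
        uniform on [ln 0.01, ln 10], initial-state coordinates uniform on the
        unit box); if ``x0`` is given it replaces the first start.
        """
        if n_starts < 1:
            raise ValidationError("n_starts must be >= 1")
        rng = np.random.default_rng(seed)
        starts = []
        for i in range(n_starts):
            if i == 0 and x0 is not None:
                xi = np.asarray(x0, dtype=float)
            else:
                xi = self._random_start(rng)
            ssr_i, x_i = self._minimise(xi)
            starts.append((ssr_i, x_i))
        best_ssr, best_x = min(starts, key=lambda s: s[0])
        rates, inits = self._unpack(best_x)
        flags = self._dispersion_flags(starts)
        return RepairResults(
            model=self,
            x=best_x,
            rates=rates,
            inits=inits,
            ssr=best_ssr,
            starts=starts,
            seed=seed,
            n_starts=n_starts,
            flags=flags,
        )

    # -- identifiability -------------------------------------------------------

    def _natural_rates(self, x: np.ndarray) -> dict[str, float]:
        k = np.exp(x[: self.n_rate_params])
        return dict(zip(self.rate_param_names, k))

    def _dispersion(self, starts) -> tuple[dict[str, float], int]:
        """Spread (max-min) of each rate among near-optimal starts."""
        best = min(s[0] for s in starts)
        band = best * (1.0 + _BAND_REL) + _BAND_ABS
        in_band = [x for ssr_i, x in starts if ssr_i <= band]
        spreads: dict[str, float] = {}
        for name in self.rate_param_names:
            vals = [self._natural_rates(x)[name] for x in in_band]
            spreads[name] = float(max(vals) - min(vals)) if len(vals) > 1 else 0.0
        return spreads, len(in_band)

    def _dispersion_flags(self, starts) -> list[str]:
        best_ssr, best_x = min(starts, key=lambda s: s[0])
        spreads, _ = self._dispersion(starts)
        best_rates = self._natural_rates(best_x)
        flags = []
        for name, spread in spreads.items():
            if spread > _SPREAD_THRESHOLD * max(abs(best_rates[name]), 1e-8):
                flags.append(f"non_identifiable:{name}")
        return flags

    def identifiability_scan(
        self, n_starts: int = 40, seed: int | None = None
    ) -> "IdentifiabilityReport":
        """Multistart dispersion diagnostic on this model's parameterisation.

        Refits from ``n_starts`` random starts, collects the starts whose SSR
        lies within 1% of the best (plus an absolute floor of 1e-12), and
        reports the spread (max - min) of each rate constant among them.  A
        spread exceeding 25% of the best-fit value raises the
        non-identifiable flag for that rate.
        """
        fitres = self.fit(n_starts=n_starts, seed=seed)
        spreads, n_in_band = self._dispersion(fitres.starts)
        best_rates = self._natural_rates(fitres.x)
        flagged = [
            name
            for name, spread in spreads.items()
            if spread > _SPREAD_THRESHOLD * max(abs(best_rates[name]), 1e-8)
        ]
        return IdentifiabilityReport(
            spreads=spreads,
            best_rates=best_rates,
            best_ssr=fitres.ssr,
            n_starts=n_starts,
            n_in_band=n_in_band,
            flagged=flagged,
        )


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Dispersion of rate estimates among near-optimal multistart fits."""

    spreads: dict[str, float]
    best_rates: dict[str, float]
    best_ssr: float
    n_starts: int
    n_in_band: int
    flagged: list[str]

    @property
    def non_identifiable(self) -> bool:
        return bool(self.flagged)


@dataclass
class RepairResults:
    """Estimates, uncertainty and diagnostics from a multistart fit."""

    model: StrandBreakRepairModel
    x: np.ndarray
    rates: RateConstants
    inits: list[CompartmentState]
    ssr: float
    starts: list
    seed: int | None
    n_starts: int
    flags: list[str] = field(default_factory=list)
    _ci: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def init(self) -> CompartmentState:
        """The (first) fitted initial state; shared across conditions by default."""
        return self.inits[0]

    def init_for(self, condition: str) -> CompartmentState:
        if self.model.share_init:
            return self.inits[0]
        return self.inits[self.model.conditions.index(condition)]

    @property
    def param_names(self) -> list[str]:
        return self.model.rate_param_names + self.model.init_param_names

    @property
    def params(self) -> pd.Series:
        vals = dict(zip(self.model.rate_param_names, np.exp(self.x[: self.model.n_rate_params])))
        groups = ["shared"] if self.model.share_init else self.model.conditions
        for g, init in zip(groups, self.inits):
            suffix = "" if self.model.share_init else f"[{g}]"
            for c in COMPARTMENTS:
                vals[f"{c}0{suffix}"] = getattr(init, c)
        return pd.Series(vals)

    @property
    def half_times_min(self) -> dict[str, float]:
        """ln(2)/k in minutes for each fitted rate constant."""
        out = {}
        for name, k in self.params.items():
            if name.startswith("k_") and k > 0:
                out[name] = half_time(k)
        return out

    # -- prediction ------------------------------------------------------------

    def trajectory(self, condition: str | None = None, times=None) -> Trajectory:
        cond = condition or self.model.conditions[0]
        if cond not in self.model.scenarios:
            raise ValidationError(f"unknown condition {cond!r}")
        if times is None:
            tmax = float(self.model.data.times.max())
            times = np.linspace(0.0, max(tmax, 2.0), 101)
        return solve(self.rates, self.model.scenarios[cond], self.init_for(cond), times)

    def predict(self, condition: str | None = None, times=None) -> Observables:
        return observe(self.trajectory(condition, times))

    def extrapolate(self, condition: str | None = None, horizon: float = 20.0) -> Trajectory:
        cond = condition or self.model.conditions[0]
        return extrapolate(
            self.rates, self.model.scenarios[cond], self.init_for(cond), horizon
        )

    # -- uncertainty -----------------------------------------------------------

    @property
    def resid_scale(self) -> float:
        """Root-mean-square residual (noise-scale estimate for the bootstrap)."""
        dof = max(self.model.nobs - self.model.nparams, 1)
        return math.sqrt(self.ssr / dof)

    def conf_int(
        self, n_boot: int = 200, seed: int | None = None, alpha: float = 0.05
    ) -> pd.DataFrame:
        """Parametric-bootstrap confidence intervals for all parameters.

        Simulates ``n_boot`` datasets from the fitted model with Gaussian
        noise at the residual scale, refits each (one start, from the point
        estimate), and reports percentile intervals.  Intervals are widened
        if necessary to contain the point estimate.  ``n_boot`` < 50 sets an
        interval-stability warning flag.
        """
        if n_boot < 1:
            raise ValidationError("n_boot must be >= 1")
        if n_boot < 50 and "ci_unstable" not in self.flags:
            self.flags.append("ci_unstable")
        est = self.params
        sigma = self.resid_scale
        if sigma == 0.0:
            ci = pd.DataFrame(
                {"estimate": est, "ci_lower": est, "ci_upper": est}
            )
            object.__setattr__(self, "_ci", ci)
            return ci

        rng = np.random.default_rng(seed)
        model = self.model
        clean = _predicted_values(model, self.x)
        draws = []
        for _ in range(n_boot):
            values = np.clip(clean + rng.normal(0.0, sigma, size=clean.size), 0.0, 1.1)
            boot_frame = model.data.frame.copy()
            boot_frame["value"] = values
            boot_model = StrandBreakRepairModel(
                boot_frame,
                scenarios=model.scenarios,
                tie_rates=model.tie_rates,
                share_init=model.share_init,
            )
            # single refit from the point estimate; bootstrap percentiles do
            # not need the final-fit tolerance
            _, x_b = boot_model._minimise(self.x.copy(), tol=1e-10)
            boot_fit = RepairResults(
                model=boot_model, x=x_b, rates=boot_model._unpack(x_b)[0],
                inits=boot_model._unpack(x_b)[1], ssr=0.0, starts=[],
                seed=None, n_starts=1,
            )
            draws.append(boot_fit.params)
        boot = pd.DataFrame(draws)
        lo = boot.quantile(alpha / 2.0)
        hi = boot.quantile(1.0 - alpha / 2.0)
        ci = pd.DataFrame(
            {
                "estimate": est,
                "ci_lower": np.minimum(lo.reindex(est.index), est),
                "ci_upper": np.maximum(hi.reindex(est.index), est),
            }
        )
        object.__setattr__(self, "_ci", ci)
        return ci

    # -- reporting -------------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        m = self.model
        lines = [
            "Strand-break repair kinetics: least-squares fit",
            "=" * 56,
            f"Conditions:        {', '.join(m.conditions)}",
            f"Observations:      {m.nobs}",
            f"Tied rates:        {m.tie_rates}   Shared init: {m.share_init}",
            f"Multistart:        {self.n_starts} starts (seed {self.seed})",
            f"SSR:               {self.ssr:.6g}",
            f"Residual scale:    {self.resid_scale:.4g}",
        ]
        if self.flags:
            lines.append(f"Flags:             {', '.join(self.flags)}")
        lines.append("-" * 56)
        header = f"{'parameter':<14}{'estimate':>10}"
        has_ci = self._ci is not None
        if has_ci:
            header += f"{'2.5%':>10}{'97.5%':>10}"
        header += f"{'t1/2 (min)':>12}"
        lines.append(header)
        for name, value in self.params.items():
            row = f"{name:<14}{value:>10.4f}"
            if has_ci:
                row += (
                    f"{self._ci.loc[name, 'ci_lower']:>10.4f}"
                    f"{self._ci.loc[name, 'ci_upper']:>10.4f}"
                )
            if name in self.half_times_min:
                row += f"{self.half_times_min[name]:>12.1f}"
            lines.append(row)
        lines.append("=" * 56)
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Data points and fitted curves for each condition (one axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
        frame = self.model.data.frame
        for i, cond in enumerate(self.model.conditions):
            color = colors[i % len(colors)]
            obs = self.predict(cond)
            ax.plot(obs.times, obs.linear_total, color=color, label=f"{cond}: linear")
            ax.plot(obs.times, obs.supercoiled, color=color, ls="--",
                    label=f"{cond}: supercoiled")
            for observable, marker in (("linear_total", "o"), ("supercoiled", "s")):
                sub = frame[(frame["condition"] == cond) & (frame["observable"] == observable)]
                ax.plot(sub["time_h"], sub["value"], marker, ms=4, ls="none", color=color)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("fraction of total signal")
        ax.legend(fontsize=8)
        return ax

    def to_dict(self) -> dict:
        """JSON-ready representation (used by results writers)."""
        d = {
            "rates": self.rates.as_dict() | {"tied": self.rates.tied},
            "init": [init.as_dict() for init in self.inits],
            "share_init": self.model.share_init,
            "tie_rates": self.model.tie_rates,
            "ssr": self.ssr,
            "seed": self.seed,
            "n_starts": self.n_starts,
            "flags": list(self.flags),
            "half_times_min": self.half_times_min,
            "multistart_trace": [
                {"ssr": s, "x": list(map(float, x))} for s, x in self.starts
            ],
        }
        if self._ci is not None:
            d["ci"] = {
                name: [float(self._ci.loc[name, "ci_lower"]),
                       float(self._ci.loc[name, "ci_upper"])]
                for name in self._ci.index
            }
        return d


def _predicted_values(model: StrandBreakRepairModel, x: np.ndarray) -> np.ndarray:
    """Model predictions aligned with the rows of ``model.data.frame``."""
    r = model._residuals(x)
    # residual = value - pred, in design order; map back to frame order
    row_order = np.concatenate([d["rows"] for d in model._design])
    values = np.concatenate([d["values"] for d in model._design])
    pred_design = values - (r / (model._sqrt_w[row_order] if model._sqrt_w is not None else 1.0))
    pred = np.empty_like(pred_design)
    pred[row_order] = pred_design
    return pred


@dataclass(frozen=True)
class EndpointComparison:
    """Unpaired two-sample t-test of an observable at one time point."""

    mean_diff: float
    t_stat: float
    p_value: float
    df: int
    n_a: int
    n_b: int


def compare_at_endpoint(
    data_a: MeasurementTable,
    data_b: MeasurementTable,
    observable: str,
    time_h: float,
    condition_a: str | None = None,
    condition_b: str | None = None,
) -> EndpointComparison:
    """Classical (pooled-variance) unpaired t-test at one time point.

    Compares replicate values of ``observable`` at ``time_h`` between the two
    tables (optionally restricted to a named condition in each); returns the
    difference of means (A - B) and the two-sided p-value.
    """
    if observable not in ("linear_total", "supercoiled"):
        raise ValidationError(f"unknown observable {observable!r}")
    a = _endpoint_values(data_a, observable, time_h, condition_a)
    b = _endpoint_values(data_b, observable, time_h, condition_b)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(
            "at least two replicates per group are required for the t-test"
        )
    t_stat, p = sp_stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(p):  # zero variance in both groups, identical means
        t_stat, p = 0.0, 1.0
    return EndpointComparison(
        mean_diff=float(np.mean(a) - np.mean(b)),
        t_stat=float(t_stat),
        p_value=float(p),
        df=len(a) + len(b) - 2,
        n_a=len(a),
        n_b=len(b),
    )


def _endpoint_values(
    table: MeasurementTable, observable: str, time_h: float, condition: str | None
) -> np.ndarray:
    frame = table.frame
    if condition is None:
        conds = table.conditions
        if len(conds) != 1:
            raise ValidationError(
                "table has multiple conditions; specify which one to compare"
            )
        condition = conds[0]
    mask = (
        (frame["condition"] == condition)
        & np.isclose(frame["time_h"], time_h)
        & (frame["observable"] == observable)
    )
    vals = frame.loc[mask, "value"].to_numpy(dtype=float)
    if vals.size == 0:
        raise ValidationError(
            f"no measurements at time_h={time_h} for observable={observable!r} "
            f"in condition {condition!r}"
        )
    return vals
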