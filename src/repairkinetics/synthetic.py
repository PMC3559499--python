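"""Synthetic time-course generation with the structure of the real assay.

The generator forward-simulates the compartment model for each scenario,
projects onto the two gel bands, and adds independent Gaussian noise per
replicate, truncated at zero (band signals cannot be negative).  With
``noise_sd = 0`` it is an exact forward model.

Also houses the inhibitor registry: each inhibitor studied maps to exactly
one parameter action — full DSB-repair arrest (``s_inh = 0``) for DNA-PKcs
inhibitors, a fractional slowing of DSB repair (``hr_factor`` < 1) for agents
impairing the homologous-recombination arm, and the identity for agents with
no detectable effect on these kinetics (PARP and topoisomerase II
inhibitors).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml

from .data import MeasurementTable
from .exceptions import ValidationError
from .kinetics import (
    CONTROL,
    CompartmentState,
    RateConstants,
    Scenario,
    observe,
    solve,
)

__all__ = [
    "GeneratorConfig",
    "generate_dataset",
    "apply_inhibitor",
    "inhibitor_names",
    "reference_config",
    "REFERENCE_RATES",
    "REFERENCE_INIT",
]

#: Published best-fit tied rates (per hour): SSB repair 0.21, DSB repair 0.74.
REFERENCE_RATES = RateConstants.tied_rates(k_s=0.21, k_d=0.74)

#: Canonical post-irradiation initial state: nearly all molecules linearised
#: and carrying SSBs, a small linear-only fraction, no intact or nicked circles.
REFERENCE_INIT = CompartmentState(S=0.0, L=0.05, LSSB=0.95, CSSB=0.0)

# inhibitor -> (s_inh, hr_factor); hr factors encode the observed fractional
# reductions in the rate of decrease of linear DNA (~30%, ~30%, ~26%, ~20%)
_INHIBITOR_ACTIONS: dict[str, tuple[int, float]] = {
    "none": (1, 1.0),
    "NU7441": (0, 1.0),       # DNA-PKcs inhibitor: DSB repair arrested
    "wortmannin": (0, 1.0),   # DNA-PKcs inhibitor: DSB repair arrested
    "KU55933": (1, 0.70),     # ATM inhibitor: ~30% slowing
    "caffeine": (1, 0.70),    # ATM/ATR inhibitor: ~30% slowing
    "mirin": (1, 0.74),       # MRN inhibitor: ~26% slowing
    "Rad51-siRNA": (1, 0.80), # Rad51 depletion: ~20% slowing
    "NU1025": (1, 1.0),       # PARP-1 inhibitor: no effect
    "1,5-IQD": (1, 1.0),      # PARP-1 inhibitor: no effect
    "ICRF-193": (1, 1.0),     # topoisomerase II inhibitor: no effect
    "F11782": (1, 1.0),       # topoisomerase II inhibitor: no effect
}


def inhibitor_names() -> tuple[str, ...]:
    return tuple(_INHIBITOR_ACTIONS)


def apply_inhibitor(
    rates: RateConstants, inhibitor: str
) -> tuple[Scenario, RateConstants]:
    """Scenario (and rates) under a named inhibitor.

    All registered actions are expressed through the scenario switches
    (``s_inh``, ``hr_factor``); the rate constants themselves pass through
    unchanged.
    """
    if inhibitor not in _INHIBITOR_ACTIONS:
        raise ValidationError(
            f"unknown inhibitor {inhibitor!r}; known: {', '.join(_INHIBITOR_ACTIONS)}"
        )
    s_inh, hr_factor = _INHIBITOR_ACTIONS[inhibitor]
    name = "control" if inhibitor == "none" else inhibitor
    return Scenario(name=name, s_inh=s_inh, hr_factor=hr_factor), rates


def scenario_for_condition(name: str) -> Scenario:
    """Resolve a condition label to a Scenario via the inhibitor registry."""
    if name == "control":
        return CONTROL
    if name in _INHIBITOR_ACTIONS:
        scenario, _ = apply_inhibitor(REFERENCE_RATES, name)
        return scenario
    raise ValidationError(
        f"condition {name!r} does not name a known scenario; pass an explicit "
        "scenarios mapping"
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic time-course generator.

    Defaults mirror the study design: five time points over the 2 h repair
    window, three independent replicates, control and DSB-arrest (NU7441)
    arms, and additive Gaussian noise with sd 0.03 on the fraction scale.
    """

    rates: RateConstants = REFERENCE_RATES
    init: CompartmentState = REFERENCE_INIT
    times: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    n_replicates: int = 3
    noise_sd: float = 0.03
    scenarios: tuple[Scenario, ...] = (CONTROL, Scenario("NU7441", s_inh=0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        times = tuple(float(t) for t in self.times)
        if 0.0 not in times:
            raise ValidationError("times must include 0")
        if len(times) < 2 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("times must be >= 2 strictly increasing values")
        if not self.scenarios:
            raise ValidationError("at least one scenario is required")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "scenarios", tuple(self.scenarios))

    def to_dict(self) -> dict:
        return {
            "rates": self.rates.as_dict() | {"tied": self.rates.tied},
            "init": self.init.as_dict(),
            "times": list(self.times),
            "n_replicates": self.n_replicates,
            "noise_sd": self.noise_sd,
            "scenarios": [asdict(s) for s in self.scenarios],
            "seed": self.seed,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        rates = d["rates"]
        return cls(
            rates=RateConstants(
                k_s=rates["k_s"], k_sd=rates["k_sd"],
                k_d=rates["k_d"], k_ds=rates["k_ds"],
                tied=bool(rates.get("tied", False)),
            ),
            init=CompartmentState(**d["init"]),
            times=tuple(d["times"]),
            n_replicates=int(d["n_replicates"]),
            noise_sd=float(d["noise_sd"]),
            scenarios=tuple(Scenario(**s) for s in d["scenarios"]),
            seed=int(d["seed"]),
        )

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def reference_config(seed: int = 0, noise_sd: float = 0.03) -> GeneratorConfig:
    """The canonical two-condition fixture at the published best-fit values."""
    return GeneratorConfig(seed=seed, noise_sd=noise_sd)


def generate_dataset(cfg: GeneratorConfig) -> MeasurementTable:
    """Simulate a replicate measurement table under the configured scenarios.

    For each scenario the model is solved at the configured times, projected
    onto (linear_total, supercoiled), and each replicate receives independent
    N(0, noise_sd^2) noise, truncated below at 0.  Fully determined by
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    records = []
    for scenario in cfg.scenarios:
        obs = observe(solve(cfg.rates, scenario, cfg.init, np.array(cfg.times)))
        clean = {"linear_total": obs.linear_total, "supercoiled": obs.supercoiled}
        for rep in range(1, cfg.n_replicates + 1):
            for observable in ("linear_total", "supercoiled"):
                noise = rng.normal(0.0, cfg.noise_sd, size=len(cfg.times)) \
                    if cfg.noise_sd > 0 else np.zeros(len(cfg.times))
                values = np.maximum(clean[observable] + noise, 0.0)
                for t, v in zip(cfg.times, values):
                    records.append(
                        {
                            "condition": scenario.name,
                            "time_h": t,
                            "replicate": rep,
                            "observable": observable,
                            "value": float(min(v, 1.1)),
                        }
                    )
    return MeasurementTable.from_records(records)
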