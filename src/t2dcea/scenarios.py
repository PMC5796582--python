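"""Scenario generation for testing and exploration.

There is no deposited dataset behind this model: its inputs are the
published base-case parameters.  This module therefore plays the synthetic
data role — it emits (a) the exact base-case parameter set, (b) randomized
but structurally valid parameter sets (row-stochastic transitions,
non-negative costs, rates in [0, 1]) for property testing, and (c)
degenerate edge cases (zero costs, zero event rates, certain death, unit
hazard ratio) that exercise documented error and boundary paths.

Random scenarios draw uniformly within bounds — deliberately not the PSA
distributions; fixtures test structure, not inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError
from .params import DPP4I, SU, ModelParameters, load_parameters

#: default uniform sampling bounds, chosen so every transition row stays
#: feasible: failure + death x HR <= 0.3 + 0.3 x 2 <= 0.9 < 1.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "event_rate": (0.0, 0.25),
    "failure_rate": (0.0, 0.30),
    "death_probability": (0.0, 0.30),
    "hazard_ratio": (0.5, 2.0),
    "event_cost": (0.0, 30000.0),
    "drug_cost": (0.0, 6000.0),
    "discount_rate": (0.0, 0.10),
}


@dataclass
class ScenarioSpec:
    """Controls for :func:`random_scenario`."""

    seed: int = 0
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    zero_costs: bool = False
    zero_event_rates: bool = False
    certain_death: bool = False
    hr_one: bool = False

    def bounds(self, key: str) -> tuple[float, float]:
        lo, hi = self.ranges.get(key, DEFAULT_RANGES[key])
        if lo > hi:
            raise ContractError(f"ranges[{key!r}]: low {lo} > high {hi}")
        return lo, hi


def base_case_scenario() -> ModelParameters:
    """The exact published base-case parameter set."""
    return load_parameters()


def random_scenario(spec: ScenarioSpec) -> ModelParameters:
    """A structurally valid random parameter set, deterministic in the seed."""
    rng = np.random.default_rng(spec.seed)
    data = base_case_scenario().to_dict()

    def u(key: str) -> float:
        lo, hi = spec.bounds(key)
        return float(rng.uniform(lo, hi))

    for band in data["mortality"]["bands"]:
        band["annual_death_probability"] = 1.0 if spec.certain_death else u("death_probability")
    # keep death probabilities non-decreasing in age (a realistic cohort)
    probs = sorted(b["annual_death_probability"] for b in data["mortality"]["bands"])
    for band, p in zip(data["mortality"]["bands"], probs):
        band["annual_death_probability"] = p

    for state in data["event_rates_by_state"].values():
        for name in state:
            state[name] = 0.0 if spec.zero_event_rates else u("event_rate")

    for name in data["unit_costs"]:
        if spec.zero_costs:
            data["unit_costs"][name] = 0.0
        else:
            data["unit_costs"][name] = u("drug_cost" if name.startswith("drug_") else "event_cost")

    fm = 0.0 if spec.certain_death else u("failure_rate")
    for key in (DPP4I, SU):
        pw = data["pathways"][key]
        pw["failure_rate_mono"] = fm
        pw["failure_rate_dual"] = 0.0 if spec.certain_death else u("failure_rate")
    hr = 1.0 if (spec.hr_one or spec.certain_death) else u("hazard_ratio")
    data["pathways"][SU]["dual_state_death_hazard_ratio"] = hr
    data["discount_rate"] = u("discount_rate")
    return ModelParameters.from_dict(data)
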