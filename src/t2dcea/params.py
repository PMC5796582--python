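"""Model inputs for the second-line type 2 diabetes treatment-pathway model.

All quantities live here as validated dataclasses: annual treatment-failure
rates, per-state adverse-event probabilities, age-banded death probabilities,
unit costs (2015 USD), drug acquisition costs, and run settings (discount
rate, horizon, start age).  Configuration is a human-editable YAML file whose
keys mirror the dataclass fields; a partial file is interpreted as a delta
over the shipped base case, so omitting e.g. ``discount_rate`` falls back to
the 3%/year default.

The module also implements the probability-to-annual-rate conversion used to
turn cumulative trial failure fractions into per-cycle transition
probabilities: an f fraction failing over y years corresponds to a constant
annual rate r with (1 - r)^y = 1 - f.
"""

from __future__ import annotations

import copy
import csv
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import ContractError, ValidationError

#: canonical pathway keys
DPP4I = "dpp4i"
SU = "su"

#: keys of ``event_rates_by_state``; the two arms share the monotherapy and
#: triple-therapy (basal insulin) states but have distinct dual states.
STATE_MONO = "mono"
STATE_DUAL_DPP4I = "dual_dpp4i"
STATE_DUAL_SU = "dual_su"
STATE_TRIPLE = "triple"

_PROB_FIELDS = (
    "severe_hypoglycemia",
    "hypoglycemia_medical_assistance",
    "myocardial_infarction",
    "heart_failure",
    "stroke",
    "weight_gain_first_year",
)


def _check_prob(name: str, value: float) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{name}: not a number ({value!r})")
    if not 0.0 <= v <= 1.0:
        raise ValidationError(f"{name}: probability {v} outside [0, 1]")
    return v


def _check_nonneg(name: str, value: float) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{name}: not a number ({value!r})")
    if v < 0:
        raise ValidationError(f"{name}: negative value {v}")
    return v


def annualize_rate(cumulative_failure_fraction: float, period: float) -> float:
    """Convert a cumulative failure fraction over ``period`` years to a
    constant annual rate.

    Solves (1 - r)^period = 1 - f for r, i.e. r = 1 - (1 - f)^(1/period).
    A 21% failure fraction over 5 years gives r = 0.046 (3 dp).
    """
    f = float(cumulative_failure_fraction)
    y = float(period)
    if not 0.0 <= f < 1.0:
        raise ContractError(f"cumulative failure fraction {f} must be in [0, 1)")
    if y <= 0:
        raise ContractError(f"period {y} must be positive")
    return 1.0 - (1.0 - f) ** (1.0 / y)


def derive_dpp4i_failure_rate(su_failure_rate: float, round_to: int | None = None) -> float:
    """Dual-therapy failure rate for metformin+DPP-4i, assumed four times
    lower than the metformin+SU rate (DPP-4i raises A1c four times slower).

    ``round_to`` optionally rounds to the reporting precision (the base case
    uses the printed 3-decimal value 0.013 rather than 0.053/4 = 0.01325).
    """
    r = _check_prob("su_failure_rate", su_failure_rate) / 4.0
    if round_to is not None:
        r = round(r, round_to)
    return r


@dataclass
class AgeBandedMortality:
    """Annual death probabilities by attained-age band.

    ``bands`` is an ordered list of (age_low, age_high, probability).  Ages
    below the first band use the first band's probability and ages above the
    last band carry the last band's probability forward — the extrapolation
    rule used for extended horizons and earlier start ages.
    """

    bands: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValidationError("mortality.bands: empty")
        bands = []
        prev_high = None
        for i, band in enumerate(self.bands):
            lo, hi, p = band
            if hi < lo:
                raise ValidationError(f"mortality.bands[{i}]: age_high {hi} < age_low {lo}")
            p = _check_prob(f"mortality.bands[{i}].annual_death_probability", p)
            if prev_high is not None and lo != prev_high + 1:
                raise ValidationError(
                    f"mortality.bands[{i}]: bands must be contiguous "
                    f"(age_low {lo}, previous age_high {prev_high})"
                )
            prev_high = hi
            bands.append((float(lo), float(hi), p))
        self.bands = bands

    def band_index(self, age: float) -> int:
        """Index of the band containing ``age``, clamped at both ends."""
        if age < self.bands[0][0]:
            return 0
        for i, (lo, hi, _p) in enumerate(self.bands):
            if lo <= age <= hi:
                return i
        return len(self.bands) - 1

    def death_probability(self, age: float) -> float:
        return self.bands[self.band_index(age)][2]


@dataclass
class EventRates:
    """Annual adverse-event probabilities attached to one health state."""

    severe_hypoglycemia: float = 0.0
    hypoglycemia_medical_assistance: float = 0.0
    myocardial_infarction: float = 0.0
    heart_failure: float = 0.0
    stroke: float = 0.0
    weight_gain_first_year: float = 0.0

    def __post_init__(self) -> None:
        for name in _PROB_FIELDS:
            setattr(self, name, _check_prob(name, getattr(self, name)))


@dataclass
class UnitCosts:
    """Per-episode / per-patient-year costs in 2015 USD."""

    myocardial_infarction: float
    heart_failure: float
    stroke: float
    hypo_medical_assistance: float
    severe_hypo: float
    weight_gain: float
    drug_metformin: float
    drug_dpp4i: float
    drug_su: float
    drug_insulin_glargine: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            setattr(self, name, _check_nonneg(f"unit_costs.{name}", getattr(self, name)))


@dataclass
class PathwaySpec:
    """One second-line strategy: which agent is added to metformin, the
    pathway's failure rates, its dual-state death hazard ratio relative to
    the DPP-4i pathway, and whether the one-time weight-gain cost applies on
    entry to dual therapy."""

    second_line_agent: str
    failure_rate_mono: float
    failure_rate_dual: float
    dual_state_death_hazard_ratio: float = 1.0
    weight_gain_transition_cost_applies: bool = False

    def __post_init__(self) -> None:
        if self.second_line_agent not in ("DPP4i", "SU"):
            raise ValidationError(
                f"second_line_agent: {self.second_line_agent!r} not one of DPP4i, SU"
            )
        self.failure_rate_mono = _check_prob("failure_rate_mono", self.failure_rate_mono)
        self.failure_rate_dual = _check_prob("failure_rate_dual", self.failure_rate_dual)
        self.dual_state_death_hazard_ratio = _check_nonneg(
            "dual_state_death_hazard_ratio", self.dual_state_death_hazard_ratio
        )

    @property
    def dual_state_key(self) -> str:
        return STATE_DUAL_DPP4I if self.second_line_agent == "DPP4i" else STATE_DUAL_SU


@dataclass
class ModelParameters:
    """The complete, validated input set for one model run."""

    mortality: AgeBandedMortality
    event_rates_by_state: dict[str, EventRates]
    unit_costs: UnitCosts
    pathways: dict[str, PathwaySpec]
    discount_rate: float = 0.03
    horizon: int = 25
    start_age: float = 60.0
    cycle_length: float = 1.0
    cost_accrual: str = "post"

    def __post_init__(self) -> None:
        self.discount_rate = _check_nonneg("discount_rate", self.discount_rate)
        self.horizon = int(self.horizon)
        if self.horizon < 1:
            raise ValidationError(f"horizon: {self.horizon} < 1")
        self.start_age = float(self.start_age)
        if float(self.cycle_length) != 1.0:
            raise ValidationError("cycle_length: fixed at 1 year in this model")
        self.cycle_length = 1.0
        if self.cost_accrual not in ("post", "pre"):
            raise ValidationError(
                f"cost_accrual: {self.cost_accrual!r} not one of 'post', 'pre'"
            )
        for key in (STATE_MONO, STATE_TRIPLE):
            if key not in self.event_rates_by_state:
                raise ValidationError(f"event_rates_by_state: missing state {key!r}")
        for key, pw in self.pathways.items():
            if pw.dual_state_key not in self.event_rates_by_state:
                raise ValidationError(
                    f"event_rates_by_state: missing dual state {pw.dual_state_key!r} "
                    f"required by pathway {key!r}"
                )

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mortality"] = {
            "bands": [
                {"age_low": lo, "age_high": hi, "annual_death_probability": p}
                for lo, hi, p in self.mortality.bands
            ]
        }
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelParameters":
        data = copy.deepcopy(dict(data))
        bands = [
            (b["age_low"], b["age_high"], b["annual_death_probability"])
            for b in data["mortality"]["bands"]
        ]
        rates = {k: EventRates(**v) for k, v in data["event_rates_by_state"].items()}
        costs = UnitCosts(**data["unit_costs"])
        pathways = {k: PathwaySpec(**v) for k, v in data["pathways"].items()}
        kwargs = {
            k: data[k]
            for k in ("discount_rate", "horizon", "start_age", "cycle_length", "cost_accrual")
            if k in data
        }
        return cls(
            mortality=AgeBandedMortality(bands),
            event_rates_by_state=rates,
            unit_costs=costs,
            pathways=pathways,
            **kwargs,
        )

    def copy(self) -> "ModelParameters":
        return ModelParameters.from_dict(self.to_dict())

    # -- convenience ---------------------------------------------------------

    def age_at_cycle(self, cycle: int) -> float:
        """Attained age at the end of cycle ``cycle`` (cycles count from 1)."""
        return self.start_age + cycle * self.cycle_length

    def band_index_at_cycle(self, cycle: int) -> int:
        return self.mortality.band_index(self.age_at_cycle(cycle))


def _base_case_dict() -> dict:
    text = resources.files("t2dcea.data").joinpath("base_case.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_parameters(source: str | Path | Mapping | None = None) -> ModelParameters:
    """Build a validated :class:`ModelParameters`.

    ``source`` may be ``None`` (shipped base case), a YAML file path, or a
    mapping.  A partial configuration is merged over the base case, so any
    omitted field takes its base-case value.
    """
    base = _base_case_dict()
    if source is None:
        data = base
    elif isinstance(source, Mapping):
        data = _deep_merge(base, source)
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"configuration file not found: {path}")
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ValidationError(f"configuration root must be a mapping: {path}")
        data = _deep_merge(base, user)
    return ModelParameters.from_dict(data)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write the full parameter set as YAML (round-trips via load_parameters)."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def export_parameters_csv(params: ModelParameters, path: str | Path) -> None:
    """Flat audit export: one row per scalar parameter."""
    rows: list[tuple[str, float, str, str]] = []
    for lo, hi, p in params.mortality.bands:
        rows.append((f"mortality.{lo:g}-{hi:g}", p, "probability/year", "annual rates"))
    for state, er in params.event_rates_by_state.items():
        for name in _PROB_FIELDS:
            rows.append(
                (f"event_rates.{state}.{name}", getattr(er, name), "probability/year",
                 "annual rates")
            )
    for name in UnitCosts.__dataclass_fields__:
        units = "2015 USD/patient-year" if name.startswith("drug_") else "2015 USD/event"
        rows.append((f"unit_costs.{name}", getattr(params.unit_costs, name), units,
                     "unit costs"))
    for key, pw in params.pathways.items():
        rows.append((f"pathways.{key}.failure_rate_mono", pw.failure_rate_mono,
                     "probability/year", "annual rates"))
        rows.append((f"pathways.{key}.failure_rate_dual", pw.failure_rate_dual,
                     "probability/year", "annual rates"))
        rows.append((f"pathways.{key}.dual_state_death_hazard_ratio",
                     pw.dual_state_death_hazard_ratio, "dimensionless", "annual rates"))
    rows.append(("discount_rate", params.discount_rate, "fraction/year", "settings"))
    rows.append(("horizon", params.horizon, "cycles", "settings"))
    rows.append(("start_age", params.start_age, "years", "settings"))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "value", "units", "source"])
        w.writerows(rows)
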