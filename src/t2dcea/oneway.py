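"""Deterministic one-way sensitivity analysis.

Each analysis re-runs both pathways with a single input moved to a low and a
high value, all else held at base, and records the resulting ICER.  The
default perturbation set follows the study protocol: event probabilities,
failure rates and costs +/-25%, insulin glargine cost +/-20%, death rates
and the dual-state death hazard ratio +/-10%; plus structural scenarios
(time horizon 20/30 years, treatment start age 55/65 with the horizon
anchored to a terminal age of 85, and convergence of the two arms'
cardiovascular event rates two years after starting dual therapy).

Parameter paths are dotted strings into the configuration tree, e.g.
``unit_costs.heart_failure`` or ``event_rates_by_state.dual_su.stroke``.
A ``*`` component fans a list value across list entries, which is how the
three age-band death probabilities are perturbed jointly:
``mortality.bands.*.annual_death_probability`` with a 3-vector.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Sequence

from .cea import CEAResult, compute_cea
from .engine import CVConvergence, run_cohort
from .errors import ContractError
from .params import DPP4I, SU, ModelParameters

TERMINAL_AGE = 85.0


@dataclass
class PerturbationSpec:
    parameter_path: str
    low_value: object
    high_value: object
    label: str

    def __post_init__(self) -> None:
        if self.low_value == self.high_value and self.low_value is not None:
            # permitted (degenerate spec) but normally a mistake; keep silent
            pass


@dataclass
class TornadoEntry:
    label: str
    icer_low: float
    icer_high: float
    base_icer: float
    low_value: object = None
    high_value: object = None

    @property
    def swing(self) -> float:
        return abs(self.icer_high - self.icer_low)

    @property
    def pct_change_low(self) -> float:
        return 100.0 * (self.icer_low - self.base_icer) / self.base_icer

    @property
    def pct_change_high(self) -> float:
        return 100.0 * (self.icer_high - self.base_icer) / self.base_icer


def assign_path(data: dict, path: str, value: object) -> None:
    """Assign ``value`` at dotted ``path`` inside a nested config dict."""
    tokens = path.split(".")

    def assign(node, toks, val):
        tok = toks[0]
        if tok == "*":
            if isinstance(node, dict):
                children = list(node.values())
            elif isinstance(node, list):
                children = node
            else:
                raise ContractError(f"'*' in {path!r} must index a list or mapping")
            vals = val if isinstance(val, (list, tuple)) else [val] * len(children)
            if len(vals) != len(children):
                raise ContractError(
                    f"value for {path!r} must have {len(children)} entries, got {len(vals)}"
                )
            for child, v in zip(children, vals):
                assign(child, toks[1:], v)
            return
        if isinstance(node, list):
            tok = int(tok)
        elif tok not in node:
            raise ContractError(f"unknown parameter path {path!r} (at {tok!r})")
        if len(toks) == 1:
            node[tok] = val
        else:
            assign(node[tok], toks[1:], val)

    assign(data, tokens, copy.deepcopy(value))


def set_parameter(params: ModelParameters, path: str, value: object) -> ModelParameters:
    """Return a copy of ``params`` with the field at ``path`` replaced."""
    data = params.to_dict()
    assign_path(data, path, value)
    return ModelParameters.from_dict(data)


def pathway_icer(params: ModelParameters, pathway_pair: tuple[str, str] = (SU, DPP4I),
                 cv_convergence: CVConvergence | None = None) -> CEAResult:
    """Run both pathways and compare (reference first in the pair)."""
    ref_key, alt_key = pathway_pair
    ref = run_cohort(ref_key, params, cv_convergence=cv_convergence)
    alt = run_cohort(alt_key, params, cv_convergence=cv_convergence)
    return compute_cea(ref, alt)


def run_one_way(
    params: ModelParameters,
    spec: PerturbationSpec,
    pathway_pair: tuple[str, str] = (SU, DPP4I),
    base_icer: float | None = None,
) -> TornadoEntry:
    """ICERs with one parameter at its low then high value, all else base."""
    if base_icer is None:
        base_icer = pathway_icer(params, pathway_pair).icer
    low = pathway_icer(set_parameter(params, spec.parameter_path, spec.low_value), pathway_pair)
    high = pathway_icer(set_parameter(params, spec.parameter_path, spec.high_value), pathway_pair)
    return TornadoEntry(
        label=spec.label,
        icer_low=low.icer,
        icer_high=high.icer,
        base_icer=base_icer,
        low_value=spec.low_value,
        high_value=spec.high_value,
    )


def default_perturbations(params: ModelParameters) -> list[PerturbationSpec]:
    """The protocol's one-way perturbation set (excluding the structural
    horizon / start-age / rate-convergence scenarios)."""

    def pm(path: str, base: float, rel: float, label: str) -> PerturbationSpec:
        return PerturbationSpec(path, base * (1 - rel), base * (1 + rel), label)

    uc = params.unit_costs
    er = params.event_rates_by_state
    specs = [
        pm("pathways.su.dual_state_death_hazard_ratio",
           params.pathways[SU].dual_state_death_hazard_ratio, 0.10,
           "Death hazard ratio of Met+SU to Met+DPP-4i"),
        # the two arms share the monotherapy failure rate; move it jointly
        PerturbationSpec("pathways.*.failure_rate_mono",
                         params.pathways[DPP4I].failure_rate_mono * 0.75,
                         params.pathways[DPP4I].failure_rate_mono * 1.25,
                         "Metformin treatment failure"),
        pm("pathways.dpp4i.failure_rate_dual",
           params.pathways[DPP4I].failure_rate_dual, 0.25, "Met+DPP-4i treatment failure"),
        pm("pathways.su.failure_rate_dual",
           params.pathways[SU].failure_rate_dual, 0.25, "Met+SU treatment failure"),
        pm("event_rates_by_state.dual_su.severe_hypoglycemia",
           er["dual_su"].severe_hypoglycemia, 0.25, "Severe hypoglycemia in Met+SU"),
        pm("event_rates_by_state.triple.severe_hypoglycemia",
           er["triple"].severe_hypoglycemia, 0.25,
           "Severe hypoglycemia in insulin glargine triple therapy"),
        pm("event_rates_by_state.dual_su.weight_gain_first_year",
           er["dual_su"].weight_gain_first_year, 0.25,
           "Weight gain in the first year of Met+SU"),
        pm("event_rates_by_state.dual_dpp4i.myocardial_infarction",
           er["dual_dpp4i"].myocardial_infarction, 0.25, "Myocardial infarction in Met+DPP-4i"),
        pm("event_rates_by_state.dual_dpp4i.heart_failure",
           er["dual_dpp4i"].heart_failure, 0.25, "Heart failure in Met+DPP-4i"),
        pm("event_rates_by_state.dual_dpp4i.stroke",
           er["dual_dpp4i"].stroke, 0.25, "Stroke in Met+DPP-4i"),
        pm("event_rates_by_state.dual_su.heart_failure",
           er["dual_su"].heart_failure, 0.25, "Heart failure in Met+SU"),
        pm("event_rates_by_state.dual_su.stroke",
           er["dual_su"].stroke, 0.25, "Stroke in Met+SU"),
        pm("unit_costs.myocardial_infarction", uc.myocardial_infarction, 0.25,
           "Costs of myocardial infarction"),
        pm("unit_costs.heart_failure", uc.heart_failure, 0.25, "Costs of heart failure"),
        pm("unit_costs.stroke", uc.stroke, 0.25, "Costs of stroke"),
        pm("unit_costs.severe_hypo", uc.severe_hypo, 0.25, "Costs of severe hypoglycemia"),
        pm("unit_costs.weight_gain", uc.weight_gain, 0.25, "Costs of weight gain"),
        pm("unit_costs.drug_insulin_glargine", uc.drug_insulin_glargine, 0.20,
           "Costs of insulin glargine"),
        PerturbationSpec("mortality.bands.*.annual_death_probability",
                         [p * 0.90 for _lo, _hi, p in params.mortality.bands],
                         [p * 1.10 for _lo, _hi, p in params.mortality.bands],
                         "Death rate"),
    ]
    return specs


def run_horizon_and_age_scenarios(
    params: ModelParameters,
    pathway_pair: tuple[str, str] = (SU, DPP4I),
    base_icer: float | None = None,
    horizons: tuple[int, int] = (20, 30),
    start_ages: tuple[float, float] = (55.0, 65.0),
) -> list[TornadoEntry]:
    """Structural scenarios: shorter/longer horizon and earlier/later
    treatment start age.

    Start-age scenarios keep the terminal age fixed at 85 (the base-case
    60 + 25), so starting at 55 runs 30 cycles and starting at 65 runs 20;
    mortality bands follow attained age with the last band carried beyond
    its upper edge and the first band applied below age 60.
    """
    if base_icer is None:
        base_icer = pathway_icer(params, pathway_pair).icer

    def icer_at(horizon: int | None = None, start_age: float | None = None) -> float:
        p = params.copy()
        if start_age is not None:
            p.start_age = float(start_age)
            p.horizon = int(round(TERMINAL_AGE - start_age))
        if horizon is not None:
            p.horizon = int(horizon)
        return pathway_icer(p, pathway_pair).icer

    lo_h, hi_h = sorted(horizons)
    lo_a, hi_a = sorted(start_ages)
    return [
        TornadoEntry("Time horizon", icer_at(horizon=lo_h), icer_at(horizon=hi_h),
                     base_icer, lo_h, hi_h),
        TornadoEntry("Age at start of metformin monotherapy",
                     icer_at(start_age=lo_a), icer_at(start_age=hi_a),
                     base_icer, lo_a, hi_a),
    ]


def run_cv_convergence_scenario(
    params: ModelParameters,
    pathway_pair: tuple[str, str] = (SU, DPP4I),
    convergence: CVConvergence | None = None,
    base_icer: float | None = None,
) -> TornadoEntry:
    """Scenario in which both dual-therapy states share common cardiovascular
    event rates from two years after starting dual therapy."""
    if convergence is None:
        convergence = CVConvergence()
    if base_icer is None:
        base_icer = pathway_icer(params, pathway_pair).icer
    value = pathway_icer(params, pathway_pair, cv_convergence=convergence).icer
    return TornadoEntry(
        "Same cardiovascular event rates from 2 years after dual therapy",
        value, value, base_icer,
        low_value=(convergence.myocardial_infarction, convergence.heart_failure,
                   convergence.stroke),
        high_value=None,
    )


def run_full_sweep(
    params: ModelParameters,
    pathway_pair: tuple[str, str] = (SU, DPP4I),
    only: str | None = None,
) -> list[TornadoEntry]:
    """All one-way analyses (parameter perturbations plus structural
    scenarios).  ``only`` keeps entries whose label contains the substring
    (case-insensitive)."""
    base = pathway_icer(params, pathway_pair).icer
    entries = [run_one_way(params, s, pathway_pair, base) for s in default_perturbations(params)]
    entries += run_horizon_and_age_scenarios(params, pathway_pair, base)
    entries.append(run_cv_convergence_scenario(params, pathway_pair, base_icer=base))
    if only is not None:
        needle = only.lower()
        entries = [e for e in entries if needle in e.label.lower()]
    return entries


def build_tornado(entries: Sequence[TornadoEntry]) -> list[TornadoEntry]:
    """Sort entries by descending ICER swing; ties break by label."""
    if not entries:
        raise ContractError("build_tornado requires at least one entry")
    return sorted(entries, key=lambda e: (-e.swing, e.label))
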