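"""Markov cohort engine.

Four health states — metformin monotherapy (MONO), metformin + second-line
agent (DUAL), dual therapy + basal insulin (TRIPLE), and absorbing DEATH —
with one-year cycles.  Transitions are forward-only: MONO can fail to DUAL,
DUAL can fail to TRIPLE, every alive state can die.  Death probabilities are
age-banded; in the sulfonylurea pathway the DUAL-state death probability is
multiplied by a hazard ratio (1.85 in the base case).

Cycle convention (normative for this package): the cohort starts 100% in
MONO at the start age; membership at cycle t (t = 1..H) is the
post-transition distribution; life-years and costs for cycle t are accrued
on that post-transition membership and discounted by (1 + r)^(-t).  No
half-cycle correction is applied.  A pre-transition cost-accrual variant is
available via ``ModelParameters.cost_accrual = "pre"``.

Duration-dependence in the DUAL state (needed for the scenario in which
cardiovascular event rates of the two arms converge two years after starting
dual therapy) is encoded by splitting DUAL into year-indexed sub-states with
identical transition behaviour but different cost loads.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ContractError, InfeasibleParametersError
from .params import (
    STATE_MONO,
    STATE_TRIPLE,
    EventRates,
    ModelParameters,
    PathwaySpec,
)

ROW_TOL = 1e-12


class HealthState(IntEnum):
    MONO = 0
    DUAL = 1
    TRIPLE = 2
    DEATH = 3


@dataclass
class CVConvergence:
    """Scenario: after ``after_years`` years in dual therapy, both arms share
    the same cardiovascular event rates."""

    myocardial_infarction: float = 0.004
    heart_failure: float = 0.020
    stroke: float = 0.020
    after_years: int = 2


@dataclass
class CohortTrace:
    """Per-cycle record of a cohort run.

    ``membership`` has H+1 rows (cycle 0 = initial distribution) over the four
    aggregated states; accrual arrays have one entry per cycle 1..H.
    """

    cycles: np.ndarray
    ages: np.ndarray
    membership: np.ndarray
    ly_discounted: np.ndarray
    ly_undiscounted: np.ndarray
    cost_discounted: np.ndarray
    cost_undiscounted: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cycle": self.cycles,
                "age": self.ages,
                "mono": self.membership[:, HealthState.MONO],
                "dual": self.membership[:, HealthState.DUAL],
                "triple": self.membership[:, HealthState.TRIPLE],
                "death": self.membership[:, HealthState.DEATH],
            }
        )
        df["ly_discounted"] = np.concatenate([[0.0], self.ly_discounted])
        df["ly_undiscounted"] = np.concatenate([[0.0], self.ly_undiscounted])
        df["cost_discounted"] = np.concatenate([[0.0], self.cost_discounted])
        df["cost_undiscounted"] = np.concatenate([[0.0], self.cost_undiscounted])
        return df


@dataclass
class PathwayResult:
    """Totals for one pathway run (discounted and undiscounted)."""

    pathway: str
    total_cost_discounted: float
    total_cost_undiscounted: float
    total_ly_discounted: float
    total_ly_undiscounted: float
    trace: CohortTrace
    discount_rate: float
    horizon: int
    start_age: float


def discount_factor(cycle: int, rate: float) -> float:
    """(1 + rate)^(-cycle) for cycle >= 1."""
    if cycle < 1:
        raise ContractError(f"cycle {cycle} must be >= 1")
    return (1.0 + rate) ** (-cycle)


def _resolve_pathway(pathway: str | PathwaySpec, params: ModelParameters) -> tuple[str, PathwaySpec]:
    if isinstance(pathway, PathwaySpec):
        for key, pw in params.pathways.items():
            if pw is pathway:
                return key, pw
        return pathway.second_line_agent.lower(), pathway
    try:
        return pathway, params.pathways[pathway]
    except KeyError:
        raise ContractError(f"unknown pathway {pathway!r}; have {sorted(params.pathways)}")


def state_annual_cost(
    state: HealthState,
    pathway: str | PathwaySpec,
    params: ModelParameters,
    cv_rates: Mapping[str, float] | None = None,
) -> float:
    """Annual cost of occupying ``state``: the regimen's drug cost plus the
    event-probability-weighted unit costs, at full floating precision.

    ``cv_rates`` optionally overrides the state's cardiovascular event rates
    (used by the rate-convergence scenario).  DEATH is rejected: the dead
    accrue nothing by definition and a direct call is an indexing bug.
    """
    _key, pw = _resolve_pathway(pathway, params)
    uc = params.unit_costs
    if state == HealthState.DEATH:
        raise ContractError("state_annual_cost called for DEATH (cost is 0 by definition)")
    if state == HealthState.MONO:
        rates = params.event_rates_by_state[STATE_MONO]
        drug = uc.drug_metformin
    elif state == HealthState.DUAL:
        rates = params.event_rates_by_state[pw.dual_state_key]
        drug = uc.drug_metformin + (
            uc.drug_dpp4i if pw.second_line_agent == "DPP4i" else uc.drug_su
        )
    elif state == HealthState.TRIPLE:
        rates = params.event_rates_by_state[STATE_TRIPLE]
        drug = uc.drug_metformin + (
            uc.drug_dpp4i if pw.second_line_agent == "DPP4i" else uc.drug_su
        ) + uc.drug_insulin_glargine
    else:  # pragma: no cover
        raise ContractError(f"unknown state {state!r}")
    mi = rates.myocardial_infarction
    hf = rates.heart_failure
    st = rates.stroke
    if cv_rates is not None:
        mi = cv_rates.get("myocardial_infarction", mi)
        hf = cv_rates.get("heart_failure", hf)
        st = cv_rates.get("stroke", st)
    return (
        drug
        + rates.severe_hypoglycemia * uc.severe_hypo
        + rates.hypoglycemia_medical_assistance * uc.hypo_medical_assistance
        + mi * uc.myocardial_infarction
        + hf * uc.heart_failure
        + st * uc.stroke
    )


def transition_cost(
    from_state: HealthState,
    to_state: HealthState,
    pathway: str | PathwaySpec,
    params: ModelParameters,
) -> float:
    """One-time cost charged on a specific state change: the expected
    weight-gain cost on entering SU dual therapy (0.51 x $289 in the base
    case); zero for every other edge and for the DPP-4i pathway."""
    _key, pw = _resolve_pathway(pathway, params)
    if (
        from_state == HealthState.MONO
        and to_state == HealthState.DUAL
        and pw.weight_gain_transition_cost_applies
    ):
        wg_rate = params.event_rates_by_state[pw.dual_state_key].weight_gain_first_year
        return wg_rate * params.unit_costs.weight_gain
    return 0.0


def build_transition_matrix(
    pathway: str | PathwaySpec,
    params: ModelParameters,
    age_band_index: int,
) -> np.ndarray:
    """4x4 row-stochastic transition matrix for one age band and pathway.

    MONO:   (1 - f_mono - d,  f_mono,           0,       d)
    DUAL:   (0,               1 - f_dual - d*HR, f_dual,  d*HR)
    TRIPLE: (0,               0,                1 - d,    d)
    DEATH:  (0,               0,                0,        1)
    """
    _key, pw = _resolve_pathway(pathway, params)
    bands = params.mortality.bands
    if not 0 <= age_band_index < len(bands):
        raise ContractError(f"age band index {age_band_index} out of range")
    d = bands[age_band_index][2]
    fm = pw.failure_rate_mono
    fd = pw.failure_rate_dual
    hr = pw.dual_state_death_hazard_ratio
    d_dual = d * hr
    M = np.array(
        [
            [1.0 - fm - d, fm, 0.0, d],
            [0.0, 1.0 - fd - d_dual, fd, d_dual],
            [0.0, 0.0, 1.0 - d, d],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    if (np.diag(M) < 0).any() or (M > 1 + ROW_TOL).any():
        raise InfeasibleParametersError(
            f"infeasible transition row for band {age_band_index} "
            f"(d={d}, HR={hr}, failure rates {fm}/{fd})"
        )
    return M


def _expand_matrix(M4: np.ndarray, n_dual: int) -> np.ndarray:
    """Expand a 4-state matrix into MONO, DUAL_1..DUAL_n, TRIPLE, DEATH.

    Dual sub-states share the 4-state DUAL row; staying moves the cohort to
    the next year-in-state sub-state (the last one absorbs further stays).
    """
    n = 3 + n_dual
    tri = 1 + n_dual
    E = np.zeros((n, n))
    E[0, 0] = M4[0, 0]
    E[0, 1] = M4[0, 1]
    E[0, -1] = M4[0, 3]
    stay, fail, die = M4[1, 1], M4[1, 2], M4[1, 3]
    for k in range(n_dual):
        i = 1 + k
        E[i, 1 + min(k + 1, n_dual - 1)] += stay
        E[i, tri] = fail
        E[i, -1] = die
    E[tri, tri] = M4[2, 2]
    E[tri, -1] = M4[2, 3]
    E[-1, -1] = 1.0
    return E


def run_cohort(
    pathway: str | PathwaySpec,
    params: ModelParameters,
    transition_overrides: Mapping[int, np.ndarray] | None = None,
    cv_convergence: CVConvergence | None = None,
) -> PathwayResult:
    """Run the annual-cycle cohort simulation for one pathway.

    ``transition_overrides`` maps an age-band index to a full 4x4 matrix
    replacing the one built from ``params`` (used by the probabilistic
    sensitivity analysis, whose Dirichlet draws live on whole rows).
    """
    key, pw = _resolve_pathway(pathway, params)
    H = params.horizon
    r = params.discount_rate
    n_dual = (cv_convergence.after_years + 1) if cv_convergence is not None else 1
    tri = 1 + n_dual

    # per-band 4x4 matrices, validated, then expanded
    mats: dict[int, np.ndarray] = {}
    for t in range(1, H + 1):
        b = params.band_index_at_cycle(t)
        if b in mats:
            continue
        if transition_overrides is not None and b in transition_overrides:
            M4 = np.asarray(transition_overrides[b], dtype=float)
            if M4.shape != (4, 4):
                raise ContractError("transition override must be 4x4")
            if (M4 < -ROW_TOL).any() or abs(M4.sum(axis=1) - 1).max() > 1e-9:
                raise InfeasibleParametersError(f"override for band {b} is not row-stochastic")
        else:
            M4 = build_transition_matrix(key, params, b)
        mats[b] = _expand_matrix(M4, n_dual)

    # per-sub-state annual costs
    cv = None if cv_convergence is None else {
        "myocardial_infarction": cv_convergence.myocardial_infarction,
        "heart_failure": cv_convergence.heart_failure,
        "stroke": cv_convergence.stroke,
    }
    cost_mono = state_annual_cost(HealthState.MONO, key, params)
    cost_dual_own = state_annual_cost(HealthState.DUAL, key, params)
    cost_dual = [cost_dual_own] * n_dual
    if cv_convergence is not None:
        cost_dual[-1] = state_annual_cost(HealthState.DUAL, key, params, cv_rates=cv)
    cost_tri = state_annual_cost(HealthState.TRIPLE, key, params)
    state_costs = np.array([cost_mono, *cost_dual, cost_tri, 0.0])

    wg_unit = transition_cost(HealthState.MONO, HealthState.DUAL, key, params)

    m = np.zeros(3 + n_dual)
    m[0] = 1.0
    membership = np.zeros((H + 1, 4))
    membership[0] = (1.0, 0.0, 0.0, 0.0)
    ly_d = np.zeros(H)
    ly_u = np.zeros(H)
    c_d = np.zeros(H)
    c_u = np.zeros(H)
    for t in range(1, H + 1):
        E = mats[params.band_index_at_cycle(t)]
        m_prev = m
        m = m_prev @ E
        if abs(m.sum() - 1.0) > 1e-9:
            raise InfeasibleParametersError("cohort membership does not sum to 1")
        df = discount_factor(t, r)
        alive = m[:-1].sum()
        ly_u[t - 1] = alive
        ly_d[t - 1] = alive * df
        basis = m if params.cost_accrual == "post" else m_prev
        cost = float(basis @ state_costs)
        # one-time weight-gain cost on the newly transitioned MONO->DUAL flux
        cost += m_prev[0] * E[0, 1] * wg_unit
        c_u[t - 1] = cost
        c_d[t - 1] = cost * df
        membership[t] = (m[0], m[1:tri].sum(), m[tri], m[-1])

    trace = CohortTrace(
        cycles=np.arange(H + 1),
        ages=params.start_age + np.arange(H + 1) * params.cycle_length,
        membership=membership,
        ly_discounted=ly_d,
        ly_undiscounted=ly_u,
        cost_discounted=c_d,
        cost_undiscounted=c_u,
    )
    return PathwayResult(
        pathway=key,
        total_cost_discounted=float(c_d.sum()),
        total_cost_undiscounted=float(c_u.sum()),
        total_ly_discounted=float(ly_d.sum()),
        total_ly_undiscounted=float(ly_u.sum()),
        trace=trace,
        discount_rate=r,
        horizon=H,
        start_age=params.start_age,
    )
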