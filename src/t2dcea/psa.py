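"""Probabilistic sensitivity analysis (second-order Monte Carlo).

Each draw samples a full parameter set from role-matched distributions —
gamma for costs, lognormal for the dual-state death hazard ratio, beta for
event probabilities, Dirichlet for the monotherapy and dual-therapy
transition rows — runs both pathways, and records the incremental cost and
incremental life-years.  The cloud of (delta C, delta E) pairs summarises
parameter uncertainty; the cost-effectiveness acceptability curve is the
fraction of draws with positive net monetary benefit as a function of the
willingness-to-pay threshold.

The study protocol names the distribution families but no hyperparameters.
Every univariate distribution here is mean-anchored at the base-case value
with its central 95% interval spanning that parameter's one-way sensitivity
range (+/-25% for event rates and costs, +/-20% for insulin glargine,
+/-10% for the hazard ratio); Dirichlet rows use concentration = base row x
``n_eff`` (default 1000).  In the sulfonylurea arm the sampled dual-row
death entry is multiplied by the lognormally sampled hazard ratio, with the
stay-probability reduced to keep the row stochastic; draws that drive the
stay-probability negative are rejected and resampled, with a counter kept.

Randomness policy: one root seed; draw ``i`` uses an independent substream
spawned deterministically from (seed, i), so results are reproducible and
independent of draw order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import oneway
from .cea import cea_from_totals
from .engine import run_cohort
from .errors import ContractError, InfeasibleParametersError
from .params import DPP4I, SU, ModelParameters

log = logging.getLogger(__name__)

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class DistributionAssignment:
    """One sampled quantity: where it lives, its family, its hyperparameters.

    ``parameter_path`` is either a dotted path into the configuration tree
    (scalar families: gamma / lognormal / beta / fixed) or a transition-row
    address ``transition_rows.{mono|dual}[.{arm}].{band}`` (dirichlet).
    """

    parameter_path: str
    family: str
    hyperparameters: dict = field(default_factory=dict)

    def mean(self) -> float | np.ndarray:
        """Analytic mean implied by the hyperparameters."""
        h = self.hyperparameters
        if self.family == "gamma":
            return h["shape"] * h["scale"]
        if self.family == "lognormal":
            return math.exp(h["mu"] + h["sigma"] ** 2 / 2.0)
        if self.family == "beta":
            return h["a"] / (h["a"] + h["b"])
        if self.family == "dirichlet":
            alpha = np.asarray(h["concentration"], dtype=float)
            return alpha / alpha.sum()
        if self.family == "fixed":
            return h["value"]
        raise ContractError(f"unknown family {self.family!r}")

    def sample(self, rng: np.random.Generator) -> float | np.ndarray:
        h = self.hyperparameters
        if self.family == "gamma":
            return rng.gamma(h["shape"], h["scale"])
        if self.family == "lognormal":
            return rng.lognormal(h["mu"], h["sigma"])
        if self.family == "beta":
            return rng.beta(h["a"], h["b"])
        if self.family == "dirichlet":
            alpha = np.asarray(h["concentration"], dtype=float)
            out = np.zeros_like(alpha)
            nz = alpha > 0
            out[nz] = rng.dirichlet(alpha[nz])
            return out
        if self.family == "fixed":
            return h["value"]
        raise ContractError(f"unknown family {self.family!r}")


# -- hyperparameter calibration (mean-anchored, 95% interval ~ +/- rel) ------

def gamma_hyper(mean: float, rel: float) -> dict:
    cv = rel / _Z95
    shape = 1.0 / cv**2
    return {"shape": shape, "scale": mean / shape}


def lognormal_hyper(mean: float, rel: float) -> dict:
    sigma = math.log1p(rel) / _Z95
    return {"mu": math.log(mean) - sigma**2 / 2.0, "sigma": sigma}


def beta_hyper(mean: float, rel: float) -> dict:
    sd = rel * mean / _Z95
    v = sd**2
    vmax = mean * (1.0 - mean)
    if v >= vmax:  # cannot happen for the study's rates; guard anyway
        v = 0.99 * vmax
    nu = vmax / v - 1.0
    return {"a": mean * nu, "b": (1.0 - mean) * nu}


def assign_default_distributions(
    params: ModelParameters,
    n_eff: float = 1000.0,
    rel_costs: float = 0.25,
    rel_insulin: float = 0.20,
    rel_hr: float = 0.10,
    rel_rates: float = 0.25,
    zero_variance: bool = False,
) -> list[DistributionAssignment]:
    """Default assignment of every sampled quantity to its family.

    ``zero_variance=True`` freezes everything at base (degenerate PSA used
    for parameter-recovery checks).
    """
    out: list[DistributionAssignment] = []

    def scalar(path: str, family: str, base: float, rel: float) -> None:
        if zero_variance:
            out.append(DistributionAssignment(path, "fixed", {"value": base}))
            return
        if base == 0.0:
            log.warning("parameter %s has zero base value; held fixed in PSA", path)
            out.append(DistributionAssignment(path, "fixed", {"value": base}))
            return
        if family == "gamma":
            out.append(DistributionAssignment(path, "gamma", gamma_hyper(base, rel)))
        elif family == "lognormal":
            out.append(DistributionAssignment(path, "lognormal", lognormal_hyper(base, rel)))
        elif family == "beta":
            out.append(DistributionAssignment(path, "beta", beta_hyper(base, rel)))
        else:  # pragma: no cover
            raise ContractError(f"unknown scalar family {family!r}")

    uc = params.unit_costs
    for name in type(uc).__dataclass_fields__:
        rel = rel_insulin if name == "drug_insulin_glargine" else rel_costs
        scalar(f"unit_costs.{name}", "gamma", getattr(uc, name), rel)

    for state, er in params.event_rates_by_state.items():
        for name in (
            "severe_hypoglycemia",
            "hypoglycemia_medical_assistance",
            "myocardial_infarction",
            "heart_failure",
            "stroke",
            "weight_gain_first_year",
        ):
            scalar(f"event_rates_by_state.{state}.{name}", "beta", getattr(er, name), rel_rates)

    scalar("pathways.su.dual_state_death_hazard_ratio", "lognormal",
           params.pathways[SU].dual_state_death_hazard_ratio, rel_hr)

    # transition rows: monotherapy row shared by both arms; a "neutral" dual
    # row per arm (hazard ratio applied after sampling).  Triple-therapy rows
    # stay at base.
    n_bands = len(params.mortality.bands)
    for b in range(n_bands):
        d = params.mortality.bands[b][2]
        fm = params.pathways[DPP4I].failure_rate_mono
        mono_row = np.array([1.0 - fm - d, fm, 0.0, d])
        if zero_variance:
            out.append(DistributionAssignment(
                f"transition_rows.mono.{b}", "fixed", {"value": mono_row}))
        else:
            out.append(DistributionAssignment(
                f"transition_rows.mono.{b}", "dirichlet",
                {"concentration": mono_row * n_eff}))
        for arm in (DPP4I, SU):
            fd = params.pathways[arm].failure_rate_dual
            dual_row = np.array([0.0, 1.0 - fd - d, fd, d])
            if zero_variance:
                out.append(DistributionAssignment(
                    f"transition_rows.dual.{arm}.{b}", "fixed", {"value": dual_row}))
            else:
                out.append(DistributionAssignment(
                    f"transition_rows.dual.{arm}.{b}", "dirichlet",
                    {"concentration": dual_row * n_eff}))
    return out


@dataclass
class SampledDraw:
    """One sampled parameter set: scalar fields folded into a
    ModelParameters plus the per-band transition-matrix overrides that carry
    the Dirichlet-sampled rows."""

    parameters: ModelParameters
    transition_rows: dict[str, dict[int, np.ndarray]]


def sample_parameters(
    assignments: Sequence[DistributionAssignment],
    params: ModelParameters,
    rng: np.random.Generator,
) -> SampledDraw:
    """Draw one structurally valid parameter set.

    Raises :class:`InfeasibleParametersError` when the hazard-ratio-scaled
    sulfonylurea dual row leaves no stay-probability; callers resample.
    """
    data = params.to_dict()
    rows_mono: dict[int, np.ndarray] = {}
    rows_dual: dict[str, dict[int, np.ndarray]] = {DPP4I: {}, SU: {}}
    hr_sampled: float | None = None

    for a in assignments:
        value = a.sample(rng)
        if a.parameter_path.startswith("transition_rows."):
            parts = a.parameter_path.split(".")
            row = np.asarray(value, dtype=float)
            if abs(row.sum() - 1.0) > 1e-9:
                row = row / row.sum()
            if parts[1] == "mono":
                rows_mono[int(parts[2])] = row
            else:
                rows_dual[parts[2]][int(parts[3])] = row
        else:
            if a.parameter_path == "pathways.su.dual_state_death_hazard_ratio":
                hr_sampled = float(value)
            oneway.assign_path(data, a.parameter_path, float(value))

    sampled = ModelParameters.from_dict(data)
    if hr_sampled is None:
        hr_sampled = sampled.pathways[SU].dual_state_death_hazard_ratio

    overrides: dict[str, dict[int, np.ndarray]] = {DPP4I: {}, SU: {}}
    n_bands = len(params.mortality.bands)
    for b in range(n_bands):
        d_base = sampled.mortality.bands[b][2]
        for arm in (DPP4I, SU):
            hr = hr_sampled if arm == SU else 1.0
            M = np.zeros((4, 4))
            M[0] = rows_mono.get(b, np.array([np.nan] * 4))
            dual = rows_dual[arm][b].copy()
            die = dual[3] * hr
            stay = 1.0 - dual[2] - die
            if stay < 0:
                raise InfeasibleParametersError(
                    f"sampled SU dual row infeasible in band {b} (HR {hr:.3f})"
                )
            M[1] = (0.0, stay, dual[2], die)
            M[2] = (0.0, 0.0, 1.0 - d_base, d_base)
            M[3] = (0.0, 0.0, 0.0, 1.0)
            overrides[arm][b] = M
    return SampledDraw(parameters=sampled, transition_rows=overrides)


@dataclass
class PSASample:
    draw_index: int
    delta_cost: float
    delta_effect: float


@dataclass
class PSAResult:
    delta_cost: np.ndarray
    delta_effect: np.ndarray
    cost_ref: np.ndarray
    cost_alt: np.ndarray
    effect_ref: np.ndarray
    effect_alt: np.ndarray
    seed: int
    n_resampled: int

    @property
    def samples(self) -> list[PSASample]:
        return [
            PSASample(i, float(c), float(e))
            for i, (c, e) in enumerate(zip(self.delta_cost, self.delta_effect))
        ]

    @property
    def mean_delta_cost(self) -> float:
        return float(self.delta_cost.mean())

    @property
    def mean_delta_effect(self) -> float:
        return float(self.delta_effect.mean())

    @property
    def sd_delta_cost(self) -> float:
        return float(self.delta_cost.std(ddof=1)) if len(self.delta_cost) > 1 else 0.0

    @property
    def sd_delta_effect(self) -> float:
        return float(self.delta_effect.std(ddof=1)) if len(self.delta_effect) > 1 else 0.0

    @property
    def icer_of_means(self) -> float:
        return self.mean_delta_cost / self.mean_delta_effect


@dataclass
class CEACCurve:
    wtp_grid: np.ndarray
    probability_cost_effective: np.ndarray


def run_psa(
    params: ModelParameters,
    n_draws: int = 1000,
    seed: int = 0,
    assignments: Sequence[DistributionAssignment] | None = None,
    pathway_pair: tuple[str, str] = (SU, DPP4I),
    max_resamples_per_draw: int = 1000,
) -> PSAResult:
    """Monte-Carlo sweep: sample, run both pathways, record increments."""
    if n_draws < 1:
        raise ContractError(f"n_draws {n_draws} must be >= 1")
    if assignments is None:
        assignments = assign_default_distributions(params)
    ref_key, alt_key = pathway_pair
    children = np.random.SeedSequence(seed).spawn(n_draws)
    dc = np.empty(n_draws)
    de = np.empty(n_draws)
    cr = np.empty(n_draws)
    ca = np.empty(n_draws)
    er = np.empty(n_draws)
    ea = np.empty(n_draws)
    n_resampled = 0
    for i in range(n_draws):
        rng = np.random.default_rng(children[i])
        for _attempt in range(max_resamples_per_draw):
            try:
                draw = sample_parameters(assignments, params, rng)
                ref = run_cohort(ref_key, draw.parameters,
                                 transition_overrides=draw.transition_rows[ref_key])
                alt = run_cohort(alt_key, draw.parameters,
                                 transition_overrides=draw.transition_rows[alt_key])
                break
            except InfeasibleParametersError:
                n_resampled += 1
        else:  # pragma: no cover
            raise InfeasibleParametersError(
                f"draw {i}: no feasible parameter set in {max_resamples_per_draw} attempts"
            )
        cr[i] = ref.total_cost_discounted
        ca[i] = alt.total_cost_discounted
        er[i] = ref.total_ly_discounted
        ea[i] = alt.total_ly_discounted
        dc[i] = ca[i] - cr[i]
        de[i] = ea[i] - er[i]
    if n_resampled:
        log.info("PSA resampled %d infeasible draw(s)", n_resampled)
    return PSAResult(
        delta_cost=dc, delta_effect=de,
        cost_ref=cr, cost_alt=ca, effect_ref=er, effect_alt=ea,
        seed=seed, n_resampled=n_resampled,
    )


def compute_ceac(result: PSAResult, wtp_grid: Sequence[float]) -> CEACCurve:
    """Probability of positive net monetary benefit at each threshold.

    NMB exactly zero counts as not cost-effective (strict inequality)."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ContractError("wtp_grid must be non-empty")
    if (np.diff(grid) < 0).any():
        raise ContractError("wtp_grid must be sorted ascending")
    nmb = grid[:, None] * result.delta_effect[None, :] - result.delta_cost[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CEACCurve(wtp_grid=grid, probability_cost_effective=prob)


def ceac_crossing(
    result: PSAResult,
    probability: float = 0.5,
    wtp_max: float = 100000.0,
    step: float = 10.0,
) -> float | None:
    """Smallest willingness-to-pay at which the acceptability probability
    reaches ``probability`` (linear interpolation on a fine grid); ``None``
    if it never does below ``wtp_max``."""
    grid = np.arange(0.0, wtp_max + step, step)
    curve = compute_ceac(result, grid)
    p = curve.probability_cost_effective
    idx = np.argmax(p >= probability)
    if p[idx] < probability:
        return None
    if idx == 0:
        return 0.0
    x0, x1 = grid[idx - 1], grid[idx]
    y0, y1 = p[idx - 1], p[idx]
    if y1 == y0:
        return float(x1)
    return float(x0 + (probability - y0) * (x1 - x0) / (y1 - y0))
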