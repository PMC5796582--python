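# Methods

## Model structure

The model is a deterministic Markov cohort simulation with four health
states — metformin monotherapy (MONO), metformin plus a second-line oral
agent (DUAL), dual therapy plus basal insulin glargine (TRIPLE), and
absorbing DEATH — and a one-year cycle. Treatment transitions are
forward-only; there is no return to an earlier line of therapy, no
remission, and no A1c dynamics: progression is driven entirely by constant
annual treatment-failure rates. Two pathways are compared that differ only
in the second-line agent: a DPP-4 inhibitor or a sulfonylurea.

Assumptions inherited from the study design: event probabilities and
failure rates are constant over the horizon; only death probabilities vary
(with attained age); the excess mortality of sulfonylurea therapy (hazard
ratio 1.85 applied multiplicatively to the dual-state death probability)
applies only while the patient is in the DUAL state; adverse events (severe
hypoglycemia, hypoglycemia needing medical assistance, myocardial
infarction, heart failure, stroke) affect costs but not transitions or
mortality; effectiveness is measured in life-years, not QALYs.

## Cycle and accrual conventions

The published description leaves the cycle accounting open; this package
fixes it as follows and treats it as normative:

- The cohort starts 100% in MONO at the start age (60 by default).
- Membership at cycle t (t = 1..H) is the post-transition distribution;
  cycle t is discounted by (1 + r)^(−t) with r = 0.03/year by default.
- Life-years per cycle = post-transition alive fraction × discount factor;
  no half-cycle correction.
- Costs per cycle use the same post-transition membership (a pre-transition
  variant is available via `cost_accrual: pre`; it is not the default
  because it reproduces the reference totals substantially worse).
- The one-time weight-gain cost in the SU arm is charged to the
  newly-transitioned MONO→DUAL flux each cycle, at that cycle's discount
  factor.
- Age bands follow attained age at the end of the cycle: from a start age
  of 60 the bands cover cycles 1–10, 11–20 and 21–25. Ages beyond the last
  band carry its death probability forward (used by 30-year horizons); ages
  below the first band use the first band's probability (used by start age
  55).
- Dead cohort fractions accrue nothing.

Under these conventions the base case gives discounted totals of
$18,890 / 12.47 LY (DPP-4i) and $7,003 / 11.86 LY (SU), an ICER of ~$19,590
per life-year gained, all within 1% of the reference values computed from
the same printed inputs. Exact agreement is not achievable: no combination
of band boundaries, pre/post accrual and discount-exponent convention
reproduces the reference life-years to the printed precision, which is
expected when a model is rebuilt from rounded published inputs.

## Start-age and horizon scenarios

One-way scenarios vary the horizon (20/30 cycles) at start age 60, and the
start age (55/65) with the *terminal* age held at 85 — i.e. 30 and 20
cycles respectively. The terminal-age anchoring is this package's reading
of a horizon defined as "ages 60–85"; it reproduces the reference start-65
ICER to 0.3%, while no examined convention reproduces the reference
start-55 value (closest: −4%).

The scenario in which the two arms' cardiovascular event rates converge
two years after starting dual therapy needs duration-dependence, which a
cohort Markov model lacks; the DUAL state is therefore split into
year-in-state sub-states (years 1, 2, 3+) with identical transition
behaviour and different cost loads. With convergence rates equal to an
arm's own rates the split is exactly equivalent to the plain model (tested).

## Parameters

All inputs ship in `src/t2dcea/data/base_case.yaml` (2015 USD, annual
probabilities). The key tunables:

| parameter | default | units | note |
|---|---|---|---|
| discount_rate | 0.03 | /year | applied to costs and life-years |
| horizon | 25 | cycles | ages 60–85 |
| start_age | 60 | years | |
| failure_rate_mono | 0.046 | /year | from 21% cumulative over 5 years |
| failure_rate_dual (SU) | 0.053 | /year | from 23.6% over 59 months |
| failure_rate_dual (DPP-4i) | 0.013 | /year | SU rate / 4, printed rounding |
| dual_state_death_hazard_ratio (SU) | 1.85 | — | dual state only |
| death probabilities | 0.021 / 0.051 / 0.107 | /year | ages 60–70 / 71–80 / 81+ |

The base case deliberately uses the *printed, rounded* failure rates rather
than re-derived higher-precision values (0.013 rather than 0.01325), since
the published transition matrices reuse the printed values verbatim;
`annualize_rate` and `derive_dpp4i_failure_rate` exist to verify and to
build alternative scenarios. Insulin glargine's $3,646/year is treated as
the complete regimen add-on cost (the published per-state drug totals
reconcile without a separate needle line item).

## Probabilistic sensitivity analysis

Families follow parameter roles: gamma for costs, lognormal for the hazard
ratio, beta for event probabilities, Dirichlet for the MONO and DUAL
transition rows (TRIPLE rows stay at base). The study protocol names these
families but no hyperparameters, so each univariate distribution is
mean-anchored at the base value with its central 95% interval spanning the
parameter's one-way range (±25% rates/costs, ±20% insulin, ±10% HR);
Dirichlet concentrations are base row × `n_eff` (default 1000). Structural
zeros are preserved (forbidden transitions are never resurrected). The SU
dual row is built from a "neutral" Dirichlet row whose death entry is then
multiplied by the sampled hazard ratio, the stay entry absorbing the
difference; draws that leave a negative stay probability are rejected and
resampled, with a counter reported. Because the rows are sampled jointly,
PSA draws are returned as a `SampledDraw` (scalar parameters plus per-band
transition-row overrides) rather than a bare parameter object.

Randomness: one root seed; draw i uses a substream spawned from (seed, i),
so results are bit-reproducible and independent of draw order. A
zero-variance assignment set reproduces the base case exactly and serves as
the parameter-recovery check. The CEAC counts NMB exactly zero as *not*
cost-effective, fixed for determinism.

With the default calibration the 1000-draw ICER of mean increments lands
within a few percent of the deterministic ICER, and the CEAC 0.5-crossing
sits near the ICER (≈ $19–20k), as it must for mean-anchored,
near-symmetric input distributions: the crossing is determined by the
median of the incremental distribution. The spread of the sampled
incremental life-years is dominated by the Dirichlet mortality noise and is
wider than the reference dispersion summaries, whose definition
(SD/SE/interval half-width) is not stated; they are not treated as
calibration targets.

## Scenario generator

`scenarios.random_scenario` emits structurally valid random parameter sets
(uniform within bounds chosen so every transition row stays feasible:
failure + death × HR ≤ 0.9) plus degenerate flags (zero costs, zero event
rates, certain death, HR = 1) for property testing. It deliberately does
*not* use the PSA distributions — fixtures probe structure (row
stochasticity, conservation, monotone mortality), not inference. Passing
these sweeps shows the engine is well-behaved over the whole feasible box,
not that the base-case inputs are clinically right; nothing in the
generator emulates patient-level heterogeneity, adherence, or secular
trends in care.

## Numerical choices

- All arithmetic at full float64 precision; rounding only in reports
  (dollars to the nearest dollar, ICERs also to the nearest $10).
- Row-stochasticity enforced to 1e-12 at matrix build, 1e-9 on sampled
  rows (renormalised) and on cohort conservation.
- Undefined ICERs (dominance, ties) are explicit `None` plus a dominance
  label; never NaN/inf from division.
- Tornado ties break by label for stable output.
- Beta calibration guards the variance at 99% of the feasible maximum for
  extreme means (cannot trigger with the shipped inputs).

## Known limitations

- Cohort-level only; no microsimulation, no patient-level variance.
- No QALY weighting, microvascular complications, adherence, or fixed-dose
  combinations; cardiovascular costs are acute-episode only.
- Constant rates over 25 years extrapolate short trials far beyond their
  follow-up; mortality beyond age 85 is a flat extrapolation.
- The published start-55 scenario and the published CEAC 0.5-crossing are
  not reproducible from the printed inputs under any convention examined
  here (see the start-age section and the PSA section); all other published
  quantities reproduce within ~1%.
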