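# t2dcea

A Markov cohort cost-effectiveness model for second-line type 2 diabetes
treatment pathways: metformin + DPP-4 inhibitor versus metformin +
sulfonylurea, each followed by basal-insulin triple therapy after dual
therapy fails. It is written for health economists and methodologists who
want a scriptable, testable version of this class of decision model —
base-case ICER estimation, one-way (tornado) sensitivity analysis, and
probabilistic sensitivity analysis with a cost-effectiveness acceptability
curve — rather than a spreadsheet.

## The model

A cohort starts at age 60 on metformin monotherapy and is followed for 25
one-year cycles through four states

```
MONO  →  DUAL (metformin + DPP-4i or SU)  →  TRIPLE (+ basal insulin)  →  DEATH
```

with forward-only treatment transitions and death reachable from every
state. Annual death probabilities are age-banded (0.021 at ages 60–70,
0.051 at 71–80, 0.107 above 81); in the sulfonylurea arm the dual-state
death probability is multiplied by a hazard ratio HR = 1.85. Treatment
failure rates come from cumulative trial fractions converted to annual
rates by r = 1 − (1 − f)^(1/y) (21% over 5 years → 0.046/year for
metformin; 23.6% over 59 months → 0.053/year for metformin+SU; the DPP-4i
dual rate is assumed 4× lower, 0.013/year).

Each alive state accrues one (discounted) life-year per cycle and an annual
cost = drug acquisition cost + Σ event probability × unit cost
(hypoglycemia, myocardial infarction, heart failure, stroke; 2015 USD), and
entering SU dual therapy charges a one-time expected weight-gain cost
(0.51 × $289). Costs and life-years are discounted at 3%/year. The
comparison is summarised by the incremental cost-effectiveness ratio

ICER = (C_DPP4i − C_SU) / (E_DPP4i − E_SU)  [$ per life-year gained],

by one-way perturbations (±25% rates/costs, ±20% insulin cost, ±10% death
rates and HR, horizon 20/30, start age 55/65, converged cardiovascular
rates after 2 years of dual therapy), and by a 1000-draw probabilistic
sensitivity analysis (gamma costs, lognormal HR, beta probabilities,
Dirichlet transition rows, all mean-anchored at base values) with CE plane
and CEAC = P(λ·ΔE − ΔC > 0) as a function of willingness-to-pay λ.

## Worked example

```
$ t2dcea base-case --out out/
discounted: dpp4i $18,890 / 12.47 LY, su $7,003 / 11.86 LY
incremental: $11,886 / 0.61 LY, ICER $19,590 per life-year gained (tradeoff_NE)
undiscounted ICER: $17,300
reports written to out
```

Read: over 25 years the DPP-4i pathway costs $18,890 per patient and yields
12.47 discounted life-years against $7,003 and 11.86 for the SU pathway —
the extra $11,886 buys 0.61 life-years, i.e. about $19,590 per life-year
gained (the pathway is more costly *and* more effective, a northeast-quadrant
trade-off). `out/` contains the summary as CSV/JSON, per-cycle cohort
traces, and a run manifest. The same analysis is available as a library:

```python
import t2dcea as t
params = t.load_parameters()                      # shipped base case
cea = t.pathway_icer(params)                      # runs both pathways
print(cea.delta_cost, cea.delta_effect, cea.icer_rounded)
```

`t2dcea oneway` writes the tornado-ordered sensitivity table and figure;
`t2dcea psa --n-draws 1000 --seed 1` writes the CE-plane samples, CEAC and
a summary (e.g. mean ΔC $11,975, mean ΔE 0.62 LY, ICER of means $19,470 at
200 draws, seed 1). Any parameter can be overridden by passing a partial
YAML file via `--config`; see `src/t2dcea/data/base_case.yaml` for the full
key set.

## Layout

- `src/t2dcea/params.py` — validated inputs, YAML config, rate conversion
- `src/t2dcea/engine.py` — transition matrices and the cohort simulation
- `src/t2dcea/cea.py` — ICER, dominance, net monetary benefit
- `src/t2dcea/oneway.py` — one-way sensitivity analyses and tornado
- `src/t2dcea/psa.py` — probabilistic sensitivity analysis and CEAC
- `src/t2dcea/scenarios.py` — base-case and randomized parameter scenarios
- `src/t2dcea/cli.py`, `reporting.py` — command line and report/figure output
- `docs/methods.md` — modelling assumptions, conventions and limitations
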