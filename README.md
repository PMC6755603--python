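# depotbia

Budget-impact analysis of switching schizophrenia patients from daily oral
antipsychotics to a long-acting injectable (aripiprazole-depot), in the
setting of German statutory health insurance — as a tested, reusable Python
pipeline.

Observational pre-post switch studies report that depot treatment roughly
quarters six-month psychiatric hospitalization rates (55.1% → 14%), and
hospitalization is the dominant cost driver of schizophrenia care. This
package is for health economists and biostatisticians who want to recompute,
stress-test or extend that kind of analysis: it covers per-case costing over
13 resource categories, prevalence-based national extrapolation with
market-share scenarios, one-way deterministic sensitivity analysis, the
study's endpoint statistics, and — since patient-level data from such studies
are not public — a calibrated synthetic-cohort generator so that every stage
is testable end to end.

## The model in brief

Per patient and six-month phase, utilization is valued as

    cost = Σ_k  q_k · u_k  +  Σ_j  e_j

with priced quantities `q_k` (hospital days, day-clinic/PIA days, emergency
contacts, depot injections, sick-leave days at 90 €/day) times unit rates
`u_k`, plus euro pass-through components `e_j` (EBM/GOÄ fee-schedule
services, medication, non-drug interventions). Indirect costs = productivity
losses; direct = total − indirect. The budget impact of a population
scenario (base population B, prevalence π, market share s) is

    ΔC = (C̄_oral − C̄_depot) · round(B·π) · s ,   C̄ = sample_total / n

computed in exact cent arithmetic (per-case values enter unrounded). One-way
sensitivity rescales a single linked cost component by `varied/base` — the
mean ± SD range for occurrence quantities, the price range for per-diems —
and ranks parameters by the induced per-case cost range. Endpoints are
paired Wilcoxon signed-rank tests; the post-switch hospitalization rate is
also tested against an external 38.1% reference with an exact one-sided
binomial test. Full details and assumptions: [docs/methods.md](docs/methods.md).

## Worked example

```python
from depotbia import (packaged_component_table, PopulationScenario,
                      compute_savings, extrapolate_total_cost,
                      split_direct_indirect_per_case)

table = packaged_component_table()            # per-case €, both arms, n = 132
print(table.per_case_total_eur("oral"))      # 9935.38
print(table.per_case_total_eur("depot"))     # 4557.56
print(split_direct_indirect_per_case(table, "oral")[0])   # 9498.36 (direct)

low = PopulationScenario(prevalence=0.008)    # 656,000 prevalent patients
result = compute_savings(table, low)
print(result.per_case_savings)                # 5377.82
print(result.cost_oral)                       # 6517606248.48
print(result.cost_depot)                      # 2989756626.67

share = PopulationScenario(prevalence=0.008, market_share=0.04)
print(extrapolate_total_cost(table, "oral", share))       # 260704249.94
```

Switching one patient saves 5377.82 € per six-month phase; at 0.8%
prevalence and full (hypothetical) substitution the oral strategy costs
≈6.52 bn € versus ≈2.99 bn € under depot treatment, and at a realistic 4%
market share the oral-arm cost is ≈260.7 m €.

Synthetic cohorts and statistics:

```python
from depotbia import CohortConfig, generate_cohort, event_rate, compare_paired

cohort = generate_cohort(CohortConfig())      # 132 patients, two phases
event_rate(cohort, "a")                       # ≈0.55 — phase-A hospitalization rate
res = compare_paired(cohort.a_hospital_days, cohort.b_hospital_days)
res.p_value                                   # far below 0.001
```

The same stages are reachable from the shell — each publication-style table
in one command:

```bash
depotbia all --out out/                       # full pipeline, component-table mode
depotbia simulate --out out/                  # synthetic cohort CSV
depotbia sensitivity --out out/ --tornado     # one-way analysis + tornado plot
```

Configuration is a JSON/YAML file (`--config`); `--seed` overrides the
configured seed, and a `locale: de` flag renders German number formatting
(`260.704.250,62 €`).

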