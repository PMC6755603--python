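# Methods

`depotbia` implements a single-period budget-impact analysis (BIA) of
switching schizophrenia patients from daily oral antipsychotics (OA) to a
long-acting injectable, aripiprazole-depot (LAI), from the perspective of
the German statutory health insurance (GKV). The design it mirrors is a
pre-post comparison: the same patients are observed for a six-month phase A
under oral treatment and a six-month phase B after the switch, so each
patient serves as their own control. This note documents the models, the
parameters that matter, the numerical conventions, and what the synthetic
cohort does and does not emulate.

## Costing model

Thirteen resource categories are costed per patient-phase:

| category | valuation |
|---|---|
| productivity loss | sick-leave days × 90 €/day |
| EBM / GOÄ outpatient services | euro pass-through (fee-schedule sums) |
| day-clinic / PIA days | days × per-diem (default 240 €, range 120–360 €) |
| EBM / GOÄ services during hospitalization | euro pass-through |
| hospital days | days × per-diem (default 237.50 €, range 90–385 €) |
| emergency services / emergency physician | contacts × 13.37 € / 171 € |
| non-drug interventions | euro pass-through |
| depot injections | injections × 515.97 € |
| medication, comorbidity medication | euro pass-through |

Productivity losses are the only indirect-cost category; direct costs are
total − indirect by definition, so the split always reconciles. Two
productivity rules are available: `all_days` (default — every sick-leave day
priced) and `sickness_benefit` (only days beyond 42 per continuous spell,
reflecting that the GKV pays sickness benefit from the seventh week; the
first six weeks fall on the employer).

**Money is held as integer euro cents** (exact rationals once a sample total
is divided by the cohort size n). Rounding (half up) happens only at
presentation. Consequences: the per-case, sample and population scales are
consistent to the cent by construction; conservation (total = Σ categories)
is exact; and national extrapolations agree with hand multiplication at any
magnitude.

Two entry modes feed the pipeline:

* **patient-level mode** — cost a cohort table record by record and
  aggregate;
* **component-table mode** — load a published per-case/sample component
  table directly. This is the canonical reproduction path: published
  category means are not all reconcilable with published utilization means
  (e.g. a per-case day-clinic cost of 121.21 € cannot be obtained from a
  46.13-day mean at any admissible per-diem), so reproducing the printed
  tables requires taking them as data. The packaged table stores the sample
  totals (cents-exact, n = 132); per-case values are the exact quotients.

## Budget-impact extrapolation

For a scenario (base population B, prevalence π, market share s):

    patients = round(B·π) · s          (s kept fractional, not rounded)
    total(arm) = per_case(arm) · patients

with `per_case = sample_total/n` at full precision, never the rounded
printed figure. Defaults: B = 82,000,000 adults aged 18–65, π ∈ {0.8%,
0.9%} (656,000–738,000 prevalent patients), s = 1.0. The full-substitution
scenario is labelled as an unrealistic upper bound in output, since depot
formulations are primarily prescribed after non-adherence; market-share
scenarios (4–12%) are the realistic range. The analysis is a single-period
comparison — no discounting, no uptake dynamics, no multi-year horizon. An
`annualize` flag (default off) doubles the six-month phase cost; reported
figures are per-phase as published.

## One-way sensitivity analysis

Each registry parameter links one uncertain quantity to one cost category.
Occurrence-type parameters vary by mean ± SD with the lower bound truncated
at 0; unit-cost parameters vary across a price range. The linked component
is rescaled by the ratio `varied/base`; every other component is untouched
(single-touch invariant), and setting the varied value to its base
reproduces the base case to the cent. The ratio rule is a design choice —
it is the unique linear rule with base-case recovery, and it reproduces the
published productivity-loss and hospital-day cells to the cent — but some
published day-clinic and emergency cells follow no rule recoverable from
the stated inputs and are therefore not asserted anywhere.

Cost-mode bases: the hospital per-diem uses the *implied* rate (per-case
component ÷ base mean days, ≈206 €/day oral, ≈232 €/day depot) unless
overridden; the day-clinic parameter uses the midpoint (480 €) of its
240–720 € variation range, with the 120–360 € fee corridor available as the
`bag_psych` preset. Parameters are ranked by the per-case cost range
(max − min, largest across arms); on the default inputs hospital days rank
first and the two emergency parameters last.

## Pre-post endpoint statistics

Endpoints are compared with two-sided Wilcoxon signed-rank tests at
α = 0.05. Zero differences are dropped before ranking (classical
convention); the exact null distribution is used up to 25 effective
tie-free pairs, above that a normal approximation with continuity
correction. A Lilliefors-type Kolmogorov–Smirnov normality screen on the
paired differences is attached as advisory metadata only — the pipeline
always reports the nonparametric test. If all pairs are tied the endpoint
is flagged degenerate and carries no p-value. Sick-leave endpoints are
computed on the employed stratum only. The phase-B hospitalization rate is
additionally tested against an external oral-treatment reference rate
(38.1%) with an exact one-sided binomial test.

Planning arithmetic: `required_sample_size` finds the smallest n detecting
a rate reduction of 11 percentage points (0.381 → 0.271) with 80% power at
one-sided α = 0.05, either by the one-sample-proportion normal
approximation (n = 114) or by an exact binomial power search over the exact
test's critical value (n = 116). Exact binomial power is sawtoothed in n;
the search returns the first n reaching the target, which is the usual
convention. `inflate_for_dropout` applies ceil(n/(1−d)); at d = 10%,
116 → 129. The method used is always recorded in the result.

## Synthetic-cohort generator

Patient-level data from the emulated study design are not public, so the
generator produces cohorts whose *marginal* structure matches configured
targets (defaults: n = 132; phase-A/B hospitalization rates 55.1%/14%;
means and SDs per quantity as published). Families:

* hospitalization: occurrence ~ Bernoulli(rate); admissions | occurrence ~
  zero-truncated Poisson with intensity solved so the unconditional mean
  matches; hospital days | admission ~ log-normal;
* day quantities (hospital, day-clinic, sick-leave days): log-normal
  parameters are solved so that the distribution **clipped at the 183-day
  phase length** reproduces the target mean and SD exactly (naive clipping
  of a moment-matched log-normal would bias the hospital-day mean by ≈0.7
  days, comparable to the Monte-Carlo tolerance). Days are integerised by
  unbiased randomized rounding;
* episodes and psychiatrist visits: negative binomial moment-matched to
  mean/SD (falling back to Poisson when not overdispersed);
* emergency contacts: Bernoulli × zero-truncated Poisson;
* euro pass-through fields: Bernoulli × log-normal; inpatient fee-schedule
  euros share the hospitalization occurrence event, so they arise only for
  hospitalized patients.

**Dependence.** All marginals are drawn through quantile functions from
Gaussian-copula uniforms. Each patient has two independent shared latents —
one mixed into every occurrence draw, one into every severity draw — with
weight `frailty_correlation` (default 0.5). Sicker patients therefore have
correlated utilization across phases and across quantities, while the
occurrence indicator stays independent of the severity draw within a
quantity; that independence is what makes the calibration exact
(unconditional mean = rate × conditional mean). A multiplicative frailty on
the Bernoulli rate was rejected because clipping at probability 1 biases
the calibrated rates.

**Chosen defaults the sources do not state.** Occurrence rates for
day-clinic use (0.65/0.25 phase A/B), sick leave among the employed
(0.90/0.50), non-drug interventions (0.5/0.3), comorbidity medication
(0.6), other-medication in phase B (0.5); EBM/GOÄ occurrence tied to the
statutory/private insurance shares (0.924/0.076); SDs for psychiatrist
visits (8/7) and € fields (chosen so the implied conditional variance is
positive — the feasibility constraint rate > mean²/(mean²+sd²) is validated
with the offending field named). Emergency occurrence rates are derived so
unconditional means match the per-case costs while user-conditional means
match the published 2.38/1.42/2.00 contact figures. Demographics use
fixed-composition assignment (largest-remainder counts, shuffled), so a
132-patient cohort has exactly 24 employed / 39 unemployed / 51 retired /
9 in education / 9 unknown, 71 female, 122 statutory-insured.

**What the generator does not emulate:** within-patient timing (episode
dates, spell structure of sick leave), treatment adherence mechanisms,
side-effect profiles, diagnosis subtypes, regional price variation, or any
tail behaviour beyond the two matched moments. Passing calibration tests
show that downstream costing and statistics behave correctly on data with
the published first- and second-moment structure — not that the generator
reproduces the real joint distribution of care trajectories.

## Numerical conventions and degenerate inputs

* Seeds: one `numpy` generator per cohort, seeded from the config; same
  config ⇒ byte-identical CSV. All derived seeds stay below 2³¹.
* Zero targets short-circuit to exact zeros; zero SD yields a point mass.
* Record validation (`validate_utilization`) never aborts: rows with day
  counts above the phase length, negative values, or hospital days without
  an admission are returned separately with the violated rule named.
* Problem sizes: the replicate calibration checks use 200 cohorts of
  n = 132 (Monte-Carlo SE of the hospital-day mean ≈ 0.26 days); the
  single-cohort sanity checks use n = 20,000. Both run in seconds.

## Known limitations

* Component-table mode reproduces the published tables; patient-level mode
  will not reproduce the published day-clinic/hospital cost components,
  because the published per-case costs are not consistent with the
  published utilization means at any stated per-diem (documented above).
* The copula correlation parameter is a latent-scale quantity; the induced
  observable correlation (≈0.2 for hospitalization indicators at the
  default 0.5) is weaker than the latent value and depends on the marginals.
* Exact Wilcoxon p-values require tie-free effective pairs; with ties the
  normal approximation is used regardless of n.
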