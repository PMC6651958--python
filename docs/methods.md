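# Methods

## Model structure

`smokesim` is a discrete-time, age-structured multi-state cohort model.
The living male (or female) population aged 15+ is held as counts per
single year of age in three smoking states — never, current, former — with
an absorbing death state. One cycle is one calendar year and consists of
two phases:

1. **Transition phase.** Per age, competing annual flows: initiation
   (never → current), cessation (current → former), relapse
   (former → current) and death from each state. Rows of the transition
   matrix are exactly stochastic; flows back into the never state and the
   flow never → former are structural zeros. A combination of rates whose
   flows out of a state exceed probability one is rejected as a contract
   violation rather than silently renormalized.
2. **Aging phase.** Every age shifts up one year, the open-ended top age
   (100+) absorbs its predecessor, and the cohort of new 15-year-olds —
   taken from the population input for the next calendar year — enters the
   never state. No migration at any other age.

Rates are supplied per 5-year band (15–19 … 70–74, 75+) and expanded to
single ages by band membership; results are reported back at band level.
Tracking single ages rather than 5-year compartments preserves cohort
drift between bands over an 11-year horizon (a pure band model blurs a
cohort across a band boundary ~1.7× too fast).

Within a cycle, transitions (including death) are applied first and aging
second: the transition rows describe simultaneous competing risks over the
year, while aging is bookkeeping between years.

## Parameters

| parameter | default | units | origin |
|---|---|---|---|
| initiation rate | 5.0% (15–19), 2.7% (20–24), 0 at 25+ | /year | 2014 survey estimates (packaged) |
| cessation rate | 1.3–13.6% by band (packaged table) | /year | 2014 survey estimates |
| relapse rate | 0.07 (explicit config key) | /year | see below |
| relative risks | 2.4 → 1.5 (current), 1.45 → 1.15 (former), declining with age | ratio | synthetic curves (see below) |
| base year / horizon | 2015 / 2025 | year | study design |
| 2010 anchor prevalence | 41.7% (male) | % | published survey anchor |
| target | 30% relative reduction 2010→2025 | — | WHO-style NCD target |

**Relapse.** Surveys rarely identify annual relapse, and the source tables
do not print one, so the model refuses to run without an explicit
`relapse_rate`. The shipped configuration sets 0.07/year, inside the range
meta-analyses report for sustained quitters, and chosen so that the
baseline synthetic run reproduces the published pattern of a slow,
monotone prevalence decline rather than the implausibly fast decline a
zero-relapse world produces. It applies uniformly across ages (no age
structure is available for it).

**Mortality partition.** All-cause rates are split into status-specific
death probabilities by the prevalence-weighted identity shown in the
README. This is the unique assignment consistent with both the RR ratios
and the all-cause rate, and it is recomputed every cycle from the
stratum's *evolving* state shares, so attribution responds to scenario
dynamics. A direct consequence: total deaths in every stratum always equal
the all-cause rate times the living population, whatever the smoking
composition, so two scenarios differ in *which* state people die from, not
in how many die. Deaths averted by a policy are therefore meaningful only
on the smoking-attributable scale (excess over the never-smoker
counterfactual, floored at zero per stratum), and that is the headline
measure; all-cause differences are emitted alongside for completeness and
are zero by construction.

**Scenario semantics.** All six shipped scenarios are constant per-age
multipliers over the whole horizon. The tax effect is read as a *relative*
multiplier (×1.0375 / ×1.075), not an absolute percentage-point jump,
matching the multiplicative coverage rule; and it is held constant per
cycle rather than compounded across years. Under that reading brief advice
(×1.198) is a stronger single lever on prevalence than taxation, so this
implementation's single-scenario ranking differs from analyses in which
sustained annual price rises accumulate; the combined and theoretical
scenarios, which drive the headline conclusion, are unaffected by the
choice. The theoretical scenario composes the tax multiplier by default
(`include_tax: false` disables it). Scenario-adjusted rates are clipped so
that each row stays feasible; the number of clipped age strata is reported
in the run manifest (zero for all shipped scenarios).

## Synthetic demography

The generator replaces restricted census/life-table/survey inputs with a
deterministic synthetic world of the right shape and magnitude:

- **Population:** asymmetric-Gaussian age pyramid (mode 45, spread 20
  below / 12 above), 27 million males 15+, growing 0.3%/year — a
  middle-aged-heavy, aging population with small entering youth cohorts.
- **Mortality:** Gompertz, `m(age) = 0.0010 · exp(0.068 · (age−15))`,
  evaluated at band midpoints (hence non-decreasing in age), constant over
  years. This yields ≈251,000 male deaths 15+ in 2016, the right order for
  the population modelled.
- **Relative risks:** smooth logistic decline toward 1 at the oldest ages
  (current ≈2.4 at mid-ages, former ≈1.45), the qualitative shape of large
  prospective-cohort estimates. They are synthetic stand-ins, never
  presented as measured values.
- **Survey microdata:** one multinomial draw per band over the seven
  duration categories; the category masses encode one year of transition
  history at the band's true rates, so the cessation and initiation ratio
  estimators recover the truth in expectation, and parameter-recovery
  tests can assert 3-standard-error agreement at n = 50,000. Relapsers are
  filed under "current, smoked ≥ 24 months" (lifetime duration), which
  introduces a ≤1%-relative downward bias on cessation at the oldest bands
  — visible only below the Monte-Carlo noise floor. An optional
  `durations` argument redistributes long-standing quitters across the
  quit-duration bins to reproduce survey-style duration heaping (65.9 /
  10.5 / 23.7% in the packaged anchors); in that mode the cessation
  estimator is deliberately *not* unbiased, because real instruments
  aren't either.

One run-level seed spawns independent sub-streams (population, mortality,
survey) via `SeedSequence`, so any stream regenerates independently and
the full pipeline is byte-identical under a fixed seed.

**What passing tests do and do not show.** The synthetic world shares the
published inputs' structure (state space, band rates, magnitudes) but not
Thai demography: its age pyramid, life table and RR curves are smooth
parametric stand-ins. Tests on it validate the *mechanics* — estimators,
transition algebra, scenario composition, dominance and conservation — and
the qualitative policy conclusion; they do not validate the published
point projections, which depend on unpublished population projections,
life tables and cohort-study RRs. Calibrated this way, the baseline
reaches 37.0% in 2025 (published: 37.8%) and the combined package 33.7%
(published: 33.7%), but such agreement should be read as consistency, not
reproduction.

## Numerical choices

- Counts are float64 person-counts; no rounding inside the engine. Display
  rounding (prevalences to 0.1 pp, death counts to whole persons) happens
  only at the reporting surface.
- Row stochasticity holds to 1e-12; conservation
  (alive(t+1) = alive(t) − deaths + entrants) to float-sum precision, and
  tests assert it at 1e-12 relative.
- Ages with zero living population get state shares (1, 0, 0) so the
  mortality partition stays defined; their flows are all zero anyway.
- Empty initiation bands default to 0 (initiation is modelled at 15–24);
  a missing *cessation* band is a hard configuration error — cessation has
  no safe default.
- Missing mortality or entrant years inside the horizon abort the run;
  the engine never extrapolates inputs.
- Percentage-vs-proportion ambiguity in target checks is normalized once
  (≤1 is read as a proportion) and logged.

## Back-cast validation

`backcast_validate` compares a projection with observed survey
prevalences at arbitrary years and reports signed differences without a
pass/fail threshold — the appropriate standard for a validation whose
reference is itself a survey estimate. In the packaged setting it is
exercised as a self-consistency check on the synthetic world (projecting
and comparing against the model's own output must give zero differences);
the published female observed prevalences (2.4 / 2.1 / 2.2% for
2007/2011/2014) ship in the anchors file for users with historical inputs.

## Known limitations

- No migration, no cigarette-intensity dimension, no e-cigarette states,
  no time-varying coverage ramps, and point projections only (no
  uncertainty intervals) — all out of scope by design.
- Female projections require user-supplied cessation/initiation tables
  (the published tables are male-only); the engine itself is sex-agnostic
  and the female prevalence fixture is shipped and tested.
- The all-cause-death renormalization means policies cannot change total
  deaths, only their attribution; models that freeze status-specific death
  rates at base year would show (larger) all-cause effects.
- The relapse rate is a single scalar; in reality relapse hazard declines
  steeply with abstinence duration.
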