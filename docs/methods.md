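# Methods

## Problem and data model

The package estimates population intake distributions of bioactive food
compounds by combining two data sources that national infrastructures keep
separately:

1. **Composition records** — analytical measurements of a compound's
   concentration in a plant food, one row per (plant, compound, publication)
   measurement, with descriptors for the part analysed, physical form,
   food-classification, heat treatment, cooking, treatment and preservation
   method, a quality code, and a reference id (unpublished sources are
   marked by a leading letter in the id).
2. **Consumption diaries** — multi-day food records per subject: food code,
   grams consumed, diary day, food group, and optionally a survey sampling
   weight. Typical designs are 3–4 diary days and 10²–10³ subjects and up.

Consumed food codes are resolved to the plant names the composition data is
keyed by, either directly or through recipes that express a composite dish
as ingredient plants with fixed weight fractions (fractions per dish must
sum to ≤ 1, so disaggregation never creates mass). Food codes outside the
mapped food list are dropped; every mapping run reports the fraction of
consumed grams that survived, so coverage is always visible.

## Refinement of composition records

Records that do not describe the food as eaten are removed before linking:

- **peel-only records** (`part == "peel"`, matched on a normalized lowercase
  label; "whole fruit with peel" is *not* excluded);
- **dry-weight records** (unit contains "dry weight"): without a moisture
  factor they cannot be combined with fresh-weight consumption amounts;
- optionally, a processing policy (`raw_only` / `processed_only`) judged
  from the four treatment descriptor fields; the default is `any`, because
  only the peel and dry-weight refinements are unambiguous rules — the
  processing descriptors are carried so users can match records to the
  consumed form when their survey distinguishes it.

Surviving levels are harmonized to mg/kg fresh weight. The unit vocabulary
covers mg/kg, mg/100 g (× 10) and µg/g (× 1), in fresh-weight variants;
anything else raises a unit error rather than guessing. Non-numeric levels
("n.d.", "traces") are skipped with a logged count: treating non-detects as
zeros would need a limit-of-detection convention the data do not carry.

## Intake simulation

For each (plant, compound) pair the surviving records form a **discrete
concentration distribution**; duplicates are kept and nothing is averaged,
so sampling reflects between-study spread. Each eating event draws a
concentration uniformly over records (fresh draw per event by default; a
per-day mode shares one draw across same-plant events of a subject-day —
identical expectation, fewer independent draws, hence wider intake tails).
Event intake is `grams × (mg/kg) / 1000`; a subject's mean daily intake
divides the diary total by **all** diary days, so non-consumption days count
as zeros (total-population convention). Fixed-dose events (scenario
capsules) bypass concentration sampling entirely and add their declared dose.

Quality codes are carried through but do not weight sampling; the record ids
stay attached to every distribution value as a hook for future
quality-weighted sampling. Records for the same plant are pooled across
varieties and cultivars.

`n_iterations` (default 1) averages the per-subject value over repeated
passes; the per-iteration population matrices can be retained
(`keep_iteration_draws`) to estimate Monte Carlo error directly, which the
enumeration checks use.

## Weighted summaries and bootstrap

- Weighted mean: Σwᵢxᵢ / Σwᵢ.
- Weighted quantile: the smallest observed value whose normalized cumulative
  weight (values ascending) reaches q — the left-continuous inverse of the
  weighted empirical CDF. No interpolation: well defined under arbitrary
  positive weights, exactly reproducible, and it reduces to the unweighted
  `inverted_cdf` quantile under equal weights (tested).
- Min/max are plain extremes.
- Standard errors: nonparametric bootstrap resampling **subjects** with
  replacement (subjects are the independent sampling units of a diary
  survey; days within a subject are not), each resampled subject keeping its
  weight; SE = sd (ddof = 1) across B replicates, default B = 1000. One set
  of resample indices serves all statistics of a summary, so SEs are
  computed on common replicates.
- Population scopes: `total` (all subjects, zeros included) and `consumers`
  (subjects with a positive value for the row's quantity). With zeros
  included, total mean = consumers-only mean × weighted consumer fraction,
  exactly.

## Scenario modelling

A scenario spec names the compound, the dose per unit (mg), units per day,
the eligible group (supplement consumers — subjects with ≥ 1 eating occasion
from the "Dietary Supplements" food group — or everyone) and an adoption
probability p. Adoption is one Bernoulli(p) draw per subject (a subject
either adds the product to their routine or not), and adopters take the
product on every diary day; a per-day Bernoulli mode is available behind
`adoption_mode="day"` for sensitivity analysis. Mean-shift identity:

    E[scenario mean] − baseline mean = dose × units/day × eligible weighted fraction × p

exact at p = 1, binomial Monte Carlo error otherwise. Scenario runs reuse
the baseline's concentration-draw substream, so a scenario differs from its
baseline only by the inserted doses — dose comparisons are exact and
quantile shifts are monotone in dose by construction. A dose must be
strictly positive; "no product" is expressed as p = 0, not dose = 0.

## Randomness and reproducibility

All randomness flows from one integer seed through named `SeedSequence`
substreams (intake draws, scenario adoption, bootstrap resampling), so
identical config + seed reproduces output files byte for byte, and adding a
scenario never perturbs baseline draws.

## Synthetic study generator

The generator emulates the structure the estimators must handle: a 4-day
diary; per-food daily Bernoulli consumption with lognormal portion sizes;
lognormal (or discrete-list) concentration models with a configurable number
of records per pair; planted peel-only and dry-weight rows for the filters;
a supplement-consumer subpopulation; optional lognormal survey weights
(mean 1). Lognormal quantities are parameterised by their natural-scale
mean, so ground truth is closed form:

    E[intake] = (p_day × mean portion [+ dish fraction contributions]) × mean concentration / 1000

Default conditions mirror a UK-adult-like diary: apple 21 g/day expected
(direct plus an apple-pie recipe at fraction 0.25), chocolate 7.6 g/day,
orange juice 35 g/day; mean concentrations 147 mg/kg apple epicatechin,
898 mg/kg chocolate epicatechin, 640 mg/kg orange-juice hesperidin; 20
records per pair; supplement-consumer fraction 0.2586 (the value implied by
a 17.3 → 35.4 mg/day shift at a 70 mg dose and p = 1). Subjects with an
empty diary are anchored in the written survey file by a zero-amount row so
total-population semantics survive the file round trip.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real surveys: habit autocorrelation across days,
day-of-week and seasonal effects, correlated food choices, under-reporting,
survey-specific dialects, and any dependence between portion size and
concentration. Tests on generated data validate the estimators'
correctness, not survey realism.

## Verification strategy and problem sizes

- Brute-force oracles: weighted quantiles against an explicit CDF walk;
  Monte Carlo population means against full enumeration of all concentration
  draw combinations on a 3-subject, 2-value fixture at 10⁴ iterations.
- Calibration: bootstrap SE(mean) against σ/√n on iid normal data
  (n = 400, B = 2000, 20% band).
- Parameter recovery: the full pipeline on 10³ generated subjects recovers
  closed-form expected intakes within 3 combined SEs (subject bootstrap SE
  plus the finite-record-sample term mean × cv/√m, cv² = e^σ² − 1).
- Scenario anchor: a 10⁴-subject study calibrated to a 17.3 mg/day
  epicatechin baseline (apple on 60% of days, 500-record concentration
  sample with mean 147 mg/kg, eligible fraction 0.2586) reproduces the
  35.4 / 53.5 mg/day scenario means at 70 / 140 mg within Monte Carlo error.

These sizes keep the whole suite in seconds while leaving every statistical
tolerance derived from the problem, not tuned to it.

## Known limitations

- No separation of uncertainty from variability (no 2-D Monte Carlo); the
  discrete record distribution conflates both.
- No habitual ("usual intake") modelling — estimates are diary-period means,
  not long-run intake distributions.
- Unit vocabulary is deliberately narrow; exotic units must be converted
  upstream or the record is rejected.
- Recipe fractions are static per dish; real recipe databases vary by
  occasion.
- Capsule scenarios ignore bioavailability and market substitution effects.
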