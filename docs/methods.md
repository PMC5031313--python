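# Methods

## The model

`damburden` estimates the annual direct medical cost attributable to
disease-associated malnutrition (DAM) — malnutrition arising from disease
processes rather than food insecurity — at the level of U.S.-style states,
for eight moderate-prevalence conditions: stroke, COPD, CHF, colorectal
cancer, breast cancer, dementia, musculoskeletal disorders and depression.
The disease set is deliberately restricted to conditions unlikely to
co-occur in the same malnourished person, which stands in for an explicit
comorbidity correction.

All quantities are indexed by disease *i* and by one of 30 demographic
cells *j*: five age bands (0–18, 19–45, 46–55, 56–64, 65+, edges
inclusive) × sex × race (white / black / other).  For state *s*:

```
cost(s) = Σ_i Σ_j  C_i · AF(PMN_ij, ΔMN) · ρ_ij · POP_j(s)

AF(PMN, ΔMN) = PMN·ΔMN / (1 + PMN·ΔMN)
```

* `C_i` — mean annual direct medical spending per patient with disease *i*
  (USD/patient/year; config input, nominal dollars, no inflation
  adjustment).
* `ρ_ij` — prevalence of disease *i* in cell *j*, estimated from survey
  microdata.
* `PMN_ij` — prevalence of malnutrition among persons with disease *i* in
  cell *j*, estimated from examination-survey measurements.
* `ΔMN` — proportional *excess* annual cost of a malnourished patient:
  malnourished cost = (1 + ΔMN) × non-malnourished cost.  ΔMN is a single
  global parameter by default (per-disease overrides supported).  We adopt
  the excess-ratio reading because it is the only one under which AF
  behaves correctly: if malnourished and non-malnourished patients cost
  the same (ΔMN = 0) the attributable cost vanishes.  AF is then exactly
  the excess share of total disease spending: with a fraction PMN of
  patients costing (1+ΔMN)·c and the rest c, mean spending is
  c·(1 + PMN·ΔMN) = C and the excess is AF·C per patient.
* `POP_j(s)` — census-style cell population of state *s*.

Roll-ups (state totals, per-capita, the 65+ restriction, national totals)
accumulate with compensated summation in a fixed canonical order (diseases
in reporting order, cells in canonical order, states alphabetical), so
reruns are bit-identical and national = Σ states = Σ diseases holds to
machine precision.

## Malnutrition screen

A person is malnourished if weight < 90% of Hamwi ideal body weight and/or
serum albumin < 3.5 g/dL; both inequalities are strict, so values exactly
at a threshold do not fire.  Hamwi ideal weight is 106 lb + 6 lb/inch over
5 ft (men) and 100 lb + 5 lb/inch over 5 ft (women); metric microdata are
converted internally (1 in = 2.54 cm, 1 lb = 0.45359237 kg).  Heights
below 5 ft extrapolate the same slope, floored at a configurable minimum
(default 50 lb) so ideal weight stays positive.

Missing albumin leaves that criterion *unknown*: the overall status is
unknown unless low weight already decides it, and unknown-status records
are excluded from both numerator and denominator of the PMN stage
(complete-case within disease).  Records missing height or weight are
excluded with a logged reason, never classified "not malnourished".
The same adult screen is applied to the 0–18 band — there is no separate
pediatric ideal-weight rule here — and the age band can be excluded via
configuration where that is a concern.

## Prevalence estimation

Both `ρ_ij` and `PMN_ij` use the design-based ratio estimator
`Σ w·y / Σ w` over in-domain records with known indicators, with standard
errors by Taylor linearization across strata and primary sampling units.
Degenerate designs (no stratum with ≥ 2 clusters) fall back to the SRS
binomial SE.  Domains where every observed indicator is identical would
make the linearized variance exactly zero — an incorrect uncertainty
statement for, say, zero observed cases among a few hundred records — so
such domains report the add-one adjusted binomial SE
`sqrt(p̃(1−p̃)/n)` with `p̃ = (k+1)/(n+2)` instead.

Disease prevalence is routed per disease: the larger interview survey
where possible, the examination survey for dementia and depression, and
the examination survey for all 0–18 cells regardless of routing.

Cells whose domain holds fewer than `min_cell_n` (default 10) contributing
records are filled by a deterministic pooling ladder: over race within
(age band, sex); then over sex within the age band; finally the
disease-wide marginal (taken from the disease's declared source survey).
The ladder level is recorded per cell.  Pooling trades a small, explicit
aggregation bias for reproducibility; there is no model-based smoothing.
Weight-scale invariance holds exactly: rescaling all sampling weights by a
positive constant changes no estimate.

## Probabilistic sensitivity analysis

Each replicate (default 1000, reported as 90% percentile intervals)
re-creates both surveys with the Rao–Wu rescaling bootstrap — within each
stratum of n_h clusters, draw n_h − 1 with replacement and multiply each
record's weight by m_c·n_h/(n_h−1); single-cluster strata are first merged
with the adjacent stratum in identifier order — and redraws cost
parameters: gamma by method of moments (shape = (mean/se)², scale =
se²/mean) where a standard error is available, otherwise uniform on
mean ± 20%.  ΔMN is held at its point value by default (so states remain
comparable across replicates) and redrawn only in the `vary_global_delta`
mode, which describes the sensitivity of the overall totals.

The point estimate is always the unresampled run; the replicate mean is
reported alongside.  Intervals are raw empirical percentiles; they are not
forced to bracket the point estimate, and entries where they fail to are
flagged.  One master seed drives everything; replicate *r* uses the
substream `SeedSequence(seed, spawn_key=(r,))`, so any replicate is
reproducible in isolation.  Failed replicates are dropped and counted;
more than 1% failures aborts.

## Synthetic data

The generator emulates the statistical structure of the real inputs —
an examination survey with measurements, a larger interview survey with
flags only, census-style population tables — from an explicit ground
truth, so every stage can be checked against known parameters.

* Cells drawn from a stated 30-vector; integer ages uniform within band;
  strata/clusters assigned round-robin; sampling weights are a per-cluster
  lognormal factor (mean 1, dispersion 0.3 by default).
* Disease flags independent Bernoulli(ρ_ij); an optional per-cluster
  log-odds random effect (default off) makes the design-preserving
  bootstrap differ from SRS when enabled.
* One latent malnutrition status per person, drawn from PMN of the
  person's *first* flagged disease in canonical order (background rate
  0.06 for disease-free persons), then realized through measurements:
  malnourished persons get either albumin uniform on [2.5, 3.4] g/dL or
  weight a uniform fraction on [0.75, 0.89] of ideal (fair coin);
  non-malnourished persons get albumin on [3.6, 5.0] and weight on
  [0.95, 1.30] of ideal.  The bands straddle the 0.90 / 3.5 thresholds by
  more than the 0.1-unit storage rounding, so the screen reproduces the
  latent label with zero errors — parameter recovery is a sharp test.

Because a comorbid person's single status may have been drawn from an
earlier disease's rate, the estimand of the PMN stage on generated data is
the closed-form mixture `GroundTruth.effective_pmn()`, not the raw `pmn`
matrix; the two coincide when PMN does not vary across diseases within a
cell.  Recovery and coverage oracles target the effective rate.

The default world has six synthetic states (0.65M–9.5M persons, varying
age structure), disease prevalences rising with age (dementia reaching
12.5% at 65+), malnutrition-given-disease rates of 5–14%, ΔMN = 0.5, and
per-disease costs of $5,000–$36,397/patient/year.  What it does *not*
emulate: real survey variable names, multi-cycle weight pooling or
calibration/oversampling, genuine comorbidity structure (flags are
independent), pediatric anthropometry, or item nonresponse (albumin is
complete by default).  Passing tests therefore demonstrate correctness of
the estimators and the cost algebra under a clean design, not robustness
to the messiness of real microdata.

## Numerical choices and verification sizes

* Strict `<` at both screen thresholds; exactly-at-threshold is negative.
* Summation: `math.fsum` in canonical order for all roll-ups.
* Percentile method for intervals (no normal approximation).
* Recovery checks run at examination n = 20,000 and interview n = 50,000;
  estimates fall within 3 design-based SEs of the generator's estimands in
  ≳95% of the 240 disease × cell entries.
* Interval coverage is checked over 100 independent worlds
  (examination n = 20,000, interview n = 40,000) × 200 replicates with
  degenerate cost specs, isolating survey-sampling uncertainty — the only
  quantity that varies across worlds, and hence the only scale on which
  nominal coverage is interpretable.  Measured coverage of the 90%
  interval is 0.86–0.92 depending on seeds: slightly below nominal,
  consistent with the remaining ≈0.5% plug-in bias of the point estimator
  (the attributable fraction is concave in PMN, so small diseased-cell
  domains bias it downward) and finite-replicate percentile noise.

## Known limitations

* Plug-in bias: at small examination sizes the national total is biased
  low (≈ −4.5% at n = 4,000, ≈ −0.5% at n = 20,000); no bias correction is
  applied.
* The pooling ladder assumes rates are exchangeable across the pooled
  margin; where PMN varies strongly by race the filled cells inherit the
  pooled average.
* Costs are nominal, payer-agnostic, direct medical only; no currency-year
  conversion, no indirect costs, no variance decomposition of the PSA.
* Albumin-dependent estimates use the single per-record weight supplied in
  the input; any lab-subsample reweighting belongs to data preparation.
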