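# Methods

## Decision problem and model structure

The package evaluates pembrolizumab (200 mg every 3 weeks, plus best
supportive care) against placebo plus best supportive care as second-line
therapy for advanced hepatocellular carcinoma (HCC), from a US payer
perspective in 2020 USD. The engine is a deterministic 3-state Markov
cohort model — progression-free (PF), postprogression (PP), dead — with a
21-day cycle matching the dosing schedule, a 3-year base-case horizon, 3%
annual discounting of both costs and health outcomes, and a $150 000/QALY
willingness-to-pay threshold.

Per-cycle transition probabilities are derived from marginal survival
laws rather than state-specific hazards, which are not identifiable from
published arm-level curves:

* the per-cycle death probability, applied identically in PF and PP, is
  the conditional exit probability of the overall-survival (OS) law,
  `p_death(t) = 1 − S_OS(t+Δ)/S_OS(t)`, floored at the age-specific
  background mortality from a life table (annual probability `q`
  converted by `1 − (1−q)^(Δ/12)`; age advances continuously from the
  starting age of 62);
* the progression probability is the progression-free-survival (PFS)
  conditional exit probability minus `p_death`, floored at 0, with PFS
  clipped pointwise to `min(S_PFS, S_OS)`.

This construction makes the alive fraction of the trace reproduce the OS
law exactly at every cycle boundary (verified in the tests), while the
PF/PP split follows the PFS law — i.e. it agrees with a partitioned
survival analysis on the alive total by construction. Flooring (rather
than adding) background mortality avoids double counting, since trial OS
already includes deaths from any cause; an additive mode is available
behind `ModelConfig(background_mode="add")`. The floor only binds when
the disease hazard falls below general-population mortality, which in
practice happens only under the cure scenario.

Half-cycle correction is trapezoidal: time-in-state accruals (life-years,
QALYs, occupancy-proportional costs) weight each cycle by the mean of its
start and end occupancy. Drug and administration costs are start-of-cycle
payments — a dose is dispensed whole to everyone progression-free at the
cycle start, capped at 35 treatment cycles (2 years) — and are therefore
not half-cycle corrected. The trace has `ceil(horizon/Δ)` cycles and the
final cycle's accrual length is truncated so that total accrual time
equals the horizon exactly; without truncation the 53rd 21-day cycle
would overshoot 36 months by 0.56 months and bias every total by ~1%.

## Survival inputs

Survival laws are Weibull in the shape/scale parameterization
`S(t) = exp(−(t/σ)^k)` (exponential, log-logistic and log-normal are also
supported for fitting and AIC comparison). Two routes produce a law:

1. **Fitting**: maximum likelihood under right censoring (via lifelines)
   on patient-level data, typically pseudo-IPD reconstructed from a
   digitized KM figure plus its number-at-risk row; the best family is
   chosen by smallest AIC (ties: fewer parameters, then family order).
2. **Calibration** from published summary statistics, used for the
   reproduction config because the fitted parameters behind the published
   model were not printed: the intervention OS solves `S(13.9) = 0.5` and
   `S(30) = 0.25` in closed form (`k ≈ 0.901`, `σ ≈ 20.88` months); the
   reference OS reuses that shape with its own median of 10.6 months
   (`σ ≈ 15.92`), consistent with the published OS hazard ratio of 0.78
   under proportional hazards.

PFS medians were not published for this trial; the reproduction config
assumes 3.0 months (pembrolizumab) and 2.8 months (placebo) with Weibull
shape 1.2, chosen as typical of second-line HCC trials and overridable in
the YAML config.

**Known consequence of summary-statistic calibration.** The calibrated
curves reproduce the published *per-arm* discounted outcomes closely
(life-years within 3.4%, QALYs within 3%), but the *between-arm* gap they
imply is wider than in the published model, whose Weibulls were fitted to
the full digitized curves: the reproduction yields ΔLY ≈ 0.213 and
ΔQALY ≈ 0.172 against published values of 0.153 and 0.138. Every
incremental quantity inherits this: the ICER comes out near $245 000/QALY
rather than $340 409, and the value-based price reduction near 39% rather
than 57.7%. The `reproduce` command prints this side-by-side comparison;
the acceptance tests encode the published values at their stated
tolerances, and the incremental ones fail for this structural reason.
Calibrating the curves to the published outputs themselves would make the
comparison circular, so it is deliberately not done. Differences between
two quantities that each carry a few percent of error are relatively much
less reproducible than the quantities themselves — a general caveat for
reproductions built on printed summaries.

## Economic parameters

| Parameter | Pembrolizumab | Placebo | Status |
|---|---|---|---|
| Drug cost per 3-week cycle | $6 915 | $0 | published |
| Administration per cycle on treatment | $150 | $150 | assumed |
| Utility, progression-free | 0.84 | 0.76 | published |
| Utility, postprogression | 0.68 | 0.68 | published |
| Fraction receiving postprogression therapy | 0.417 | 0.474 | published |
| Postprogression therapy cost per cycle | $6 620 | $5 963 | published |
| Postprogression therapy duration | 6 cycles | 6 cycles | assumed |
| End-of-life cost | $0 | $0 | assumed (equal care nets out) |
| Grade 3–4 adverse-event costs/decrements | none | none | assumed (schema supports them) |

Postprogression therapy is costed per *newly* progressing patient as
(treated fraction × per-cycle cost × a fixed-duration discounted
annuity), not over the whole PP occupancy: the published description ties
the cost to courses of later-line therapy of finite duration, and a
6-cycle (~4.2-month) course is in line with second-line HCC treatment
durations. Adverse-event inputs default to empty because the underlying
supplementary table is unavailable; the `ae_profile` schema accepts
(probability, one-time cost, one-time QALY decrement) triples applied at
model start.

Because the placebo arm's published absolute total cost bundles
unpublished supportive-care components, absolute totals are not
reproducible; only incremental costs are meaningful here.

## Sensitivity, threshold, scenario and subgroup analyses

One-way analysis perturbs each parameter to its published CI bound where
one exists (OS hazard ratio 0.61–1.00; placebo PF utility 0.59–0.93;
pembrolizumab price $5 531–$8 297; postprogression prices $5 596–$7 944
and $4 770–$7 156) and to ±20% of base otherwise, recomputing the ICER at
each bound; rows are sorted by spread. ICERs are capped at $2 000 000 for
display when the incremental QALY approaches zero (the HR→1 limit). The
hazard ratio enters by rescaling the intervention OS from the reference
curve under proportional hazards with the shared shape
(`σ_int = σ_ref · HR^(−1/k)`), which is also how subgroup hazard ratios
are applied.

The PSA draws all parameters independently (no published correlation
structure): beta for utilities and fractions, gamma for costs, lognormal
for the hazard ratio, each parameterized by method of moments with the
one-way range read as a 95% interval. Out-of-domain draws are rejected
and redrawn with the count reported. The acceptability curve is the
fraction of draws with positive net monetary benefit,
`NMB = WTP·ΔQALY − Δcost`, on a WTP grid. Default 10 000 draws; the test
suite and acceptance script use 2 000, which bounds Monte-Carlo error on
CEAC points by ~0.011 (1/√n).

The threshold analysis bisects on the pembrolizumab per-cycle price until
the ICER is within $1/QALY of the target; because incremental cost is
affine in price at fixed survival, the result matches the closed-form
inversion (tested to $0.01).

Scenarios: `cure_30mo` switches the per-cycle death probability to
background mortality alone for cycles starting at or after month 30, in
both arms (at a 3-year horizon this affects only the final six months, so
its ICER effect is modest); `dose_400q6w` models 400 mg every 6 weeks as
cost-neutral per unit of drug time with half the administration visits;
`horizon` re-runs at 5 or 10 years, or lifetime (until the alive fraction
falls below 1e-6 or age 100).

## Synthetic trial data

The generator exists so every upstream stage is testable without any
external data. It emulates a KEYNOTE-240-like trial: 278 vs 135 patients
(2:1), Weibull OS/PFS with the base-case parameters above, uniform
accrual over 18 months and administrative censoring at a 30-month data
cutoff. OS and PFS times are drawn comonotonically — one shared uniform
per patient through each law's inverse survival — so both marginals are
exactly the generating laws while progression never follows death (an
independent-draws-with-flooring scheme was rejected because flooring
distorts the OS marginal by up to 0.08 when PFS is not much shorter than
OS). Digitization samples the KM estimate on a regular grid with optional
clipped, re-monotonized Gaussian jitter; `jitter_sd=0` gives exact step
values. At-risk tables count records with time ≥ t.

What the generator does **not** emulate — and hence what passing
round-trip tests do not establish about real figures: digitization bias
that is systematic rather than i.i.d. (axis miscalibration, curve
overplotting), non-proportional hazards or delayed-separation shapes
typical of immunotherapy KM curves, informative censoring, and
adverse-event or response outcomes.

## Reconstruction algorithm

Pseudo-IPD reconstruction inverts the product-limit estimator interval by
interval between consecutive risk-table times: event counts at each
digitized step are chosen to track the curve's absolute level (which
self-corrects integer rounding drift), and the interval's censoring count
is iterated until the implied end-of-interval at-risk count matches the
table, with censor times spread evenly through the interval so the
procedure is deterministic. Residual integer infeasibility is resolved in
favor of the risk table (extra end-of-interval censorings, or trimming
the latest events). A drop recorded exactly at a risk-table time is
attributed to the interval ending there, with the reconstructed event
times nudged infinitesimally earlier — continuous event times almost
surely avoid the boundary, and this keeps round-trip at-risk counts
exact. Records remaining after the last curve point are administratively
censored there. An optional total-event constraint rescales interval
event counts by largest-remainder rounding. Noisy digitizations are first
repaired with a non-increasing isotonic regression (pool-adjacent
violators). On noiseless synthetic digitizations the round-trip sup-norm
error is below 0.02 across all tested seeds, arms and endpoints.

## Numerical choices

* Cycle length: 21 days = 0.6899 months, with 1 month = 365.25/12 days;
  53 cycles cover the 3-year horizon (last cycle truncated).
* Discount factors are evaluated at cycle starts, `(1+r)^(−t/12)`.
* Occupancy conservation holds to 1e-9 per cycle; discounted life-years
  agree with closed-form quadrature within 1% in exponential limits.
* Bisection tolerance $1/QALY on the ICER (≈ $0.03 on the price).
* AIC ties broken by parameter count, then by family declaration order.
* ICER display cap $2 000 000/QALY; dominance replaces the ICER when the
  incremental QALY or cost is non-positive.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); the simulator derives independent
  per-(arm, endpoint) streams from the seed via CRC-tagged spawn keys.

## Limitations

Beyond the calibration caveat above: no state-specific post-progression
hazards (death risk in PP equals that in PF at the same calendar time);
no treatment-effect waning or cure-fraction mixture modelling outside the
structural 30-month cure scenario; adverse events enter only as one-time
cost/utility hits; the life table is a smooth geometric approximation
rather than official national tables; and the 400 mg q6w scenario is
cost-neutral on drug by construction, so it cannot reproduce schedule
effects driven by per-mg price differences.
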