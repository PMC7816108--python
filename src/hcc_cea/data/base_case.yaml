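# Base-case reproduction configuration: second-line pembrolizumab vs
# placebo for advanced hepatocellular carcinoma, US payer perspective,
# 2020 USD.  Values marked [printed] come from the published trial/CEA
# summaries; values marked [assumed] are documented package defaults
# standing in for unpublished supplementary inputs.

model:
  cycle_days: 21            # [printed] 3-weekly treatment cycle
  horizon_years: 3          # [printed] base-case time horizon
  discount_rate_annual: 0.03  # [printed] 3% for costs and outcomes
  start_age_years: 62       # [assumed] cohort starting age
  max_treatment_cycles: 35  # [printed] treatment up to 35 cycles (2 years)
  half_cycle_correction: true  # [printed]
  background_mode: floor    # [assumed] background mortality as a hazard floor

arms:
  placebo:
    role: reference
    drug_cost_per_cycle: 0.0
    admin_cost_per_cycle: 150.0        # [assumed] infusion visit, both arms
    utility_pf: 0.76                   # [printed]
    utility_pp: 0.68                   # [printed]
    postprog_treated_fraction: 0.474   # [printed] 47.4% received later therapy
    postprog_cost_per_cycle: 5963.0    # [printed]
    postprog_duration_cycles: 6        # [assumed] ~4.2 months of later therapy
    eol_cost: 0.0                      # [assumed] equal end-of-life care nets out
    survival:
      os: {median_months: 10.6, shape: shared}   # [printed median; shape tied to intervention]
      pfs: {median_months: 2.8, shape: 1.2}      # [assumed] PFS not printed
  pembrolizumab:
    role: intervention
    drug_cost_per_cycle: 6915.0        # [printed] 200 mg q3w, 2020 ASP
    admin_cost_per_cycle: 150.0        # [assumed]
    utility_pf: 0.84                   # [printed]
    utility_pp: 0.68                   # [printed]
    postprog_treated_fraction: 0.417   # [printed]
    postprog_cost_per_cycle: 6620.0    # [printed]
    postprog_duration_cycles: 6        # [assumed]
    eol_cost: 0.0                      # [assumed]
    survival:
      os: {median_months: 13.9, landmark_time_months: 30.0, landmark_survival: 0.25}  # [printed]
      pfs: {median_months: 3.0, shape: 1.2}      # [assumed]

hr_os: 0.78   # [printed] OS hazard ratio, pembrolizumab vs placebo

life_table:   # [assumed] approximate US annual death probabilities
  age_min: 60
  age_max: 100
  q_min: 0.011
  q_max: 0.30

# One-way ranges: printed CIs where available, otherwise +/-20% of base.
# The same entries drive the PSA (beta for utilities/fractions, gamma for
# costs, lognormal for the hazard ratio; (low, high) read as a 95% CI).
sensitivity:
  - {path: hr_os, base: 0.78, low: 0.61, high: 1.00, distribution: lognormal,
     label: "OS hazard ratio"}
  - {path: placebo.utility_pf, base: 0.76, low: 0.59, high: 0.93, distribution: beta,
     label: "Utility, progression-free (placebo)"}
  - {path: pembrolizumab.drug_cost_per_cycle, base: 6915.0, low: 5531.0, high: 8297.0,
     distribution: gamma, label: "Pembrolizumab price per cycle"}
  - {path: pembrolizumab.postprog_cost_per_cycle, base: 6620.0, low: 5596.0, high: 7944.0,
     distribution: gamma, label: "Postprogression therapy price (pembrolizumab)"}
  - {path: placebo.postprog_cost_per_cycle, base: 5963.0, low: 4770.0, high: 7156.0,
     distribution: gamma, label: "Postprogression therapy price (placebo)"}
  - {path: pembrolizumab.utility_pf, base: 0.84, low: 0.672, high: 1.0, distribution: beta,
     label: "Utility, progression-free (pembrolizumab)"}
  - {path: shared.utility_pp, base: 0.68, low: 0.544, high: 0.816, distribution: beta,
     label: "Utility, postprogression"}
  - {path: pembrolizumab.postprog_treated_fraction, base: 0.417, low: 0.3336, high: 0.5004,
     distribution: beta, label: "Fraction treated postprogression (pembrolizumab)"}
  - {path: placebo.postprog_treated_fraction, base: 0.474, low: 0.3792, high: 0.5688,
     distribution: beta, label: "Fraction treated postprogression (placebo)"}
  - {path: shared.admin_cost_per_cycle, base: 150.0, low: 120.0, high: 180.0,
     distribution: gamma, label: "Administration cost per cycle"}

psa:
  n_draws: 10000
  wtp_max: 500000.0
  wtp_step: 10000.0

wtp: 150000.0   # [printed] willingness-to-pay threshold, $/QALY

# Published base-case values, used only for the side-by-side console
# comparison printed by the `reproduce` command.
published:
  life_years: {placebo: 1.171, pembrolizumab: 1.324}
  qalys: {placebo: 0.816, pembrolizumab: 0.954}
  incremental_cost: 47057.0
  incremental_qaly: 0.138
  incremental_ly: 0.153
  icer_per_qaly: 340409.0
  icer_per_ly: 308377.0
  threshold_price: 2925.0
  threshold_reduction_pct: 57.7
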