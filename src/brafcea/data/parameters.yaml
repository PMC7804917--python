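# Base-case clinical parameters with one-way sensitivity ranges.
# Probabilities are fractions (not percent); times are in months unless noted.
# Entries of the form {base, low, high} carry their deterministic sensitivity
# range; `dist` names the probabilistic-sensitivity sampling family.

survival:
  standard_chemo_pfs:
    family: weibull
    lam: 0.2415957
    kappa: 1.280836
    source: BEACON standard-chemotherapy arm, reconstructed IPD fit
  regorafenib_pfs:
    family: weibull
    lam: 0.1579101
    kappa: 1.439624
    source: CORRECT trial, reconstructed IPD fit
  nivo_ipi_pfs:
    family: gompertz
    lam: 0.0674932
    gamma: -0.1807722
    source: CheckMate-142, reconstructed IPD fit

# PFS hazard ratio of doublet therapy vs standard chemotherapy, applied on the
# cumulative-hazard scale to the fitted standard-chemotherapy Weibull.
doublet_hr: {base: 0.40, low: 0.31, high: 0.52, dist: lognormal}

discount_annual: {base: 0.03, low: 0.015, high: 0.06}

# Share of the standard-chemotherapy arm receiving cetuximab + FOLFIRI
# (remainder receives cetuximab + irinotecan alone).
pct_folfiri: {base: 0.50, low: 0.0, high: 1.0, dist: beta}

# Probability of discontinuing each line because of adverse events,
# applied within the first two months on the line.
ae_discontinue:
  standard: {base: 0.052, low: 0.026, high: 0.078, dist: beta}
  doublet: {base: 0.051, low: 0.025, high: 0.076, dist: beta}
  regorafenib: {base: 0.084, low: 0.042, high: 0.126, dist: beta}
  nivo_ipi: {base: 0.134, low: 0.067, high: 0.202, dist: beta}

# Probability of treatment mortality because of adverse events, applied once
# at line entry.  No treatment-related deaths were reported for nivolumab
# plus ipilimumab in its source trial, hence 0 with no range.
ae_mortality:
  standard: {base: 0.005, low: 0.003, high: 0.008, dist: beta}
  doublet: {base: 0.005, low: 0.002, high: 0.007, dist: beta}
  regorafenib: {base: 0.016, low: 0.008, high: 0.024, dist: beta}
  nivo_ipi: {base: 0.0, low: 0.0, high: 0.0, dist: beta}

# Fraction of the cohort with high microsatellite instability, routed to
# nivolumab plus ipilimumab at first progression.
pct_msi_h: {base: 0.08, low: 0.04, high: 0.12, dist: beta}

# Nivolumab drug cost stops after this many doses; ipilimumab after 4 doses
# per its trial regimen.  State occupancy continues past the cap.
nivo_max_doses: {base: 24, low: 18, high: 30}
ipi_max_doses: 4

start_age: {base: 61, low: 26, high: 91}   # years
pct_male: 0.47
pct_one_prior_line: 0.66   # cohort descriptor only; does not alter transitions

# Mean residence in best supportive care, established by calibrating model
# median overall survival to the trial medians below.
bsc_months: 0.5
os_target_months: {doublet: 9.3, standard: 5.9}

# Health-state utility for all alive states (dead = 0).
utility: {base: 0.66, low: 0.59, high: 0.735, dist: beta}

wtp_per_qaly: 150000
horizon_cycles: 480   # 40 years of 1-month cycles

# Scenario toggles
half_cycle_correction: false
ae_discontinuation_to_bsc: false   # if true, discontinuers go to BSC, not next line
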