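# Methods

`brafcea` implements a discrete-time Markov cohort model comparing two
treatment strategies for metastatic *BRAF* V600E–mutated colorectal cancer
beyond the first line: **doublet therapy** (encorafenib + cetuximab) and
**standard chemotherapy** (cetuximab + irinotecan-based regimens). This note
records the model, its assumptions, the numerical choices, and the places
where the design was genuinely open.

## Model structure

Health states: first-line treatment (progression-free), nivolumab +
ipilimumab (MSI-high patients only, after first progression), regorafenib,
best supportive care (BSC), and death. Cycles are 1 month; the horizon is
480 cycles (40 years), by which point cohort survival is negligible. Costs
and utilities are discounted at 3%/year, applied per cycle as
`(1 + r)^(-cycle/12)`.

Every transient state carries a time-in-state (tunnel) clock, because the
progression hazards are non-constant: each line's progression probability in
its tunnel cycle *k* is

```
p_k = 1 - S((k+1)Δ) / S(kΔ),    Δ = 1 month,
```

with S the line's parametric progression-free-survival law on the line's own
clock. The laws use the proportional-hazards Weibull form
`S(t) = exp(-λ t^κ)` and the Gompertz form
`S(t) = exp(-(λ/γ)(e^{γt} - 1))`; these parameterizations (not the
scale/shape forms used by scipy/lifelines) match the printed parameter
magnitudes, and the conversion is documented in `brafcea.survival`. The
doublet arm's first-line law is the fitted standard-chemotherapy Weibull
with the trial hazard ratio (0.40) applied on the cumulative-hazard scale,
`S^hr` — the only reading supported by the published parameter table, which
reports one fitted chemotherapy law plus an HR.

Within each cycle three independent competing risks act on every occupied
(state, clock) bin: progression/discontinuation (`p_move`), in-state death
(`p_die`, used for one-time treatment mortality at line entry), and
background mortality (`g`, from the life table, advancing with cohort age):

```
stay  = (1 - p_move)(1 - p_die)(1 - g)
death = 1 - (1 - p_die)(1 - g)
move  = p_move (1 - p_die)(1 - g)
```

Movers split across destination states (the MSI-H fraction, 8%, routes to
nivolumab + ipilimumab at first progression; everyone else to regorafenib).
Adverse-event discontinuation is spread as two equal per-cycle probabilities
over a line's first two months and routes discontinuers to the next line —
in the source trials "discontinuation" means stopping the study drug, not
stopping care; a config toggle (`ae_discontinuation_to_bsc`) sends
discontinuers to BSC instead, which required destination fractions that vary
with time in state (supported by the engine). Treatment mortality applies
once, at line entry (clock 0), since a single per-line probability with no
time profile is given.

### Best supportive care and calibration

BSC residence is the model's one calibrated quantity. A mean residence of
`m` months is represented as a fractional-cycle tunnel: death during tunnel
cycle `a` with probability `1−f` or cycle `a+1` with probability `f`, where
`a + f = max(m − 0.5, 0)`. Counting deaths at cycle midpoints, the expected
death time is exactly `m` months after BSC entry, and the model's
median-survival readout varies continuously in `m` — which the calibration
needs. The flip side is that residences at or below half a month are
indistinguishable at monthly resolution (all die during their first BSC
cycle), so the calibration objective plateaus on [0.1, 0.5].

Calibration is an exhaustive grid search (0.1–6.0 months, step 0.05)
minimizing the summed absolute deviation of model median overall survival
from the trial medians (9.3 months doublet, 5.9 months standard), one shared
residence for both arms (a single calibrated value is reported upstream).
Ties resolve to the smallest residence and are all reported. On the base
inputs the optimum is the entire tie set [0.1, 0.5] — containing the
half-month value the bundled config ships — with achieved medians 9.44
(doublet) and 6.98 (standard). The doublet target is met; the standard
target is not reachable by any BSC residence: with the printed fitted laws,
standard-arm survival is the sum of the first-line Weibull (median 2.28,
mean 2.81 months) and the regorafenib Weibull (median 2.79, mean 3.27
months) plus BSC, and that sum's median exceeds 6 months even in continuous
time. The shared knob therefore trades the two arms off, exactly as a
calibration that "most closely reflects" both medians must.

### Median survival readout

Median overall survival is read from the cohort trace by linear
interpolation of the alive fraction between the bracketing cycle
boundaries; "not reached" is an explicit status, not a number.

## Payoffs

Utility is 0.66 for every alive state (0 for death), accrued as
utility/12 QALYs per monthly cycle, weighted by start-of-cycle occupancy.
No half-cycle correction is applied in the base case (none is part of the
reference analysis); a `half_cycle_correction` flag switches accrual to the
average of start- and end-of-cycle occupancy so the effect can be
quantified.

Costs (2019 USD) accrue per cycle by state and time-in-state:

* **Drugs.** Oral agents at flat monthly prices (encorafenib $8,049.80,
  regorafenib $19,536.48). Intravenous agents per administered dose at the
  vial-rounded doses of the cost table (e.g. cetuximab $3,102.40/500 mg).
  Dosing frequencies follow each agent's trial regimen and are config
  values: cetuximab 4.33 doses/month (weekly); FOLFIRI and irinotecan 2.17
  (every 2 weeks); nivolumab 1.44 (every 3 weeks) while combined with
  ipilimumab (4 combination doses), then 2.17 (every 2 weeks) until the
  24-dose cap, after which drug cost stops while state occupancy continues.
  The standard arm mixes 50% FOLFIRI / 50% irinotecan-only backbones.
* **Administration.** Per infusion visit: first-hour code + preinfusion
  medication; one additional hour on cetuximab visits; an
  additional-sequence code when a second drug is infused the same day. Oral
  agents carry no administration cost. The exact billing composition per
  visit is not specified upstream; this is a documented assumption.
* **Monitoring.** Monthly office visit + CBC, CEA, ALT, AST, lipase, plus
  half of a CT abdomen/pelvis (scans every other month): $323.65/month in
  every treatment state. BSC accrues no treatment or monitoring cost (no
  BSC cost line exists in the source cost table).
* **One-time costs.** An expected adverse-event management cost at each line
  start, `Σ incidence × cost` over an editable AE table. The bundled AE
  table is a **synthetic placeholder** (the event-level schedule underlying
  the reference analysis is in unpublished supplementary material);
  its base-case contribution is ~$1,000–3,000 per line, small against drug
  costs, and it is held fixed in the PSA. End-of-life care ($42,740.36)
  applies on every entry to death — disease, toxicity, or background —
  discounted at the entry cycle.

The incremental cost-effectiveness ratio is incremental cost over
incremental QALYs; dominance and near-zero incremental QALYs are reported as
flags, never as ratios. Ratios are always computed from unrounded totals.

## Published-curve stage

For testing and for re-deriving the bundled survival parameters from new
curves, the package includes the full published-curve pipeline: a digitized
KM curve plus numbers-at-risk table is converted to pseudo individual-
patient data with an iterative Guyot-style interval algorithm (censor counts
solved so implied numbers at risk match the published table, censors
interleaved uniformly with events), then fitted by right-censored maximum
likelihood (Nelder–Mead on log-parameters; convergence tolerance 1e-6 on the
log-likelihood; non-convergence is an explicit status). AIC = 2k − 2logL
supports family selection. lifelines' Weibull fitter serves as an
independent cross-check in the tests; since no digitized curves from the
source trials are bundled, this stage is validated purely by simulation
round-trips (simulate → KM → reconstruct → fit recovers generating
parameters within 10% at n = 1000).

## Sensitivity analyses

* **One-way.** Each parameter with a printed range is set to its bounds with
  everything else at base; parameters moving the ICER by more than
  $5,000/QALY enter the tornado table. The calibrated BSC residence is held
  at its base value throughout.
* **Probabilistic.** 10,000 draws; gamma for costs, beta for probabilities
  and the utility, log-normal for the hazard ratio (95% CI mapped to
  log-scale percentiles, median pinned at 0.40). Distributions are
  moment-matched: mean = base value, SD = (high − low)/3.92; costs without a
  printed range use SD = 20% of the mean. The discount rate, starting age
  and nivolumab dose cap have no stated sampling family and are varied
  one-way only. Draws are independent across parameters (no correlation
  information is available). CEACs use net-monetary-benefit accounting, so
  draws with negative incremental QALYs are counted, not dropped. Fixed
  seeds make the PSA bit-reproducible.
* **Threshold pricing.** Incremental cost is exactly linear in the
  encorafenib and cetuximab unit prices, so the ICER surface over price
  discounts (1% steps) is computed in closed form from the base run's
  component-wise discounted spend; tests cross-check it against full
  reruns. The contour reports the encorafenib discount reaching the
  $150,000/QALY willingness-to-pay at each cetuximab discount.
* **Scenario.** A BSC-only variant removes the post-progression treatment
  lines (progression → BSC → death), with the calibrated residence
  unchanged.

## Synthetic data and the life table

The synthetic-data module generates every test input: right-censored cohorts
from known laws by inverse-transform sampling (Gompertz laws with a survival
plateau require censoring or an administrative cutoff — patients past the
plateau never progress), product-limit curves with numbers-at-risk via
lifelines, and the config fixtures. The bundled life table is a synthetic
Gompertz–Makeham stand-in for published US all-cause tables
(`q(age) = A + B e^{C·age}`, sex-specific constants anchored to US rates at
ages 30–90, ages 26–100); it is swappable via the life-table config path.
Passing tests therefore demonstrate internal consistency and faithful
implementation of the published parameters, not agreement with any
particular real-world life table or with the unpublished AE cost schedule.

## Numerical choices

* Tunnel depth per state is truncated where in-state survival falls below
  1e-14 or the hazard has flattened to within 1e-15 per cycle; beyond the
  depth the final hazard is held, which is exact to those tolerances (the
  negative-shape Gompertz hazard decays to zero, so plateau survivors
  accumulate in the final bin).
* Mass conservation is enforced at 1e-9 per cycle; absorbing mass is
  monotone by construction.
* Cohort propagation runs through a single nested-loop kernel, JIT-compiled
  with numba when available (a pure-Python fallback implements the identical
  algorithm); one full strategy evaluation takes ~10 ms, which keeps the
  10,000-draw PSA in minutes.
* Root-finding and survival evaluations use absolute tolerance 1e-8 or
  better; `S(kΔ) = 0` underflow in the transition-probability ratio returns
  p = 1 with a logged warning.
* Ages are floored to integer years for life-table lookup; ages beyond the
  table use the terminal row with a warning.

## Known limitations

* The standard-chemotherapy arm's calibrated median OS (6.98 months)
  overshoots the 5.9-month trial median for the structural reason given
  above; incremental results are less affected since both arms share the
  post-progression chain.
* Monthly cycles without half-cycle correction bias state residences upward
  by roughly half a cycle per line transition relative to continuous time;
  the bias largely cancels between arms.
* Dosing frequencies, visit-level billing composition, the AE management
  schedule, and the life table are documented assumptions; they shift
  absolute costs by a few percent but the qualitative conclusion (ICER far
  above $150,000/QALY, unreachable by encorafenib discounts alone) is robust
  to all of them.
* The triplet (binimetinib) arm, oxaliplatin-based comparators,
  covariate-adjusted or spline-based survival extrapolation, and
  value-of-information analysis are out of scope.
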