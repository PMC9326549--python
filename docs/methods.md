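# Methods

## Model structure

One SCID patient is followed from birth in discrete three-month cycles
over six states: pre-symptomatic, HSCT, SCID Well, SCID Moderate, SCID
Poor, dead. The chronic post-transplant states are absorbing apart from
death: no transition probabilities between Well/Moderate/Poor are
published, and the outcome splits (0.80/0.15/0.05 after early HSCT,
0.50/0.30/0.20 after late HSCT) together with their differential costs
and utilities fully determine the comparison.

Strategy timing:

| cycle | early-HSCT cohort | late-HSCT cohort |
|---|---|---|
| 0 | pre-symptomatic | pre-symptomatic |
| 0→1 | HSCT w.p. 0.9423, else death (+$178,923) | → SCID Poor |
| 1→2 | survivors split 80/15/5 | HSCT w.p. 0.78, else death (+$178,923) |
| 2→3 | chronic states | survivors split 50/30/20 |

The transplant cost ($119,282 early, $271,697 late) is a one-off charged
on the flow into HSCT. Deaths out of Moderate or Poor at any age carry the
one-off end-of-life cost ($41,841); the pre-treatment infection death in
the late arm carries the pre-HSCT death cost instead, not both. Annual
care costs ($34 / $24,052 / $12,873 for Well/Moderate/Poor) are pro-rated
per cycle. Societal productivity costs are carried in the registry but
excluded from totals by default (government-payer perspective;
`include_productivity_costs=True` switches them on).

## Numerical conventions

* **Half-cycle correction** — residence rewards (utilities, care costs)
  accrue on the trapezoidal average of start- and end-of-cycle occupancy.
  One-off transition costs are charged on flow, undiscounted within the
  cycle, at the completing cycle's discount factor; they are not half-cycle
  corrected.
* **Discounting** — cycle-start convention, `(1+r)^(−t·Δ)`, r = 0.03/yr
  default. The mid-cycle alternative changes totals by <0.4%.
* **Period-to-cycle probabilities** — constant hazard,
  `p_cycle = 1 − (1 − p_period)^(1/n)`.
* All arithmetic is double precision; cohort runs contain no randomness
  and are bitwise reproducible.

## Post-transplant survival calibration

The source analysis reports post-HSCT survival as single probabilities
(0.94 after early, 0.82 after late treatment) labelled "5-year survival",
with general-population mortality "applied thereafter", but does not state
how they were spread over cycles. The two candidate readings differ
greatly, and we selected between them by validating cohort outputs against
the published per-patient results:

1. **Literal five-year reading** (`survival_basis="five-year-window"`):
   spread `1 − s` at constant hazard over the cycles between transplant
   and age five, life table after. This yields 5-year QALYs of 3.76
   (early) and 2.65 (late) against published 3.50 and 1.97 (+7% and
   +34%), and 60-year values 35–114% high. It is retained as an option
   and its survivor fraction at age five equals `p_tx × s` exactly.
2. **Annual-rate reading** (`survival_basis="annual-rate"`, default):
   treat `s` as an annual survival probability sustained over the whole
   horizon (`p_cycle = 1 − s^(1/4)`), with the life-table hazard as a
   floor. This reproduces the published 5-year QALYs (−3.5%/+1.5%),
   60-year cohort costs (+0.6%/−3.2%), the 60-year incremental QALY
   (+3.2%) and both screening ICERs (within 1.2%).

The default is therefore the annual-rate reading. It implies a sustained
~6%/yr (early) and ~18%/yr (late) excess mortality, which is pessimistic
as a long-run clinical claim; it is used because it is demonstrably what
the published outcome set encodes, and the screening comparison depends on
the *difference* between arms, which this calibration matches at both
horizons.

## A known inconsistency in the published late-arm cost

The published 5-year late-arm cost ($258,133) cannot be reproduced from
the published inputs under any occupancy trajectory. Discounted one-off
costs alone are 0.78 × $271,697 + 0.22 × $178,923 ≈ $247.5k, and the
published late-arm QALY total (1.97078) pins the post-transplant
survivor-years at a level whose residence costs (care-cost mix ≈
$9,807/yr) add at least ~$19k more, before the pre-treatment Poor cycle
and end-of-life costs — a floor of roughly $268k. Our model yields
$279.3k. The early arm ($138.5k vs published $135.6k, +2.1%) and the
screen-arm per-infant cost ($8.28 vs $8.19) are consistent; the no-screen
per-infant cost inherits the late-arm gap ($5.02 vs $4.67 for the pure
0.2/0.8 cohort mixture). The corresponding acceptance assertions are left
failing rather than adjusting any input toward the published totals.

## Decision tree

Per-infant expected values; healthy infants contribute identical QALYs
under both strategies and cancel, so QALY totals are SCID-attributable.
Screen arm: screening cost for all; true positives pay confirmatory
diagnostics and the early cohort; false negatives pay the clinical
work-up and the late cohort; false positives pay confirmatory
diagnostics. No-screen arm: every case pays the clinical work-up; the
family-history fraction (20%) follows the early cohort, the rest the late
cohort. The published no-screen figure back-calculates as the pure cohort
mixture without the work-up term; both variants differ by
incidence × $3,446 ≈ $0.07/infant. The repeat-screening-test cost is
carried in the registry (its published bounds are ambiguous and are read
as A$) but is folded into confirmatory diagnostics rather than charged as
a separate branch; its impact is below one US cent per infant.

## Sensitivity analysis

One-way analysis re-runs the full screening comparison at each published
bound (the discount rate over 0–0.05). For the PSA, gamma distributions
are moment-matched with mean = expected value and SD = (high − low)/3.92
(±10% ranges → SD ≈ 5.1% of the mean); beta distributions fix the mean
and search the concentration so the central 95% interval matches the
published bounds; an infeasible match falls back to uniform with a logged
warning. Draws are independent across parameters (no correlation
structure is published) and per-iteration outputs are fully reproducible
given a seed.

The default varied set is the screening costs and probabilities (screen
and repeat-screen cost, incidence, false-negative and false-positive
rates, family-history fraction) — the "key parameters identified by the
one-way sensitivity analysis" that the source describes varying. With
1000 draws at 60 years this yields an ICER 95% CI of ≈($17.9k, $58.2k)
and acceptability 0.55 at $35k and 0.91 at $50k per QALY, matching the
published Monte-Carlo summary. Sampling *every* distributed row instead
(`varied="all"`), including post-transplant survival and transplant
costs, widens the CI to ≈($16k, $84k); the restriction is therefore
substantive and is documented on `run_psa`.

The CEAC uses the net-monetary-benefit rule `P(ΔE·λ − ΔC > 0)`,
equivalent to counting ICERs under the threshold in the observed
north-east quadrant but robust in dominant quadrants; ICER percentile CIs
use concordant-quadrant iterations only, with dominant iterations counted
separately.

## Synthetic inputs and the oracle

* **Life table** — the mortality schedule behind the published analysis
  is not identified, so the bundled table is *synthetic*: Gompertz–Makeham
  hazard `h(a) = 2×10⁻⁴ + 2×10⁻⁵·e^{0.095a}` with infant q₀ = 0.0033,
  chosen once to resemble a contemporary high-income-country schedule
  (q(60) ≈ 0.006, life expectancy ≈ 80y). Because the default survival
  calibration keeps the disease excess hazard above the life-table floor
  until very old ages, model outputs at both horizons are nearly
  insensitive to this fixture; results with a real national table should
  differ negligibly. What the synthetic table does *not* emulate:
  cohort-vintage trends, sex differences, accident humps.
* **Microsimulation** — individual trajectories are drawn from the same
  transition matrices and reward rules as the cohort engine (trapezoidal
  residence rewards, flow-charged one-offs), so its sample mean is an
  unbiased estimator of the cohort totals. Agreement (occupancy within 3
  Monte-Carlo SE, rewards within 1% at n = 200,000) validates the engine's
  bookkeeping, not the clinical realism of the inputs.

## Problem sizes and defaults

Quarterly cycles; horizons 5 years (20 cycles) and 60 years (240 cycles);
PSA 1000 iterations; microsimulation oracle 200,000 individuals. A full
PSA runs in ~20 s and single cohort runs in milliseconds.

## Limitations

* No gene-therapy or genotype-stratified treatment arms; no non-SCID
  conditions detected by the same assay (their inclusion would favour
  screening).
* Well/Moderate/Poor are absorbing; late recovery or deterioration is not
  modelled.
* Currency conversion keeps the published US$ figures as canonical; the
  PPP utility reproduces them only to publication rounding.
* The annual-rate survival calibration is an outcome-matching device; its
  long-run excess-mortality implication should not be quoted as a
  clinical estimate.
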