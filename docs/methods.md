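# Methods

## Model structure

The model is a deterministic annual-cycle Markov cohort simulation of
dialysis-dependent CKD-5 patients with secondary hyperparathyroidism over a
10-year horizon. The published state space is hemodialysis (HD), peritoneal
dialysis (PD), kidney transplantation (TX) and death (DEAD, absorbing);
direct HD↔PD switching does not occur, and transplanted patients can return
to either dialysis modality (graft failure) or die. Two annual transition
tables exist per arm ("1 year" and ">1 year").

Internally the engine runs on five states, splitting TX into a one-cycle
tunnel `TX_Y1` and an established state `TX_EST`:

* dialysis rows route their →TX mass into `TX_Y1`;
* `TX_Y1` always carries the "1 year" transplant row and `TX_EST` the
  ">1 year" row — first-year transplant dynamics follow time since the graft,
  not model time, matching the separate first-year transplant cost;
* surviving transplant mass flows `TX_Y1 → TX_EST → TX_EST`;
* HD/PD rows switch from the "1 year" to the ">1 year" table at model
  cycle 2.

Printed transition rows carry rounding residue up to 3 × 10⁻⁵ (the
comparator transplant rows sum to 1.00003); rows within 10⁻³ of 1 are
repaired on the diagonal ("stay") entry only, preserving every printed
transition intensity. Traces conserve probability mass to 10⁻¹².

## Intervention-arm derivation

The paricalcitol matrices are derived from the comparator matrices by

* death entries × 0.85 (published relative risk), rounded **half-up to
  3 decimals**;
* transplant-linked entries (dialysis→TX; TX→HD, TX→PD) × (1 − 0.23)
  (published "risk adjustment"), rounded **half-up to 4 decimals**;
* stay entry recomputed as the remainder, so derived rows sum to exactly 1.

Rounding is decimal (via `decimal.Decimal` on the shortest decimal rendering),
applied before the remainder. This is the unique order/precision reproducing
all 32 published intervention cells bit-exactly, including
0.150 × 0.85 = 0.1275 → 0.128, which round-half-even misses. The pipeline
loads the published matrices verbatim by default and keeps the derivation as
a cross-check, since printed values are the source of record. The published
table's TX→PD entry 0.00403 is inconsistent with the stated product
0.05 × (1 − 0.9146) = 0.00427; the printed value is used.

## Costs, utilities and accrual

Per cycle, HD/PD occupants accrue the dialysis cost, the arm's drug cost
(year-1 schedule in cycle 1 — paricalcitol's dose-titration year — then the
later schedule) and a hospitalization cost; `TX_Y1` accrues the first-year
transplant cost, `TX_EST` the follow-up cost, DEAD nothing. The comparator's
drug cost is the **sum** of calcitriol and cinacalcet (one combined regimen).
All values are 2020 RMB; no inflation or currency conversion.

Hospitalization: the parameter sheet gives per-arm inpatient costs
(¥19,557.85 / ¥19,375.57) and annual hospitalization counts (2.40 / 2.61).
Whether the costs are per stay (to be multiplied by the counts) or already
annual is ambiguous in the source; the flag `inpatient_is_annual` selects the
interpretation and participates in calibration. Treating the printed values
as **annual** is the only interpretation consistent with the published totals
(the per-stay × frequency reading inflates every total by ≈ 19–20%).

Discounting (5%/year on costs and QALYs) and occupancy timing are governed by
two flags: `discount_convention` (first cycle undiscounted, i.e. (1+r)^−(k−1),
vs. all cycles discounted, (1+r)^−k) and `accrual` (end-of-cycle occupancy,
start-of-cycle, or their mean — the half-cycle correction). The source states
neither; the calibrated configuration uses **all cycles discounted** with
**end-of-cycle accrual** and no half-cycle correction.

## Calibration of the unprinted starting split

The cohort starts entirely on dialysis; the HD/PD split is cited to a
registry report without a printed value. `calibrate_initial_split` grid
searches `initial_hd_fraction` ∈ [0.50, 1.00] (step 0.0005), optionally
scanning the 12 convention-flag combinations, minimising the sum of squared
relative errors against the four published base-case totals. Because the
trace — hence every total — is linear in the initial occupancy vector, the
grid is evaluated exactly from two basis runs (all-HD and all-PD starts) per
arm; this equals brute-force evaluation to machine precision and keeps the
search under 0.1 s. On synthetic scenarios a planted split is recovered
within one grid step; a configuration whose HD and PD rows, costs and
utilities coincide is flagged non-identifiable.

The calibrated point is `initial_hd_fraction = 0.794` with the conventions
above, reproducing the four published totals to 0.22 % / 0.23 % / 0.40 % /
0.44 % and the QALY increment to 0.1 % (0.1832 vs. 0.183).

**Known discrepancy.** The published cost increment is ¥6,925.612, the
difference of the two published totals. The calibrated model yields a saving
of ¥9,056.2. The increment is a difference of totals ~70× larger, so the
±0.2 % per-arm residuals (opposite in sign) dominate it. No combination of
split, discount convention, accrual convention, inpatient interpretation or
">1 year" onset cycle matches the increment *and* the four totals
simultaneously: forcing the increment toward ¥6,926 (split ≈ 0.99) pushes all
four totals and the QALY increment to ≈ 2.3 % error. The calibration
therefore keeps its declared objective (the four totals), and the residual
increment error is reported by `CalibrationResult.rel_errors` rather than
hidden. Dominance — cheaper and more effective — is reproduced at every grid
point. A cost is never accrued in the DEAD state and no terminal-cycle
correction is applied.

## Sensitivity analyses

**One-way.** Each parameter with a published range is set to its low/high
bound with everything else at base, and the full deterministic pipeline is
re-run. The default tornado outcome is the iNMB at ¥217,113/QALY, because
base-case dominance makes raw ICERs sign-unstable; ICER output with dominance
flags is available. Ranges follow the published construction rules, which
`check_consistency` re-derives: −52 %/+20 % for centrally tendered prices
(drugs, dialysis, follow-up transplant care), ±20 % for hospitalization and
first-year transplant costs, ±10 % for utilities, matched at the printed
precision of each bound. One published bound carries a final-digit artifact
(99,228.25 × 1.2 = 119,073.90 vs. the printed 119,073.89); bounds are matched
within one unit in the last printed digit and the strict difference stays
visible in the report.

**Probabilistic.** 1000 Monte Carlo iterations sample every distributed
parameter: gamma for costs (scale parameterization, mean = αβ — verified
against the parameter sheet, where the rate reading is off by orders of
magnitude) and beta for utilities. Parameters shared between arms are drawn
once per iteration, so no spurious incremental variance is created; transition
probabilities have no published distributions and stay fixed, which lets the
PSA reuse the two deterministic traces. The gamma scale printed for
calcitriol (0.39) is its base value 3942/10000 rounded to two decimals, so
that distribution's analytic mean (3900) misses the base by 1.07 % — the only
parameter exceeding a 0.5 % tolerance; the printed value is kept and the
consistency report flags it. The CEAC reports, per threshold, the fraction of
iterations with strictly positive iNMB (boundary ties count as not
cost-effective); the point estimate at ¥217,113 carries a binomial 95 %
interval (±1.2 points near 96 % at n = 1000). EVPI is
E[maxₐ NMBₐ] − maxₐ E[NMBₐ] per person (non-negative by Jensen's inequality;
residue below 10⁻⁹ of the NMB scale is snapped to exactly 0 so the
no-uncertainty identity holds) and scales by the 10,000-patient cohort for
the population value; both are emitted.

Random streams for scenario generation, PSA and microsimulation are
independent named streams derived from one master seed (`rng_stream`), so
changing iterations in one stage never perturbs another; identical seeds give
bit-identical outputs.

## Synthetic scenarios and the microsimulation oracle

`random_scenario` emulates the statistical structure of the published
parameter sheet without copying it: Dirichlet-drawn row-stochastic matrices
respecting the structural zeros and the absorbing death state, death
probabilities within a configurable range, positive costs with gamma
uncertainty at a configurable coefficient of variation (shape = 1/cv²),
utilities with matched-mean beta uncertainty (variance capped to stay
admissible), tender-rule OWSA ranges, and a uniform starting split. Every
generated configuration passes the same validation as the fixture. What it
does **not** emulate: age/sex structure, secular trends, correlation between
costs and utilities, or arm-linked effect parameters — so passing tests
demonstrate the *arithmetic* of the pipeline on valid inputs, not clinical
realism.

`microsim_oracle` simulates individual patient paths by categorical sampling
from the same expanded matrices and accrues each patient's discounted cost
and QALYs under the same convention flags as the cohort engine. Cohort totals
agree with microsimulation means within 3 standard errors at n = 100,000 on
the fixture, and trace discrepancies shrink at the 1/√n Monte Carlo rate —
an independent check of the trace arithmetic.

## Numerical choices and problem sizes

* Row-sum tolerance 10⁻³ with diagonal repair; conservation tolerance 10⁻¹².
* Calibration grid step 0.0005; ties broken toward the first combination in
  a fixed scan order; non-identifiable objectives return the lower grid edge
  with a warning.
* Dominance uses weak inequalities on the cost side (ΔC ≤ 0, ΔE > 0 is
  dominant); ΔE = 0 is classified "undefined" and no ICER is reported.
* Default problem sizes keep the full test suite and the reproduction script
  comfortably interactive: 1000 PSA iterations (as published; 10 seeds in the
  headline check), 10⁶ draws for distribution-fidelity checks, 10⁵ microsim
  patients on the fixture, 3–5 × 10⁴ on synthetic scenarios.

## Known limitations

* The published cost increment cannot be matched simultaneously with the
  published totals (see calibration above); the model family reproduces five
  of the six published base-case quantities within 0.5 % and the increment's
  direction and dominance, not its printed magnitude.
* The calibrated HD share (0.794) is an estimate conditional on the model
  structure, not registry data.
* No age/sex stratification, no parametric survival extrapolation beyond the
  10-cycle horizon, no indirect/societal costs, no adverse-event costs, no
  EVPPI — matching the scope of the source analysis.
* The per-tablet drug-cost arithmetic behind the paricalcitol annual costs
  (dose titration over the first 18 weeks) is not re-derived; the annual
  values are taken as printed. The cinacalcet and calcitriol annualizations
  (weekly/7 × 365) do reconcile and are kept as fixture self-tests.
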