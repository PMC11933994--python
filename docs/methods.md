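# Methods

## Model structure and assumptions

The engine is a deterministic expected-value (cohort) state-transition model
with a monthly cycle and a 10-year (120-cycle) horizon. Occupancy is a
fractional person-count per (age stratum, health state), with the two listed
states additionally resolved by months-since-listing (a tunnel dimension)
so wait-time distributions can be read off the trace.

Key structural assumptions:

- **Closed cohort.** The 662,190 patients present at model start are the
  entire population; no incident CKD/ESKD patients enter later. Flow totals
  therefore decline slowly over the decade as the cohort depletes.
- **No aging across strata.** Patients keep their entry age band for all
  10 years.
- **Competing risks as mutually exclusive one-step probabilities.** Within
  a cycle, the exits from an origin state are applied simultaneously with no
  event ordering and no half-cycle correction; at monthly granularity the
  discrepancy between ordering conventions is small. Competing exits that
  would sum above 1 raise an explicit error — the engine never renormalises
  silently.
- **Listing duration.** Newly listed mass enters the duration-0 bucket at
  the end of its listing cycle and is first at risk of transplant the
  following month. Listed CKD patients who progress to dialysis move
  laterally into the dialysis-listed tunnel at the same duration: they stay
  on the list and their wait-time clock keeps running.
- **Removal is terminal for listing.** Removed patients face elevated
  mortality (p_death_removed ≥ p_death_dialysis is enforced) and cannot be
  relisted. Graft failure returns patients to unlisted dialysis, from which
  they can be relisted; a relisting starts a fresh wait-time clock.
- **Perioperative deaths** count both as a transplant (flow totals, KM
  event) and as a death.

## Probability conversions

Annual registry rates are converted to monthly probabilities with the
constant-hazard formula `p_m = 1 − (1 − p_a)^(1/12)`; the inverse is exact
and round-trips to ≤ 1e−12. All stored parameters are monthly.

## Calibration

Five observable flows (waiting-list additions, DDT, LDT, removals,
waiting-list deaths) are calibrated to their 2022 annual registry totals.
Each flow maps to one parameter block (the two listing probabilities move
together); a block is rescaled by a common multiplier across strata — so the
base set's stratum profile is preserved — solved by Brent root-finding
against the simulated first-year total. Blocks are swept in decreasing order
of target size (dominant flows stabilise the at-risk pools the smaller ones
see), and sweeps repeat until every flow is within tolerance (default 0.5%,
the validation bar; cap 50 sweeps). Calibration targets first-year event
*counts*, not steady-state rates, because validation compares year-1 model
output to the registry year. The whole procedure is deterministic and takes
well under a second at the default cohort size.

## Scenario mechanics

- **List expansion** (10%/50%) scales the initial listed occupancy (drawn
  proportionally from the corresponding unlisted pools, applied equally to
  the CKD and dialysis lists) and the two listing probabilities by the same
  factor.
- **Organ supply as a count budget.** The status quo runs probability-driven
  and its realized per-cycle DDT/LDT counts define every other strategy's
  budgets (× the supply multiplier); budgets therefore track the status quo
  year by year rather than holding a single annual figure. Each cycle the
  allocator scales per-cell transplant probabilities by a common λ
  (relative allocation across strata/durations preserved) so expected
  transplants equal the budget, solving a monotone 1-D root problem exactly
  when no cap binds and by Brent otherwise.
- **Allocation caps.** Each cell's transplant probability is capped at its
  competing-exit headroom (1 minus the cell's death/removal/progression
  probabilities). Under the largest supply expansions the shrinking late-
  horizon candidate pool cannot absorb the full budget; the shortfall is
  left unused and flagged per cycle in the budget log, rather than aborting
  the run or pushing exit probabilities above 1.
- **Off-list LDT is also budgeted** in non-status-quo strategies (at the
  status quo's realized counts), because transplant numbers are fixed by
  design across strategies; under LDT expansion the *incremental* budget,
  baseline × (multiplier − 1), goes to wait-listed patients (uniform
  per-person allocation, as no baseline on-list LDT pathway exists).

## Wait-time estimation

All listing spells pool onto a common time-since-listing axis: mass at
duration t−1 at a cycle start is at risk during month t. Transplant (DDT
plus on-list LDT) is the event; deaths on the list and removals censor, and
mass still listed at the horizon is administratively censored in the month
it last completed. Death and removal are treated as censoring, not as
competing risks — the standard product-limit approach for this outcome,
whose known optimism (it assumes censored patients would eventually be
transplanted) is inherited deliberately; an Aalen–Johansen competing-risk
estimator is a documented extension, not implemented.

The product-limit formula runs directly on expected fractional counts (no
rounding to whole persons), consistent with an expected-value engine.
Quantiles follow the step-function definition (smallest month with
S(t) ≤ 1 − q), returning an explicit `None` when the curve never reaches the
level within the horizon — the "median not calculable" situation familiar
from registry data. Reported tables use linear interpolation between the
bracketing monthly grid points to give sub-month resolution; both values are
available.

## Synthetic inputs

The published supplementary parameter table is not available, so
`synthetic.generate_parameter_set` builds parameter sets anchored to printed
magnitudes: the five flow blocks are seeded analytically from the 2022
registry totals divided by the default initial at-risk pools (landing within
a few percent of the targets before calibration), with mild stratum
profiles normalised so they do not shift totals. Clinical rates not under
calibration (progression ~25%/yr; CKD mortality 2–10%/yr, dialysis 8–25%/yr,
post-removal 15–42%/yr, post-transplant 1–6%/yr by stratum; graft failure
3–5%/yr; perioperative mortality 0.3–0.6%) are stated assumptions in
plausible clinical ranges, jittered ±7% per parameter by the seed (one
factor per parameter keeps the removal ≥ dialysis mortality ordering).

The default cohort split is likewise an explicit assumption: 530,000
dialysis patients (12.4% wait-listed, the printed status-quo listing share)
and 132,190 CKD patients, with an 89,000-person waiting list whose
difference is listed preemptively from the CKD pool; stratum shares
approximate a mean age near 59 years. Because the true parameter table is
unavailable, absolute wait-time levels are not expected to match published
point estimates; the calibrated registry flows, the estimator algebra, and
the ordering of strategies are the tested surface, and passing tests say
nothing about parameter values the registry totals do not constrain.

## Microsimulation oracle

`synthetic.microsimulate` draws individual patients through the *same*
transition tables the cohort engine consumes (shared by object identity, so
the two state graphs cannot diverge), using per-cycle categorical draws. It
is probability-driven (status-quo dynamics) and serves two cross-checks: per-
state occupancy proportions at cycles 12/60/120 must sit within 3 Monte-Carlo
standard errors of the cohort expectations at n = 50,000, and the pooled
cohort KM median must agree within ±1 month with a standard event-table
Kaplan–Meier fit (lifelines) to the simulated listing spells. The 3-SE band
trades a sliver of strictness for a negligible flake rate; the fixed seeds
make the suite deterministic in practice.

## Numerical choices

- Occupancy conservation is asserted every cycle at 1e−9 relative; the
  engine is linear in cohort size by construction.
- Budget satisfaction: expected transplants equal the per-cycle budget to
  1e−6 relative whenever the candidate pool suffices.
- Brent root-finds use xtol ≈ 1e−14/1e−15; calibration accepts a solved flow
  within max(0.5 events/yr, 1e−6 relative).
- Risk-set tables validate the ledger identity n_{t+1} = n_t − d_t − c_t at
  1e−9; empty risk months contribute factor 1 to the product limit.
- Duration buckets span 0…horizon; mass that would outrun the grid pools in
  the top bucket (unreachable at the default horizon).
- Parameter CSVs are written at 17 significant digits and read back with
  round-trip float parsing, so save→load is exact.

## Problem sizes

Default runs use the full 662,190-person cohort (cost is independent of
cohort size in an expected-value model), the complete 19-strategy grid over
120 cycles, and a 50,000-patient microsimulation for the oracle checks; the
entire analysis, including calibration, completes in a few seconds.

## Known limitations

No blood type, sensitisation, or geographic allocation detail; no active vs
inactive list status; no delayed graft function or primary non-function; no
organ-quality (KDPI) tiers; no costs, utilities, or discounting; no COVID-era
mortality adjustment; no incident patients. Wait time counts from listing
within the model window, excluding time accrued before model start by
prevalent listees — these omissions bias wait-time levels downward, which is
another reason the scenario medians should be read relative to one another.
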