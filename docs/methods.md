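# Methods

## Decision problem and model structure

The package models adults newly diagnosed with major depressive disorder who
have failed a single antidepressant medication trial, and compares two
strategies from that point to the end of expected life: switching to rTMS,
or continuing with further antidepressant pharmacotherapy attempts.  Four
age cohorts are modeled through their expected additional years of life
(likely value and range): mid-20s 48 (33–63), mid-30s 38 (23–53), mid-40s 28
(13–43), mid-50s 16 (3–29).

Each arm is a discrete-time cohort Markov model with an annual cycle (one
model stage = one year of life) over the attempt-expanded state space

| state | meaning |
|---|---|
| `in_treatment_k`, k = 1..4 | k-th attempt with the arm's own therapy |
| `remission_maintenance` | remitted; maintenance medication + psychotherapy |
| `response_maintenance` | responded without remitting; maintained at a lower utility |
| `relapse` | lost response/remission this year; re-treated next cycle |
| `ect` | fallback after four failed attempts; remains until remission |
| `death` | absorbing |

Transitions per cycle: an in-treatment patient remits with probability
`p_rem(k)`, responds with `p_resp(k)`, otherwise moves to the next attempt
(or to ECT after attempt 4).  Success diminishes with each prior failed
attempt of the same therapy: `p(k) = p(1) · a^(k−1)` with a single
multiplicative attenuation factor `a` per arm (a per-attempt vector is
accepted where finer control is wanted).  Maintenance states relapse with an
annual probability; relapse routes back to attempt 1 of the same arm
(`relapse_reentry_attempt` in the config generalizes this to any attempt
index, covering the reading in which the attempt counter does not reset).
The ECT state remits with an annual probability and otherwise continues ECT
— treatment trials continue indefinitely rather than ending in a permanent
"untreatable" state.

Background mortality is a constant annual hazard `1/LE_likely` applied first
each cycle as a competing risk (clinical transitions share the surviving
mass), with a hard stop at the horizon.  This keeps the two anchors — a
per-stage death state and a fixed life-expectancy horizon — consistent:
expected survival within the model is of the order of the cohort's life
expectancy, and nobody outlives the horizon.  Setting
`include_background_mortality: false` gives a pure fixed-horizon model.

## Rewards, discounting, numerical conventions

Costs are nominal 2016 USD per state-year built from unit rates: an rTMS
treatment year bills one initial session (CPT 90867) plus the remaining
`sessions/year − 1` sessions at the repeat rate (CPT 90868) plus
motor-threshold re-determinations (CPT 90869); a pharmacotherapy treatment
year bills 12 months of drug supply.  Both arms add psychotherapy and the
"other direct" annual medical costs common to every alive state; maintenance
and relapse years carry maintenance medication plus psychotherapy; the ECT
year carries an annual course cost.  Utilities are Euro-QoL indices in
[0, 1] per state-year, with death fixed at 0 and the ordering
remission ≥ response ≥ non-response enforced at validation.

Totals discount at 3%/year with `1/(1+r)^t`, cycle 0 undiscounted, rewards
accruing on start-of-cycle occupancy over cycles `0..T−1`.  There is no
half-cycle correction by default; `half_cycle_correction: true` switches to
the average of start- and end-of-cycle occupancy for comparison.  Transition
matrices are validated row-stochastic to an absolute tolerance of 1e-9 per
row (a safe double-precision margin); cohort traces conserve mass to the
same tolerance.

Reporting rounds incremental cost to whole dollars, incremental QALYs to two
decimals and the ICER to the nearest dollar, which reproduces the published
ratio arithmetic exactly.  Ties are never dominance: ΔC = 0 reports ICER 0,
ΔQ = 0 reports ±∞, identical outcomes are "equivalent".  On the
cost-effectiveness plane, boundary points are assigned to the closed-east /
closed-north quadrant so scatter tallies always partition.

## Sensitivity analyses

*One-way*: the NMB difference (rTMS − pharmacotherapy) is evaluated on a
≥ 21-point grid over the parameter's [low, high] range; every sign change is
refined by bisection to the requested tolerance.  Multiple crossings are all
reported and flagged non-monotone.  At the default willingness-to-pay of 0
the threshold is exactly the value at which rTMS stops (or starts) being the
less costly lifetime strategy.

*Tornado*: each parameter in turn is set to its range ends with all others
at base.  The default objective is the **incremental** NMB — the quantity
that decides between the arms — so costs common to both arms cancel and the
ranking reflects decision-relevant uncertainty; `objective="focal"` scores
the rTMS arm's own NMB instead, for users who want the single-strategy
convention.  Ranking is by descending spread with alphabetical tie-break, so
it is invariant to input order.

*PSA*: second-order (parameter-uncertainty) Monte Carlo.  Each draw samples
every distributed parameter, re-runs both arms as full cohort models, and
records the incremental (ΔQ, ΔC) point; 1,000 iterations by default.  One
RNG substream per draw index (NumPy `SeedSequence.spawn`) makes results
reproducible and order-independent.  Draws violating a role bound are
rejected and resampled (error after 1,000 rejections); jointly infeasible
draws (per-arm remission + response > 1) are likewise rejected as a pair.
The alternative reading of the published 1,000-run Monte Carlo — first-order
patient-path microsimulation — is deliberately not implemented; parameter
sampling is the interpretation consistent with assessing the stability of
the base case.

Default distributions when a config declares only a range: mean = the point
estimate, sd = (high − low)/4; beta (moment-matched) for probabilities and
utilities, gamma for costs and counts, uniform for unrestricted rates, a
point mass for zero-width ranges, and a logged fallback to uniform on
[low, high] when the moment match is infeasible.

## Synthetic scenarios: what they emulate and what they do not

The original analysis keeps its variable values and distribution families in
unpublished supplementary appendices.  The `paper-anchored` regime (and the
four bundled cohort configs) pins every value the main text prints and fills
the remainder with the reconstructions below, chosen once as
order-of-magnitude plausible values and **not** calibrated against the
published lifetime totals (that inverse problem is under-determined and is
an explicit non-goal).

| parameter | base [low, high] | status |
|---|---|---|
| cost_per_rtms_session (CPT 90868) | $206 [100, 300] | printed ($206; $100–300 probe range) |
| rtms_sessions_per_year | 25.3 [8, 43] | printed (25.3 ± 16.7, range 8–43) |
| drug_cost_monthly | $372.50 [100, 450] | printed ($372.50; $100 generic low) |
| other_direct_annual | $9,140 [8,500, 9,800] | printed components ($1,440 + $7,700); narrow range, common to both arms |
| discount_rate | 0.03 | printed |
| cost_rtms_initial_session (CPT 90867) | $250 [150, 350] | reconstruction |
| cost_rtms_mt_redetermination (CPT 90869) | $60 [30, 120] | reconstruction |
| rtms_mt_redeterminations_per_year | 1 [0, 4] | reconstruction |
| psychotherapy_session_rate × sessions/yr | $85 × 12 | reconstruction |
| ect_course_cost_annual | $10,000 [7,000, 15,000] | reconstruction |
| p_remission_rtms / p_response_rtms | 0.35 [0.20, 0.50] / 0.25 [0.15, 0.35] | reconstruction |
| p_remission_pharma / p_response_pharma | 0.25 [0.15, 0.40] / 0.20 [0.10, 0.30] | reconstruction |
| attenuation (rTMS / pharma) | 0.80 [0.60, 1.00] / 0.75 [0.55, 0.95] | reconstruction |
| relapse_annual (rTMS / pharma) | 0.25 [0.10, 0.40] / 0.30 [0.15, 0.45] | reconstruction |
| p_remission_ect | 0.50 [0.30, 0.70] | reconstruction |
| utilities (remission/response/relapse/in-treatment/ECT/non-response) | 0.85/0.72/0.55/0.58/0.55/0.50 (±0.10) | reconstruction |

Utilities are arm-independent (nothing suggests the same health state was
valued differently per arm).  The `random-valid` regime draws everything
uniformly within role bounds subject to the joint invariants (including
jointly feasible remission + response range highs), and `stress` emits
boundary cases; both exist for property testing, not realism.

Consequently, passing tests show that the machinery is correct — the engine
matches closed-form geometric sums, the economics reproduces the printed
ratio arithmetic exactly, thresholds match exhaustive grid search, the
qualitative sensitivity structure (per-session cost, monthly drug cost and
sessions/year as the top three tornado drivers; a substantial dominant-SE
PSA fraction) emerges under the anchored scenario — but the model-computed
absolute lifetime totals and threshold values characterize the
reconstruction, not the original unpublished inputs.  Real claims data would
additionally feature age-dependent mortality, cost inflation, adherence and
adverse-event effects, all outside this model's scope (as they were outside
the original's).

## Problem sizes and known limitations

The bundled analyses run cohorts of 9 states over 16–63 annual cycles; the
full PSA (1,000 draws × 2 arms) completes in about a second, and the
exhaustive 10,001-point grid oracle used in the test suite batches matrix
propagation across the grid axis.  Limitations: no psychotherapy-only or
combination arms; no adverse-event disutilities or adherence modeling; a
single constant mortality hazard rather than a life table; ECT priced as a
flat annual course; two-strategy comparisons only (no >2-way efficiency
frontier).
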