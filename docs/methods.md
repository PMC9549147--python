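# Methods

## Model structure

The model is a cohort state-transition (Markov) model over an ordered care
sequence.  Treatment states carry a per-cycle pain-relief probability, a
per-cycle adverse-event incidence vector (constant over the occupancy of
the state), a per-cycle drug cost and an optional one-time procedure cost
(TKA).  The cycle length is 6 months and the horizon is lifetime (start age
45, capped at age 110, with early stopping once the alive fraction is below
1e-9).

The compartment space is the product of treatment states with a chronic
cardiovascular sub-state.  The sub-state distinguishes, per chronic event
kind (stroke, MI, heart failure), the two half-year cycles after the event
cycle ("first year" in the cost schedules) from the maintenance phase; only
the first chronic event per patient is modelled, and competing chronic
onsets are allocated proportionally if their per-cycle probabilities sum
above 1 (they never do on the packaged inputs).  Transient events (GI
discomfort, symptomatic ulcer) last one cycle and are carried as
expected-value incidences rather than compartments.

Per-cycle ordering: background mortality first; survivors then experience
adverse events and the stay/advance split on the pain-relief outcome, which
are treated as independent.  Transitions are irreversible (no mass ever
returns to an earlier treatment).

**Terminal failure.**  Death is the state after the last treatment: a
patient whose pain persists on the final rung (TKA, per-cycle probability
1 − 0.5122) advances to death like any other progression.  This is the only
reading consistent with the source model's structure (the care sequence
ends in the death state) and with its lifetime QALY magnitudes (2.4–5.0
from age 45, impossible under background mortality alone).  A
`terminal_failure: remain` option keeps failures in the last state instead,
for models where the last rung is genuinely absorbing.

**Background mortality.**  The source analysis publishes no mortality
input.  The packaged table (`life_table_demo_synthetic.csv`) is synthetic: a
Gompertz-like schedule with q(45) ≈ 0.003/year doubling every 8 years,
capped at 1 from age 110.  Under the terminal-failure rule it is a
second-order input (most death flow comes from TKA failure).  A constant
per-cycle mode exists for testing and toy models.

## Accrual conventions

* Start-of-cycle accrual on start-of-cycle occupancy; both cost and QALY
  streams discount at the same 3%/year, evaluated at the cycle start
  (`accrual_timing: mid` shifts evaluation to the midpoint — a half-cycle
  style correction; there is no half-cycle correction by default).
* Responders accrue the no-pain utility (0.62), failures the moderate-pain
  utility (0.56) for the cycle in the state they are leaving.
* Transient AEs: acute cost and one-cycle disutility in the event cycle,
  computed from survivor occupancy × incidence.
* Chronic AEs: acute cost in the event cycle; half the first-year cost in
  each of the next two cycles; half the subsequent-year cost every cycle
  thereafter; the disutility applies every cycle from the event onward.
  The even split of the annual figures over two 6-month cycles is the
  least-assumption mapping of the three-row published schedules.
* Drug costs are per 6-month cycle at the stated maximum daily dose
  (diclofenac 128 + omeprazole 94 = 222; TA injection 2 × 114 = 228 per
  cycle); TKA is a one-time 78,925 THB at entry.  One outpatient visit per
  cycle (travel 143 + food 53 = 196 THB) accrues for every alive patient.
  Laboratory costs, doctor fees and productivity losses are declared but
  unpublished in the source costing; they default to 0
  (`indirect_cost_per_cycle` is the hook) without any claim of fidelity.
* If a chronic disutility pushes a compartment utility below 0 it is
  floored at 0 and counted (`utility_floored_compartments`).

Etoricoxib's position within sequences is not printed in the source; it is
placed after diclofenac+PPI (conventional NSAID → COX-2 selective
escalation) and before TA injection.

## Frontier analysis

Strict dominance (cost ≤ and QALY ≥, one strict) is removed first, then
iterated extended dominance until segment ICERs increase strictly along the
frontier.  Labels: the designated reference strategy keeps `reference` only
while undominated; a frontier strategy that strictly dominates the
reference is `dominant`; other frontier members are `on_frontier` and carry
the ICER versus the previous frontier point in QALY order.  Exact duplicate
(cost, QALY) pairs are both kept and flagged as ties.

## Sensitivity analysis

**Distributions.**  Method-of-moments fits reproduce the published mean and
SE exactly: gamma for costs (shape = (m/se)², scale = se²/m), beta for
probabilities, utilities and disutility magnitudes (ν = m(1−m)/se² − 1),
log-normal for the pain-relief transition probabilities (σ² =
ln(1 + se²/m²)), truncated to [0, 1] after sampling.  Sampling disutilities
on the magnitude preserves the sign.  Infeasible beta moments
(se² ≥ m(1−m)) raise an error naming the parameter.

**Missing SEs.**  Table-1 probabilities are published without SEs; they
default to se = 20% of the mean, overridable per parameter
(`uncertainty.overrides`).  Treatment drug costs (no published SE) stay
fixed in the PSA.  The visit cost samples gamma with se 13 (the published
travel/food SEs combined in quadrature).  Note the consequence for the
diclofenac+PPI pain-relief probability (mean 0.8647): about 19% of its
truncated log-normal draws clamp to exactly 1.0, a degenerate "nobody
progresses" draw in which earlier glucosamine cannot prolong life and the
incremental QALY versus standard care can turn slightly negative.  This is
why the CE-plane lower-right share for early glucosamine vs standard is
~92–93% here while the source reports 100%: the source's (unpublished)
probability SEs were evidently much smaller than the 20% default.

**PSA mechanics.**  One root seed; each parameter draws from its own
substream keyed by a hash of its dotted path, so adding a parameter leaves
the others' draws unchanged and runs are bit-reproducible.  All strategies
within an iteration are evaluated on the same parameter draw.  Independent
utility draws occasionally invert the pair; the moderate-pain draw is then
clipped down to the no-pain draw.

**DSA.**  One-way ranges re-run the full pipeline twice with the parameter
pinned.  Published ranges are used where printed (moderate-pain utility
0.35–0.77 — which exceeds the no-pain utility, so pinning deliberately
allows the inversion; TKA cost 78,533–79,316); the remaining configured
ranges default to ±20% of base, probabilities clipped to [0, 1].  The
output metric is the incremental net monetary benefit at 160,000 THB/QALY
of the combined strategy versus early glucosamine (ICER is available but
suffers sign pathologies when the increment crosses quadrants).  Two
consequences worth knowing: the glucosamine cycle-cost bar is exactly zero
for this comparison (both arms take glucosamine at the same position before
they diverge, so the cost cancels), and the diclofenac pain-relief bar is
the widest because its default range's upper clip at 1.0 makes the two
compared arms identical (iNMB 0).  Among the two *published* ranges the
moderate-pain utility bar is more than 100× the TKA-cost bar, matching the
source's most/least-sensitive statement.

**CE plane / CEAC.**  Quadrants partition all draws; axis points count
toward the more favourable quadrant (ΔE ≥ 0 and ΔC ≤ 0 is lower-right).
The pairwise CEAC is the fraction of draws with NMB(a) ≥ NMB(b); the
multi-way CEAC assigns each draw to the arg-max NMB strategy (ties to the
first listed), so probabilities sum to 1.  Default WTP grid: 0–320,000 THB
in 5,000 steps.

## Synthetic data

The generator emits random, validated models with the same shape as the
packaged inputs: 2–8 ordered treatments (terminal last), sparse AE
incidences, gamma-ready cost schedules, an ordered utility pair, and either
constant mortality or a Gompertz-like age table.  Generated SEs span 5–30%
of means; a dedicated negative generator produces a model violating the
beta feasibility bound for error-path tests.  Toy models with printed
parameters back the oracle tests: a 2-treatment/3-cycle model checked
against exhaustive path enumeration, and a no-AE two-state chain with
geometric-series closed-form totals.  Synthetic models exercise the code
paths and invariants (conservation, monotone death, discount monotonicity)
— passing them says nothing about any particular real population.

## Problem sizes

The default test run uses: 1,000 random models for the conservation fuzz,
1,000 PSA iterations on the packaged model (matching the source's count),
100,000 draws for the sampling-oracle checks, and 4-cycle horizons for the
path-enumeration oracle (branching growth makes longer exact enumeration
pointless).  The acceptance script runs the full six-strategy base case and
a 1,000-iteration PSA.

## Known limitations

* Absolute cost/QALY totals are not claimed to reproduce the published
  table: the mortality input, several accrual conventions, indirect-cost
  values and the WOMAC-to-probability conversion are unpublished.  The
  dominance pattern, the frontier membership and the
  threshold comparisons do reproduce.
* No adverse-event-attributable excess mortality; background mortality only.
* No treatment re-challenge, revision surgery, microsimulation, budget
  impact, or correlated PSA sampling (EVPI is out of scope).
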