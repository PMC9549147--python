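# oacea — cost-utility analysis of knee-osteoarthritis care sequences

`oacea` is a Markov cohort modelling package for economic evaluation of knee
osteoarthritis (OA) treatment sequencing, built around the published Thai
analysis of adding crystalline glucosamine sulfate and/or etoricoxib to the
standard reimbursed care pathway.  It is written for health-economics and
HTA analysts who want the model as auditable, re-runnable code: every input
is a plain YAML/CSV file, every output a number the library computed.

## The model

A cohort of patients aged 45 starts on the first rung of an ordered care
sequence — for standard care: acetaminophen → diclofenac + PPI →
triamcinolone acetonide (TA) injection → total knee arthroplasty (TKA) →
death.  Each 6-month cycle, a patient on rung *i* either has their pain
controlled (probability *p_i*, Table-1 "pain relief") and stays, or advances
to rung *i + 1*; advancing past the last rung reaches the absorbing death
state.  Transitions are irreversible and background mortality applies at
every age.  Adverse events ride along as sub-states: transient events (GI
discomfort, symptomatic ulcer) accrue a one-off cost and one-cycle
disutility; the first chronic cardiovascular event (stroke, MI, heart
failure) switches the patient into a permanent sub-state with an acute /
first-year / maintenance cost schedule and a lifelong disutility.

Per cycle, with start-of-cycle occupancy *x_t* and discount rate *r* = 3%
per year:

    Cost_t  = Σ_s x_t(s) · (c_s + visit) + one-time costs · entrants + AE costs
    QALY_t  = 0.5 · Σ_s x_t(s) · [ p_s·u_np + (1 − p_s)·u_mp + disutilities ]
    Total   = Σ_t (1 + r)^(−t/2) · (Cost_t, QALY_t)

with u_np = 0.62 (pain controlled) and u_mp = 0.56 (uncontrolled; the
utility a failing patient accrues in the state they are leaving).
Strategies are compared by dominance and the incremental cost-effectiveness
ratio ICER = ΔC/ΔE against the Thai willingness-to-pay threshold of 160,000
THB/QALY (36.16 THB/USD).  One-way sensitivity analysis pins single
parameters at range bounds (tornado); probabilistic sensitivity analysis
samples costs from gamma, probabilities/utilities from beta, and pain-relief
(transition) probabilities from truncated log-normal distributions — all
fitted by the method of moments — yielding the CE plane and CEAC.

## Worked example

```bash
python examples/published_table_frontier.py
```

```
standard                                                            161,282 THB  2.39 QALY  dominated
standard_plus_glucosamine_before_diclofenac_ppi                     150,878 THB  3.26 QALY  dominant
standard_plus_glucosamine_after_diclofenac_ppi                      192,561 THB  3.26 QALY  dominated
standard_plus_etoricoxib                                            418,268 THB  4.44 QALY  dominated
standard_plus_etoricoxib_plus_glucosamine_before_diclofenac_ppi     366,819 THB  4.98 QALY  on_frontier  ICER 125,547 THB/QALY (3,472 USD/QALY)
standard_plus_etoricoxib_plus_glucosamine_after_diclofenac_ppi      431,478 THB  4.98 QALY  dominated
```

Reading: adding glucosamine *before* diclofenac+PPI is **dominant** — it
costs less and yields more QALYs than standard care; delayed glucosamine,
etoricoxib alone, and the combined-after sequence are dominated.  The only
frontier step is the combined before-sequence at 125,547 THB per extra QALY
(3,472 USD), under the 160,000 THB/QALY threshold, hence cost-effective.

Running the full Markov model rather than the published table
(`python examples/base_case.py`) reproduces the same qualitative frontier
with this package's own accrual conventions and mortality input:
early glucosamine saves 1,589 THB and gains 0.39 QALYs versus standard
care, and the combined strategy's ICER against it is 56,931 THB/QALY.

Other examples: `examples/tornado.py` (one-way sensitivity),
`examples/psa_ce_plane_ceac.py` (probabilistic sensitivity),
`examples/synthetic_model.py` (random model generation).  The same
capabilities are exposed as a CLI:

```bash
oacea basecase --config src/oacea/fixtures/thailand_oa_2022.yaml --out out/
oacea psa --config src/oacea/fixtures/thailand_oa_2022.yaml --n 1000 --seed 1 --out out/
```

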