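"""Full Markov cohort base case on the packaged Thai knee-OA model.

Runs all six care sequences from age 45 over a lifetime horizon (6-month
cycles, 3% annual discount) and prints discounted totals with dominance
labels.  Costs are per cohort member in THB.
"""

from oacea import dominance_frontier, load_fixture_model, run_cea, thb_to_usd

model = load_fixture_model()
results = run_cea(model)
frontier = dominance_frontier(results, reference="standard")

for r in results:
    label = frontier.labels[r.strategy]
    print(
        f"{r.strategy:65s} cost {r.total_cost:>9,.0f} THB "
        f"({thb_to_usd(r.total_cost):>6,.0f} USD)  "
        f"{r.total_qaly:5.2f} QALY  {label}"
    )

print()
print("frontier:", " -> ".join(frontier.frontier))
for name, icer in frontier.icers.items():
    print(f"ICER of {name} vs previous frontier point: {icer:,.0f} THB/QALY")
print()
print(f"Willingness-to-pay threshold: {model.econ.wtp_per_qaly:,.0f} THB/QALY;")
print("a frontier ICER below it makes the costlier strategy cost-effective.")
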