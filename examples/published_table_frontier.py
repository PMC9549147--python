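"""Dominance and ICER arithmetic on the published base-case table.

Feeds the six published (cost THB, QALY) pairs into the frontier analysis
and prints each strategy's dominance label plus the ICER along the frontier,
in THB and USD at 36.16 THB/USD.
"""

from oacea import CEAResult, dominance_frontier, load_published_base_case, thb_to_usd

rows = load_published_base_case()
results = [CEAResult(s, c, q, c, q) for s, c, q in rows]
frontier = dominance_frontier(results, reference="standard")

for strategy, cost, qaly in rows:
    label = frontier.labels[strategy]
    icer = frontier.icers.get(strategy)
    extra = f"  ICER {icer:,.0f} THB/QALY ({thb_to_usd(icer):,.0f} USD/QALY)" if icer else ""
    print(f"{strategy:65s} {cost:>9,.0f} THB  {qaly:4.2f} QALY  {label}{extra}")

print()
print("A 'dominant' strategy costs less and yields more QALYs than the")
print("reference (standard care); the frontier ICER is the extra cost per")
print("extra QALY of stepping up to the next undominated strategy.")
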