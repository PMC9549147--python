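"""Probabilistic sensitivity analysis: CE plane and CEAC.

Samples every uncertain parameter from its fitted distribution (costs gamma,
probabilities/utilities beta, pain-relief probabilities truncated log-normal)
and re-runs all strategies per draw.  Prints the quadrant shares for early
glucosamine vs standard care and the probability that the combined strategy
is cost-effective versus early glucosamine at the Thai threshold.

Uses 200 iterations to stay quick; pass a larger n for production runs.
"""

import numpy as np

from oacea import ce_plane, ceac, load_fixture_model, run_psa

model = load_fixture_model()
psa = run_psa(model, n_iter=200, seed=7)

glu = "standard_plus_glucosamine_before_diclofenac_ppi"
combined = "standard_plus_etoricoxib_plus_glucosamine_before_diclofenac_ppi"

plane = ce_plane(psa, (glu, "standard"))
print("CE plane, early glucosamine vs standard (ΔC, ΔE per draw):")
for quadrant, share in plane["proportions"].items():
    print(f"  {quadrant:12s} {100 * share:5.1f}%")
print("  lower_right = cheaper AND more effective (dominant draws)")

wtp = model.econ.wtp_per_qaly
curve = ceac(psa, wtp_grid=np.arange(0, 320_001, 20_000.0),
             comparison=(combined, glu))
print(f"\nCEAC, combined strategy vs early glucosamine:")
for w, p in zip(curve.wtp, curve.probabilities["pairwise"]):
    marker = " <- Thai WTP" if w == wtp else ""
    print(f"  WTP {w:>9,.0f} THB/QALY: P(cost-effective) = {p:4.2f}{marker}")
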