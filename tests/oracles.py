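"""Independent oracles for the engine and economics tests.

Deliberately naive implementations: a brute-force enumeration of individual
patient trajectories, and analytic geometric-series sums for the two-state
chain.  They share no code with the package's recursion.
"""

from __future__ import annotations

import numpy as np

from oacea.parameters import CHRONIC_AES, ModelSpec

# chronic status labels in the engine's compartment order
STATUSES = ["none"] + [
    f"{k}:{p}" for k in CHRONIC_AES for p in ("y1a", "y1b", "chronic")
]


def enumerate_paths(model: ModelSpec, strategy_name: str, n_cycles: int) -> np.ndarray:
    """Occupancy matrix (n_cycles x compartments) by exhaustive branching.

    Each branch carries a single patient fraction through one cycle:
    background death first, then (survivors only) chronic-event onset for
    patients without a prior chronic event, then stay vs advance on the
    pain-relief outcome.  Advancing from the last treatment state reaches
    death.  Chronic phases age y1a -> y1b -> chronic.
    """
    strat = model.strategy(strategy_name)
    seq = strat.sequence
    n = len(seq)
    width = n * len(STATUSES) + 1
    occ = np.zeros((n_cycles, width))
    cycle_len = model.econ.cycle_length_years
    start_age = model.econ.start_age_years
    terminal_to_death = model.econ.terminal_failure == "progress_to_death"

    def comp(i, status):
        return i * len(STATUSES) + STATUSES.index(status)

    def aged(status):
        if status == "none":
            return "none"
        kind, phase = status.split(":")
        return f"{kind}:{'y1b' if phase == 'y1a' else 'chronic'}"

    def walk(cycle, i, status, mass):
        if mass == 0.0:
            return
        if i is None:  # dead
            if cycle < n_cycles:
                occ[cycle, -1] += mass
                walk(cycle + 1, None, None, mass)
            return
        if cycle >= n_cycles:
            return
        occ[cycle, comp(i, status)] += mass

        st = model.states[seq[i]]
        q = model.mortality.per_cycle_prob(start_age + cycle * cycle_len, cycle_len)
        walk(cycle + 1, None, None, mass * q)
        surv = mass * (1.0 - q)

        # (end-of-cycle status, probability) branches
        if status == "none":
            hazards = [(k, st.ae_prob(k)) for k in CHRONIC_AES]
            total = sum(h for _, h in hazards)
            scale = 1.0 / total if total > 1.0 else 1.0
            branches = [("none", max(0.0, 1.0 - scale * total))]
            branches += [(f"{k}:y1a", scale * h) for k, h in hazards if h > 0]
        else:
            branches = [(aged(status), 1.0)]

        p_advance = 1.0 - st.pain_relief_prob
        for new_status, p_status in branches:
            m = surv * p_status
            stay = m * (1.0 - p_advance)
            move = m * p_advance
            walk(cycle + 1, i, new_status, stay)
            if i + 1 < n:
                walk(cycle + 1, i + 1, new_status, move)
            elif terminal_to_death:
                walk(cycle + 1, None, None, move)
            else:
                walk(cycle + 1, i, new_status, move)

    walk(0, 0, "none", 1.0)
    return occ


def two_state_closed_form(
    relief_a: float,
    relief_b: float,
    q: float,
    cost_a: float,
    cost_b: float,
    u_np: float,
    u_mp: float,
    rate: float,
    n_cycles: int,
    cycle_len: float = 0.5,
):
    """Partial geometric-series totals for the two-treatment chain.

    Occupancies: A(t) = alpha^t with alpha = (1-q) * relief_a;
    B(t) = (1-q)(1-relief_a) (alpha^t - beta^t)/(alpha - beta) with
    beta = (1-q) * relief_b.  Costs/QALYs accrue on start-of-cycle occupancy
    discounted at t * cycle_len years, summed over the first n_cycles cycles.
    """
    alpha = (1.0 - q) * relief_a
    beta = (1.0 - q) * relief_b
    delta = (1.0 + rate) ** (-cycle_len)

    def geom(x):  # sum_{t<n} x^t
        if x == 1.0:
            return float(n_cycles)
        return (1.0 - x**n_cycles) / (1.0 - x)

    sum_a = geom(delta * alpha)
    if alpha == beta:
        # sum t * x^(t-1) form; not needed for the test parameterisations
        raise NotImplementedError("degenerate alpha == beta")
    k = (1.0 - q) * (1.0 - relief_a) / (alpha - beta)
    sum_b = k * (geom(delta * alpha) - geom(delta * beta))

    u_a = relief_a * u_np + (1.0 - relief_a) * u_mp
    u_b = relief_b * u_np + (1.0 - relief_b) * u_mp
    cost = cost_a * sum_a + cost_b * sum_b
    qaly = cycle_len * (u_a * sum_a + u_b * sum_b)
    return cost, qaly
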