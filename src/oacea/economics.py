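"""Discounted cost/QALY accrual and cost-effectiveness comparison.

Accrual conventions (see also the methods note):

* per cycle, every occupant of a treatment state accrues that state's cycle
  cost plus outpatient-visit and indirect costs; one-time costs accrue at
  state entry;
* responders (fraction ``pain_relief_prob``) accrue the no-pain utility,
  failures the moderate-pain utility for that cycle in the state they are
  leaving;
* transient adverse events accrue their acute cost and a one-cycle
  disutility in the cycle of occurrence; chronic events accrue the acute
  cost in the event cycle, half the first-year cost in each of the next two
  cycles, half the subsequent-year cost in every later cycle, and their
  disutility every cycle from the event onward;
* both streams are discounted at the same annual rate, evaluated at the
  start of each cycle by default (``econ.accrual_timing = "mid"`` shifts the
  evaluation to the cycle midpoint).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import CHRONIC_STATUSES, N_STATUS, CohortTrace, run_cohort
from .parameters import AE_KINDS, CHRONIC_AES, TRANSIENT_AES, ModelSpec

__all__ = [
    "CEAResult",
    "FrontierResult",
    "discount_factor",
    "accrue",
    "run_cea",
    "icer",
    "nmb",
    "thb_to_usd",
    "dominance_frontier",
]


def discount_factor(t: float, rate: float) -> float:
    """Present-value factor ``(1 + rate)**(-t)`` for time ``t`` in years."""
    if t < 0:
        raise ValueError(f"cannot discount at negative time t={t}")
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    return (1.0 + rate) ** (-t)


@dataclass
class CEAResult:
    """Discounted (and undiscounted) totals per cohort member."""

    strategy: str
    total_cost: float
    total_qaly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    life_years: float = float("nan")  # discounted
    utility_floored_compartments: int = 0


def accrue(trace: CohortTrace, model: ModelSpec) -> CEAResult:
    """Turn a cohort trace into discounted cost and QALY totals."""
    econ = model.econ
    u = model.utilities
    T, n = trace.n_cycles, trace.n_states
    occ3 = trace.occupancy[:, :-1].reshape(T, n, N_STATUS)
    state_occ = occ3.sum(axis=2)  # (T, n)
    alive = trace.alive()

    states = [model.states[name] for name in trace.state_names]
    cycle_cost = np.array([s.cycle_cost for s in states])
    one_time = np.array([s.one_time_cost for s in states])
    relief = np.array([s.pain_relief_prob for s in states])

    # -- costs ------------------------------------------------------------
    cost = state_occ @ cycle_cost
    cost += alive * (econ.visit_cost_per_cycle + econ.indirect_cost_per_cycle)
    cost += trace.entrants @ one_time
    acute = np.array([model.ae_costs[k].acute_cost if k in model.ae_costs else 0.0
                      for k in AE_KINDS])
    cost += trace.events @ acute
    for i, kind in enumerate(CHRONIC_AES):
        if kind not in model.ae_costs:
            continue
        sched = model.ae_costs[kind]
        c = 1 + 3 * i
        first_year_occ = occ3[:, :, c].sum(axis=1) + occ3[:, :, c + 1].sum(axis=1)
        maint_occ = occ3[:, :, c + 2].sum(axis=1)
        cost += first_year_occ * (sched.first_year_cost / 2.0)
        cost += maint_occ * (sched.subsequent_year_cost / 2.0)

    # -- utilities ---------------------------------------------------------
    state_util = relief * u.no_pain + (1.0 - relief) * u.moderate_pain  # (n,)
    util_matrix = np.tile(state_util[:, None], (1, N_STATUS))
    for i, kind in enumerate(CHRONIC_AES):
        du = model.ae_costs[kind].disutility if kind in model.ae_costs else 0.0
        util_matrix[:, 1 + 3 * i : 4 + 3 * i] += du
    floored = int((util_matrix < 0).sum())
    util_matrix = np.maximum(util_matrix, 0.0)
    util = (occ3 * util_matrix[None, :, :]).sum(axis=(1, 2))
    event_du = np.array(
        [abs(model.ae_costs[k].disutility) if k in model.ae_costs else 0.0
         for k in AE_KINDS]
    )
    util -= trace.events @ event_du  # event-cycle disutilities
    qaly = econ.cycle_length_years * util

    # -- discounting -------------------------------------------------------
    t_acc = np.arange(T) * econ.cycle_length_years
    if econ.accrual_timing == "mid":
        t_acc = t_acc + econ.cycle_length_years / 2.0
    disc = (1.0 + econ.annual_discount_rate) ** (-t_acc)

    return CEAResult(
        strategy=trace.strategy,
        total_cost=float(disc @ cost),
        total_qaly=float(disc @ qaly),
        undiscounted_cost=float(cost.sum()),
        undiscounted_qaly=float(qaly.sum()),
        life_years=float(econ.cycle_length_years * (disc @ alive)),
        utility_floored_compartments=floored,
    )


def run_cea(model: ModelSpec, strategies: list[str] | None = None) -> list[CEAResult]:
    """Run every (or the named) strategies end to end: cohort + accrual."""
    names = strategies or [s.name for s in model.strategies]
    return [accrue(run_cohort(name, model), model) for name in names]


def icer(a: CEAResult, b: CEAResult) -> float:
    """Incremental cost-effectiveness ratio of ``a`` versus ``b`` (THB/QALY)."""
    dq = a.total_qaly - b.total_qaly
    if dq == 0:
        raise ValueError(
            "ICER undefined for equal QALYs; compare costs directly "
            f"({a.strategy} vs {b.strategy})"
        )
    return (a.total_cost - b.total_cost) / dq


def nmb(result: CEAResult, wtp: float) -> float:
    """Net monetary benefit at willingness-to-pay ``wtp`` (THB/QALY)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * result.total_qaly - result.total_cost


def thb_to_usd(amount_thb: float, fx: float = 36.16) -> float:
    """Convert THB to USD at ``fx`` THB per USD (unrounded)."""
    if fx <= 0:
        raise ValueError("fx must be > 0")
    return amount_thb / fx


@dataclass
class FrontierResult:
    """Dominance labels and frontier ICERs for a set of strategies.

    ``labels`` maps strategy -> one of ``reference``, ``dominant``,
    ``dominated``, ``extended_dominated``, ``on_frontier``.  The designated
    reference keeps the label ``reference`` only while it sits on the
    frontier; a frontier strategy that strictly dominates the reference is
    labelled ``dominant``.  ``icers`` holds, for each non-initial frontier
    strategy, its ICER against the previous frontier point in QALY order.
    """

    labels: dict[str, str]
    icers: dict[str, float]
    frontier: list[str]  # in increasing-QALY order
    ties: list[tuple[str, str]] = field(default_factory=list)


def _strictly_dominates(x: CEAResult, y: CEAResult) -> bool:
    return (
        x.total_cost <= y.total_cost
        and x.total_qaly >= y.total_qaly
        and (x.total_cost < y.total_cost or x.total_qaly > y.total_qaly)
    )


def dominance_frontier(
    results: list[CEAResult], reference: str | None = None
) -> FrontierResult:
    """Classify strategies by dominance and compute frontier ICERs.

    Strict dominance is removed first (ties on QALY broken by cost), then
    extended dominance: candidates whose incremental ICER exceeds that of the
    next segment are removed until ICERs increase strictly along the
    frontier.
    """
    if len(results) < 2:
        raise ValueError("dominance analysis needs at least 2 strategies")
    if reference is None:
        reference = results[0].strategy
    by_name = {r.strategy: r for r in results}
    if reference not in by_name:
        raise ValueError(f"unknown reference strategy '{reference}'")

    ties = [
        (a.strategy, b.strategy)
        for i, a in enumerate(results)
        for b in results[i + 1 :]
        if a.total_cost == b.total_cost and a.total_qaly == b.total_qaly
    ]

    labels: dict[str, str] = {}
    for r in results:
        if any(
            _strictly_dominates(other, r)
            for other in results
            if other.strategy != r.strategy
        ):
            labels[r.strategy] = "dominated"

    candidates = sorted(
        (r for r in results if r.strategy not in labels),
        key=lambda r: (r.total_qaly, r.total_cost),
    )

    def _safe_icer(x: CEAResult, y: CEAResult) -> float | None:
        # equal-QALY pairs among candidates are exact duplicates (flagged
        # as ties above); their segment carries no ICER
        return None if x.total_qaly == y.total_qaly else icer(x, y)

    # iterated extended dominance on the strictly-undominated set
    while True:
        if len(candidates) < 3:
            break
        removed = False
        for j in range(1, len(candidates) - 1):
            lo, mid, hi = candidates[j - 1], candidates[j], candidates[j + 1]
            seg1, seg2 = _safe_icer(mid, lo), _safe_icer(hi, mid)
            if seg1 is not None and seg2 is not None and seg1 >= seg2:
                labels[mid.strategy] = "extended_dominated"
                del candidates[j]
                removed = True
                break
        if not removed:
            break

    frontier = [r.strategy for r in candidates]
    icers: dict[str, float] = {}
    for prev, cur in zip(candidates, candidates[1:]):
        val = _safe_icer(cur, prev)
        if val is not None:
            icers[cur.strategy] = val

    ref_result = by_name[reference]
    for r in candidates:
        name = r.strategy
        if name == reference:
            labels[name] = "reference"
        elif _strictly_dominates(r, ref_result):
            labels[name] = "dominant"
        else:
            labels[name] = "on_frontier"
    return FrontierResult(labels=labels, icers=icers, frontier=frontier, ties=ties)
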