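"""Cohort state-transition engine.

A strategy's compartment space is the product of its treatment states and a
chronic cardiovascular sub-state, plus one absorbing death compartment.  The
chronic sub-state distinguishes, for each chronic event kind (stroke, MI,
heart failure), the two half-year cycles following the event cycle (``y1a``,
``y1b`` — the "first year" of the published cost schedules) from the
maintenance phase (``chronic``); only the first chronic event per patient is
modelled.

Per cycle, background mortality is applied first; survivors then (i)
experience adverse events — chronic onsets move the sub-state, transient
events are recorded as expected incidences — and (ii) either stay (pain
relieved, per-cycle probability ``pain_relief_prob``) or advance to the next
treatment state.  Advancing from the last treatment state reaches death when
``econ.terminal_failure == "progress_to_death"`` (the default: the care
sequence ends in the death state); with ``"remain"`` failures stay in the
last state.  Transitions are irreversible: no mass ever moves to an earlier
treatment state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    AE_KINDS,
    CHRONIC_AES,
    TRANSIENT_AES,
    ModelSpec,
    StrategyDef,
    TreatmentState,
)

__all__ = [
    "CHRONIC_STATUSES",
    "N_STATUS",
    "CohortTrace",
    "progression_prob",
    "compartment_labels",
    "build_cycle_transition",
    "run_cohort",
]

#: Chronic sub-state labels, index 0 = no chronic event.
CHRONIC_STATUSES = ("none",) + tuple(
    f"{kind}:{phase}" for kind in CHRONIC_AES for phase in ("y1a", "y1b", "chronic")
)
N_STATUS = len(CHRONIC_STATUSES)  # 10

#: status-array column slices per chronic kind
_KIND_COLS = {kind: 1 + 3 * i for i, kind in enumerate(CHRONIC_AES)}

_ALIVE_TOL = 1e-9


def progression_prob(state: TreatmentState) -> float:
    """Per-cycle probability of advancing to the next treatment state.

    Treatment failure is the persistence of pain, so this is simply the
    complement of the per-cycle pain-relief probability.
    """
    return 1.0 - state.pain_relief_prob


@dataclass
class CohortTrace:
    """Per-cycle cohort occupancy and event incidence for one strategy.

    ``occupancy`` rows are start-of-cycle cohort fractions over the
    compartments (last column = death) and sum to 1.  ``events`` holds the
    expected per-cycle incidence of each adverse-event kind (columns in
    ``AE_KINDS`` order) among that cycle's survivors of background mortality;
    ``entrants`` the fraction newly entering each treatment state at the
    start of the cycle.
    """

    strategy: str
    state_names: list[str]
    occupancy: np.ndarray  # (T, n_states * N_STATUS + 1)
    events: np.ndarray  # (T, len(AE_KINDS))
    entrants: np.ndarray  # (T, n_states)
    ages: np.ndarray  # (T,)
    truncated: bool = False

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def alive(self) -> np.ndarray:
        """Alive fraction at the start of each cycle."""
        return 1.0 - self.occupancy[:, -1]

    def state_occupancy(self) -> np.ndarray:
        """(T, n_states) occupancy summed over chronic sub-states."""
        T = self.n_cycles
        return self.occupancy[:, :-1].reshape(T, self.n_states, N_STATUS).sum(axis=2)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per cycle, compartment and event columns."""
        cols = compartment_labels(self.state_names)
        df = pd.DataFrame(self.occupancy, columns=cols)
        df.insert(0, "cycle", np.arange(self.n_cycles))
        df.insert(1, "age", self.ages)
        for j, kind in enumerate(AE_KINDS):
            df[f"incidence_{kind}"] = self.events[:, j]
        for j, name in enumerate(self.state_names):
            df[f"entrants_{name}"] = self.entrants[:, j]
        return df


def compartment_labels(state_names: list[str]) -> list[str]:
    labels = [f"{s}|{c}" for s in state_names for c in CHRONIC_STATUSES]
    labels.append("death")
    return labels


def _strategy_arrays(strategy: StrategyDef, model: ModelSpec):
    states = [model.states[name] for name in strategy.sequence]
    relief = np.array([s.pain_relief_prob for s in states])
    advance = 1.0 - relief
    # chronic onset hazards, proportionally rescaled if they exceed 1
    chron = np.array([[s.ae_prob(k) for k in CHRONIC_AES] for s in states])
    total = chron.sum(axis=1)
    over = total > 1.0
    if over.any():
        chron[over] /= total[over, None]
    trans = np.array([[s.ae_prob(k) for k in TRANSIENT_AES] for s in states])
    return states, relief, advance, chron, trans


def _step(alive, death, q, relief, advance, chron, terminal_to_death):
    """One cycle of the cohort recursion.

    ``alive`` is the (n_states, N_STATUS) occupancy matrix; returns the next
    (alive, death) pair plus the chronic-onset incidences and the per-state
    entrant fractions of the coming cycle.
    """
    surv = alive * (1.0 - q)
    death = death + q * alive.sum()

    # chronic sub-state evolution among survivors
    end = np.zeros_like(surv)
    onset_total = surv[:, 0, None] * chron  # (n, 3) new events per kind
    end[:, 0] = surv[:, 0] * (1.0 - chron.sum(axis=1))
    for kind_i in range(len(CHRONIC_AES)):
        c = 1 + 3 * kind_i
        end[:, c] = onset_total[:, kind_i]  # event cycle -> y1a next cycle
        end[:, c + 1] = surv[:, c]  # y1a -> y1b
        end[:, c + 2] = surv[:, c + 1] + surv[:, c + 2]  # y1b/chronic -> chronic

    # progression (irreversible, one state forward; last state -> death)
    stay = end * relief[:, None]
    move = end * advance[:, None]
    nxt = stay.copy()
    nxt[1:] += move[:-1]
    if terminal_to_death:
        death = death + move[-1].sum()
    else:
        nxt[-1] += move[-1]
    entrants = move[:-1].sum(axis=1)  # mass entering states 1..n-1
    return nxt, death, onset_total.sum(axis=0), entrants


def run_cohort(
    strategy: StrategyDef | str,
    model: ModelSpec,
    max_cycles: int | None = None,
) -> CohortTrace:
    """Run the cohort recursion for one strategy over the lifetime horizon.

    The whole cohort starts in the first treatment state at
    ``econ.start_age_years``; the recursion stops once the alive fraction
    drops below 1e-9 or the horizon (``econ.max_age_years``) is reached, in
    which case the trace is flagged as truncated.
    """
    if isinstance(strategy, str):
        strategy = model.strategy(strategy)
    econ = model.econ
    states, relief, advance, chron, trans = _strategy_arrays(strategy, model)
    n = len(states)
    terminal_to_death = econ.terminal_failure == "progress_to_death"

    horizon = int(
        np.ceil((econ.max_age_years - econ.start_age_years) / econ.cycle_length_years)
    )
    if max_cycles is not None:
        horizon = min(horizon, max_cycles)

    occ_rows, event_rows, entrant_rows, ages = [], [], [], []
    alive = np.zeros((n, N_STATUS))
    alive[0, 0] = 1.0
    death = 0.0
    entrants_now = np.zeros(n)
    entrants_now[0] = 1.0
    truncated = False
    for t in range(horizon):
        age = econ.start_age_years + t * econ.cycle_length_years
        occ_rows.append(np.append(alive.ravel(), death))
        ages.append(age)
        entrant_rows.append(entrants_now)

        q = model.mortality.per_cycle_prob(age, econ.cycle_length_years)
        surv_state = alive.sum(axis=1) * (1.0 - q)
        transient_inc = surv_state @ trans  # (2,) per transient kind
        alive, death, chronic_inc, adv_entrants = _step(
            alive, death, q, relief, advance, chron, terminal_to_death
        )
        event_rows.append(np.concatenate([transient_inc, chronic_inc]))
        entrants_now = np.zeros(n)
        entrants_now[1:] = adv_entrants

        if alive.sum() < _ALIVE_TOL:
            break
    else:
        truncated = alive.sum() >= _ALIVE_TOL

    return CohortTrace(
        strategy=strategy.name,
        state_names=list(strategy.sequence),
        occupancy=np.asarray(occ_rows),
        events=np.asarray(event_rows),
        entrants=np.asarray(entrant_rows),
        ages=np.asarray(ages),
        truncated=truncated,
    )


def build_cycle_transition(
    strategy: StrategyDef | str, model: ModelSpec, age: float
) -> np.ndarray:
    """Row-stochastic one-cycle transition matrix over the compartments.

    Rows/columns follow :func:`compartment_labels`; the death row is
    absorbing.  Built by pushing unit masses through the same step used by
    :func:`run_cohort`, so the two cannot disagree.
    """
    if isinstance(strategy, str):
        strategy = model.strategy(strategy)
    _, relief, advance, chron, _ = _strategy_arrays(strategy, model)
    n = len(strategy.sequence)
    terminal_to_death = model.econ.terminal_failure == "progress_to_death"
    q = model.mortality.per_cycle_prob(age, model.econ.cycle_length_years)

    dim = n * N_STATUS + 1
    mat = np.zeros((dim, dim))
    for idx in range(dim - 1):
        unit = np.zeros((n, N_STATUS))
        unit[idx // N_STATUS, idx % N_STATUS] = 1.0
        nxt, death, _, _ = _step(
            unit, 0.0, q, relief, advance, chron, terminal_to_death
        )
        mat[idx, :-1] = nxt.ravel()
        mat[idx, -1] = death
    mat[-1, -1] = 1.0
    return mat
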