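"""Synthetic model generation.

Produces random but structurally valid care-sequence models with the same
statistical shape as the published Thai knee-OA inputs: ordered treatment
states with per-cycle pain-relief probabilities, adverse-event incidences
and cost schedules, a utility pair, and a background-mortality schedule
(constant or a Gompertz-like increasing age table).  Used by the property
tests as a model fuzzer, and hosts the small hand-enumerable toy models the
oracle tests are built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    AE_KINDS,
    CHRONIC_AES,
    TRANSIENT_AES,
    AECostSchedule,
    DsaRange,
    EconSettings,
    ModelSpec,
    MortalitySchedule,
    StrategyDef,
    TreatmentState,
    UncertaintySettings,
    UtilitySet,
)

__all__ = [
    "SyntheticModelConfig",
    "generate_model",
    "gompertz_life_table",
    "toy_model_3cycle",
    "toy_model_2state",
]


@dataclass
class SyntheticModelConfig:
    """Ranges for the random model generator (all probabilities per cycle)."""

    n_treatment_states: int = 4
    seed: int = 0
    pain_relief_range: tuple[float, float] = (0.05, 0.95)
    ae_incidence_range: tuple[float, float] = (0.0, 0.25)
    cycle_cost_range: tuple[float, float] = (100.0, 6000.0)
    one_time_cost_range: tuple[float, float] = (20000.0, 100000.0)
    utility_range: tuple[float, float] = (0.4, 0.95)
    mortality_mode: str = "age_table"  # or "constant"
    constant_death_prob: float = 0.01
    discount_rate: float = 0.03
    #: SE fractions for generated uncertainty; the upper end deliberately
    #: brushes against the beta feasibility bound in the negative generator.
    se_fraction_range: tuple[float, float] = (0.05, 0.30)
    allow_ae: bool = True

    def validate(self) -> None:
        if not 2 <= self.n_treatment_states <= 8:
            raise ValueError("n_treatment_states must be in [2, 8]")


def gompertz_life_table(
    start_age: float = 45.0,
    q0: float = 0.003,
    doubling_years: float = 8.0,
    band_years: float = 5.0,
    cap_age: float = 110.0,
) -> list[tuple[float, float, float]]:
    """Gompertz-like annual death probabilities in age bands, capped at 1."""
    rows = []
    b = np.log(2.0) / doubling_years
    age = start_age
    while age < cap_age:
        q = min(1.0, q0 * np.exp(b * (age - start_age)))
        rows.append((age, age + band_years, round(float(q), 6)))
        age += band_years
    rows.append((cap_age, float("inf"), 1.0))
    return rows


def generate_model(config: SyntheticModelConfig) -> ModelSpec:
    """Generate a random validated model, deterministic in the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_treatment_states

    states: dict[str, TreatmentState] = {}
    names = [f"treatment_{chr(ord('a') + i)}" for i in range(n)]
    for i, name in enumerate(names):
        ae = {}
        if config.allow_ae:
            lo, hi = config.ae_incidence_range
            for kind in AE_KINDS:
                # sparse incidences: roughly half the (state, kind) pairs
                ae[kind] = float(rng.uniform(lo, hi)) if rng.random() < 0.5 else 0.0
        terminal = i == n - 1
        states[name] = TreatmentState(
            name=name,
            pain_relief_prob=float(rng.uniform(*config.pain_relief_range)),
            cycle_cost=0.0 if terminal else float(rng.uniform(*config.cycle_cost_range)),
            one_time_cost=float(rng.uniform(*config.one_time_cost_range))
            if terminal
            else 0.0,
            ae_incidence=ae,
            is_terminal_treatment=terminal,
        )

    strategies = [StrategyDef(name="full_sequence", sequence=list(names))]
    if n >= 3:
        skipped = names[:1] + names[2:]
        strategies.append(StrategyDef(name="skip_second", sequence=skipped))

    ae_costs = {}
    for kind in AE_KINDS:
        chronic = kind in CHRONIC_AES
        acute = float(rng.uniform(500, 150000))
        se_frac = rng.uniform(*config.se_fraction_range)
        first = float(rng.uniform(1000, 10000)) if chronic else 0.0
        subseq = float(rng.uniform(1000, 15000)) if chronic else 0.0
        ae_costs[kind] = AECostSchedule(
            name=kind,
            acute_cost=acute,
            first_year_cost=first,
            subsequent_year_cost=subseq,
            disutility=float(-rng.uniform(0.005, 0.08)),
            acute_cost_se=acute * se_frac,
            first_year_cost_se=first * se_frac,
            subsequent_year_cost_se=subseq * se_frac,
            disutility_se=0.0002,
        )

    u_lo, u_hi = config.utility_range
    u_pair = np.sort(rng.uniform(u_lo, u_hi, size=2))
    utilities = UtilitySet(
        no_pain=float(u_pair[1]),
        moderate_pain=float(u_pair[0]),
        no_pain_se=0.01,
        moderate_pain_se=0.02,
    )

    if config.mortality_mode == "constant":
        mortality = MortalitySchedule(
            mode="constant", per_cycle_death_prob=config.constant_death_prob
        )
    else:
        mortality = MortalitySchedule(
            mode="age_table",
            age_table=gompertz_life_table(q0=float(rng.uniform(0.001, 0.01))),
        )

    econ = EconSettings(
        annual_discount_rate=config.discount_rate,
        visit_cost_per_cycle=float(rng.uniform(0, 500)),
    )

    first_state = names[0]
    spec = ModelSpec(
        states=states,
        strategies=strategies,
        ae_costs=ae_costs,
        utilities=utilities,
        econ=econ,
        mortality=mortality,
        uncertainty=UncertaintySettings(
            default_se_fraction=float(rng.uniform(*config.se_fraction_range))
        ),
        dsa_ranges=[
            DsaRange(
                param=f"states.{first_state}.pain_relief_prob",
                low=max(0.0, states[first_state].pain_relief_prob * 0.8),
                high=min(1.0, states[first_state].pain_relief_prob * 1.2),
            ),
            DsaRange(
                param="utilities.moderate_pain",
                low=utilities.moderate_pain * 0.8,
                high=min(utilities.no_pain, utilities.moderate_pain * 1.2),
            ),
        ],
    )
    return spec.validate()


def infeasible_beta_model(seed: int = 0) -> ModelSpec:
    """Negative-test generator: a model whose PSA moments violate the beta
    feasibility bound (se^2 >= mean(1-mean)) for one utility parameter."""
    spec = generate_model(SyntheticModelConfig(n_treatment_states=2, seed=seed))
    m = spec.utilities.moderate_pain
    spec.utilities.moderate_pain_se = float(np.sqrt(m * (1 - m)) * 1.01)
    return spec


def toy_model_3cycle() -> ModelSpec:
    """Fixed 2-treatment toy model for the path-enumeration oracle.

    Parameter values (printed so the enumeration can be checked by hand):

    * treatment_a: pain_relief 0.6, cycle_cost 100, GI discomfort 0.1,
      stroke 0.2
    * treatment_b (terminal): pain_relief 0.7, one_time_cost 1000, MI 0.05
    * utilities 0.9 / 0.7; constant per-cycle death probability 0.1;
      discount 3%/year; visit cost 10 per cycle; failure in treatment_b
      progresses to death.
    * stroke: acute 1000, first-year 200, subsequent-year 100,
      disutility -0.05; MI: acute 500, disutility -0.04;
      GI discomfort: acute 50, disutility -0.02.
    """
    states = {
        "treatment_a": TreatmentState(
            name="treatment_a",
            pain_relief_prob=0.6,
            cycle_cost=100.0,
            ae_incidence={"gi_discomfort": 0.1, "stroke": 0.2},
        ),
        "treatment_b": TreatmentState(
            name="treatment_b",
            pain_relief_prob=0.7,
            one_time_cost=1000.0,
            ae_incidence={"mi": 0.05},
            is_terminal_treatment=True,
        ),
    }
    ae_costs = {
        "gi_discomfort": AECostSchedule("gi_discomfort", 50.0, disutility=-0.02),
        "stroke": AECostSchedule(
            "stroke", 1000.0, first_year_cost=200.0, subsequent_year_cost=100.0,
            disutility=-0.05,
        ),
        "mi": AECostSchedule("mi", 500.0, disutility=-0.04),
    }
    return ModelSpec(
        states=states,
        strategies=[
            StrategyDef(name="toy", sequence=["treatment_a", "treatment_b"])
        ],
        ae_costs=ae_costs,
        utilities=UtilitySet(no_pain=0.9, moderate_pain=0.7),
        econ=EconSettings(visit_cost_per_cycle=10.0, max_age_years=55.0),
        mortality=MortalitySchedule(mode="constant", per_cycle_death_prob=0.1),
    ).validate()


def toy_model_2state(
    relief_a: float = 0.5,
    relief_b: float = 0.8,
    death_prob: float = 0.1,
    cost_a: float = 100.0,
    cost_b: float = 50.0,
    discount_rate: float = 0.03,
) -> ModelSpec:
    """Two treatments, no adverse events: cost/QALY totals have a
    geometric-series closed form (used as an analytic oracle)."""
    states = {
        "state_a": TreatmentState("state_a", relief_a, cycle_cost=cost_a),
        "state_b": TreatmentState(
            "state_b", relief_b, cycle_cost=cost_b, is_terminal_treatment=True
        ),
    }
    return ModelSpec(
        states=states,
        strategies=[StrategyDef(name="two_state", sequence=["state_a", "state_b"])],
        ae_costs={},
        utilities=UtilitySet(no_pain=0.8, moderate_pain=0.6),
        econ=EconSettings(
            annual_discount_rate=discount_rate,
            visit_cost_per_cycle=0.0,
            max_age_years=2000.0,  # effectively unbounded horizon
        ),
        mortality=MortalitySchedule(mode="constant", per_cycle_death_prob=death_prob),
    ).validate()
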