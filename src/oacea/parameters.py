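"""Model schema, validation and configuration I/O.

The model is parameterised by a set of treatment states (one rung of a care
sequence each), adverse-event cost/disutility schedules, a utility pair for
controlled vs uncontrolled pain, economic settings and a background-mortality
schedule.  Configurations are plain YAML documents; the packaged fixture
``fixtures/thailand_oa_2022.yaml`` carries the published Thai knee-OA inputs.

All money is in Thai baht (THB); all probabilities are per 6-month model cycle
unless stated otherwise.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "TRANSIENT_AES",
    "CHRONIC_AES",
    "AE_KINDS",
    "SchemaError",
    "ValidationError",
    "UnknownStateError",
    "AECostSchedule",
    "TreatmentState",
    "StrategyDef",
    "UtilitySet",
    "EconSettings",
    "MortalitySchedule",
    "ParamUncertainty",
    "UncertaintySettings",
    "DsaRange",
    "ModelSpec",
    "load_model",
    "write_model",
    "validate_strategy",
    "fixture_path",
    "load_fixture_model",
    "load_published_base_case",
]

#: Adverse events resolving within the cycle of occurrence.
TRANSIENT_AES = ("gi_discomfort", "symptomatic_ulcer")
#: Cardiovascular events leaving a permanent sub-state (first event only).
CHRONIC_AES = ("stroke", "mi", "heart_failure")
AE_KINDS = TRANSIENT_AES + CHRONIC_AES


class SchemaError(ValueError):
    """A required field is missing or has the wrong shape."""


class ValidationError(ValueError):
    """A field value violates a model invariant."""


class UnknownStateError(KeyError):
    """A strategy references a treatment state that is not defined."""


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise SchemaError(f"missing field '{key}' in {context}")
    return mapping[key]


def _check_prob(value: float, what: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{what} must be in [0, 1], got {value}")
    return value


def _check_nonneg(value: float, what: str) -> float:
    value = float(value)
    if value < 0:
        raise ValidationError(f"{what} must be >= 0, got {value}")
    return value


@dataclass
class AECostSchedule:
    """Cost and utility consequences of one adverse-event kind.

    ``acute_cost`` accrues in the cycle of the event.  For chronic events,
    ``first_year_cost`` covers the following year (two cycles) and
    ``subsequent_year_cost`` every year thereafter; transient events have
    no follow-on costs.  ``disutility`` is a (non-positive) decrement to the
    health-state utility — one cycle for transient events, every cycle from
    the event onward for chronic ones.
    """

    name: str
    acute_cost: float
    first_year_cost: float = 0.0
    subsequent_year_cost: float = 0.0
    disutility: float = 0.0
    acute_cost_se: float = 0.0
    first_year_cost_se: float = 0.0
    subsequent_year_cost_se: float = 0.0
    disutility_se: float = 0.0

    def validate(self) -> None:
        if self.name not in AE_KINDS:
            raise ValidationError(f"unknown adverse-event kind '{self.name}'")
        for what in ("acute_cost", "first_year_cost", "subsequent_year_cost"):
            _check_nonneg(getattr(self, what), f"{self.name}.{what}")
        if not -1.0 <= self.disutility <= 0.0:
            raise ValidationError(
                f"{self.name}.disutility must be in [-1, 0], got {self.disutility}"
            )
        if self.name in TRANSIENT_AES and (
            self.first_year_cost != 0 or self.subsequent_year_cost != 0
        ):
            raise ValidationError(
                f"transient event '{self.name}' cannot carry follow-on costs"
            )

    @property
    def is_chronic(self) -> bool:
        return self.name in CHRONIC_AES


@dataclass
class TreatmentState:
    """One rung of a care sequence.

    ``pain_relief_prob`` is the per-cycle probability that pain is controlled
    and the patient stays; its complement is the per-cycle probability of
    advancing to the next rung (or, from the last rung, to death).
    ``ae_incidence`` maps adverse-event kinds to per-cycle probabilities,
    constant over the occupancy of the state.
    """

    name: str
    pain_relief_prob: float
    cycle_cost: float = 0.0
    one_time_cost: float = 0.0
    ae_incidence: dict[str, float] = field(default_factory=dict)
    is_terminal_treatment: bool = False

    def validate(self) -> None:
        _check_prob(self.pain_relief_prob, f"{self.name}.pain_relief_prob")
        _check_nonneg(self.cycle_cost, f"{self.name}.cycle_cost")
        _check_nonneg(self.one_time_cost, f"{self.name}.one_time_cost")
        for kind, p in self.ae_incidence.items():
            if kind not in AE_KINDS:
                raise ValidationError(
                    f"{self.name}: unknown adverse-event kind '{kind}'"
                )
            _check_prob(p, f"{self.name}.ae_incidence[{kind}]")

    def ae_prob(self, kind: str) -> float:
        return float(self.ae_incidence.get(kind, 0.0))


@dataclass
class StrategyDef:
    """An ordered care sequence; the last entry is the terminal treatment."""

    name: str
    sequence: list[str]


@dataclass
class UtilitySet:
    """EQ-5D utilities for controlled ('no pain') vs uncontrolled pain."""

    no_pain: float
    moderate_pain: float
    no_pain_se: float = 0.0
    moderate_pain_se: float = 0.0

    def validate(self, allow_inversion: bool = False) -> None:
        _check_prob(self.no_pain, "utilities.no_pain")
        _check_prob(self.moderate_pain, "utilities.moderate_pain")
        if not allow_inversion and self.moderate_pain > self.no_pain:
            raise ValidationError(
                "utilities must satisfy moderate_pain <= no_pain, got "
                f"{self.moderate_pain} > {self.no_pain}"
            )


@dataclass
class EconSettings:
    """Economic evaluation settings (societal perspective, THB)."""

    annual_discount_rate: float = 0.03
    cycle_length_years: float = 0.5
    wtp_per_qaly: float = 160_000.0
    fx_thb_per_usd: float = 36.16
    start_age_years: float = 45.0
    max_age_years: float = 110.0
    visit_cost_per_cycle: float = 196.0
    indirect_cost_per_cycle: float = 0.0
    #: "start" discounts each cycle's accrual at its start time, "mid" at the
    #: cycle midpoint (a half-cycle-style correction).
    accrual_timing: str = "start"
    #: "progress_to_death": failure in the last treatment advances to death
    #: (death is the state after the last rung); "remain": failures stay put.
    terminal_failure: str = "progress_to_death"

    def validate(self) -> None:
        if self.annual_discount_rate < 0:
            raise ValidationError("annual_discount_rate must be >= 0")
        if self.cycle_length_years <= 0:
            raise ValidationError("cycle_length_years must be > 0")
        if self.fx_thb_per_usd <= 0:
            raise ValidationError("fx_thb_per_usd must be > 0")
        if self.max_age_years <= self.start_age_years:
            raise ValidationError("max_age_years must exceed start_age_years")
        if self.accrual_timing not in ("start", "mid"):
            raise ValidationError("accrual_timing must be 'start' or 'mid'")
        if self.terminal_failure not in ("progress_to_death", "remain"):
            raise ValidationError(
                "terminal_failure must be 'progress_to_death' or 'remain'"
            )
        _check_nonneg(self.visit_cost_per_cycle, "visit_cost_per_cycle")
        _check_nonneg(self.indirect_cost_per_cycle, "indirect_cost_per_cycle")


@dataclass
class MortalitySchedule:
    """Background (all-cause) mortality.

    ``constant`` mode applies one per-cycle death probability at every age;
    ``age_table`` mode interpolates a step table of annual probabilities by
    age band, converted per cycle as ``1 - (1 - q)**cycle_length_years``.
    """

    mode: str = "constant"
    per_cycle_death_prob: float = 0.0
    #: rows of (age_from, age_to, annual_prob); bands contiguous, last band
    #: open-ended via age_to = inf.
    age_table: list[tuple[float, float, float]] = field(default_factory=list)

    def validate(self) -> None:
        if self.mode not in ("constant", "age_table"):
            raise ValidationError(f"unknown mortality mode '{self.mode}'")
        if self.mode == "constant":
            _check_prob(self.per_cycle_death_prob, "per_cycle_death_prob")
        else:
            if not self.age_table:
                raise ValidationError("age_table mode requires a non-empty table")
            prev_hi = None
            for lo, hi, q in self.age_table:
                if hi <= lo:
                    raise ValidationError(f"empty age band [{lo}, {hi})")
                if prev_hi is not None and lo != prev_hi:
                    raise ValidationError(
                        f"age bands must be contiguous; gap/overlap at {lo}"
                    )
                _check_prob(q, f"annual death probability for band [{lo}, {hi})")
                prev_hi = hi

    def annual_prob(self, age: float) -> float:
        if self.mode == "constant":
            raise ValueError("annual_prob undefined for constant mode")
        for lo, hi, q in self.age_table:
            if lo <= age < hi:
                return q
        raise ValidationError(f"age {age} outside mortality table coverage")

    def per_cycle_prob(self, age: float, cycle_length_years: float) -> float:
        """Per-cycle death probability at the given exact age."""
        if self.mode == "constant":
            return self.per_cycle_death_prob
        q = self.annual_prob(age)
        return 1.0 - (1.0 - q) ** cycle_length_years


@dataclass
class ParamUncertainty:
    """Second-order uncertainty description for one scalar parameter."""

    name: str
    mean: float
    se: float
    dist_family: str  # gamma | beta | lognormal | fixed
    dsa_low: float | None = None
    dsa_high: float | None = None

    def validate(self) -> None:
        if self.se < 0:
            raise ValidationError(f"{self.name}: se must be >= 0")
        if self.dist_family not in ("gamma", "beta", "lognormal", "fixed"):
            raise ValidationError(
                f"{self.name}: unknown distribution family '{self.dist_family}'"
            )
        if self.dsa_low is not None and self.dsa_high is not None:
            if not self.dsa_low <= self.mean <= self.dsa_high:
                raise ValidationError(
                    f"{self.name}: DSA range [{self.dsa_low}, {self.dsa_high}] "
                    f"must bracket the mean {self.mean}"
                )


@dataclass
class UncertaintySettings:
    """PSA configuration: a proportional default SE for parameters published
    without one, plus per-parameter overrides keyed by dotted path."""

    default_se_fraction: float = 0.20
    overrides: dict[str, dict] = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 <= self.default_se_fraction:
            raise ValidationError("default_se_fraction must be >= 0")


@dataclass
class DsaRange:
    """One-way deterministic sensitivity range for a dotted parameter path."""

    param: str
    low: float
    high: float

    def validate(self) -> None:
        if self.low > self.high:
            raise ValidationError(f"{self.param}: DSA low > high")


@dataclass
class ModelSpec:
    """A fully assembled, validated model configuration."""

    states: dict[str, TreatmentState]
    strategies: list[StrategyDef]
    ae_costs: dict[str, AECostSchedule]
    utilities: UtilitySet
    econ: EconSettings
    mortality: MortalitySchedule
    uncertainty: UncertaintySettings = field(default_factory=UncertaintySettings)
    dsa_ranges: list[DsaRange] = field(default_factory=list)

    def validate(self, allow_utility_inversion: bool = False) -> "ModelSpec":
        if not self.states:
            raise SchemaError("model defines no treatment states")
        for st in self.states.values():
            st.validate()
        for sched in self.ae_costs.values():
            sched.validate()
        self.utilities.validate(allow_inversion=allow_utility_inversion)
        self.econ.validate()
        self.mortality.validate()
        self.uncertainty.validate()
        for rng in self.dsa_ranges:
            rng.validate()
        if not self.strategies:
            raise SchemaError("model defines no strategies")
        for strat in self.strategies:
            validate_strategy(strat, self.states)
        return self

    def strategy(self, name: str) -> StrategyDef:
        for s in self.strategies:
            if s.name == name:
                return s
        raise UnknownStateError(f"no strategy named '{name}'")

    def copy(self) -> "ModelSpec":
        return copy.deepcopy(self)

    # -- dotted-path parameter access (used by sensitivity analyses) -------

    def get_param(self, path: str) -> float:
        obj, attr = self._resolve(path)
        if isinstance(obj, dict):
            return float(obj[attr])
        return float(getattr(obj, attr))

    def set_param(self, path: str, value: float) -> None:
        obj, attr = self._resolve(path)
        if isinstance(obj, dict):
            obj[attr] = float(value)
        else:
            setattr(obj, attr, float(value))

    def _resolve(self, path: str):
        parts = path.split(".")
        try:
            if parts[0] == "states":
                state = self.states[parts[1]]
                if parts[2] == "ae_incidence":
                    return state.ae_incidence, parts[3]
                return state, parts[2]
            if parts[0] == "ae_costs":
                return self.ae_costs[parts[1]], parts[2]
            if parts[0] == "utilities":
                return self.utilities, parts[1]
            if parts[0] == "econ":
                return self.econ, parts[1]
            if parts[0] == "mortality":
                return self.mortality, parts[1]
        except (KeyError, IndexError) as exc:
            raise UnknownStateError(f"cannot resolve parameter path '{path}'") from exc
        raise UnknownStateError(f"cannot resolve parameter path '{path}'")


def validate_strategy(
    strategy: StrategyDef, states: Mapping[str, TreatmentState]
) -> None:
    """Check ordering constraints of a care sequence.

    The sequence must be non-empty, without repeats, reference only known
    states, and place the terminal treatment (and only it) last.
    """
    if not strategy.sequence:
        raise ValidationError(f"strategy '{strategy.name}': empty sequence")
    seen: dict[str, int] = {}
    for pos, name in enumerate(strategy.sequence):
        if name not in states:
            raise UnknownStateError(
                f"strategy '{strategy.name}': unknown state '{name}' at "
                f"position {pos}; known states: {sorted(states)}"
            )
        if name in seen:
            raise ValidationError(
                f"strategy '{strategy.name}': state '{name}' repeated at "
                f"positions {seen[name]} and {pos}"
            )
        seen[name] = pos
    for pos, name in enumerate(strategy.sequence):
        terminal = states[name].is_terminal_treatment
        last = pos == len(strategy.sequence) - 1
        if terminal and not last:
            raise ValidationError(
                f"strategy '{strategy.name}': terminal treatment '{name}' "
                f"must be last (found at position {pos})"
            )
        if last and not terminal:
            raise ValidationError(
                f"strategy '{strategy.name}': last state '{name}' is not a "
                "terminal treatment"
            )


# ---------------------------------------------------------------------------
# YAML (de)serialisation


def _parse_states(raw: Mapping, context: str) -> dict[str, TreatmentState]:
    states = {}
    for name, body in raw.items():
        if not isinstance(body, Mapping):
            raise SchemaError(f"state '{name}' must be a mapping")
        states[name] = TreatmentState(
            name=name,
            pain_relief_prob=float(_require(body, "pain_relief_prob", f"state '{name}'")),
            cycle_cost=float(body.get("cycle_cost", 0.0)),
            one_time_cost=float(body.get("one_time_cost", 0.0)),
            ae_incidence={k: float(v) for k, v in (body.get("ae_incidence") or {}).items()},
            is_terminal_treatment=bool(body.get("is_terminal_treatment", False)),
        )
    return states


def _parse_mortality(raw: Mapping, base_dir: Path | None) -> MortalitySchedule:
    mode = raw.get("mode", "constant")
    if mode == "constant":
        return MortalitySchedule(
            mode="constant",
            per_cycle_death_prob=float(raw.get("per_cycle_death_prob", 0.0)),
        )
    rows: list[tuple[float, float, float]] = []
    if "table_file" in raw:
        path = Path(raw["table_file"])
        if not path.is_absolute() and base_dir is not None:
            path = base_dir / path
        import csv

        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                hi = rec["age_to"]
                rows.append(
                    (
                        float(rec["age_from"]),
                        float("inf") if hi in ("", "inf") else float(hi),
                        float(rec["annual_prob"]),
                    )
                )
    else:
        for rec in _require(raw, "age_table", "mortality"):
            hi = rec["age_to"]
            rows.append(
                (
                    float(rec["age_from"]),
                    float("inf") if hi in ("", "inf", None) else float(hi),
                    float(rec["annual_prob"]),
                )
            )
    return MortalitySchedule(mode="age_table", age_table=rows)


def _build_spec(doc: Mapping, base_dir: Path | None) -> ModelSpec:
    if not isinstance(doc, Mapping):
        raise SchemaError("configuration document must be a mapping")
    states = _parse_states(_require(doc, "states", "model"), "states")
    strategies = [
        StrategyDef(name=name, sequence=list(seq))
        for name, seq in _require(doc, "strategies", "model").items()
    ]
    ae_costs = {}
    for name, body in (doc.get("ae_costs") or {}).items():
        ae_costs[name] = AECostSchedule(
            name=name,
            acute_cost=float(_require(body, "acute_cost", f"ae_costs '{name}'")),
            first_year_cost=float(body.get("first_year_cost", 0.0)),
            subsequent_year_cost=float(body.get("subsequent_year_cost", 0.0)),
            disutility=float(body.get("disutility", 0.0)),
            acute_cost_se=float(body.get("acute_cost_se", 0.0)),
            first_year_cost_se=float(body.get("first_year_cost_se", 0.0)),
            subsequent_year_cost_se=float(body.get("subsequent_year_cost_se", 0.0)),
            disutility_se=float(body.get("disutility_se", 0.0)),
        )
    util_raw = _require(doc, "utilities", "model")
    utilities = UtilitySet(
        no_pain=float(_require(util_raw, "no_pain", "utilities")),
        moderate_pain=float(_require(util_raw, "moderate_pain", "utilities")),
        no_pain_se=float(util_raw.get("no_pain_se", 0.0)),
        moderate_pain_se=float(util_raw.get("moderate_pain_se", 0.0)),
    )
    econ_raw = doc.get("economics") or {}
    known = {f.name for f in dataclasses.fields(EconSettings)}
    unknown = set(econ_raw) - known
    if unknown:
        raise SchemaError(f"unknown economics fields: {sorted(unknown)}")
    econ = EconSettings(**econ_raw)
    mortality = _parse_mortality(doc.get("mortality") or {}, base_dir)
    unc_raw = doc.get("uncertainty") or {}
    uncertainty = UncertaintySettings(
        default_se_fraction=float(unc_raw.get("default_se_fraction", 0.20)),
        overrides={k: dict(v) for k, v in (unc_raw.get("overrides") or {}).items()},
    )
    dsa_ranges = [
        DsaRange(param=r["param"], low=float(r["low"]), high=float(r["high"]))
        for r in (doc.get("dsa") or [])
    ]
    return ModelSpec(
        states=states,
        strategies=strategies,
        ae_costs=ae_costs,
        utilities=utilities,
        econ=econ,
        mortality=mortality,
        uncertainty=uncertainty,
        dsa_ranges=dsa_ranges,
    ).validate()


def load_model(config_path: str | Path) -> ModelSpec:
    """Read and validate a model configuration from YAML."""
    path = Path(config_path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _build_spec(doc, path.parent)


def model_to_dict(spec: ModelSpec) -> dict:
    """Serialise a ModelSpec to the YAML document structure."""
    doc: dict = {"states": {}, "strategies": {}, "ae_costs": {}}
    for name, st in spec.states.items():
        body: dict = {"pain_relief_prob": st.pain_relief_prob}
        if st.cycle_cost:
            body["cycle_cost"] = st.cycle_cost
        if st.one_time_cost:
            body["one_time_cost"] = st.one_time_cost
        if st.ae_incidence:
            body["ae_incidence"] = dict(st.ae_incidence)
        if st.is_terminal_treatment:
            body["is_terminal_treatment"] = True
        doc["states"][name] = body
    for strat in spec.strategies:
        doc["strategies"][strat.name] = list(strat.sequence)
    for name, sched in spec.ae_costs.items():
        body = {"acute_cost": sched.acute_cost}
        for f in (
            "first_year_cost",
            "subsequent_year_cost",
            "disutility",
            "acute_cost_se",
            "first_year_cost_se",
            "subsequent_year_cost_se",
            "disutility_se",
        ):
            v = getattr(sched, f)
            if v:
                body[f] = v
        doc["ae_costs"][name] = body
    doc["utilities"] = {
        "no_pain": spec.utilities.no_pain,
        "moderate_pain": spec.utilities.moderate_pain,
        "no_pain_se": spec.utilities.no_pain_se,
        "moderate_pain_se": spec.utilities.moderate_pain_se,
    }
    doc["economics"] = dataclasses.asdict(spec.econ)
    if spec.mortality.mode == "constant":
        doc["mortality"] = {
            "mode": "constant",
            "per_cycle_death_prob": spec.mortality.per_cycle_death_prob,
        }
    else:
        doc["mortality"] = {
            "mode": "age_table",
            "age_table": [
                {
                    "age_from": lo,
                    "age_to": "inf" if hi == float("inf") else hi,
                    "annual_prob": q,
                }
                for lo, hi, q in spec.mortality.age_table
            ],
        }
    doc["uncertainty"] = {
        "default_se_fraction": spec.uncertainty.default_se_fraction,
        "overrides": spec.uncertainty.overrides,
    }
    if spec.dsa_ranges:
        doc["dsa"] = [
            {"param": r.param, "low": r.low, "high": r.high} for r in spec.dsa_ranges
        ]
    return doc


def write_model(spec: ModelSpec, path: str | Path) -> None:
    """Write a model configuration back to YAML (round-trips load_model)."""
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(spec), fh, sort_keys=False)


def loads_model(text: str) -> ModelSpec:
    """Parse a model configuration from a YAML string."""
    return _build_spec(yaml.safe_load(text), None)


# ---------------------------------------------------------------------------
# Packaged fixtures


def fixture_path(name: str) -> Path:
    """Path of a packaged fixture file."""
    return Path(resources.files("oacea") / "fixtures" / name)


def load_fixture_model(name: str = "thailand_oa_2022.yaml") -> ModelSpec:
    """Load the packaged Thai knee-OA model (published inputs)."""
    return load_model(fixture_path(name))


def load_published_base_case(name: str = "thailand_oa_2022_base_case.csv"):
    """Published per-strategy (cost THB, QALY) pairs of the Thai base case.

    These are printed results used as *inputs* to the frontier arithmetic
    (dominance labels, ICERs, currency conversion), independent of the model
    run.  Returns a list of (strategy, cost_thb, qaly) tuples in table order.
    """
    import csv

    rows = []
    with open(fixture_path(name), newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append((rec["strategy"], float(rec["cost_thb"]), float(rec["qaly"])))
    return rows
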