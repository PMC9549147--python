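"""Deterministic and probabilistic sensitivity analysis.

Distribution families follow the class rule of the source analysis: costs
sample from gamma distributions, adverse-event probabilities, utilities and
disutility magnitudes from beta distributions, and the pain-relief (state
transition) probabilities from log-normal distributions truncated to [0, 1].
All families are fitted by the method of moments so the analytic mean and SD
equal the published estimate and standard error.

Parameters published without a standard error use a proportional default
(``uncertainty.default_se_fraction``, 20% of the mean unless configured);
parameters with zero mean or zero SE are held fixed.  Sampling uses one root
seed with a deterministic per-parameter substream (derived from the
parameter's dotted path), so adding or removing one parameter does not
perturb the draws of the others.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import CEAResult, icer, nmb, run_cea
from .parameters import (
    CHRONIC_AES,
    ModelSpec,
    ParamUncertainty,
    ValidationError,
)

__all__ = [
    "gamma_from_moments",
    "beta_from_moments",
    "lognormal_from_moments",
    "sample_parameter",
    "build_uncertain_parameters",
    "TornadoEntry",
    "one_way_dsa",
    "run_dsa",
    "PSAResult",
    "run_psa",
    "ce_plane",
    "CEACCurve",
    "ceac",
    "default_wtp_grid",
]


# ---------------------------------------------------------------------------
# Method-of-moments distribution fits


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) with the given mean and SD."""
    if mean <= 0 or se <= 0:
        raise ValidationError(f"gamma fit needs mean, se > 0 (got {mean}, {se})")
    shape = (mean / se) ** 2
    scale = se**2 / mean
    return shape, scale


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta (alpha, beta) with the given mean and SD.

    Feasibility requires ``se**2 < mean * (1 - mean)``.
    """
    if not 0 < mean < 1:
        raise ValidationError(f"beta fit needs 0 < mean < 1 (got {mean})")
    if se <= 0:
        raise ValidationError(f"beta fit needs se > 0 (got {se})")
    var = se**2
    if var >= mean * (1 - mean):
        raise ValidationError(
            f"infeasible beta moments: se^2 = {var:g} >= mean(1-mean) = "
            f"{mean * (1 - mean):g}"
        )
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


def lognormal_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) of the underlying normal with the given
    arithmetic mean and SD."""
    if mean <= 0 or se <= 0:
        raise ValidationError(f"lognormal fit needs mean, se > 0 (got {mean}, {se})")
    sigma2 = math.log(1.0 + se**2 / mean**2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_parameter(
    param: ParamUncertainty, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Draw ``n`` values for one parameter from its fitted distribution.

    Negative means (disutilities) sample their magnitude and restore the
    sign; log-normal draws used as probabilities are truncated to [0, 1] by
    the caller's family assignment (handled here via clipping).
    """
    mean, se = param.mean, param.se
    if param.dist_family == "fixed" or se == 0 or mean == 0:
        return np.full(n, mean)
    sign = -1.0 if mean < 0 else 1.0
    m = abs(mean)
    if param.dist_family == "gamma":
        shape, scale = gamma_from_moments(m, se)
        draws = rng.gamma(shape, scale, size=n)
    elif param.dist_family == "beta":
        a, b = beta_from_moments(m, se)
        draws = rng.beta(a, b, size=n)
    elif param.dist_family == "lognormal":
        mu, sigma = lognormal_from_moments(m, se)
        draws = np.clip(rng.lognormal(mu, sigma, size=n), 0.0, 1.0)
    else:  # pragma: no cover - guarded by ParamUncertainty.validate
        raise ValidationError(f"unknown family '{param.dist_family}'")
    return sign * draws


# ---------------------------------------------------------------------------
# Uncertain-parameter registry


def _family_for(path: str) -> str:
    if ".pain_relief_prob" in path:
        return "lognormal"
    if ".ae_incidence." in path or path.startswith("utilities."):
        return "beta"
    if ".disutility" in path:
        return "beta"  # sampled on the magnitude
    return "gamma"  # costs


def build_uncertain_parameters(model: ModelSpec) -> list[ParamUncertainty]:
    """Enumerate every uncertain scalar of a model with its family and SE.

    Covered by default: state pain-relief and adverse-event probabilities
    (proportional default SE), adverse-event cost schedules and disutilities
    (published SEs), the utility pair, and any dotted paths listed in
    ``uncertainty.overrides``.  Treatment costs are published without SEs and
    stay fixed unless an override supplies one.
    """
    frac = model.uncertainty.default_se_fraction
    overrides = model.uncertainty.overrides
    params: list[ParamUncertainty] = []

    def add(path: str, mean: float, se: float | None, family: str | None = None):
        ov = overrides.get(path, {})
        se = float(ov.get("se", se if se is not None else 0.0))
        family = str(ov.get("family", family or _family_for(path)))
        if se == 0 or mean == 0:
            family = "fixed"
        p = ParamUncertainty(name=path, mean=mean, se=se, dist_family=family)
        p.validate()
        params.append(p)

    for name, st in model.states.items():
        add(f"states.{name}.pain_relief_prob", st.pain_relief_prob,
            frac * st.pain_relief_prob)
        for kind, prob in st.ae_incidence.items():
            add(f"states.{name}.ae_incidence.{kind}", prob, frac * prob)
    for kind, sched in model.ae_costs.items():
        add(f"ae_costs.{kind}.acute_cost", sched.acute_cost, sched.acute_cost_se)
        if kind in CHRONIC_AES:
            add(f"ae_costs.{kind}.first_year_cost", sched.first_year_cost,
                sched.first_year_cost_se)
            add(f"ae_costs.{kind}.subsequent_year_cost", sched.subsequent_year_cost,
                sched.subsequent_year_cost_se)
        add(f"ae_costs.{kind}.disutility", sched.disutility, sched.disutility_se)
    add("utilities.no_pain", model.utilities.no_pain, model.utilities.no_pain_se)
    add("utilities.moderate_pain", model.utilities.moderate_pain,
        model.utilities.moderate_pain_se)
    covered = {p.name for p in params}
    for path, ov in overrides.items():
        if path not in covered:
            add(path, model.get_param(path), ov.get("se"), ov.get("family"))
    return params


def _substream(root_seed: int, name: str) -> np.random.Generator:
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([root_seed, key]))


def sample_parameter_table(
    model: ModelSpec, n_iter: int, seed: int
) -> pd.DataFrame:
    """(n_iter x parameter) table of sampled values, one substream each."""
    cols = {}
    for p in build_uncertain_parameters(model):
        try:
            cols[p.name] = sample_parameter(p, _substream(seed, p.name), n_iter)
        except ValidationError as exc:
            raise ValidationError(f"parameter '{p.name}': {exc}") from exc
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity (tornado)


@dataclass
class TornadoEntry:
    """One bar of a tornado diagram."""

    param: str
    low: float
    high: float
    output_at_low: float
    output_at_high: float

    @property
    def bar_width(self) -> float:
        return abs(self.output_at_high - self.output_at_low)


def _apply_params(
    model: ModelSpec, assignments: dict[str, float], clip_utilities: bool = True
) -> ModelSpec:
    pinned = model.copy()
    for path, value in assignments.items():
        pinned.set_param(path, value)
    if clip_utilities:
        # independent PSA draws occasionally invert the utility pair; clip
        if pinned.utilities.moderate_pain > pinned.utilities.no_pain:
            pinned.utilities.moderate_pain = pinned.utilities.no_pain
        pinned.validate()
    else:
        # DSA may pin moderate-pain utility above no-pain (published ranges
        # extend that far); everything else stays strictly validated
        pinned.validate(allow_utility_inversion=True)
    return pinned


def _comparison_metric(
    model: ModelSpec, comparison: tuple[str, str], metric: str, wtp: float
) -> float:
    res = run_cea(model, list(comparison))
    if metric == "inmb":
        return nmb(res[0], wtp) - nmb(res[1], wtp)
    if metric == "icer":
        return icer(res[0], res[1])
    raise ValueError(f"unknown DSA metric '{metric}'")


def one_way_dsa(
    model: ModelSpec,
    param: str,
    low: float,
    high: float,
    comparison: tuple[str, str],
    metric: str = "inmb",
    wtp: float | None = None,
) -> TornadoEntry:
    """Re-run the base case twice with one parameter pinned at its bounds.

    The default output metric is the incremental net monetary benefit of
    ``comparison[0]`` versus ``comparison[1]`` at the model's
    willingness-to-pay threshold (``metric="icer"`` switches to the ICER).
    """
    if low > high:
        raise ValidationError(f"{param}: low {low} > high {high}")
    wtp = model.econ.wtp_per_qaly if wtp is None else wtp
    out = [
        _comparison_metric(
            _apply_params(model, {param: v}, clip_utilities=False),
            comparison, metric, wtp,
        )
        for v in (low, high)
    ]
    return TornadoEntry(param=param, low=low, high=high,
                        output_at_low=out[0], output_at_high=out[1])


def run_dsa(
    model: ModelSpec,
    comparison: tuple[str, str],
    metric: str = "inmb",
    wtp: float | None = None,
) -> list[TornadoEntry]:
    """All configured one-way ranges, sorted by descending bar width."""
    seen = set()
    entries = []
    for rng in model.dsa_ranges:
        if rng.param in seen:
            continue
        seen.add(rng.param)
        entries.append(
            one_way_dsa(model, rng.param, rng.low, rng.high, comparison,
                        metric=metric, wtp=wtp)
        )
    return sorted(entries, key=lambda e: e.bar_width, reverse=True)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass
class PSAResult:
    """Monte-Carlo (cost, QALY) pairs per strategy.

    ``costs`` and ``qalys`` are (n_iter x n_strategies) arrays; every
    strategy within one iteration is evaluated on the same sampled parameter
    set (common random parameters).
    """

    strategies: list[str]
    costs: np.ndarray
    qalys: np.ndarray
    parameters: pd.DataFrame
    seed: int

    @property
    def n_iter(self) -> int:
        return self.costs.shape[0]

    def column(self, strategy: str) -> int:
        return self.strategies.index(strategy)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (iteration, strategy)."""
        rows = []
        for j, name in enumerate(self.strategies):
            rows.append(
                pd.DataFrame(
                    {
                        "iteration": np.arange(self.n_iter),
                        "strategy": name,
                        "cost": self.costs[:, j],
                        "qaly": self.qalys[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def mean_results(self) -> list[CEAResult]:
        return [
            CEAResult(
                strategy=name,
                total_cost=float(self.costs[:, j].mean()),
                total_qaly=float(self.qalys[:, j].mean()),
                undiscounted_cost=float("nan"),
                undiscounted_qaly=float("nan"),
            )
            for j, name in enumerate(self.strategies)
        ]


def run_psa(
    model: ModelSpec,
    n_iter: int = 1000,
    seed: int = 0,
    strategies: list[str] | None = None,
) -> PSAResult:
    """Monte-Carlo PSA: sample all uncertain parameters, re-run every
    strategy per iteration, record discounted (cost, QALY) pairs."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    names = strategies or [s.name for s in model.strategies]
    table = sample_parameter_table(model, n_iter, seed)
    costs = np.empty((n_iter, len(names)))
    qalys = np.empty((n_iter, len(names)))
    for i in range(n_iter):
        spec_i = _apply_params(model, dict(table.iloc[i]))
        for j, res in enumerate(run_cea(spec_i, names)):
            costs[i, j] = res.total_cost
            qalys[i, j] = res.total_qaly
    return PSAResult(strategies=names, costs=costs, qalys=qalys,
                     parameters=table, seed=seed)


def ce_plane(
    psa: PSAResult, comparison: tuple[str, str]
) -> dict:
    """Incremental cost-effectiveness plane of ``comparison[0]`` vs ``[1]``.

    Quadrant shares partition all draws; points on an axis count toward the
    more favourable quadrant (lower-right beats upper-right beats the rest),
    so a draw with ΔE >= 0 and ΔC <= 0 is 'lower_right' (dominant).
    """
    ja, jb = psa.column(comparison[0]), psa.column(comparison[1])
    dc = psa.costs[:, ja] - psa.costs[:, jb]
    de = psa.qalys[:, ja] - psa.qalys[:, jb]
    lower_right = (de >= 0) & (dc <= 0)
    upper_right = (de >= 0) & (dc > 0)
    lower_left = (de < 0) & (dc < 0)
    upper_left = (de < 0) & (dc >= 0)
    n = psa.n_iter
    return {
        "delta_cost": dc,
        "delta_qaly": de,
        "proportions": {
            "lower_right": lower_right.mean(),
            "upper_right": upper_right.mean(),
            "lower_left": lower_left.mean(),
            "upper_left": upper_left.mean(),
        },
        "n": n,
    }


def default_wtp_grid() -> np.ndarray:
    """0 to 320,000 THB/QALY in 5,000 steps."""
    return np.arange(0, 320_001, 5_000, dtype=float)


@dataclass
class CEACCurve:
    """Probability of cost-effectiveness over a willingness-to-pay grid."""

    wtp: np.ndarray
    probabilities: pd.DataFrame  # one column per strategy (or 'pairwise')

    def at(self, wtp_value: float, column: str) -> float:
        idx = int(np.argmin(np.abs(self.wtp - wtp_value)))
        return float(self.probabilities[column].iloc[idx])

    def to_frame(self) -> pd.DataFrame:
        df = self.probabilities.copy()
        df.insert(0, "wtp", self.wtp)
        return df


def ceac(
    psa: PSAResult,
    wtp_grid: np.ndarray | None = None,
    comparison: tuple[str, str] | None = None,
) -> CEACCurve:
    """Cost-effectiveness acceptability curve(s).

    Pairwise (``comparison`` given): fraction of draws in which the first
    strategy's net monetary benefit is at least the second's.  Multi-way
    (default): fraction of draws in which each strategy attains the maximal
    net monetary benefit (ties resolved to the first-listed strategy, so the
    probabilities sum to 1 at every grid point).
    """
    wtp = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    if wtp.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    if comparison is not None:
        ja, jb = psa.column(comparison[0]), psa.column(comparison[1])
        probs = np.empty(wtp.size)
        for i, w in enumerate(wtp):
            nmb_a = w * psa.qalys[:, ja] - psa.costs[:, ja]
            nmb_b = w * psa.qalys[:, jb] - psa.costs[:, jb]
            probs[i] = (nmb_a >= nmb_b).mean()
        return CEACCurve(wtp=wtp, probabilities=pd.DataFrame({"pairwise": probs}))
    probs = np.zeros((wtp.size, len(psa.strategies)))
    for i, w in enumerate(wtp):
        nmb_all = w * psa.qalys - psa.costs  # (n_iter, n_strategies)
        best = np.argmax(nmb_all, axis=1)  # ties -> lowest index
        for j in range(len(psa.strategies)):
            probs[i, j] = (best == j).mean()
    return CEACCurve(
        wtp=wtp, probabilities=pd.DataFrame(probs, columns=psa.strategies)
    )
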