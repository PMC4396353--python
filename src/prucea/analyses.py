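"""Base case, deterministic sensitivity, scenarios and probabilistic analysis.

The deterministic pipeline is: response evidence -> transition matrix ->
cohort trace -> per-state cost profiles and utilities -> discounted totals ->
incremental statistics.  One-way analysis re-runs that pipeline at the printed
parameter bounds; scenarios apply a documented settings delta; the
probabilistic analysis re-runs it for thousands of parameter draws (beta for
probabilities and utilities, gamma for resource quantities) and summarizes
them as a ratio-of-means ICER and a cost-effectiveness acceptability curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import costing
from .engine import CohortTrace, build_transitions, run_cohort
from .outcomes import CEAResult, accrue_qalys, incremental_analysis
from .parameters import ModelParameters, PHASES, default_parameters

__all__ = [
    "ArmOutcome",
    "evaluate_arm",
    "run_base_case",
    "SensitivityItem",
    "default_sensitivity_items",
    "run_one_way",
    "SCENARIOS",
    "run_scenario",
    "sample_parameters",
    "PSAResult",
    "run_psa",
    "ceac",
]


# ---------------------------------------------------------------------------
# deterministic pipeline


@dataclass(frozen=True)
class ArmOutcome:
    arm: str
    trace: CohortTrace
    ledger: costing.CostLedger
    cost: float
    qalys: float


def _survival_weights(params: ModelParameters, horizon: int) -> np.ndarray | None:
    p = params.analysis.monthly_death_probability
    if p <= 0.0:
        return None
    return (1.0 - p) ** np.arange(horizon + 1)


def evaluate_arm(params: ModelParameters, arm: str) -> ArmOutcome:
    """Run the full deterministic pipeline for one strategy arm."""
    arms = params.active_arms()
    evidence = arms.prucalopride if arm == "prucalopride" else arms.laxative
    a = params.analysis
    tm = build_transitions(
        r4=evidence.r4,
        r12=evidence.r12,
        switch_response=params.clinical.switch_response,
        horizon=a.horizon_months,
        stopping_rule=a.stopping_rule,
        arm=arm,
    )
    trace = run_cohort(tm)
    survival = _survival_weights(params, a.horizon_months)
    profile = costing.build_cost_profiles(params, a.horizon_months)[arm]
    ledger = costing.accrue_costs(
        trace.occupancy, profile, a.discount_rate_costs, survival
    )
    qalys = accrue_qalys(
        trace, params.utilities, arm, a.discount_rate_effects, survival
    )
    return ArmOutcome(arm=arm, trace=trace, ledger=ledger, cost=ledger.total, qalys=qalys)


def run_base_case(params: ModelParameters | None = None) -> CEAResult:
    """Deterministic cost-utility result for the configured settings."""
    p = params if params is not None else default_parameters()
    pru = evaluate_arm(p, "prucalopride")
    lax = evaluate_arm(p, "laxative")
    return incremental_analysis(pru.cost, lax.cost, pru.qalys, lax.qalys)


# ---------------------------------------------------------------------------
# one-way sensitivity


@dataclass(frozen=True)
class SensitivityItem:
    """A parameter varied to its low/high value, all else fixed.

    ``path`` is either a dotted attribute/key path into the bundle (the value
    is replaced) or one of the special response handles
    ``prucalopride_week4_response`` / ``prucalopride_week12_response``, which
    override the response proportions directly.  Varying the week-4 response
    also moves the week-12 response according to the configured linkage
    (default: the absolute week-4 to week-12 attrition mass is preserved).
    """

    path: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"{self.path}: low > high")


def _set_dotted(obj: Any, path: str, value: float) -> None:
    parts = path.split(".")
    for part in parts[:-1]:
        if isinstance(obj, Mapping) or isinstance(obj, dict):
            obj = obj[part]
        else:
            obj = getattr(obj, part)
    last = parts[-1]
    if isinstance(obj, dict):
        if last not in obj:
            raise KeyError(f"unknown parameter path {path!r}")
        obj[last] = value
    else:
        if not hasattr(obj, last):
            raise AttributeError(f"unknown parameter path {path!r}")
        setattr(obj, last, value)


def _apply_item(params: ModelParameters, path: str, value: float) -> ModelParameters:
    p = params.copy_deep()
    arms = p.active_arms()
    if path == "prucalopride_week4_response":
        r4_default = arms.prucalopride.r4
        r12_default = arms.prucalopride.r12
        if p.analysis.oneway_response_linkage == "attrition":
            r12 = value - (r4_default - r12_default)
        else:
            r12 = value * r12_default / r4_default
        arms.prucalopride.week4.proportion_override = value
        arms.prucalopride.week12.proportion_override = float(np.clip(r12, 0.0, 1.0))
    elif path == "prucalopride_week12_response":
        arms.prucalopride.week12.proportion_override = value
    else:
        _set_dotted(p, path, value)
    return p


def default_sensitivity_items(params: ModelParameters) -> list[SensitivityItem]:
    """The published one-way set: week-4 and week-12 response at their 95%
    interval bounds, and both DBC tariffs at +/-25%."""
    hosp = params.costs.units["dbc_hospitalization"].cost
    spec = params.costs.units["dbc_specialist"].cost
    return [
        SensitivityItem("prucalopride_week4_response", 0.244, 0.314),
        SensitivityItem("prucalopride_week12_response", 0.204, 0.250),
        SensitivityItem(
            "costs.units.dbc_hospitalization.cost", 0.75 * hosp, 1.25 * hosp
        ),
        SensitivityItem("costs.units.dbc_specialist.cost", 0.75 * spec, 1.25 * spec),
    ]


def run_one_way(
    params: ModelParameters | None = None,
    items: Sequence[SensitivityItem] | None = None,
) -> pd.DataFrame:
    """Tornado table: base case re-run at each item's low and high value."""
    p = params if params is not None else default_parameters()
    items = list(items) if items is not None else default_sensitivity_items(p)
    base = run_base_case(p)
    records = []
    for item in items:
        results = {}
        for side, value in (("low", item.low), ("high", item.high)):
            res = run_base_case(_apply_item(p, item.path, value))
            results[side] = res
        records.append(
            {
                "parameter": item.path,
                "low_value": item.low,
                "high_value": item.high,
                "icer_low": results["low"].icer,
                "icer_high": results["high"].icer,
                "cost_intervention_low": results["low"].cost_intervention,
                "cost_intervention_high": results["high"].cost_intervention,
                "qaly_intervention_low": results["low"].qaly_intervention,
                "qaly_intervention_high": results["high"].qaly_intervention,
                "icer_base": base.icer,
                "spread": abs(results["low"].icer - results["high"].icer),
            }
        )
    frame = pd.DataFrame.from_records(records)
    return frame.sort_values("spread", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# scenarios


def _scn_women(p: ModelParameters) -> None:
    p.analysis.population = "women"


def _scn_pacqol(p: ModelParameters) -> None:
    p.analysis.endpoint = "pacqol_satisfaction"


def _scn_no_stopping(p: ModelParameters) -> None:
    p.analysis.stopping_rule = False


def _scn_no_complications(p: ModelParameters) -> None:
    p.analysis.include_complications = False


def _scn_dose(p: ModelParameters) -> None:
    p.analysis.dose = "1.5mg"


def _scn_indirect(p: ModelParameters) -> None:
    p.analysis.include_indirect = True


def _scn_no_transport(p: ModelParameters) -> None:
    p.analysis.include_transport = False


def _scn_los(p: ModelParameters) -> None:
    p.analysis.hospital_costing = "los_daily"


def _scn_3y(p: ModelParameters) -> None:
    p.analysis.horizon_months = 36
    p.analysis.discount_rate_costs = 0.04
    p.analysis.discount_rate_effects = 0.015


def _scn_mortality(p: ModelParameters) -> None:
    # hook: no national life-table rate ships with the model; override the
    # monthly death probability in config to activate the scenario.
    pass


def _scn_inflate_2014(p: ModelParameters) -> None:
    p.analysis.target_year = 2014


SCENARIOS: dict[str, Callable[[ModelParameters], None]] = {
    "women_only": _scn_women,
    "pacqol_endpoint": _scn_pacqol,
    "no_stopping_rule": _scn_no_stopping,
    "no_complications": _scn_no_complications,
    "dose_1_5mg": _scn_dose,
    "indirect_costs": _scn_indirect,
    "no_transport": _scn_no_transport,
    "los_hospital_cost": _scn_los,
    "horizon_3y": _scn_3y,
    "mortality": _scn_mortality,
    "inflate_2014": _scn_inflate_2014,
}


def run_scenario(
    params: ModelParameters | None = None, name: str = "", **overrides: float
) -> CEAResult:
    """Apply one documented scenario delta and re-run the base case.

    The input bundle is never mutated.  ``overrides`` are applied to the
    analysis settings after the scenario delta (used e.g. to supply a death
    rate to the mortality hook).
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    p = (params if params is not None else default_parameters()).copy_deep()
    SCENARIOS[name](p)
    for key, value in overrides.items():
        setattr(p.analysis, key, value)
    return run_base_case(p)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


def _beta_mm(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Beta draw by method of moments; degenerate when the variance is 0 or
    infeasible for the mean."""
    if sd <= 0.0 or mean <= 0.0 or mean >= 1.0:
        return mean
    var = min(sd * sd, 0.999 * mean * (1.0 - mean))
    nu = mean * (1.0 - mean) / var - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def _gamma_mm(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Gamma draw with the given coefficient of variation (shape ``1/cv^2``)."""
    if mean <= 0.0 or cv <= 0.0:
        return mean
    shape = 1.0 / (cv * cv)
    return float(rng.gamma(shape, mean / shape))


def _beta_mm_ppf(u: float, mean: float, sd: float) -> float:
    """Quantile of the method-of-moments beta at probability ``u``."""
    from scipy.stats import beta as beta_dist

    if sd <= 0.0 or mean <= 0.0 or mean >= 1.0:
        return mean
    var = min(sd * sd, 0.999 * mean * (1.0 - mean))
    nu = mean * (1.0 - mean) / var - 1.0
    return float(beta_dist.ppf(u, mean * nu, (1.0 - mean) * nu))


def sample_parameters(
    params: ModelParameters, rng: np.random.Generator
) -> ModelParameters:
    """Draw one stochastic parameter bundle.

    Response probabilities are beta-distributed with the trial counts as
    shape parameters; Delphi probabilities are beta with SE = 20% of the
    mean; resource quantities (and lengths of stay) are gamma with SE = 25%
    of the mean; utilities are beta with SE = 0.05, drawn with a common
    random quantile per health-state role so that the uncertainty of the
    instrument mapping shifts both arms together while each utility keeps its
    marginal distribution.  Tariffs and prices are held fixed.
    """
    p = params.copy_deep()
    psa = p.psa

    arms = p.active_arms()
    for arm in (arms.prucalopride, arms.laxative):
        for ev in (arm.week4, arm.week12):
            failures = ev.total - ev.responders
            if ev.responders > 0 and failures > 0:
                ev.proportion_override = float(rng.beta(ev.responders, failures))
            else:
                ev.proportion_override = ev.responders / ev.total

    se = psa.probability_se_fraction
    c = p.clinical
    c.switch_response = _beta_mm(rng, c.switch_response, se * c.switch_response)
    c.referral_after_failure = _beta_mm(
        rng, c.referral_after_failure, se * c.referral_after_failure
    )
    c.hospitalization_after_failure = _beta_mm(
        rng, c.hospitalization_after_failure, se * c.hospitalization_after_failure
    )
    for rates in c.complications.values():
        for column in ("weeks_1_4", "weeks_5_12", "switch"):
            m = getattr(rates, column)
            setattr(rates, column, _beta_mm(rng, m, se * m))

    u_se = psa.utility_se
    un = p.utilities
    quantile = rng.random()  # one shared quantile: the mapping shifts all
    for obj, attr in (                        # state utilities together
        (un.prucalopride, "start"),
        (un.prucalopride, "weeks_5_12"),
        (un.prucalopride, "responder"),
        (un.laxative, "start"),
        (un.laxative, "weeks_5_12"),
        (un.laxative, "responder"),
        (un, "switch_start"),
        (un, "switch_responder"),
        (un, "dropout"),
    ):
        mean = getattr(obj, attr)
        setattr(obj, attr, _beta_mm_ppf(quantile, mean, u_se))

    cv = psa.resource_se_fraction
    res = p.resources
    for table in (res.consultations, res.procedures):
        for row in table.values():
            for phase in PHASES:
                row[phase] = _gamma_mm(rng, row[phase], cv)
    for mgmt in res.complication_management.values():
        mgmt.pcp = _gamma_mm(rng, mgmt.pcp, cv)
        mgmt.specialist = _gamma_mm(rng, mgmt.specialist, cv)
        mgmt.los_days = _gamma_mm(rng, mgmt.los_days, cv)

    return p


@dataclass(frozen=True)
class PSAResult:
    samples: pd.DataFrame
    ceac: pd.DataFrame
    icer: float  # ratio of mean incremental cost to mean incremental QALYs
    convergence: pd.DataFrame
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.samples)

    def probability_cost_effective(self, threshold: float) -> float:
        nmb = threshold * self.samples["delta_qaly"] - self.samples["delta_cost"]
        return float((nmb > 0).mean())


def ceac(
    delta_costs: Iterable[float],
    delta_qalys: Iterable[float],
    thresholds: Iterable[float],
) -> pd.DataFrame:
    """Probability the intervention is cost-effective per threshold.

    For each willingness-to-pay value the probability is the fraction of
    draws with positive net monetary benefit.
    """
    dc = np.asarray(list(delta_costs), dtype=float)
    de = np.asarray(list(delta_qalys), dtype=float)
    if dc.size == 0:
        raise ValueError("empty sample set")
    records = [
        (lam, float((lam * de - dc > 0).mean())) for lam in thresholds
    ]
    return pd.DataFrame(records, columns=["threshold", "probability"])


def run_psa(
    params: ModelParameters | None = None,
    n_draws: int | None = None,
    seed: int = 0,
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through the model."""
    p = params if params is not None else default_parameters()
    n = n_draws if n_draws is not None else p.psa.n_draws
    if n < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    rows = np.empty((n, 4))
    for i in range(n):
        draw = sample_parameters(p, rng)
        pru = evaluate_arm(draw, "prucalopride")
        lax = evaluate_arm(draw, "laxative")
        rows[i] = (pru.cost, lax.cost, pru.qalys, lax.qalys)
    samples = pd.DataFrame(
        rows, columns=["cost_intervention", "cost_comparator",
                       "qaly_intervention", "qaly_comparator"]
    )
    samples["delta_cost"] = samples["cost_intervention"] - samples["cost_comparator"]
    samples["delta_qaly"] = samples["qaly_intervention"] - samples["qaly_comparator"]
    icer = float(samples["delta_cost"].mean() / samples["delta_qaly"].mean())
    thresholds = np.arange(
        0.0, p.psa.threshold_max + p.psa.threshold_step / 2, p.psa.threshold_step
    )
    curve = ceac(samples["delta_cost"], samples["delta_qaly"], thresholds)
    running = pd.DataFrame(
        {
            "draw": np.arange(1, n + 1),
            "running_icer": (
                samples["delta_cost"].expanding().mean()
                / samples["delta_qaly"].expanding().mean()
            ).to_numpy(),
        }
    )
    return PSAResult(
        samples=samples, ceac=curve, icer=icer, convergence=running, seed=seed
    )
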