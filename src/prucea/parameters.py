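"""Typed model inputs, configuration loading and basic conversions.

Every printed input of the cost-utility model lives in a validated parameter
bundle (:class:`ModelParameters`).  The shipped default configuration holds the
published values: pooled pivotal-trial responder counts, Delphi-panel
probabilities and resource-use quantities, Dutch list prices, costing-manual
and DBC tariffs, utilities, and the analysis settings of the 1-year base case.
User configuration files are deep-merged over these defaults and re-validated;
unknown keys are rejected.
"""

from __future__ import annotations

import copy
import importlib.resources
import math
from pathlib import Path
from typing import Any, Literal, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.stats import norm

__all__ = [
    "ResponseEvidence",
    "ArmParameters",
    "TrialArms",
    "ModelParameters",
    "default_parameters",
    "load_config",
    "period_to_monthly",
    "inflate",
    "weighted_laxative_daily_cost",
    "proportion_ci",
    "fidelity_table",
]

PHASES = (
    "weeks_1_4",
    "weeks_5_12",
    "maintenance",
    "switch_weeks_1_4",
    "switch_maintenance",
)

STATE_NAMES = (
    "start_w1_4",
    "start_w5_8",
    "start_w9_12",
    "maintenance",
    "switch_w1_4",
    "switch_w5_8",
    "switch_w9_12",
    "switch_maintenance",
    "dropout",
)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


# ---------------------------------------------------------------------------
# clinical layer


class ResponseEvidence(_Strict):
    """Responder count out of a trial arm total.

    ``proportion_override`` lets sensitivity and probabilistic analyses set the
    response probability directly (the printed one-way bounds are proportions,
    not counts); when unset the proportion is ``responders / total``.
    """

    responders: int = Field(ge=0)
    total: int = Field(gt=0)
    proportion_override: float | None = Field(default=None, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _counts_consistent(self) -> "ResponseEvidence":
        if self.responders > self.total:
            raise ValueError(
                f"responders ({self.responders}) exceed total ({self.total})"
            )
        return self

    @property
    def proportion(self) -> float:
        if self.proportion_override is not None:
            return self.proportion_override
        return self.responders / self.total


class ArmParameters(_Strict):
    """Week-4 and week-12 response evidence for one strategy arm."""

    week4: ResponseEvidence
    week12: ResponseEvidence

    @property
    def r4(self) -> float:
        return self.week4.proportion

    @property
    def r12(self) -> float:
        return self.week12.proportion


class TrialArms(_Strict):
    prucalopride: ArmParameters
    laxative: ArmParameters


class ComplicationRates(_Strict):
    weeks_1_4: float = Field(ge=0.0, le=1.0)
    weeks_5_12: float = Field(ge=0.0, le=1.0)
    switch: float = Field(ge=0.0, le=1.0)


class ClinicalInputs(_Strict):
    bowel_function: TrialArms
    bowel_function_women: TrialArms
    pacqol_satisfaction: TrialArms
    switch_response: float = Field(ge=0.0, le=1.0)
    referral_after_failure: float = Field(ge=0.0, le=1.0)
    hospitalization_after_failure: float = Field(ge=0.0, le=1.0)
    complications: dict[str, ComplicationRates]


# ---------------------------------------------------------------------------
# utilities


class ArmUtilities(_Strict):
    start: float = Field(ge=0.0, le=1.0)
    weeks_5_12: float = Field(ge=0.0, le=1.0)
    responder: float = Field(ge=0.0, le=1.0)


class UtilitySet(_Strict):
    """Annual state utilities (QALY weight while occupying the state)."""

    prucalopride: ArmUtilities
    laxative: ArmUtilities
    switch_start: float = Field(ge=0.0, le=1.0)
    switch_responder: float = Field(ge=0.0, le=1.0)
    dropout: float = Field(ge=0.0, le=1.0)


# ---------------------------------------------------------------------------
# resource layer


def _check_phase_row(row: Mapping[str, float]) -> None:
    missing = set(PHASES) - set(row)
    if missing:
        raise ValueError(f"missing phase columns: {sorted(missing)}")


class ResourceTable(_Strict):
    """Monthly contact and procedure counts per model phase (Delphi panel)."""

    consultations: dict[str, dict[str, float]]
    procedures: dict[str, dict[str, float]]
    complication_management: dict[str, "ComplicationManagement"]

    @model_validator(mode="after")
    def _validate_rows(self) -> "ResourceTable":
        for table in (self.consultations, self.procedures):
            for item, row in table.items():
                _check_phase_row(row)
                for phase, count in row.items():
                    if count < 0:
                        raise ValueError(f"{item}.{phase}: count must be >= 0")
        return self


class ComplicationManagement(_Strict):
    pcp: float = Field(ge=0.0)
    specialist: float = Field(ge=0.0)
    hospitalization_fraction: float = Field(ge=0.0, le=1.0)
    los_days: float = Field(ge=0.0)


# ---------------------------------------------------------------------------
# cost layer


class DrugSchedule(_Strict):
    first_pack_daily: float = Field(ge=0.0)
    after_pack_daily: float = Field(ge=0.0)
    costing_year: int


class PrucalopridePrices(_Strict):
    mg2: DrugSchedule
    mg1: DrugSchedule


class LaxativeItem(_Strict):
    daily_cost: float = Field(ge=0.0)
    start_share: float = Field(ge=0.0, le=1.0)
    switch_share: float = Field(ge=0.0, le=1.0)
    costing_year: int


class UnitCost(_Strict):
    cost: float = Field(ge=0.0)
    costing_year: int


class TransportInputs(_Strict):
    km_pcp: float = Field(ge=0.0)
    km_specialist: float = Field(ge=0.0)
    km_dietician: float = Field(ge=0.0)
    cost_per_km: float = Field(ge=0.0)
    parking: float = Field(ge=0.0)
    costing_year: int


class IndirectCostInputs(_Strict):
    absence_share: float = Field(ge=0.0, le=1.0)
    days_missed_per_month: float = Field(ge=0.0)
    cost_per_hour: float = Field(ge=0.0)
    annual_working_hours: float = Field(ge=0.0)
    working_age_share: float = Field(ge=0.0, le=1.0)
    hours_per_day: float = Field(ge=0.0)


class CostInputs(_Strict):
    prucalopride: PrucalopridePrices
    laxatives: dict[str, LaxativeItem]
    prescription_fee: float = Field(ge=0.0)
    units: dict[str, UnitCost]
    procedure_prices: dict[str, float]
    transport: TransportInputs
    inflation: dict[int, float]
    indirect: IndirectCostInputs

    @model_validator(mode="after")
    def _shares_sum_to_one(self) -> "CostInputs":
        for phase, attr in (("start", "start_share"), ("switch", "switch_share")):
            total = sum(getattr(it, attr) for it in self.laxatives.values())
            if abs(total - 1.0) > 0.005:
                raise ValueError(
                    f"laxative {phase} shares sum to {total:.4f}, expected 1.0"
                )
        for name, price in self.procedure_prices.items():
            if price < 0:
                raise ValueError(f"procedure_prices.{name}: must be >= 0")
        return self


# ---------------------------------------------------------------------------
# state mapping


class ComplicationPhase(_Strict):
    column: Literal["weeks_1_4", "weeks_5_12", "switch"]
    period_months: int = Field(ge=1)


class StateMapping(_Strict):
    """Which printed column and tariff each health state draws from."""

    resource_columns: dict[str, str]
    specialist_tariff: dict[str, Literal["dbc", "manual"]]
    complication_phases: dict[str, ComplicationPhase]

    @model_validator(mode="after")
    def _states_known(self) -> "StateMapping":
        for field_name in ("resource_columns", "specialist_tariff"):
            table = getattr(self, field_name)
            unknown = set(table) - set(STATE_NAMES)
            if unknown:
                raise ValueError(f"{field_name}: unknown states {sorted(unknown)}")
            missing = set(STATE_NAMES) - set(table)
            if missing:
                raise ValueError(f"{field_name}: missing states {sorted(missing)}")
        unknown = set(self.complication_phases) - set(STATE_NAMES)
        if unknown:
            raise ValueError(f"complication_phases: unknown states {sorted(unknown)}")
        for state, col in self.resource_columns.items():
            if col not in PHASES:
                raise ValueError(f"resource_columns.{state}: unknown column {col!r}")
        return self


# ---------------------------------------------------------------------------
# analysis settings


class AnalysisSettings(_Strict):
    horizon_months: int = Field(ge=3)
    discount_rate_costs: float = Field(ge=0.0, le=1.0)
    discount_rate_effects: float = Field(ge=0.0, le=1.0)
    stopping_rule: bool
    include_complications: bool
    include_transport: bool
    include_parking: bool
    include_indirect: bool
    dose: Literal["2mg", "1.5mg"]
    population: Literal["all", "women"]
    endpoint: Literal["bowel_function", "pacqol_satisfaction"]
    hospital_costing: Literal["dbc", "los_daily"]
    target_year: int
    cycle_days: float = Field(gt=0.0)
    first_pack_days: int = Field(gt=0)
    maintenance_days_year1: float = Field(gt=0.0)
    maintenance_days_later: float = Field(gt=0.0)
    treatment_day_cap: float = Field(gt=0.0, le=366.0)
    monthly_death_probability: float = Field(ge=0.0, le=1.0)
    oneway_response_linkage: Literal["attrition", "ratio"]

    @model_validator(mode="after")
    def _cap_consistent(self) -> "AnalysisSettings":
        if self.maintenance_days_year1 > self.treatment_day_cap:
            raise ValueError(
                "maintenance_days_year1 exceeds treatment_day_cap"
            )
        if self.maintenance_days_later > self.treatment_day_cap:
            raise ValueError("maintenance_days_later exceeds treatment_day_cap")
        return self


class PSASettings(_Strict):
    n_draws: int = Field(ge=1)
    probability_se_fraction: float = Field(ge=0.0)
    resource_se_fraction: float = Field(ge=0.0)
    utility_se: float = Field(ge=0.0)
    threshold_max: float = Field(gt=0.0)
    threshold_step: float = Field(gt=0.0)


class ModelParameters(_Strict):
    """The complete, validated input bundle for the decision model."""

    clinical: ClinicalInputs
    utilities: UtilitySet
    resources: ResourceTable
    costs: CostInputs
    mapping: StateMapping
    analysis: AnalysisSettings
    psa: PSASettings

    def copy_deep(self) -> "ModelParameters":
        return self.model_copy(deep=True)

    # -- convenience -------------------------------------------------------

    def active_arms(self) -> TrialArms:
        """Response evidence selected by the population/endpoint settings."""
        if self.analysis.endpoint == "pacqol_satisfaction":
            return self.clinical.pacqol_satisfaction
        if self.analysis.population == "women":
            return self.clinical.bowel_function_women
        return self.clinical.bowel_function

    def unit_cost(self, name: str) -> float:
        """Unit cost inflated to the analysis target year."""
        item = self.costs.units[name]
        return inflate(
            item.cost, item.costing_year, self.analysis.target_year,
            self.costs.inflation,
        )


# ---------------------------------------------------------------------------
# operations


def period_to_monthly(p: float, period_months: int | float) -> float:
    """Convert a period probability to a monthly one at constant rate.

    Uses ``1 - (1 - p) ** (1 / k)``, the standard actuarial conversion: the
    monthly probability that, compounded over ``k`` months, reproduces the
    period probability.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if period_months < 1:
        raise ValueError("period_months must be >= 1")
    return 1.0 - (1.0 - p) ** (1.0 / period_months)


def inflate(
    cost: float,
    from_year: int,
    to_year: int,
    rates: Mapping[int, float],
) -> float:
    """Inflate ``cost`` from its costing year to the target year.

    The rate labelled ``y`` applies to the ``y -> y + 1`` step, so the product
    runs over ``from_year .. to_year - 1``.  Identity when the years match.
    """
    if to_year < from_year:
        raise ValueError("target year precedes costing year")
    factor = 1.0
    for year in range(from_year, to_year):
        if year not in rates:
            raise KeyError(f"no inflation rate for year {year}")
        factor *= 1.0 + rates[year]
    return cost * factor


def weighted_laxative_daily_cost(
    laxatives: Mapping[str, LaxativeItem],
    phase: Literal["start", "switch"],
) -> float:
    """Share-weighted daily cost of the laxative basket (nominal prices)."""
    attr = "start_share" if phase == "start" else "switch_share"
    total_share = sum(getattr(it, attr) for it in laxatives.values())
    if abs(total_share - 1.0) > 0.005:
        raise ValueError(f"{phase} shares sum to {total_share:.4f}, expected 1.0")
    return sum(getattr(it, attr) * it.daily_cost for it in laxatives.values())


def proportion_ci(
    evidence: ResponseEvidence, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided Wilson score interval for a binomial proportion."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    n = evidence.total
    if n == 0:
        raise ValueError("total must be positive")
    p = evidence.responders / n
    z = norm.ppf(0.5 + level / 2.0)
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    low = 0.0 if evidence.responders == 0 else max(0.0, centre - half)
    high = 1.0 if evidence.responders == n else min(1.0, centre + half)
    return low, high


# ---------------------------------------------------------------------------
# configuration plumbing


def _deep_merge(base: dict[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    merged = dict(base)
    for key, value in override.items():
        if (
            key in merged
            and isinstance(merged[key], dict)
            and isinstance(value, Mapping)
        ):
            merged[key] = _deep_merge(merged[key], value)
        else:
            merged[key] = copy.deepcopy(value)
    return merged


def _default_dict() -> dict[str, Any]:
    ref = importlib.resources.files("prucea.data") / "default_config.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def default_parameters() -> ModelParameters:
    """The full default bundle (every numeric field equals its printed value,
    plus the documented mapping/calibration defaults)."""
    return ModelParameters.model_validate(_default_dict())


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> ModelParameters:
    """Load defaults, deep-merge a YAML file and explicit overrides, validate.

    ``overrides`` may use nested dicts or dotted keys
    (``{"analysis.horizon_months": 36}``).
    """
    data = _default_dict()
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        with open(p, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh)
        if user is None:
            user = {}
        if not isinstance(user, Mapping):
            raise ValueError(f"config file {p} does not contain a mapping")
        data = _deep_merge(data, user)
    if overrides:
        expanded: dict[str, Any] = {}
        for key, value in overrides.items():
            parts = key.split(".")
            node = expanded
            for part in parts[:-1]:
                node = node.setdefault(part, {})
            node[parts[-1]] = value
        data = _deep_merge(data, expanded)
    return ModelParameters.model_validate(data)


# ---------------------------------------------------------------------------
# printed-source fidelity export


def fidelity_table(params: ModelParameters | None = None):
    """DataFrame of printed inputs next to the bundle values (audit trail)."""
    import pandas as pd

    p = params or default_parameters()
    bf = p.clinical.bowel_function
    rows: list[tuple[str, float, float, str]] = [
        ("prucalopride week-4 responders", bf.prucalopride.week4.responders, 178, "response table"),
        ("prucalopride week-12 responders", bf.prucalopride.week12.responders, 151, "response table"),
        ("placebo-proxy week-4 responders", bf.laxative.week4.responders, 68, "response table"),
        ("placebo-proxy week-12 responders", bf.laxative.week12.responders, 73, "response table"),
        ("switch response", p.clinical.switch_response, 0.654, "Delphi panel"),
        ("referral after failure", p.clinical.referral_after_failure, 0.282, "Delphi panel"),
        ("hospitalization after failure", p.clinical.hospitalization_after_failure, 0.049, "Delphi panel"),
        ("utility prucalopride start", p.utilities.prucalopride.start, 0.786, "utility mapping"),
        ("utility prucalopride responder", p.utilities.prucalopride.responder, 0.890, "utility mapping"),
        ("utility laxative responder", p.utilities.laxative.responder, 0.879, "utility mapping"),
        ("utility dropout", p.utilities.dropout, 0.784, "utility mapping"),
        ("prucalopride 2 mg first-pack daily", p.costs.prucalopride.mg2.first_pack_daily, 2.77, "price list"),
        ("prucalopride 2 mg daily thereafter", p.costs.prucalopride.mg2.after_pack_daily, 2.49, "price list"),
        ("prescription fee", p.costs.prescription_fee, 6.35, "price list"),
        ("PCP consultation", p.costs.units["pcp"].cost, 28.00, "costing manual"),
        ("specialist (costing manual)", p.costs.units["specialist_manual"].cost, 72.00, "costing manual"),
        ("DBC polyclinic tariff", p.costs.units["dbc_specialist"].cost, 195.89, "DBC list"),
        ("DBC hospitalization tariff", p.costs.units["dbc_hospitalization"].cost, 3102.00, "DBC list"),
        ("cost per km", p.costs.transport.cost_per_km, 0.20, "costing manual"),
        ("inflation 2009", p.costs.inflation[2009], 0.012, "statistics office"),
        ("inflation 2010", p.costs.inflation[2010], 0.013, "statistics office"),
    ]
    printed_comp = {
        "hemorrhoids": 0.19,
        "anal_fissures": 0.07,
        "fecal_incontinence": 0.08,
        "perianal_thrombosis": 0.07,
        "rectal_prolapse": 0.034,
        "fecal_impaction": 0.141,
    }
    for name, printed in printed_comp.items():
        rows.append(
            (
                f"complication {name} weeks 1-4",
                p.clinical.complications[name].weeks_1_4,
                printed,
                "Delphi panel",
            )
        )
    return pd.DataFrame(rows, columns=["parameter", "value", "printed", "source"])
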