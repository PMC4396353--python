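"""Per-cycle costing of state occupancy.

Five cost components are computed per (arm, health state, cycle): drug
acquisition (including the fixed prescription fee), medical resource use
(consultations and procedures), expected complication management, patient
transport, and — scenario only — productivity losses.  All unit costs are
inflated from their costing year to the analysis target year.

The mapping from health states to printed resource/complication columns and
to the specialist tariff (DBC episode vs costing-manual consultation) lives in
the parameter bundle and is documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import HealthState, N_STATES
from .parameters import (
    ModelParameters,
    inflate,
    period_to_monthly,
    weighted_laxative_daily_cost,
)

__all__ = [
    "COMPONENTS",
    "StateCostProfile",
    "CostLedger",
    "drug_cost_per_cycle",
    "resource_cost_per_cycle",
    "complication_cost_per_cycle",
    "transport_cost_per_cycle",
    "indirect_cost_per_cycle",
    "build_cost_profiles",
    "hospitalization_cost",
]

COMPONENTS = ("drug", "medical", "complication", "transport", "indirect")

#: laxative basket phase per state: switch-phase weights after a failure
_LAX_PHASE = {
    HealthState.START_W1_4: "start",
    HealthState.START_W5_8: "start",
    HealthState.START_W9_12: "start",
    HealthState.MAINTENANCE: "start",
    HealthState.SWITCH_W1_4: "switch",
    HealthState.SWITCH_W5_8: "switch",
    HealthState.SWITCH_W9_12: "switch",
    HealthState.SWITCH_MAINTENANCE: "switch",
    HealthState.DROPOUT: "switch",
}

_RESPONDER_STATES = frozenset(
    {HealthState.MAINTENANCE, HealthState.SWITCH_MAINTENANCE}
)

#: face-to-face consultation types and their travel distance key
_FACE_TO_FACE = {
    "specialist": "km_specialist",
    "pcp": "km_pcp",
    "nurse": "km_pcp",  # nurse co-located with the PCP practice
    "dietician": "km_dietician",
}

_CONSULT_UNIT = {
    "specialist_telephone": "pcp_telephone",  # no separate tariff printed
    "pcp": "pcp",
    "pcp_telephone": "pcp_telephone",
    "nurse": "nurse",
    "dietician": "dietician",
}


def _state_key(state: HealthState) -> str:
    return state.name.lower()


def _specialist_unit(params: ModelParameters, state: HealthState) -> float:
    tariff = params.mapping.specialist_tariff[_state_key(state)]
    name = "dbc_specialist" if tariff == "dbc" else "specialist_manual"
    return params.unit_cost(name)


def _prucalopride_schedule(params: ModelParameters):
    """Daily prices for the configured dose; the 1.5 mg scenario prices the
    day at the mean of the 1 mg and 2 mg rates (50/50 dose split)."""
    prices = params.costs.prucalopride
    year = prices.mg2.costing_year
    rates = params.costs.inflation
    target = params.analysis.target_year

    def infl(x: float) -> float:
        return inflate(x, year, target, rates)

    if params.analysis.dose == "2mg":
        return infl(prices.mg2.first_pack_daily), infl(prices.mg2.after_pack_daily)
    first = (prices.mg1.first_pack_daily + prices.mg2.first_pack_daily) / 2.0
    after = (prices.mg1.after_pack_daily + prices.mg2.after_pack_daily) / 2.0
    return infl(first), infl(after)


def _laxative_daily(params: ModelParameters, phase: str) -> float:
    nominal = weighted_laxative_daily_cost(params.costs.laxatives, phase)
    year = next(iter(params.costs.laxatives.values())).costing_year
    return inflate(nominal, year, params.analysis.target_year, params.costs.inflation)


def drug_cost_per_cycle(
    arm: str,
    state: HealthState,
    cycle: int,
    params: ModelParameters,
) -> float:
    """Drug acquisition cost (including prescription fees) for one cycle.

    Prucalopride start states: the first cycle is priced on the 28-day
    starter pack, later start cycles at the post-pack daily rate over a
    30.4-day month.  Maintenance spreads the annual treatment-day allowance
    (130 days in year 1 after the 90-day start phase, 220 days thereafter)
    uniformly over that year's maintenance cycles, with one prescription fee
    per 28 treatment days.  Switch/drop-out states and the whole comparator
    arm are priced on the share-weighted laxative basket.
    """
    if arm not in ("prucalopride", "laxative"):
        raise ValueError(f"unknown arm {arm!r}")
    a = params.analysis
    fee = params.costs.prescription_fee
    on_prucalopride = arm == "prucalopride" and state in (
        HealthState.START_W1_4,
        HealthState.START_W5_8,
        HealthState.START_W9_12,
        HealthState.MAINTENANCE,
    )
    if on_prucalopride:
        first_daily, after_daily = _prucalopride_schedule(params)
        if state == HealthState.START_W1_4:
            return first_daily * a.first_pack_days + fee
        if state in (HealthState.START_W5_8, HealthState.START_W9_12):
            return after_daily * a.cycle_days + fee
        # maintenance
        year = cycle // 12
        days = a.maintenance_days_year1 if year == 0 else a.maintenance_days_later
        days = min(days, a.treatment_day_cap)
        n_cycles = 9 if year == 0 else 12  # maintenance starts at cycle 3
        annual = days * after_daily + (days / 28.0) * fee
        return annual / n_cycles
    daily = _laxative_daily(params, _LAX_PHASE[state])
    return daily * a.cycle_days + fee


def resource_cost_per_cycle(state: HealthState, params: ModelParameters) -> float:
    """Consultation and procedure cost for one cycle in ``state``."""
    column = params.mapping.resource_columns[_state_key(state)]
    total = 0.0
    for item, row in params.resources.consultations.items():
        count = row[column]
        if item == "specialist":
            unit = _specialist_unit(params, state)
        elif item == "specialist_telephone":
            unit = params.unit_cost(_CONSULT_UNIT[item])
        else:
            unit = params.unit_cost(_CONSULT_UNIT[item])
        total += count * unit
    for item, row in params.resources.procedures.items():
        total += row[column] * params.costs.procedure_prices.get(item, 0.0)
    return total


def hospitalization_cost(params: ModelParameters, complication: str) -> float:
    """Cost of one constipation-related hospitalization.

    Default: the fixed DBC hospitalization tariff.  The length-of-stay
    scenario prices the stay as LOS x daily cost, where the daily cost is the
    DBC tariff divided by the incidence-weighted mean LOS across
    complications (cost-neutral at baseline, responsive to LOS changes).
    """
    dbc = params.unit_cost("dbc_hospitalization")
    if params.analysis.hospital_costing == "dbc":
        return dbc
    mgmt = params.resources.complication_management
    probs = params.clinical.complications
    weights = {
        name: probs[name].weeks_1_4 * mgmt[name].hospitalization_fraction
        for name in mgmt
    }
    total_w = sum(weights.values())
    mean_los = sum(w * mgmt[n].los_days for n, w in weights.items()) / total_w
    daily = dbc / mean_los
    return mgmt[complication].los_days * daily


def complication_cost_per_cycle(
    state: HealthState, params: ModelParameters
) -> float:
    """Expected monthly complication-management cost in ``state``.

    The Delphi period probability of each complication (for the column mapped
    to this state) is converted to a monthly probability and multiplied by the
    management bundle: PCP and specialist consultations plus the expected
    hospitalization cost.  States without a mapped complication phase accrue
    nothing, as does every state when complications are excluded.
    """
    if not params.analysis.include_complications:
        return 0.0
    phase = params.mapping.complication_phases.get(_state_key(state))
    if phase is None:
        return 0.0
    pcp_unit = params.unit_cost("pcp")
    spec_unit = params.unit_cost("dbc_specialist")
    total = 0.0
    for name, rates in params.clinical.complications.items():
        p_period = getattr(rates, phase.column)
        p_month = period_to_monthly(p_period, phase.period_months)
        mgmt = params.resources.complication_management[name]
        bundle = (
            mgmt.pcp * pcp_unit
            + mgmt.specialist * spec_unit
            + mgmt.hospitalization_fraction * hospitalization_cost(params, name)
        )
        total += p_month * bundle
    return total


def transport_cost_per_cycle(state: HealthState, params: ModelParameters) -> float:
    """Round-trip travel cost for the face-to-face contacts of one cycle."""
    if not params.analysis.include_transport:
        return 0.0
    t = params.costs.transport
    km_cost = inflate(
        t.cost_per_km, t.costing_year, params.analysis.target_year,
        params.costs.inflation,
    )
    column = params.mapping.resource_columns[_state_key(state)]
    total = 0.0
    for item, km_key in _FACE_TO_FACE.items():
        count = params.resources.consultations[item][column]
        distance = getattr(t, km_key)
        total += count * 2.0 * distance * km_cost
        if params.analysis.include_parking:
            total += count * t.parking
    return total


def indirect_cost_per_cycle(state: HealthState, params: ModelParameters) -> float:
    """Monthly productivity loss (scenario only), zero for responder states."""
    if not params.analysis.include_indirect:
        return 0.0
    if state in _RESPONDER_STATES:
        return 0.0
    ind = params.costs.indirect
    return (
        ind.working_age_share
        * ind.absence_share
        * ind.days_missed_per_month
        * ind.hours_per_day
        * ind.cost_per_hour
    )


@dataclass(frozen=True)
class StateCostProfile:
    """Per-cycle cost components, arrays of shape ``(horizon, 9)``."""

    arm: str
    drug: np.ndarray
    medical: np.ndarray
    complication: np.ndarray
    transport: np.ndarray
    indirect: np.ndarray

    def component(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def total(self) -> np.ndarray:
        return self.drug + self.medical + self.complication + self.transport + self.indirect


def build_cost_profiles(
    params: ModelParameters, horizon: int | None = None
) -> dict[str, StateCostProfile]:
    """Compose all cost components for every (arm, state, cycle)."""
    h = horizon if horizon is not None else params.analysis.horizon_months
    profiles: dict[str, StateCostProfile] = {}
    for arm in ("prucalopride", "laxative"):
        drug = np.zeros((h, N_STATES))
        medical = np.zeros((h, N_STATES))
        complication = np.zeros((h, N_STATES))
        transport = np.zeros((h, N_STATES))
        indirect = np.zeros((h, N_STATES))
        for state in HealthState:
            j = int(state)
            medical[:, j] = resource_cost_per_cycle(state, params)
            complication[:, j] = complication_cost_per_cycle(state, params)
            transport[:, j] = transport_cost_per_cycle(state, params)
            indirect[:, j] = indirect_cost_per_cycle(state, params)
            for t in range(h):
                drug[t, j] = drug_cost_per_cycle(arm, state, t, params)
        profiles[arm] = StateCostProfile(
            arm=arm,
            drug=drug,
            medical=medical,
            complication=complication,
            transport=transport,
            indirect=indirect,
        )
    return profiles


@dataclass(frozen=True)
class CostLedger:
    """Discounted cost accrual per arm, cycle and component."""

    arm: str
    per_cycle: pd.DataFrame  # columns: cycle, component, cost

    @property
    def total(self) -> float:
        return float(self.per_cycle["cost"].sum())

    def component_total(self, name: str) -> float:
        sel = self.per_cycle[self.per_cycle["component"] == name]
        return float(sel["cost"].sum())


def accrue_costs(
    trace_occupancy: np.ndarray,
    profile: StateCostProfile,
    discount_rate: float,
    survival: np.ndarray | None = None,
) -> CostLedger:
    """Accrue discounted costs over a trace.

    ``trace_occupancy`` has ``horizon + 1`` rows; row ``t`` is the occupancy
    during month ``t + 1``, and the final row (the post-horizon state) does
    not accrue.  Discounting is annual: all cycles of year ``y`` share the
    factor ``1 / (1 + rate) ** y``.  ``survival`` optionally weights each
    cycle (mortality hook).
    """
    h = profile.drug.shape[0]
    occ = trace_occupancy[:h]
    if survival is not None:
        occ = occ * survival[:h, None]
    years = np.arange(h) // 12
    df = 1.0 / (1.0 + discount_rate) ** years
    records = []
    for name in COMPONENTS:
        comp = profile.component(name)
        per_cycle = (occ * comp).sum(axis=1) * df
        for t in range(h):
            records.append((t, name, per_cycle[t]))
    frame = pd.DataFrame(records, columns=["cycle", "component", "cost"])
    return CostLedger(arm=profile.arm, per_cycle=frame)
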