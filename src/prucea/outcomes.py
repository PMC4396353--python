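"""QALY accrual, discounting and incremental cost-effectiveness statistics."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import CohortTrace, HealthState
from .parameters import ModelParameters, UtilitySet

__all__ = [
    "state_utilities",
    "discount_factor",
    "accrue_qalys",
    "CEAResult",
    "incremental_analysis",
    "net_monetary_benefit",
]


def state_utilities(utilities: UtilitySet, arm: str) -> np.ndarray:
    """Annual utility per health state for one arm, indexed by state."""
    if arm == "prucalopride":
        own = utilities.prucalopride
    elif arm == "laxative":
        own = utilities.laxative
    else:
        raise ValueError(f"unknown arm {arm!r}")
    u = np.empty(len(HealthState))
    u[HealthState.START_W1_4] = own.start
    u[HealthState.START_W5_8] = own.weeks_5_12
    u[HealthState.START_W9_12] = own.weeks_5_12
    u[HealthState.MAINTENANCE] = own.responder
    for s in (HealthState.SWITCH_W1_4, HealthState.SWITCH_W5_8, HealthState.SWITCH_W9_12):
        u[s] = utilities.switch_start
    u[HealthState.SWITCH_MAINTENANCE] = utilities.switch_responder
    u[HealthState.DROPOUT] = utilities.dropout
    return u


def discount_factor(cycle: int, annual_rate: float) -> float:
    """Annual-step discount factor for a 1-based monthly cycle index.

    All cycles of the first year are undiscounted; year ``y`` (0-based) gets
    ``1 / (1 + rate) ** y``.
    """
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    year = (cycle - 1) // 12
    return 1.0 / (1.0 + annual_rate) ** year


def accrue_qalys(
    trace: CohortTrace,
    utilities: UtilitySet,
    arm: str,
    discount_rate: float = 0.0,
    survival: np.ndarray | None = None,
) -> float:
    """Discounted QALY total over a cohort trace.

    Each month in a state contributes one twelfth of its annual utility,
    weighted by occupancy and the annual discount factor.  Row ``t`` of the
    trace is the occupancy during month ``t + 1``; the final row does not
    accrue.
    """
    u = state_utilities(utilities, arm)
    h = trace.n_cycles
    occ = trace.occupancy[:h]
    if survival is not None:
        occ = occ * survival[:h, None]
    years = np.arange(h) // 12
    df = 1.0 / (1.0 + discount_rate) ** years
    return float(((occ @ u) / 12.0 * df).sum())


@dataclass(frozen=True)
class CEAResult:
    """Per-arm discounted totals and incremental statistics."""

    cost_intervention: float
    cost_comparator: float
    qaly_intervention: float
    qaly_comparator: float
    intervention: str = "prucalopride"
    comparator: str = "laxative"

    @property
    def delta_cost(self) -> float:
        return self.cost_intervention - self.cost_comparator

    @property
    def delta_qaly(self) -> float:
        return self.qaly_intervention - self.qaly_comparator

    @property
    def dominance(self) -> str | None:
        """Quadrant label, or ``None`` when a meaningful ICER exists."""
        dc, de = self.delta_cost, self.delta_qaly
        if dc == 0.0 and de == 0.0:
            return "equivalent"
        if dc <= 0.0 and de >= 0.0:
            return "dominant"
        if dc >= 0.0 and de <= 0.0:
            return "dominated"
        return None

    @property
    def icer(self) -> float:
        """Incremental cost per QALY gained (NaN when dominance applies)."""
        if self.dominance is not None:
            return math.nan
        return self.delta_cost / self.delta_qaly

    def to_frame(self) -> pd.DataFrame:
        """Three-row summary in the usual cost/QALY/ICER table layout."""
        icer = self.icer
        return pd.DataFrame(
            [
                (self.intervention, self.cost_intervention, self.qaly_intervention, ""),
                (self.comparator, self.cost_comparator, self.qaly_comparator, ""),
                (
                    "difference",
                    self.delta_cost,
                    self.delta_qaly,
                    self.dominance if self.dominance is not None else f"{icer:.0f}",
                ),
            ],
            columns=["arm", "cost", "qalys", "icer"],
        )


def incremental_analysis(
    cost_a: float, cost_b: float, qaly_a: float, qaly_b: float
) -> CEAResult:
    """Incremental statistics of strategy A (intervention) vs B (comparator)."""
    return CEAResult(
        cost_intervention=cost_a,
        cost_comparator=cost_b,
        qaly_intervention=qaly_a,
        qaly_comparator=qaly_b,
    )


def net_monetary_benefit(result: CEAResult, threshold: float) -> float:
    """``threshold * dQALY - dCost`` at willingness-to-pay ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return threshold * result.delta_qaly - result.delta_cost
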