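"""Nine-state Markov structure and cohort propagation.

The model follows a treated cohort through monthly cycles: three start states
covering the first 12 weeks of therapy, an absorbing maintenance state for
responders, a mirrored switch pathway for week-4 (and late) failures, an
absorbing switch-maintenance state for second-line responders, and an
absorbing drop-out state for second-line failures.  With the week-4 stopping
rule active, non-responders leave initial therapy after the first cycle; late
failures (the week-4 minus week-12 response mass) exit at the end of the
start pathway.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

__all__ = [
    "HealthState",
    "ABSORBING_STATES",
    "TransitionMatrix",
    "CohortTrace",
    "build_transitions",
    "run_cohort",
    "microsimulate",
]


class HealthState(IntEnum):
    START_W1_4 = 0
    START_W5_8 = 1
    START_W9_12 = 2
    MAINTENANCE = 3
    SWITCH_W1_4 = 4
    SWITCH_W5_8 = 5
    SWITCH_W9_12 = 6
    SWITCH_MAINTENANCE = 7
    DROPOUT = 8


N_STATES = len(HealthState)

ABSORBING_STATES = frozenset(
    {HealthState.MAINTENANCE, HealthState.SWITCH_MAINTENANCE, HealthState.DROPOUT}
)

#: transitions drawn in the model structure (from-state -> allowed to-states)
ALLOWED_TRANSITIONS: dict[HealthState, frozenset[HealthState]] = {
    HealthState.START_W1_4: frozenset(
        {HealthState.START_W5_8, HealthState.SWITCH_W1_4}
    ),
    HealthState.START_W5_8: frozenset(
        {HealthState.START_W9_12, HealthState.SWITCH_W1_4}
    ),
    HealthState.START_W9_12: frozenset(
        {HealthState.MAINTENANCE, HealthState.SWITCH_W1_4}
    ),
    HealthState.MAINTENANCE: frozenset({HealthState.MAINTENANCE}),
    HealthState.SWITCH_W1_4: frozenset(
        {HealthState.SWITCH_W5_8, HealthState.DROPOUT}
    ),
    HealthState.SWITCH_W5_8: frozenset(
        {HealthState.SWITCH_W9_12, HealthState.DROPOUT}
    ),
    HealthState.SWITCH_W9_12: frozenset(
        {HealthState.SWITCH_MAINTENANCE, HealthState.DROPOUT}
    ),
    HealthState.SWITCH_MAINTENANCE: frozenset({HealthState.SWITCH_MAINTENANCE}),
    HealthState.DROPOUT: frozenset({HealthState.DROPOUT}),
}


@dataclass(frozen=True)
class TransitionMatrix:
    """Cycle-indexed transition probabilities, shape ``(horizon, 9, 9)``.

    ``probs[t]`` propagates occupancy from cycle ``t`` to cycle ``t + 1``.
    """

    probs: np.ndarray
    arm: str = ""

    def __post_init__(self) -> None:
        p = self.probs
        if p.ndim != 3 or p.shape[1:] != (N_STATES, N_STATES):
            raise ValueError(f"expected (horizon, 9, 9) array, got {p.shape}")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("transition probabilities outside [0, 1]")
        rowsums = p.sum(axis=2)
        if not np.allclose(rowsums, 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        for s, allowed in ALLOWED_TRANSITIONS.items():
            forbidden = [j for j in range(N_STATES) if HealthState(j) not in allowed]
            if np.any(np.abs(p[:, int(s), forbidden]) > 1e-12):
                raise ValueError(f"forbidden transition out of {s.name}")

    @property
    def horizon(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy fractions per cycle; row 0 is the starting cohort."""

    occupancy: np.ndarray  # shape (horizon + 1, 9)
    arm: str = ""

    def __post_init__(self) -> None:
        occ = self.occupancy
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise ValueError(f"expected (cycles, 9) array, got {occ.shape}")
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("cycle occupancies must sum to 1")
        absorbing = [int(s) for s in ABSORBING_STATES]
        if np.any(np.diff(occ[:, absorbing], axis=0) < -1e-10):
            raise ValueError("absorbing-state occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        """Number of monthly cycles covered (rows minus the starting row)."""
        return self.occupancy.shape[0] - 1

    def state(self, state: HealthState) -> np.ndarray:
        return self.occupancy[:, int(state)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format trace (arm, cycle, state, occupancy)."""
        records = [
            (self.arm, t, HealthState(j).name, self.occupancy[t, j])
            for t in range(self.occupancy.shape[0])
            for j in range(N_STATES)
        ]
        return pd.DataFrame(records, columns=["arm", "cycle", "state", "occupancy"])


def build_transitions(
    r4: float,
    r12: float,
    switch_response: float,
    horizon: int,
    stopping_rule: bool = True,
    arm: str = "",
) -> TransitionMatrix:
    """Build the cycle-indexed transition matrix for one strategy arm.

    ``r4`` and ``r12`` are the unconditional week-4 and weeks-1-12 response
    probabilities; the engine converts them to the conditional week-12
    retention ``r12 / r4`` among week-4 responders, capped at 1 (the placebo
    proxy prints a week-12 response slightly above its week-4 response, which
    the pathway structure cannot represent).  With the stopping rule off,
    everyone remains on initial therapy for 12 weeks and the full failure mass
    ``1 - r12`` exits into the switch pathway at the end of the start phase.
    """
    for name, v in (("r4", r4), ("r12", r12), ("switch_response", switch_response)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if horizon < 3:
        raise ValueError("horizon must cover the three initial phases")
    if r4 == 0.0 and r12 > 0.0:
        raise ValueError("r4 = 0 with r12 > 0: conditional retention undefined")

    if stopping_rule:
        p_continue = r4
        retention = min(1.0, r12 / r4) if r4 > 0 else 0.0
    else:
        p_continue = 1.0
        retention = r12

    S = HealthState
    m = np.zeros((N_STATES, N_STATES))
    m[S.START_W1_4, S.START_W5_8] = p_continue
    m[S.START_W1_4, S.SWITCH_W1_4] = 1.0 - p_continue
    m[S.START_W5_8, S.START_W9_12] = 1.0
    m[S.START_W9_12, S.MAINTENANCE] = retention
    m[S.START_W9_12, S.SWITCH_W1_4] = 1.0 - retention
    m[S.SWITCH_W1_4, S.SWITCH_W5_8] = switch_response
    m[S.SWITCH_W1_4, S.DROPOUT] = 1.0 - switch_response
    m[S.SWITCH_W5_8, S.SWITCH_W9_12] = 1.0
    m[S.SWITCH_W9_12, S.SWITCH_MAINTENANCE] = 1.0
    for s in ABSORBING_STATES:
        m[s, s] = 1.0

    probs = np.broadcast_to(m, (horizon, N_STATES, N_STATES)).copy()
    return TransitionMatrix(probs=probs, arm=arm)


def run_cohort(tm: TransitionMatrix, horizon: int | None = None) -> CohortTrace:
    """Propagate a unit cohort starting in START_W1_4 through the matrix."""
    h = tm.horizon if horizon is None else horizon
    if h < 3:
        raise ValueError("horizon must cover the three initial phases")
    if h > tm.horizon:
        raise ValueError("horizon exceeds the transition matrix")
    occ = np.zeros((h + 1, N_STATES))
    occ[0, HealthState.START_W1_4] = 1.0
    for t in range(h):
        occ[t + 1] = occ[t] @ tm.probs[t]
    return CohortTrace(occupancy=occ, arm=tm.arm)


def microsimulate(
    tm: TransitionMatrix,
    n_patients: int,
    horizon: int | None = None,
    seed: int = 0,
) -> CohortTrace:
    """Empirical trace from independent patient random walks.

    Validation oracle for :func:`run_cohort`: by the law of large numbers the
    empirical occupancy converges to the deterministic cohort trace.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    h = tm.horizon if horizon is None else horizon
    rng = np.random.default_rng(seed)
    states = np.full(n_patients, int(HealthState.START_W1_4), dtype=np.int64)
    occ = np.zeros((h + 1, N_STATES))
    occ[0] = np.bincount(states, minlength=N_STATES) / n_patients
    for t in range(h):
        cum = np.cumsum(tm.probs[t], axis=1)
        u = rng.random(n_patients)
        new_states = np.empty_like(states)
        for s in np.unique(states):
            mask = states == s
            new_states[mask] = np.searchsorted(cum[s], u[mask], side="right")
        states = np.minimum(new_states, N_STATES - 1)
        occ[t + 1] = np.bincount(states, minlength=N_STATES) / n_patients
    return CohortTrace(occupancy=occ, arm=tm.arm)
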