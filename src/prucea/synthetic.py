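"""Synthetic trial and resource-panel generators.

These generators emulate the data-generating layers behind the model inputs:
the pivotal-trial responder counts (per-patient binomial response at week 4
and conditional retention through week 12) and the elicited resource-use
quantities (gamma-distributed panel estimates).  They close the loop
simulate -> estimate -> model, so every downstream stage can be validated
against known generating parameters without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ArmParameters, ResponseEvidence

__all__ = [
    "SyntheticTrial",
    "simulate_trial",
    "estimate_arm_parameters",
    "SyntheticResourcePanel",
    "simulate_resource_panel",
]


@dataclass(frozen=True)
class SyntheticTrial:
    """Per-patient responder flags for one simulated trial arm.

    Week-12 response is nested within week-4 response, mirroring the model's
    conditional retention structure (a week-12 responder must have responded
    at week 4).
    """

    week4: np.ndarray  # bool, shape (n,)
    week12: np.ndarray  # bool, shape (n,)
    pacqol: np.ndarray  # bool, shape (n,)
    p4: float
    p12: float
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.week12 & ~self.week4):
            raise ValueError("week-12 responders must be week-4 responders")

    @property
    def n(self) -> int:
        return self.week4.size

    def to_frame(self, arm: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient": np.arange(self.n),
                "arm": arm,
                "week4": self.week4.astype(int),
                "week12": self.week12.astype(int),
                "pacqol": self.pacqol.astype(int),
            }
        )


def simulate_trial(
    p4: float,
    p12: float,
    n: int,
    seed: int = 0,
    p_pacqol: float | None = None,
) -> SyntheticTrial:
    """Simulate one trial arm of ``n`` patients.

    Week-4 response is Bernoulli(``p4``); week-4 responders retain response
    through week 12 with the conditional probability ``p12 / p4``.  The
    PAC-QOL satisfaction flag is drawn independently with probability
    ``p_pacqol`` (defaults to ``p4``).
    """
    if not 0.0 <= p12 <= p4 <= 1.0:
        raise ValueError("require 0 <= p12 <= p4 <= 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    week4 = rng.random(n) < p4
    retention = p12 / p4 if p4 > 0 else 0.0
    week12 = week4 & (rng.random(n) < retention)
    pq = p4 if p_pacqol is None else p_pacqol
    pacqol = rng.random(n) < pq
    return SyntheticTrial(
        week4=week4, week12=week12, pacqol=pacqol, p4=p4, p12=p12, seed=seed
    )


def estimate_arm_parameters(trial: SyntheticTrial) -> ArmParameters:
    """Recover arm-level response evidence from a simulated trial.

    Feeding the result into the transition builder yields a cohort whose
    cycle-3 maintenance mass equals the observed week-12 proportion exactly.
    """
    n4 = int(trial.week4.sum())
    n12 = int(trial.week12.sum())
    if n12 > 0 and n4 == 0:
        raise ValueError("week-12 responders without week-4 responders")
    return ArmParameters(
        week4=ResponseEvidence(responders=n4, total=trial.n),
        week12=ResponseEvidence(responders=n12, total=trial.n),
    )


@dataclass(frozen=True)
class SyntheticResourcePanel:
    """Gamma-sampled monthly quantities for a panel of virtual respondents."""

    samples: pd.DataFrame  # one column per item, one row per respondent
    means: dict[str, float]
    cv: float
    seed: int

    def panel_means(self) -> pd.Series:
        return self.samples.mean()


def simulate_resource_panel(
    profile: dict[str, float],
    cv: float,
    n: int,
    seed: int = 0,
) -> SyntheticResourcePanel:
    """Sample ``n`` respondents around a resource-use profile.

    Each item is gamma-distributed with mean equal to the profile value and
    standard deviation ``cv`` times the mean (shape ``1 / cv**2``); zero-mean
    items stay identically zero.
    """
    if cv <= 0.0:
        raise ValueError("cv must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    shape = 1.0 / (cv * cv)
    data = {}
    for item, mean in profile.items():
        if mean > 0:
            data[item] = rng.gamma(shape, mean / shape, size=n)
        else:
            data[item] = np.zeros(n)
    return SyntheticResourcePanel(
        samples=pd.DataFrame(data), means=dict(profile), cv=cv, seed=seed
    )
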