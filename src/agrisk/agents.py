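"""Policy agents standing in for human participants, plus the synthetic
cohort generator.

The three named strategies (risk averse, opportunistic, risk tolerant) are
formalized as threshold policies over a perceived-threat estimate.  They
are explicit modeling conventions for generating synthetic behavior with a
controllable risk ordering — not fitted human decision rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .engine import (
    INCREASE,
    NO_ACTION,
    REVEAL_BIOSECURITY,
    REVEAL_DISEASE,
    DecisionAction,
    Observation,
)

__all__ = [
    "Strategy",
    "PolicyParams",
    "LotteryBehavior",
    "CohortSpec",
    "Participant",
    "ThresholdPolicy",
    "perceived_threat",
    "decide",
    "make_cohort",
]


class Strategy(str, Enum):
    RISK_AVERSE = "risk_averse"
    OPPORTUNISTIC = "opportunistic"
    RISK_TOLERANT = "risk_tolerant"


@dataclass(frozen=True)
class PolicyParams:
    """Parameters of one agent's in-game decision rule.

    ``hidden_prior`` is the agent's assumed next-month infection probability
    when every neighbor's status is cloaked; with partial information it is
    downweighted by the fraction of facilities still hidden.
    ``reveal_price_sensitivity`` multiplies the reveal propensity once per
    $1,000 of price above the base $1,000 (default 0.5: propensity halves
    at the $2,000 price point).
    """

    strategy: Strategy = Strategy.OPPORTUNISTIC
    threat_threshold: float = 0.05
    reveal_propensity: float = 0.2
    reveal_price_sensitivity: float = 0.5
    hidden_prior: float = 0.15

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategy", Strategy(self.strategy))
        for name in (
            "threat_threshold",
            "reveal_propensity",
            "reveal_price_sensitivity",
            "hidden_prior",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def perceived_threat(obs: Observation, params: PolicyParams) -> float:
    """Estimated probability the agent's facility is infected next month.

    Known-infected facilities contribute their true transmission
    probability (same kernel as the engine); hidden facilities contribute
    through the configured prior, scaled by the hidden fraction.  Under
    full visibility this equals the engine's combined probability exactly;
    under full cloaking it equals the prior.
    """
    tp = obs.transmission
    d = obs.distances[obs.infection_view == 1.0]
    if d.size:
        raw = np.minimum(tp.p_inf / np.maximum(d, tp.min_distance) ** 2, 1.0)
        p = raw * tp.level_retention(obs.own_level)
        threat_known = 1.0 - float(np.prod(1.0 - p))
    else:
        threat_known = 0.0
    n = obs.infection_view.size
    hidden_fraction = float(np.isnan(obs.infection_view).sum()) / n if n else 0.0
    return float(
        1.0 - (1.0 - threat_known) * (1.0 - params.hidden_prior * hidden_fraction)
    )


def _effective_reveal_propensity(params: PolicyParams, price: float) -> float:
    steps = max(price - 1_000.0, 0.0) / 1_000.0
    return float(
        np.clip(
            params.reveal_propensity * params.reveal_price_sensitivity ** steps,
            0.0,
            1.0,
        )
    )


@dataclass
class ThresholdPolicy:
    """Threshold decision rule implementing the three named strategies."""

    params: PolicyParams

    def choose_reveals(
        self, obs: Observation, rng: np.random.Generator
    ) -> list[DecisionAction]:
        actions: list[DecisionAction] = []
        if obs.can_reveal_disease:
            p = _effective_reveal_propensity(
                self.params, obs.treatment.reveal_price_disease
            )
            if rng.random() < p:
                actions.append(REVEAL_DISEASE)
        if obs.can_reveal_biosecurity:
            p = _effective_reveal_propensity(
                self.params, obs.treatment.reveal_price_biosecurity
            )
            if rng.random() < p:
                actions.append(REVEAL_BIOSECURITY)
        return actions

    def choose_upgrade(
        self, obs: Observation, rng: np.random.Generator
    ) -> DecisionAction | None:
        if not obs.can_upgrade:
            return None
        s = self.params.strategy
        if s is Strategy.RISK_AVERSE:
            return INCREASE
        if s is Strategy.RISK_TOLERANT:
            return None
        if perceived_threat(obs, self.params) >= self.params.threat_threshold:
            return INCREASE
        return None


def decide(
    obs: Observation, params: PolicyParams, rng: np.random.Generator
) -> list[DecisionAction]:
    """One-shot decision for a single month: reveal purchases followed by
    the upgrade choice (evaluated on the same observation).

    The engine's round loop re-observes between the two phases so reveals
    can inform the upgrade; this convenience wrapper composes both phases
    for direct use on a fixed observation.
    """
    policy = ThresholdPolicy(params)
    actions = policy.choose_reveals(obs, rng)
    upgrade = policy.choose_upgrade(obs, rng)
    if upgrade is not None:
        actions.append(upgrade)
    return actions or [NO_ACTION]


@dataclass(frozen=True)
class LotteryBehavior:
    """Generative lottery behavior of a cohort: participants switch from the
    safe to the risky option near ``switch_row`` and flip individual choices
    with ``error_rate`` (inattention / fatigue noise)."""

    switch_row_mean: float = 6.2
    switch_row_sd: float = 2.0
    error_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.switch_row_sd < 0:
            raise ValueError("switch_row_sd must be non-negative")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Distributional description of one synthetic participant group.

    Policy parameters are drawn per participant from truncated normals
    (normal draws clipped to the valid range).
    """

    name: str
    n_participants: int
    strategy: Strategy = Strategy.OPPORTUNISTIC
    threat_threshold_mean: float = 0.05
    threat_threshold_sd: float = 0.02
    reveal_propensity_mean: float = 0.2
    reveal_propensity_sd: float = 0.1
    reveal_price_sensitivity: float = 0.5
    hidden_prior: float = 0.15
    lottery: LotteryBehavior = field(default_factory=LotteryBehavior)

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategy", Strategy(self.strategy))
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if isinstance(self.lottery, dict):
            object.__setattr__(self, "lottery", LotteryBehavior(**self.lottery))


@dataclass(frozen=True)
class Participant:
    participant_id: str
    cohort: str
    policy_params: PolicyParams
    lottery_switch_row: int
    lottery_error_rate: float


def make_cohort(spec: CohortSpec, rng_seed) -> list[Participant]:
    """Draw a reproducible cohort of participant parameter sets."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n = spec.n_participants
    thresholds = np.clip(
        rng.normal(spec.threat_threshold_mean, spec.threat_threshold_sd, n), 0.0, 1.0
    )
    propensities = np.clip(
        rng.normal(spec.reveal_propensity_mean, spec.reveal_propensity_sd, n), 0.0, 1.0
    )
    switch_rows = np.clip(
        np.rint(rng.normal(spec.lottery.switch_row_mean, spec.lottery.switch_row_sd, n)),
        1,
        11,
    ).astype(int)
    participants = []
    for i in range(n):
        participants.append(
            Participant(
                participant_id=f"{spec.name}-{i:03d}",
                cohort=spec.name,
                policy_params=PolicyParams(
                    strategy=spec.strategy,
                    threat_threshold=float(thresholds[i]),
                    reveal_propensity=float(propensities[i]),
                    reveal_price_sensitivity=spec.reveal_price_sensitivity,
                    hidden_prior=spec.hidden_prior,
                ),
                lottery_switch_row=int(switch_rows[i]),
                lottery_error_rate=spec.lottery.error_rate,
            )
        )
    return participants
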