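"""Round and session orchestration: actions, observation masking, economy
bookkeeping, and the month loop.

Flow of one round: the world is freshly initialized (player at biosecurity
"None"), then for up to six months the policy observes a masked view of the
world, optionally purchases reveals (which update its view within the same
month), optionally upgrades its own biosecurity, and the disease spreads.
If the player's facility becomes infected, the round ends immediately and
the infection penalty is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Protocol

import numpy as np

from .economy import EconomyParams
from .treatments import TreatmentSpec, Visibility
from .world import (
    MONTHS_PER_ROUND,
    PLAYER_ID,
    LayoutParams,
    TransmissionParams,
    WorldState,
    init_world,
    step_month,
)

__all__ = [
    "ActionKind",
    "DecisionAction",
    "IllegalActionError",
    "Observation",
    "MonthRecord",
    "RoundResult",
    "RoundState",
    "Policy",
    "observe",
    "apply_action",
    "run_round",
    "run_session",
    "records_to_rows",
]


class ActionKind(str, Enum):
    NO_ACTION = "no_action"
    INCREASE_BIOSECURITY = "increase_biosecurity"
    REVEAL_DISEASE = "reveal_disease"
    REVEAL_BIOSECURITY = "reveal_biosecurity"


@dataclass(frozen=True)
class DecisionAction:
    kind: ActionKind

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ActionKind(self.kind))


NO_ACTION = DecisionAction(ActionKind.NO_ACTION)
INCREASE = DecisionAction(ActionKind.INCREASE_BIOSECURITY)
REVEAL_DISEASE = DecisionAction(ActionKind.REVEAL_DISEASE)
REVEAL_BIOSECURITY = DecisionAction(ActionKind.REVEAL_BIOSECURITY)


class IllegalActionError(ValueError):
    """A policy emitted an action that is illegal in the current state."""


@dataclass
class Observation:
    """Masked per-month view handed to a policy.

    ``infection_view``/``biosecurity_view`` hold one float per computer
    facility: the true value where visible or currently revealed, NaN where
    hidden.  Distances (player to each computer facility) are always
    visible, as in the game's map display.
    """

    month: int
    own_level: int
    balance: float
    distances: np.ndarray
    infection_view: np.ndarray
    biosecurity_view: np.ndarray
    treatment: TreatmentSpec
    transmission: TransmissionParams
    can_reveal_disease: bool
    can_reveal_biosecurity: bool
    can_upgrade: bool


@dataclass(frozen=True)
class MonthRecord:
    round_id: int
    month: int  # 1-based
    actions: tuple[ActionKind, ...]
    spend: float
    post_decision_biosecurity: int
    infected_this_month: bool


@dataclass(frozen=True)
class RoundResult:
    months_played: int
    final_balance_delta: float
    infected: bool
    treatment: TreatmentSpec


@dataclass
class RoundState:
    """Mutable in-round state: world, budget, reveal masks, monthly flags."""

    world: WorldState
    treatment: TreatmentSpec
    economy: EconomyParams
    transmission: TransmissionParams
    balance: float
    total_spend: float = 0.0
    upgraded_this_month: bool = False
    disease_revealed_this_month: bool = False
    biosecurity_revealed: bool = False
    disease_revealed_ids: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )
    biosecurity_revealed_ids: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )

    def begin_month(self) -> None:
        # Disease reveals are a current-month snapshot; biosecurity reveals
        # persist (statuses are static within the round).
        self.upgraded_this_month = False
        self.disease_revealed_this_month = False
        self.disease_revealed_ids = np.empty(0, dtype=np.int64)

    def nearest_computer_ids(self) -> np.ndarray:
        d = self.world.distances[PLAYER_ID, 1:]
        k = min(self.economy.reveal_count, self.world.n_computer)
        order = np.argsort(d, kind="stable")[:k]
        return order + 1  # facility ids


def observe(state: RoundState) -> Observation:
    world = state.world
    t = state.treatment
    n = world.n_computer
    if t.disease_visibility is Visibility.VISIBLE:
        inf_view = world.infected[1:].astype(float)
    else:
        inf_view = np.full(n, np.nan)
        if t.disease_visibility is Visibility.REVEALABLE:
            ids = state.disease_revealed_ids
            inf_view[ids - 1] = world.infected[ids]
    if t.biosecurity_visibility is Visibility.VISIBLE:
        bio_view = world.levels[1:].astype(float)
    else:
        bio_view = np.full(n, np.nan)
        if t.biosecurity_visibility is Visibility.REVEALABLE:
            ids = state.biosecurity_revealed_ids
            bio_view[ids - 1] = world.levels[ids]
    return Observation(
        month=world.month,
        own_level=world.player_level,
        balance=state.balance,
        distances=world.distances[PLAYER_ID, 1:],
        infection_view=inf_view,
        biosecurity_view=bio_view,
        treatment=t,
        transmission=state.transmission,
        can_reveal_disease=(
            t.disease_visibility is Visibility.REVEALABLE
            and not state.disease_revealed_this_month
        ),
        can_reveal_biosecurity=(
            t.biosecurity_visibility is Visibility.REVEALABLE
            and not state.biosecurity_revealed
        ),
        can_upgrade=(not state.upgraded_this_month and world.player_level < 3),
    )


def apply_action(state: RoundState, action: DecisionAction) -> float:
    """Apply one action to the round state; returns the dollars spent.

    Raises :class:`IllegalActionError` for an upgrade at level High, a
    second upgrade in the same month, a reveal under a non-revealable
    treatment, or a redundant reveal purchase.
    """
    kind = action.kind
    if kind is ActionKind.NO_ACTION:
        return 0.0
    if kind is ActionKind.INCREASE_BIOSECURITY:
        if state.world.player_level >= 3:
            raise IllegalActionError("biosecurity already at High (absorbing maximum)")
        if state.upgraded_this_month:
            raise IllegalActionError("at most one biosecurity increase per month")
        state.world.levels[PLAYER_ID] += 1
        state.upgraded_this_month = True
        cost = state.economy.upgrade_cost
    elif kind is ActionKind.REVEAL_DISEASE:
        if state.treatment.disease_visibility is not Visibility.REVEALABLE:
            raise IllegalActionError(
                "disease reveal not purchasable under this treatment"
            )
        if state.disease_revealed_this_month:
            raise IllegalActionError("disease already revealed this month")
        state.disease_revealed_ids = state.nearest_computer_ids()
        state.disease_revealed_this_month = True
        cost = state.treatment.reveal_price_disease
    elif kind is ActionKind.REVEAL_BIOSECURITY:
        if state.treatment.biosecurity_visibility is not Visibility.REVEALABLE:
            raise IllegalActionError(
                "biosecurity reveal not purchasable under this treatment"
            )
        if state.biosecurity_revealed:
            raise IllegalActionError("biosecurity already revealed this round")
        state.biosecurity_revealed_ids = state.nearest_computer_ids()
        state.biosecurity_revealed = True
        cost = state.treatment.reveal_price_biosecurity
    else:  # pragma: no cover - exhaustive enum
        raise IllegalActionError(f"unknown action {kind}")
    state.balance -= cost
    state.total_spend += cost
    return float(cost)


class Policy(Protocol):
    """Decision rule of one simulated participant."""

    def choose_reveals(
        self, obs: Observation, rng: np.random.Generator
    ) -> list[DecisionAction]: ...

    def choose_upgrade(
        self, obs: Observation, rng: np.random.Generator
    ) -> DecisionAction | None: ...


def run_round(
    world: WorldState,
    policy: Policy,
    treatment: TreatmentSpec,
    economy: EconomyParams,
    transmission: TransmissionParams,
    rng: np.random.Generator,
    round_id: int = 0,
) -> tuple[RoundResult, list[MonthRecord]]:
    """Play one round (up to six months) with a fresh world.

    Reveal purchases resolve before the upgrade decision, so the policy's
    upgrade choice can use information it just paid for.  On player
    infection the round truncates and the infection penalty applies.
    Illegal policy actions raise; they are not silently corrected.
    """
    if world.player_level != 0 or world.player_infected:
        raise ValueError("run_round requires a fresh world (player at None, clean)")
    state = RoundState(
        world=world,
        treatment=treatment,
        economy=economy,
        transmission=transmission,
        balance=economy.round_endowment,
    )
    records: list[MonthRecord] = []
    infected = False
    for month in range(1, MONTHS_PER_ROUND + 1):
        state.begin_month()
        actions: list[ActionKind] = []
        spend = 0.0
        obs = observe(state)
        reveals = policy.choose_reveals(obs, rng)
        for action in reveals:
            spend += apply_action(state, action)
            actions.append(action.kind)
        if reveals:  # purchased information feeds the upgrade decision
            obs = observe(state)
        upgrade = policy.choose_upgrade(obs, rng)
        if upgrade is not None and upgrade.kind is not ActionKind.NO_ACTION:
            spend += apply_action(state, upgrade)
            actions.append(upgrade.kind)
        if not actions:
            actions.append(ActionKind.NO_ACTION)
        state.world = step_month(state.world, transmission, rng)
        infected = state.world.player_infected
        records.append(
            MonthRecord(
                round_id=round_id,
                month=month,
                actions=tuple(actions),
                spend=spend,
                post_decision_biosecurity=state.world.player_level,
                infected_this_month=infected,
            )
        )
        if infected:
            state.balance -= economy.infection_penalty
            break
    delta = (
        economy.round_endowment
        - state.total_spend
        - (economy.infection_penalty if infected else 0.0)
    )
    result = RoundResult(
        months_played=len(records),
        final_balance_delta=delta,
        infected=infected,
        treatment=treatment,
    )
    return result, records


def run_session(
    policy: Policy,
    schedule: list[TreatmentSpec],
    economy: EconomyParams,
    transmission: TransmissionParams,
    rng_seed,
    n_facilities: int = 50,
    layout: LayoutParams | None = None,
) -> tuple[list[RoundResult], list[list[MonthRecord]]]:
    """Play every round of a schedule with world re-initialization between
    rounds; returns per-round results and month records.

    Session profit is the sum of the per-round balance deltas.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    results: list[RoundResult] = []
    all_records: list[list[MonthRecord]] = []
    for round_id, treatment in enumerate(schedule):
        world = init_world(n_facilities, rng, layout)
        result, records = run_round(
            world, policy, treatment, economy, transmission, rng, round_id=round_id
        )
        results.append(result)
        all_records.append(records)
    return results, all_records


def session_profit(results: list[RoundResult]) -> float:
    return float(sum(r.final_balance_delta for r in results))


def records_to_rows(
    participant_id: str,
    cohort: str,
    results: list[RoundResult],
    all_records: list[list[MonthRecord]],
) -> list[dict]:
    """Flatten session output into tidy decision-log rows (one per
    participant-round-month)."""
    rows = []
    for result, records in zip(results, all_records):
        t = result.treatment
        for rec in records:
            rows.append(
                {
                    "participant_id": participant_id,
                    "cohort": cohort,
                    "round_id": rec.round_id,
                    "disease_visibility": t.disease_visibility.value,
                    "biosecurity_visibility": t.biosecurity_visibility.value,
                    "reveal_price_disease": t.reveal_price_disease,
                    "reveal_price_biosecurity": t.reveal_price_biosecurity,
                    "month": rec.month,
                    "action_increase": ActionKind.INCREASE_BIOSECURITY
                    in rec.actions,
                    "action_reveal_disease": ActionKind.REVEAL_DISEASE
                    in rec.actions,
                    "action_reveal_biosecurity": ActionKind.REVEAL_BIOSECURITY
                    in rec.actions,
                    "spend": rec.spend,
                    "post_decision_biosecurity": rec.post_decision_biosecurity,
                    "infected": rec.infected_this_month,
                }
            )
    return rows
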