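"""Digital paired-lottery (multiple price list) risk instrument.

Ten paired choices contrast a low-spread "safe" Option A against a
high-spread "risky" Option B.  Row k pays the high outcome of either option
with probability k/10, so the risky option's expected value overtakes the
safe option's as the list progresses; risk attitude is summarized by the
fraction of safe choices.  Realizing one randomly drawn row for payment
makes every row incentive-compatible.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np

__all__ = [
    "LotteryRow",
    "LotterySchedule",
    "LotteryRecord",
    "RiskScore",
    "RiskCategory",
    "build_schedule",
    "EXPO_SCHEDULE",
    "MTURK_SCHEDULE",
    "expected_values",
    "EVMaximizer",
    "Maximin",
    "NoisySwitcher",
    "simulate_choices",
    "score",
    "realize_payout",
    "cohort_switch_profile",
]

N_ROWS = 10


@dataclass(frozen=True)
class LotteryRow:
    p_high: float
    a_high: float
    a_low: float
    b_high: float
    b_low: float


@dataclass(frozen=True)
class LotterySchedule:
    rows: tuple[LotteryRow, ...]

    def __post_init__(self) -> None:
        if len(self.rows) != N_ROWS:
            raise ValueError(f"a schedule has exactly {N_ROWS} rows")

    def row(self, k: int) -> LotteryRow:
        if not 1 <= k <= N_ROWS:
            raise ValueError(f"row must be in 1..{N_ROWS}, got {k}")
        return self.rows[k - 1]


def build_schedule(
    payoffs_A: tuple[float, float], payoffs_B: tuple[float, float]
) -> LotterySchedule:
    """Construct the ten-row schedule from (high, low) payoffs per option.

    Option A must have the narrower payoff spread (it is the safe option).
    """
    a_high, a_low = payoffs_A
    b_high, b_low = payoffs_B
    for v in (a_high, a_low, b_high, b_low):
        if v <= 0:
            raise ValueError("payoffs must be positive")
    if (a_high - a_low) >= (b_high - b_low):
        raise ValueError("Option A's payoff spread must be smaller than Option B's")
    rows = tuple(
        LotteryRow(p_high=k / 10.0, a_high=a_high, a_low=a_low, b_high=b_high, b_low=b_low)
        for k in range(1, N_ROWS + 1)
    )
    return LotterySchedule(rows=rows)


#: Payoff schedule used for in-person (trade-show) participants.
EXPO_SCHEDULE = build_schedule((2.00, 1.60), (3.85, 0.10))
#: Payoff schedule used for online participants.
MTURK_SCHEDULE = build_schedule((0.60, 0.50), (1.10, 0.05))


def expected_values(schedule: LotterySchedule, row: int) -> tuple[float, float]:
    """Probability-weighted mean payoff of each option at one row."""
    r = schedule.row(row)
    ev_a = r.p_high * r.a_high + (1.0 - r.p_high) * r.a_low
    ev_b = r.p_high * r.b_high + (1.0 - r.p_high) * r.b_low
    return ev_a, ev_b


@dataclass(frozen=True)
class LotteryRecord:
    """Ten A/B choices of one participant, plus the realized payment draw."""

    participant_id: str
    choices: tuple[str, ...]
    realized_row: int | None = None
    realized_payout: float | None = None

    def __post_init__(self) -> None:
        if len(self.choices) != N_ROWS:
            raise ValueError(f"exactly {N_ROWS} choices required")
        if any(c not in ("A", "B") for c in self.choices):
            raise ValueError("choices must be 'A' or 'B'")


class RiskCategory(str, Enum):
    RISK_AVERSE = "risk_averse"
    RISK_NEUTRAL = "risk_neutral"
    RISK_TOLERANT = "risk_tolerant"


@dataclass(frozen=True)
class RiskScore:
    safe_ratio: float
    category: RiskCategory
    switch_count: int


class EVMaximizer:
    """Chooses the option with the higher expected value (ties -> A)."""

    def choose(self, schedule: LotterySchedule, row: int, rng) -> str:
        ev_a, ev_b = expected_values(schedule, row)
        return "A" if ev_a >= ev_b else "B"


class Maximin:
    """Compares worst-case payoffs (row 10 is a certain-payoff comparison)."""

    def choose(self, schedule: LotterySchedule, row: int, rng) -> str:
        r = schedule.row(row)
        if r.p_high >= 1.0:  # degenerate certain row
            return "A" if r.a_high >= r.b_high else "B"
        worst_a = min(r.a_high, r.a_low)
        worst_b = min(r.b_high, r.b_low)
        return "A" if worst_a >= worst_b else "B"


@dataclass(frozen=True)
class NoisySwitcher:
    """Safe prefix up to (not including) ``switch_row``, then risky; each
    choice independently flipped with probability ``error_rate``."""

    switch_row: int
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.switch_row <= N_ROWS + 1:
            raise ValueError("switch_row must be in 1..11")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")

    def choose(self, schedule: LotterySchedule, row: int, rng) -> str:
        base = "A" if row < self.switch_row else "B"
        if self.error_rate and rng.random() < self.error_rate:
            return "B" if base == "A" else "A"
        return base


def simulate_choices(
    schedule: LotterySchedule, agent, rng, participant_id: str = "agent"
) -> LotteryRecord:
    """Run an agent through all ten rows of a schedule."""
    choices = tuple(agent.choose(schedule, k, rng) for k in range(1, N_ROWS + 1))
    return LotteryRecord(participant_id=participant_id, choices=choices)


def score(record: LotteryRecord) -> RiskScore:
    """Safe-choice ratio, category, and switch count of one record.

    Exactly 4 safe choices is risk neutral; more is risk averse, fewer is
    risk tolerant.  ``switch_count`` counts every adjacent A<->B alternation.
    """
    n_safe = sum(1 for c in record.choices if c == "A")
    if n_safe > 4:
        category = RiskCategory.RISK_AVERSE
    elif n_safe < 4:
        category = RiskCategory.RISK_TOLERANT
    else:
        category = RiskCategory.RISK_NEUTRAL
    switches = sum(
        1 for a, b in zip(record.choices, record.choices[1:]) if a != b
    )
    return RiskScore(
        safe_ratio=n_safe / N_ROWS, category=category, switch_count=switches
    )


def realize_payout(
    record: LotteryRecord, schedule: LotterySchedule, rng
) -> tuple[int, bool, float]:
    """Draw one row uniformly and realize the chosen option's outcome.

    Returns (row, high_outcome, payout in USD).
    """
    if not hasattr(rng, "integers"):
        rng = np.random.default_rng(rng)
    row = 1 + int(rng.integers(0, N_ROWS))
    r = schedule.row(row)
    high = bool(rng.random() < r.p_high)
    choice = record.choices[row - 1]
    if choice == "A":
        payout = r.a_high if high else r.a_low
    else:
        payout = r.b_high if high else r.b_low
    return row, high, float(payout)


_BUCKETS = ("0", "1", "2", "3", ">3")


def cohort_switch_profile(records: Iterable[LotteryRecord]) -> dict:
    """Histogram of switch counts over buckets {0, 1, 2, 3, >3}.

    Returns ``{"counts": {...}, "percent": {...}, "n": n}``.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one record")
    counts = {b: 0 for b in _BUCKETS}
    for rec in records:
        s = score(rec).switch_count
        counts[str(s) if s <= 3 else ">3"] += 1
    n = len(records)
    percent = {b: 100.0 * c / n for b, c in counts.items()}
    return {"counts": counts, "percent": percent, "n": n}
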