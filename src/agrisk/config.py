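"""Experiment configuration, end-to-end orchestration, and packaged
fixtures.

All randomness flows from one master seed through named child streams
(schedule, cohort draws, per-participant sessions and lotteries), so a
configuration plus seed maps to byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agents import CohortSpec, LotteryBehavior, Participant, ThresholdPolicy, make_cohort
from .compare import ComparisonReport, PlanEntry, compare_cohorts, default_plan, validate_plan
from .economy import EconomyParams
from .engine import records_to_rows, run_session, session_profit
from .logio import decision_log_frame
from .lottery import (
    EXPO_SCHEDULE,
    MTURK_SCHEDULE,
    LotteryRecord,
    LotterySchedule,
    NoisySwitcher,
    build_schedule,
    realize_payout,
    score,
    simulate_choices,
)
from .metrics import summarize_participants
from .treatments import TreatmentSpec, generate_treatment_schedule
from .world import LayoutParams, TransmissionParams

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "lottery_schedule_from_name",
    "simulate_cohort",
    "run_experiment",
    "make_fixtures",
]

_LOTTERY_PRESETS = {"expo": EXPO_SCHEDULE, "mturk": MTURK_SCHEDULE}


def lottery_schedule_from_name(name_or_payoffs) -> LotterySchedule:
    if isinstance(name_or_payoffs, LotterySchedule):
        return name_or_payoffs
    if isinstance(name_or_payoffs, str):
        try:
            return _LOTTERY_PRESETS[name_or_payoffs]
        except KeyError:
            raise ValueError(
                f"unknown lottery preset {name_or_payoffs!r}; "
                f"known: {sorted(_LOTTERY_PRESETS)}"
            ) from None
    payoffs = name_or_payoffs
    return build_schedule(tuple(payoffs["A"]), tuple(payoffs["B"]))


def _default_cohorts() -> list[CohortSpec]:
    # Two groups mirroring the study design: an industry-fair-like cohort
    # with a higher propensity to buy information and an online-marketplace
    # cohort with a lower one; lottery behavior set from each group's
    # safe-ratio mean/spread.
    return [
        CohortSpec(
            name="expo",
            n_participants=50,
            reveal_propensity_mean=0.4,
            reveal_propensity_sd=0.15,
            lottery=LotteryBehavior(switch_row_mean=6.2, switch_row_sd=2.2, error_rate=0.05),
        ),
        CohortSpec(
            name="mturk",
            n_participants=50,
            reveal_propensity_mean=0.2,
            reveal_propensity_sd=0.15,
            lottery=LotteryBehavior(switch_row_mean=6.2, switch_row_sd=2.0, error_rate=0.02),
        ),
    ]


@dataclass
class ExperimentConfig:
    """Complete description of one synthetic experiment."""

    seed: int = 0
    n_facilities: int = 50
    arena_side: float = 10.0
    n_rounds: int = 32
    schedule: list[TreatmentSpec] | None = None  # explicit override
    economy: EconomyParams = field(default_factory=EconomyParams)
    transmission: TransmissionParams = field(default_factory=TransmissionParams)
    cohorts: list[CohortSpec] = field(default_factory=_default_cohorts)
    lottery_schedule: str | dict = "expo"
    plan: list[PlanEntry] | None = None  # None -> default plan

    def __post_init__(self) -> None:
        if len(self.cohorts) < 1:
            raise ValueError("need at least one cohort")
        if self.plan is not None:
            validate_plan(self.plan)
        lottery_schedule_from_name(self.lottery_schedule)  # fail fast

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if hasattr(obj, "value"):  # Enum
                return obj.value
            return obj

        d = {
            "seed": self.seed,
            "n_facilities": self.n_facilities,
            "arena_side": self.arena_side,
            "n_rounds": self.n_rounds,
            "schedule": enc(self.schedule) if self.schedule is not None else None,
            "economy": enc(self.economy),
            "transmission": enc(self.transmission),
            "cohorts": enc(self.cohorts),
            "lottery_schedule": self.lottery_schedule,
            "plan": enc(self.plan) if self.plan is not None else None,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if d.get("schedule") is not None:
            d["schedule"] = [TreatmentSpec(**s) for s in d["schedule"]]
        if "economy" in d and isinstance(d["economy"], dict):
            d["economy"] = EconomyParams(**d["economy"])
        if "transmission" in d and isinstance(d["transmission"], dict):
            d["transmission"] = TransmissionParams(**d["transmission"])
        if "cohorts" in d:
            d["cohorts"] = [
                c if isinstance(c, CohortSpec) else CohortSpec(**c)
                for c in d["cohorts"]
            ]
        if d.get("plan") is not None:
            d["plan"] = [
                e if isinstance(e, PlanEntry) else PlanEntry(**e) for e in d["plan"]
            ]
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    decision_log: pd.DataFrame
    lottery_records: list[LotteryRecord]
    lottery_scores: pd.DataFrame
    summaries: dict[str, pd.DataFrame]
    report: ComparisonReport | None
    profits: dict[str, float]


def simulate_cohort(
    participants: list[Participant],
    schedule: list[TreatmentSpec],
    economy: EconomyParams,
    transmission: TransmissionParams,
    seed_seq: np.random.SeedSequence,
    n_facilities: int = 50,
    layout: LayoutParams | None = None,
) -> tuple[list[dict], dict[str, float]]:
    """Run every participant of a cohort through the full session; returns
    tidy decision-log rows and per-participant session profits."""
    rows: list[dict] = []
    profits: dict[str, float] = {}
    children = seed_seq.spawn(len(participants))
    for participant, child in zip(participants, children):
        rng = np.random.default_rng(child)
        policy = ThresholdPolicy(participant.policy_params)
        results, records = run_session(
            policy, schedule, economy, transmission, rng, n_facilities, layout
        )
        rows.extend(
            records_to_rows(participant.participant_id, participant.cohort, results, records)
        )
        profits[participant.participant_id] = session_profit(results)
    return rows, profits


def _run_lotteries(
    participants: list[Participant],
    schedule: LotterySchedule,
    seed_seq: np.random.SeedSequence,
) -> list[LotteryRecord]:
    records = []
    children = seed_seq.spawn(len(participants))
    for participant, child in zip(participants, children):
        rng = np.random.default_rng(child)
        agent = NoisySwitcher(
            switch_row=participant.lottery_switch_row,
            error_rate=participant.lottery_error_rate,
        )
        rec = simulate_choices(
            schedule, agent, rng, participant_id=participant.participant_id
        )
        row, _, payout = realize_payout(rec, schedule, rng)
        records.append(
            dataclasses.replace(rec, realized_row=row, realized_payout=payout)
        )
    return records


def lottery_scores_frame(records: list[LotteryRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        s = score(rec)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "safe_ratio": s.safe_ratio,
                "risk_category": s.category.value,
                "switch_count": s.switch_count,
            }
        )
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """End-to-end pipeline: cohorts -> game sessions -> exit lotteries ->
    summaries -> two-cohort comparison report.

    Fully deterministic for a given (config, seed): identical reruns give
    identical artifacts.  The comparison report covers the first two
    cohorts; with a single cohort no report is produced.
    """
    plan = config.plan if config.plan is not None else default_plan()
    validate_plan(plan)
    master = np.random.SeedSequence(config.seed)
    ss_schedule, ss_cohorts, ss_sessions, ss_lottery = master.spawn(4)

    schedule = (
        config.schedule
        if config.schedule is not None
        else generate_treatment_schedule(
            config.n_rounds, np.random.default_rng(ss_schedule)
        )
    )
    layout = LayoutParams(arena_side=config.arena_side)
    lottery_sched = lottery_schedule_from_name(config.lottery_schedule)

    all_rows: list[dict] = []
    all_lottery: list[LotteryRecord] = []
    profits: dict[str, float] = {}
    cohort_children = ss_cohorts.spawn(len(config.cohorts))
    session_children = ss_sessions.spawn(len(config.cohorts))
    lottery_children = ss_lottery.spawn(len(config.cohorts))
    for spec, c_child, s_child, l_child in zip(
        config.cohorts, cohort_children, session_children, lottery_children
    ):
        participants = make_cohort(spec, np.random.default_rng(c_child))
        rows, cohort_profits = simulate_cohort(
            participants,
            schedule,
            config.economy,
            config.transmission,
            s_child,
            config.n_facilities,
            layout,
        )
        all_rows.extend(rows)
        profits.update(cohort_profits)
        all_lottery.extend(_run_lotteries(participants, lottery_sched, l_child))

    log = decision_log_frame(all_rows)
    scores = lottery_scores_frame(all_lottery)
    summaries = {}
    for spec in config.cohorts:
        cohort_log = log[log["cohort"] == spec.name]
        summaries[spec.name] = summarize_participants(
            cohort_log, config.economy, scores
        )
    report = None
    if len(config.cohorts) >= 2:
        a, b = config.cohorts[0].name, config.cohorts[1].name
        report = compare_cohorts(
            summaries[a], summaries[b], plan, labels=(a, b)
        )
    return ExperimentResult(
        config=config,
        decision_log=log,
        lottery_records=all_lottery,
        lottery_scores=scores,
        summaries=summaries,
        report=report,
        profits=profits,
    )


# ---------------------------------------------------------------------------
# Packaged fixtures

#: The four one-tailed reveal-contrast p-values forming one FDR family in
#: the report structure this pipeline mirrors.
_REVEAL_P_FAMILY = {
    "infection_1000": 0.0487,
    "infection_2000": 0.2835,
    "biosecurity_1000": 0.0013,
    "biosecurity_2000": 0.0587,
}


def make_fixtures(kind: str, seed: int = 0):
    """Small packaged datasets for tests and demos.

    Kinds: ``worked_examples`` (the hand-checkable rating months and the
    four-test p family), ``null_cohorts`` (two identically distributed
    cohort specs), ``shifted_reveal`` (cohorts differing only in reveal
    propensity, 0.4 vs 0.2), ``lottery_textbook`` (records with known
    switch-count buckets).
    """
    if kind == "worked_examples":
        return {
            "rating_statuses": [0, 0, 1, 1, 2, 2],
            "reveal_p_family": dict(_REVEAL_P_FAMILY),
        }
    if kind == "null_cohorts":
        base = dict(
            n_participants=50,
            reveal_propensity_mean=0.3,
            reveal_propensity_sd=0.1,
        )
        return [
            CohortSpec(name="null_a", **base),
            CohortSpec(name="null_b", **base),
        ]
    if kind == "shifted_reveal":
        return [
            CohortSpec(
                name="high_reveal",
                n_participants=50,
                reveal_propensity_mean=0.4,
                reveal_propensity_sd=0.15,
            ),
            CohortSpec(
                name="low_reveal",
                n_participants=50,
                reveal_propensity_mean=0.2,
                reveal_propensity_sd=0.15,
            ),
        ]
    if kind == "lottery_textbook":
        rng = np.random.default_rng(seed)
        patterns = (
            ["A" * 4 + "B" * 6] * 4  # single switch, risk neutral
            + ["A" * 6 + "B" * 4] * 2  # single switch, risk averse
            + ["A" * 10]  # never switches
            + ["AAABBBAABB"]  # three switches
            + ["ABABABABAB"]  # many switches
            + ["B" * 10]  # never switches (all risky)
        )
        records = []
        for i, pat in enumerate(patterns):
            rec = LotteryRecord(participant_id=f"fx-{i:02d}", choices=tuple(pat))
            row, _, payout = realize_payout(rec, EXPO_SCHEDULE, rng)
            records.append(
                dataclasses.replace(rec, realized_row=row, realized_payout=payout)
            )
        return records
    raise ValueError(f"unknown fixture kind {kind!r}")
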