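"""Behavioral metrics computed from decision logs.

The central metric is the biosecurity investment rating R: the mean
post-decision biosecurity status (0..3) over a participant's decision
months.  Truncated rounds contribute only the months actually played, so R
is normalized by the total number of decisions made.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .economy import EconomyParams
from .engine import MonthRecord

__all__ = [
    "STRATA",
    "biosecurity_rating",
    "reveal_summary",
    "session_profits",
    "summarize_participants",
]

#: Named treatment strata of the decision log (column, value) filters.
STRATA: Mapping[str, tuple[str, str] | None] = {
    "all": None,
    "dis_visible": ("disease_visibility", "visible"),
    "dis_hidden": ("disease_visibility", "hidden"),
    "dis_reveal": ("disease_visibility", "revealable"),
    "bio_visible": ("biosecurity_visibility", "visible"),
    "bio_hidden": ("biosecurity_visibility", "hidden"),
    "bio_reveal": ("biosecurity_visibility", "revealable"),
}


def _filter_stratum(log: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum not in STRATA:
        raise KeyError(f"unknown stratum {stratum!r}; known: {sorted(STRATA)}")
    flt = STRATA[stratum]
    if flt is None:
        return log
    col, value = flt
    return log[log[col] == value]


def biosecurity_rating(month_records, stratum_filter: str | None = None) -> float:
    """Biosecurity investment rating R: mean post-decision status over the
    selected decision months (0 = None .. 3 = High).

    ``month_records`` may be a sequence of integer statuses, a sequence of
    :class:`MonthRecord`, or decision-log rows (DataFrame); the optional
    ``stratum_filter`` names a treatment stratum and applies to DataFrames.
    """
    if isinstance(month_records, pd.DataFrame):
        df = month_records
        if stratum_filter is not None:
            df = _filter_stratum(df, stratum_filter)
        statuses = df["post_decision_biosecurity"].to_numpy(dtype=float)
    else:
        records = list(month_records)
        if records and isinstance(records[0], MonthRecord):
            statuses = np.array(
                [r.post_decision_biosecurity for r in records], dtype=float
            )
        else:
            statuses = np.asarray(records, dtype=float)
        if stratum_filter is not None:
            raise ValueError("stratum_filter requires decision-log rows")
    if statuses.size == 0:
        raise ValueError("empty stratum: no decision months to rate")
    if np.any(statuses < 0) or np.any(statuses > 3):
        raise ValueError("biosecurity statuses must be in 0..3")
    return float(statuses.mean())


def reveal_summary(log: pd.DataFrame) -> pd.DataFrame:
    """Per-participant reveal counts and spend by information type and price.

    Returns one row per participant with columns
    ``reveals_{disease|bio}_{price}`` for every price occurring in the log,
    plus ``spend_disease``/``spend_bio`` dollar totals.  Cohort aggregates
    are column sums over the cohort's participants.
    """
    required = {"participant_id", "action_reveal_disease", "action_reveal_biosecurity"}
    missing = required - set(log.columns)
    if missing:
        raise ValueError(f"decision log lacks columns: {sorted(missing)}")
    participants = log[["participant_id", "cohort"]].drop_duplicates()
    out = participants.set_index("participant_id")

    prices = sorted(
        set(log["reveal_price_disease"].dropna().unique())
        | set(log["reveal_price_biosecurity"].dropna().unique())
    )
    for info, flag_col, price_col in (
        ("disease", "action_reveal_disease", "reveal_price_disease"),
        ("bio", "action_reveal_biosecurity", "reveal_price_biosecurity"),
    ):
        spend = pd.Series(0.0, index=out.index)
        for price in prices:
            mask = log[flag_col] & (log[price_col] == price)
            counts = (
                log[mask].groupby("participant_id").size().reindex(out.index, fill_value=0)
            )
            out[f"reveals_{info}_{int(price)}"] = counts.astype(int)
            spend = spend + counts * price
        out[f"spend_{info}"] = spend
    return out.reset_index()


def session_profits(log: pd.DataFrame, economy: EconomyParams) -> pd.Series:
    """Per-participant session profit reconstructed from the log:
    sum over rounds of (endowment - spends - penalty if infected)."""
    per_round = log.groupby(["participant_id", "round_id"]).agg(
        spend=("spend", "sum"), infected=("infected", "any")
    )
    delta = (
        economy.round_endowment
        - per_round["spend"]
        - economy.infection_penalty * per_round["infected"]
    )
    return delta.groupby("participant_id").sum().rename("session_profit")


def summarize_participants(
    log: pd.DataFrame,
    economy: EconomyParams | None = None,
    lottery_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the per-participant summary table the comparison pipeline
    consumes: R per treatment stratum, session profit, reveal counts and
    spend, and (when provided) lottery safe ratio / category / switches.

    ``lottery_scores`` must have columns ``participant_id``, ``safe_ratio``,
    ``risk_category``, ``switch_count``.
    """
    economy = economy or EconomyParams()
    out = reveal_summary(log).set_index("participant_id")
    for stratum in STRATA:
        rated = (
            _filter_stratum(log, stratum)
            .groupby("participant_id")["post_decision_biosecurity"]
            .mean()
        )
        out[f"r_{stratum}"] = rated.reindex(out.index)
    out["session_profit"] = session_profits(log, economy).reindex(out.index)
    if lottery_scores is not None:
        ls = lottery_scores.set_index("participant_id")
        for col in ("safe_ratio", "risk_category", "switch_count"):
            out[col] = ls[col].reindex(out.index)
    return out.reset_index()
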