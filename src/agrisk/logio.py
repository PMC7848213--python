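"""Serialization of decision logs and lottery records (tidy CSV and JSON).

The decision log is the analysis pipeline's sole input: one row per
participant-round-month with the treatment descriptor, the actions taken,
the spend, the post-decision biosecurity status, and the infection flag.
Both formats round-trip losslessly, including column order and dtypes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .lottery import N_ROWS, LotteryRecord

__all__ = [
    "DECISION_LOG_COLUMNS",
    "SchemaError",
    "decision_log_frame",
    "validate_decision_log",
    "write_decision_log",
    "read_decision_log",
    "lottery_records_frame",
    "frame_to_lottery_records",
    "write_lottery_records",
    "read_lottery_records",
]


class SchemaError(ValueError):
    """A serialized table violates the expected schema."""


# Column -> pandas dtype, in canonical order.
DECISION_LOG_COLUMNS: dict[str, str] = {
    "participant_id": "string",
    "cohort": "string",
    "round_id": "int64",
    "disease_visibility": "string",
    "biosecurity_visibility": "string",
    "reveal_price_disease": "float64",
    "reveal_price_biosecurity": "float64",
    "month": "int64",
    "action_increase": "bool",
    "action_reveal_disease": "bool",
    "action_reveal_biosecurity": "bool",
    "spend": "float64",
    "post_decision_biosecurity": "int64",
    "infected": "bool",
}

_VISIBILITIES = {"visible", "hidden", "revealable"}


def decision_log_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a schema-conformant decision log from tidy row dicts."""
    df = pd.DataFrame(rows, columns=list(DECISION_LOG_COLUMNS))
    return df.astype(DECISION_LOG_COLUMNS)


def validate_decision_log(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema and per-row invariants; raises SchemaError naming the
    first offending row."""
    missing = [c for c in DECISION_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"decision log lacks columns {missing}")
    df = df[list(DECISION_LOG_COLUMNS)].astype(DECISION_LOG_COLUMNS)
    checks = [
        (~df["month"].between(1, 6), "month outside 1..6"),
        (
            ~df["post_decision_biosecurity"].between(0, 3),
            "biosecurity status outside 0..3",
        ),
        (~df["disease_visibility"].isin(_VISIBILITIES), "bad disease_visibility"),
        (
            ~df["biosecurity_visibility"].isin(_VISIBILITIES),
            "bad biosecurity_visibility",
        ),
        (df["spend"] < 0, "negative spend"),
    ]
    for bad, reason in checks:
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"row {row}: {reason}")
    return df


def write_decision_log(df: pd.DataFrame, path) -> None:
    """Write a decision log as .csv or .json (by extension)."""
    path = Path(path)
    df = validate_decision_log(df)
    if path.suffix == ".csv":
        df.to_csv(path, index=False)
    elif path.suffix == ".json":
        records = df.to_dict(orient="records")
        for rec in records:  # NaN -> null for strict JSON
            for k, v in rec.items():
                if isinstance(v, float) and np.isnan(v):
                    rec[k] = None
        path.write_text(json.dumps(records, indent=1))
    else:
        raise ValueError(f"unsupported extension {path.suffix!r} (use .csv or .json)")


def read_decision_log(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
    elif path.suffix == ".json":
        df = pd.DataFrame(
            json.loads(path.read_text()), columns=list(DECISION_LOG_COLUMNS)
        )
    else:
        raise ValueError(f"unsupported extension {path.suffix!r} (use .csv or .json)")
    if df.empty:
        df = pd.DataFrame(columns=list(DECISION_LOG_COLUMNS))
    return validate_decision_log(df)


# ---------------------------------------------------------------------------
# Lottery records

_LOTTERY_COLUMNS = (
    ["participant_id"]
    + [f"choice_{k}" for k in range(1, N_ROWS + 1)]
    + ["realized_row", "realized_payout"]
)


def lottery_records_frame(records: list[LotteryRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"participant_id": r.participant_id}
        row.update({f"choice_{k}": r.choices[k - 1] for k in range(1, N_ROWS + 1)})
        row["realized_row"] = np.nan if r.realized_row is None else r.realized_row
        row["realized_payout"] = (
            np.nan if r.realized_payout is None else r.realized_payout
        )
        rows.append(row)
    df = pd.DataFrame(rows, columns=_LOTTERY_COLUMNS)
    return df


def frame_to_lottery_records(df: pd.DataFrame) -> list[LotteryRecord]:
    missing = [c for c in _LOTTERY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"lottery table lacks columns {missing}")
    records = []
    for i, row in df.iterrows():
        choices = tuple(str(row[f"choice_{k}"]) for k in range(1, N_ROWS + 1))
        if any(c not in ("A", "B") for c in choices):
            raise SchemaError(f"row {i}: choices must be 'A' or 'B'")
        realized_row = row["realized_row"]
        realized_payout = row["realized_payout"]
        records.append(
            LotteryRecord(
                participant_id=str(row["participant_id"]),
                choices=choices,
                realized_row=None if pd.isna(realized_row) else int(realized_row),
                realized_payout=(
                    None if pd.isna(realized_payout) else float(realized_payout)
                ),
            )
        )
    return records


def write_lottery_records(records: list[LotteryRecord], path) -> None:
    path = Path(path)
    df = lottery_records_frame(records)
    if path.suffix == ".csv":
        df.to_csv(path, index=False)
    elif path.suffix == ".json":
        recs = df.to_dict(orient="records")
        for rec in recs:
            for k, v in rec.items():
                if isinstance(v, float) and np.isnan(v):
                    rec[k] = None
        path.write_text(json.dumps(recs, indent=1))
    else:
        raise ValueError(f"unsupported extension {path.suffix!r}")


def read_lottery_records(path) -> list[LotteryRecord]:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
    elif path.suffix == ".json":
        df = pd.DataFrame(json.loads(path.read_text()), columns=_LOTTERY_COLUMNS)
    else:
        raise ValueError(f"unsupported extension {path.suffix!r}")
    return frame_to_lottery_records(df)
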