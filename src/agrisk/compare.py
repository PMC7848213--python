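"""Two-cohort comparison pipeline: a declarative test plan evaluated over
per-participant summary tables, with per-family FDR adjustment.

The default plan mirrors the report structure of the behavioral study this
package emulates: R ratings per treatment stratum and session profit
(two-tailed rank tests), reveal counts per information type and price
(one-tailed rank tests sharing one four-test FDR family), the lottery
safe-ratio distribution (KS), and rank correlations between in-game and
lottery risk measures, including the conditional correlation restricted to
participants with at least one infection-information reveal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .stats import fdr_adjust, ks_two_sample, mann_whitney_u, spearman

__all__ = [
    "PlanEntry",
    "TestResult",
    "ComparisonReport",
    "default_plan",
    "validate_plan",
    "compare_cohorts",
]

_TESTS = ("mann_whitney", "ks", "spearman")
_TAILS = ("two", "one_greater", "one_less")
_SCOPES = ("a", "b", "pooled")


@dataclass(frozen=True)
class PlanEntry:
    """One contrast of the comparison plan.

    ``column`` names the summary column for two-sample tests; ``x_col`` and
    ``y_col`` the variable pair for rank correlations.  ``subset`` is an
    optional pandas query applied to the summaries first.  Entries sharing
    a non-null ``family`` are FDR-adjusted together.
    """

    label: str
    test: str
    column: str | None = None
    x_col: str | None = None
    y_col: str | None = None
    tail: str = "two"
    family: str | None = None
    subset: str | None = None
    scope: str = "pooled"  # spearman only: which cohort(s) to correlate over


@dataclass
class TestResult:
    label: str
    test: str
    statistic_name: str
    statistic: float
    p_raw: float
    tail: str
    n_a: int
    n_b: int
    family: str | None = None
    p_adj: float | None = None


@dataclass
class ComparisonReport:
    cohort_a: str
    cohort_b: str
    results: list[TestResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.results])

    def to_json(self) -> str:
        return json.dumps(
            {
                "cohort_a": self.cohort_a,
                "cohort_b": self.cohort_b,
                "results": [asdict(r) for r in self.results],
            },
            indent=2,
            default=lambda o: None if (isinstance(o, float) and np.isnan(o)) else o,
        )

    def to_text(self) -> str:
        lines = [f"Comparison: {self.cohort_a} vs {self.cohort_b}", "-" * 64]
        for r in self.results:
            adj = f", p_adj={r.p_adj:.3g}" if r.p_adj is not None else ""
            lines.append(
                f"{r.label:<38} {r.statistic_name}={r.statistic:.4g} "
                f"p={r.p_raw:.3g}{adj} ({r.tail}, n={r.n_a}/{r.n_b})"
            )
        return "\n".join(lines)


def default_plan(rating_strata: tuple[str, ...] | None = None) -> list[PlanEntry]:
    """The report-structure plan: rating contrasts per stratum, profit,
    reveal contrasts (one FDR family of four), lottery KS, and the
    in-game-vs-lottery rank correlations."""
    strata = rating_strata or (
        "all",
        "dis_visible",
        "bio_visible",
        "bio_hidden",
        "bio_reveal",
        "dis_hidden",
        "dis_reveal",
    )
    plan = [
        PlanEntry(label=f"R rating [{s}]", test="mann_whitney", column=f"r_{s}", tail="two")
        for s in strata
    ]
    plan.append(
        PlanEntry(label="session profit", test="mann_whitney", column="session_profit", tail="two")
    )
    for info, pretty in (("disease", "infection"), ("bio", "biosecurity")):
        for price in (1000, 2000):
            plan.append(
                PlanEntry(
                    label=f"{pretty} reveals @${price}",
                    test="mann_whitney",
                    column=f"reveals_{info}_{price}",
                    tail="one_greater",
                    family="reveals",
                )
            )
    plan.append(PlanEntry(label="lottery safe ratio", test="ks", column="safe_ratio"))
    for scope, who in (("a", "cohort A"), ("b", "cohort B"), ("pooled", "all")):
        plan.append(
            PlanEntry(
                label=f"R vs safe ratio [{who}]",
                test="spearman",
                x_col="r_all",
                y_col="safe_ratio",
                scope=scope,
            )
        )
    # Conditional correlation: infection reveals vs R among participants
    # with at least one infection-information reveal, per cohort.
    for scope, who in (("a", "cohort A"), ("b", "cohort B")):
        plan.append(
            PlanEntry(
                label=f"infection reveals vs R | >=1 reveal [{who}]",
                test="spearman",
                x_col="reveals_disease_total",
                y_col="r_all",
                subset="reveals_disease_total >= 1",
                scope=scope,
            )
        )
    return plan


def _validate_plan(plan: list[PlanEntry], columns: set[str] | None = None) -> None:
    """Check a plan's structure; with ``columns`` also check metric names.

    ``columns=None`` performs the structural part only, which lets an
    orchestrator fail fast on a malformed plan before simulating.
    """
    for e in plan:
        if e.test not in _TESTS:
            raise ValueError(f"{e.label!r}: unknown test {e.test!r}")
        if e.tail not in _TAILS:
            raise ValueError(f"{e.label!r}: unknown tail {e.tail!r}")
        if e.scope not in _SCOPES:
            raise ValueError(f"{e.label!r}: unknown scope {e.scope!r}")
        needed = [e.x_col, e.y_col] if e.test == "spearman" else [e.column]
        for col in needed:
            if col is None:
                raise ValueError(f"{e.label!r}: plan entry is missing a column")
            if columns is not None and col not in columns:
                raise ValueError(f"{e.label!r}: unknown metric column {col!r}")


def validate_plan(plan: list[PlanEntry]) -> None:
    """Structural plan validation (test/tail/scope names, columns present)."""
    _validate_plan(plan, columns=None)


def _with_derived(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    disease_cols = [c for c in df.columns if c.startswith("reveals_disease_")]
    bio_cols = [c for c in df.columns if c.startswith("reveals_bio_")]
    if disease_cols:
        df["reveals_disease_total"] = df[disease_cols].sum(axis=1)
    if bio_cols:
        df["reveals_bio_total"] = df[bio_cols].sum(axis=1)
    return df


def compare_cohorts(
    summaries_a: pd.DataFrame,
    summaries_b: pd.DataFrame,
    plan: list[PlanEntry] | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> ComparisonReport:
    """Evaluate a comparison plan over two cohorts' summary tables.

    The plan is validated before any test runs; entries sharing a family
    receive Benjamini–Hochberg adjusted p-values.
    """
    plan = default_plan() if plan is None else plan
    a = _with_derived(summaries_a)
    b = _with_derived(summaries_b)
    _validate_plan(plan, set(a.columns) & set(b.columns))
    report = ComparisonReport(cohort_a=labels[0], cohort_b=labels[1])
    for e in plan:
        sa = a.query(e.subset) if e.subset else a
        sb = b.query(e.subset) if e.subset else b
        if e.test == "spearman":
            if e.scope == "a":
                pool = sa
            elif e.scope == "b":
                pool = sb
            else:
                pool = pd.concat([sa, sb], ignore_index=True)
            pair = pool[[e.x_col, e.y_col]].dropna()
            if len(pair) < 3:
                # Too few pairs to correlate; report a degenerate entry.
                r, p = float("nan"), float("nan")
            else:
                r, p = spearman(pair[e.x_col], pair[e.y_col])
            result = TestResult(
                label=e.label, test=e.test, statistic_name="r_s", statistic=r,
                p_raw=p, tail="two", family=e.family,
                n_a=len(pair) if e.scope != "b" else 0,
                n_b=len(pair) if e.scope != "a" else 0,
            )
        else:
            xa = sa[e.column].dropna().to_numpy()
            xb = sb[e.column].dropna().to_numpy()
            if xa.size == 0 or xb.size == 0:
                report.results.append(
                    TestResult(
                        label=e.label, test=e.test,
                        statistic_name="U" if e.test == "mann_whitney" else "D",
                        statistic=float("nan"), p_raw=float("nan"),
                        tail=e.tail, family=e.family, n_a=xa.size, n_b=xb.size,
                    )
                )
                continue
            if e.test == "mann_whitney":
                stat, p = mann_whitney_u(xa, xb, tail=e.tail)
                name = "U"
            else:
                stat, p = ks_two_sample(xa, xb)
                name = "D"
            result = TestResult(
                label=e.label, test=e.test, statistic_name=name, statistic=stat,
                p_raw=p, tail=e.tail if e.test == "mann_whitney" else "two",
                family=e.family, n_a=xa.size, n_b=xb.size,
            )
        report.results.append(result)

    # Per-family FDR adjustment.
    families: dict[str, list[int]] = {}
    for i, r in enumerate(report.results):
        if r.family is not None:
            families.setdefault(r.family, []).append(i)
    for idx in families.values():
        idx = [i for i in idx if not np.isnan(report.results[i].p_raw)]
        if not idx:
            continue
        adjusted = fdr_adjust([report.results[i].p_raw for i in idx])
        for i, p_adj in zip(idx, adjusted):
            report.results[i].p_adj = float(p_adj)
    return report
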