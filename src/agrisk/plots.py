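"""Violin-plot rendering of rating and reveal distributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["violin_by_cohort"]


def violin_by_cohort(
    summaries: dict[str, pd.DataFrame],
    column: str,
    out_path=None,
    title: str | None = None,
):
    """Violin plot of one summary metric, one violin per cohort.

    Returns the matplotlib Figure; writes to ``out_path`` (SVG/PNG by
    extension) when given.
    """
    labels, data = [], []
    for name, df in summaries.items():
        values = df[column].dropna().to_numpy()
        if values.size:
            labels.append(name)
            data.append(values)
    if not data:
        raise ValueError(f"no data to plot for column {column!r}")
    fig, ax = plt.subplots(figsize=(1.8 + 1.4 * len(data), 4.0))
    parts = ax.violinplot(data, showmeans=True, showextrema=False)
    for body in parts["bodies"]:
        body.set_alpha(0.6)
    ax.set_xticks(range(1, len(labels) + 1), labels)
    ax.set_ylabel(column)
    ax.set_title(title or column)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path)
        plt.close(fig)
    return fig
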