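"""Figure helpers: DSC/HD boxplots and stacked rating bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .review import RATING_SCALE

__all__ = ["metric_boxplots", "rating_bars"]


def metric_boxplots(metrics_by_name: dict[str, pd.DataFrame], path) -> None:
    """Side-by-side boxplots of per-vertebra DSC and HD for named cohorts."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    names = list(metrics_by_name)
    axes[0].boxplot([metrics_by_name[n]["dsc"].dropna() for n in names], tick_labels=names)
    axes[0].set_ylabel("DSC")
    axes[1].boxplot([metrics_by_name[n]["hd_mm"].dropna() for n in names], tick_labels=names)
    axes[1].set_ylabel("HD (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def rating_bars(rating_table: pd.DataFrame, path) -> None:
    """Stacked bars of the 4-point rating distribution per contour source."""
    fig, ax = plt.subplots(figsize=(5, 4))
    bottoms = [0.0] * len(rating_table.index)
    totals = rating_table.sum(axis=1)
    for rating in RATING_SCALE:
        frac = (rating_table.get(rating, 0) / totals).fillna(0.0)
        ax.bar(rating_table.index, frac, bottom=bottoms, label=f"rating {rating}")
        bottoms = [b + f for b, f in zip(bottoms, frac)]
    ax.set_ylabel("proportion of contours")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
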