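"""Presentation-only figures.

Nothing numeric originates here: every plot takes the already-computed
frames from the pipeline.  Uses matplotlib with the non-interactive Agg
backend so figures can be written headlessly.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .survival import KMCurve


def plot_km(curve: KMCurve, ax=None, label: str | None = None, month_length: float = 30.4375):
    """Step plot of a fitted product-limit curve, x-axis in months."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t = np.concatenate([[0.0], curve.event_times]) / month_length
    s = np.concatenate([[1.0], curve.survival])
    ax.step(t, s, where="post", label=label)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    if label:
        ax.legend()
    return ax


def plot_lot_flows(flows: pd.DataFrame, ax=None):
    """Stacked-bar rendition of line-to-line regimen flows.

    One bar per line number, segments sized by outflow counts; a light
    stand-in for a full Sankey diagram that needs no extra dependencies.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    if not len(flows):
        return ax
    for line, group in flows.groupby("line"):
        counts = group.groupby("from_regimen")["n"].sum().sort_values(ascending=False)
        bottom = 0
        for regimen, n in counts.items():
            ax.bar(line, n, bottom=bottom, width=0.6)
            if n >= counts.sum() * 0.05:
                ax.text(line, bottom + n / 2, f"{regimen} ({n})",
                        ha="center", va="center", fontsize=7)
            bottom += n
    ax.set_xlabel("line of therapy")
    ax.set_ylabel("patients")
    ax.set_xticks(sorted(flows["line"].unique()))
    return ax


def plot_drug_survival(table: pd.DataFrame, ax=None):
    """Horizontal bars of median drug survival with CI whiskers."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * max(len(table), 4) + 1))
    df = table.dropna(subset=["median_months"]).sort_values("median_months")
    y = np.arange(len(df))
    ax.barh(y, df["median_months"], height=0.6)
    for i, (_, row) in enumerate(df.iterrows()):
        lo, hi = row["ci_low_months"], row["ci_high_months"]
        if pd.notna(lo) and pd.notna(hi) and np.isfinite(hi):
            ax.plot([lo, hi], [i, i], color="black", lw=1)
    ax.set_yticks(y, df["drug_code"])
    ax.set_xlabel("median drug survival (months)")
    return ax
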