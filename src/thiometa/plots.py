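"""Optional forest and funnel plots (matplotlib, file output only)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["forest_plot", "funnel_plot"]


def forest_plot(forest: pd.DataFrame, path: str | Path, log_scale: bool = True) -> Path:
    """Render a forest table (as produced by meta.forest_frame) to a file."""
    df = forest.dropna(subset=["effect"]).reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(df) + 1.2))
    y = range(len(df))[::-1]
    ax.errorbar(
        df["effect"], list(y),
        xerr=[df["effect"] - df["ci_low"], df["ci_high"] - df["effect"]],
        fmt="s", color="k", ecolor="k", capsize=2, markersize=4,
    )
    ax.set_yticks(list(y))
    ax.set_yticklabels(df["study_id"])
    if log_scale:
        ax.set_xscale("log")
        ax.axvline(1.0, color="grey", lw=0.8)
    else:
        ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("effect (95% CI)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def funnel_plot(points: pd.DataFrame, guides: pd.DataFrame, path: str | Path) -> Path:
    """Funnel plot: per-study effect vs SE with the pseudo-95% triangle."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(guides["lower"], guides["se"], "--", color="grey", lw=0.8)
    ax.plot(guides["upper"], guides["se"], "--", color="grey", lw=0.8)
    ax.scatter(points["effect"], points["se"], color="k", s=18)
    ax.invert_yaxis()
    ax.set_xlabel("effect (log scale for OR)")
    ax.set_ylabel("standard error")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
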