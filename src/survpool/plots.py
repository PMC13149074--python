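"""Matplotlib figures for effect surfaces and rankings."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_survival_surface", "plot_hr_surface", "plot_rankings"]


def plot_survival_surface(surface, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for trt, df in surface.survival.groupby("treatment"):
        ax.plot(df["time_months"], df["mean"], label=trt, lw=1.4)
        ax.fill_between(df["time_months"], df["lo"], df["hi"], alpha=0.12)
    ax.set_xlabel("Months")
    ax.set_ylabel("Survival probability")
    ax.set_ylim(0, 1)
    ax.set_title(f"{surface.endpoint}: extrapolated survival")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_hr_surface(surface, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for trt, df in surface.hazard_ratio.groupby("treatment"):
        ax.plot(df["time_months"], df["mean"], label=trt, lw=1.4)
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("Months")
    ax.set_ylabel("Hazard ratio vs reference")
    ax.set_yscale("log")
    ax.set_title(f"{surface.endpoint}: time-dependent hazard ratios")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_rankings(rankings, path: str | Path) -> Path:
    times = sorted(rankings["time_months"].unique())
    fig, axes = plt.subplots(
        1, len(times), figsize=(3.2 * len(times), 4.5), sharey=False, squeeze=False
    )
    for ax, tp in zip(axes[0], times):
        sub = rankings[np.isclose(rankings["time_months"], tp)]
        y = np.arange(len(sub))[::-1]
        ax.errorbar(
            sub["mean"],
            y,
            xerr=[sub["mean"] - sub["lo"], sub["hi"] - sub["mean"]],
            fmt="o",
            ms=4,
            capsize=2,
        )
        ax.set_yticks(y)
        ax.set_yticklabels(sub["treatment"], fontsize=7)
        ax.set_xlabel("Predicted survival")
        ax.set_title(f"{tp:g} months", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
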