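"""Plot bundle: attendance profile, dose timing, spacing, delay curves, forest plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_attendance_profile",
    "plot_weekly_timing",
    "plot_spacing_histogram",
    "plot_delay_curves",
    "plot_forest",
]


def plot_attendance_profile(profile: pd.DataFrame, schedule=None, path=None):
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(profile["age"], profile["attending"], drawstyle="steps-post")
    if schedule is not None:
        for d in schedule.doses:
            ax.axvspan(d.window_start, d.window_end, alpha=0.15)
    ax.set_xlabel("infant age (days)")
    ax.set_ylabel("infants attending")
    ax.set_title("Study participation by age")
    return _finish(fig, path)


def plot_weekly_timing(weekly: pd.DataFrame, path=None):
    fig, ax = plt.subplots(figsize=(7, 4))
    for dose, grp in weekly.groupby("dose_number"):
        ax.bar(grp["week"] + 0.25 * (dose - 2), grp["count"], width=0.25, label=f"dose {dose}")
    ax.set_xlabel("week of age")
    ax.set_ylabel("vaccinations")
    ax.legend()
    ax.set_title("Vaccinations per week, by dose")
    return _finish(fig, path)


def plot_spacing_histogram(spacing: pd.DataFrame, min_interval: int = 28, path=None):
    pairs = sorted(spacing["dose_pair"].unique())
    fig, axes = plt.subplots(1, max(len(pairs), 1), figsize=(4 * max(len(pairs), 1), 3.5), squeeze=False)
    for ax, pair in zip(axes[0], pairs):
        grp = spacing[spacing["dose_pair"] == pair]
        ax.bar(grp["spacing"], grp["count"], color=np.where(grp["compressed"], "tab:red", "tab:blue"))
        ax.axvline(min_interval - 0.5, ls="--", color="k", lw=0.8)
        ax.set_title(f"doses {pair}")
        ax.set_xlabel("spacing (days)")
    axes[0][0].set_ylabel("vaccinations")
    return _finish(fig, path)


def plot_delay_curves(curves, schedule, path=None):
    fig, ax = plt.subplots(figsize=(7, 4))
    for curve in curves:
        ages = np.clip(curve.ages, 0, None)
        ax.step(ages, curve.cum_prob, where="post",
                label=f"dose {curve.dose_number} ({curve.assumption})")
        ax.axvline(schedule.dose(curve.dose_number).target_age, color="grey", lw=0.8)
    for q in (0.5, 0.75, 0.9):
        ax.axhline(q, ls=":", color="grey", lw=0.8)
    ax.set_xlabel("infant age (days)")
    ax.set_ylabel("cumulative administration probability")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    return _finish(fig, path)


def plot_forest(screen: pd.DataFrame, path=None):
    outcomes = list(screen["outcome"].unique())
    fig, axes = plt.subplots(1, len(outcomes), figsize=(3.5 * len(outcomes), 0.35 * screen["covariate"].nunique() + 2), squeeze=False, sharey=True)
    covs = list(screen["covariate"].unique())
    ypos = {c: i for i, c in enumerate(covs)}
    for ax, outcome in zip(axes[0], outcomes):
        sub = screen[screen["outcome"] == outcome]
        for _, row in sub.iterrows():
            y = ypos[row["covariate"]]
            if row["defined"] and np.isfinite(row["rr"]):
                ax.plot([row["ci_low"], row["ci_high"]], [y, y], color="tab:blue")
                ax.plot(row["rr"], y, "o", color="tab:blue", ms=4)
        ax.axvline(1.0, color="grey", ls="--", lw=0.8)
        ax.set_xscale("log")
        ax.set_title(outcome)
    axes[0][0].set_yticks(range(len(covs)), covs)
    return _finish(fig, path)


def _finish(fig, path):
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path
    return fig
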