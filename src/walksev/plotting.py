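"""Optional figure export (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def severity_edss_scatter(subject_severity: pd.DataFrame, path: Path,
                          hc_edss: float = 0.0) -> None:
    """Scatter of per-subject mean severity against mean EDSS with the
    least-squares line, coloured by group.

    ``subject_severity`` is the frame produced by the CV experiment
    (columns subject_id, group, severity, edss); healthy controls are
    plotted at ``hc_edss``.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = subject_severity.assign(edss=subject_severity["edss"]
                                 .fillna(hc_edss))
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"hc": "tab:green", "mild": "tab:orange", "mod": "tab:red"}
    for group, grp in df.groupby("group"):
        ax.scatter(grp["edss"], grp["severity"], s=18, alpha=0.8,
                   color=colors.get(group, "tab:gray"), label=group)
    slope, intercept = np.polyfit(df["edss"], df["severity"], 1)
    xs = np.linspace(df["edss"].min(), df["edss"].max(), 50)
    ax.plot(xs, slope * xs + intercept, "k-", lw=1)
    ax.set_xlabel("mean EDSS")
    ax.set_ylabel("mean severity $\\hat{y}$")
    ax.set_ylim(-0.1, 2.1)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def severity_trend_panel(daily: pd.DataFrame, trend: pd.DataFrame,
                         subject_id: str, path: Path,
                         event_days: list[int] | None = None) -> None:
    """One subject's daily severities (points) with the 7-day trend (line)
    and optional event markers — the per-subject longitudinal view."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = daily[daily["subject_id"] == subject_id]
    t = trend[trend["subject_id"] == subject_id]
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(d["study_day"], d["value"], "o", ms=3, alpha=0.6,
            label="daily $\\hat{y}_d$")
    ax.plot(t["study_day"], t["trend"], "-", lw=2, color="tab:blue",
            label="7-day trend $\\hat{z}$")
    for day in event_days or []:
        ax.axvline(day, color="k", lw=1)
    ax.set_xlabel("study day")
    ax.set_ylabel("severity")
    ax.set_ylim(-0.1, 2.1)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
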