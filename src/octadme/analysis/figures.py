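"""Per-month group trajectory summaries and the change-from-baseline figures."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def trajectory_summary(
    deltas: pd.DataFrame,
    eyes: pd.DataFrame,
    group_col: str,
    value_col: str,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Mean change per month per group with t-based confidence limits.

    CI = mean +/- t(1 - (1-ci)/2, n-1) * SE; single-observation cells get
    NaN limits.
    """
    merged = deltas.merge(eyes[["patient_id", "eye", group_col]],
                          on=["patient_id", "eye"], how="inner")
    merged = merged.dropna(subset=[group_col, value_col])
    rows = []
    for (month, grp), sub in merged.groupby(["month", group_col], sort=True):
        vals = sub[value_col].to_numpy(float)
        n = len(vals)
        mean = float(vals.mean())
        if n > 1:
            se = vals.std(ddof=1) / np.sqrt(n)
            half = float(stats.t.ppf(1 - (1 - ci) / 2, n - 1) * se)
        else:
            half = np.nan
        rows.append({"month": month, "group": grp, "n": n, "mean": mean,
                     "ci_lo": mean - half, "ci_hi": mean + half})
    return pd.DataFrame(rows)


def plot_trajectories(
    deltas: pd.DataFrame,
    eyes: pd.DataFrame,
    group_col: str,
    out_path: str,
    value_cols: tuple[str, str] = ("d_bcva_letters", "d_crt1_um"),
    labels: tuple[str, str] = ("BCVA change (ETDRS letters)", "1 mm CRT reduction (µm)"),
) -> str:
    """Two-panel mean-change figure (BCVA, CRT) with 95% CI error bars."""
    fig, axes = plt.subplots(1, len(value_cols), figsize=(5 * len(value_cols), 4))
    axes = np.atleast_1d(axes)
    for ax, col, label in zip(axes, value_cols, labels):
        summary = trajectory_summary(deltas, eyes, group_col, col)
        for grp, sub in summary.groupby("group"):
            sub = sub.sort_values("month")
            yerr = (sub["mean"] - sub["ci_lo"]).to_numpy()
            ax.errorbar(sub["month"], sub["mean"], yerr=yerr, marker="o",
                        capsize=3, label=f"{group_col}={grp}")
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.set_xlabel("month")
        ax.set_ylabel(label)
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
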