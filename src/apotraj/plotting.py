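"""Trajectory figures: per-group mean curves with 95% CI bands."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

_AXIS_LABELS = {
    "time_rel": "Years relative to first pregnancy (negative = before)",
    "age": "Age (years)",
}
_OUTCOME_LABELS = {
    "sbp": "Systolic BP (mmHg)",
    "dbp": "Diastolic BP (mmHg)",
    "bmi": "BMI (kg/m$^2$)",
    "total_chol": "Total cholesterol (mmol/L)",
    "hdl_chol": "HDL cholesterol (mmol/L)",
    "glucose": "Glucose (mmol/L)",
}


def plot_trajectories(results, grid, ax=None, ci: bool = True):
    """Plot predicted group trajectories from a fitted results object."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    traj = results.predict_trajectories(grid)
    for group, sub in traj.groupby("group", sort=False):
        (line,) = ax.plot(sub["axis_value"], sub["estimate"], label=str(group))
        if ci:
            ax.fill_between(sub["axis_value"], sub["lower"], sub["upper"],
                            alpha=0.2, color=line.get_color())
    t = results.model.table
    ax.set_xlabel(_AXIS_LABELS[results.model.axis])
    ax.set_ylabel(_OUTCOME_LABELS.get(t.outcome, t.outcome))
    ax.set_title(f"{t.outcome} by {t.exposure}")
    ax.legend(title=t.exposure, fontsize=8)
    if results.model.axis == "time_rel":
        ax.axvline(0.0, color="grey", lw=0.8, ls=":")
    return ax


def save_trajectory_plot(results, path, grid) -> str:
    ax = plot_trajectories(results, grid)
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)
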