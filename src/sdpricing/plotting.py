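"""Figure export: premium-subsystem overlays, stability and sensitivity
comparisons. Matplotlib with the Agg backend; every function returns the
Figure and optionally writes it to a path."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .core import Trajectory  # noqa: E402
from .experiments import SensitivityRun, StabilityReport  # noqa: E402

__all__ = ["plot_series", "plot_stability", "plot_sensitivity"]


def _save(fig, path):
    if path is not None:
        fig.savefig(Path(path), dpi=150, bbox_inches="tight")
    return fig


def plot_series(traj: Trajectory, names: list[str], path: str | Path | None = None,
                ylabel: str = "score (dimensionless)"):
    """Overlay selected variable series against time."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for name in names:
        ax.plot(traj.times, traj.series[name], label=name)
    ax.set_xlabel("time (years)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    return _save(fig, path)


def plot_stability(report: StabilityReport, trajectories: dict[float, Trajectory],
                   stock_name: str, path: str | Path | None = None):
    """Overlay the stock series from runs at different Euler steps."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for dt in report.step_sizes:
        traj = trajectories[dt]
        ax.plot(traj.times, traj.series[stock_name], label=f"dt = {dt:g}")
    ax.set_xlabel("time (years)")
    ax.set_ylabel(stock_name)
    ax.legend(fontsize=8)
    return _save(fig, path)


def plot_sensitivity(runs: list[SensitivityRun], stock_name: str,
                     path: str | Path | None = None):
    """Overlay the stock under each one-at-a-time perturbation."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for run in runs:
        ax.plot(run.trajectory.times, run.trajectory.series[stock_name],
                label=f"{run.parameter} (x{run.scale:g})")
    ax.set_xlabel("time (years)")
    ax.set_ylabel(stock_name)
    ax.legend(fontsize=7)
    return _save(fig, path)
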