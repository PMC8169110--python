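"""Simple trajectory and sensitivity figures (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt

from .dynamics import TrajectorySeries


def plot_trajectories(trajectories: dict[str, TrajectorySeries], ax=None):
    """Tumor volume over time, one line per arm."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for arm, traj in trajectories.items():
        ax.plot(traj.times, traj.V, label=arm)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("tumor volume (mm$^3$)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_kd_sensitivity(final_volumes: dict[str, float], ax=None):
    """Bar chart of final tumor volume under Kd perturbation."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    labels = list(final_volumes)
    ax.bar(labels, [final_volumes[k] for k in labels], color="#777777")
    ax.set_ylabel("final tumor volume (mm$^3$)")
    ax.set_xlabel("Kd perturbation")
    return ax
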