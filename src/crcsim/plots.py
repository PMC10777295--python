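"""Plot helpers mirroring the reference figures (trajectory, delay overlay
with division markers, dosage sweep with determination band, knockout
overlay)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .model import SPECIES
from .simulate import Trajectory

_ASC_COLOR = "#b22222"


def plot_trajectory(traj: Trajectory, path: str | Path, all_species: bool = True):
    fig, ax = plt.subplots(figsize=(7, 4.2))
    if all_species:
        for i, name in enumerate(SPECIES):
            lw = 2.2 if name == "ASC" else 1.0
            ax.plot(traj.times, traj.states[:, i], label=name, linewidth=lw)
        ax.legend(fontsize=8, ncol=2)
    else:
        ax.plot(traj.times, traj.x, color=_ASC_COLOR, linewidth=2.2, label="ASC")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (AU)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_tau_overlay(sweep, path: str | Path):
    fig, ax = plt.subplots(figsize=(7, 4.2))
    n = max(len(sweep.axis_values) - 1, 1)
    for i, (tau, traj, feat) in enumerate(
        zip(sweep.axis_values, sweep.trajectories, sweep.features)
    ):
        color = plt.cm.Reds(0.35 + 0.6 * i / n) if tau > 0 else "black"
        ax.plot(traj.times, traj.x, color=color, label=f"tau = {tau:g} h")
        if feat.t_zero is not None:
            ax.axvline(feat.t_zero, color=color, linestyle="--", linewidth=0.8)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("ASC (AU)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_dosage_sweep(sweep, threshold: float, path: str | Path):
    fig, ax = plt.subplots(figsize=(7, 4.2))
    n = max(len(sweep.axis_values) - 1, 1)
    top = max((f.x_peak for f in sweep.features), default=threshold) * 1.1
    ax.axhspan(threshold, max(top, threshold * 1.3), color="paleturquoise",
               alpha=0.5, label="determination range")
    for i, (kx, traj) in enumerate(zip(sweep.axis_values, sweep.trajectories)):
        ax.plot(traj.times, traj.x, color=plt.cm.viridis(i / n),
                label=f"k_x = {kx:g}")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("ASC (AU)")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_knockouts(wt_traj: Trajectory, reports, trajectories, path: str | Path):
    fig, ax = plt.subplots(figsize=(7, 4.2))
    ax.plot(wt_traj.times, wt_traj.x, color="black", linewidth=2.2, label="wild type")
    for rep, traj in zip(reports, trajectories):
        ax.plot(traj.times, traj.x, linewidth=1.2, label=f"{rep.gene}-")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("ASC (AU)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
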