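"""Optional matplotlib rendering of sweep grids and trajectories.

Imported lazily by the CLI so the core library has no hard graphics
dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .model import Trajectory
from .sweeps import SweepResult

__all__ = ["plot_sweep_heatmaps", "plot_trajectory"]


def plot_sweep_heatmaps(result: SweepResult, path: str | Path, title: str = "") -> Path:
    """Side-by-side equilibrium coverage and confidence heatmaps."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), constrained_layout=True)
    y_labels = [
        f"[{v[0]:.2f},{v[1]:.2f}]" if isinstance(v, tuple) else f"{v:.2f}"
        for v in result.axis1.values
    ]
    for ax, mat, label in (
        (axes[0], result.equilibrium_coverage, "equilibrium coverage (V+)"),
        (axes[1], result.equilibrium_confidence, "equilibrium confidence (A+)"),
    ):
        im = ax.imshow(
            np.asarray(mat), origin="lower", aspect="auto", vmin=0, vmax=1, cmap="RdBu"
        )
        ax.set_title(label)
        ax.set_xlabel(result.axis2.parameter)
        ax.set_ylabel(result.axis1.parameter)
        ax.set_xticks(range(len(result.axis2)), [f"{v:.2g}" for v in result.axis2.values], rotation=90, fontsize=6)
        ax.set_yticks(range(len(result.axis1)), y_labels, fontsize=6)
        fig.colorbar(im, ax=ax)
    if title:
        fig.suptitle(title)
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_trajectory(trajectory: Trajectory, path: str | Path, title: str = "") -> Path:
    """Phenotype and trait frequencies over iterations."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = trajectory.to_dataframe()
    fig, ax = plt.subplots(figsize=(7, 4), constrained_layout=True)
    for col, style in (
        ("freq_VpAp", "-"),
        ("freq_VpAm", "--"),
        ("freq_VmAp", "-."),
        ("freq_VmAm", ":"),
    ):
        ax.plot(df["iteration"], df[col], style, label=col.replace("freq_", ""))
    ax.plot(df["iteration"], df["coverage"], "k-", lw=2, label="coverage (V+)")
    ax.plot(df["iteration"], df["confidence"], "m-", lw=2, label="confidence (A+)")
    ax.set_xlabel("iteration")
    ax.set_ylabel("frequency")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
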