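"""Radar scatter plots with gate overlays (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .template import GateRegion


def plot_radar(
    points: np.ndarray,
    gates: dict[str, GateRegion],
    path,
    title: str = "",
    max_points: int = 20_000,
    seed: int = 0,
) -> None:
    """Scatter projected blasts with the gate polygons overlaid."""
    points = np.asarray(points)
    if points.shape[0] > max_points:
        rng = np.random.default_rng(seed)
        points = points[np.sort(rng.choice(points.shape[0], max_points, replace=False))]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(points[:, 0], points[:, 1], s=1, alpha=0.3, color="crimson", lw=0)
    styles = {"hypergranular": ("black", "-"), "microgranular": ("gray", "--")}
    for name, gate in gates.items():
        color, ls = styles.get(name, ("tab:blue", "-"))
        verts = np.vstack([gate.vertices, gate.vertices[:1]])
        ax.plot(verts[:, 0], verts[:, 1], color=color, ls=ls, lw=1.5, label=name)
    ax.set_xlabel("radar x")
    ax.set_ylabel("radar y")
    ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
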