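"""Wireframe rendering of discriminant-axis shape endpoints.

2-D shapes are drawn directly; 3-D shapes as two orthogonal projections
(x-y and x-z).  Points are connected in index order as a light guide.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def _draw(ax, shape: np.ndarray, cols: tuple[int, int], color: str, label: str) -> None:
    xy = shape[:, cols]
    ax.plot(xy[:, 0], xy[:, 1], "-", lw=0.6, alpha=0.4, color=color)
    ax.plot(xy[:, 0], xy[:, 1], "o", ms=3, color=color, label=label)


def plot_shape_pair(
    endpoint_minus: np.ndarray,
    endpoint_plus: np.ndarray,
    path: str | Path,
    title: str = "",
) -> None:
    """Save an SVG/PNG comparing the two endpoint shapes."""
    minus = np.asarray(endpoint_minus, float)
    plus = np.asarray(endpoint_plus, float)
    m = minus.shape[1]
    if m == 2:
        fig, ax = plt.subplots(figsize=(4, 4))
        _draw(ax, minus, (0, 1), "tab:blue", "negative end")
        _draw(ax, plus, (0, 1), "tab:red", "positive end")
        ax.set_aspect("equal")
        ax.legend(fontsize=7)
        axes = [ax]
    else:
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 4))
        for ax, cols, name in ((ax1, (0, 1), "x-y"), (ax2, (0, 2), "x-z")):
            _draw(ax, minus, cols, "tab:blue", "negative end")
            _draw(ax, plus, cols, "tab:red", "positive end")
            ax.set_aspect("equal")
            ax.set_title(name, fontsize=8)
        ax1.legend(fontsize=7)
        axes = [ax1, ax2]
    for ax in axes:
        ax.tick_params(labelsize=6)
    if title:
        fig.suptitle(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def save_wireframes(report, outdir: str | Path) -> None:
    """Write one wireframe SVG per comparison in an element report."""
    outdir = Path(outdir)
    for pair_name, ep in report.endpoints.items():
        plot_shape_pair(
            np.asarray(ep["endpoint_minus"]),
            np.asarray(ep["endpoint_plus"]),
            outdir / f"{report.element}_{pair_name}_wireframe.svg",
            title=f"{report.element}: {pair_name.replace('__vs__', ' vs ')}",
        )
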