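"""PNG rendering of TF maps, importance maps and cluster patterns."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .spectral import FREQS
from .synthdata import T_START_MS


def _extent():
    return [T_START_MS, 1000.0, FREQS[0], FREQS[-1] + 1]


def plot_map(values: np.ndarray, title: str = "", path=None, cmap: str = "viridis"):
    """Render one 146 x 48 matrix as a time-frequency image."""
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(
        values, aspect="auto", origin="lower", extent=_extent(), cmap=cmap
    )
    ax.axvline(0, color="w", lw=0.8, ls="--")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(title)
    fig.colorbar(im, ax=ax)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_contrast(labels: np.ndarray, title: str = "", path=None):
    """Render a tri-state contrast map (neither/both/A/B-dominant)."""
    cmap = matplotlib.colors.ListedColormap(["white", "lightgray", "crimson", "royalblue"])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.imshow(
        labels, aspect="auto", origin="lower", extent=_extent(), cmap=cmap,
        vmin=-0.5, vmax=3.5,
    )
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
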