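"""Snapshot rendering.

Colour conventions follow the usual presentation of this model:
cooperators blue and defectors red per layer; cross-layer pairs CC blue,
DD red, CD lightgrey, DC black.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless rendering

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .engine import BilayerState
from .errors import InvalidParameterError
from .io import snapshot_text

__all__ = ["render_snapshot", "pair_codes"]

_LAYER_CMAP = ListedColormap(["tab:red", "tab:blue"])  # 0 = D, 1 = C
_PAIR_CMAP = ListedColormap(["tab:blue", "lightgrey", "black", "tab:red"])  # CC, CD, DC, DD


def pair_codes(state: BilayerState) -> np.ndarray:
    """Integer map of cross-layer pairs: 0=CC, 1=CD, 2=DC, 3=DD."""
    plus, minus = state.strategies[1], state.strategies[0]
    return (1 - plus) * 2 + (1 - minus)


def render_snapshot(state: BilayerState, mode: str = "pairs"):
    """Render a configuration.

    Modes: ``per_layer`` (two panels, C blue / D red), ``pairs`` (one panel
    with the four pair colours) or ``text`` (the plain snapshot format,
    returned as a string).
    """
    if mode == "text":
        return snapshot_text(state)
    if mode == "per_layer":
        fig, axes = plt.subplots(1, 2, figsize=(8, 4))
        for ax, slot, label in ((axes[0], 1, "layer +1"), (axes[1], 0, "layer -1")):
            ax.imshow(state.strategies[slot], cmap=_LAYER_CMAP, vmin=0, vmax=1, interpolation="none")
            ax.set_title(label)
            ax.set_xticks([])
            ax.set_yticks([])
        fig.tight_layout()
        return fig
    if mode == "pairs":
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.imshow(pair_codes(state), cmap=_PAIR_CMAP, vmin=0, vmax=3, interpolation="none")
        ax.set_title("pairs (CC blue, CD lightgrey, DC black, DD red)", fontsize=9)
        ax.set_xticks([])
        ax.set_yticks([])
        fig.tight_layout()
        return fig
    raise InvalidParameterError(f"unknown render mode {mode!r}")
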