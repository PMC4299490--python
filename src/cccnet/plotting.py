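"""Minimal plots: ordered binding matrix and a circular competition web."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_cocluster_matrix(B: pd.DataFrame, row_assignment: pd.Series,
                          col_assignment: pd.Series, ax=None):
    """Heatmap of the binding matrix with rows/columns ordered by co-cluster."""
    import matplotlib.pyplot as plt

    rows = row_assignment.sort_values().index
    cols = col_assignment.sort_values().index
    M = B.loc[rows, cols]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 8))
    ax.imshow(M.to_numpy(), aspect="auto", cmap="Greys", interpolation="nearest")
    ax.set_xticks(range(len(cols)), cols, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_xlabel("cell type")
    ax.set_ylabel("ligand (ordered by co-cluster)")
    return ax


def plot_competition_web(P: pd.DataFrame, ax=None, min_share: float = 0.02):
    """Circular apparent-competition web; edge width ~ PAC share at each end."""
    import matplotlib.pyplot as plt

    cells = list(P.index)
    theta = np.linspace(0, 2 * np.pi, len(cells), endpoint=False)
    pos = {c: (np.cos(t), np.sin(t)) for c, t in zip(cells, theta)}
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for i in cells:
        for j in cells:
            if i >= j:
                continue
            share = max(P.loc[i, j], P.loc[j, i])
            if share < min_share:
                continue
            (x0, y0), (x1, y1) = pos[i], pos[j]
            ax.plot([x0, x1], [y0, y1], color="tab:blue", alpha=0.6, lw=8 * share)
    for c, (x, y) in pos.items():
        ax.text(x * 1.1, y * 1.1, c, ha="center", va="center", fontsize=8)
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
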