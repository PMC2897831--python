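"""Delta-delta comparison of ligand space and sequence space.

For every receptor shared by two distance matrices, its mean distance to
all other shared receptors is computed in each space (both matrices
min-max renormalized over the shared off-diagonal first, so the axes are
comparable) and plotted against each other.  Points on the X = Y
diagonal keep their relative position between spaces; the residual
``mean_y − mean_x`` is positive for receptors that are relatively more
isolated in space Y.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .profiles import minmax_offdiagonal


def delta_delta(
    Dx: DistanceMatrix, Dy: DistanceMatrix, stat: str = "mean"
) -> pd.DataFrame:
    """Per-receptor mean (or median) distances in two spaces.

    Returns a DataFrame with columns ``target_id``, ``mean_x``,
    ``mean_y``, ``residual`` (= mean_y − mean_x), sorted by target id.
    Self-distances are excluded from the averages.
    """
    if stat not in {"mean", "median"}:
        raise ValueError(f"unknown statistic {stat!r}")
    shared = sorted(set(Dx.ids) & set(Dy.ids))
    if len(shared) < 3:
        raise ValueError(f"label intersection has {len(shared)} targets; need >= 3")
    X = minmax_offdiagonal(Dx.filter(shared).data)
    Y = minmax_offdiagonal(Dy.filter(shared).data)
    n = len(shared)
    mask = ~np.eye(n, dtype=bool)
    agg = np.mean if stat == "mean" else np.median
    mx = np.array([agg(X[i, mask[i]]) for i in range(n)])
    my = np.array([agg(Y[i, mask[i]]) for i in range(n)])
    return pd.DataFrame(
        {"target_id": shared, "mean_x": mx, "mean_y": my, "residual": my - mx}
    )


def plot_delta_delta(
    table: pd.DataFrame, out_path: str | Path, annotate: bool = True
) -> Path:
    """Scatter with the X = Y diagonal; a TSV next to the image is always written.

    The numbers are the contract; the plot is decoration.
    """
    if table.empty:
        raise ValueError("empty delta-delta table")
    out_path = Path(out_path)
    tsv_path = out_path.with_suffix(".tsv")
    table.to_csv(tsv_path, sep="\t", index=False)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(table["mean_x"], table["mean_y"], s=18, zorder=3)
    lim = [0, max(1.0, table[["mean_x", "mean_y"]].to_numpy().max()) * 1.05]
    ax.plot(lim, lim, color="0.6", lw=1, zorder=1)
    if annotate:
        for _, row in table.iterrows():
            ax.annotate(row["target_id"], (row["mean_x"], row["mean_y"]), fontsize=6)
    ax.set_xlabel("mean distance, substructure space")
    ax.set_ylabel("mean distance, sequence space")
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
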