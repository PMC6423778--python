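"""Figure helpers: clustered heatmaps, dendrograms and secretome bars."""

from __future__ import annotations

import numpy as np
import pandas as pd

from stemsig.secretome import CytokineProfile
from stemsig.signatures import ClusterTree, SubsetMatrix


def heatmap(
    matrix: pd.DataFrame,
    path,
    row_order: list[str] | None = None,
    col_order: list[str] | None = None,
    log2: bool = True,
    cmap: str = "viridis",
) -> None:
    """Save a heatmap, optionally with dendrogram-derived axis orders."""
    import matplotlib.pyplot as plt

    data = matrix
    if row_order is not None:
        data = data.loc[row_order]
    if col_order is not None:
        data = data[col_order]
    values = np.log2(data.to_numpy() + 1.0) if log2 else data.to_numpy()
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * data.shape[1]), max(4, 0.08 * data.shape[0]))
    )
    im = ax.imshow(values, aspect="auto", cmap=cmap, interpolation="nearest")
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="log2(signal + 1)" if log2 else "signal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def clustered_heatmap(subset: SubsetMatrix, path, **kwargs) -> None:
    """Heatmap of a subset matrix ordered by its row/column trees."""
    row_order = subset.row_tree.leaf_order() if subset.row_tree else None
    col_order = subset.col_tree.leaf_order() if subset.col_tree else None
    heatmap(subset.matrix, path, row_order=row_order, col_order=col_order, **kwargs)


def dendrogram(tree: ClusterTree, path) -> None:
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy

    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(tree.labels)), 4))
    hierarchy.dendrogram(
        tree.linkage_matrix, labels=tree.labels, ax=ax, color_threshold=0
    )
    ax.set_ylabel("merge height")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def secretome_bars(
    profiles: dict[str, CytokineProfile], path, min_percent: float = 0.0
) -> None:
    """Grouped bar plot of percent-of-reference values per preparation."""
    import matplotlib.pyplot as plt

    preps = list(profiles)
    analytes = sorted(
        {
            a
            for p in profiles.values()
            for a, v in p.percent_of_reference.items()
            if v >= min_percent
        }
    )
    x = np.arange(len(analytes))
    width = 0.8 / max(len(preps), 1)
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(analytes)), 4))
    for i, prep in enumerate(preps):
        vals = [profiles[prep].percent_of_reference.get(a, 0.0) for a in analytes]
        ax.bar(x + i * width, vals, width, label=prep)
    ax.axhline(5, color="grey", ls="--", lw=0.8)
    ax.axhline(20, color="black", ls="--", lw=0.8)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(analytes, rotation=90, fontsize=6)
    ax.set_ylabel("% of reference")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
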