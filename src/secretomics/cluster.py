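"""Column centering, WPGMA (weighted-linkage) clustering and heatmap rendering.

The secretome abundance table is visualized as a hierarchically clustered
heatmap: columns (samples) are centered so that cell values are differences of
normalized spectra from the sample mean, and rows and columns are ordered by
WPGMA dendrograms on Euclidean distances.

WPGMA ("weighted" linkage) merges the closest pair of clusters at each step
and defines the distance from the merged cluster to any third cluster as the
plain arithmetic mean of its two constituents' distances, irrespective of
cluster sizes.  The implementation below is a direct O(n^3) agglomeration
with a deterministic tie-break (lowest cluster-id pair first) so that merge
trees are reproducible across platforms; scipy's linkage output format is
used so results interoperate with scipy/seaborn dendrogram tooling.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

import matplotlib

matplotlib.use("Agg")  # headless rendering; must precede pyplot import
import matplotlib.pyplot as plt  # noqa: E402
import seaborn as sns  # noqa: E402


def center_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Subtract each column's mean; every output column sums to zero."""
    if len(table) == 0 or table.shape[1] == 0:
        raise ValueError("cannot center an empty table")
    values = table.astype(float)
    return values - values.mean(axis=0)


def weighted_linkage(distances) -> np.ndarray:
    """WPGMA merge tree in scipy linkage format.

    Parameters
    ----------
    distances : square symmetric matrix with zero diagonal, or a condensed
        distance vector as produced by :func:`scipy.spatial.distance.pdist`.

    Returns
    -------
    numpy.ndarray of shape (n-1, 4): columns are the two merged cluster ids,
    the merge height, and the size of the new cluster.  Leaves are ids
    ``0..n-1``; the cluster created at step k has id ``n+k``.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim == 1:
        D = squareform(D)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance input must be square or condensed")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distances must be nonnegative")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")

    n = D.shape[0]
    if n < 2:
        return np.empty((0, 4))
    # dist maps frozen (a, b) id pairs (a < b) to current cluster distances
    dist: dict[tuple[int, int], float] = {
        (i, j): D[i, j] for i in range(n) for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    Z = np.empty((n - 1, 4))
    for step in range(n - 1):
        # closest pair; ties broken on the lexicographically smallest id pair
        (a, b), height = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        new = n + step
        for k in active - {a, b}:
            dak = dist[(min(a, k), max(a, k))]
            dbk = dist[(min(b, k), max(b, k))]
            dist[(k, new)] = 0.5 * (dak + dbk)
        active -= {a, b}
        for pair in [p for p in dist if a in p or b in p]:
            del dist[pair]
        active.add(new)
        size[new] = size[a] + size[b]
        Z[step] = (a, b, height, size[new])
    return Z


@dataclasses.dataclass
class HeatmapResult:
    """Clustered heatmap: ordered centered matrix plus the merge trees."""

    matrix: pd.DataFrame  # centered values, rows/cols in dendrogram leaf order
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_order: list[int]
    col_order: list[int]


def _leaf_order(Z: np.ndarray, n: int) -> list[int]:
    from scipy.cluster.hierarchy import leaves_list

    return list(leaves_list(Z)) if Z is not None and n > 1 else list(range(n))


def clustermap(
    table: pd.DataFrame,
    metric: str = "euclidean",
    out_image: str | Path | None = None,
    center: bool = True,
) -> HeatmapResult:
    """Cluster a (loci x samples) abundance table and optionally render it.

    Columns are centered (unless ``center=False``), WPGMA trees are computed
    on row and column ``metric`` distances, and rows/columns are reordered by
    dendrogram leaf order.  Rendering uses a grayscale ramp (white = lower,
    black = higher abundance).  Axes with a single element are left unordered
    and unclustered.
    """
    values = center_columns(table) if center else table.astype(float)
    nrow, ncol = values.shape
    row_Z = weighted_linkage(pdist(values.to_numpy(), metric)) if nrow > 1 else None
    col_Z = weighted_linkage(pdist(values.to_numpy().T, metric)) if ncol > 1 else None
    row_order = _leaf_order(row_Z, nrow)
    col_order = _leaf_order(col_Z, ncol)
    ordered = values.iloc[row_order, col_order]

    if out_image is not None:
        if row_Z is not None and col_Z is not None:
            grid = sns.clustermap(
                values,
                row_linkage=row_Z,
                col_linkage=col_Z,
                cmap="Greys",
                figsize=(max(4, 0.5 * ncol + 2), max(4, 0.2 * nrow + 2)),
            )
            grid.savefig(out_image, dpi=150)
            plt.close(grid.fig)
        else:  # degenerate axis: plain heatmap in computed order
            fig, ax = plt.subplots(
                figsize=(max(4, 0.5 * ncol + 2), max(2, 0.2 * nrow + 1))
            )
            sns.heatmap(ordered, cmap="Greys", ax=ax)
            fig.savefig(out_image, dpi=150, bbox_inches="tight")
            plt.close(fig)

    return HeatmapResult(
        matrix=ordered,
        row_linkage=row_Z,
        col_linkage=col_Z,
        row_order=row_order,
        col_order=col_order,
    )


def linkage_frame(Z: np.ndarray) -> pd.DataFrame:
    """Merge tree as a table (cluster_a, cluster_b, height, size)."""
    return pd.DataFrame(
        Z, columns=["cluster_a", "cluster_b", "height", "size"]
    ).astype({"cluster_a": int, "cluster_b": int, "size": int})
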