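"""Two-way agglomerative clustering of the consensus-filtered expression
matrix, with uncentered correlation similarity and average (UPGMA) linkage.

"Uncentered correlation" is the zero-centered cosine used by the Cluster 3.0
program: sum(x*y) / sqrt(sum(x^2) * sum(y^2)) with no mean subtraction.
Dissimilarity is 1 - similarity; inter-cluster distance is the unweighted
average of all cross-pair dissimilarities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .consensus_model import ConsensusModel

logger = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """An agglomerative tree: scipy-style merge list plus leaf ordering.

    ``merges`` rows are (node_a, node_b, height, size) with leaves numbered
    0..n-1 and internal nodes n..2n-2; ``labels`` are the item names in leaf
    index order; ``leaf_order`` is the display ordering of leaf indices.
    """

    merges: np.ndarray
    labels: list
    leaf_order: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def ordered_labels(self) -> list:
        return [self.labels[i] for i in self.leaf_order]


def uncentered_correlation(x, y) -> float:
    """Cosine about zero: sum(xy) / sqrt(sum(x^2) sum(y^2)).

    A zero-norm vector has similarity 0 to everything (with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("uncentered_correlation needs two equal-length 1-D vectors")
    nx = np.dot(x, x)
    ny = np.dot(y, y)
    if nx == 0 or ny == 0:
        logger.warning("zero-norm vector in uncentered correlation; similarity defined as 0")
        return 0.0
    return float(np.dot(x, y) / np.sqrt(nx * ny))


def uncentered_similarity_matrix(m: np.ndarray) -> np.ndarray:
    """Pairwise uncentered correlation between the rows of ``m``."""
    m = np.asarray(m, dtype=float)
    norms = np.sqrt((m * m).sum(axis=1))
    zero = norms == 0
    if zero.any():
        logger.warning("%d zero-norm row(s); their similarities defined as 0", int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    sim = (m @ m.T) / np.outer(safe, safe)
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    np.fill_diagonal(sim, np.where(zero, 0.0, 1.0))
    return np.clip(sim, -1.0, 1.0)


def filter_for_clustering(
    c: ConsensusModel, expr: pd.DataFrame, min_structures: int = 5
) -> tuple[list, list, pd.DataFrame]:
    """Keep genes with consensus calls in at least ``min_structures``
    structures (boundary inclusive), then drop structures left without any
    call among the kept genes.  Returns (genes, structures, filtered expr).
    """
    if not c.calls.index.equals(expr.index) and set(c.calls.index) - set(expr.index):
        raise ValueError("expression matrix missing genes present in the consensus model")
    nz = c.calls != 0
    gene_counts = nz.sum(axis=1)
    genes = list(gene_counts.index[gene_counts >= min_structures])
    if not genes:
        raise ValueError(
            f"no gene has calls in >= {min_structures} structures; lower min_structures"
        )
    struct_counts = nz.loc[genes].sum(axis=0)
    structures = list(struct_counts.index[struct_counts > 0])
    filtered = expr.loc[genes, structures]
    logger.info("clustering filter kept %d genes x %d structures", len(genes), len(structures))
    return genes, structures, filtered


def average_linkage_cluster(
    m: pd.DataFrame | np.ndarray, axis: str = "rows", similarity=None
) -> Dendrogram:
    """UPGMA tree over rows (or columns) under 1 - similarity dissimilarity.

    ``similarity`` maps a 2-D array to a pairwise row-similarity matrix and
    defaults to uncentered correlation.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    if isinstance(m, pd.DataFrame):
        labels = list(m.index if axis == "rows" else m.columns)
        arr = m.to_numpy(dtype=float)
    else:
        arr = np.asarray(m, dtype=float)
        n_items = arr.shape[0] if axis == "rows" else arr.shape[1]
        labels = list(range(n_items))
    if axis == "columns":
        arr = arr.T
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    sim_fn = similarity or uncentered_similarity_matrix
    sim = sim_fn(arr)
    d = 1.0 - np.asarray(sim, dtype=float)
    if np.isnan(d).any():
        i, j = np.argwhere(np.isnan(d))[0]
        raise ValueError(f"NaN dissimilarity between items {labels[i]!r} and {labels[j]!r}")
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    condensed = squareform((d + d.T) / 2.0, checks=False)
    merges = hierarchy.linkage(condensed, method="average")
    leaf_order = np.asarray(hierarchy.leaves_list(merges))
    return Dendrogram(merges=merges, labels=labels, leaf_order=leaf_order)


def two_way_cluster(
    m: pd.DataFrame, similarity=None
) -> tuple[Dendrogram, Dendrogram, pd.DataFrame]:
    """Cluster both genes (rows) and structures (columns); return both trees
    and the matrix reordered by each tree's leaf ordering."""
    row_tree = average_linkage_cluster(m, axis="rows", similarity=similarity)
    col_tree = average_linkage_cluster(m, axis="columns", similarity=similarity)
    reordered = m.iloc[row_tree.leaf_order, col_tree.leaf_order]
    return row_tree, col_tree, reordered


def cut_tree(tree: Dendrogram, height: float) -> pd.Series:
    """Flat clusters from a height cut; labels 1..k by scipy convention."""
    flat = hierarchy.fcluster(tree.merges, t=height, criterion="distance")
    return pd.Series(flat, index=tree.labels)


# ---------------------------------------------------------------------------
# Cluster 3.0 / TreeView style plain-text export
# ---------------------------------------------------------------------------


def _tree_lines(tree: Dendrogram, prefix: str) -> list[str]:
    n = tree.n_leaves
    lines = []
    for i, (a, b, h, _size) in enumerate(tree.merges):
        a, b = int(a), int(b)
        na = f"{prefix}{a}X" if a < n else f"NODE{a - n + 1}X"
        nb = f"{prefix}{b}X" if b < n else f"NODE{b - n + 1}X"
        lines.append(f"NODE{i + 1}X\t{na}\t{nb}\t{1.0 - h:.6f}")
    return lines


def write_treeview(
    prefix: str | Path, m: pd.DataFrame, row_tree: Dendrogram, col_tree: Dendrogram
) -> None:
    """Write <prefix>.cdt / .gtr / .atr text files (TreeView-compatible)."""
    prefix = Path(prefix)
    Path(f"{prefix}.gtr").write_text("\n".join(_tree_lines(row_tree, "GENE")) + "\n")
    Path(f"{prefix}.atr").write_text("\n".join(_tree_lines(col_tree, "ARRY")) + "\n")
    rows = []
    col_ids = [f"ARRY{j}X" for j in col_tree.leaf_order]
    col_names = [str(m.columns[j]) for j in col_tree.leaf_order]
    rows.append("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(col_names))
    rows.append("AID\t\t\t\t" + "\t".join(col_ids))
    rows.append("EWEIGHT\t\t\t\t" + "\t".join(["1"] * len(col_ids)))
    for i in row_tree.leaf_order:
        name = str(m.index[i])
        vals = "\t".join(f"{m.iat[i, j]:.6g}" for j in col_tree.leaf_order)
        rows.append(f"GENE{i}X\t{name}\t{name}\t1\t{vals}")
    Path(f"{prefix}.cdt").write_text("\n".join(rows) + "\n")
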