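"""Weighted gene coexpression network: soft-power adjacency, topological
overlap, module detection, module eigengenes, kME and intramodular
connectivity.

The network is unsigned: adjacency a_ij = |pearson(g_i, g_j)|^beta with the
soft power beta = 9 by default, which suppresses weak correlations while
keeping the network weighted.  Topological overlap (TOM) augments direct
adjacency with shared weighted neighbours:

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),  i != j

with connectivity k_i = sum_u a_iu (zero diagonal) and TOM_ii = 1.  Modules
are detected by average-linkage clustering of the TOM dissimilarity
d = 1 - TOM with a static height cut and a minimum module size; clusters
smaller than the minimum are left unassigned (label 0) and module labels are
ordered by decreasing size.

Each module is summarised by its eigengene (ME): the first right singular
direction of the row-standardized module submatrix, sign-oriented to
correlate positively with the module's mean profile.  kME is the Pearson
correlation of a gene's profile with its module's ME; K-within is the sum of
a gene's topological overlaps with its module co-members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

DEFAULT_BETA = 9
DEFAULT_MIN_MODULE_SIZE = 30


@dataclass
class CoexpressionNetwork:
    """Adjacency (and optionally TOM) over a fixed gene order."""

    genes: list
    adjacency: np.ndarray
    beta: float
    tom: np.ndarray | None = None


@dataclass
class ModuleAssignment:
    """Gene -> module label; 0 = unassigned.  Labels 1..m are ordered by
    decreasing module size."""

    labels: pd.Series

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def sizes(self) -> pd.Series:
        counts = self.labels[self.labels > 0].value_counts().sort_index()
        return counts

    def members(self, module: int) -> list:
        return list(self.labels.index[self.labels == module])


@dataclass
class Eigengene:
    """One module's summary profile and per-gene membership statistics."""

    module: int
    me: pd.Series                 # unit-norm structure-level profile
    variance_explained: float
    kme: pd.Series                # gene -> Pearson(gene profile, ME)
    k_within: pd.Series           # gene -> sum of TOM with co-members


def adjacency_from_expression(m: pd.DataFrame, beta: float = DEFAULT_BETA) -> CoexpressionNetwork:
    """Unsigned soft-threshold adjacency a_ij = |r_ij|^beta, zero diagonal.

    Constant gene rows get correlation 0 to everything, with a warning.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if m.shape[1] < 3:
        raise ValueError("need at least 3 structures to correlate across")
    arr = m.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant gene row(s); correlations defined as 0",
                       int(constant.sum()))
    centered = arr - arr.mean(axis=1, keepdims=True)
    safe = np.where(constant, 1.0, np.sqrt((centered * centered).sum(axis=1)))
    r = (centered @ centered.T) / np.outer(safe, safe)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    r = np.clip(r, -1.0, 1.0)
    a = np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    return CoexpressionNetwork(genes=list(m.index), adjacency=a, beta=beta)


def topological_overlap(net: CoexpressionNetwork) -> np.ndarray:
    """Unsigned TOM of the network's adjacency; stores and returns it."""
    a = net.adjacency
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a  # sum_u a_iu a_uj (diagonal of a is 0)
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / den
    tom[den == 0] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    net.tom = tom
    return tom


def detect_modules(
    tom: np.ndarray | CoexpressionNetwork,
    cut_height: float,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    genes: list | None = None,
) -> ModuleAssignment:
    """Average-linkage tree on d = 1 - TOM, static cut at ``cut_height``.

    Clusters smaller than ``min_module_size`` are unassigned (0); surviving
    modules are relabelled 1..m by decreasing size (ties by first
    occurrence).
    """
    if isinstance(tom, CoexpressionNetwork):
        genes = genes or tom.genes
        tom = tom.tom if tom.tom is not None else topological_overlap(tom)
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if genes is None:
        genes = list(range(n))
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    condensed = squareform(np.maximum((d + d.T) / 2.0, 0.0), checks=False)
    merges = hierarchy.linkage(condensed, method="average")
    flat = hierarchy.fcluster(merges, t=cut_height, criterion="distance")
    counts = pd.Series(flat).value_counts()
    keep = counts.index[counts >= min_module_size]
    order = sorted(keep, key=lambda c: (-counts[c], int(np.argmax(flat == c))))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([relabel.get(c, 0) for c in flat], index=genes)
    if not relabel:
        logger.warning("height cut produced no module of size >= %d; all genes unassigned",
                       min_module_size)
    return ModuleAssignment(labels=labels)


def module_eigengene(sub: pd.DataFrame) -> tuple[pd.Series, float]:
    """First right singular direction of a row-standardized module submatrix.

    Returns the unit-norm structure-level eigengene profile, sign-oriented
    to correlate positively with the module's mean standardized profile, and
    the fraction of variance it explains.
    """
    if sub.shape[0] < 2:
        raise ValueError("module must have at least 2 genes")
    arr = sub.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    keep = sd.ravel() > 0
    if not keep.any():
        raise ValueError("module submatrix is degenerate (all rows constant)")
    std = (arr[keep] - arr[keep].mean(axis=1, keepdims=True)) / sd[keep]
    _u, s, vt = np.linalg.svd(std, full_matrices=False)
    if s[0] == 0:
        raise ValueError("module submatrix is degenerate (rank 0)")
    me = vt[0]
    mean_profile = std.mean(axis=0)
    if np.dot(me, mean_profile) < 0:
        me = -me
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    return pd.Series(me, index=sub.columns), var_explained


def kme(gene_profile: pd.Series | np.ndarray, me: pd.Series | np.ndarray) -> float:
    """Module membership: Pearson correlation of a gene's profile with an ME."""
    g = np.asarray(gene_profile, dtype=float)
    e = np.asarray(me, dtype=float)
    if g.std() == 0 or e.std() == 0:
        logger.warning("constant profile in kME; defined as 0")
        return 0.0
    return float(np.corrcoef(g, e)[0, 1])


def k_within(gene, module_genes, tom: pd.DataFrame) -> float:
    """Intramodular connectivity: sum of TOM with co-members, self excluded."""
    others = [g for g in module_genes if g != gene]
    return float(tom.loc[gene, others].sum())


def summarize_modules(
    expr: pd.DataFrame, assignment: ModuleAssignment, tom: np.ndarray
) -> list[Eigengene]:
    """Compute ME, variance explained, kME, and K-within for every module."""
    tom_df = pd.DataFrame(tom, index=expr.index, columns=expr.index)
    out = []
    for mod in assignment.module_ids:
        members = assignment.members(mod)
        sub = expr.loc[members]
        me, var_exp = module_eigengene(sub)
        kmes = pd.Series({g: kme(expr.loc[g], me) for g in members})
        kwi = pd.Series({g: k_within(g, members, tom_df) for g in members})
        out.append(Eigengene(module=mod, me=me, variance_explained=var_exp,
                             kme=kmes, k_within=kwi))
    return out
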