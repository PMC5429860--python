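"""Independent reference implementations used to check the package.

Everything here is written as literally and naively as possible — explicit
loops, enumeration, closed forms — and never shares code with the package
under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def group_mean_columns(matrix, sample_structures):
    """Per-structure column means by an explicit loop.

    ``matrix``: probes x samples (2-D list/array); ``sample_structures``:
    structure id per sample column.  Returns {structure: [row means]}.
    """
    matrix = np.asarray(matrix, dtype=float)
    out = {}
    for s in sorted(set(sample_structures)):
        cols = [j for j, sj in enumerate(sample_structures) if sj == s]
        means = []
        for i in range(matrix.shape[0]):
            means.append(sum(matrix[i, j] for j in cols) / len(cols))
        out[s] = means
    return out


def zscore_rows(matrix):
    """Two-pass mean / sample-sd standardization, row by row."""
    matrix = np.asarray(matrix, dtype=float)
    out = np.empty_like(matrix)
    for i in range(matrix.shape[0]):
        row = matrix[i]
        n = len(row)
        mean = sum(row) / n
        var = sum((x - mean) ** 2 for x in row) / (n - 1)
        sd = math.sqrt(var)
        for j in range(n):
            out[i, j] = 0.0 if sd == 0 else (row[j] - mean) / sd
    return out


def threshold_calls(z, t):
    """Element-wise sign(z) * [|z| >= t]."""
    z = np.asarray(z, dtype=float)
    out = np.zeros(z.shape, dtype=int)
    for i in range(z.shape[0]):
        for j in range(z.shape[1]):
            if z[i, j] >= t:
                out[i, j] = 1
            elif z[i, j] <= -t:
                out[i, j] = -1
    return out


def two_thirds(k):
    return math.ceil(2 * k / 3)


def consensus_cell(donor_calls, criterion, n_donors):
    """Literal per-cell application of one consensus rule.

    ``donor_calls``: one value per donor, each in {-1, 0, 1, None} where
    None means the donor did not sample the structure.  Returns (call,
    support).
    """
    present = [c for c in donor_calls if c is not None]
    k = len(present)
    up = sum(1 for c in present if c == 1)
    down = sum(1 for c in present if c == -1)
    if criterion == "MD1":
        min_k, req = 2, two_thirds(k)
    elif criterion == "MD2":
        min_k, req = n_donors, k
    elif criterion == "MD3":
        min_k, req = 2, (k if k <= 4 else two_thirds(k))
    elif criterion == "MD4":
        min_k, req = 4, two_thirds(k)
    else:
        raise ValueError(criterion)
    if k >= min_k and up >= req and down == 0:
        return 1, up
    if k >= min_k and down >= req and up == 0:
        return -1, down
    return 0, 0


def consensus_matrix(stack, criterion):
    """Apply :func:`consensus_cell` to every cell of a donors x genes x
    structures array (NaN = unsampled)."""
    n_donors, n_genes, n_structs = stack.shape
    calls = np.zeros((n_genes, n_structs), dtype=int)
    support = np.zeros((n_genes, n_structs), dtype=int)
    for g in range(n_genes):
        for s in range(n_structs):
            vals = [None if math.isnan(stack[d, g, s]) else int(stack[d, g, s])
                    for d in range(n_donors)]
            calls[g, s], support[g, s] = consensus_cell(vals, criterion, n_donors)
    return calls, support


def uncentered_corr(x, y):
    """Scalar-loop cosine about zero."""
    sxy = sxx = syy = 0.0
    for a, b in zip(x, y):
        sxy += a * b
        sxx += a * a
        syy += b * b
    if sxx == 0 or syy == 0:
        return 0.0
    return sxy / math.sqrt(sxx * syy)


def naive_upgma(dist):
    """O(n^3) UPGMA on a full dissimilarity matrix.

    Returns the sorted list of merge heights (cluster-average distances).
    """
    dist = np.asarray(dist, dtype=float)
    clusters = [[i] for i in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                total = 0.0
                for i in clusters[a]:
                    for j in clusters[b]:
                        total += dist[i, j]
                avg = total / (len(clusters[a]) * len(clusters[b]))
                if best is None or avg < best[0]:
                    best = (avg, a, b)
        h, a, b = best
        heights.append(h)
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return sorted(heights)


def pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    num = float(((x - mx) * (y - my)).sum())
    den = math.sqrt(float(((x - mx) ** 2).sum()) * float(((y - my) ** 2).sum()))
    return 0.0 if den == 0 else num / den


def adjacency_loop(expr, beta):
    """Element-wise |pearson|^beta with zero diagonal."""
    expr = np.asarray(expr, dtype=float)
    n = expr.shape[0]
    a = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                a[i, j] = abs(pearson(expr[i], expr[j])) ** beta
    return a


def tom_loop(adj):
    """Triple-loop topological overlap."""
    adj = np.asarray(adj, dtype=float)
    n = adj.shape[0]
    k = [sum(adj[i, u] for u in range(n)) for i in range(n)]
    tom = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(adj[i, u] * adj[u, j] for u in range(n))
            den = min(k[i], k[j]) + 1.0 - adj[i, j]
            tom[i, j] = (shared + adj[i, j]) / den if den != 0 else 0.0
    return tom


def hypergeom_upper_tail_enum(N, K, n, k):
    """P[overlap >= k] by enumerating every size-n draw from an N-urn with
    K marked items."""
    items = list(range(N))
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(items, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted p-values by the literal step-up loop."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def mann_whitney_auc(scores, labels):
    """Pairwise concordance probability with ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    u = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                u += 1.0
            elif sp == sn:
                u += 0.5
    return u / (len(pos) * len(neg))


def variance_explained_along(direction, std_matrix):
    """Fraction of total variance of the row-standardized matrix captured by
    projecting onto a unit direction."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    proj = std_matrix @ direction
    return float((proj ** 2).sum() / (std_matrix ** 2).sum())
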