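"""Hypergeometric over-representation of gene sets against annotation terms.

For a query of n genes drawn from a background of N genes, a term covering
K background genes, and an observed overlap of k genes, the enrichment
p-value is the upper tail P[X >= k] of the hypergeometric(N, K, n)
distribution.  Multiple testing across terms is corrected with
Benjamini-Hochberg by default (Bonferroni also available).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

CORRECTIONS = ("BH", "bonferroni", "none")


@dataclass
class AnnotationSets:
    """Named term gene sets over a declared background universe."""

    sets: dict
    background: frozenset

    def __post_init__(self) -> None:
        self.background = frozenset(self.background)
        clean = {}
        for term, genes in self.sets.items():
            genes = frozenset(genes)
            if not genes:
                raise ValueError(f"term {term!r} is empty")
            stray = genes - self.background
            if stray:
                raise ValueError(
                    f"term {term!r} has genes outside the background: {sorted(stray)[:5]}"
                )
            clean[str(term)] = genes
        self.sets = clean


@dataclass
class EnrichmentResult:
    term_id: str
    overlap: int
    query_size: int
    term_size: int
    background_size: int
    p_value: float
    adjusted_p: float | None = None


def hypergeom_test(
    query: Iterable, term: Iterable, background: Iterable
) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation test.

    ``p = P[X >= k]`` where X counts term genes in a size-n draw from the
    background.  Query and term must be subsets of the background.
    """
    query = frozenset(query)
    term = frozenset(term)
    background = frozenset(background)
    offenders = sorted(query - background)
    if offenders:
        raise ValueError(f"query genes not in background: {offenders[:10]}")
    offenders = sorted(term - background)
    if offenders:
        raise ValueError(f"term genes not in background: {offenders[:10]}")
    N, K, n = len(background), len(term), len(query)
    k = len(query & term)
    # survival function is P[X > k-1] = P[X >= k]
    p = float(hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        term_id="", overlap=k, query_size=n, term_size=K,
        background_size=N, p_value=min(max(p, 0.0), 1.0),
    )


def enrich_all(
    query: Iterable, sets: AnnotationSets, correction: str = "BH"
) -> list[EnrichmentResult]:
    """Test every term; adjust p-values; sort by (p, term_id).

    Returns one :class:`EnrichmentResult` per term with ``adjusted_p``
    filled in; ties in p break deterministically by term id.
    """
    query = frozenset(query)
    if not query:
        raise ValueError("query gene set is empty")
    if correction not in CORRECTIONS:
        raise ValueError(f"correction must be one of {CORRECTIONS}")
    results = []
    for term_id in sorted(sets.sets):
        r = hypergeom_test(query, sets.sets[term_id], sets.background)
        r.term_id = term_id
        results.append(r)
    pvals = [r.p_value for r in results]
    if correction == "BH":
        adj = multipletests(pvals, method="fdr_bh")[1]
    elif correction == "bonferroni":
        adj = multipletests(pvals, method="bonferroni")[1]
    else:
        adj = pvals
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def read_gmt(path: str | Path, background: Iterable | None = None) -> AnnotationSets:
    """Read GMT (term <tab> description <tab> gene...) term sets.

    If no background is given, the union of all term genes is used.
    """
    sets: dict[str, frozenset] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need term, description, genes): {line[:50]!r}")
        sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    bg = frozenset(background) if background is not None else frozenset().union(*sets.values())
    return AnnotationSets(sets=sets, background=bg)


def write_results(results: list[EnrichmentResult], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)
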