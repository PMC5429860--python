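"""Per-donor z-scoring, signed thresholding, probe collapse, and the four
cross-donor consensus criteria (MD1-MD4).

The model-building idea: within each donor, a gene's expression across all
sampled brain structures is standardized to z-scores, so each (gene,
structure) cell measures how far that structure deviates from the gene's
whole-brain mean in units of its cross-structure standard deviation.  Cells
with |z| >= 2.0 (boundary inclusive) are signed calls (+1 up, -1 down); other
sampled cells are 0; unsampled structures stay masked.  A consensus call is
made for a (gene, structure) cell when enough of the donors that actually
sampled the structure agree in sign and no sampling donor significantly
disagrees (strict unidirectionality).

Four preset criteria trade coverage against stringency.  With k the number
of donors sampling a structure and n the donor cohort size:

========  ==================  =========================================
criterion  sampling floor      same-sign significant donors required
========  ==================  =========================================
MD1        k >= 2              ceil(2k/3)
MD2        k = n               k (every donor)
MD3        k >= 2              k if k <= 4, else ceil(2k/3)
MD4        k >= 4              ceil(2k/3)
========  ==================  =========================================

Two-thirds support uses the ceiling, so k = 5 requires 4 agreeing donors.
The presets nest: every MD2 call is an MD3 call, every MD3 call an MD1 call,
and every MD4 call an MD1 call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io_model import ProbeMap, StructureMatrix

logger = logging.getLogger(__name__)

DEFAULT_Z_THRESHOLD = 2.0

CRITERIA_NAMES = ("MD1", "MD2", "MD3", "MD4")


@dataclass
class ZMatrix:
    """One donor's gene (or probe) x structure standard scores.

    Rows are standardized over the donor's sampled structures only; columns
    for unsampled structures are absent.
    """

    donor_id: str
    z: pd.DataFrame

    @property
    def structures(self) -> list[str]:
        return list(self.z.columns)


@dataclass
class PatternMatrix:
    """One donor's signed significance calls in {-1, 0, +1}.

    0 means sampled-but-not-significant; unsampled structures are absent
    columns, never zeros — the consensus rules count sampling donors.
    """

    donor_id: str
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        bad = ~self.calls.isin((-1, 0, 1)).to_numpy()
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"pattern cell out of domain at gene {self.calls.index[i]!r}, "
                f"structure {self.calls.columns[j]!r}: {self.calls.iat[i, j]!r}"
            )

    @property
    def structures(self) -> list[str]:
        return list(self.calls.columns)


@dataclass(frozen=True)
class ConsensusCriteria:
    """A named consensus rule.

    ``min_donors_sampled`` is the sampling floor on k; ``required_support``
    maps an array of k values to the number of same-sign significant donors
    required at each k.
    """

    name: str
    min_donors_sampled: int
    required_support: Callable[[np.ndarray], np.ndarray]


def _two_thirds(k: np.ndarray) -> np.ndarray:
    return np.ceil(2.0 * k / 3.0).astype(int)


def criteria_preset(name: str, n_donors: int) -> ConsensusCriteria:
    """Return one of the MD1-MD4 preset criteria for a cohort of n donors."""
    if name == "MD1":
        return ConsensusCriteria("MD1", 2, _two_thirds)
    if name == "MD2":
        return ConsensusCriteria("MD2", n_donors, lambda k: np.asarray(k, dtype=int))
    if name == "MD3":
        return ConsensusCriteria(
            "MD3", 2, lambda k: np.where(np.asarray(k) <= 4, np.asarray(k, int), _two_thirds(k))
        )
    if name == "MD4":
        return ConsensusCriteria("MD4", 4, _two_thirds)
    raise ValueError(f"unknown criteria {name!r}; presets are {', '.join(CRITERIA_NAMES)}")


@dataclass
class ConsensusModel:
    """Gene x structure consensus calls plus supporting-donor counts.

    ``calls`` in {-1, 0, +1}; ``support`` holds, where a call was made, how
    many donors carried the same-sign significant pattern; ``k_sampled``
    counts donors sampling each structure.
    """

    criteria_name: str
    calls: pd.DataFrame
    support: pd.DataFrame
    k_sampled: pd.Series

    @property
    def genes(self) -> pd.Index:
        return self.calls.index

    @property
    def structures(self) -> pd.Index:
        return self.calls.columns


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def zscore_transform(m: StructureMatrix) -> ZMatrix:
    """Standardize each row over the donor's sampled structures.

    Per row, z = (x - mean) / sd with sd using denominator n-1.  Constant
    rows become all-zero with a logged warning; rows with fewer than two
    sampled values are dropped with a warning.
    """
    vals = m.values
    n_obs = vals.notna().sum(axis=1)
    droppable = n_obs < 2
    if droppable.any():
        dropped = list(vals.index[droppable])
        logger.warning(
            "donor %s: dropping %d row(s) with <2 sampled structures (e.g. %s)",
            m.donor_id, len(dropped), dropped[:3],
        )
        vals = vals.loc[~droppable]
    arr = vals.to_numpy(dtype=float)
    mean = np.nanmean(arr, axis=1, keepdims=True)
    sd = np.nanstd(arr, axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        logger.warning(
            "donor %s: %d constant row(s) set to all-zero z (e.g. %s)",
            m.donor_id, int(constant.sum()), list(vals.index[constant][:3]),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[constant, :] = 0.0
    z[np.isnan(arr)] = np.nan
    return ZMatrix(m.donor_id, pd.DataFrame(z, index=vals.index, columns=vals.columns))


def threshold_patterns(z: ZMatrix, z_threshold: float = DEFAULT_Z_THRESHOLD) -> PatternMatrix:
    """Signed thresholding: +1 where z >= t, -1 where z <= -t, else 0.

    The comparison is inclusive at the boundary (z = t is a call).
    """
    if not z_threshold > 0:
        raise ValueError(f"z_threshold must be positive, got {z_threshold}")
    arr = z.z.to_numpy(dtype=float)
    calls = np.zeros(arr.shape, dtype=int)
    with np.errstate(invalid="ignore"):
        calls[arr >= z_threshold] = 1
        calls[arr <= -z_threshold] = -1
    if np.isnan(arr).any():
        raise ValueError(f"donor {z.donor_id}: z matrix has NaN cells within sampled columns")
    return PatternMatrix(z.donor_id, pd.DataFrame(calls, index=z.z.index, columns=z.z.columns))


def collapse_probes(
    matrices: Sequence[StructureMatrix], pm: ProbeMap
) -> tuple[list[StructureMatrix], pd.Series]:
    """Collapse probe-level matrices to gene level by the max-variance probe.

    For each gene, the probe with maximal variance of expression across
    sampled structures — pooled over all donors — represents the gene in
    every donor.  Ties break to the lexicographically smallest probe id
    (logged).  Genes whose probes carry no usable data are dropped with a
    warning.  Returns the gene-level matrices and the chosen probe per gene.
    """
    pooled = pd.concat([m.values for m in matrices], axis=1)
    unknown = pooled.index.difference(pm.mapping.index)
    if len(unknown):
        raise ValueError(f"probes missing from probe map: {list(unknown[:5])}")
    var = pooled.var(axis=1, ddof=1)  # pandas skips NaN; <2 values -> NaN
    info = pd.DataFrame({
        "gene": pm.mapping.reindex(pooled.index),
        "var": var,
    })
    info = info.sort_index()
    chosen: dict[str, str] = {}
    n_ties = 0
    for gene, grp in info.groupby("gene", sort=True):
        usable = grp.dropna(subset=["var"])
        if usable.empty:
            logger.warning("gene %s has no probe with usable data; dropped", gene)
            continue
        best = usable["var"].max()
        winners = usable.index[usable["var"] == best]
        if len(winners) > 1:
            n_ties += 1
            logger.info("gene %s: variance tie among probes %s; keeping %s",
                        gene, list(winners), min(winners))
        chosen[gene] = min(winners)
    if n_ties:
        logger.warning("%d gene(s) had probe-variance ties broken lexicographically", n_ties)
    if not chosen:
        raise ValueError("no gene has a probe with usable data")
    sel = pd.Series(chosen).sort_index()
    out = []
    for m in matrices:
        sub = m.values.loc[sel.values]
        sub.index = sel.index
        out.append(StructureMatrix(m.donor_id, sub, m.scale_flag))
    return out, sel


def build_consensus(
    patterns: Sequence[PatternMatrix], crit: ConsensusCriteria
) -> ConsensusModel:
    """Apply a consensus criterion across donors' pattern matrices.

    For every (gene, structure): let k be the number of donors whose matrix
    covers the cell, up/down the counts of +1/-1 calls among them.  A call is
    made iff k >= the criterion's sampling floor, max(up, down) >= the
    required support at k, and min(up, down) = 0 (any opposing significant
    donor vetoes).  The call's sign is the majority sign and its support the
    agreeing-donor count.
    """
    if len(patterns) < 2:
        raise ValueError("consensus needs at least 2 donors")
    genes = sorted(set().union(*(p.calls.index for p in patterns)))
    structures = sorted(set().union(*(p.calls.columns for p in patterns)))
    stack = np.full((len(patterns), len(genes), len(structures)), np.nan)
    for i, p in enumerate(patterns):
        aligned = p.calls.reindex(index=genes, columns=structures)
        stack[i] = aligned.to_numpy(dtype=float)
    sampled = ~np.isnan(stack)
    k = sampled.sum(axis=0)
    up = (stack == 1).sum(axis=0)
    down = (stack == -1).sum(axis=0)
    req = crit.required_support(np.maximum(k, 1))
    eligible = k >= crit.min_donors_sampled
    pos = eligible & (up >= req) & (down == 0)
    neg = eligible & (down >= req) & (up == 0)
    calls = pos.astype(int) - neg.astype(int)
    support = np.where(pos, up, 0) + np.where(neg, down, 0)
    struct_counts = pd.Series(
        [sum(s in p.calls.columns for p in patterns) for s in structures],
        index=structures, dtype=int,
    )
    return ConsensusModel(
        criteria_name=crit.name,
        calls=pd.DataFrame(calls, index=genes, columns=structures),
        support=pd.DataFrame(support.astype(int), index=genes, columns=structures),
        k_sampled=struct_counts,
    )


def average_z(zmats: Sequence[ZMatrix]) -> pd.DataFrame:
    """Donor-averaged z profile: mean z per (gene, structure) over the donors
    that sampled the structure.  Cells no donor covers are NaN."""
    genes = sorted(set().union(*(z.z.index for z in zmats)))
    structures = sorted(set().union(*(z.z.columns for z in zmats)))
    acc = np.zeros((len(genes), len(structures)))
    cnt = np.zeros((len(genes), len(structures)))
    for zm in zmats:
        a = zm.z.reindex(index=genes, columns=structures).to_numpy(dtype=float)
        m = ~np.isnan(a)
        acc[m] += a[m]
        cnt[m] += 1
    with np.errstate(invalid="ignore"):
        avg = acc / cnt
    return pd.DataFrame(avg, index=genes, columns=structures)


def model_summary(c: ConsensusModel) -> dict:
    """Coverage summary of a consensus model.

    Reports the fraction of genes with at least one call, the number of
    structures carrying at least one call, per-structure gene counts ranked
    descending, and the histogram of per-gene structure counts.
    """
    nz = c.calls != 0
    genes_with_call = int(nz.any(axis=1).sum())
    per_structure = nz.sum(axis=0).sort_values(ascending=False, kind="stable")
    per_gene = nz.sum(axis=1)
    hist = per_gene[per_gene > 0].value_counts().sort_index()
    return {
        "criteria": c.criteria_name,
        "n_genes": int(c.calls.shape[0]),
        "n_structures": int(c.calls.shape[1]),
        "n_genes_with_call": genes_with_call,
        "fraction_genes_with_call": genes_with_call / c.calls.shape[0] if len(c.calls) else 0.0,
        "n_structures_with_call": int((per_structure > 0).sum()),
        "per_structure_gene_counts": per_structure[per_structure > 0],
        "per_gene_structure_histogram": hist,
    }
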