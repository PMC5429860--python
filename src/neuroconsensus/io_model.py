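"""Data model and file I/O for multi-donor brain expression studies.

The pipeline consumes per-donor microarray-style exports: a probe x sample
expression table, a sample annotation mapping each sample to a brain-structure
identifier, a structure ontology (id, acronym, name, parent), and a
probe-to-gene map.  It emits and re-reads its own signed pattern / consensus
matrix format: TSV with a header of structure ids, one row per gene, cells in
{-1, 0, 1, NA} where NA means "structure not sampled" — distinct from 0,
which means "sampled but not significant".

All tables are plain UTF-8 CSV/TSV with a header row; probe, gene and
structure identifiers are opaque strings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALE_FLAGS = ("linear", "log2")

_PATTERN_CELLS = {"-1": -1.0, "0": 0.0, "1": 1.0, "+1": 1.0, "NA": np.nan}


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class StructureOntology:
    """Brain-structure ontology: a forest of (id, acronym, name, parent_id).

    ``table`` columns: structure_id, acronym, name, parent_id (empty/NaN for
    roots).  Validation enforces unique ids, existing parents, and acyclicity.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"structure_id", "acronym", "name", "parent_id"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"ontology table missing columns: {sorted(missing)}")
        self.table = self.table.copy()
        self.table["structure_id"] = self.table["structure_id"].astype(str)
        self.validate()

    @property
    def ids(self) -> set[str]:
        return set(self.table["structure_id"])

    def parent_of(self) -> dict[str, str | None]:
        out: dict[str, str | None] = {}
        for sid, pid in zip(self.table["structure_id"], self.table["parent_id"]):
            out[sid] = None if pd.isna(pid) or pid == "" else str(pid)
        return out

    def validate(self) -> None:
        ids = self.table["structure_id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate structure ids: {sorted(set(dup))}")
        parent = self.parent_of()
        known = set(parent)
        for sid, pid in parent.items():
            if pid is not None and pid not in known:
                raise ValueError(f"structure {sid!r} has unknown parent {pid!r}")
        # Walk ancestor chains; revisiting a node within one chain is a cycle.
        for sid in parent:
            seen = {sid}
            cur = parent[sid]
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"ontology parent links contain a cycle through {cur!r}")
                seen.add(cur)
                cur = parent[cur]


@dataclass
class DonorExpression:
    """One donor's probe x sample expression matrix plus sample annotation.

    ``expr`` rows are probes, columns are sample ids; ``sample_annotation``
    maps every sample id to a structure id.  ``scale_flag`` records whether
    values are linear-scale or log2; downstream z-scoring is invariant to it.
    """

    donor_id: str
    expr: pd.DataFrame
    sample_annotation: pd.Series
    scale_flag: str = "linear"

    def __post_init__(self) -> None:
        if self.scale_flag not in SCALE_FLAGS:
            raise ValueError(f"scale_flag must be one of {SCALE_FLAGS}, got {self.scale_flag!r}")
        if self.expr.index.duplicated().any():
            dups = sorted(set(self.expr.index[self.expr.index.duplicated()]))
            raise ValueError(f"duplicate probe ids in donor {self.donor_id}: {dups[:5]}")
        if self.expr.columns.duplicated().any():
            dups = sorted(set(self.expr.columns[self.expr.columns.duplicated()]))
            raise ValueError(f"duplicate sample ids in donor {self.donor_id}: {dups[:5]}")
        missing = [s for s in self.expr.columns if s not in self.sample_annotation.index]
        if missing:
            raise ValueError(
                f"donor {self.donor_id}: no structure annotation for sample(s) {missing[:5]}"
            )
        self.sample_annotation = self.sample_annotation.loc[list(self.expr.columns)].astype(str)

    @property
    def n_probes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    def structures(self) -> list[str]:
        """Distinct structure ids sampled by this donor, sorted."""
        return sorted(set(self.sample_annotation))

    def validate_against_ontology(self, ontology: StructureOntology) -> None:
        unknown = sorted(set(self.sample_annotation) - ontology.ids)
        if unknown:
            raise ValueError(
                f"donor {self.donor_id}: annotated structures not in ontology: {unknown[:5]}"
            )


@dataclass
class ProbeMap:
    """Many-to-one probe -> gene mapping."""

    mapping: pd.Series  # index: probe_id, values: gene_id

    def __post_init__(self) -> None:
        if self.mapping.index.duplicated().any():
            dups = sorted(set(self.mapping.index[self.mapping.index.duplicated()]))
            raise ValueError(f"probe mapped more than once: {dups[:5]}")
        self.mapping = self.mapping.astype(str)

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.mapping))

    def probes_for(self, gene: str) -> list[str]:
        return sorted(self.mapping.index[self.mapping == gene])


@dataclass
class StructureMatrix:
    """Per-donor matrix with one column per distinct sampled structure.

    Replicate samples of a structure have been averaged.  Structures the
    donor never sampled are simply absent (the explicit mask); they are never
    encoded as zeros, because downstream consensus rules count how many
    donors sampled each structure.
    """

    donor_id: str
    values: pd.DataFrame  # rows: probes or genes, columns: structure ids
    scale_flag: str = "linear"

    @property
    def structures(self) -> list[str]:
        return list(self.values.columns)

    def sampled_mask(self, all_structures: Iterable[str]) -> pd.Series:
        cols = set(self.values.columns)
        idx = list(all_structures)
        return pd.Series([s in cols for s in idx], index=idx, dtype=bool)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_donor_expression(
    expr_path: str | Path,
    annotation_path: str | Path,
    scale_flag: str = "linear",
    donor_id: str | None = None,
    sep: str | None = None,
) -> DonorExpression:
    """Read a probe x sample expression table and its sample annotation.

    The expression file has probe ids in the first column and sample ids in
    the header.  The annotation file has columns ``sample_id`` and
    ``structure_id``.  Missing annotation for any sample is a hard error that
    names the sample.
    """
    expr = pd.read_csv(expr_path, sep=sep or _sep_for(expr_path), index_col=0)
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    annot = pd.read_csv(annotation_path, sep=sep or _sep_for(annotation_path), dtype=str)
    if not {"sample_id", "structure_id"} <= set(annot.columns):
        raise ValueError(
            f"annotation file {annotation_path} must have columns sample_id, structure_id"
        )
    annotation = annot.set_index("sample_id")["structure_id"]
    donor = donor_id or Path(expr_path).stem
    d = DonorExpression(donor, expr, annotation, scale_flag)
    logger.info(
        "read donor %s: %d probes x %d samples (%d structures)",
        donor, d.n_probes, d.n_samples, len(d.structures()),
    )
    return d


def write_donor_expression(
    d: DonorExpression, expr_path: str | Path, annotation_path: str | Path
) -> None:
    d.expr.to_csv(expr_path, sep=_sep_for(expr_path), index_label="probe_id")
    ann = d.sample_annotation.rename("structure_id")
    ann.to_csv(annotation_path, sep=_sep_for(annotation_path), index_label="sample_id")


def merge_replicate_samples(d: DonorExpression) -> StructureMatrix:
    """Average replicate samples that share a structure annotation.

    Returns a matrix with one column per distinct structure; each cell is the
    arithmetic mean (on the stored scale) of that structure's replicates.
    Order of samples does not matter.
    """
    groups = d.sample_annotation
    merged = d.expr.T.groupby(groups).mean().T
    merged = merged[sorted(merged.columns)]
    return StructureMatrix(d.donor_id, merged, d.scale_flag)


def read_ontology(path: str | Path, sep: str | None = None) -> StructureOntology:
    table = pd.read_csv(path, sep=sep or _sep_for(path), dtype=str)
    return StructureOntology(table)


def write_ontology(o: StructureOntology, path: str | Path) -> None:
    o.table.to_csv(path, sep=_sep_for(path), index=False)


def read_probe_map(path: str | Path, sep: str | None = None) -> ProbeMap:
    table = pd.read_csv(path, sep=sep or _sep_for(path), dtype=str)
    if not {"probe_id", "gene_id"} <= set(table.columns):
        raise ValueError(f"probe map {path} must have columns probe_id, gene_id")
    return ProbeMap(table.set_index("probe_id")["gene_id"])


def write_probe_map(pm: ProbeMap, path: str | Path) -> None:
    pm.mapping.rename("gene_id").to_csv(path, sep=_sep_for(path), index_label="probe_id")


def write_call_matrix(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a gene x structure signed-call matrix; NaN cells become ``NA``.

    Cells must be in {-1, 0, +1, NaN}.
    """
    vals = calls.to_numpy(dtype=float)
    ok = np.isnan(vals) | np.isin(vals, (-1.0, 0.0, 1.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValueError(
            f"invalid call {vals[i, j]!r} at gene {calls.index[i]!r}, "
            f"structure {calls.columns[j]!r}"
        )
    out = calls.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_call_matrix(path: str | Path) -> pd.DataFrame:
    """Read a signed-call matrix written by :func:`write_call_matrix`.

    Any cell outside {-1, 0, 1, NA} raises with its row/column coordinates.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)

    def _parse(cell: str, gene: str, structure: str) -> float:
        try:
            return _PATTERN_CELLS[cell.strip()]
        except KeyError:
            raise ValueError(
                f"invalid pattern cell {cell!r} at gene {gene!r}, structure {structure!r}"
            ) from None

    data = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        for i, gene in enumerate(raw.index):
            data[i, j] = _parse(raw.iat[i, j], gene, col)
    return pd.DataFrame(data, index=raw.index, columns=raw.columns)


def write_consensus_model(model, prefix: str | Path) -> None:
    """Write a consensus model as ``<prefix>.calls.tsv`` + support + metadata."""
    prefix = Path(prefix)
    write_call_matrix(model.calls, f"{prefix}.calls.tsv")
    model.support.to_csv(f"{prefix}.support.tsv", sep="\t", index_label="gene_id")
    meta = {
        "criteria_name": model.criteria_name,
        "structure_donor_counts": {k: int(v) for k, v in model.k_sampled.items()},
    }
    Path(f"{prefix}.meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_consensus_model(prefix: str | Path):
    from .consensus_model import ConsensusModel

    prefix = Path(prefix)
    calls = read_call_matrix(f"{prefix}.calls.tsv")
    support = pd.read_csv(f"{prefix}.support.tsv", sep="\t", index_col=0)
    support.index = support.index.astype(str)
    meta = json.loads(Path(f"{prefix}.meta.json").read_text())
    k_sampled = pd.Series(meta["structure_donor_counts"]).reindex(calls.columns).astype(int)
    return ConsensusModel(
        criteria_name=meta["criteria_name"],
        calls=calls.astype(int),
        support=support.astype(int),
        k_sampled=k_sampled,
    )
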