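"""neuroconsensus: cross-donor consensus models of brain-structure gene
expression, with downstream clustering, coexpression-module, enrichment and
disease-gene classification stages, plus a synthetic multi-donor simulator
with planted ground truth."""

from .io_model import (
    DonorExpression,
    ProbeMap,
    StructureMatrix,
    StructureOntology,
    merge_replicate_samples,
    read_donor_expression,
    read_ontology,
    read_probe_map,
)
from .consensus_model import (
    ConsensusCriteria,
    ConsensusModel,
    PatternMatrix,
    ZMatrix,
    average_z,
    build_consensus,
    collapse_probes,
    criteria_preset,
    model_summary,
    threshold_patterns,
    zscore_transform,
)
from .synthetic_data import PlantedSignal, SimConfig, default_signals, simulate_donors

__version__ = "0.1.0"

__all__ = [
    "DonorExpression", "ProbeMap", "StructureMatrix", "StructureOntology",
    "merge_replicate_samples", "read_donor_expression", "read_ontology",
    "read_probe_map", "ConsensusCriteria", "ConsensusModel", "PatternMatrix",
    "ZMatrix", "average_z", "build_consensus", "collapse_probes",
    "criteria_preset", "model_summary", "threshold_patterns",
    "zscore_transform", "PlantedSignal", "SimConfig", "default_signals",
    "simulate_donors", "__version__",
]


def run_consensus_pipeline(donors, probe_map, criteria="MD1", z_threshold=2.0):
    """Convenience end-to-end run: replicate merge, probe collapse, z-score,
    threshold, consensus.  Returns (model, zmatrices, gene-level matrices)."""
    merged = [merge_replicate_samples(d) for d in donors]
    gene_level, _chosen = collapse_probes(merged, probe_map)
    zmats = [zscore_transform(m) for m in gene_level]
    patterns = [threshold_patterns(z, z_threshold) for z in zmats]
    crit = criteria_preset(criteria, n_donors=len(donors))
    model = build_consensus(patterns, crit)
    return model, zmats, gene_level
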