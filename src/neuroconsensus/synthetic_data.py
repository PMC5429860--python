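"""Synthetic multi-donor brain expression data with planted ground truth.

Emulates the shape of a multi-donor microarray study of the brain: six
donors, on the order of 190 fine anatomical structures with donor-variable
coverage (each donor samples each structure independently with probability
``structure_sampling_prob``, so some structures appear in only a subset of
donors), one or more replicate samples per sampled structure, and several
probes per gene.  Structure-specific up/down expression signals are planted
on a Gaussian noise background and recorded in a truth table, so every
downstream stage — z-scoring, thresholding, probe collapse, consensus,
clustering, classification — can be scored against known answers.

Generative model, per donor d, gene g, structure s:

    value(g, s) = mu_g + b_{d,g,s} + shift(g, s, d)

with gene baseline mu_g ~ U(6, 12) (a log2-intensity-like range),
cross-structure noise b ~ N(0, noise_sd), and shift = direction x
effect_size x noise_sd for planted (g, s) cells in donors selected by the
signal's penetrance.  Probe p of gene g reports

    mu_g + gain_p * (value - mu_g) + eps,   eps ~ N(0, replicate_noise_sd)

per replicate sample.  One designated probe per gene has gain 1.0 and all
others a smaller gain, so the max-variance representative probe has a
deterministic right answer recorded in the truth table.  Because z-scores
are location/scale invariant per row, the gain rescaling leaves the planted
z-signal intact through probe collapse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import DonorExpression, ProbeMap, StructureOntology

HIGH_VARIANCE_GAIN = 1.0
LOW_VARIANCE_GAIN = 0.6


@dataclass(frozen=True)
class PlantedSignal:
    """A block of genes shifted up or down in a set of structures.

    ``effect_size`` is the shift in units of the cross-structure noise SD;
    ``donor_penetrance`` is the fraction of donors carrying the signal.
    """

    gene_ids: frozenset
    structure_ids: frozenset
    direction: int
    effect_size: float
    donor_penetrance: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative (0 = planted null)")
        if not 0 < self.donor_penetrance <= 1:
            raise ValueError("donor_penetrance must be in (0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Study-shape parameters for the simulator.

    Defaults mirror the emulated study design: 6 donors, 190 structures,
    donor-variable structure coverage, replicate samples per structure drawn
    as 1 + Poisson(replicates_per_structure - 1), and 2 probes per gene.
    """

    n_donors: int = 6
    n_structures: int = 190
    n_genes: int = 1000
    probes_per_gene: int = 2
    replicates_per_structure: float = 2.0
    structure_sampling_prob: float = 0.85
    noise_sd: float = 1.0
    replicate_noise_sd: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_donors", "n_structures", "n_genes", "probes_per_gene"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.structure_sampling_prob <= 1:
            raise ValueError("structure_sampling_prob must be in (0, 1]")
        if self.replicates_per_structure < 1:
            raise ValueError("replicates_per_structure must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def gene_id(i: int) -> str:
    return f"G{i:05d}"


def structure_id(i: int) -> str:
    return f"S{i:03d}"


def donor_id(i: int) -> str:
    return f"D{i + 1}"


def _make_ontology(n_structures: int) -> StructureOntology:
    """A two-level forest: a root, ~10 coarse regions, structures as leaves."""
    n_regions = max(1, min(10, n_structures))
    rows = [("BR", "BR", "brain (root)", "")]
    for r in range(n_regions):
        rows.append((f"R{r:02d}", f"R{r:02d}", f"region {r}", "BR"))
    for s in range(n_structures):
        region = f"R{s % n_regions:02d}"
        rows.append((structure_id(s), structure_id(s), f"structure {s}", region))
    table = pd.DataFrame(rows, columns=["structure_id", "acronym", "name", "parent_id"])
    return StructureOntology(table)


def _make_probe_map(n_genes: int, probes_per_gene: int) -> tuple[ProbeMap, pd.Series]:
    probes, genes, designated = [], [], {}
    for g in range(n_genes):
        gid = gene_id(g)
        for p in range(probes_per_gene):
            pid = f"{gid}_p{p}"
            probes.append(pid)
            genes.append(gid)
        designated[gid] = f"{gid}_p0"  # gain-1.0 probe; max variance by design
    pm = ProbeMap(pd.Series(genes, index=pd.Index(probes, name="probe_id")))
    return pm, pd.Series(designated).sort_index()


def simulate_donors(
    cfg: SimConfig, signals: Sequence[PlantedSignal] = ()
) -> tuple[list[DonorExpression], StructureOntology, ProbeMap, dict]:
    """Generate a reproducible multi-donor dataset with planted signals.

    Returns the per-donor expression objects, the structure ontology, the
    probe map, and a truth dict with:

    - ``signals``: DataFrame of every planted (gene, structure, direction,
      effect_size, carrier donors),
    - ``representative_probes``: the designated max-variance probe per gene,
    - ``config``: the SimConfig used (seed included).
    """
    all_genes = {gene_id(i) for i in range(cfg.n_genes)}
    all_structs = {structure_id(i) for i in range(cfg.n_structures)}
    for s in signals:
        if not set(s.gene_ids) <= all_genes:
            raise ValueError("signal gene ids outside configured gene range")
        if not set(s.structure_ids) <= all_structs:
            raise ValueError("signal structure ids outside configured structure range")

    # Separate streams: carrier-donor choices must not perturb the noise
    # realisation, so a zero-effect signal equals a signal-free run exactly.
    _data_seed, _carrier_seed = np.random.SeedSequence(cfg.rng_seed).spawn(2)
    rng = np.random.default_rng(_data_seed)
    carrier_rng = np.random.default_rng(_carrier_seed)
    ontology = _make_ontology(cfg.n_structures)
    pm, designated = _make_probe_map(cfg.n_genes, cfg.probes_per_gene)

    genes = [gene_id(i) for i in range(cfg.n_genes)]
    structs = [structure_id(i) for i in range(cfg.n_structures)]
    gene_index = {g: i for i, g in enumerate(genes)}
    struct_index = {s: i for i, s in enumerate(structs)}
    probe_ids = list(pm.mapping.index)
    probe_gene_idx = np.array([gene_index[g] for g in pm.mapping.values])
    gains = np.where(
        pm.mapping.index.isin(designated.values), HIGH_VARIANCE_GAIN, LOW_VARIANCE_GAIN
    )

    mu = rng.uniform(6.0, 12.0, size=cfg.n_genes)

    # Carrier donors per signal, chosen once for the whole cohort.
    carriers: list[np.ndarray] = []
    for s in signals:
        n_carry = max(1, int(round(s.donor_penetrance * cfg.n_donors)))
        carriers.append(np.sort(carrier_rng.choice(cfg.n_donors, size=n_carry, replace=False)))

    truth_rows = []
    for s, dset in zip(signals, carriers):
        for g in sorted(s.gene_ids):
            for st in sorted(s.structure_ids):
                truth_rows.append((g, st, s.direction, s.effect_size,
                                   ";".join(donor_id(d) for d in dset)))
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "structure_id", "direction", "effect_size", "donors"]
    )

    donors: list[DonorExpression] = []
    for d in range(cfg.n_donors):
        for _attempt in range(100):
            sampled = rng.random(cfg.n_structures) < cfg.structure_sampling_prob
            if sampled.any():
                break
        else:
            raise RuntimeError("could not sample any structure for a donor")
        s_idx = np.flatnonzero(sampled)

        # Gene x sampled-structure latent values.
        value = mu[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, len(s_idx)))
        col_of = {int(si): j for j, si in enumerate(s_idx)}
        for sig, dset in zip(signals, carriers):
            if d not in dset:
                continue
            shift = sig.direction * sig.effect_size * cfg.noise_sd
            gi = [gene_index[g] for g in sorted(sig.gene_ids)]
            sj = [col_of[struct_index[st]] for st in sorted(sig.structure_ids)
                  if struct_index[st] in col_of]
            if sj:
                value[np.ix_(gi, sj)] += shift

        reps = 1 + rng.poisson(cfg.replicates_per_structure - 1.0, size=len(s_idx))
        sample_struct_col = np.repeat(np.arange(len(s_idx)), reps)
        sample_ids, ann = [], []
        for j, si in enumerate(s_idx):
            for r in range(reps[j]):
                sample_ids.append(f"{donor_id(d)}_{structure_id(int(si))}_r{r + 1}")
                ann.append(structure_id(int(si)))

        centered = value - mu[:, None]  # genes x sampled structures
        probe_vals = (
            mu[probe_gene_idx][:, None]
            + gains[:, None] * centered[probe_gene_idx][:, sample_struct_col]
            + rng.normal(0.0, cfg.replicate_noise_sd, size=(len(probe_ids), len(sample_ids)))
        )
        expr = pd.DataFrame(probe_vals, index=pd.Index(probe_ids, name="probe_id"),
                            columns=sample_ids)
        annotation = pd.Series(ann, index=sample_ids)
        donors.append(DonorExpression(donor_id(d), expr, annotation, scale_flag="log2"))

    truth_dict = {
        "signals": truth,
        "representative_probes": designated,
        "config": cfg,
    }
    return donors, ontology, pm, truth_dict


def default_signals(
    cfg: SimConfig,
    n_signal_genes: int = 100,
    structures_per_gene: int = 3,
    effect_size: float = 4.0,
    donor_penetrance: float = 1.0,
    seed: int = 12345,
) -> list[PlantedSignal]:
    """Per-gene planted signals: each signal gene gets its own small set of
    structures, half the genes shifted up and half down.

    Gene/structure choices come from ``seed`` so the layout is independent of
    the noise realisation in :func:`simulate_donors`.
    """
    rng = np.random.default_rng(seed)
    if n_signal_genes > cfg.n_genes:
        raise ValueError("more signal genes than genes")
    gene_pick = rng.choice(cfg.n_genes, size=n_signal_genes, replace=False)
    out = []
    for i, g in enumerate(sorted(gene_pick)):
        st = rng.choice(cfg.n_structures, size=structures_per_gene, replace=False)
        out.append(PlantedSignal(
            gene_ids=frozenset({gene_id(int(g))}),
            structure_ids=frozenset(structure_id(int(s)) for s in st),
            direction=1 if i % 2 == 0 else -1,
            effect_size=effect_size,
            donor_penetrance=donor_penetrance,
        ))
    return out
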