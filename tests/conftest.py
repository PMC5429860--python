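import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from neuroconsensus import SimConfig, default_signals, simulate_donors
from neuroconsensus.io_model import DonorExpression, ProbeMap, StructureOntology


@pytest.fixture(scope="session")
def small_sim():
    """Six donors, 50 structures, 200 genes, 10 planted single-gene signals."""
    cfg = SimConfig(n_donors=6, n_structures=50, n_genes=200, rng_seed=7)
    signals = default_signals(cfg, n_signal_genes=10, structures_per_gene=3,
                              effect_size=4.0, seed=70)
    donors, ontology, pm, truth = simulate_donors(cfg, signals)
    return {"cfg": cfg, "signals": signals, "donors": donors,
            "ontology": ontology, "probe_map": pm, "truth": truth}


@pytest.fixture()
def tiny_donor():
    """3 probes x 4 samples; structures STA (replicates) and STB."""
    expr = pd.DataFrame(
        [[2.0, 4.0, 1.0, 7.0],
         [1.0, 1.0, 1.0, 1.0],
         [0.0, 2.0, 4.0, 6.0]],
        index=["p1", "p2", "p3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    annot = pd.Series({"s1": "STA", "s2": "STA", "s3": "STB", "s4": "STB"})
    return DonorExpression("donorA", expr, annot)


@pytest.fixture()
def tiny_ontology():
    return StructureOntology(pd.DataFrame({
        "structure_id": ["ROOT", "STA", "STB"],
        "acronym": ["ROOT", "STA", "STB"],
        "name": ["root", "structure a", "structure b"],
        "parent_id": ["", "ROOT", "ROOT"],
    }))


@pytest.fixture()
def tiny_probe_map():
    return ProbeMap(pd.Series({"p1": "g1", "p2": "g1", "p3": "g2"}))


def random_pattern_stack(rng, n_donors=6, n_genes=200, n_structs=50,
                         p_unsampled=0.2, p_up=0.25, p_down=0.25):
    """Donors x genes x structures array over {-1, 0, 1, NaN}.

    Sampling masks are per (donor, structure), as in real donors; call signs
    are per cell.  Biasing p_up vs p_down makes unanimous-agreement criteria
    fire often enough to exercise on small grids.
    """
    stack = np.zeros((n_donors, n_genes, n_structs))
    for d in range(n_donors):
        sampled = rng.random(n_structs) >= p_unsampled
        calls = rng.choice([-1, 0, 1], size=(n_genes, n_structs),
                           p=[p_down, 1 - p_up - p_down, p_up]).astype(float)
        calls[:, ~sampled] = np.nan
        stack[d] = calls
    return stack
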