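import numpy as np
import pandas as pd
import pytest

from arid1a_hcc.signature import GeneSignature, compute_gene_stats, derive_signature
from arid1a_hcc.synthetic_data import default_mouse_truth, simulate_mouse_experiment


@pytest.fixture(scope="session")
def mouse_experiment():
    """Canonical planted experiment: 1000 genes, 50 DE at effect 4, 10 vs 10."""
    truth = default_mouse_truth(seed=11)
    expr, labels, truth = simulate_mouse_experiment(1000, truth.n_per_group, truth)
    return expr, labels, truth


@pytest.fixture(scope="session")
def mouse_signature(mouse_experiment):
    expr, labels, _ = mouse_experiment
    stats = compute_gene_stats(expr, labels, classes=("WT", "KO"))
    return derive_signature(stats)


@pytest.fixture()
def toy_signature():
    entries = pd.DataFrame(
        {"weight": [12.0, -9.0, 7.5, -6.0],
         "direction": ["up", "down", "up", "down"]},
        index=pd.Index(["SIGA", "SIGB", "SIGC", "SIGD"], name="gene_id"))
    return GeneSignature(entries=entries)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
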