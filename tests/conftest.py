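"""Shared fixtures: the standard simulated tissue and its derived scores.

All heavy simulations are session-scoped so the whole suite pays for them
once.  Seeds are fixed; every fixture is deterministic.
"""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import retfid as rf

FIXTURE_SEED = 1
FETAL_AGES = tuple(float(a) for a in np.linspace(50, 200, 12))


@pytest.fixture(scope="session")
def tissue_sim():
    """Default-fixture mature tissue: 7 types, 2000 genes, 4 batches."""
    cfg = rf.SimConfig.default_fixture(seed=FIXTURE_SEED)
    return rf.simulate_tissue(cfg)


@pytest.fixture(scope="session")
def batch_scores(tissue_sim):
    m, ann, _ = tissue_sim
    return rf.score_batches(m, ann)


@pytest.fixture(scope="session")
def avg_scores(batch_scores):
    return rf.average_scores(batch_scores)


@pytest.fixture(scope="session")
def mature_reference(tissue_sim):
    m, ann, _ = tissue_sim
    return rf.build_reference([(m, ann)], group="mature")


@pytest.fixture(scope="session")
def fetal_sim():
    """Age-resolved fetal series from the same truth seed: 12 batches."""
    cfg = rf.SimConfig.default_fixture(seed=FIXTURE_SEED,
                                       ages_dpc=list(FETAL_AGES),
                                       n_batches=12)
    return rf.simulate_tissue(cfg)


@pytest.fixture(scope="session")
def fetal_scored(fetal_sim):
    m, ann, _ = fetal_sim
    pairs = []
    for ism in rf.score_batches(m, ann):
        sub = ann[ann["batch"] == ism.batch]
        pairs.append((ism, float(sub["age_dpc"].mean())))
    return pairs


@pytest.fixture(scope="session")
def fetal_reference(fetal_sim):
    m, ann, _ = fetal_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rf.build_reference([(m, ann)], group="fetal")


@pytest.fixture(scope="session")
def reference_train(tissue_sim):
    """Log-normalized tissue expression + labels for the rejector."""
    m, ann, _ = tissue_sim
    ln = rf.log_normalize(m)
    labels = (ann.set_index("cell_id")
              .loc[ln.cells.to_numpy(), "cell_type"].to_numpy())
    return ln, labels


def tiny_lognorm(values, cell_types, genes=None):
    """Build a small lognorm ExpressionMatrix + annotation for unit tests."""
    values = np.asarray(values, float)
    n_genes, n_cells = values.shape
    genes = genes or [f"g{i + 1}" for i in range(n_genes)]
    cells = [f"c{i}" for i in range(n_cells)]
    m = rf.ExpressionMatrix(sp.csr_matrix(values), genes, cells,
                            layer="lognorm")
    ann = pd.DataFrame({"cell_id": cells, "cell_type": list(cell_types),
                        "dataset": "d", "batch": "b",
                        "source": "tissue_mature"})
    return m, ann


@pytest.fixture
def worked_example():
    """3 genes x 2 types: g1 on only in A, g2 only in B, g3 constant."""
    values = [[2, 2, 0, 0],
              [0, 0, 2, 2],
              [1, 1, 1, 1]]
    return tiny_lognorm(values, ["A", "A", "B", "B"])
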