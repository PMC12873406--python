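"""Shared fixtures: the synthetic study dataset and its expensive
downstream products are computed once per session."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import scrobust as sr

FIXTURE_SEED = 2024


@pytest.fixture(scope="session")
def small_study():
    """The deterministic desk-scale study: dataset + planted ground truth."""
    return sr.fixture_small(FIXTURE_SEED)


@pytest.fixture(scope="session")
def de_table_mixed(small_study):
    """Mixed-mode hurdle DE for the DEG-bearing cluster (computed once)."""
    dataset, _ = small_study
    return sr.run_de(dataset, "ExN_A", mode="mixed")


@pytest.fixture(scope="session")
def robustness_mixed(de_table_mixed):
    return sr.robustness_scores(de_table_mixed, sr.make_grid())


@pytest.fixture
def tiny_dataset():
    """Hand-written 3-cell x 4-gene dataset for exact-arithmetic tests."""
    counts = sp.csr_matrix(
        np.array(
            [
                [5, 0, 3, 2],
                [0, 1, 0, 0],
                [4, 4, 4, 4],
            ]
        )
    )
    cell_meta = pd.DataFrame(
        {
            "sample_id": ["S1", "S1", "S2"],
            "cluster_label": ["A", "A", "B"],
            "major_class": ["Neuron", "Neuron", "Glia"],
        },
        index=pd.Index(["c1", "c2", "c3"], name="barcode"),
    )
    sample_meta = pd.DataFrame(
        {
            "diagnosis": ["case", "control"],
            "age": [50.0, 60.0],
            "sex": ["M", "F"],
        },
        index=pd.Index(["S1", "S2"], name="sample_id"),
    )
    gene_meta = pd.DataFrame(
        {
            "symbol": ["g1", "g2", "g3", "MT-1"],
            "is_protein_coding": [True, True, False, False],
            "is_mito": [False, False, False, True],
        },
        index=pd.Index(["G1", "G2", "G3", "G4"], name="gene_id"),
    )
    return sr.CellGeneDataset(counts, cell_meta, sample_meta, gene_meta)
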