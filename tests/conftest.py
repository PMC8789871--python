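import numpy as np
import pandas as pd
import pytest

from alveonet.data import ExpressionDataset, LRDatabase


def make_meta(n, conditions=None, cell_types=None, subjects=None, compartments=None,
              mito=None, unspliced=None):
    """Assemble a minimal valid annotation table."""
    return pd.DataFrame(
        {
            "cell_id": [f"c{i:03d}" for i in range(n)],
            "subject_id": subjects if subjects is not None else ["s0"] * n,
            "condition": conditions if conditions is not None else ["control"] * n,
            "cell_type": cell_types if cell_types is not None else ["A"] * n,
            "compartment": compartments if compartments is not None else ["epithelial"] * n,
            "mito_fraction": mito if mito is not None else [0.05] * n,
            "unspliced_fraction": unspliced if unspliced is not None else [0.2] * n,
        }
    )


def make_dataset(counts, **meta_kwargs) -> ExpressionDataset:
    counts = np.asarray(counts)
    n, g = counts.shape
    genes = meta_kwargs.pop("genes", [f"g{j}" for j in range(g)])
    return ExpressionDataset(counts=counts, gene_ids=genes, cell_meta=make_meta(n, **meta_kwargs))


def random_dataset(seed, n_cells=50, n_genes=8, n_types=3, n_subjects=2):
    """Random two-condition dataset for property tests."""
    rng = np.random.default_rng(seed)
    counts = rng.poisson(3.0, size=(n_cells, n_genes))
    conditions = rng.choice(["control", "disease"], size=n_cells).tolist()
    cell_types = rng.choice([f"T{i}" for i in range(n_types)], size=n_cells).tolist()
    subjects = [
        f"{c}_s{i}" for c, i in zip(conditions, rng.integers(0, n_subjects, size=n_cells))
    ]
    meta = make_meta(
        n_cells,
        conditions=conditions,
        cell_types=cell_types,
        subjects=subjects,
        mito=rng.uniform(0, 0.15, size=n_cells).tolist(),
        unspliced=rng.uniform(0.15, 0.5, size=n_cells).tolist(),
    )
    return ExpressionDataset(counts=counts, gene_ids=[f"g{j}" for j in range(n_genes)], cell_meta=meta)


@pytest.fixture
def tiny_dataset():
    """3 cells x 2 genes with handmade counts."""
    return make_dataset([[10, 0], [5, 5], [0, 3]])


@pytest.fixture
def lr_db():
    return LRDatabase(
        pairs=[
            ("CXCL12", "CXCR4", "CXCL"),
            ("WNT2B", "FZD1", "WNT"),
        ]
    )
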