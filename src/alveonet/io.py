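"""Readers and writers for the pipeline's on-disk formats.

Expression input is MatrixMarket (genes × cells on disk, the dominant
repository convention; transposed to cells × genes in memory) plus a
plain-text gene list and a TSV annotation table.  Ligand–receptor pairs come
from a 3-column CSV (ligand, receptor, mode).  Network outputs go to CSV,
GraphML (via networkx) or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .data import REQUIRED_CELL_META, ExpressionDataset, LRDatabase

EDGE_COLUMNS = [
    "source",
    "target",
    "ligand",
    "receptor",
    "mode",
    "weight_norm",
    "weight_scaled",
    "pct_ligand",
    "pct_receptor",
]


def read_expression_dataset(matrix_path, genes_path, annotations_path) -> ExpressionDataset:
    """Read MTX counts (genes × cells on disk) + gene list + annotation TSV."""
    matrix = scipy.io.mmread(str(matrix_path))
    genes = [line.strip() for line in Path(genes_path).read_text().splitlines() if line.strip()]
    meta = pd.read_csv(annotations_path, sep="\t", dtype={"cell_id": str, "subject_id": str})
    missing = [c for c in REQUIRED_CELL_META if c not in meta.columns]
    if missing:
        raise ValueError(f"annotation table missing required column(s): {missing}")
    n_genes_disk, n_cells_disk = matrix.shape
    if n_genes_disk != len(genes):
        raise ValueError(
            f"gene axis mismatch: matrix has {n_genes_disk} rows but gene list "
            f"has {len(genes)} entries"
        )
    if n_cells_disk != len(meta):
        raise ValueError(
            f"cell axis mismatch: matrix has {n_cells_disk} columns but annotation "
            f"table has {len(meta)} rows"
        )
    counts = sp.csr_matrix(matrix.T)
    data = counts.data
    if data.size and not np.allclose(data, np.round(data)):
        raise ValueError("count matrix contains non-integer entries")
    counts = counts.astype(np.int64)
    return ExpressionDataset(counts=counts, gene_ids=genes, cell_meta=meta)


def write_expression_dataset(dataset: ExpressionDataset, out_dir) -> dict[str, Path]:
    """Write the MTX (genes × cells) + gene list + annotation TSV triplet."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.txt",
        "annotations": out / "annotations.tsv",
    }
    mat = sp.coo_matrix(sp.csr_matrix(dataset.counts).T)
    scipy.io.mmwrite(str(paths["matrix"]), mat, field="integer")
    paths["genes"].write_text("\n".join(dataset.gene_ids) + "\n")
    dataset.cell_meta.to_csv(paths["annotations"], sep="\t", index=False)
    return paths


def read_lr_database(path) -> LRDatabase:
    """Read a ligand,receptor,mode CSV into an :class:`LRDatabase`."""
    table = pd.read_csv(path)
    required = {"ligand", "receptor", "mode"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ligand–receptor table missing column(s): {sorted(missing)}")
    if table.empty:
        raise ValueError("ligand–receptor table is empty")
    return LRDatabase(pairs=list(table[["ligand", "receptor", "mode"]].itertuples(index=False, name=None)))


def write_lr_database(lrdb: LRDatabase, path) -> Path:
    path = Path(path)
    lrdb.to_frame().to_csv(path, index=False)
    return path


# -- network outputs ---------------------------------------------------------

def _edges_frame(obj) -> tuple[pd.DataFrame, list[str], dict]:
    """Normalize a Connectome or DifferentialEdgeSet into (edges, nodes, meta)."""
    nodes = list(getattr(obj, "nodes", []))
    edges = obj.edges.copy()
    meta = {"condition": getattr(obj, "condition", None)}
    return edges, nodes, meta


def write_network_outputs(obj, path, format: str = "csv") -> Path:
    """Write a Connectome or DifferentialEdgeSet edge table.

    ``format`` is one of ``csv`` (full-precision edge table), ``graphml``
    (per-pair multi-edges via networkx) or ``json``.
    """
    supported = ("csv", "graphml", "json")
    if format not in supported:
        raise ValueError(f"unknown format {format!r}; supported formats: {supported}")
    edges, nodes, meta = _edges_frame(obj)
    if not nodes:
        raise ValueError("cannot write a network with an empty node set")
    path = Path(path)
    if format == "csv":
        edges.to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        payload = {
            "nodes": nodes,
            "meta": meta,
            "edges": edges.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1, default=float))
    else:
        import networkx as nx

        graph = nx.MultiDiGraph()
        graph.add_nodes_from(nodes)
        for row in edges.to_dict(orient="records"):
            attrs = {k: v for k, v in row.items() if k not in ("source", "target")}
            graph.add_edge(row["source"], row["target"], **attrs)
        nx.write_graphml(graph, path)
    return path


def read_edges_csv(path) -> pd.DataFrame:
    """Round-trip reader for the CSV edge table written above."""
    return pd.read_csv(path)


def read_network_graphml(path):
    import networkx as nx

    return nx.read_graphml(path, force_multigraph=True)
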