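"""Core domain containers for the connectome pipeline.

The single source of truth for expression data is :class:`ExpressionDataset`,
which carries the raw UMI count matrix (cells × genes), the optional
CP10K/log1p ``normalized`` layer, the optional per-gene z-scored ``scaled``
layer, and a per-cell metadata table.  Downstream stages never touch raw
files; they consume these containers.

Layers that have not been computed yet are ``None`` (never silently zero),
so calling a stage out of order fails loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: columns the per-cell annotation table must provide
REQUIRED_CELL_META = (
    "cell_id",
    "subject_id",
    "condition",
    "cell_type",
    "compartment",
    "mito_fraction",
    "unspliced_fraction",
)


def _to_dense(matrix) -> np.ndarray:
    if sp.issparse(matrix):
        return np.asarray(matrix.todense())
    return np.asarray(matrix)


@dataclass
class ExpressionDataset:
    """Cells × genes UMI counts plus optional derived layers and metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, cells × genes (dense ndarray or scipy
        sparse).
    gene_ids
        Unique gene symbols, one per column.
    cell_meta
        DataFrame with one row per cell, columns :data:`REQUIRED_CELL_META`.
        ``total_transcripts`` is always (re)computed from the counts.
    normalized, scaled
        Derived layers; absent (``None``) until the corresponding stage ran.
    """

    counts: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_meta: pd.DataFrame
    normalized: np.ndarray | None = None
    scaled: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"gene_ids are not unique: {dupes[:5]}")
        n_cells, n_genes = self.counts.shape
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"gene axis mismatch: counts have {n_genes} columns but "
                f"{len(self.gene_ids)} gene ids were given"
            )
        if len(self.cell_meta) != n_cells:
            raise ValueError(
                f"cell axis mismatch: counts have {n_cells} rows but cell_meta "
                f"has {len(self.cell_meta)} records"
            )
        missing = [c for c in REQUIRED_CELL_META if c not in self.cell_meta.columns]
        if missing:
            raise ValueError(f"cell_meta missing required column(s): {missing}")
        data = self.counts.data if sp.issparse(self.counts) else self.counts
        arr = np.asarray(data)
        if arr.size:
            if np.any(arr < 0):
                raise ValueError("counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral (UMI counts)")
        self.cell_meta = self.cell_meta.reset_index(drop=True).copy()
        totals = np.asarray(self.counts.sum(axis=1)).ravel()
        self.cell_meta["total_transcripts"] = totals.astype(np.int64)

    # -- basic introspection -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def total_transcripts(self) -> np.ndarray:
        return self.cell_meta["total_transcripts"].to_numpy()

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in dataset") from None

    def counts_dense(self) -> np.ndarray:
        return _to_dense(self.counts)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionDataset":
        """Return a new dataset keeping cells where ``mask`` is True (order kept)."""
        mask = np.asarray(mask, dtype=bool)
        counts = self.counts[mask]
        return ExpressionDataset(
            counts=counts,
            gene_ids=list(self.gene_ids),
            cell_meta=self.cell_meta.loc[mask].reset_index(drop=True),
            normalized=None if self.normalized is None else self.normalized[mask],
            scaled=None if self.scaled is None else self.scaled[mask],
        )

    def with_layer(self, **layers) -> "ExpressionDataset":
        return replace(self, **layers)

    def to_anndata(self):
        """Export to an :class:`anndata.AnnData` (counts in ``layers['counts']``)."""
        import anndata as ad

        X = self.normalized if self.normalized is not None else self.counts_dense().astype(float)
        adata = ad.AnnData(
            X=np.asarray(X, dtype=float),
            obs=self.cell_meta.set_index("cell_id", drop=False),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene")),
        )
        adata.layers["counts"] = self.counts_dense()
        if self.scaled is not None:
            adata.layers["scaled"] = np.asarray(self.scaled)
        return adata


@dataclass(frozen=True)
class QCThresholds:
    """Per-cell retention thresholds.

    A cell is retained iff ``total_transcripts >= min_transcripts`` and
    ``mito_fraction <= max_mito_fraction`` and
    ``unspliced_fraction >= min_unspliced_fraction`` — i.e. removal uses the
    strict inequalities of the originating protocols (<1000 transcripts,
    >20 % mitochondrial, <12 % unspliced for human tissue).
    """

    min_transcripts: int = 1000
    max_mito_fraction: float = 0.20
    min_unspliced_fraction: float = 0.12
    preset: str = "custom"

    def __post_init__(self) -> None:
        if self.min_transcripts < 0:
            raise ValueError("min_transcripts must be >= 0")
        for name in ("max_mito_fraction", "min_unspliced_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def human(cls) -> "QCThresholds":
        return cls(1000, 0.20, 0.12, preset="human")

    @classmethod
    def mouse(cls) -> "QCThresholds":
        return cls(1000, 0.05, 0.075, preset="mouse")

    @classmethod
    def from_preset(cls, name: str) -> "QCThresholds":
        presets = {"human": cls.human, "mouse": cls.mouse}
        if name not in presets:
            raise ValueError(f"unknown QC preset {name!r}; choose from {sorted(presets)}")
        return presets[name]()


@dataclass
class LRDatabase:
    """Ligand–receptor pair vocabulary with signaling-mode labels."""

    pairs: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        deduped: list[tuple[str, str, str]] = []
        for ligand, receptor, mode in self.pairs:
            ligand, receptor, mode = str(ligand), str(receptor), str(mode)
            if not ligand or not receptor:
                raise ValueError("ligand and receptor symbols must be non-empty")
            if not mode:
                raise ValueError(f"pair ({ligand}, {receptor}) has an empty mode label")
            key = (ligand, receptor)
            if key in seen:
                if seen[key] != mode:
                    raise ValueError(
                        f"pair ({ligand}, {receptor}) listed with conflicting modes "
                        f"{seen[key]!r} and {mode!r}"
                    )
                continue
            seen[key] = mode
            deduped.append((ligand, receptor, mode))
        self.pairs = deduped

    @property
    def modes(self) -> set[str]:
        return {mode for _, _, mode in self.pairs}

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for ligand, receptor, _ in self.pairs:
            out.add(ligand)
            out.add(receptor)
        return out

    def pairs_for_mode(self, mode: str) -> list[tuple[str, str, str]]:
        return [p for p in self.pairs if p[2] == mode]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["ligand", "receptor", "mode"])

    def __len__(self) -> int:
        return len(self.pairs)


class ClusterProfileSet:
    """Per (condition, cell type, gene) expression summaries.

    Backed by a long-format DataFrame with columns ``condition``,
    ``cell_type``, ``gene``, ``mean_norm``, ``mean_z``, ``pct_expressing``,
    ``n_cells``.  The connectome is built entirely from these summaries.
    """

    COLUMNS = ("condition", "cell_type", "gene", "mean_norm", "mean_z", "pct_expressing", "n_cells")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"profile table missing column(s): {missing}")
        self.table = table.reset_index(drop=True)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())

    def for_condition(self, condition: str) -> pd.DataFrame:
        sub = self.table[self.table["condition"] == condition]
        if sub.empty:
            raise KeyError(
                f"condition {condition!r} absent from profiles; have {self.conditions}"
            )
        return sub

    def pivot(self, condition: str, value: str) -> pd.DataFrame:
        """Genes × cell-types matrix of one summary statistic for a condition."""
        sub = self.for_condition(condition)
        return sub.pivot_table(index="gene", columns="cell_type", values=value, fill_value=0.0)
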