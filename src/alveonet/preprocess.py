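"""QC, normalization, scaling, cluster profiling, DE, markers, composition.

The preprocessing contract mirrors common single-cell practice: cells are
filtered on total transcripts, mitochondrial fraction and unspliced
fraction; retained counts are normalized to counts-per-10,000 and
log1p-transformed; the scaled layer holds per-gene z-scores (optionally
after regressing out a per-cell covariate such as the mitochondrial
fraction), clipped to a maximum magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import benjamini_hochberg, bonferroni, rank_sum_test
from .data import ClusterProfileSet, ExpressionDataset, QCThresholds

logger = logging.getLogger(__name__)


# -- QC ----------------------------------------------------------------------

def qc_filter(
    dataset: ExpressionDataset,
    thresholds: QCThresholds,
    return_report: bool = False,
):
    """Remove cells failing any QC criterion (strict-inequality removal).

    Retained cells satisfy ``total >= min_transcripts``, ``mito <= max_mito``
    and ``unspliced >= min_unspliced``; cell order is preserved and genes are
    untouched.  With ``return_report=True`` also returns a dict of removal
    counts per criterion (a cell can count against several criteria).
    """
    for col in ("mito_fraction", "unspliced_fraction"):
        if col not in dataset.cell_meta.columns:
            raise ValueError(f"dataset missing QC column {col!r}")
    totals = dataset.total_transcripts
    mito = dataset.cell_meta["mito_fraction"].to_numpy(dtype=float)
    unspliced = dataset.cell_meta["unspliced_fraction"].to_numpy(dtype=float)

    fail_total = totals < thresholds.min_transcripts
    fail_mito = mito > thresholds.max_mito_fraction
    fail_unspliced = unspliced < thresholds.min_unspliced_fraction
    keep = ~(fail_total | fail_mito | fail_unspliced)

    report = {
        "n_input": int(dataset.n_cells),
        "n_retained": int(keep.sum()),
        "removed_low_transcripts": int(fail_total.sum()),
        "removed_high_mito": int(fail_mito.sum()),
        "removed_low_unspliced": int(fail_unspliced.sum()),
        "removed_total": int((~keep).sum()),
        "preset": thresholds.preset,
    }
    if dataset.n_cells and not keep.any():
        raise ValueError(
            "QC removed every cell; review thresholds "
            f"(min_transcripts={thresholds.min_transcripts}, "
            f"max_mito_fraction={thresholds.max_mito_fraction}, "
            f"min_unspliced_fraction={thresholds.min_unspliced_fraction})"
        )
    filtered = dataset.subset_cells(keep)
    if return_report:
        return filtered, report
    return filtered


# -- normalization & scaling -------------------------------------------------

def normalize_cp10k(dataset: ExpressionDataset) -> ExpressionDataset:
    """CP10K/log1p: ``normalized[c,g] = ln(1 + 1e4 * counts[c,g] / total[c])``."""
    totals = dataset.total_transcripts.astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        cell = dataset.cell_meta["cell_id"].iloc[zero[0]]
        raise ValueError(f"cell {cell!r} has zero total transcripts; run qc_filter first")
    counts = dataset.counts_dense().astype(float)
    normalized = np.log1p(1e4 * counts / totals[:, None])
    return dataset.with_layer(normalized=normalized)


def scale_genes(
    dataset: ExpressionDataset,
    covariate: str | None = "mito_fraction",
    clip: float = 10.0,
) -> ExpressionDataset:
    """Per-gene z-scores of the normalized layer, clipped to ``[-clip, clip]``.

    If ``covariate`` names a per-cell metadata column (default the
    mitochondrial fraction), each gene is first replaced by the residuals of
    an ordinary least-squares fit on that covariate (with intercept).
    Standardization uses the sample standard deviation (n−1); constant genes
    map to all-zero columns.
    """
    if dataset.normalized is None:
        raise ValueError("normalized layer absent; run normalize_cp10k first")
    values = np.asarray(dataset.normalized, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("scaling requires at least 2 cells")
    if covariate is not None:
        if covariate not in dataset.cell_meta.columns:
            raise ValueError(f"covariate column {covariate!r} not in cell_meta")
        x = dataset.cell_meta[covariate].to_numpy(dtype=float)
        design = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(design, values, rcond=None)
        values = values - design @ beta
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    # genes constant (possibly only after regression, up to float noise) map to zero
    constant = sd <= 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[:, constant] = 0.0
    z = np.clip(z, -clip, clip)
    return dataset.with_layer(scaled=z)


# -- cluster profiles --------------------------------------------------------

def cluster_profiles(
    dataset: ExpressionDataset,
    group_by: tuple[str, str] = ("condition", "cell_type"),
) -> ClusterProfileSet:
    """Mean normalized / mean z / percent-expressing per group × gene."""
    if dataset.normalized is None:
        raise ValueError("normalized layer absent; run normalize_cp10k first")
    for key in group_by:
        if key not in dataset.cell_meta.columns:
            raise ValueError(f"group key {key!r} missing from cell_meta")
    counts = dataset.counts_dense()
    normalized = np.asarray(dataset.normalized)
    scaled = None if dataset.scaled is None else np.asarray(dataset.scaled)

    records = []
    groups = dataset.cell_meta.groupby(list(group_by), sort=True, observed=True).indices
    for key, idx in groups.items():
        condition, cell_type = key if isinstance(key, tuple) else (key,) * 2
        idx = np.asarray(idx)
        mean_norm = normalized[idx].mean(axis=0)
        mean_z = scaled[idx].mean(axis=0) if scaled is not None else np.zeros(dataset.n_genes)
        pct = (counts[idx] > 0).mean(axis=0)
        frame = pd.DataFrame(
            {
                "condition": condition,
                "cell_type": cell_type,
                "gene": dataset.gene_ids,
                "mean_norm": mean_norm,
                "mean_z": mean_z,
                "pct_expressing": pct,
                "n_cells": len(idx),
            }
        )
        records.append(frame)
    if not records:
        raise ValueError("no cells to profile")
    return ClusterProfileSet(pd.concat(records, ignore_index=True))


# -- differential expression -------------------------------------------------

@dataclass
class DEResult:
    """Per-gene differential expression between two conditions in a cell type."""

    table: pd.DataFrame
    cell_type: str
    cond_a: str
    cond_b: str
    n_a: int
    n_b: int


def differential_expression(
    dataset: ExpressionDataset,
    cell_type: str,
    cond_a: str,
    cond_b: str,
    min_pct: float = 0.0,
    min_fc: float = 0.0,
    correction: str = "bonferroni",
) -> DEResult:
    """Two-sided rank-sum DE on the normalized layer.

    Fold change is ``(mean_lin_a + 1) / (mean_lin_b + 1)`` with
    ``mean_lin = mean(exp(normalized) − 1)``, so the reported log2 fold
    change exponentiates back to the printed linear fc.  The multiple-testing
    correction (Bonferroni by default, BH optional) runs over genes passing
    the pre-filters: expressed in at least ``min_pct`` of either group and
    ``|log2 fc| >= min_fc``.
    """
    if dataset.normalized is None:
        raise ValueError("normalized layer absent; run normalize_cp10k first")
    meta = dataset.cell_meta
    if cell_type not in set(meta["cell_type"]):
        raise ValueError(f"unknown cell_type {cell_type!r}")
    for cond in (cond_a, cond_b):
        if cond not in set(meta["condition"]):
            raise ValueError(f"unknown condition {cond!r}")
    in_type = meta["cell_type"] == cell_type
    idx_a = np.flatnonzero(in_type & (meta["condition"] == cond_a))
    idx_b = np.flatnonzero(in_type & (meta["condition"] == cond_b))
    if len(idx_a) < 3 or len(idx_b) < 3:
        raise ValueError(
            f"need >= 3 cells per condition in {cell_type!r}; "
            f"got {len(idx_a)} ({cond_a}) and {len(idx_b)} ({cond_b})"
        )
    normalized = np.asarray(dataset.normalized)
    counts = dataset.counts_dense()
    lin = np.expm1(normalized)
    mean_lin_a = lin[idx_a].mean(axis=0)
    mean_lin_b = lin[idx_b].mean(axis=0)
    fc = (mean_lin_a + 1.0) / (mean_lin_b + 1.0)
    log2_fc = np.log2(fc)
    pct_a = (counts[idx_a] > 0).mean(axis=0)
    pct_b = (counts[idx_b] > 0).mean(axis=0)
    tested = (np.maximum(pct_a, pct_b) >= min_pct) & (np.abs(log2_fc) >= min_fc)

    pvals = np.full(dataset.n_genes, np.nan)
    for g in np.flatnonzero(tested):
        _, pvals[g] = rank_sum_test(normalized[idx_a, g], normalized[idx_b, g])
    n_tested = int(tested.sum())
    adj = np.full(dataset.n_genes, np.nan)
    if n_tested:
        if correction == "bonferroni":
            adj[tested] = bonferroni(pvals[tested], n_tested)
        elif correction == "bh":
            adj[tested] = benjamini_hochberg(pvals[tested])
        else:
            raise ValueError(f"unknown correction {correction!r}; use 'bonferroni' or 'bh'")

    table = pd.DataFrame(
        {
            "gene": dataset.gene_ids,
            "mean_lin_a": mean_lin_a,
            "mean_lin_b": mean_lin_b,
            "fold_change": fc,
            "log2_fold_change": log2_fc,
            "pct_a": pct_a,
            "pct_b": pct_b,
            "tested": tested,
            "p_value": pvals,
            "p_adjusted": adj,
        }
    )
    return DEResult(table=table, cell_type=cell_type, cond_a=cond_a, cond_b=cond_b,
                    n_a=len(idx_a), n_b=len(idx_b))


# -- marker scoring (diagnostic odds ratio) ----------------------------------

def marker_dor(dataset: ExpressionDataset, cell_type_key: str = "cell_type") -> pd.DataFrame:
    """Rank marker genes per cell type by the diagnostic odds ratio.

    Detection is ``count > 0``.  With the 0.5 continuity correction,
    ``DOR = ((TP+0.5)(TN+0.5)) / ((FP+0.5)(FN+0.5))`` is always finite and
    positive.  Rows are ranked per cell type by DOR descending, ties broken
    by in-type percent expressing then gene id.
    """
    if cell_type_key not in dataset.cell_meta.columns:
        raise ValueError(f"cell_type key {cell_type_key!r} missing from cell_meta")
    labels = dataset.cell_meta[cell_type_key].to_numpy()
    types = sorted(pd.unique(labels))
    if len(types) < 2:
        raise ValueError("marker scoring needs >= 2 cell types (no out-group otherwise)")
    detected = dataset.counts_dense() > 0
    frames = []
    for ct in types:
        in_type = labels == ct
        n_in, n_out = int(in_type.sum()), int((~in_type).sum())
        tp = detected[in_type].sum(axis=0).astype(float)
        fp = detected[~in_type].sum(axis=0).astype(float)
        fn = n_in - tp
        tn = n_out - fp
        dor = ((tp + 0.5) * (tn + 0.5)) / ((fp + 0.5) * (fn + 0.5))
        frame = pd.DataFrame(
            {
                "cell_type": ct,
                "gene": dataset.gene_ids,
                "TP": tp.astype(int),
                "FP": fp.astype(int),
                "FN": fn.astype(int),
                "TN": tn.astype(int),
                "pct_expressing": tp / max(n_in, 1),
                "DOR": dor,
            }
        )
        frame = frame.sort_values(
            ["DOR", "pct_expressing", "gene"], ascending=[False, False, True]
        ).reset_index(drop=True)
        frame["rank"] = np.arange(1, len(frame) + 1)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# -- compositional comparison ------------------------------------------------

@dataclass
class ProportionResult:
    table: pd.DataFrame
    compartment: str
    cond_a: str
    cond_b: str
    excluded_subjects: list[str]


def compare_proportions(
    dataset: ExpressionDataset,
    compartment: str,
    cond_a: str = "disease",
    cond_b: str = "control",
    denominator: str = "compartment",
    center: str = "mean",
) -> ProportionResult:
    """Compare per-subject cell-type proportions between conditions.

    Proportions are computed per subject within the stated compartment
    (``denominator='dataset'`` uses all of a subject's cells instead), tested
    per cell type with the two-sided rank-sum across subjects, and corrected
    across cell types with Benjamini–Hochberg.  The fold change is
    mean (or median) proportion ``cond_a`` / ``cond_b``; a zero ``cond_b``
    mean with non-zero ``cond_a`` is flagged +inf.
    """
    meta = dataset.cell_meta
    if "compartment" not in meta.columns:
        raise ValueError("cell_meta missing 'compartment' column")
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    sub = meta[meta["compartment"] == compartment]
    if sub.empty:
        raise ValueError(f"no cells in compartment {compartment!r}")

    excluded = []
    all_subjects = meta[["subject_id", "condition"]].drop_duplicates()
    compartment_subjects = set(sub["subject_id"])
    for sid in all_subjects["subject_id"]:
        if sid not in compartment_subjects:
            excluded.append(sid)
            logger.warning("subject %s has 0 cells in compartment %s; excluded", sid, compartment)

    denom_source = sub if denominator == "compartment" else meta[meta["subject_id"].isin(compartment_subjects)]
    cell_types = sorted(sub["cell_type"].unique())
    counts = sub.groupby(["subject_id", "cell_type"], observed=True).size()
    totals = denom_source.groupby("subject_id", observed=True).size()
    cond_of = dict(zip(all_subjects["subject_id"], all_subjects["condition"]))

    props = counts.unstack(fill_value=0).reindex(columns=cell_types, fill_value=0)
    props = props.div(totals.reindex(props.index), axis=0)

    subjects_a = [s for s in props.index if cond_of.get(s) == cond_a]
    subjects_b = [s for s in props.index if cond_of.get(s) == cond_b]
    if len(subjects_a) < 2 or len(subjects_b) < 2:
        raise ValueError(
            f"need >= 2 subjects per condition with cells in {compartment!r}; "
            f"got {len(subjects_a)} ({cond_a}) and {len(subjects_b)} ({cond_b})"
        )

    rows = []
    for ct in cell_types:
        a = props.loc[subjects_a, ct].to_numpy()
        b = props.loc[subjects_b, ct].to_numpy()
        center_a = float(np.mean(a) if center == "mean" else np.median(a))
        center_b = float(np.mean(b) if center == "mean" else np.median(b))
        if center_b == 0.0:
            fc = np.inf if center_a > 0 else np.nan
        else:
            fc = center_a / center_b
        _, p = rank_sum_test(a, b)
        rows.append(
            {
                "cell_type": ct,
                f"prop_{cond_a}": center_a,
                f"prop_{cond_b}": center_b,
                "fold_change": fc,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = benjamini_hochberg(table["p_value"].to_numpy())
    return ProportionResult(
        table=table, compartment=compartment, cond_a=cond_a, cond_b=cond_b,
        excluded_subjects=excluded,
    )
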