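"""Synthetic multi-subject, two-condition scRNA-seq generator.

The generator emulates the study design every pipeline stage assumes:
discrete annotated cell types from multiple subjects per condition,
negative-binomial UMI counts with log-normal subject and library-size
factors, ligand/receptor genes carrying planted condition × cell-type fold
changes, and Beta-distributed mitochondrial / unspliced QC fields with a
configurable fraction of cells drawn from QC-violating components.

Counts are gamma–Poisson: ``lam ~ Gamma(shape=θ, scale=m/θ)``,
``count ~ Poisson(lam)`` so that ``E = m`` and ``Var = m + m²/θ``.  One
global seed drives a documented stream-splitting scheme (a child stream per
condition × subject × cell type), so adding cell types or subjects does not
perturb existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ExpressionDataset, LRDatabase

CONDITIONS = ("control", "disease")


@dataclass(frozen=True)
class PlantedEffect:
    """Multiply gene ``gene``'s mean by ``fold`` in (cell_type, condition)."""

    gene: str
    cell_type: str
    condition: str
    fold: float


@dataclass
class SimulationConfig:
    cell_types: list[str]
    genes: list[str]
    #: cell_type -> gene -> baseline NB mean; genes not listed fall back to
    #: ``default_mean`` (shared across cell types)
    baseline_means: dict[str, dict[str, float]]
    default_mean: float = 15.0
    compartments: dict[str, str] = field(default_factory=dict)
    n_subjects_per_condition: int = 8
    cells_per_subject_per_type: tuple[int, int] = (30, 50)
    dispersion: float = 10.0
    library_sigma: float = 0.25
    subject_sigma: float = 0.15
    lr_panel: list[tuple[str, str, str]] = field(default_factory=list)
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    mito_beta: tuple[float, float] = (4.0, 60.0)
    unspliced_beta: tuple[float, float] = (20.0, 50.0)
    contamination_fraction: float = 0.0
    contaminated_mito_beta: tuple[float, float] = (30.0, 45.0)
    contaminated_unspliced_beta: tuple[float, float] = (3.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("genes must be unique")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.library_sigma < 0 or self.subject_sigma < 0:
            raise ValueError("library_sigma and subject_sigma must be >= 0")
        if not (0.0 <= self.contamination_fraction <= 1.0):
            raise ValueError("contamination_fraction must lie in [0, 1]")
        lo, hi = self.cells_per_subject_per_type
        if lo < 1 or hi < lo:
            raise ValueError("cells_per_subject_per_type must be a (lo, hi) range with 1 <= lo <= hi")
        gene_set = set(self.genes)
        for ct in self.baseline_means:
            if ct not in self.cell_types:
                raise ValueError(f"baseline_means references unknown cell type {ct!r}")
            for g in self.baseline_means[ct]:
                if g not in gene_set:
                    raise ValueError(f"baseline_means references unknown gene {g!r}")
        for eff in self.planted_effects:
            if eff.fold <= 0:
                raise ValueError(f"planted fold must be > 0, got {eff.fold} for {eff.gene}")
            if eff.gene not in gene_set:
                raise ValueError(f"planted effect on unknown gene {eff.gene!r}")
            if eff.cell_type not in self.cell_types:
                raise ValueError(f"planted effect on unknown cell type {eff.cell_type!r}")
            if eff.condition not in CONDITIONS:
                raise ValueError(f"planted effect on unknown condition {eff.condition!r}")
        for ligand, receptor, mode in self.lr_panel:
            for g in (ligand, receptor):
                if g not in gene_set:
                    raise ValueError(f"LR panel references gene {g!r} not in the panel")
            if not mode:
                raise ValueError(f"LR pair ({ligand}, {receptor}) missing a mode label")

    # -- helpers -------------------------------------------------------------
    def mean_vector(self, cell_type: str, condition: str) -> np.ndarray:
        """Per-gene NB mean for one (cell type, condition) incl. planted folds."""
        per_type = self.baseline_means.get(cell_type, {})
        mu = np.array([per_type.get(g, self.default_mean) for g in self.genes], dtype=float)
        for eff in self.planted_effects:
            if eff.cell_type == cell_type and eff.condition == condition:
                mu[self.genes.index(eff.gene)] *= eff.fold
        return mu

    def lr_database(self) -> LRDatabase:
        return LRDatabase(pairs=list(self.lr_panel))

    def to_yaml(self, path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["planted_effects"] = [asdict(e) for e in self.planted_effects]
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["planted_effects"] = [PlantedEffect(**e) for e in payload.get("planted_effects", [])]
        payload["lr_panel"] = [tuple(p) for p in payload.get("lr_panel", [])]
        payload["cells_per_subject_per_type"] = tuple(payload["cells_per_subject_per_type"])
        for key in ("mito_beta", "unspliced_beta", "contaminated_mito_beta", "contaminated_unspliced_beta"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *key]))


def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> ExpressionDataset:
    """Draw a complete :class:`ExpressionDataset` from the generative model.

    ``seed`` overrides ``config.seed``; the same seed yields a bit-identical
    dataset.
    """
    seed = config.seed if seed is None else int(seed)
    theta = float(config.dispersion)
    count_blocks: list[np.ndarray] = []
    meta_rows: list[dict] = []

    for ci, condition in enumerate(CONDITIONS):
        for si in range(config.n_subjects_per_condition):
            subject_id = f"{condition}_s{si:02d}"
            subj_rng = _stream(seed, 101, ci, si)
            subject_effect = float(np.exp(subj_rng.normal(0.0, config.subject_sigma)))
            for ti, cell_type in enumerate(config.cell_types):
                rng = _stream(seed, 202, ci, si, ti)
                lo, hi = config.cells_per_subject_per_type
                n_cells = int(rng.integers(lo, hi + 1))
                mu = config.mean_vector(cell_type, condition)
                lib = np.exp(rng.normal(0.0, config.library_sigma, size=n_cells))
                mean = mu[None, :] * (subject_effect * lib)[:, None]
                lam = rng.gamma(shape=theta, scale=mean / theta)
                counts = rng.poisson(lam).astype(np.int64)
                count_blocks.append(counts)

                qc_rng = _stream(seed, 303, ci, si, ti)
                contaminated = qc_rng.random(n_cells) < config.contamination_fraction
                mito = qc_rng.beta(*config.mito_beta, size=n_cells)
                unspliced = qc_rng.beta(*config.unspliced_beta, size=n_cells)
                # contaminated cells: half high-mito, half low-unspliced
                kind = qc_rng.random(n_cells) < 0.5
                bad_mito = qc_rng.beta(*config.contaminated_mito_beta, size=n_cells)
                bad_unspliced = qc_rng.beta(*config.contaminated_unspliced_beta, size=n_cells)
                mito = np.where(contaminated & kind, bad_mito, mito)
                unspliced = np.where(contaminated & ~kind, bad_unspliced, unspliced)

                compartment = config.compartments.get(cell_type, "unassigned")
                for i in range(n_cells):
                    meta_rows.append(
                        {
                            "cell_id": f"{subject_id}_{cell_type}_{i:03d}",
                            "subject_id": subject_id,
                            "condition": condition,
                            "cell_type": cell_type,
                            "compartment": compartment,
                            "mito_fraction": float(mito[i]),
                            "unspliced_fraction": float(unspliced[i]),
                            "qc_contaminated": bool(contaminated[i]),
                        }
                    )
    counts = np.vstack(count_blocks)
    meta = pd.DataFrame(meta_rows)
    return ExpressionDataset(counts=counts, gene_ids=list(config.genes), cell_meta=meta)


def planted_truth(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth differential edges implied by the planted effects.

    Enumerates (source, target, ligand, receptor, mode) combinations whose
    ligand and receptor both carry planted disease increases (fold > 1), with
    the count-scale expectations ``lfc = log2(fold)`` and perturbation equal
    to their product.
    """
    lig_up = {}
    rec_up = {}
    for eff in config.planted_effects:
        if eff.condition != "disease" or eff.fold <= 1.0:
            continue
        lig_up.setdefault(eff.gene, {})[eff.cell_type] = eff.fold
        rec_up.setdefault(eff.gene, {})[eff.cell_type] = eff.fold
    rows = []
    for ligand, receptor, mode in config.lr_panel:
        for source, fold_l in lig_up.get(ligand, {}).items():
            for target, fold_r in rec_up.get(receptor, {}).items():
                lfc_l, lfc_r = np.log2(fold_l), np.log2(fold_r)
                rows.append(
                    {
                        "source": source,
                        "target": target,
                        "ligand": ligand,
                        "receptor": receptor,
                        "mode": mode,
                        "expected_lfc_ligand": float(lfc_l),
                        "expected_lfc_receptor": float(lfc_r),
                        "expected_perturbation": float(lfc_l * lfc_r),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "source", "target", "ligand", "receptor", "mode",
            "expected_lfc_ligand", "expected_lfc_receptor", "expected_perturbation",
        ],
    )


# -- the default end-to-end scenario ----------------------------------------

#: signaling-mode labels used by the default scenario
DEFAULT_MODES = ("CXCL", "WNT", "PDGF", "Semaphorins")


def default_copd_scenario(seed: int = 7) -> SimulationConfig:
    """Two-condition alveolar-niche scenario with a planted CXCL shift.

    Six cell types (a gCap-like capillary sender plus epithelial, stromal
    and immune receivers), 8 + 8 subjects, 200 genes, 20 ligand–receptor
    pairs over 4 signaling modes.  The disease condition plants a 4-fold
    CXCL12 increase in the gCap-like type and 2-fold CXCR4 increases in the
    two immune receiver types, emulating increased outgoing capillary
    CXCL-motif signaling.  CXCL ligands are capillary-restricted, so the
    expected recovery is: gCap tops the outgoing CXCL fold-change ranking
    and the gCap→immune CXCL12–CXCR4 edges top the both-increased
    perturbation ranking.
    """
    cell_types = ["AT1", "AT2", "Fibroblast", "gCap", "AlvMacrophage", "Tcell"]
    compartments = {
        "AT1": "epithelial",
        "AT2": "epithelial",
        "Fibroblast": "stromal",
        "gCap": "endothelial",
        "AlvMacrophage": "immune",
        "Tcell": "immune",
    }
    lr_panel = [
        ("CXCL12", "CXCR4", "CXCL"),
        ("CXCL12", "CXCR3", "CXCL"),
        ("CXCL12", "ACKR3", "CXCL"),
        ("CXCL1", "CXCR2", "CXCL"),
        ("CXCL2", "CXCR2", "CXCL"),
        ("WNT2B", "FZD1", "WNT"),
        ("WNT5A", "FZD2", "WNT"),
        ("WNT3A", "LRP6", "WNT"),
        ("WNT7A", "FZD10", "WNT"),
        ("WNT4", "FZD6", "WNT"),
        ("PDGFA", "PDGFRA", "PDGF"),
        ("PDGFB", "PDGFRB", "PDGF"),
        ("PDGFC", "PDGFRA", "PDGF"),
        ("PDGFD", "PDGFRB", "PDGF"),
        ("PDGFA", "PDGFRB", "PDGF"),
        ("SEMA3A", "NRP1", "Semaphorins"),
        ("SEMA3B", "NRP2", "Semaphorins"),
        ("SEMA4D", "PLXNB1", "Semaphorins"),
        ("SEMA6A", "PLXNA4", "Semaphorins"),
        ("SEMA5A", "PLXNB3", "Semaphorins"),
    ]
    markers = {
        "AT1": "AGER",
        "AT2": "SFTPC",
        "Fibroblast": "COL1A1",
        "gCap": "FCN3",
        "AlvMacrophage": "MARCO",
        "Tcell": "CD3E",
    }
    lr_genes: list[str] = []
    for ligand, receptor, _ in lr_panel:
        for g in (ligand, receptor):
            if g not in lr_genes:
                lr_genes.append(g)
    n_filler = 200 - len(lr_genes) - len(markers)
    filler = [f"G{i:03d}" for i in range(n_filler)]
    genes = lr_genes + list(markers.values()) + filler

    zero = 0.0
    baseline: dict[str, dict[str, float]] = {ct: {} for ct in cell_types}
    for ct in cell_types:
        # ligand–receptor genes default to absent; switched on per family below
        for g in lr_genes:
            baseline[ct][g] = zero
        # marker genes: strong in the home type, trace elsewhere
        for home, marker in markers.items():
            baseline[ct][marker] = 5.0 if ct == home else 0.05
    # CXCL ligands are capillary-restricted; CXCL receptors are broadly expressed
    baseline["gCap"]["CXCL12"] = 2.0
    baseline["gCap"]["CXCL1"] = 0.5
    baseline["gCap"]["CXCL2"] = 0.5
    for ct in cell_types:
        for rec in ("CXCR4", "CXCR3", "ACKR3", "CXCR2"):
            baseline[ct][rec] = 0.8
    # WNT: epithelial/stromal ligands, epithelial+stromal+capillary receptors
    for ct in ("AT2", "Fibroblast"):
        for lig in ("WNT2B", "WNT5A", "WNT3A", "WNT7A", "WNT4"):
            baseline[ct][lig] = 1.0
    for ct in ("AT1", "AT2", "Fibroblast", "gCap"):
        for rec in ("FZD1", "FZD2", "LRP6", "FZD10", "FZD6"):
            baseline[ct][rec] = 0.8
    # PDGF: epithelial ligands → stromal/capillary receptors
    for ct in ("AT1", "AT2"):
        for lig in ("PDGFA", "PDGFB", "PDGFC", "PDGFD"):
            baseline[ct][lig] = 1.0
    for ct in ("Fibroblast", "gCap"):
        for rec in ("PDGFRA", "PDGFRB"):
            baseline[ct][rec] = 1.0
    # Semaphorins: AT1/stromal ligands → capillary/macrophage receptors
    for ct in ("AT1", "Fibroblast"):
        for lig in ("SEMA3A", "SEMA3B", "SEMA4D", "SEMA6A", "SEMA5A"):
            baseline[ct][lig] = 1.0
    for ct in ("gCap", "AlvMacrophage"):
        for rec in ("NRP1", "NRP2", "PLXNB1", "PLXNA4", "PLXNB3"):
            baseline[ct][rec] = 1.0

    planted = [
        PlantedEffect("CXCL12", "gCap", "disease", 4.0),
        PlantedEffect("CXCR4", "AlvMacrophage", "disease", 2.0),
        PlantedEffect("CXCR4", "Tcell", "disease", 2.0),
    ]
    return SimulationConfig(
        cell_types=cell_types,
        genes=genes,
        baseline_means=baseline,
        default_mean=15.0,
        compartments=compartments,
        n_subjects_per_condition=8,
        cells_per_subject_per_type=(30, 50),
        dispersion=10.0,
        library_sigma=0.25,
        subject_sigma=0.15,
        lr_panel=lr_panel,
        planted_effects=planted,
        contamination_fraction=0.05,
        seed=seed,
    )
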