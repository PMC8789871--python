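"""Model/Results interface over the full communication analysis.

``CellCommunicationModel`` is built from an :class:`ExpressionDataset` and
an :class:`LRDatabase`; ``fit()`` runs QC → normalization → scaling →
cluster profiles → per-condition connectomes → pathway statistics →
differential connectome and returns a :class:`CellCommunicationResults`
object carrying every table the analysis produces, with ``summary()``,
export and plotting helpers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential as diff
from . import pathways as pw
from . import preprocess as pp
from .connectome import Connectome, NodeCentrality, build_connectome, cumulative_pair_weights, hits_centrality
from .data import ExpressionDataset, LRDatabase, QCThresholds
from .io import read_expression_dataset, read_lr_database, write_network_outputs


class CellCommunicationModel:
    """Two-condition cell–cell communication model over cell types.

    Parameters
    ----------
    dataset
        Annotated counts; QC/normalization are (re)run inside ``fit``.
    lr_database
        Ligand–receptor pair vocabulary with signaling-mode labels.
    conditions
        ``(control_label, disease_label)``; fold changes and log-fold changes
        are disease over control.
    qc
        :class:`QCThresholds` (default: the human preset).
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        lr_database: LRDatabase,
        conditions: tuple[str, str] = ("control", "disease"),
        qc: QCThresholds | None = None,
        gate: float = 0.05,
        scale_covariate: str | None = "mito_fraction",
        scale_clip: float = 10.0,
    ):
        self.dataset = dataset
        self.lr_database = lr_database
        self.conditions = tuple(conditions)
        self.qc = qc if qc is not None else QCThresholds.human()
        self.gate = float(gate)
        self.scale_covariate = scale_covariate
        self.scale_clip = float(scale_clip)

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_files(cls, matrix_path, genes_path, annotations_path, lr_path, **kwargs):
        dataset = read_expression_dataset(matrix_path, genes_path, annotations_path)
        lrdb = read_lr_database(lr_path)
        return cls(dataset, lrdb, **kwargs)

    @classmethod
    def from_simulation(cls, config, seed: int | None = None, **kwargs):
        from .simulate import simulate_dataset

        dataset = simulate_dataset(config, seed=seed)
        return cls(dataset, config.lr_database(), **kwargs)

    # -- fitting -------------------------------------------------------------
    def fit(
        self,
        min_perturbation: float = 0.10,
        fc_threshold: float = 0.3,
        top_k: int = 3,
        durbin_blocks: str = "type_direction",
    ) -> "CellCommunicationResults":
        cond_ctrl, cond_dis = self.conditions
        filtered, qc_report = pp.qc_filter(self.dataset, self.qc, return_report=True)
        normalized = pp.normalize_cp10k(filtered)
        scaled = pp.scale_genes(normalized, covariate=self.scale_covariate, clip=self.scale_clip)
        profiles = pp.cluster_profiles(scaled)

        connectomes = {
            cond: build_connectome(profiles, self.lr_database, cond, gate=self.gate)
            for cond in self.conditions
        }
        centrality = {cond: hits_centrality(con) for cond, con in connectomes.items()}

        modes = sorted(self.lr_database.modes)
        mode_summaries: dict[str, pd.DataFrame] = {}
        mode_centralities: dict[tuple[str, str], NodeCentrality] = {}
        durbin_rows = []
        fc_frames = []
        for mode in modes:
            per_cond = {}
            for cond in self.conditions:
                con = connectomes[cond]
                per_cond[cond] = pw.mode_node_weights(con, mode)
                try:
                    mode_centralities[(mode, cond)] = pw.mode_centrality(con, mode)
                except ValueError:
                    pass  # mode with no positive-weight edges in this condition
            pooled = pw.scale_mode_direction(per_cond[cond_ctrl], per_cond[cond_dis])
            mode_summaries[mode] = pooled

            # Durbin: scaled directional node weight, blocks = cell type (× direction)
            if durbin_blocks == "type_direction":
                block_keys = ["node", "direction"]
            elif durbin_blocks == "type":
                block_keys = ["node"]
            else:
                raise ValueError("durbin_blocks must be 'type_direction' or 'type'")
            wide = pooled.pivot_table(
                index=block_keys, columns="condition", values="scaled_weight", aggfunc="mean"
            )[list(self.conditions)]
            res = pw.durbin_test(wide)
            durbin_rows.append(
                {
                    "mode": mode,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "method": res.method,
                    "k_blocks": res.k_blocks,
                }
            )
            fc_frames.append(pw.mode_fold_changes(per_cond[cond_ctrl], per_cond[cond_dis]))

        durbin = pd.DataFrame(durbin_rows)
        mode_fc = pd.concat(fc_frames, ignore_index=True) if fc_frames else pd.DataFrame()
        flagged = pw.flag_changed_modes(mode_fc, mode_centralities, fc_threshold=fc_threshold, top_k=top_k)

        diffset = diff.differential_connectome(
            profiles, profiles, self.lr_database,
            condition_ctrl=cond_ctrl, condition_dis=cond_dis, gate=self.gate,
        )
        circos = diff.filter_circos(diffset, min_perturbation=min_perturbation, gate=self.gate)

        return CellCommunicationResults(
            model=self,
            dataset=scaled,
            qc_report=qc_report,
            profiles=profiles,
            connectomes=connectomes,
            centrality=centrality,
            mode_summaries=mode_summaries,
            mode_centralities=mode_centralities,
            durbin=durbin,
            mode_fold_changes=mode_fc,
            flagged_modes=flagged,
            differential=diffset,
            circos=circos,
        )


@dataclass
class CellCommunicationResults:
    """Everything ``CellCommunicationModel.fit`` computes, with reporting helpers."""

    model: CellCommunicationModel
    dataset: ExpressionDataset
    qc_report: dict
    profiles: object
    connectomes: dict[str, Connectome]
    centrality: dict[str, NodeCentrality]
    mode_summaries: dict[str, pd.DataFrame]
    mode_centralities: dict[tuple[str, str], NodeCentrality]
    durbin: pd.DataFrame
    mode_fold_changes: pd.DataFrame
    flagged_modes: pd.DataFrame
    differential: diff.DifferentialEdgeSet
    circos: diff.DifferentialEdgeSet

    # -- convenience ---------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(next(iter(self.connectomes.values())).nodes)

    def top_perturbed_edges(self, n: int = 10) -> pd.DataFrame:
        return (
            self.circos.edges.sort_values("perturbation", ascending=False)
            .head(n)
            .reset_index(drop=True)
        )

    def ranked_mode_fold_changes(self, mode: str, direction: str = "outgoing") -> pd.DataFrame:
        sub = self.mode_fold_changes
        sub = sub[(sub["mode"] == mode) & (sub["direction"] == direction)]
        sub = sub[~(sub["infinite"] | sub["undefined"])]
        return sub.sort_values("fold_change", ascending=False).reset_index(drop=True)

    def summary(self) -> str:
        cond_ctrl, cond_dis = self.model.conditions
        lines = []
        lines.append("Cell-cell communication analysis")
        lines.append("=" * 52)
        lines.append(f"conditions: {cond_ctrl} vs {cond_dis}    gate: >{self.model.gate:.0%} expressing")
        lines.append(
            f"cells: {self.qc_report['n_retained']}/{self.qc_report['n_input']} retained after QC "
            f"(preset {self.qc_report['preset']})"
        )
        for cond, con in self.connectomes.items():
            lines.append(f"connectome[{cond}]: {len(con.edges)} edges over {len(con.nodes)} cell types")
        lines.append("")
        lines.append("Kleinberg centrality (global connectome, max-1 rescaled)")
        for cond, cent in self.centrality.items():
            frame = cent.to_frame().sort_values("hub", ascending=False)
            top = ", ".join(f"{r.node} ({r.hub:.2f})" for r in frame.head(3).itertuples())
            lines.append(f"  top hubs [{cond}]: {top}")
        lines.append("")
        lines.append("Signaling-mode Durbin tests (scaled directional node weights)")
        for row in self.durbin.itertuples(index=False):
            lines.append(
                f"  {row.mode:<14s} T = {row.statistic:6.3f}  df = {row.df}  p = {row.p_value:.4g}"
            )
        if len(self.flagged_modes):
            lines.append("")
            lines.append(f"Flagged mode changes (|log2 fc| > threshold among top-centrality nodes):")
            for row in self.flagged_modes.itertuples(index=False):
                fc = "inf" if not np.isfinite(row.fold_change) else f"{row.fold_change:.2f}"
                lines.append(f"  {row.mode:<14s} {row.node:<14s} {row.direction:<9s} fc = {fc}")
        lines.append("")
        lines.append(
            f"Differential connectome: {len(self.differential)} scored edges, "
            f"{len(self.circos)} pass the circos filter"
        )
        top = self.top_perturbed_edges(3)
        for row in top.itertuples(index=False):
            lines.append(
                f"  {row.source} -> {row.target}  {row.ligand}/{row.receptor}"
                f"  perturbation = {row.perturbation:.3f}"
            )
        return "\n".join(lines)

    # -- exports -------------------------------------------------------------
    def to_directory(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}
        for cond, con in self.connectomes.items():
            p = out / f"connectome_{cond}.csv"
            write_network_outputs(con, p, "csv")
            written[f"connectome_{cond}"] = p
            cent = out / f"centrality_{cond}.csv"
            self.centrality[cond].to_frame().to_csv(cent, index=False)
            written[f"centrality_{cond}"] = cent
        if self.mode_summaries:
            p = out / "mode_summaries.csv"
            pd.concat(self.mode_summaries.values(), ignore_index=True).to_csv(p, index=False)
            written["mode_summaries"] = p
        for name, frame in (
            ("durbin", self.durbin),
            ("mode_fold_changes", self.mode_fold_changes),
            ("flagged_modes", self.flagged_modes),
        ):
            p = out / f"{name}.csv"
            frame.to_csv(p, index=False)
            written[name] = p
        p = out / "differential_edges.csv"
        self.differential.edges.to_csv(p, index=False)
        written["differential_edges"] = p
        p = out / "circos_edges.csv"
        diff.export_circos_table(self.circos, p)
        written["circos_edges"] = p
        p = out / "qc_report.json"
        p.write_text(json.dumps(self.qc_report, indent=1))
        written["qc_report"] = p
        return written

    # -- plotting ------------------------------------------------------------
    def plot_network(self, condition: str, ax=None):
        """Node-level network: edge width ∝ nondirected cumulative weight,
        node size ∝ hub score."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        import networkx as nx

        con = self.connectomes[condition]
        pooled = cumulative_pair_weights(con, directed=False)
        graph = nx.Graph()
        graph.add_nodes_from(con.nodes)
        for row in pooled.itertuples(index=False):
            graph.add_edge(row.node_a, row.node_b, weight=row.weight)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        pos = nx.circular_layout(graph)
        cent = self.centrality[condition]
        sizes = [300 + 1200 * cent.hub_of(n) for n in graph.nodes]
        weights = [graph[u][v]["weight"] for u, v in graph.edges]
        wmax = max(weights) if weights else 1.0
        widths = [0.5 + 4.0 * w / wmax for w in weights]
        nx.draw_networkx(graph, pos=pos, ax=ax, node_size=sizes, width=widths, font_size=8)
        ax.set_title(f"Connectome ({condition})")
        ax.set_axis_off()
        return ax

    def plot_mode_centrality(self, mode: str, ax=None):
        """Dot plot of cumulative mode weights vs hub/authority per condition."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        pooled = self.mode_summaries[mode]
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        markers = {"outgoing": "o", "incoming": "s"}
        for (direction, cond), sub in pooled.groupby(["direction", "condition"], observed=True):
            ax.scatter(
                sub["node"], sub["scaled_weight"],
                marker=markers[direction], label=f"{direction} / {cond}", alpha=0.7,
            )
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_ylabel("scaled cumulative weight")
        ax.set_title(f"{mode} signaling by cell type")
        ax.legend(fontsize=7)
        ax.tick_params(axis="x", rotation=45)
        return ax
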