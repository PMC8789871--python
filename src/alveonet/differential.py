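"""Differential connectome: per-edge log-fold changes and perturbation scores.

For every ligand–receptor edge present in either condition's gated
connectome, the ligand's log2 fold change is computed on the source cell
type's mean normalized expression and the receptor's on the target's; the
perturbation score is the absolute product of the two.  The chord-diagram
("circos") filter keeps edges where both molecules increase in disease, both
are expressed in at least 5 % of their cell types in disease, and the
perturbation score is at least 0.10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ClusterProfileSet, LRDatabase
from .connectome import build_connectome

DIFF_COLUMNS = [
    "source", "target", "ligand", "receptor", "mode",
    "lfc_ligand", "lfc_receptor", "perturbation",
    "pct_ligand_control", "pct_ligand_disease",
    "pct_receptor_control", "pct_receptor_disease",
]


@dataclass
class DifferentialEdgeSet:
    nodes: list[str]
    edges: pd.DataFrame
    condition: str = "disease_vs_control"
    log_base: float = 2.0
    stabilizer: float = 1e-9

    def __len__(self) -> int:
        return len(self.edges)


def differential_connectome(
    profiles_ctrl: ClusterProfileSet,
    profiles_dis: ClusterProfileSet,
    lrdb: LRDatabase,
    condition_ctrl: str = "control",
    condition_dis: str = "disease",
    gate: float = 0.05,
    stabilizer: float = 1e-9,
) -> DifferentialEdgeSet:
    """Score every edge present in either condition's gated connectome.

    ``lfc = log2((mean_norm_dis + δ) / (mean_norm_ctrl + δ))`` with δ a small
    stabilizer (default 1e−9) guarding zero means; perturbation is
    ``|lfc_ligand × lfc_receptor|``.  Edges absent from both gated
    connectomes are not scored.
    """
    ctrl_types = set(profiles_ctrl.for_condition(condition_ctrl)["cell_type"])
    dis_types = set(profiles_dis.for_condition(condition_dis)["cell_type"])
    if ctrl_types != dis_types:
        raise ValueError(
            f"cell-type sets differ between conditions: {sorted(ctrl_types ^ dis_types)}"
        )
    con_ctrl = build_connectome(profiles_ctrl, lrdb, condition_ctrl, gate=gate)
    con_dis = build_connectome(profiles_dis, lrdb, condition_dis, gate=gate)
    nodes = sorted(ctrl_types)

    mean_ctrl = profiles_ctrl.pivot(condition_ctrl, "mean_norm")
    mean_dis = profiles_dis.pivot(condition_dis, "mean_norm")
    pct_ctrl = profiles_ctrl.pivot(condition_ctrl, "pct_expressing")
    pct_dis = profiles_dis.pivot(condition_dis, "pct_expressing")

    key_cols = ["source", "target", "ligand", "receptor", "mode"]
    keys = pd.concat(
        [con_ctrl.edges[key_cols], con_dis.edges[key_cols]], ignore_index=True
    ).drop_duplicates().reset_index(drop=True)

    rows = []
    for source, target, ligand, receptor, mode in keys.itertuples(index=False):
        lc = float(mean_ctrl.at[ligand, source]) if ligand in mean_ctrl.index else 0.0
        ld = float(mean_dis.at[ligand, source]) if ligand in mean_dis.index else 0.0
        rc = float(mean_ctrl.at[receptor, target]) if receptor in mean_ctrl.index else 0.0
        rd = float(mean_dis.at[receptor, target]) if receptor in mean_dis.index else 0.0
        lfc_l = float(np.log2((ld + stabilizer) / (lc + stabilizer)))
        lfc_r = float(np.log2((rd + stabilizer) / (rc + stabilizer)))
        rows.append(
            {
                "source": source, "target": target, "ligand": ligand,
                "receptor": receptor, "mode": mode,
                "lfc_ligand": lfc_l, "lfc_receptor": lfc_r,
                "perturbation": abs(lfc_l * lfc_r),
                "pct_ligand_control": float(pct_ctrl.at[ligand, source]) if ligand in pct_ctrl.index else 0.0,
                "pct_ligand_disease": float(pct_dis.at[ligand, source]) if ligand in pct_dis.index else 0.0,
                "pct_receptor_control": float(pct_ctrl.at[receptor, target]) if receptor in pct_ctrl.index else 0.0,
                "pct_receptor_disease": float(pct_dis.at[receptor, target]) if receptor in pct_dis.index else 0.0,
            }
        )
    edges = pd.DataFrame(rows, columns=DIFF_COLUMNS)
    return DifferentialEdgeSet(nodes=nodes, edges=edges, stabilizer=stabilizer)


def filter_circos(
    diffset: DifferentialEdgeSet,
    min_perturbation: float = 0.10,
    gate: float = 0.05,
    pct_condition: str = "disease",
) -> DifferentialEdgeSet:
    """Apply the chord-diagram filter chain and record per-edge flags.

    Retains edges with (1) both ligand and receptor increased
    (``lfc > 0`` for both), (2) ligand and receptor expressed in at least
    ``gate`` of their cell types in the chosen condition (disease by
    default, ``pct_condition='both'`` requires it in both), and
    (3) ``perturbation >= min_perturbation``.
    """
    edges = diffset.edges.copy()
    both_increased = (edges["lfc_ligand"] > 0) & (edges["lfc_receptor"] > 0)
    if pct_condition == "disease":
        expressed = (edges["pct_ligand_disease"] >= gate) & (edges["pct_receptor_disease"] >= gate)
    elif pct_condition == "both":
        expressed = (
            (edges["pct_ligand_disease"] >= gate) & (edges["pct_receptor_disease"] >= gate)
            & (edges["pct_ligand_control"] >= gate) & (edges["pct_receptor_control"] >= gate)
        )
    else:
        raise ValueError("pct_condition must be 'disease' or 'both'")
    strong = edges["perturbation"] >= min_perturbation
    edges["pass_both_increased"] = both_increased
    edges["pass_pct_gate"] = expressed
    edges["pass_min_perturbation"] = strong
    kept = edges[both_increased & expressed & strong].reset_index(drop=True)
    return DifferentialEdgeSet(
        nodes=list(diffset.nodes), edges=kept, condition=diffset.condition,
        log_base=diffset.log_base, stabilizer=diffset.stabilizer,
    )


def export_circos_table(diffset: DifferentialEdgeSet, path) -> Path:
    """CSV of (source, target, ligand, receptor, perturbation), perturbation
    descending with lexicographic (source, target, ligand) tie-break."""
    path = Path(path)
    table = diffset.edges[["source", "target", "ligand", "receptor", "perturbation"]].copy()
    table = table.sort_values(
        ["perturbation", "source", "target", "ligand"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table.to_csv(path, index=False, float_format="%.17g")
    return path
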