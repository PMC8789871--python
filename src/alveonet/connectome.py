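"""Directed ligand–receptor connectome over cell types + HITS centrality.

An edge source → target exists for an (ligand, receptor) pair when more than
``gate`` (default 5 %) of cells of the source type express the ligand and of
the target type express the receptor.  The edge weight is the product of the
mean expression of ligand (in the source) and receptor (in the target) —
once on the normalized layer (``weight_norm``) and once on the z-scored
layer (``weight_scaled``).  Node importance uses Kleinberg's HITS: hub
scores flag dominant senders, authority scores dominant receivers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ClusterProfileSet, LRDatabase
from .io import EDGE_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class Connectome:
    nodes: list[str]
    edges: pd.DataFrame
    condition: str
    gate: float = 0.05
    n_skipped_pairs: int = 0
    #: modes of the LR database the connectome was built from; a mode may be
    #: known yet have no surviving edges (all its pairs gated out)
    known_modes: list[str] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise ValueError(f"edge table missing column(s): {missing}")
        known = set(self.nodes)
        bad = set(self.edges["source"]) | set(self.edges["target"])
        if bad - known:
            raise ValueError(f"edges reference unknown nodes: {sorted(bad - known)}")

    @property
    def modes(self) -> list[str]:
        return sorted(self.edges["mode"].unique())

    def filter_mode(self, mode: str) -> "Connectome":
        available = sorted(set(self.modes) | set(self.known_modes or []))
        if mode not in available:
            raise ValueError(f"unknown mode {mode!r}; available modes: {available}")
        return Connectome(
            nodes=list(self.nodes),
            edges=self.edges[self.edges["mode"] == mode].reset_index(drop=True),
            condition=self.condition,
            gate=self.gate,
            known_modes=self.known_modes,
        )

    def drop_self_edges(self) -> "Connectome":
        keep = self.edges["source"] != self.edges["target"]
        return Connectome(self.nodes, self.edges[keep].reset_index(drop=True),
                          self.condition, self.gate, known_modes=self.known_modes)


@dataclass
class NodeCentrality:
    """Hub/authority scores rescaled so each vector's maximum is 1."""

    nodes: list[str]
    hub: np.ndarray
    authority: np.ndarray
    iterations: int
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node": self.nodes, "hub": self.hub, "authority": self.authority})

    def hub_of(self, node: str) -> float:
        return float(self.hub[self.nodes.index(node)])

    def authority_of(self, node: str) -> float:
        return float(self.authority[self.nodes.index(node)])


def build_connectome(
    profiles: ClusterProfileSet,
    lrdb: LRDatabase,
    condition: str,
    gate: float = 0.05,
) -> Connectome:
    """Create the gated directed LR connectome for one condition.

    Pairs whose ligand or receptor gene is absent from the profiles are
    skipped with a logged warning (their count is kept on the result) so that
    public LR lists can be used against reduced gene panels.
    """
    sub = profiles.for_condition(condition)
    nodes = sorted(sub["cell_type"].unique())
    mean_norm = profiles.pivot(condition, "mean_norm")
    mean_z = profiles.pivot(condition, "mean_z")
    pct = profiles.pivot(condition, "pct_expressing")
    mean_norm = mean_norm.reindex(columns=nodes)
    mean_z = mean_z.reindex(columns=nodes)
    pct = pct.reindex(columns=nodes)
    genes = set(mean_norm.index)

    rows = []
    n_skipped = 0
    for ligand, receptor, mode in lrdb.pairs:
        if ligand not in genes or receptor not in genes:
            n_skipped += 1
            logger.warning(
                "skipping pair (%s, %s): gene absent from profiles", ligand, receptor
            )
            continue
        lig_pct = pct.loc[ligand].to_numpy()
        rec_pct = pct.loc[receptor].to_numpy()
        lig_norm = mean_norm.loc[ligand].to_numpy()
        rec_norm = mean_norm.loc[receptor].to_numpy()
        lig_z = mean_z.loc[ligand].to_numpy()
        rec_z = mean_z.loc[receptor].to_numpy()
        for i, source in enumerate(nodes):
            if not (lig_pct[i] > gate):
                continue
            for j, target in enumerate(nodes):
                if not (rec_pct[j] > gate):
                    continue
                rows.append(
                    (
                        source, target, ligand, receptor, mode,
                        lig_norm[i] * rec_norm[j],
                        lig_z[i] * rec_z[j],
                        lig_pct[i], rec_pct[j],
                    )
                )
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    if n_skipped:
        logger.warning("skipped %d of %d ligand–receptor pairs", n_skipped, len(lrdb))
    return Connectome(nodes=nodes, edges=edges, condition=condition, gate=gate,
                      n_skipped_pairs=n_skipped, known_modes=sorted(lrdb.modes))


def cumulative_pair_weights(
    connectome: Connectome,
    directed: bool = True,
    weight: str = "weight_norm",
) -> pd.DataFrame:
    """Summed edge weights per node pair (directed or pooled nondirected).

    The nondirected entry {A, B} is directed(A→B) + directed(B→A); this is
    what network plots use for edge thickness.
    """
    edges = connectome.edges
    if edges.empty:
        cols = ["source", "target", "weight"] if directed else ["node_a", "node_b", "weight"]
        return pd.DataFrame(columns=cols)
    grouped = edges.groupby(["source", "target"], observed=True)[weight].sum().reset_index()
    grouped = grouped.rename(columns={weight: "weight"})
    if directed:
        return grouped
    key = grouped.apply(lambda r: tuple(sorted((r["source"], r["target"]))), axis=1)
    pooled = grouped.assign(node_a=[k[0] for k in key], node_b=[k[1] for k in key])
    out = pooled.groupby(["node_a", "node_b"], observed=True)["weight"].sum().reset_index()
    return out


def node_adjacency(connectome: Connectome, weight_kind: str = "norm") -> tuple[np.ndarray, list[str]]:
    """Node-level weighted adjacency W (summed directed edge weights).

    For ``weight_kind='scaled'`` negative products are clipped to 0 first
    (HITS is undefined for mixed-sign weights).
    """
    if weight_kind not in ("norm", "scaled"):
        raise ValueError("weight_kind must be 'norm' or 'scaled'")
    col = "weight_norm" if weight_kind == "norm" else "weight_scaled"
    nodes = list(connectome.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for source, target, w in connectome.edges[["source", "target", col]].itertuples(index=False):
        W[index[source], index[target]] += max(w, 0.0) if weight_kind == "scaled" else w
    return W, nodes


def hits_scores(W: np.ndarray, tol: float = 1e-10, max_iter: int = 1000):
    """HITS power iteration on an adjacency matrix; max-1 rescaled scores.

    Iterates authority ← Wᵀ·hub, hub ← W·authority with 2-norm normalization
    each step.  Returns (hub, authority, iterations, converged).
    """
    n = W.shape[0]
    if not np.any(W > 0):
        raise ValueError("no positive signaling weight: HITS undefined on an all-zero graph")
    if np.any(W < 0):
        raise ValueError("HITS requires non-negative weights")
    hub = np.ones(n) / np.sqrt(n)
    authority = np.ones(n) / np.sqrt(n)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        new_auth = W.T @ hub
        norm = np.linalg.norm(new_auth)
        if norm > 0:
            new_auth /= norm
        new_hub = W @ new_auth
        norm = np.linalg.norm(new_hub)
        if norm > 0:
            new_hub /= norm
        if (np.max(np.abs(new_hub - hub)) < tol and np.max(np.abs(new_auth - authority)) < tol):
            hub, authority = new_hub, new_auth
            converged = True
            break
        hub, authority = new_hub, new_auth
    hub = np.maximum(hub, 0.0)
    authority = np.maximum(authority, 0.0)
    if hub.max() > 0:
        hub = hub / hub.max()
    if authority.max() > 0:
        authority = authority / authority.max()
    return hub, authority, iterations, converged


def hits_centrality(
    connectome: Connectome,
    weight_kind: str = "norm",
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> NodeCentrality:
    """Kleinberg hub/authority centrality of the node-level summed graph."""
    W, nodes = node_adjacency(connectome, weight_kind)
    hub, authority, iterations, converged = hits_scores(W, tol=tol, max_iter=max_iter)
    return NodeCentrality(nodes=nodes, hub=hub, authority=authority,
                          iterations=iterations, converged=converged)
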