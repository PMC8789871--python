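"""Signaling-mode (pathway) statistics.

The connectome is partitioned into pathway subnetworks by the mode label of
each ligand–receptor pair (CXCL, WNT, PDGF, ...).  Per mode this module
computes directional cumulative node weights on *unscaled* (normalized-mean)
edge weights, pools and standardizes them by mode × direction across the two
conditions, computes mode-restricted hub/authority scores, tests
condition differences with the Durbin rank test over blocks, and ranks
per-node fold changes of cumulative edge weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .connectome import Connectome, NodeCentrality, hits_centrality


# -- directional node weights ------------------------------------------------

def mode_node_weights(connectome: Connectome, mode: str) -> pd.DataFrame:
    """Cumulative outgoing/incoming node weights within one signaling mode.

    Uses ``weight_norm`` (unscaled average expression products).  Every node
    of the connectome appears in both directions; nodes without surviving
    mode edges get weight 0.
    """
    sub = connectome.filter_mode(mode)
    rows = []
    for direction, key in (("outgoing", "source"), ("incoming", "target")):
        sums = sub.edges.groupby(key, observed=True)["weight_norm"].sum()
        for node in connectome.nodes:
            rows.append(
                {
                    "mode": mode,
                    "node": node,
                    "direction": direction,
                    "condition": connectome.condition,
                    "cumulative_weight": float(sums.get(node, 0.0)),
                }
            )
    return pd.DataFrame(rows)


def scale_mode_direction(summary_a: pd.DataFrame, summary_b: pd.DataFrame) -> pd.DataFrame:
    """Standardize cumulative weights pooled across the two conditions.

    Within each (mode, direction) the 2 × n_nodes weights are pooled and
    z-scored (sample sd, n−1); zero-variance pools map to all-zero.  The two
    inputs must cover identical node sets.
    """
    nodes_a = set(summary_a["node"])
    nodes_b = set(summary_b["node"])
    if nodes_a != nodes_b:
        raise ValueError(
            f"node sets differ between conditions: {sorted(nodes_a ^ nodes_b)}"
        )
    pooled = pd.concat([summary_a, summary_b], ignore_index=True).copy()

    def _z(values: pd.Series) -> pd.Series:
        sd = values.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return pd.Series(np.zeros(len(values)), index=values.index)
        return (values - values.mean()) / sd

    pooled["scaled_weight"] = (
        pooled.groupby(["mode", "direction"], observed=True)["cumulative_weight"]
        .transform(_z)
    )
    return pooled


def mode_centrality(connectome: Connectome, mode: str, weight_kind: str = "norm") -> NodeCentrality:
    """HITS hub/authority scores on the mode-filtered edge set."""
    return hits_centrality(connectome.filter_mode(mode), weight_kind=weight_kind)


# -- Durbin rank test --------------------------------------------------------

@dataclass(frozen=True)
class DurbinResult:
    statistic: float
    df: int
    p_value: float
    method: str
    k_blocks: int
    t_treatments: int


def _as_block_table(values) -> np.ndarray:
    if isinstance(values, pd.DataFrame):
        arr = values.to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a blocks × treatments table")
    if np.isnan(arr).any():
        raise ValueError(
            "incomplete block design: every block must contain every treatment "
            "exactly once (incomplete designs unsupported)"
        )
    return arr


def _durbin_statistic(arr: np.ndarray) -> float:
    k, t = arr.shape
    ranks = np.apply_along_axis(rankdata, 1, arr)
    col_sums = ranks.sum(axis=0)
    centered = col_sums - k * (t + 1) / 2.0
    return float(12.0 / (k * t * (t + 1)) * np.sum(centered**2))


def durbin_test(
    values,
    method: str = "chi2",
    n_permutations: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> DurbinResult:
    """Durbin rank test on a complete blocks × treatments table.

    Blocks are ranked internally (average ranks for ties) and the statistic
    is the complete-design reduction
    ``T = 12/(k t (t+1)) Σ_j (R_j − k(t+1)/2)²``, equal to the Friedman
    statistic on the same table.  ``method='chi2'`` refers T to a chi-square
    with t−1 df (the omnibus two-sided test); ``method='permutation'``
    enumerates (or samples) within-block treatment-label permutations and
    reports the upper-tail p ``P(T* ≥ T)``.
    """
    arr = _as_block_table(values)
    k, t = arr.shape
    if t < 2 or k < 1:
        raise ValueError("need >= 1 block and >= 2 treatments")
    T = _durbin_statistic(arr)
    df = t - 1
    if method == "chi2":
        p = float(chi2.sf(T, df)) if T > 0 else 1.0
        return DurbinResult(T, df, p, "chi2", k, t)
    if method != "permutation":
        raise ValueError("method must be 'chi2' or 'permutation'")

    perms = list(permutations(range(t)))
    n_exhaustive = len(perms) ** k
    eps = 1e-9
    if n_exhaustive <= n_permutations:
        # full enumeration via mixed-radix counting over per-block permutations
        count = 0
        total = 0
        idx = np.zeros(k, dtype=int)
        base = len(perms)
        for code in range(n_exhaustive):
            c = code
            permuted = np.empty_like(arr)
            for b in range(k):
                permuted[b] = arr[b, list(perms[c % base])]
                c //= base
            if _durbin_statistic(permuted) >= T - eps:
                count += 1
            total += 1
        p = count / total
        return DurbinResult(T, df, float(p), "permutation-exact", k, t)

    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    count = 0
    for _ in range(n_permutations):
        permuted = np.empty_like(arr)
        for b in range(k):
            permuted[b] = gen.permutation(arr[b])
        if _durbin_statistic(permuted) >= T - eps:
            count += 1
    p = count / n_permutations
    return DurbinResult(T, df, float(p), "permutation-mc", k, t)


# -- fold changes and mode flagging ------------------------------------------

def mode_fold_changes(
    summary_ctrl: pd.DataFrame,
    summary_dis: pd.DataFrame,
    mode: str | None = None,
) -> pd.DataFrame:
    """Per (node, direction) fold change of unscaled cumulative weight.

    ``fc = weight(disease) / weight(control)``; control 0 with disease > 0 is
    flagged infinite, both 0 flagged undefined — both excluded from ranked fc
    tables by callers.
    """
    a = summary_dis if mode is None else summary_dis[summary_dis["mode"] == mode]
    b = summary_ctrl if mode is None else summary_ctrl[summary_ctrl["mode"] == mode]
    key = ["mode", "node", "direction"]
    merged = pd.merge(
        a[key + ["cumulative_weight"]].rename(columns={"cumulative_weight": "weight_disease"}),
        b[key + ["cumulative_weight"]].rename(columns={"cumulative_weight": "weight_control"}),
        on=key,
        how="outer",
    ).fillna(0.0)
    dis = merged["weight_disease"].to_numpy()
    ctrl = merged["weight_control"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = dis / ctrl
    fc = np.where((ctrl == 0) & (dis > 0), np.inf, fc)
    fc = np.where((ctrl == 0) & (dis == 0), np.nan, fc)
    merged["fold_change"] = fc
    merged["infinite"] = np.isinf(fc)
    merged["undefined"] = np.isnan(fc)
    return merged


def flag_changed_modes(
    fold_changes: pd.DataFrame,
    centralities: Mapping[tuple[str, str], NodeCentrality],
    fc_threshold: float = 0.3,
    top_k: int = 3,
) -> pd.DataFrame:
    """Flag (mode, node, direction) entries with large edge-weight change.

    For each mode and direction, the candidate set is the union over the two
    conditions of the ``top_k`` nodes by the matching Kleinberg score (hub
    for outgoing, incoming uses authority).  Candidates with
    ``|log2 fc| > fc_threshold`` (including infinite fc) are flagged.

    ``centralities`` maps ``(mode, condition)`` to mode-restricted
    :class:`NodeCentrality` objects.
    """
    flagged = []
    for mode, sub in fold_changes.groupby("mode", observed=True):
        mode_cents = {cond: c for (m, cond), c in centralities.items() if m == mode}
        for direction in ("outgoing", "incoming"):
            score_attr = "hub" if direction == "outgoing" else "authority"
            candidates: set[str] = set()
            for cent in mode_cents.values():
                frame = cent.to_frame().sort_values(score_attr, ascending=False)
                candidates.update(frame["node"].head(top_k))
            dsub = sub[(sub["direction"] == direction) & (sub["node"].isin(candidates))]
            for row in dsub.itertuples(index=False):
                if row.undefined:
                    continue
                log2_fc = np.inf if row.infinite else abs(np.log2(row.fold_change)) if row.fold_change > 0 else np.inf
                if log2_fc > fc_threshold:
                    flagged.append(
                        {
                            "mode": mode,
                            "node": row.node,
                            "direction": direction,
                            "fold_change": row.fold_change,
                            "abs_log2_fc": float(log2_fc),
                        }
                    )
    out = pd.DataFrame(flagged, columns=["mode", "node", "direction", "fold_change", "abs_log2_fc"])
    return out.sort_values(["mode", "direction", "node"]).reset_index(drop=True) if len(out) else out
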