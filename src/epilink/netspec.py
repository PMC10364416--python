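"""Cross-state network similarity, clustering, and activity specificity.

State networks are compared with the extended (weighted) Jaccard similarity
of their ABC edge-weight vectors over a common edge universe; 1 - f gives a
distance for hierarchical clustering.  Activity specificity of an element is
scored with a Shannon-entropy statistic, and elements/EPIs are called
state-specific by a strict majority rule over per-sample activity.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import SampleTable, UsageMatrix
from .reconstruct import StateNetwork


def edge_universe(networks: Mapping[str, StateNetwork]) -> list[tuple[str, str]]:
    """Union of edges over all states, lexicographically ordered."""
    edges = set()
    for net in networks.values():
        edges.update(net.edges)
    return sorted(edges, key=lambda eg: (eg[1], eg[0]))


def edge_weight_vectors(networks: Mapping[str, StateNetwork]) -> pd.DataFrame:
    """States x edges matrix of ABC weights (0 where an edge is absent)."""
    universe = edge_universe(networks)
    index = pd.MultiIndex.from_tuples(universe, names=["enhancer_id", "gene_id"]) \
        if universe else pd.MultiIndex.from_arrays([[], []], names=["enhancer_id", "gene_id"])
    data = {
        state: [networks[state].edges.get(edge, 0.0) for edge in universe]
        for state in sorted(networks)
    }
    return pd.DataFrame(data, index=index).T


def extended_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Extended (Tanimoto) Jaccard similarity f = <a,b> / (|a|^2 + |b|^2 - <a,b>).

    Reduces to the binary Jaccard index for 0/1 vectors.  Undefined when both
    vectors are all zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    dot = float(a @ b)
    denom = float(a @ a) + float(b @ b) - dot
    if denom == 0:
        raise ValueError("undefined similarity: both vectors are all-zero")
    return dot / denom


def _tree_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _tree_to_newick(node.get_left(), labels)
    right = _tree_to_newick(node.get_right(), labels)
    dist = node.dist
    ld = dist - node.get_left().dist
    rd = dist - node.get_right().dist
    return f"({left}:{ld:.6g},{right}:{rd:.6g})"


def cluster_states(
    networks: Mapping[str, StateNetwork], linkage: str = "average"
) -> tuple[pd.DataFrame, np.ndarray, str]:
    """Hierarchically cluster states by 1 - extended Jaccard of their edges.

    Returns the symmetric distance matrix (states x states), the scipy
    linkage matrix, and the merge tree serialized in Newick.  A pair of
    all-zero networks has undefined similarity and is treated as distance 1
    with a warning.
    """
    states = sorted(networks)
    if len(states) < 2:
        raise ValueError("need >= 2 states to cluster")
    vectors = edge_weight_vectors(networks)
    n = len(states)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                f = extended_jaccard(vectors.iloc[i].to_numpy(), vectors.iloc[j].to_numpy())
            except ValueError:
                warnings.warn(
                    f"undefined similarity between {states[i]} and {states[j]}; "
                    "using distance 1"
                )
                f = 0.0
            dist[i, j] = dist[j, i] = 1.0 - f
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    tree = hierarchy.to_tree(Z)
    newick = _tree_to_newick(tree, states) + ";"
    matrix = pd.DataFrame(dist, index=states, columns=states)
    return matrix, Z, newick


def plot_dendrogram(Z: np.ndarray, labels: Sequence[str], ax=None):
    """Render the state dendrogram (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    hierarchy.dendrogram(Z, labels=list(labels), ax=ax)
    ax.set_ylabel("1 - extended Jaccard")
    return ax


def entropy_specificity(y: np.ndarray) -> float:
    """Shannon-entropy specificity of an activity row over m samples.

    S = log2(m) + sum_j p_j log2 p_j with p_j = y_j / sum(y); zero entries
    contribute 0.  S is 0 for perfectly uniform activity and log2(m) for
    activity confined to a single sample.  An all-zero row is undefined
    (returns nan).
    """
    y = np.asarray(y, dtype=float)
    if (y < 0).any():
        raise ValueError("activity must be non-negative")
    total = y.sum()
    if total == 0:
        return float("nan")
    p = y / total
    nz = p > 0
    return float(np.log2(y.size) + np.sum(p[nz] * np.log2(p[nz])))


def specificity_scores(activity) -> pd.Series:
    """Entropy specificity per element of an activity matrix (nan if silent)."""
    return pd.Series(
        {eid: entropy_specificity(activity.row(eid)) for eid in activity.element_ids},
        name="specificity",
    )


def state_specific(
    usage: UsageMatrix | pd.DataFrame, sample_table: SampleTable
) -> dict[str, list[str]]:
    """Elements specific to one state by the strict >50% / <50% rule.

    An element is specific to state s iff it is active in more than half of
    s's samples and in fewer than half of the samples of every other state
    (both inequalities strict).  Any boolean elements x samples frame works,
    so the rule applies to CREs (usage flags) and to EPIs (per-sample active
    flags) alike.  Each element is specific to at most one state.
    """
    data = usage.data if isinstance(usage, UsageMatrix) else usage.astype(bool)
    states = sample_table.states
    fractions = pd.DataFrame(
        {state: data[sample_table.samples_of(state)].mean(axis=1) for state in states}
    )
    out: dict[str, list[str]] = {state: [] for state in states}
    for element, row in fractions.iterrows():
        above = row > 0.5
        if above.sum() == 1 and (row[~above] < 0.5).all():
            out[row.index[above.argmax()]].append(element)
    return out


def epi_activity_frame(records_by_sample) -> pd.DataFrame:
    """Per-sample EPI active flags as a boolean (edge x sample) frame.

    Input is ``EpiResults.records_by_sample``; row index is "enhancer|gene".
    """
    cells: dict[str, dict[str, bool]] = {}
    for sample_id, records in records_by_sample.items():
        for rec in records:
            key = f"{rec.enhancer_id}|{rec.gene_id}"
            cells.setdefault(key, {})[sample_id] = rec.active
    frame = pd.DataFrame(cells).T.sort_index()
    return (frame == True).astype(bool)  # noqa: E712 -- NaN (absent) maps to False
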