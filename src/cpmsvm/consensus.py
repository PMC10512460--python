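"""Consensus edges across CV folds and network-pair count summaries.

Edges selected in at least a stated fraction of cross-validation folds
("consensus edges", conventionally 90%, inclusive) are the stable part
of the predictive signature.  For interpretation they are aggregated by
atlas network: each selected edge increments the count for its pair of
canonical networks, yielding a symmetric network-by-network count
matrix whose diagonal holds within-network edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import Atlas, edge_node_pairs, n_edges_for_nodes
from .cpm import DirectionalFeatureSelection

__all__ = [
    "EdgeMask",
    "NetworkCountMatrix",
    "consensus_edges",
    "network_pair_counts",
    "top_networks",
]


@dataclass
class EdgeMask:
    """A directional set of edges in canonical edge order."""

    selected: np.ndarray
    direction: str

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.direction not in ("increased", "decreased"):
            raise ValueError(
                f"direction must be 'increased' or 'decreased', got {self.direction!r}"
            )

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


def consensus_edges(
    fold_selections: list[DirectionalFeatureSelection],
    direction: str,
    fraction: float = 0.9,
) -> EdgeMask:
    """Edges appearing in >= ``fraction`` of folds' masks for one direction.

    The boundary is inclusive: an edge present in exactly
    ``fraction * n_folds`` folds is selected.  ``fraction = 1.0`` is the
    intersection of the fold masks; any fraction small enough that one
    fold suffices gives their union.
    """
    if not fold_selections:
        raise ValueError("fold_selections is empty")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n_edges = fold_selections[0].n_edges
    counts = np.zeros(n_edges, dtype=np.int64)
    for sel in fold_selections:
        m = sel.mask(direction)
        if m.size != n_edges:
            raise ValueError("fold selections disagree on n_edges")
        counts += m
    # integer threshold avoids float boundary artifacts (0.9 * 100 etc.)
    required = max(1, int(np.ceil(fraction * len(fold_selections) - 1e-9)))
    return EdgeMask(counts >= required, direction)


@dataclass
class NetworkCountMatrix:
    """Symmetric network-pair counts of selected edges."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        L = len(self.labels)
        if self.counts.shape != (L, L):
            raise ValueError("counts shape does not match label count")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")

    @property
    def total_edges(self) -> int:
        """Total selected edges (upper triangle plus diagonal)."""
        return int(np.triu(self.counts).sum())


def network_pair_counts(mask: EdgeMask | np.ndarray, atlas: Atlas) -> NetworkCountMatrix:
    """Count selected edges per (network, network) pair.

    Each selected edge (i, j) increments the symmetric cell for
    (network(i), network(j)); within-network edges land on the diagonal
    and are counted once each.
    """
    selected = mask.selected if isinstance(mask, EdgeMask) else np.asarray(mask, bool)
    expected = n_edges_for_nodes(atlas.n_nodes)
    if selected.size != expected:
        raise ValueError(
            f"mask has {selected.size} edges, atlas with {atlas.n_nodes} nodes "
            f"implies {expected}"
        )
    net = atlas.network_index()
    L = len(atlas.networks)
    iu, ju = edge_node_pairs(atlas.n_nodes)
    a = net[iu[selected]]
    b = net[ju[selected]]
    counts = np.zeros((L, L), dtype=np.int64)
    np.add.at(counts, (np.minimum(a, b), np.maximum(a, b)), 1)
    counts = counts + np.triu(counts, k=1).T
    return NetworkCountMatrix(list(atlas.networks), counts)


def top_networks(
    counts: NetworkCountMatrix, k: int
) -> list[tuple[tuple[str, str], int]]:
    """Network pairs ranked by selected-edge count, descending.

    Ties are broken lexicographically by the (sorted) pair of labels.
    Zero-count pairs are included, so an all-zero matrix ranks every
    pair lexicographically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    entries = []
    L = len(counts.labels)
    for a in range(L):
        for b in range(a, L):
            la, lb = sorted((counts.labels[a], counts.labels[b]))
            entries.append(((la, lb), int(counts.counts[a, b])))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return entries[:k]
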