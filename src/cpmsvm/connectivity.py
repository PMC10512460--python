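"""Fisher-z functional connectivity and the canonical edge-vector layout.

A "node" is an atlas parcel; a "connectivity matrix" holds, for one
subject, the Fisher-z transformed Pearson correlation between the mean
time courses of every node pair.  An "edge" is one node pair, i.e. one
off-diagonal entry of the symmetric matrix.  Everything downstream
(feature selection, masks, consensus edges) works on the canonical
edge vector: the strict upper triangle in row-major order, pairs (i, j)
with i < j and 0-based node indices.  That ordering is a contract:
``vectorize_edges`` / ``devectorize_edges`` define it and every mask in
the package refers to it.

Self-connectivity is excluded by convention: the stored diagonal is
identically 0 (arctanh(1) is undefined and the diagonal carries no
information).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NETWORK_LABELS",
    "Atlas",
    "ConnectivityMatrix",
    "TimeSeriesPanel",
    "compute_fc",
    "devectorize_edges",
    "edge_node_pairs",
    "fisher_z",
    "n_edges_for_nodes",
    "n_nodes_for_edges",
    "vectorize_edges",
]

#: Canonical large-scale network labels, in fixed reporting order:
#: cerebellum, subcortical, salience, visual association, visual A,
#: visual B, motor, default mode, frontoparietal, medial frontal.
NETWORK_LABELS = ("CBL", "SC", "SAL", "VAs", "VI", "VII", "Mot", "DMN", "FP", "MF")

#: Tolerance for accepting a user-supplied matrix as symmetric.
SYMMETRY_TOL = 1e-12


def n_edges_for_nodes(n_nodes: int) -> int:
    """Number of unordered node pairs, n(n-1)/2."""
    if n_nodes < 1:
        raise ValueError(f"n_nodes must be >= 1, got {n_nodes}")
    return n_nodes * (n_nodes - 1) // 2


def n_nodes_for_edges(n_edges: int) -> int:
    """Invert n(n-1)/2; raises if ``n_edges`` is not a triangular number."""
    n = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if n_edges < 0 or n * (n - 1) // 2 != n_edges:
        raise ValueError(f"{n_edges} is not n(n-1)/2 for any integer n")
    return n


def edge_node_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Node index pairs (i, j), i < j, in canonical edge order."""
    return np.triu_indices(n_nodes, k=1)


def fisher_z(r):
    """Fisher r-to-z transform, ``arctanh(r)``.

    Accepts a scalar or array of correlation coefficients with |r| < 1.
    The transform is odd and strictly increasing; it maps r to an
    approximately normal variate, which is why connectivity is stored on
    the z scale.

    Raises
    ------
    ValueError
        If any |r| >= 1 (a degenerate, perfectly correlated or constant
        pair of time courses).
    """
    arr = np.asarray(r, dtype=float)
    bad = np.abs(arr) >= 1.0
    if np.any(bad):
        offending = np.atleast_1d(arr)[np.atleast_1d(bad)][0]
        raise ValueError(
            f"fisher_z requires |r| < 1; got r = {offending!r} "
            "(perfectly correlated or constant signal)"
        )
    out = np.arctanh(arr)
    return out if out.ndim else float(out)


@dataclass
class TimeSeriesPanel:
    """Per-subject node x time signal arrays.

    ``data[s]`` has shape (n_nodes, n_timepoints_s); all subjects must
    share n_nodes, but timepoint counts may differ (scan lengths vary
    after motion scrubbing upstream).
    """

    subject_ids: list[str]
    data: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.subject_ids) != len(self.data):
            raise ValueError("subject_ids and data must have equal length")
        if not self.data:
            raise ValueError("panel is empty")
        self.data = [np.asarray(d, dtype=float) for d in self.data]
        n_nodes = self.data[0].shape[0]
        for sid, d in zip(self.subject_ids, self.data):
            if d.ndim != 2:
                raise ValueError(f"subject {sid}: time series must be 2-D")
            if d.shape[0] != n_nodes:
                raise ValueError(
                    f"subject {sid}: {d.shape[0]} nodes, expected {n_nodes}"
                )
            if d.shape[1] < 3:
                raise ValueError(
                    f"subject {sid}: needs >= 3 timepoints, got {d.shape[1]}"
                )
            if not np.all(np.isfinite(d)):
                raise ValueError(f"subject {sid}: non-finite values in time series")

    @property
    def n_nodes(self) -> int:
        return self.data[0].shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.data)


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity with a zero diagonal."""

    values: np.ndarray
    n_nodes: int = field(default=0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {v.shape}")
        if not self.n_nodes:
            self.n_nodes = v.shape[0]
        if self.n_nodes != v.shape[0]:
            raise ValueError("declared n_nodes does not match matrix shape")
        off = v[~np.eye(self.n_nodes, dtype=bool)]
        if off.size and not np.all(np.isfinite(off)):
            raise ValueError("non-finite off-diagonal connectivity values")
        asym = np.max(np.abs(v - v.T)) if v.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(
                f"matrix asymmetric beyond tolerance ({asym:.3g} > {SYMMETRY_TOL})"
            )
        # symmetrize residual rounding noise, then zero the diagonal
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v


def compute_fc(panel: TimeSeriesPanel) -> list[ConnectivityMatrix]:
    """Pearson-correlate every node pair per subject and Fisher-z transform.

    Time courses are mean-centered per node (implicit in Pearson r); no
    detrending or filtering happens here — those belong to upstream
    preprocessing.

    Raises
    ------
    ValueError
        If any node time course has zero variance (names subject and
        node) or two distinct nodes are perfectly correlated.
    """
    out = []
    for sid, d in zip(panel.subject_ids, panel.data):
        sd = d.std(axis=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise ValueError(
                f"subject {sid}: node {int(dead[0])} has zero-variance time course"
            )
        r = np.corrcoef(d)
        iu, ju = np.triu_indices(panel.n_nodes, k=1)
        hit = np.abs(r[iu, ju]) >= 1.0 - 1e-12
        if np.any(hit):
            k = int(np.flatnonzero(hit)[0])
            raise ValueError(
                f"subject {sid}: nodes {int(iu[k])} and {int(ju[k])} are perfectly "
                "correlated (duplicated signal)"
            )
        z = np.arctanh(np.clip(r, -1.0, 1.0) * (1 - np.eye(panel.n_nodes)))
        z = (z + z.T) / 2.0
        np.fill_diagonal(z, 0.0)
        out.append(ConnectivityMatrix(z))
    return out


def vectorize_edges(m: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Strict upper triangle of a connectivity matrix, canonical order."""
    if not isinstance(m, ConnectivityMatrix):
        m = ConnectivityMatrix(m)
    iu, ju = np.triu_indices(m.n_nodes, k=1)
    return m.values[iu, ju].copy()


def devectorize_edges(v: np.ndarray, n_nodes: int) -> ConnectivityMatrix:
    """Rebuild the symmetric zero-diagonal matrix from a canonical edge vector."""
    v = np.asarray(v, dtype=float).ravel()
    expected = n_edges_for_nodes(n_nodes)
    if v.size != expected:
        raise ValueError(
            f"edge vector has length {v.size}, expected {expected} for "
            f"{n_nodes} nodes"
        )
    m = np.zeros((n_nodes, n_nodes))
    iu, ju = np.triu_indices(n_nodes, k=1)
    m[iu, ju] = v
    m[ju, iu] = v
    return ConnectivityMatrix(m)


@dataclass
class Atlas:
    """Node-to-network assignment.

    ``node_network[i]`` is the network label of node i.  ``networks``
    fixes the reporting order: canonical labels first (in the standard
    order), then any unknown labels in order of first appearance.
    """

    node_network: np.ndarray
    networks: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.node_network = np.asarray(self.node_network, dtype=object)
        if self.node_network.ndim != 1 or self.node_network.size == 0:
            raise ValueError("node_network must be a non-empty 1-D label vector")
        self.node_network = self.node_network.astype(str)
        present = set(self.node_network.tolist())
        if self.networks is None:
            ordered = [l for l in NETWORK_LABELS if l in present]
            seen = set(ordered)
            for l in self.node_network.tolist():
                if l not in seen:
                    ordered.append(l)
                    seen.add(l)
            self.networks = ordered
        else:
            missing = present - set(self.networks)
            if missing:
                raise ValueError(f"labels missing from network order: {sorted(missing)}")

    @property
    def n_nodes(self) -> int:
        return self.node_network.size

    def network_index(self) -> np.ndarray:
        """Per-node integer index into ``networks``."""
        lut = {l: k for k, l in enumerate(self.networks)}
        return np.array([lut[l] for l in self.node_network.tolist()], dtype=int)
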