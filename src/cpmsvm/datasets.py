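"""The subjects-by-edges cohort container consumed by every analysis."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import n_edges_for_nodes, n_nodes_for_edges

__all__ = ["CohortDataset"]


@dataclass
class CohortDataset:
    """A cohort: one row of Fisher-z edge values per subject.

    Labels follow the clinical coding used throughout: patient = 1,
    control = 0.  Both classes must be present with at least two
    subjects each (edge-label correlation needs the degrees of freedom).
    """

    subject_ids: list[str]
    edges: np.ndarray
    labels: np.ndarray
    n_nodes: int = field(default=0)

    def __post_init__(self) -> None:
        self.edges = np.ascontiguousarray(self.edges, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.edges.ndim != 2:
            raise ValueError("edges must be a 2-D (subjects x edges) array")
        n, e = self.edges.shape
        if len(self.subject_ids) != n or self.labels.shape != (n,):
            raise ValueError("subject_ids, edges and labels disagree on n_subjects")
        if not np.all(np.isfinite(self.edges)):
            raise ValueError("non-finite edge values")
        uniq = set(np.unique(self.labels).tolist())
        if not uniq <= {0, 1}:
            raise ValueError(f"labels must be 0 (control) or 1 (patient), got {sorted(uniq)}")
        self.labels = self.labels.astype(np.int64)
        counts = np.bincount(self.labels, minlength=2)
        if counts[0] < 2 or counts[1] < 2:
            raise ValueError(
                f"need >= 2 subjects per class, got {counts[0]} controls / "
                f"{counts[1]} patients"
            )
        if not self.n_nodes:
            self.n_nodes = n_nodes_for_edges(e)
        elif n_edges_for_nodes(self.n_nodes) != e:
            raise ValueError(
                f"{e} edges inconsistent with n_nodes = {self.n_nodes} "
                f"(expected {n_edges_for_nodes(self.n_nodes)})"
            )

    @property
    def n_subjects(self) -> int:
        return self.edges.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(n_controls, n_patients)."""
        c = np.bincount(self.labels, minlength=2)
        return int(c[0]), int(c[1])

    def subset(self, idx: np.ndarray) -> "CohortDataset":
        """Row subset (e.g. a CV fold); validates the result."""
        idx = np.asarray(idx)
        return CohortDataset(
            [self.subject_ids[i] for i in idx],
            self.edges[idx],
            self.labels[idx],
            n_nodes=self.n_nodes,
        )
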