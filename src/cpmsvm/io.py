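"""Reading and writing the on-disk formats: matrices, phenotypes, atlases.

Conventions:

* per-subject connectivity: one square delimited text file per subject,
  named ``<subject id>.csv`` (or ``.txt``/``.tsv``), comma- or
  whitespace-delimited;
* per-subject time series: same naming, rows = nodes, columns =
  timepoints;
* phenotype table: delimited text with header ``subject,label``
  (label 1 = patient, 0 = control); extra covariate columns are carried
  along but ignored by the analyses;
* atlas: two-column table with header ``node,network``, nodes 0..n-1 in
  order.

Matrix files may store raw Pearson r or Fisher-z values; the reader
requires an explicit declaration (``values="r"`` or ``values="z"``) and
transforms raw r on load, since all downstream analysis is on the z
scale.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import Atlas, ConnectivityMatrix, fisher_z, vectorize_edges
from .datasets import CohortDataset

__all__ = [
    "load_atlas",
    "load_cohort",
    "load_matrix",
    "load_phenotype",
    "load_timeseries",
    "save_atlas",
    "save_cohort_matrices",
    "write_edge_list",
    "write_json",
    "write_network_counts",
]

_MATRIX_SUFFIXES = (".csv", ".txt", ".tsv")


def _read_delimited_array(path: Path) -> np.ndarray:
    """Delimited numeric text; sniffs comma vs whitespace."""
    first = path.read_text().lstrip().splitlines()[0] if path.stat().st_size else ""
    delim = "," if "," in first else None
    arr = np.loadtxt(path, delimiter=delim, ndmin=2)
    return arr


def load_matrix(path: str | Path, values: str) -> ConnectivityMatrix:
    """One subject's square connectivity matrix from delimited text."""
    if values not in ("r", "z"):
        raise ValueError("values must be 'r' (raw Pearson) or 'z' (Fisher-z)")
    path = Path(path)
    arr = _read_delimited_array(path)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{path.name}: matrix is {arr.shape}, expected square")
    if values == "r":
        off = ~np.eye(arr.shape[0], dtype=bool)
        z = np.zeros_like(arr)
        z[off] = fisher_z(arr[off])
        arr = z
    return ConnectivityMatrix(arr)


def load_timeseries(path: str | Path) -> np.ndarray:
    """One subject's node x time array from delimited text."""
    return _read_delimited_array(Path(path))


def load_phenotype(path: str | Path) -> pd.DataFrame:
    """Phenotype table with at least ``subject`` and ``label`` columns."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype={"subject": str})
    for col in ("subject", "label"):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    bad = ~df["label"].isin([0, 1])
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(
            f"{path.name}: row {row} (subject {df.loc[row, 'subject']}) has "
            f"label {df.loc[row, 'label']!r}; labels must be 0 or 1"
        )
    return df


def _find_subject_file(matrix_dir: Path, subject: str) -> Path:
    for suffix in _MATRIX_SUFFIXES:
        p = matrix_dir / f"{subject}{suffix}"
        if p.exists():
            return p
    raise FileNotFoundError(
        f"no matrix file for subject {subject!r} in {matrix_dir} "
        f"(tried {', '.join(_MATRIX_SUFFIXES)})"
    )


def load_cohort(
    matrix_dir: str | Path, phenotype_path: str | Path, values: str
) -> CohortDataset:
    """Assemble a cohort from per-subject matrix files and a phenotype table.

    Subjects are ordered as in the phenotype table; every row must have
    a matching matrix file and all matrices must agree on n_nodes.
    """
    matrix_dir = Path(matrix_dir)
    pheno = load_phenotype(phenotype_path)
    rows = []
    n_nodes = None
    for _, rec in pheno.iterrows():
        path = _find_subject_file(matrix_dir, rec["subject"])
        m = load_matrix(path, values)
        if n_nodes is None:
            n_nodes = m.n_nodes
        elif m.n_nodes != n_nodes:
            raise ValueError(
                f"{path.name}: {m.n_nodes} nodes, expected {n_nodes} "
                "(all subjects must share the atlas)"
            )
        rows.append(vectorize_edges(m))
    return CohortDataset(
        pheno["subject"].tolist(),
        np.vstack(rows),
        pheno["label"].to_numpy(),
        n_nodes=n_nodes,
    )


def save_cohort_matrices(
    data: CohortDataset, out_dir: str | Path, fmt: str = "%.10g"
) -> Path:
    """Write per-subject matrix CSVs plus ``phenotype.csv``; returns the dir."""
    from .connectivity import devectorize_edges

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sid, row in zip(data.subject_ids, data.edges):
        m = devectorize_edges(row, data.n_nodes)
        np.savetxt(out_dir / f"{sid}.csv", m.values, delimiter=",", fmt=fmt)
    pd.DataFrame({"subject": data.subject_ids, "label": data.labels}).to_csv(
        out_dir / "phenotype.csv", index=False
    )
    return out_dir


def load_atlas(path: str | Path) -> Atlas:
    """Two-column ``node,network`` table; nodes must be 0..n-1 in order."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("node", "network"):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    nodes = df["node"].to_numpy()
    if not np.array_equal(nodes, np.arange(len(df))):
        raise ValueError(f"{path.name}: node column must be 0..n-1 in order")
    return Atlas(df["network"].astype(str).to_numpy())


def save_atlas(atlas: Atlas, path: str | Path) -> None:
    pd.DataFrame(
        {"node": np.arange(atlas.n_nodes), "network": atlas.node_network}
    ).to_csv(path, index=False)


def write_edge_list(
    mask, fold_fraction: np.ndarray | None, n_nodes: int, path: str | Path
) -> None:
    """Consensus mask as a delimited edge list (node_i, node_j, direction, fraction)."""
    from .connectivity import edge_node_pairs

    iu, ju = edge_node_pairs(n_nodes)
    idx = np.flatnonzero(mask.selected)
    frac = (
        np.asarray(fold_fraction)[idx]
        if fold_fraction is not None
        else np.ones(idx.size)
    )
    pd.DataFrame(
        {
            "node_i": iu[idx],
            "node_j": ju[idx],
            "direction": mask.direction,
            "fold_fraction": frac,
        }
    ).to_csv(path, index=False)


def write_network_counts(counts, path_csv: str | Path) -> None:
    """Labeled CSV for a NetworkCountMatrix."""
    pd.DataFrame(counts.counts, index=counts.labels, columns=counts.labels).to_csv(
        path_csv
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
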