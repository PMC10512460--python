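"""Synthetic cohorts with planted bidirectional connectivity effects.

The generator emulates the statistical structure the analysis assumes
about case-control connectivity studies: per-subject Fisher-z edge
vectors drawn around cohort-level edge baselines, with a sparse set of
edges shifted *down* in patients (hypoconnectivity) and a sparse set
shifted *up* (hyperconnectivity).  A two-site design reproduces the
multi-site asymmetry in which decreased-edge effects are shared across
sites while increased-edge effects are site-specific: both sites plant
the same decreased set, each draws its own increased set with a
configurable overlap, and each site has an independent baseline (a site
effect).

Effects are planted directly in Fisher-z edge space by default — the
analysis consumes z edges, and z-space planting gives exact control of
effect size in units of the subject noise SD.  A slower time-series
route (:func:`generate_timeseries_cohort`) draws multivariate-normal
node signals whose population correlations carry the planted group
differences, exercising the connectivity stage end to end.

Default magnitudes are chosen to look like real resting-state cohorts:
edge baselines around z = 0.25 with SD 0.15 across edges, subject noise
SD 0.2, and planted shifts of one noise SD — a moderate, realistically
detectable case-control effect.  All draws descend from one integer
seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .connectivity import (
    Atlas,
    NETWORK_LABELS,
    devectorize_edges,
    edge_node_pairs,
    n_edges_for_nodes,
    TimeSeriesPanel,
)
from .datasets import CohortDataset

__all__ = [
    "EffectPlan",
    "SiteDesign",
    "generate_cohort",
    "generate_two_sites",
    "generate_timeseries_cohort",
    "make_atlas",
    "sample_effect_plan",
    "edges_within_networks",
]


@dataclass
class EffectPlan:
    """Where and how strongly group effects are planted.

    ``delta`` is the patient-minus-control shift per planted edge in
    Fisher-z units (added on increased edges, subtracted on decreased
    ones); ``noise_sd`` is the subject-level Gaussian SD, so
    ``delta / noise_sd`` is the per-edge effect size d.
    """

    n_nodes: int = 60
    increased_edges: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    decreased_edges: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    delta: float = 0.2
    baseline_mean: float = 0.25
    baseline_sd: float = 0.15
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        self.increased_edges = np.unique(np.asarray(self.increased_edges, dtype=int))
        self.decreased_edges = np.unique(np.asarray(self.decreased_edges, dtype=int))
        E = self.n_edges
        for name, idx in (("increased", self.increased_edges),
                          ("decreased", self.decreased_edges)):
            if idx.size and (idx.min() < 0 or idx.max() >= E):
                raise ValueError(f"{name}_edges out of range for {E} edges")
        if np.intersect1d(self.increased_edges, self.decreased_edges).size:
            raise ValueError("increased and decreased edge sets must be disjoint")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")

    @property
    def n_edges(self) -> int:
        return n_edges_for_nodes(self.n_nodes)


def sample_effect_plan(
    n_nodes: int,
    n_increased: int,
    n_decreased: int,
    seed: int,
    delta: float = 0.2,
    baseline_mean: float = 0.25,
    baseline_sd: float = 0.15,
    noise_sd: float = 0.2,
) -> EffectPlan:
    """Draw disjoint random increased/decreased edge sets."""
    E = n_edges_for_nodes(n_nodes)
    if n_increased + n_decreased > E:
        raise ValueError(
            f"{n_increased}+{n_decreased} planted edges exceed {E} available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(E, size=n_increased + n_decreased, replace=False)
    return EffectPlan(
        n_nodes=n_nodes,
        increased_edges=chosen[:n_increased],
        decreased_edges=chosen[n_increased:],
        delta=delta,
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
        noise_sd=noise_sd,
    )


def edges_within_networks(atlas: Atlas, networks: set[str] | list[str]) -> np.ndarray:
    """Canonical edge indices whose both endpoints lie in ``networks``."""
    networks = set(networks)
    in_net = np.array([l in networks for l in atlas.node_network.tolist()])
    iu, ju = edge_node_pairs(atlas.n_nodes)
    return np.flatnonzero(in_net[iu] & in_net[ju])


def _subject_edges(
    rng: np.random.Generator, plan: EffectPlan, baseline: np.ndarray, n: int,
    patient: bool,
) -> np.ndarray:
    x = baseline + rng.normal(0.0, plan.noise_sd, size=(n, plan.n_edges))
    if patient:
        x[:, plan.increased_edges] += plan.delta
        x[:, plan.decreased_edges] -= plan.delta
    return x


def generate_cohort(
    plan: EffectPlan,
    n_controls: int,
    n_patients: int,
    seed: int,
    id_prefix: str = "",
) -> CohortDataset:
    """One cohort of Fisher-z edge vectors with planted group effects.

    Edge baselines (the control-group means) are drawn once per cohort
    from ``Normal(baseline_mean, baseline_sd)``; each subject adds
    independent ``Normal(0, noise_sd)`` noise per edge, and patients add
    ``+delta`` on increased and ``-delta`` on decreased planted edges.
    Controls come first (label 0), then patients (label 1).
    """
    if n_controls < 2 or n_patients < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    baseline = rng.normal(plan.baseline_mean, plan.baseline_sd, size=plan.n_edges)
    controls = _subject_edges(rng, plan, baseline, n_controls, patient=False)
    patients = _subject_edges(rng, plan, baseline, n_patients, patient=True)
    edges = np.vstack([controls, patients])
    labels = np.concatenate([np.zeros(n_controls, int), np.ones(n_patients, int)])
    ids = [f"{id_prefix}con-{i:03d}" for i in range(n_controls)] + [
        f"{id_prefix}scz-{i:03d}" for i in range(n_patients)
    ]
    return CohortDataset(ids, edges, labels, n_nodes=plan.n_nodes)


@dataclass
class SiteDesign:
    """Two-site study layout.

    The decreased edge set is shared by both sites; each site gets
    ``n_increased_per_site`` increased edges of which a fraction
    ``increased_overlap`` is common to the two sites (0 = fully
    site-specific, 1 = identical increased maps).  ``site_sizes`` is
    ((n_controls, n_patients), ...) per site.  ``site_seeds``, when
    given, pins each site's cohort draw so one site can be regenerated
    without touching the other.
    """

    n_shared_decreased: int = 30
    n_increased_per_site: int = 30
    increased_overlap: float = 0.0
    site_sizes: tuple[tuple[int, int], tuple[int, int]] = ((30, 30), (30, 30))
    site_seeds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.increased_overlap <= 1.0):
            raise ValueError("increased_overlap must be in [0, 1]")
        if self.n_shared_decreased < 0 or self.n_increased_per_site < 0:
            raise ValueError("edge set sizes must be >= 0")


def generate_two_sites(
    design: SiteDesign,
    plan: EffectPlan,
    seed: int,
    return_plans: bool = False,
):
    """Two cohorts sharing decreased effects, with site-specific increases.

    ``plan`` supplies the scale (n_nodes, delta, baselines, noise);
    its own edge sets are ignored in favor of the design's layout.
    Baselines are drawn independently per site (a site effect), so only
    the planted group *differences* — not the raw connectivity values —
    transfer across sites.
    """
    E = plan.n_edges
    n_shared_inc = int(round(design.increased_overlap * design.n_increased_per_site))
    n_specific = design.n_increased_per_site - n_shared_inc
    needed = design.n_shared_decreased + n_shared_inc + 2 * n_specific
    if needed > E:
        raise ValueError(
            f"design needs {needed} distinct edges but only {E} exist"
        )
    ss = np.random.SeedSequence(seed)
    layout_ss, s1_ss, s2_ss = ss.spawn(3)
    rng = np.random.default_rng(layout_ss)
    chosen = rng.choice(E, size=needed, replace=False)
    dec = chosen[: design.n_shared_decreased]
    k = design.n_shared_decreased
    shared_inc = chosen[k : k + n_shared_inc]
    inc1 = np.concatenate([shared_inc, chosen[k + n_shared_inc : k + n_shared_inc + n_specific]])
    inc2 = np.concatenate([shared_inc, chosen[k + n_shared_inc + n_specific : needed]])
    if design.site_seeds is not None:
        seeds = design.site_seeds
    else:
        seeds = (
            int(s1_ss.generate_state(1)[0] % (2**31)),
            int(s2_ss.generate_state(1)[0] % (2**31)),
        )
    sites = []
    plans = []
    for tag, inc, (nc, npat), s in (
        ("s1-", inc1, design.site_sizes[0], seeds[0]),
        ("s2-", inc2, design.site_sizes[1], seeds[1]),
    ):
        site_plan = replace(plan, increased_edges=inc, decreased_edges=dec)
        plans.append(site_plan)
        sites.append(generate_cohort(site_plan, nc, npat, s, id_prefix=tag))
    if return_plans:
        return sites[0], sites[1], plans[0], plans[1]
    return sites[0], sites[1]


def _nearest_correlation(R: np.ndarray, eig_floor: float = 1e-4) -> np.ndarray:
    """Clip eigenvalues at a positive floor and renormalize to unit diagonal."""
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    w = np.maximum(w, eig_floor)
    R2 = (V * w) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return R2


def generate_timeseries_cohort(
    plan: EffectPlan,
    n_controls: int,
    n_patients: int,
    n_timepoints: int,
    seed: int,
    repair_tol: float = 0.5,
) -> tuple[TimeSeriesPanel, np.ndarray]:
    """Node time series whose population correlations carry the planted effects.

    Per subject, a target Fisher-z edge vector is drawn exactly as in
    :func:`generate_cohort`, mapped through tanh to correlations,
    projected to the nearest valid correlation matrix (eigenvalue
    clipping + renormalization), and used as the covariance of
    ``n_timepoints`` i.i.d. multivariate-normal samples.  Computing
    connectivity on the output recovers the planted group differences as
    ``n_timepoints`` grows.

    Raises
    ------
    ValueError
        If the projection moves some correlation by more than
        ``repair_tol`` (the target was too far from a valid correlation
        structure to be meaningfully repaired).
    """
    if n_controls < 2 or n_patients < 2:
        raise ValueError("need at least 2 subjects per group")
    if n_timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    baseline = rng.normal(plan.baseline_mean, plan.baseline_sd, size=plan.n_edges)
    labels = np.concatenate([np.zeros(n_controls, int), np.ones(n_patients, int)])
    ids = [f"con-{i:03d}" for i in range(n_controls)] + [
        f"scz-{i:03d}" for i in range(n_patients)
    ]
    data = []
    for lab in labels:
        z = baseline + rng.normal(0.0, plan.noise_sd, size=plan.n_edges)
        if lab == 1:
            z[plan.increased_edges] += plan.delta
            z[plan.decreased_edges] -= plan.delta
        R = np.tanh(devectorize_edges(z, plan.n_nodes).values)
        np.fill_diagonal(R, 1.0)
        R_ok = _nearest_correlation(R)
        dev = np.max(np.abs(R_ok - R))
        if dev > repair_tol:
            raise ValueError(
                f"target correlation matrix not repairable within tolerance "
                f"(max deviation {dev:.3f} > {repair_tol})"
            )
        L = np.linalg.cholesky(R_ok + 1e-12 * np.eye(plan.n_nodes))
        ts = L @ rng.standard_normal((plan.n_nodes, n_timepoints))
        data.append(ts)
    return TimeSeriesPanel(ids, data), labels


def make_atlas(
    n_nodes: int,
    network_sizes: list[int] | None = None,
    labels: list[str] | None = None,
) -> Atlas:
    """Contiguous block assignment of nodes to canonical networks.

    Defaults emulate a 10-network parcellation: nodes are split into 10
    near-equal contiguous blocks labeled in the canonical order.
    """
    if labels is None:
        if network_sizes is not None and len(network_sizes) != len(NETWORK_LABELS):
            labels = [f"N{i}" for i in range(len(network_sizes))]
        else:
            labels = list(NETWORK_LABELS)
    if network_sizes is None:
        base = n_nodes // len(labels)
        rem = n_nodes % len(labels)
        network_sizes = [base + (1 if i < rem else 0) for i in range(len(labels))]
    if len(network_sizes) != len(labels):
        raise ValueError("network_sizes and labels must have equal length")
    if sum(network_sizes) != n_nodes:
        raise ValueError(
            f"network sizes sum to {sum(network_sizes)}, expected {n_nodes}"
        )
    node_network = []
    for lab, size in zip(labels, network_sizes):
        node_network.extend([lab] * size)
    return Atlas(np.asarray(node_network, dtype=object), networks=list(labels))
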