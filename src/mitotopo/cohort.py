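"""Synthetic subject-labelled MIN cohorts.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage of the pipeline can be exercised without the
(hundreds of GB) raw image data:

* per subject, thousands-scale collections of small connected components
  whose size distribution decays geometrically, P(s) ~ k^s, with a
  group-dependent base k (the disease group forms larger components, i.e.
  larger k);
* a triangle-closure propensity steering transitivity and the
  triangle-motif census;
* a chain bias steering ASPL/diameter upward and efficiency downward
  (path-like wiring) — the directionality reported for disease vs control.

The wiring model is generative scaffolding of this package (the measured
metrics, not the construction, are the object of study): a spanning tree
built by sequential attachment — each new node attaches to the previous
node with probability ``chain_bias`` (path-like), otherwise to a uniformly
random earlier node — followed by extra links, each closing a random open
triad with probability ``triangle_propensity`` and otherwise joining a
random non-adjacent pair.  Link weights are uniform integers in [2, 20];
they never affect topology metrics, only I/O round-trips.

Default group parameters are calibrated to the *direction* of the reported
disease/control contrasts, not their magnitudes (no per-group effect sizes
are published): group A (PD-like) has heavier size tails, more triangle
closure and more chain-like wiring than group B (control-like).  Disease
subjects carry a severity scalar that modulates their parameters around the
group values and generates a correlated synthetic UPDRS clinical score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from mitotopo.errors import InvalidParameterError
from mitotopo.network import MitoNetwork

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "SyntheticCohort",
    "sample_component_sizes",
    "generate_component",
    "generate_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of one synthetic cohort.

    Defaults mirror a realistic clinical-cohort scale (11 disease vs 10
    control subjects) at
    a desk-scale number of components per subject, with group contrasts in
    the reported directions.
    """

    n_group_a: int = 11  # PD-like
    n_group_b: int = 10  # control-like
    components_per_subject: int = 200
    size_slope_a: float = 0.75
    size_slope_b: float = 0.65
    min_size: int = 2
    max_size: int = 30
    triangle_propensity_a: float = 0.6
    triangle_propensity_b: float = 0.3
    chain_bias_a: float = 0.7
    chain_bias_b: float = 0.35
    extra_link_rate: float = 0.3  # expected extra links per node
    seed: int = 0

    def __post_init__(self):
        for name in ("n_group_a", "n_group_b", "components_per_subject"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be positive")
        for name in ("size_slope_a", "size_slope_b"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise InvalidParameterError(
                    f"{name} must lie strictly inside (0, 1)"
                )
        for name in (
            "triangle_propensity_a",
            "triangle_propensity_b",
            "chain_bias_a",
            "chain_bias_b",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        if self.min_size < 2:
            raise InvalidParameterError("min_size must be >= 2")
        if self.min_size > self.max_size:
            raise InvalidParameterError("min_size must be <= max_size")
        if self.extra_link_rate < 0:
            raise InvalidParameterError("extra_link_rate must be >= 0")


@dataclass
class SubjectRecord:
    """One subject: the unit of cross-validation."""

    subject_id: str
    group: str  # "PD" or "control"
    side: str = "NA"
    updrs: float | None = None
    networks: list[MitoNetwork] = field(default_factory=list)

    def components(self) -> list[nx.Graph]:
        from mitotopo.metrics import extract_components

        out = []
        for net in self.networks:
            out.extend(extract_components(net.graph))
        return out


@dataclass
class SyntheticCohort:
    subjects: list[SubjectRecord]
    provenance: CohortSpec

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]


def sample_component_sizes(
    slope_k: float,
    n: int,
    min_size: int,
    max_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n component sizes from p(s) proportional to k^s on [min, max].

    The truncated geometric-family distribution is sampled exactly (discrete
    support; no continuous approximation).
    """
    if not 0.0 < slope_k < 1.0:
        raise InvalidParameterError("slope_k must lie strictly inside (0, 1)")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if min_size > max_size:
        raise InvalidParameterError("min_size must be <= max_size")
    support = np.arange(min_size, max_size + 1)
    logp = support * np.log(slope_k)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return rng.choice(support, size=n, p=p)


def generate_component(
    size: int,
    triangle_propensity: float,
    chain_bias: float,
    rng: np.random.Generator,
    n_extra: int | None = None,
    extra_link_rate: float = 0.3,
    weight_range: tuple[int, int] = (2, 20),
) -> nx.Graph:
    """One connected component with tunable wiring.

    Spanning tree by sequential attachment (previous node with probability
    ``chain_bias``, else uniform earlier node: chain_bias=1 gives a path,
    0 gives a random recursive tree), then ``n_extra`` extra links (default
    Binomial(size, extra_link_rate)), each closing a random open triad with
    probability ``triangle_propensity``, else joining a random non-adjacent
    pair.  Edge attribute ``weight`` holds a uniform integer voxel-count
    stand-in.
    """
    if size < 2:
        raise InvalidParameterError("components need at least 2 nodes")
    if not 0.0 <= triangle_propensity <= 1.0:
        raise InvalidParameterError("triangle_propensity must lie in [0, 1]")
    if not 0.0 <= chain_bias <= 1.0:
        raise InvalidParameterError("chain_bias must lie in [0, 1]")
    g = nx.Graph()
    g.add_nodes_from(range(size))
    for i in range(1, size):
        if i == 1 or rng.random() < chain_bias:
            parent = i - 1
        else:
            parent = int(rng.integers(0, i))
        g.add_edge(parent, i)
    if n_extra is None:
        n_extra = int(rng.binomial(size, extra_link_rate))
    max_edges = size * (size - 1) // 2
    for _ in range(n_extra):
        if g.number_of_edges() >= max_edges:
            break
        edge = None
        if rng.random() < triangle_propensity:
            edge = _random_open_triad(g, rng)
        if edge is None:
            edge = _random_nonadjacent_pair(g, rng)
        if edge is not None:
            g.add_edge(*edge)
    lo, hi = weight_range
    for u, v in g.edges():
        g[u][v]["weight"] = int(rng.integers(lo, hi + 1))
    return g


def _random_open_triad(g: nx.Graph, rng) -> tuple[int, int] | None:
    """A non-adjacent pair sharing a neighbor (closing it makes a triangle)."""
    centers = [v for v in g.nodes() if g.degree(v) >= 2]
    if not centers:
        return None
    for _ in range(20):
        c = centers[int(rng.integers(0, len(centers)))]
        nbrs = list(g.neighbors(c))
        i, j = rng.choice(len(nbrs), size=2, replace=False)
        u, v = nbrs[int(i)], nbrs[int(j)]
        if not g.has_edge(u, v):
            return u, v
    return None


def _random_nonadjacent_pair(g: nx.Graph, rng) -> tuple[int, int] | None:
    n = g.number_of_nodes()
    for _ in range(50):
        u, v = rng.integers(0, n, size=2)
        if u != v and not g.has_edge(int(u), int(v)):
            return int(u), int(v)
    return None


def _subject_params(
    spec: CohortSpec, group: str, severity: float
) -> tuple[float, float, float]:
    """(size_slope, triangle_propensity, chain_bias) for one subject.

    Disease subjects deviate from the control-group values by
    severity x (group A - group B); severity 1 reproduces the group-A
    values exactly, so the group mean matches the spec.
    """
    if group == "control":
        return (
            spec.size_slope_b,
            spec.triangle_propensity_b,
            spec.chain_bias_b,
        )
    slope = spec.size_slope_b + severity * (
        spec.size_slope_a - spec.size_slope_b
    )
    tri = spec.triangle_propensity_b + severity * (
        spec.triangle_propensity_a - spec.triangle_propensity_b
    )
    chain = spec.chain_bias_b + severity * (
        spec.chain_bias_a - spec.chain_bias_b
    )
    eps = 1e-6
    return (
        float(np.clip(slope, eps, 1 - eps)),
        float(np.clip(tri, 0.0, 1.0)),
        float(np.clip(chain, 0.0, 1.0)),
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Deterministic synthetic cohort from (spec, spec.seed).

    Each subject holds two networks (left and right side), splitting the
    subject's components between them.  Disease-group subjects get a
    severity scalar ~ U(0.7, 1.3) (mean 1, hence group-mean parameters equal
    the spec values) and a synthetic UPDRS score increasing with severity;
    control subjects have no UPDRS.
    """
    rng = np.random.default_rng(spec.seed)
    subjects: list[SubjectRecord] = []
    plan = [("PD", i) for i in range(spec.n_group_a)] + [
        ("control", i) for i in range(spec.n_group_b)
    ]
    for group, idx in plan:
        sid = f"{'P' if group == 'PD' else 'C'}{idx:02d}"
        if group == "PD":
            severity = float(rng.uniform(0.7, 1.3))
            updrs = float(
                np.clip(15.0 + 35.0 * severity + rng.normal(0.0, 2.0), 0, 108)
            )
        else:
            severity = 0.0
            updrs = None
        slope, tri, chain = _subject_params(spec, group, severity)
        sizes = sample_component_sizes(
            slope, spec.components_per_subject, spec.min_size, spec.max_size,
            rng,
        )
        halves = np.array_split(np.arange(spec.components_per_subject), 2)
        networks = []
        for side, part in zip(("left", "right"), halves):
            union = nx.Graph()
            offset = 0
            for ci in part:
                comp = generate_component(
                    int(sizes[ci]), tri, chain, rng,
                    extra_link_rate=spec.extra_link_rate,
                )
                union.add_nodes_from(
                    (offset + v for v in comp.nodes())
                )
                union.add_edges_from(
                    (offset + u, offset + v, d)
                    for u, v, d in comp.edges(data=True)
                )
                offset += comp.number_of_nodes()
            networks.append(
                MitoNetwork(
                    graph=union,
                    subject_id=sid,
                    side=side,
                    network_id=f"{sid}_{side}",
                )
            )
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=group,
                side="NA",
                updrs=updrs,
                networks=networks,
            )
        )
    return SyntheticCohort(subjects=subjects, provenance=spec)
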