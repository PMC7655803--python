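"""Per-component topology metrics for mitochondria interaction networks.

A *component* is one maximal connected subgraph of a MIN — a set of locally
interacting mitochondria — and is the unit on which every metric here is
evaluated.  All metrics are topological: a link exists wherever the adjacency
weight is positive, and voxel-count weights are ignored (they matter only for
I/O fidelity).

Metrics that are undefined for a given component (pairwise metrics on a
single node, assortativity on a regular graph) are returned as ``None``
rather than raised: the analysis keeps size-1 components for size statistics
while excluding them from metric distributions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from mitotopo.errors import InvalidParameterError

__all__ = [
    "MetricVector",
    "extract_components",
    "normalized_degree",
    "link_density",
    "max_degree",
    "shortest_path_stats",
    "aspl",
    "diameter",
    "efficiency",
    "modularity_louvain",
    "assortativity",
    "transitivity",
    "information_content",
    "small_worldness",
    "compute_metrics",
    "global_metric_distribution",
    "METRIC_NAMES",
]

#: metrics produced by :func:`compute_metrics`, in output order
METRIC_NAMES = (
    "link_density",
    "max_degree",
    "aspl",
    "diameter",
    "efficiency",
    "modularity",
    "assortativity",
    "transitivity",
    "information_content",
)


@dataclass
class MetricVector:
    """Metric battery of one connected component.

    ``None`` marks an undefined metric (excluded from downstream
    distributions), never an error.
    """

    size: int
    links: int
    normalized_degrees: list[float] = field(default_factory=list)
    link_density: float | None = None
    max_degree: int | None = None
    aspl: float | None = None
    diameter: int | None = None
    efficiency: float | None = None
    modularity: float | None = None
    assortativity: float | None = None
    transitivity: float | None = None
    information_content: float | None = None
    small_worldness: float | None = None

    def as_dict(self) -> dict:
        d = {"size": self.size, "links": self.links}
        for name in METRIC_NAMES:
            d[name] = getattr(self, name)
        d["small_worldness"] = self.small_worldness
        return d


def extract_components(graph: nx.Graph) -> list[nx.Graph]:
    """Dissect a possibly disconnected MIN into connected components.

    Returns subgraph copies sorted by descending size, ties broken by the
    smallest node id contained.
    """
    comps = [graph.subgraph(c).copy() for c in nx.connected_components(graph)]
    comps.sort(key=lambda g: (-g.number_of_nodes(), min(g.nodes())))
    return comps


def normalized_degree(component: nx.Graph) -> list[float]:
    """k* = k/N per node (ordered by node id), N the component size."""
    n = component.number_of_nodes()
    return [component.degree(v) / n for v in sorted(component.nodes())]


def link_density(component: nx.Graph) -> float | None:
    """Fraction of possible links present: 2l / (N(N-1)); None for N < 2."""
    n = component.number_of_nodes()
    if n < 2:
        return None
    return 2.0 * component.number_of_edges() / (n * (n - 1))


def max_degree(component: nx.Graph) -> int | None:
    """Degree of the most connected node; None for N < 2."""
    if component.number_of_nodes() < 2:
        return None
    return max(d for _, d in component.degree())


def shortest_path_stats(component: nx.Graph) -> tuple[float, int, float]:
    """ASPL, diameter and efficiency from one all-pairs BFS sweep.

    Distances are topological (hop counts).  Raises ``InvalidParameterError``
    on a disconnected input: geodesic metrics are meaningful only per
    component.
    """
    n = component.number_of_nodes()
    if n < 2:
        raise InvalidParameterError("pairwise metrics need at least 2 nodes")
    total = 0.0
    inv_total = 0.0
    diam = 0
    npairs = n * (n - 1)  # ordered pairs
    reached = 0
    for _, dists in nx.all_pairs_shortest_path_length(component):
        for d in dists.values():
            if d == 0:
                continue
            reached += 1
            total += d
            inv_total += 1.0 / d
            if d > diam:
                diam = d
    if reached != npairs:
        raise InvalidParameterError("component is not connected")
    return total / npairs, diam, inv_total / npairs


def aspl(component: nx.Graph) -> float:
    """Average shortest path length over ordered node pairs."""
    return shortest_path_stats(component)[0]


def diameter(component: nx.Graph) -> int:
    """Greatest shortest-path length between any pair of nodes."""
    return shortest_path_stats(component)[1]


def efficiency(component: nx.Graph) -> float:
    """Harmonic mean of geodesic distances: mean of 1/d over ordered pairs."""
    return shortest_path_stats(component)[2]


def modularity_louvain(
    component: nx.Graph, seed: int = 0
) -> tuple[list[set], float]:
    """Louvain community partition and its Newman–Girvan modularity Q.

    Runs igraph's multilevel (Louvain) algorithm on a canonicalized node
    ordering with a seeded RNG, so the result is reproducible for a given
    labeled graph.  (networkx's Louvain can oscillate without terminating
    on some small dense graphs, so it is not used here.)
    """
    import random as _random

    import igraph

    if component.number_of_edges() == 0:
        raise InvalidParameterError("modularity needs at least one link")
    nodes = sorted(component.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    edges = sorted(
        (index[u], index[v]) if index[u] < index[v] else (index[v], index[u])
        for u, v in component.edges()
    )
    ig = igraph.Graph(n=len(nodes), edges=edges)
    igraph.set_random_number_generator(_random.Random(seed))
    clustering = ig.community_multilevel()
    igraph.set_random_number_generator(_random)
    parts = [
        {nodes[i] for i in cluster} for cluster in clustering
    ]
    q = nx.community.modularity(component, parts, weight=None)
    return parts, q


def assortativity(component: nx.Graph) -> float | None:
    """Pearson correlation between the degrees of the two endpoints of links.

    Each undirected link contributes both orientations.  Returns ``None``
    (undefined) when either endpoint-degree margin has zero variance — e.g.
    on regular graphs, where the correlation is 0/0.
    """
    if component.number_of_edges() == 0:
        return None
    deg = dict(component.degree())
    x, y = [], []
    for u, v in component.edges():
        x.extend((deg[u], deg[v]))
        y.extend((deg[v], deg[u]))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(r)


def transitivity(component: nx.Graph) -> float:
    """Density of triangles: 3 x triangles / connected triples (0 if none)."""
    return float(nx.transitivity(component))


def information_content(component: nx.Graph) -> float:
    """Bits lost under iterative pairwise node merging (mesoscale regularity).

    Greedy procedure on the binary adjacency matrix: at each of the N-1
    steps, merge the node pair whose rows disagree in the fewest positions
    (each disagreement costs one bit to encode; the entries within the pair
    are excluded), ties broken by the lowest original node-id pair; merged
    rows are combined by union.  The score is the total number of bits
    accumulated.  Regular structures (e.g. complete graphs) yield 0; the
    more irregular the mesoscale structure, the higher the score.
    """
    nodes = sorted(component.nodes())
    n = len(nodes)
    if n < 2:
        return 0.0
    a = nx.to_numpy_array(component, nodelist=nodes, weight=None).astype(bool)
    labels = list(range(n))  # minimal original index in each merged group
    total = 0.0
    while a.shape[0] > 1:
        m = a.shape[0]
        diff = (a[:, None, :] != a[None, :, :]).sum(axis=2)
        # entries between the pair itself do not count as disagreements
        diff = diff - 2 * a.astype(int)
        iu = np.triu_indices(m, k=1)
        costs = diff[iu]
        # tie-break on the lowest original node-id pair
        order = sorted(
            range(len(costs)),
            key=lambda t: (costs[t], labels[iu[0][t]], labels[iu[1][t]]),
        )
        best = order[0]
        i, j = int(iu[0][best]), int(iu[1][best])
        total += float(costs[best])
        a[i] = a[i] | a[j]
        a[:, i] = a[:, i] | a[:, j]
        a[i, i] = False
        keep = [t for t in range(m) if t != j]
        a = a[np.ix_(keep, keep)]
        labels[i] = min(labels[i], labels[j])
        del labels[j]
    return total


def small_worldness(
    component: nx.Graph, null_summary: "object"
) -> float | None:
    """S-W = (T/<T_rand>) / (ASPL/<ASPL_rand>) against the component's null.

    ``null_summary`` is a :class:`mitotopo.nullmodel.NullEnsemble` (or any
    object with ``n``, ``l`` and a ``mean(metric)`` method) built for this
    component.  Returns ``None`` when the null mean transitivity is zero.
    """
    n = component.number_of_nodes()
    l = component.number_of_edges()
    if (null_summary.n, null_summary.l) != (n, l):
        raise InvalidParameterError(
            f"null ensemble ({null_summary.n},{null_summary.l}) does not "
            f"match component ({n},{l})"
        )
    t_rand = null_summary.mean("transitivity")
    a_rand = null_summary.mean("aspl")
    if t_rand is None or a_rand is None or t_rand == 0 or a_rand == 0:
        return None
    t = transitivity(component)
    a = aspl(component)
    return (t / t_rand) / (a / a_rand)


def compute_metrics(component: nx.Graph, seed: int = 0) -> MetricVector:
    """Full metric battery for one connected component.

    Size-1 components get size/links only; size-2 components get the
    pairwise metrics but a vacuous transitivity of 0.
    """
    n = component.number_of_nodes()
    l = component.number_of_edges()
    mv = MetricVector(size=n, links=l)
    mv.normalized_degrees = normalized_degree(component)
    if n < 2:
        return mv
    mv.link_density = link_density(component)
    mv.max_degree = max_degree(component)
    mv.aspl, mv.diameter, mv.efficiency = shortest_path_stats(component)
    _, mv.modularity = modularity_louvain(component, seed=seed)
    mv.assortativity = assortativity(component)
    mv.transitivity = transitivity(component)
    mv.information_content = information_content(component)
    return mv


def global_metric_distribution(
    values: Iterable[tuple[int, float | None]],
    size_filter: tuple[int, int] | None = None,
) -> list[float]:
    """Pool per-component metric values across a subject or group.

    Parameters
    ----------
    values
        ``(size, value)`` pairs, one per component; ``None``/NaN values
        (undefined metrics) are dropped.
    size_filter
        Optional inclusive ``(min_size, max_size)`` bounds applied before
        pooling.
    """
    if size_filter is not None:
        lo, hi = size_filter
        if lo > hi:
            raise InvalidParameterError(
                f"inverted size filter bounds ({lo}, {hi})"
            )
    out = []
    for size, value in values:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        if size_filter is not None and not (lo <= size <= hi):
            continue
        out.append(float(value))
    return out
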