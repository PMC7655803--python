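"""Connected-random-graph null model and Z-score normalization.

Every component is normalized against an ensemble of (by default) 100
random graphs with exactly the same number of nodes n and links l, each kept
only if it forms a single connected component — the biologically plausible
null of "same amount of material, random wiring".  The null is G(n, l)
conditioned on connectivity (uniform over connected labeled graphs with l
links); degree sequences are *not* preserved, which matters for Z-score
magnitudes and is therefore stated here prominently.

Sampling is by rejection (uniform G(n, l) draws until connected, capped at
10^4 attempts); for sparse large graphs where connectivity is too rare the
sampler falls back to a spanning-tree-plus-random-extra-links construction,
which is biased toward tree-like graphs, and emits a warning.

Observed metric M is normalized as Z = (M - mu(M_R)) / sigma(M_R) with
mu, sigma the ensemble mean and SD.  A zero ensemble SD yields an explicit
"undefined" record (dropped from downstream distributions), never +-inf.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from mitotopo import metrics as _metrics
from mitotopo import motifs as _motifs
from mitotopo.errors import InvalidParameterError

__all__ = [
    "NullEnsemble",
    "ZScoreRecord",
    "NullCache",
    "random_connected_graph",
    "build_null",
    "zscore",
    "zscore_probability",
    "default_bin_edges",
]

#: per-graph metrics summarized in a null ensemble
NULL_METRIC_NAMES = (
    "max_degree",
    "aspl",
    "diameter",
    "efficiency",
    "modularity",
    "assortativity",
    "transitivity",
    "information_content",
)

_REJECTION_CAP = 10_000


def _random_prufer_tree(n: int, rng: np.random.Generator) -> nx.Graph:
    """Uniform random labeled tree on n nodes (Prüfer decode)."""
    if n == 1:
        g = nx.Graph()
        g.add_node(0)
        return g
    if n == 2:
        g = nx.Graph()
        g.add_edge(0, 1)
        return g
    seq = rng.integers(0, n, size=n - 2)
    return nx.from_prufer_sequence(list(int(x) for x in seq))


def _connected(n: int, edges) -> bool:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merged = 0
    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            merged += 1
    return merged == n - 1


def random_connected_graph(
    n: int, l: int, rng: np.random.Generator, cap: int = _REJECTION_CAP
) -> nx.Graph:
    """One draw from G(n, l) conditioned on connectivity.

    Nodes are labeled 0..n-1.  Raises ``InvalidParameterError`` unless
    2 <= n and n-1 <= l <= n(n-1)/2.  For l = n-1 the conditional law is
    exactly the uniform distribution over labeled trees, which Prüfer
    sampling draws directly (no rejection needed, no bias).
    """
    if n < 2:
        raise InvalidParameterError("null graphs need n >= 2")
    max_l = n * (n - 1) // 2
    if not (n - 1 <= l <= max_l):
        raise InvalidParameterError(
            f"link count {l} outside [{n - 1}, {max_l}] for n={n}"
        )
    if l == n - 1:
        return _random_prufer_tree(n, rng)
    g, _ = _rejection_draw(n, l, rng, cap)
    if g is not None:
        return g
    warnings.warn(
        f"rejection cap hit for (n={n}, l={l}); falling back to the biased "
        "spanning-tree-plus-extra-links sampler",
        RuntimeWarning,
        stacklevel=2,
    )
    return _tree_plus_links(n, l, rng)


def _rejection_draw(n, l, rng, cap):
    """Up to ``cap`` uniform G(n, l) draws; (graph or None, tries used)."""
    pairs = list(itertools.combinations(range(n), 2))
    for tries in range(1, cap + 1):
        idx = rng.choice(len(pairs), size=l, replace=False)
        edges = [pairs[i] for i in idx]
        if _connected(n, edges):
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from(edges)
            return g, tries
    return None, cap


def _tree_plus_links(n, l, rng):
    """Biased constructive fallback: uniform tree + uniform extra links."""
    tree = _random_prufer_tree(n, rng)
    present = {tuple(sorted(e)) for e in tree.edges()}
    free = [
        p for p in itertools.combinations(range(n), 2) if p not in present
    ]
    extra = rng.choice(len(free), size=l - (n - 1), replace=False)
    tree.add_edges_from(free[i] for i in extra)
    return tree


@dataclass
class NullEnsemble:
    """100-network null for one (n, l) class, with per-metric summaries.

    ``summaries`` maps metric/motif name to the array of per-member values
    (NaN where a member's metric was undefined).
    """

    n: int
    l: int
    n_random: int
    summaries: dict[str, np.ndarray] = field(default_factory=dict)
    graphs: list[nx.Graph] | None = None

    def values(self, metric: str) -> np.ndarray:
        arr = self.summaries[metric]
        return arr[~np.isnan(arr)]

    def mean(self, metric: str) -> float | None:
        v = self.values(metric)
        return float(v.mean()) if v.size else None

    def sd(self, metric: str) -> float | None:
        """Sample SD (ddof=1) over the defined ensemble values."""
        v = self.values(metric)
        if v.size < 2:
            return None
        return float(v.std(ddof=1))


@dataclass
class ZScoreRecord:
    """Eq.-style normalization record: z = (M - mu) / sigma."""

    metric: str
    m: float
    mu: float | None
    sigma: float | None
    z: float | None
    undefined: bool
    component_id: object = None


def build_null(
    component: nx.Graph | tuple[int, int],
    n_random: int = 100,
    rng: np.random.Generator | int | None = None,
    metric_names: tuple[str, ...] = NULL_METRIC_NAMES,
    count_motifs: bool = True,
    keep_graphs: bool = False,
) -> NullEnsemble:
    """Build the matched null ensemble for one component (or an (n, l) pair).

    Each member is a connected graph with exactly the component's node and
    link counts; metric and motif summaries are cached on the ensemble.
    """
    if isinstance(component, tuple):
        n, l = component
    else:
        n = component.number_of_nodes()
        l = component.number_of_edges()
    if n < 2:
        raise InvalidParameterError("null ensembles need components of size >= 2")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    columns: dict[str, list[float]] = {m: [] for m in metric_names}
    if count_motifs:
        for cls in _motifs.MOTIF_CLASSES:
            columns[cls] = []
    graphs = [] if keep_graphs else None
    # the rejection budget is shared across the ensemble: sparse (n, l)
    # classes where connectivity is rare would otherwise spend thousands
    # of draws on every member without ever tripping the per-graph cap
    budget = _REJECTION_CAP
    warned = False
    max_l = n * (n - 1) // 2
    if not (n - 1 <= l <= max_l):
        raise InvalidParameterError(
            f"link count {l} outside [{n - 1}, {max_l}] for n={n}"
        )
    for i in range(n_random):
        if l == n - 1:
            g = _random_prufer_tree(n, rng)  # exact conditional law
        else:
            g = None
            if budget > 0:
                g, used = _rejection_draw(n, l, rng, budget)
                budget -= used
            if g is None:
                if not warned:
                    warnings.warn(
                        f"rejection budget exhausted for (n={n}, l={l}); "
                        "remaining members use the biased "
                        "spanning-tree-plus-extra-links sampler",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    warned = True
                g = _tree_plus_links(n, l, rng)
        if graphs is not None:
            graphs.append(g)
        vals = _null_member_metrics(g, metric_names, seed=i)
        if count_motifs:
            vals.update(
                (k, float(v))
                for k, v in _motifs.count_motifs(g).as_dict().items()
            )
        for key in columns:
            v = vals.get(key)
            columns[key].append(np.nan if v is None else float(v))
    summaries = {k: np.asarray(v, dtype=float) for k, v in columns.items()}
    return NullEnsemble(
        n=n, l=l, n_random=n_random, summaries=summaries, graphs=graphs
    )


def _null_member_metrics(
    g: nx.Graph, metric_names: tuple[str, ...], seed: int
) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    want_paths = {"aspl", "diameter", "efficiency"} & set(metric_names)
    if want_paths:
        a, d, e = _metrics.shortest_path_stats(g)
        out.update({"aspl": a, "diameter": d, "efficiency": e})
    if "max_degree" in metric_names:
        out["max_degree"] = _metrics.max_degree(g)
    if "modularity" in metric_names:
        out["modularity"] = _metrics.modularity_louvain(g, seed=seed)[1]
    if "assortativity" in metric_names:
        out["assortativity"] = _metrics.assortativity(g)
    if "transitivity" in metric_names:
        out["transitivity"] = _metrics.transitivity(g)
    if "information_content" in metric_names:
        out["information_content"] = _metrics.information_content(g)
    return {k: out.get(k) for k in metric_names}


def zscore(
    m: float, ensemble: NullEnsemble, metric: str, component_id=None
) -> ZScoreRecord:
    """Z-score one observed metric value against its null ensemble summary."""
    if metric not in ensemble.summaries:
        raise InvalidParameterError(f"no null summary for metric {metric!r}")
    mu = ensemble.mean(metric)
    sigma = ensemble.sd(metric)
    if mu is None or sigma is None or sigma == 0.0:
        return ZScoreRecord(metric, m, mu, sigma, None, True, component_id)
    return ZScoreRecord(
        metric, m, mu, sigma, (m - mu) / sigma, False, component_id
    )


class NullCache:
    """Deterministic (n, l)-keyed cache of null-ensemble summaries.

    The ensemble for a given (n, l) is seeded from ``(seed, n, l)``, so it
    is reproducible regardless of the order components are processed in.
    """

    def __init__(
        self,
        n_random: int = 100,
        seed: int = 0,
        metric_names: tuple[str, ...] = NULL_METRIC_NAMES,
        count_motifs: bool = True,
    ):
        self.n_random = n_random
        self.seed = seed
        self.metric_names = metric_names
        self.count_motifs = count_motifs
        self._cache: dict[tuple[int, int], NullEnsemble] = {}

    def get(self, n: int, l: int) -> NullEnsemble:
        key = (n, l)
        if key not in self._cache:
            rng = np.random.default_rng([self.seed, n, l])
            self._cache[key] = build_null(
                (n, l),
                n_random=self.n_random,
                rng=rng,
                metric_names=self.metric_names,
                count_motifs=self.count_motifs,
            )
        return self._cache[key]


def default_bin_edges(
    lo: float = -5.0, hi: float = 5.0, width: float = 0.5
) -> np.ndarray:
    """Default Z-histogram bins: width 0.5 over [-5, 5], open outer bins."""
    inner = np.arange(lo, hi + width / 2, width)
    return np.concatenate(([-np.inf], inner, [np.inf]))


def zscore_probability(
    records: list[ZScoreRecord] | np.ndarray,
    bin_edges: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Probability m/n of each Z bin: m components in the bin, n defined total.

    Undefined records are dropped (their count is simply excluded from n).
    Returns ``(bin_edges, probabilities)``; probabilities sum to 1 whenever
    the bins cover the full data range.
    """
    if bin_edges is None:
        bin_edges = default_bin_edges()
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or bin_edges.size < 2 or np.any(
        np.diff(bin_edges) <= 0
    ):
        raise InvalidParameterError("bin edges must be strictly increasing")
    if isinstance(records, np.ndarray):
        z = records[np.isfinite(records)]
    else:
        z = np.asarray(
            [r.z for r in records if not r.undefined], dtype=float
        )
    if z.size == 0:
        raise InvalidParameterError("no defined Z scores to bin")
    counts, _ = np.histogram(z, bins=bin_edges)
    return bin_edges, counts / z.size
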