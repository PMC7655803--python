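"""Induced 3- and 4-node motif census.

Counts, per connected component, the induced occurrences of the two
connected 3-node classes (the open "V-shape" path and the triangle) and all
six connected 4-node isomorphism classes (path/U-shape, star, paw, cycle,
diamond, complete).  Counting is induced (mfinder convention): a node subset
is classified by the subgraph containing *all* links among it, so partially
and fully connected patterns are mutually exclusive.  Enumeration is
exhaustive over all C(s,3) + C(s,4) subsets; MIN components are small, so
O(s^4) is acceptable.

The diagram-name mapping used throughout the package: the "paw-like" 4-node
motif is the triangle with a pendant link (``p4_paw``) and the "U-shape" is
the 4-node path (``p4_path``); both names are conventions on diagram classes
and can be remapped by the caller if needed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, fields

import networkx as nx

from mitotopo.errors import InvalidParameterError

__all__ = ["MotifCounts", "MOTIF_CLASSES", "count_motifs", "motif_zscores"]

MOTIF_CLASSES = (
    "v3",
    "tri3",
    "p4_path",
    "p4_star",
    "p4_paw",
    "p4_cycle",
    "p4_diamond",
    "p4_k4",
)


@dataclass
class MotifCounts:
    """Induced connected motif counts of one component."""

    v3: int = 0
    tri3: int = 0
    p4_path: int = 0
    p4_star: int = 0
    p4_paw: int = 0
    p4_cycle: int = 0
    p4_diamond: int = 0
    p4_k4: int = 0

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _build_quad_table() -> list[str | None]:
    """Class name per 6-bit edge mask over node quadruple (i<j<k<m).

    Bit order: (ij, ik, im, jk, jm, km).  ``None`` marks a disconnected
    induced subgraph (not a motif).
    """
    pairs = list(itertools.combinations(range(4), 2))
    table: list[str | None] = []
    for mask in range(64):
        g = nx.Graph()
        g.add_nodes_from(range(4))
        for b, (u, v) in enumerate(pairs):
            if mask >> b & 1:
                g.add_edge(u, v)
        if g.number_of_edges() < 3 or not nx.is_connected(g):
            table.append(None)
            continue
        ne = g.number_of_edges()
        degs = sorted(d for _, d in g.degree())
        if ne == 3:
            table.append("p4_star" if degs == [1, 1, 1, 3] else "p4_path")
        elif ne == 4:
            table.append("p4_cycle" if degs == [2, 2, 2, 2] else "p4_paw")
        elif ne == 5:
            table.append("p4_diamond")
        else:
            table.append("p4_k4")
    return table


_QUAD_TABLE = _build_quad_table()


def count_motifs(component: nx.Graph) -> MotifCounts:
    """Exhaustive induced census of connected 3-/4-node patterns.

    Components with fewer than 3 nodes return all-zero counts; 4-node
    fields are zero when s = 3.
    """
    counts = MotifCounts()
    nodes = sorted(component.nodes())
    adj = {v: set(component.neighbors(v)) for v in nodes}
    for i, j, k in itertools.combinations(nodes, 3):
        e = (j in adj[i]) + (k in adj[i]) + (k in adj[j])
        if e == 2:
            counts.v3 += 1
        elif e == 3:
            counts.tri3 += 1
    for i, j, k, m in itertools.combinations(nodes, 4):
        ai, aj, ak = adj[i], adj[j], adj[k]
        mask = (
            (j in ai)
            | (k in ai) << 1
            | (m in ai) << 2
            | (k in aj) << 3
            | (m in aj) << 4
            | (m in ak) << 5
        )
        cls = _QUAD_TABLE[mask]
        if cls is not None:
            setattr(counts, cls, getattr(counts, cls) + 1)
    return counts


def motif_zscores(counts: MotifCounts, null_ensemble) -> dict[str, object]:
    """Z-score each motif class against a matched null ensemble.

    ``null_ensemble`` must be a :class:`mitotopo.nullmodel.NullEnsemble`
    whose summaries include the motif classes.  Returns one
    :class:`mitotopo.nullmodel.ZScoreRecord` per class; classes whose null
    SD is zero come back flagged undefined.
    """
    from mitotopo.nullmodel import zscore

    records = {}
    for cls in MOTIF_CLASSES:
        if cls not in null_ensemble.summaries:
            raise InvalidParameterError(
                f"null ensemble carries no summary for motif {cls!r}"
            )
        records[cls] = zscore(
            float(getattr(counts, cls)), null_ensemble, cls
        )
    return records
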