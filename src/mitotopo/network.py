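"""Core container: one weighted mitochondria interaction network."""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from mitotopo.errors import InvalidParameterError

__all__ = ["MitoNetwork"]


@dataclass
class MitoNetwork:
    """One imaged cell's/ganglion's MIN.

    ``graph`` is an undirected ``networkx.Graph`` whose edge attribute
    ``weight`` holds the voxel count of the traced link (a positive integer,
    at least 2 since both terminal node voxels are counted).  The graph may
    be disconnected; components are the unit of analysis.
    """

    graph: nx.Graph
    subject_id: str | None = None
    side: str = "NA"  # left / right / NA
    network_id: str | None = None
    node_coords: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.side not in ("left", "right", "NA"):
            raise InvalidParameterError(f"invalid side {self.side!r}")
        for u, v, w in self.graph.edges(data="weight", default=1):
            if w <= 0:
                raise InvalidParameterError(
                    f"non-positive link weight on ({u}, {v})"
                )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    def to_adjacency(self) -> np.ndarray:
        """Symmetric voxel-count adjacency matrix (zero diagonal).

        Row/column order follows sorted node ids.
        """
        nodes = sorted(self.graph.nodes())
        return nx.to_numpy_array(
            self.graph, nodelist=nodes, weight="weight", dtype=int
        )
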