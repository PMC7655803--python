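"""Embed synthetic components as clean 3D voxel skeletons.

Round-trip fixture generator for the skeleton-extraction stage: a connected
graph is drawn as a one-voxel-wide 26-connected skeleton whose extracted
network is isomorphic to the input, with the realized per-link voxel counts
recorded as the expected weights.

Embedding scheme
----------------
Nodes are placed on the y-axis at distinct heights (``spacing`` voxels
apart, in random order).  Each link is routed as a voxel path that is
*strictly monotone in y* — every step advances y by one while x and z may
each change by at most one.  Monotonicity guarantees the path is self-clean
(non-consecutive voxels are never 26-adjacent), and a breadth-first search
per link enforces clearance: no path voxel may touch any previously placed
voxel except its own endpoints.  The first/last steps leave/enter the node
voxel in pairwise non-adjacent directions, which caps the embeddable degree
at 8 per node (4 toward higher y, 4 toward lower); graphs that exceed this,
or that the router cannot untangle after bounded retries with a larger
bounding box, raise :class:`~mitotopo.errors.EmbeddingError`.

The realized link weight is ``|y_u - y_v| + 1`` voxels (both node voxels
included), matching the extraction convention.

Degree-2 nodes are unobservable
-------------------------------
Extraction defines a node as a voxel with 26-neighbor count different from
2, so a graph node of degree 2 drawn into a skeleton is indistinguishable
from link interior — no embedding can preserve it.  (Extracted MINs never
contain degree-2 nodes for the same reason.)  The rasterizer therefore
*smooths* the input first: chains through degree-2 nodes are contracted,
and the returned ``graph`` is this smoothed graph with realized weights —
identical to the input whenever the input has no degree-2 nodes.  Parallel
chains produced by smoothing are drawn as separate voxel paths and summed
into one expected link (the extraction convention).  Components that smooth
to a self-loop or to a pure cycle cannot be drawn with y-monotone paths and
raise :class:`~mitotopo.errors.EmbeddingError`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from mitotopo.errors import EmbeddingError, InvalidParameterError
from mitotopo.skeleton import VoxelSkeleton

__all__ = ["RasterizedComponent", "rasterize_to_skeleton"]

_MOVES = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1),
          (1, 1), (1, -1), (-1, 1), (-1, -1)]
# pairwise non-adjacent step offsets: several links can share a node side
# only if each uses its own corner direction
_CORNERS = [(1, 1), (1, -1), (-1, 1), (-1, -1)]
_OFFSETS = [
    off
    for off in itertools.product((-1, 0, 1), repeat=3)
    if off != (0, 0, 0)
]


@dataclass
class RasterizedComponent:
    """A voxel skeleton plus the graph it is expected to re-extract to."""

    skeleton: VoxelSkeleton
    graph: nx.Graph  # edge attribute "weight" = realized voxel count
    node_coords: dict  # node -> voxel coordinate in the volume


def rasterize_to_skeleton(
    component: nx.Graph,
    rng: np.random.Generator | int | None = None,
    spacing: int = 6,
    max_retries: int = 10,
) -> RasterizedComponent:
    """Draw a connected component as a clean binary voxel skeleton.

    Parameters
    ----------
    component
        Connected graph; existing edge weights are ignored (the realized
        voxel counts become the expected weights).
    spacing
        Vertical distance between consecutive node heights (>= 4); a single
        link between height-adjacent nodes has weight ``spacing + 1``.
    """
    if component.number_of_nodes() < 2:
        raise InvalidParameterError("rasterization needs at least 2 nodes")
    if not nx.is_connected(component):
        raise InvalidParameterError("component must be connected")
    if spacing < 4:
        raise InvalidParameterError("spacing must be >= 4")
    # spacing >= 6 guarantees near-node layers of neighbouring heights
    # cannot interact; 4 and 5 are allowed for simple fixtures
    smoothed = _smooth(component)
    if max(d for _, d in smoothed.degree()) > 8:
        raise EmbeddingError(
            "a clean 26-connected skeleton supports node degree <= 8"
        )
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    nodes = sorted(smoothed.nodes())
    for attempt in range(max_retries):
        half_width = 6 + 3 * attempt
        order = rng.permutation(len(nodes))
        result = _try_embed(smoothed, nodes, order, spacing, half_width)
        if result is not None:
            return result
    raise EmbeddingError(
        f"could not embed component after {max_retries} retries"
    )


def _smooth(component: nx.Graph) -> nx.MultiGraph:
    """Contract chains through degree-2 nodes into direct (multi-)edges."""
    keep = [v for v in component.nodes() if component.degree(v) != 2]
    if not keep:
        raise EmbeddingError(
            "component is a pure cycle; it would extract as a single node"
        )
    m = nx.MultiGraph()
    m.add_nodes_from(keep)
    seen: set[frozenset] = set()
    for start in keep:
        for first in component.neighbors(start):
            chain_id = frozenset((frozenset((start, first)),))
            prev, cur = start, first
            edges_used = [frozenset((start, first))]
            while component.degree(cur) == 2:
                nxt = next(
                    w for w in component.neighbors(cur) if w != prev
                )
                prev, cur = cur, nxt
                edges_used.append(frozenset((prev, cur)))
            key = frozenset(edges_used)
            if key in seen:
                continue
            seen.add(key)
            if cur == start:
                raise EmbeddingError(
                    "smoothing produced a self-loop (pendant cycle); "
                    "not drawable with y-monotone paths"
                )
            m.add_edge(start, cur)
    return m


def _try_embed(smoothed, nodes, order, spacing, half_width):
    ys = {nodes[i]: 1 + int(pos) * spacing for i, pos in enumerate(order)}
    pos3 = {v: (0, ys[v], 0) for v in nodes}
    occupied = set(pos3.values())
    edges = sorted(
        (tuple(sorted((u, v), key=lambda w: ys[w]))
         for u, v in smoothed.edges()),
        key=lambda e: ys[e[1]] - ys[e[0]],
    )
    out_count = {v: 0 for v in nodes}
    in_count = {v: 0 for v in nodes}
    for u, v in edges:
        out_count[u] += 1
        in_count[v] += 1
    if max(out_count.values()) > 4 or max(in_count.values()) > 4:
        return None  # this height order needs >4 links on one node side
    paths = []
    for u, v in edges:
        path = _route(
            pos3[u],
            pos3[v],
            occupied,
            half_width,
            node_ys=sorted(ys.values()),
            corners_only_start=out_count[u] > 1,
            corners_only_end=in_count[v] > 1,
        )
        if path is None:
            return None
        occupied.update(path)
        paths.append((u, v, path))
    all_voxels = set(occupied)
    if not _verify_clean(all_voxels, pos3, smoothed):
        return None
    xs = [p[0] for p in all_voxels]
    ys_ = [p[1] for p in all_voxels]
    zs = [p[2] for p in all_voxels]
    ox, oy, oz = min(xs) - 1, min(ys_) - 1, min(zs) - 1
    vol = np.zeros(
        (max(xs) - ox + 2, max(ys_) - oy + 2, max(zs) - oz + 2),
        dtype=np.uint8,
    )
    for x, y, z in all_voxels:
        vol[x - ox, y - oy, z - oz] = 1
    out = nx.Graph()
    out.add_nodes_from(nodes)
    for u, v, path in paths:
        w = len(path) + 2
        if out.has_edge(u, v):  # parallel chains collapse with summed count
            out[u][v]["weight"] += w
        else:
            out.add_edge(u, v, weight=w)
    coords = {
        v: (p[0] - ox, p[1] - oy, p[2] - oz) for v, p in pos3.items()
    }
    return RasterizedComponent(
        skeleton=VoxelSkeleton(volume=vol), graph=out, node_coords=coords
    )


def _route(
    pu, pv, occupied, half_width, node_ys,
    corners_only_start=False, corners_only_end=False,
):
    """BFS a y-monotone, clearance-1 voxel path between two node voxels.

    Besides staying non-adjacent to every committed voxel, interior voxels
    keep a Chebyshev distance of at least 3 from every node voxel that is
    not one of the two endpoints (protecting the attachment slots of nodes
    the path cruises past), and the two layers nearest each endpoint stay
    inside the quadrant of the corner they use, so sibling links at a node
    cannot shadow each other's slots.  Returns the interior voxel list
    (excluding both node voxels), or None.
    """
    xu, yu, zu = pu
    xv, yv, zv = pv
    start_moves = _CORNERS if corners_only_start else _MOVES
    end_moves = _CORNERS if corners_only_end else _MOVES
    other_ys = [w for w in node_ys if w not in (yu, yv)]

    def clear(p, allow):
        if p in occupied:
            return False
        x, y, z = p
        if abs(x) > half_width or abs(z) > half_width:
            return False
        if max(abs(x), abs(z)) < 3:
            for yw in other_ys:
                if abs(y - yw) <= 2:
                    return False
        for dx, dy, dz in _OFFSETS:
            q = (x + dx, y + dy, z + dz)
            if q in occupied and q not in allow:
                return False
        return True

    frontier = {}
    for dx, dz in start_moves:
        p = (xu + dx, yu + 1, zu + dz)
        if clear(p, {pu}):
            frontier[(p[0], p[2])] = None  # parent pointer
    layers = [frontier]
    y = yu + 1
    while y < yv - 1 and layers[-1]:
        y += 1
        allow = {pv} if y == yv - 1 else frozenset()
        nxt = {}
        for (x, z) in layers[-1]:
            for dx, dz in _MOVES:
                key = (x + dx, z + dz)
                if key in nxt:
                    continue
                if y == yu + 2 and corners_only_start:
                    # stay in the start corner's quadrant
                    if (key[0] - xu) * (x - xu) < 1 or (
                        key[1] - zu
                    ) * (z - zu) < 1:
                        continue
                if (
                    y == yv - 1
                    and corners_only_end
                    and abs(key[0] - xv) <= 1
                    and abs(key[1] - zv) <= 1
                ):
                    # arrival-corner candidates must come from their quadrant
                    if (x - xv) * (key[0] - xv) < 1 or (
                        z - zv
                    ) * (key[1] - zv) < 1:
                        continue
                if clear((key[0], y, key[1]), allow):
                    nxt[key] = (x, z)
        layers.append(nxt)
    if y != yv - 1 or not layers[-1]:
        return None
    # pick an end voxel adjacent to the target node
    end = None
    for dx, dz in end_moves:
        key = (xv + dx, zv + dz)
        if key in layers[-1]:
            end = key
            break
    if end is None:
        return None
    path = []
    key = end
    for depth in range(len(layers) - 1, -1, -1):
        path.append((key[0], yu + 1 + depth, key[1]))
        key = layers[depth][key]
        if key is None:
            break
    path.reverse()
    return path


def _verify_clean(voxels, node_pos, component):
    """Independent geometric check: neighbor counts match the graph."""
    node_set = set(node_pos.values())
    degree = {p: component.degree(v) for v, p in node_pos.items()}
    for p in voxels:
        x, y, z = p
        cnt = sum(
            1
            for dx, dy, dz in _OFFSETS
            if (x + dx, y + dy, z + dz) in voxels
        )
        want = degree[p] if p in node_set else 2
        if cnt != want:
            return False
    return True
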