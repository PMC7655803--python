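"""Skeleton volumes to weighted graphs, and the voxel round trip."""

import networkx as nx
import numpy as np
import pytest
import tifffile

from mitotopo.cohort import generate_component
from mitotopo.errors import EmbeddingError, InvalidParameterError
from mitotopo.rasterize import rasterize_to_skeleton
from mitotopo.skeleton import (
    VoxelSkeleton,
    load_mask_stack,
    skeleton_to_network,
    skeletonize_mask,
)


def _volume(coords, shape):
    vol = np.zeros(shape, dtype=np.uint8)
    for c in coords:
        vol[c] = 1
    return vol


class TestSkeletonToNetwork:
    def test_straight_line_of_five(self):
        vol = _volume([(1, y, 1) for y in range(1, 6)], (3, 7, 3))
        net = skeleton_to_network(VoxelSkeleton(vol))
        assert net.n_nodes == 2 and net.n_links == 1
        (_, _, w), = net.graph.edges(data="weight")
        assert w == 5

    def test_t_shape(self):
        # three 3-voxel arms sharing one junction voxel: the junction, plus
        # 3 endpoints; each traced link covers 4 voxels (junction..tip).
        # Arms leave along pairwise non-adjacent corner directions so the
        # junction is the only voxel with 3 neighbors.
        j = (5, 5, 5)
        coords = [j]
        for d in [(1, 1, 1), (1, -1, -1), (-1, 1, -1)]:
            coords += [
                tuple(j[i] + t * d[i] for i in range(3)) for t in (1, 2, 3)
            ]
        net = skeleton_to_network(VoxelSkeleton(_volume(coords, (10, 10, 10))))
        assert net.n_nodes == 4 and net.n_links == 3
        assert sorted(w for _, _, w in net.graph.edges(data="weight")) == [
            4, 4, 4,
        ]
        degs = sorted(d for _, d in net.graph.degree())
        assert degs == [1, 1, 1, 3]

    def test_adjacent_branch_points_weight_two(self):
        # two face-adjacent junctions, each with two corner spurs: the
        # junction-junction link has no interior voxels, so weight 2
        a, b = (5, 5, 5), (5, 6, 5)
        coords = [a, b, (4, 4, 5), (6, 4, 5), (4, 7, 5), (6, 7, 5)]
        net = skeleton_to_network(VoxelSkeleton(_volume(coords, (9, 9, 9))))
        assert net.n_nodes == 6 and net.n_links == 5
        weights = sorted(w for _, _, w in net.graph.edges(data="weight"))
        assert weights == [2, 2, 2, 2, 2]
        assert sorted(d for _, d in net.graph.degree()) == [1, 1, 1, 1, 3, 3]

    def test_isolated_voxel_is_size_one_component(self):
        vol = _volume([(1, 1, 1), (3, 3, 3)], (6, 6, 6))
        net = skeleton_to_network(VoxelSkeleton(vol))
        assert net.n_nodes == 2 and net.n_links == 0

    def test_pure_cycle_collapses_to_single_node(self):
        # a diamond-shaped 26-connected loop of degree-2 voxels
        coords = [(2, 1, 1), (3, 2, 1), (2, 3, 1), (1, 2, 1)]
        net = skeleton_to_network(VoxelSkeleton(_volume(coords, (5, 5, 3))))
        assert net.n_nodes == 1 and net.n_links == 0

    def test_voxel_conservation(self, rng):
        # with thr=0 every skeleton voxel is a node or on exactly one link
        # (simple smoothed graphs only: a collapsed parallel path shares
        # its terminal voxels twice and is checked by the round trip)
        for _ in range(20):
            comp = _embeddable_component(rng, simple_only=True)
            rc = rasterize_to_skeleton(comp, rng=rng)
            net = skeleton_to_network(rc.skeleton)
            total = rc.skeleton.n_foreground
            link_interior = sum(
                w for _, _, w in net.graph.edges(data="weight")
            ) - 2 * net.n_links
            assert link_interior + net.n_nodes == total


class TestRoundTrip:
    def test_hundred_random_components(self, rng):
        done = 0
        while done < 100:
            comp = _embeddable_component(rng)
            try:
                rc = rasterize_to_skeleton(comp, rng=rng)
            except EmbeddingError:
                continue
            net = skeleton_to_network(rc.skeleton)
            gm = nx.algorithms.isomorphism.GraphMatcher(
                net.graph,
                rc.graph,
                edge_match=lambda a, b: a.get("weight") == b.get("weight"),
            )
            assert gm.is_isomorphic()
            done += 1

    def test_component_count_preserved(self, rng):
        comp = _embeddable_component(rng)
        rc = rasterize_to_skeleton(comp, rng=rng)
        net = skeleton_to_network(rc.skeleton)
        assert nx.number_connected_components(net.graph) == 1

    def test_degree_cap(self, rng):
        with pytest.raises(EmbeddingError):
            rasterize_to_skeleton(nx.star_graph(9), rng=rng)

    def test_single_edge_straight_segment(self):
        rc = rasterize_to_skeleton(nx.path_graph(2), rng=0, spacing=4)
        assert rc.skeleton.n_foreground == 5
        assert rc.graph[0][1]["weight"] == 5
        xs, ys, zs = np.nonzero(rc.skeleton.volume)
        assert len(set(xs)) == 1 and len(set(zs)) == 1  # straight in y


def _embeddable_component(rng, simple_only=False):
    from mitotopo.rasterize import _smooth

    while True:
        comp = generate_component(int(rng.integers(4, 18)), 0.3, 0.5, rng)
        try:
            sm = _smooth(comp)
        except EmbeddingError:
            continue
        if max(d for _, d in sm.degree()) > 8:
            continue
        if simple_only and any(
            sm.number_of_edges(u, v) > 1 for u, v in sm.edges()
        ):
            continue
        return comp


class TestSkeletonizeMask:
    def test_thin_bar_unchanged(self):
        vol = _volume([(1, y, 1) for y in range(1, 8)], (3, 9, 3))
        skel = skeletonize_mask(vol)
        assert skel.n_foreground == 7
        np.testing.assert_array_equal(skel.volume, vol)

    def test_empty_volume(self):
        skel = skeletonize_mask(np.zeros((4, 4, 4), dtype=np.uint8))
        assert skel.n_foreground == 0

    def test_solid_cube_single_component(self):
        vol = np.zeros((7, 7, 7), dtype=np.uint8)
        vol[1:6, 1:6, 1:6] = 1
        skel = skeletonize_mask(vol)
        assert skel.n_foreground >= 1
        from scipy import ndimage

        _, n = ndimage.label(skel.volume, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_non_binary_rejected(self):
        with pytest.raises(InvalidParameterError):
            skeletonize_mask(np.full((3, 3, 3), 7, dtype=np.uint8))


class TestLoadMaskStack:
    def test_stack_orientation_and_binarization(self, tmp_path):
        stack = np.zeros((3, 4, 4), dtype=np.uint8)  # 3 slices of 4x4
        stack[1, 2, 3] = 255
        path = tmp_path / "stack.tif"
        tifffile.imwrite(path, stack)
        vol = load_mask_stack(path)
        assert vol.shape == (4, 4, 3)
        assert set(np.unique(vol)) <= {0, 1}
        assert vol[2, 3, 1] == 1

    def test_inconsistent_slices_rejected(self, tmp_path):
        path = tmp_path / "ragged.tif"
        with tifffile.TiffWriter(path) as tw:
            tw.write(np.zeros((4, 4), dtype=np.uint8))
            tw.write(np.zeros((5, 5), dtype=np.uint8))
        with pytest.raises(InvalidParameterError):
            load_mask_stack(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(Exception):
            load_mask_stack(tmp_path / "absent.tif")
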