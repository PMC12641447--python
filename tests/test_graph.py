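"""Skeletonization, branch tracing, morphometry, terminal-branch rule."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wmhflow import synthetic as syn
from wmhflow.errors import EmptyInputError, SeedSnapError
from wmhflow.graph import (VesselBranch, VascularNetwork, branch_morphometry,
                           build_network, identify_terminal_branches, skeletonize)
from wmhflow.volume import VoxelVolume


def _tube_mask(shape=(40, 9, 9), axis_yz=(4, 4), radius=1.6, spacing=1.0):
    grid = np.zeros(shape, dtype=bool)
    y, z = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]), indexing="ij")
    disc = (y - axis_yz[0]) ** 2 + (z - axis_yz[1]) ** 2 <= radius ** 2
    grid[2:-2, :, :] = disc[None, :, :]
    return VoxelVolume(grid=grid, spacing=(spacing,) * 3)


class TestSkeletonize:
    def test_straight_tube_gives_thin_axial_path(self):
        vol = _tube_mask()
        skel = skeletonize(vol)
        # one voxel per axial position along the tube interior
        per_slice = skel.sum(axis=(1, 2))
        assert (per_slice[5:-5] == 1).all()

    def test_topology_preserved_for_two_components(self):
        from scipy import ndimage
        grid = np.zeros((30, 10, 10), dtype=bool)
        grid[2:12, 3:6, 3:6] = True
        grid[18:28, 3:6, 3:6] = True
        skel = skeletonize(VoxelVolume(grid=grid, spacing=(1, 1, 1)))
        _, n = ndimage.label(skel, structure=np.ones((3, 3, 3)))
        assert n == 2

    def test_y_shape_has_one_junction_neighborhood(self):
        tree = syn.generate_arterial_tree(depth=2, root_radius=1.2, root_length=15.0)
        shape, origin = syn.fit_grid(tree, 0.5)
        vol = syn.voxelize_tree(tree, 0.5, shape, origin)
        root = tree.branch(tree.root_ids[0])
        net = build_network(skeletonize(vol), vol, [root.start])
        deg3_nodes = [n for n, d in net.node_degrees().items() if d >= 3]
        assert len(deg3_nodes) == 1

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyInputError):
            skeletonize(VoxelVolume(grid=np.zeros((5, 5, 5), bool), spacing=(1, 1, 1)))


class TestBuildNetwork:
    def test_depth3_tree_recovered_exactly(self, depth3_tree, recovered_network):
        net = recovered_network
        assert len(net.branches) == len(depth3_tree.branches) == 7
        roles = [b.role for b in net.branches]
        assert roles.count("terminal-outlet") == 4
        assert roles.count("inflow") == 1

    def test_straight_tube_single_inflow_branch(self, straight_tube_tree,
                                                straight_tube_volume):
        vol = straight_tube_volume
        root = straight_tube_tree.branches[0]
        net = build_network(skeletonize(vol), vol, [root.start])
        assert len(net.branches) == 1
        assert net.branches[0].role == "inflow"
        assert len(net.terminal_node_ids()) == 1  # far end drains

    def test_tube_radius_recovered_within_tolerance(self, straight_tube_tree,
                                                    straight_tube_volume):
        vol = straight_tube_volume
        root = straight_tube_tree.branches[0]
        net = build_network(skeletonize(vol), vol, [root.start])
        assert net.branches[0].mean_radius == pytest.approx(root.radius, abs=0.3)

    def test_unreachable_seed_raises(self, straight_tube_volume):
        with pytest.raises(SeedSnapError):
            build_network(skeletonize(straight_tube_volume), straight_tube_volume,
                          [np.array([999.0, 999.0, 999.0])])

    def test_pruning_keeps_inflow_to_terminal_paths(self, recovered_network):
        import networkx as nx
        g = recovered_network.as_multigraph()
        for t in recovered_network.terminal_node_ids():
            assert any(nx.has_path(g, s, t)
                       for s in recovered_network.inflow_inlet_node_ids)

    def test_cycle_broken_with_warning(self):
        # two parallel tubes joined at both ends form one loop
        grid = np.zeros((30, 12, 5), dtype=bool)
        grid[2:28, 2:4, 1:4] = True
        grid[2:28, 8:10, 1:4] = True
        grid[2:5, 2:10, 1:4] = True
        grid[25:28, 2:10, 1:4] = True
        vol = VoxelVolume(grid=grid, spacing=(1, 1, 1))
        skel = skeletonize(vol)
        with pytest.warns(UserWarning, match="loop"):
            net = build_network(skel, vol, [vol.world(np.argwhere(skel)[:1])[0]],
                                prune_length=1.0)
        import networkx as nx
        assert nx.is_forest(nx.Graph(net.as_multigraph()))


class TestMorphometry:
    def test_straight_polyline(self):
        b = VesselBranch(0, np.array([[0, 0, 0], [0, 0, 5.0], [0, 0, 10.0]]),
                         np.ones(3), (0, 1))
        m = branch_morphometry(b)
        assert m.length == pytest.approx(10.0)
        assert m.tortuosity == pytest.approx(1.0)

    def test_semicircle_tortuosity_is_pi_over_2(self):
        theta = np.linspace(0, np.pi, 200)
        pts = np.stack([10 * np.cos(theta), 10 * np.sin(theta), np.zeros_like(theta)], 1)
        b = VesselBranch(0, pts, np.ones(len(pts)), (0, 1))
        assert branch_morphometry(b).tortuosity == pytest.approx(np.pi / 2, rel=1e-3)

    def test_two_point_branch_has_unit_tortuosity(self):
        b = VesselBranch(0, np.array([[0, 0, 0], [3.0, 4.0, 0]]), np.ones(2), (0, 1))
        m = branch_morphometry(b)
        assert m.length == pytest.approx(m.length / m.tortuosity) == pytest.approx(5.0)

    def test_coincident_endpoints_flagged(self):
        theta = np.linspace(0, 2 * np.pi, 50)
        pts = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], 1)
        pts[-1] = pts[0]  # exactly closed
        b = VesselBranch(0, pts, np.ones(len(pts)), (0, 0))
        with pytest.warns(UserWarning, match="coincident"):
            m = branch_morphometry(b)
        assert np.isnan(m.tortuosity)

    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=2, max_size=12, unique=True))
    def test_tortuosity_at_least_one(self, pts):
        pts = np.asarray(pts)
        if np.linalg.norm(pts[-1] - pts[0]) < 1e-9:
            return
        b = VesselBranch(0, pts, np.ones(len(pts)), (0, 1))
        assert b.tortuosity >= 1.0 - 1e-12

    def test_recovered_morphometry_matches_ground_truth(self, depth3_tree,
                                                        recovered_network):
        gt_lengths = np.sort([b.length for b in depth3_tree.branches])
        rec_lengths = np.sort([b.length for b in recovered_network.branches])
        np.testing.assert_allclose(rec_lengths, gt_lengths, rtol=0.10)
        gt_tau = np.sort([b.tortuosity for b in depth3_tree.branches])
        rec_tau = np.sort([b.tortuosity for b in recovered_network.branches])
        assert np.max(np.abs(rec_tau - gt_tau)) < 0.1


class TestTerminalBranches:
    def _net(self, diameters, roles):
        branches = []
        nodes = {}
        for i, (d, role) in enumerate(zip(diameters, roles)):
            pts = np.array([[0, 0, 2.0 * i], [0, 0, 2.0 * i + 10]])
            b = VesselBranch(i, pts, np.full(2, d / 2), (2 * i, 2 * i + 1), role=role)
            branches.append(b)
            nodes[2 * i] = pts[0]
            nodes[2 * i + 1] = pts[1]
        return VascularNetwork(branches=branches, nodes=nodes, inflow_branch_ids={0})

    def test_equal_diameters_give_empty_set(self):
        net = self._net([1.0, 1.0, 1.0], ["inflow", "terminal-outlet", "terminal-outlet"])
        assert identify_terminal_branches(net) == set()

    def test_only_thin_terminal_outlets_selected(self):
        net = self._net([2.0, 0.8, 1.4], ["inflow", "terminal-outlet", "internal"])
        assert identify_terminal_branches(net) == {1}

    def test_leaf_generation_selected_on_synthetic_tree(self, depth3_tree,
                                                        recovered_network):
        terminal = identify_terminal_branches(recovered_network)
        assert len(terminal) == 4  # the leaf generation of the depth-3 tree
        mean_d = np.mean([b.diameter for b in recovered_network.branches])
        for bid in terminal:
            assert recovered_network.branch(bid).diameter < mean_d

    def test_single_branch_network_empty(self):
        net = self._net([1.0], ["inflow"])
        assert identify_terminal_branches(net) == set()
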