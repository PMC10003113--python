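"""Skeleton-graph decomposition: fixtures, oracle equivalence, metrics."""

import math

import numpy as np
import pytest
from fixtures_rasters import FIXTURES
from oracle_utils import oracle_summary
from skimage import morphology as skmorph

from photoskin import mito


def _summarize(graph, trees):
    counts = graph.node_counts()
    return {
        "n_endpoints": counts["endpoint"],
        "n_isolated": counts["isolated"],
        "n_junctions": counts["junction"],
        "n_trees": len(trees),
        "n_branches": sum(t.n_branches for t in trees),
        "total_length": sum(t.length for t in trees),
    }


class TestFixtureShapes:
    def test_axial_line(self):
        g = mito.build_graph(FIXTURES["axial_line"], 1.0)
        assert g.node_counts() == {"junction": 0, "endpoint": 2, "isolated": 0}
        assert len(g.edges) == 1
        assert g.edges[0].length == pytest.approx(10.0)

    def test_axial_line_length_scales_with_pixel_size(self):
        g = mito.build_graph(FIXTURES["axial_line"], 0.3)
        assert g.edges[0].length == pytest.approx(10 * 0.3)

    def test_diagonal_line_sqrt2_steps(self):
        g = mito.build_graph(FIXTURES["diagonal_line"], 1.0)
        assert len(g.edges) == 1
        assert g.edges[0].length == pytest.approx(7 * math.sqrt(2.0))

    def test_t_shape_one_junction_three_branches(self):
        g = mito.build_graph(FIXTURES["t_shape"], 1.0)
        counts = g.node_counts()
        assert counts["junction"] == 1
        assert counts["endpoint"] == 3
        trees = mito.decompose_trees(g)
        assert len(trees) == 1
        assert trees[0].n_branches == 3

    def test_plus_shape_four_branches(self):
        g = mito.build_graph(FIXTURES["plus_shape"], 1.0)
        assert g.node_counts()["junction"] == 1
        assert g.node_counts()["endpoint"] == 4
        assert len(g.edges) == 4

    def test_isolated_pixel_is_zero_length_tree(self):
        g = mito.build_graph(FIXTURES["isolated_pixel"], 1.0)
        assert g.node_counts() == {"junction": 0, "endpoint": 0, "isolated": 1}
        assert len(g.edges) == 0
        trees = mito.decompose_trees(g)
        assert len(trees) == 1
        assert trees[0].length == 0.0

    def test_diamond_ring_is_single_closed_branch(self):
        g = mito.build_graph(FIXTURES["diamond_ring"], 1.0)
        assert g.node_counts() == {"junction": 0, "endpoint": 0, "isolated": 0}
        assert len(g.edges) == 1
        assert g.edges[0].nodes is None
        trees = mito.decompose_trees(g)
        assert len(trees) == 1
        assert trees[0].length == pytest.approx(12 * math.sqrt(2.0))

    def test_two_components_two_trees(self):
        g = mito.build_graph(FIXTURES["two_components"], 1.0)
        assert len(mito.decompose_trees(g)) == 2

    def test_empty_skeleton_empty_graph(self):
        g = mito.build_graph(np.zeros((5, 5), dtype=bool), 1.0)
        assert g.nodes == () and g.edges == ()
        assert mito.decompose_trees(g) == []


@pytest.mark.parametrize("name", sorted(FIXTURES))
def test_graph_matches_exhaustive_oracle(name):
    """Counts and lengths equal the brute-force pixel-adjacency enumeration."""
    skel = FIXTURES[name]
    g = mito.build_graph(skel, 1.0)
    trees = mito.decompose_trees(g)
    got = _summarize(g, trees)
    expected = oracle_summary(skel, 1.0)
    assert got["n_endpoints"] == expected["n_endpoints"], name
    assert got["n_isolated"] == expected["n_isolated"], name
    assert got["n_junctions"] == expected["n_junctions"], name
    assert got["n_trees"] == expected["n_trees"], name
    assert got["n_branches"] == expected["n_branches"], name
    assert got["total_length"] == pytest.approx(expected["total_length"]), name


def test_graph_matches_oracle_on_random_skeletons():
    """Oracle equivalence holds on skeletons of random blob sets."""
    for seed in range(50):
        rng = np.random.default_rng(seed)
        img = np.zeros((15, 15), dtype=bool)
        rr, cc = np.ogrid[:15, :15]
        for _ in range(rng.integers(1, 4)):
            r, c = rng.integers(2, 13, size=2)
            rad = int(rng.integers(1, 4))
            img |= (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
        skel = mito.skeletonize_mask(img)
        g = mito.build_graph(skel, 1.0)
        got = _summarize(g, mito.decompose_trees(g))
        expected = oracle_summary(skel, 1.0)
        for key in ("n_endpoints", "n_isolated", "n_junctions", "n_trees", "n_branches"):
            assert got[key] == expected[key], (seed, key)
        assert got["total_length"] == pytest.approx(expected["total_length"]), seed


def test_every_skeleton_pixel_in_exactly_one_edge_or_node():
    for name, skel in FIXTURES.items():
        g = mito.build_graph(skel, 1.0)
        node_px = {p for n in g.nodes for p in n.pixels}
        edge_px = {p for e in g.edges for p in e.path}
        covered = node_px | edge_px
        assert covered == {tuple(p) for p in np.argwhere(skel)}, name


class TestSkeletonize:
    def test_solid_bar_thins_to_medial_line(self):
        bar = np.zeros((7, 15), dtype=bool)
        bar[2:5, 2:13] = True
        skel = mito.skeletonize_mask(bar)
        assert skel.sum() <= 11
        assert bar[skel].all()  # skeleton lies inside the mask
        g = mito.build_graph(skel, 1.0)
        assert len(g.edges) == 1
        assert g.node_counts()["endpoint"] == 2
        assert g.edges[0].length == pytest.approx(10.0, abs=2.0)

    def test_empty_mask_gives_empty_skeleton(self):
        assert mito.skeletonize_mask(np.zeros((4, 4), dtype=bool)).sum() == 0

    def test_component_count_preserved_on_random_blobs(self):
        from scipy import ndimage as ndi

        s8 = np.ones((3, 3), dtype=int)
        for seed in range(50):
            rng = np.random.default_rng(seed)
            img = np.zeros((40, 40), dtype=bool)
            rr, cc = np.ogrid[:40, :40]
            for _ in range(6):
                r, c = rng.integers(5, 35, size=2)
                rad = int(rng.integers(2, 5))
                img |= (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
            before = ndi.label(img, structure=s8)[1]
            after = ndi.label(mito.skeletonize_mask(img), structure=s8)[1]
            assert before == after, seed


class TestNetworkMetrics:
    def test_hand_checked_arithmetic(self):
        """One tree with branches of 4, 3, 3 um."""
        tree = mito.Tree(node_ids=(0, 1), edge_ids=(0, 1, 2), length=10.0, branch_lengths=(4.0, 3.0, 3.0))
        m = mito.network_metrics([tree])
        assert m.network_total_length == pytest.approx(10.0)
        assert m.avg_branch_length == pytest.approx(10.0 / 3.0)
        assert m.max_branch_length == pytest.approx(4.0)
        assert m.trees_per_length == pytest.approx(0.1)

    def test_empty_network_reports_missing_not_zero(self):
        m = mito.network_metrics([])
        assert m.network_total_length == 0.0
        assert m.n_trees == 0
        assert math.isnan(m.trees_per_length)
        assert math.isnan(m.avg_tree_length)
        assert math.isnan(m.avg_branch_length)

    def test_length_conservation_branches_vs_trees(self):
        """Sum of branch lengths equals tree length equals network total."""
        for name, skel in FIXTURES.items():
            g = mito.build_graph(skel, 0.7)
            trees = mito.decompose_trees(g)
            for t in trees:
                assert t.length == pytest.approx(sum(t.branch_lengths), rel=1e-9)
            m = mito.network_metrics(trees)
            assert m.network_total_length == pytest.approx(
                sum(e.length for e in g.edges), rel=1e-9
            ), name

    def test_metric_ratio_invariants(self):
        g = mito.build_graph(FIXTURES["t_shape"], 1.0)
        m = mito.network_metrics(mito.decompose_trees(g))
        assert m.avg_tree_length == pytest.approx(m.network_total_length / m.n_trees)
        assert m.trees_per_length == pytest.approx(m.n_trees / m.network_total_length)
        assert m.branches_per_length == pytest.approx(m.n_branches / m.network_total_length)


class TestAggregateWell:
    def _metrics(self, total, n_trees=2):
        trees = [
            mito.Tree(node_ids=(i,), edge_ids=(i,), length=total / n_trees, branch_lengths=(total / n_trees,))
            for i in range(n_trees)
        ]
        return mito.network_metrics(trees)

    def test_single_cell_identity(self):
        m = self._metrics(100.0)
        well = mito.aggregate_well([m])
        assert well["network_total_length"] == pytest.approx(100.0)
        assert well["n_cells"] == 1

    def test_two_cell_mean(self):
        well = mito.aggregate_well([self._metrics(100.0), self._metrics(300.0)])
        assert well["network_total_length"] == pytest.approx(200.0)

    def test_zero_cells_is_an_error(self):
        with pytest.raises(ValueError):
            mito.aggregate_well([])


class TestSegmentation:
    def test_constant_image_no_contrast(self):
        with pytest.raises(ValueError, match="no contrast"):
            mito.segment_mitochondria(np.full((10, 10), 7.0))

    def test_inverted_contrast_gives_identical_mask(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, size=(30, 30))
        img[10:20, 10:20] += 500
        mask = mito.segment_mitochondria(img)
        inv = mito.segment_mitochondria(img.max() - img, invert=True)
        assert np.array_equal(mask, inv)

    def test_non_finite_rejected(self):
        img = np.ones((5, 5))
        img[0, 0] = np.nan
        with pytest.raises(ValueError):
            mito.segment_mitochondria(img)
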