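"""Link-community discovery, partition density, and the module map."""
import numpy as np
import pytest

from siglinc import (BlockSpec, SignedNetwork, balanced_block_network,
                     extract_modules, link_clustering_coefficients,
                     link_similarity_scores, module_map, partition_density,
                     sweep_partition_density)


@pytest.fixture
def two_triangles_bridge():
    """Two positive triangles joined by a positive bridge with score 0."""
    return SignedNetwork([("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
                          ("d", "e", 1), ("e", "f", 1), ("d", "f", 1),
                          ("c", "d", 1)])


class TestSimilarityScores:
    def test_worked_example(self, e1):
        scores = link_similarity_scores(link_clustering_coefficients(e1))
        assert scores[("1", "2")] == pytest.approx(2 / 3)

    def test_pendant_edge_zero(self):
        net = SignedNetwork([("a", "b", 1), ("b", "c", 1)])
        scores = link_similarity_scores(link_clustering_coefficients(net))
        assert scores[("a", "b")] == 0.0

    def test_triangle_edge_one(self):
        tri = SignedNetwork([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        scores = link_similarity_scores(link_clustering_coefficients(tri))
        assert all(s == 1.0 for s in scores.values())

    def test_equals_slc_under_default_convention(self):
        from conftest import random_net
        net = random_net(12)
        table = link_clustering_coefficients(net)
        scores = link_similarity_scores(table, sign=1)
        slc = {(r.source, r.target): r.slc
               for r in table.itertuples(index=False) if r.sign == 1}
        assert scores == pytest.approx(slc)

    def test_sign_filter(self, e1):
        neg = link_similarity_scores(link_clustering_coefficients(e1),
                                     sign=-1)
        assert set(neg) == {("1", "5"), ("2", "4"), ("2", "5")}


class TestPartitionDensity:
    def test_clique_partitions_are_one(self):
        tri = [("a", "b"), ("b", "c"), ("a", "c")]
        k4 = [(u, v) for u in "wxyz" for v in "wxyz" if u < v]
        assert partition_density([tri]) == 1.0
        assert partition_density([tri, k4]) == 1.0

    def test_tree_partitions_are_zero(self):
        path = [("a", "b"), ("b", "c")]
        star = [("h", x) for x in "ijk"]
        assert partition_density([path]) == 0.0
        assert partition_density([path, star]) == 0.0

    def test_worked_three_community_value(self):
        tri = [("a", "b"), ("b", "c"), ("a", "c")]
        assert partition_density([tri, [("x", "y")]]) == pytest.approx(0.75)

    def test_single_edge_community_contributes_zero(self):
        assert partition_density([[("x", "y")]]) == 0.0

    def test_disconnected_community_errors(self):
        with pytest.raises(ValueError, match="cannot connect"):
            partition_density([[("a", "b"), ("c", "d")]])

    def test_relabel_invariance(self):
        tri = [("a", "b"), ("b", "c"), ("a", "c")]
        renamed = [("q", "r"), ("r", "s"), ("q", "s")]
        assert partition_density([tri, [("x", "y")]]) == \
            partition_density([renamed, [("u", "t")]])


class TestSweep:
    def test_two_triangles_bridge(self, two_triangles_bridge):
        sweep = sweep_partition_density(two_triangles_bridge)
        assert list(sweep["cutoff"]) == [1.0, 0.0]
        top = sweep.iloc[0]
        assert (top.n_edges, top.n_communities) == (6, 2)
        assert top.density == pytest.approx(1.0)
        bottom = sweep.iloc[1]
        assert (bottom.n_edges, bottom.n_communities) == (7, 1)
        assert bottom.density < 1.0

    def test_single_triangle_density_one_everywhere(self):
        tri = SignedNetwork([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        sweep = sweep_partition_density(tri)
        assert (sweep["density"] == 1.0).all()

    def test_negative_sweep_on_balanced_network_non_increasing(self):
        net, _ = balanced_block_network(BlockSpec(sizes=(5, 5), seed=2))
        sweep = sweep_partition_density(net, sign=-1)
        dens = sweep["density"].to_numpy()
        assert (np.diff(dens) <= 1e-12).all()
        assert dens.argmax() == 0  # no interior maximum

    def test_lowest_cutoff_is_connected_components(self,
                                                   two_triangles_bridge):
        sweep = sweep_partition_density(two_triangles_bridge)
        last = sweep.iloc[-1]
        assert last.n_edges == 7
        assert last.n_communities == 1  # one connected component

    def test_no_edges_of_sign_errors(self):
        tri = SignedNetwork([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        with pytest.raises(ValueError, match="no edges"):
            sweep_partition_density(tri, sign=-1)

    @pytest.mark.parametrize("seed", range(5))
    def test_incremental_density_matches_direct_formula(self, seed):
        from conftest import random_net
        from siglinc.linkcomm import _communities_at_cutoff
        net = random_net(seed, n_max=20, positive_fraction=0.7)
        if net.n_positive == 0:
            pytest.skip("no positive edges in draw")
        scores = link_similarity_scores(link_clustering_coefficients(net))
        sweep = sweep_partition_density(net, scores)
        ordered = sorted(scores, key=lambda e: (-scores[e], e))
        for row in sweep.itertuples(index=False):
            comms = _communities_at_cutoff(ordered, scores, row.cutoff)
            assert row.density == pytest.approx(partition_density(comms))


class TestExtractModules:
    def test_two_triangles_bridge(self, two_triangles_bridge):
        partition, modules = extract_modules(two_triangles_bridge)
        assert partition.cutoff == 1.0
        assert sorted(sorted(m.genes) for m in modules) == \
            [["a", "b", "c"], ["d", "e", "f"]]

    def test_single_edge_network_no_modules(self):
        net = SignedNetwork([("a", "b", 1)])
        partition, modules = extract_modules(net, min_genes=3)
        assert modules == []
        assert partition.n_sign_edges == 1

    def test_edges_partitioned_disjointly(self, two_triangles_bridge):
        partition, _ = extract_modules(two_triangles_bridge)
        seen = set()
        for comm in partition.communities:
            for e in comm.edges:
                assert e not in seen
                seen.add(e)

    def test_tie_rule_flips_cutoff(self):
        tri = SignedNetwork([("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
                             ("c", "d", 1), ("d", "e", 1), ("c", "e", 1)])
        stringent, _ = extract_modules(tri, tie_rule="stringent")
        inclusive, _ = extract_modules(tri, tie_rule="inclusive")
        assert stringent.cutoff >= inclusive.cutoff

    def test_planted_block_recovery(self):
        """Modules at the D-max cutoff recover planted blocks."""
        jaccards = []
        for seed in range(5):
            net, labels = balanced_block_network(
                BlockSpec(sizes=(20,) * 4, p_in=0.8, p_out=0.3,
                          sign_noise=0.05, seed=seed))
            _, modules = extract_modules(net, min_genes=3)
            blocks = {}
            for node, b in labels.items():
                blocks.setdefault(b, set()).add(node)
            per_block = []
            for members in blocks.values():
                best = max((len(members & m.genes) / len(members | m.genes)
                            for m in modules), default=0.0)
                per_block.append(best)
            jaccards.append(float(np.mean(per_block)))
        assert float(np.median(jaccards)) >= 0.9


class TestModuleMap:
    def test_balanced_blocks(self, balanced_pair):
        net, labels = balanced_pair
        blocks = {}
        for node, b in labels.items():
            blocks.setdefault(b, set()).add(node)
        mmap = module_map(net, list(blocks.values()))
        assert (mmap.nodes["pos_density"] == 1.0).all()
        assert (mmap.nodes["neg_density"] == 0.0).all()
        assert len(mmap.edges) == 1
        assert mmap.edges.iloc[0].n_links == 9
        assert mmap.edges.iloc[0].prop_negative == 1.0

    def test_worked_example(self, e1):
        mmap = module_map(e1, [{"1", "2", "3"}, {"4", "5"}])
        edge = mmap.edges.iloc[0]
        assert edge.n_links == 4
        assert edge.prop_negative == pytest.approx(3 / 4)

    def test_no_spanning_links_no_meta_edge(self):
        net = SignedNetwork([("a", "b", 1), ("x", "y", 1)])
        mmap = module_map(net, [{"a", "b"}, {"x", "y"}])
        assert len(mmap.edges) == 0
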