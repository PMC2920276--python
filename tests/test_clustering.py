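import networkx as nx
import numpy as np
import pytest

from phylofoot.clustering import (
    ClusteringConfig,
    ScoredCluster,
    autotune_cutoffs,
    build_g3,
    build_similarity_graph,
    cluster_score,
    extend_sites,
    find_quasi_cliques,
    graph_density,
    induce_subgraphs,
    merge_overlapping_sites,
    rank_clusters,
    run_clustering_pipeline,
)
from phylofoot.ensemble import BuiltinGibbsSampler
from phylofoot.genome import Genome, Site
from phylofoot.motifs import motif_similarity
from conftest import consensus_motif, random_motif


class TestSimilarityGraph:
    def test_cutoff_one_gives_edgeless_graph(self, rng):
        ms = [random_motif(rng, f"m{i}") for i in range(5)]
        g = build_similarity_graph(ms, 1.0)
        assert g.number_of_edges() == 0

    def test_identical_motifs_form_triangle(self):
        ms = [consensus_motif("ACGTTGCACGTATGCA", mid=f"m{i}") for i in range(3)]
        g = build_similarity_graph(ms, 0.5)
        assert g.number_of_edges() == 3
        assert all(w == pytest.approx(1.0) for _, _, w in g.edges(data="weight"))

    def test_edges_match_brute_force_oracle(self, rng):
        ms = [random_motif(rng, f"m{i}", n_sites=4) for i in range(30)]
        cutoff = 0.15
        g = build_similarity_graph(ms, cutoff)
        expected = set()
        for i in range(30):
            for j in range(i + 1, 30):
                if motif_similarity(ms[i], ms[j]) > cutoff:
                    expected.add(frozenset((ms[i].id, ms[j].id)))
        got = {frozenset(e) for e in g.edges}
        assert got == expected

    def test_invalid_cutoff(self, rng):
        with pytest.raises(ValueError, match="cutoff"):
            build_similarity_graph([random_motif(rng)], 0.0)


class TestGraphDensity:
    def test_triangle(self):
        g = nx.complete_graph(3)
        assert graph_density(g) == pytest.approx(1.0)

    def test_path(self):
        g = nx.path_graph(3)
        assert graph_density(g) == pytest.approx(2 / 3)

    def test_edgeless(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2])
        assert graph_density(g) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            graph_density(nx.Graph())


class TestAutotune:
    def test_density_monotone_in_cutoff(self, rng):
        ms = [random_motif(rng, f"m{i}", n_sites=3) for i in range(40)]
        from phylofoot.motifs import pairwise_similarity
        from phylofoot.clustering import _density_at
        S = pairwise_similarity(ms)
        densities = [_density_at(S, c) for c in np.linspace(0.05, 0.9, 15)]
        assert all(a >= b - 1e-12 for a, b in zip(densities, densities[1:]))

    def test_degenerate_pool_falls_back_with_warning(self):
        ms = [consensus_motif("ACGTTGCACGTATGCA", mid=f"m{i}") for i in range(6)]
        with pytest.warns(UserWarning, match="midpoint"):
            alpha, beta = autotune_cutoffs(ms)
        assert alpha == pytest.approx(0.25) and beta == pytest.approx(0.40)

    def test_tuned_cutoffs_hit_target_densities(self, rng):
        # an engineered pool: several tight families of varying size, so the
        # density curve is smooth enough to bisect on
        ms = []
        k = 0
        for fam in range(12):
            cons = "".join("ACGT"[b] for b in rng.integers(0, 4, 16))
            for j in range(6):
                sites = []
                for i in range(5):
                    s = list(cons)
                    for p in range(16):
                        if rng.random() < 0.05 + 0.03 * fam:
                            s[p] = "ACGT"[rng.integers(0, 4)]
                    sites.append(Site("g", i * 60, i * 60 + 16, "+", "".join(s)))
                from phylofoot.motifs import BackgroundModel, Motif
                ms.append(Motif(id=f"m{k}", sites=sites,
                                background=BackgroundModel.uniform()))
                k += 1
        from phylofoot.motifs import pairwise_similarity
        from phylofoot.clustering import _density_at
        S = pairwise_similarity(ms)
        target_g1 = float(_density_at(S, 0.25))
        target_g2 = float(_density_at(S, 0.40))
        if target_g1 > _density_at(S, 0.3) and target_g2 > _density_at(S, 0.45):
            alpha, beta = autotune_cutoffs(
                ms, target_density_g1=target_g1,
                target_density_g2=(target_g2, target_g2))
            assert abs(_density_at(S, alpha) - target_g1) <= 0.2 * max(target_g1, 1)
            assert abs(_density_at(S, beta) - target_g2) <= 0.2 * max(target_g2, 1)


class TestBuildG3:
    def test_mean_weight_rule_strictly_greater(self):
        g1 = nx.Graph()
        g1.add_edge("a", "c", weight=0.4)
        g1.add_nodes_from(["b"])
        g3 = build_g3([{"a", "b"}], g1, alpha=0.2)
        # w̄({a,b},{c}) = 0.4/2 = 0.2, not > 0.2
        assert g3.number_of_edges() == 0

    def test_no_g1_edges_no_g3_edge(self):
        g1 = nx.Graph()
        g1.add_nodes_from(["a", "b", "c"])
        g3 = build_g3([{"a"}, {"b"}], g1, alpha=0.1)
        assert g3.number_of_edges() == 0

    def test_singletons_reduce_to_g1_edge_rule(self):
        g1 = nx.Graph()
        g1.add_edge("a", "b", weight=0.5)
        g3 = build_g3([], g1, alpha=0.3)
        assert g3.has_edge(("a",), ("b",))
        assert g3.edges[("a",), ("b",)]["weight"] == 0.5


class TestInduceSubgraphs:
    def test_expansion_conserves_motifs_and_edges(self):
        g1 = nx.Graph()
        g1.add_weighted_edges_from([("a", "b", 0.5), ("b", "c", 0.6), ("c", "d", 0.7)])
        clusters = [{("a", "b"), ("c",)}, {("d",)}]
        subs = induce_subgraphs(g1, clusters)
        assert sorted(sorted(s.nodes) for s in subs) == [["a", "b", "c"], ["d"]]
        assert set(subs[0].edges) == {("a", "b"), ("b", "c")}


class TestQuasiCliques:
    def test_whole_clique_is_one_quasi_clique(self):
        g = nx.complete_graph(5)
        (qc,) = find_quasi_cliques(g)
        assert qc == set(range(5))

    def test_majority_overlap_merges(self):
        # two triangles sharing an edge: cliques {a,b,c} and {b,c,d} share
        # 2 > 0.5*3 nodes -> merged
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("a", "c"), ("b", "c"),
                          ("b", "d"), ("c", "d")])
        (qc,) = find_quasi_cliques(g)
        assert qc == {"a", "b", "c", "d"}

    def test_small_overlap_not_merged(self):
        # two triangles sharing one node: overlap 1 of 3, not a majority
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("a", "c"), ("b", "c"),
                          ("c", "d"), ("c", "e"), ("d", "e")])
        qcs = find_quasi_cliques(g)
        assert len(qcs) == 2

    def test_output_covers_every_node(self, rng):
        for _ in range(10):
            g = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(1 << 30)))
            nx.set_edge_attributes(g, 1.0, "weight")
            covered = set().union(*find_quasi_cliques(g)) if g.number_of_nodes() else set()
            assert covered == set(g.nodes)


def _genome_for_sites():
    rng = np.random.default_rng(77)
    return Genome(id="gm", sequence="".join("ACGT"[b] for b in rng.integers(0, 4, 1000)))


def _site(g, start, end, strand="+"):
    return Site(genome_id=g.id, start=start, end=end, strand=strand,
                seq=g.slice(start, end, strand))


class TestMergeOverlappingSites:
    def test_exactly_eight_bases_not_merged(self):
        g = _genome_for_sites()
        merged = merge_overlapping_sites(
            [_site(g, 100, 116), _site(g, 108, 124)], {"gm": g})
        assert len(merged) == 2

    def test_nine_bases_merged_to_union(self):
        g = _genome_for_sites()
        merged = merge_overlapping_sites(
            [_site(g, 100, 116), _site(g, 107, 123)], {"gm": g})
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (100, 123)
        assert merged[0].seq == g.slice(100, 123, "+")

    def test_disjoint_unchanged(self):
        g = _genome_for_sites()
        merged = merge_overlapping_sites(
            [_site(g, 100, 116), _site(g, 300, 316)], {"gm": g})
        assert len(merged) == 2

    def test_duplicates_collapse(self):
        g = _genome_for_sites()
        merged = merge_overlapping_sites([_site(g, 100, 116)] * 3, {"gm": g})
        assert len(merged) == 1

    def test_transitive_chain(self):
        g = _genome_for_sites()
        merged = merge_overlapping_sites(
            [_site(g, 100, 116), _site(g, 106, 122), _site(g, 112, 128)], {"gm": g})
        assert len(merged) == 1 and (merged[0].start, merged[0].end) == (100, 128)


class TestExtendSites:
    def test_pad_both_ends(self):
        g = _genome_for_sites()
        (ext,) = extend_sites([_site(g, 100, 116)], {"gm": g}, pad=10)
        assert (ext.start, ext.end) == (90, 126)

    def test_clipped_at_origin(self):
        g = _genome_for_sites()
        (ext,) = extend_sites([_site(g, 3, 19)], {"gm": g}, pad=10)
        assert ext.start == 0


class TestClusterScore:
    def test_uniform_motif_scores_zero(self, bg):
        m = consensus_motif("ACGT", n_sites=1)
        # build an exactly-uniform motif: four rotations of ACGT
        from phylofoot.motifs import Motif
        sites = [Site("g", i * 20, i * 20 + 4, "+", s)
                 for i, s in enumerate(["ACGT", "CGTA", "GTAC", "TACG"])]
        m = Motif(id="u", sites=sites, background=bg, delta=0.0)
        assert cluster_score(m, 4, 4) == pytest.approx(0.0, abs=1e-12)

    def test_hard_motif_full_coverage_two_bits(self, bg):
        from phylofoot.motifs import Motif
        sites = [Site("g", i * 30, i * 30 + 8, "+", "ACGTACGT") for i in range(5000)]
        m = Motif(id="h", sites=sites, background=bg)
        assert cluster_score(m, 5000, 5000) == pytest.approx(2.0, abs=0.01)

    def test_linear_in_coverage(self):
        m = consensus_motif("ACGTACGTACGTACGT", n_sites=10)
        assert cluster_score(m, 5, 10) == pytest.approx(cluster_score(m, 10, 10) / 2)

    def test_empty_cluster_rejected(self):
        m = consensus_motif("ACGT")
        with pytest.raises(ValueError):
            cluster_score(m, 0, 0)


class TestRankClusters:
    def _sc(self, cid, score, N):
        g = _genome_for_sites()
        sites = [_site(g, 100 * i, 100 * i + 16) for i in range(N)]
        return ScoredCluster(id=cid, genome_id="gm", sites=sites,
                             best_motif=consensus_motif("ACGTACGTACGTACGT"),
                             score=score)

    def test_descending_scores(self):
        out = rank_clusters([self._sc("a", 0.1, 2), self._sc("b", 0.9, 2)])
        assert [c.id for c in out] == ["b", "a"]
        assert [c.rank for c in out] == [1, 2]

    def test_tie_broken_by_larger_n(self):
        out = rank_clusters([self._sc("a", 0.5, 2), self._sc("b", 0.5, 5)])
        assert [c.id for c in out] == ["b", "a"]

    def test_output_is_permutation(self):
        clusters = [self._sc(f"c{i}", 0.1 * i, 2) for i in range(6)]
        out = rank_clusters(list(clusters))
        assert sorted(c.id for c in out) == sorted(c.id for c in clusters)
        assert sorted(c.rank for c in out) == list(range(1, 7))


class TestPipelineEdgeCases:
    def test_empty_input_empty_output(self):
        res = run_clustering_pipeline([], {}, BuiltinGibbsSampler(), ClusteringConfig())
        assert res.ranked == {}

    def test_config_validates_alpha_beta(self):
        with pytest.raises(ValueError, match="alpha"):
            ClusteringConfig(alpha=0.5, beta=0.4)

    def test_gamma_defaults_to_beta(self):
        cfg = ClusteringConfig(alpha=0.2, beta=0.37)
        assert cfg.gamma == 0.37
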