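import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phylofoot.genome import Gene, Genome, Operon
from phylofoot.orthology import (
    OrthologMap,
    bdbh_orthologs,
    build_scoor,
    build_sequence_sets,
    coors_from_components,
    extract_upstream,
    scoor_graph,
)


def hits(rows):
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue", "bitscore"])


class TestBDBH:
    def test_mutual_best_kept(self):
        ab = hits([("a1", "b1", 1e-30, 200.0)])
        ba = hits([("b1", "a1", 1e-30, 200.0)])
        assert ("a1", "b1") in bdbh_orthologs(ab, ba)

    def test_non_mutual_dropped(self):
        ab = hits([("a1", "b1", 1e-30, 200.0)])
        ba = hits([("b1", "c1", 1e-40, 300.0), ("b1", "a1", 1e-30, 200.0)])
        assert len(bdbh_orthologs(ab, ba)) == 0

    def test_cutoff_excludes_weak_mutual_best(self):
        ab = hits([("a1", "b1", 1e-10, 80.0)])
        ba = hits([("b1", "a1", 1e-10, 80.0)])
        assert len(bdbh_orthologs(ab, ba, evalue_cutoff=1e-20)) == 0

    def test_tie_breaking_by_bitscore_then_id(self):
        ab = hits([("a1", "b2", 1e-30, 100.0), ("a1", "b1", 1e-30, 200.0)])
        ba = hits([("b1", "a1", 1e-30, 200.0)])
        assert ("a1", "b1") in bdbh_orthologs(ab, ba)

    def test_symmetry(self, rng):
        # random reciprocal tables: swapping directions gives the same map
        genes_a = [f"a{i}" for i in range(8)]
        genes_b = [f"b{i}" for i in range(8)]
        rows_ab, rows_ba = [], []
        for qa in genes_a:
            for sb in rng.choice(genes_b, size=3, replace=False):
                e = 10.0 ** -rng.integers(10, 60)
                rows_ab.append((qa, sb, e, 100 + rng.integers(100)))
        for qb in genes_b:
            for sa in rng.choice(genes_a, size=3, replace=False):
                e = 10.0 ** -rng.integers(10, 60)
                rows_ba.append((qb, sa, e, 100 + rng.integers(100)))
        m1 = bdbh_orthologs(hits(rows_ab), hits(rows_ba))
        m2 = bdbh_orthologs(hits(rows_ba), hits(rows_ab))
        assert m1.pairs() == m2.pairs()


def _operon(oid, gid, genes, strand="+", start=0, end=100):
    return Operon(id=oid, genome_id=gid, gene_ids=genes, strand=strand,
                  start=start, end=end)


def _omap(pairs):
    m = OrthologMap()
    for a, b in pairs:
        m.add(a, b)
    return m


class TestBuildScoor:
    def test_no_orthologs_gives_singleton(self):
        seed = _operon("o1", "gA", ["a1", "a2"])
        ops = {"gA": [seed], "gB": [_operon("o2", "gB", ["b1"])]}
        s = build_scoor(seed, ops, _omap([]))
        assert s.members == {"o1"}

    @pytest.mark.parametrize("covered,recruited", [
        (3, True),    # 3/4 >= 0.5
        (2, True),    # exactly 50% qualifies ("at least 50%")
        (1, False),   # 1/4 < 0.5
    ])
    def test_coverage_fraction_rule(self, covered, recruited):
        seed = _operon("o1", "gA", ["a1", "a2", "a3", "a4"])
        cand = _operon("o2", "gB", ["b1", "b2", "b3", "b4"])
        ops = {"gA": [seed], "gB": [cand]}
        pairs = [(f"a{i+1}", f"b{i+1}") for i in range(covered)]
        s = build_scoor(seed, ops, _omap(pairs))
        assert ("o2" in s.members) == recruited

    def test_best_candidate_by_ortholog_count(self):
        seed = _operon("o1", "gA", ["a1", "a2", "a3", "a4"])
        c2 = _operon("p2", "gB", ["b1", "b2"])
        c3 = _operon("p3", "gB", ["c1", "c2", "c3"])
        ops = {"gA": [seed], "gB": [c2, c3]}
        pairs = [("a1", "b1"), ("a2", "b2"), ("a1", "c1")]
        # p2 covers 2 seed genes, p3 covers 1 -> p2 wins (and only one recruited)
        s = build_scoor(seed, ops, _omap(pairs + [("a2", "c2"), ("a3", "c3")]))
        assert "p3" in s.members and "p2" not in s.members  # p3 covers 3 > 2
        s = build_scoor(seed, ops, _omap(pairs))
        assert "p2" in s.members and "p3" not in s.members


class TestScoorGraph:
    def _scoors(self, member_sets):
        from phylofoot.orthology import SCOOR
        return [SCOOR(seed_operon=f"s{i}", members=set(ms))
                for i, ms in enumerate(member_sets)]

    def test_full_containment_edge(self):
        g = scoor_graph(self._scoors([{"o1", "o2", "o3"},
                                      {"o1", "o2", "o3", "o4", "o5"}]))
        assert g.number_of_edges() == 1

    def test_low_containment_no_edge(self):
        g = scoor_graph(self._scoors([{"o1", "o2", "o3"},
                                      {"o1", "o4", "o5", "o6"}]))
        # shares 1 of 3 -> 1/3 < 0.7 (seed operon ids s0, s1 included in members)
        assert g.number_of_edges() == 0

    def test_disjoint_no_edge(self):
        g = scoor_graph(self._scoors([{"o1", "o2"}, {"o3", "o4"}]))
        assert g.number_of_edges() == 0

    def test_lower_containment_never_shrinks_coors(self):
        rng = np.random.default_rng(0)
        universe = [f"o{i}" for i in range(12)]
        sets = [set(rng.choice(universe, size=rng.integers(2, 6), replace=False))
                for _ in range(10)]
        scoors = self._scoors(sets)
        sizes = {}
        for frac in (0.9, 0.7, 0.5, 0.3):
            coors = coors_from_components(scoor_graph(scoors, frac))
            sizes[frac] = sorted(len(c.operons) for c in coors)
        assert max(sizes[0.3]) >= max(sizes[0.9])


class TestCoorsFromComponents:
    def test_edgeless_gives_singletons(self):
        from phylofoot.orthology import SCOOR
        g = scoor_graph([SCOOR(seed_operon=f"s{i}", members={f"s{i}"}) for i in range(4)])
        coors = coors_from_components(g)
        assert len(coors) == 4
        assert all(len(c.operons) == 1 for c in coors)

    def test_path_becomes_one_coor(self):
        g = nx.Graph()
        for i, members in enumerate([{"a", "b"}, {"b", "c"}, {"c", "d"}]):
            g.add_node(f"s{i}", members=frozenset(members))
        g.add_edge("s0", "s1")
        g.add_edge("s1", "s2")
        (coor,) = coors_from_components(g)
        assert coor.operons == {"a", "b", "c", "d"}

    def test_matches_union_find_oracle(self, rng):
        # random SCOOR graphs vs a hand-rolled union-find
        for _ in range(30):
            n = int(rng.integers(2, 40))
            g = nx.gnp_random_graph(n, 0.08, seed=int(rng.integers(1 << 30)))
            relabel = {i: f"s{i}" for i in g.nodes}
            g = nx.relabel_nodes(g, relabel)
            for node in g.nodes:
                g.nodes[node]["members"] = frozenset({node.replace("s", "o")})
            parent = {v: v for v in g.nodes}

            def find(v):
                while parent[v] != v:
                    parent[v] = parent[parent[v]]
                    v = parent[v]
                return v

            for u, v in g.edges:
                parent[find(u)] = find(v)
            expected = {}
            for v in g.nodes:
                expected.setdefault(find(v), set()).add(v)
            got = {frozenset(c.member_scoors) for c in coors_from_components(g)}
            assert got == {frozenset(s) for s in expected.values()}

    def test_operon_to_coor_is_partition(self, small_bundle):
        from phylofoot.pipeline import build_coors
        b = small_bundle
        build = build_coors(b.genomes, b.operons_by_genome, b.hit_tables)
        seen = {}
        for coor in build.coors:
            for op in coor.operons:
                assert op not in seen, "operon assigned to two COORs"
                seen[op] = coor.id
        assert set(seen) == set(b.operons)


class TestExtractUpstream:
    def _genome(self, length=6000):
        g = Genome(id="g", sequence="".join(
            "ACGT"[i % 4] for i in range(length)))
        return g

    def test_plus_strand_bounded_by_previous_gene(self):
        g = self._genome()
        g.add_gene(Gene(id="prev", genome_id="g", start=1000, end=1500, strand="+"))
        g.add_gene(Gene(id="x", genome_id="g", start=2000, end=2500, strand="+"))
        op = Operon(id="op", genome_id="g", gene_ids=["x"], strand="+", start=2000, end=2500)
        site = extract_upstream(op, g)
        assert (site.start, site.end, len(site)) == (1500, 2000, 500)

    def test_operon_at_origin_linear_none(self):
        g = self._genome()
        g.add_gene(Gene(id="x", genome_id="g", start=0, end=500, strand="+"))
        op = Operon(id="op", genome_id="g", gene_ids=["x"], strand="+", start=0, end=500)
        assert extract_upstream(op, g) is None

    def test_truncation_to_max_len(self):
        g = self._genome(9000)
        g.add_gene(Gene(id="prev", genome_id="g", start=2000, end=3000, strand="+"))
        g.add_gene(Gene(id="x", genome_id="g", start=5000, end=5600, strand="+"))
        op = Operon(id="op", genome_id="g", gene_ids=["x"], strand="+", start=5000, end=5600)
        site = extract_upstream(op, g)
        assert (site.start, site.end) == (4200, 5000)

    def test_circular_genome_clips_at_origin(self):
        # Site intervals are strictly linear, so even on a circular replicon
        # the upstream region stops at the origin
        g = Genome(id="g", sequence="".join("ACGT"[i % 4] for i in range(3000)),
                   topology="circular")
        g.add_gene(Gene(id="x", genome_id="g", start=100, end=700, strand="+"))
        g.add_gene(Gene(id="y", genome_id="g", start=2500, end=2900, strand="+"))
        op = Operon(id="op", genome_id="g", gene_ids=["x"], strand="+", start=100, end=700)
        site = extract_upstream(op, g, max_len=800)
        assert (site.start, site.end) == (0, 100)

    def test_minus_strand_reads_downstream_gap(self):
        g = self._genome()
        g.add_gene(Gene(id="x", genome_id="g", start=1000, end=1600, strand="-"))
        g.add_gene(Gene(id="nxt", genome_id="g", start=2100, end=2600, strand="+"))
        op = Operon(id="op", genome_id="g", gene_ids=["x"], strand="-", start=1000, end=1600)
        site = extract_upstream(op, g)
        assert (site.start, site.end, site.strand) == (1600, 2100, "-")
        assert site.seq == g.slice(1600, 2100, "-")


class TestBuildSequenceSets:
    def test_small_coor_dropped(self, small_bundle):
        from phylofoot.orthology import COOR
        b = small_bundle
        ops = {op.id: op for ops_ in b.operons_by_genome.values() for op in ops_}
        two = COOR(id="c", operons=set(list(ops)[:2]), member_scoors=set())
        assert build_sequence_sets([two], ops, b.genomes) == []

    def test_full_coor_kept(self, small_bundle):
        from phylofoot.pipeline import build_coors
        b = small_bundle
        build = build_coors(b.genomes, b.operons_by_genome, b.hit_tables)
        assert all(len(ss.entries) >= 3 for ss in build.sequence_sets)
        assert all(0 < len(site) <= 800 for ss in build.sequence_sets
                   for _, site in ss.entries)
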