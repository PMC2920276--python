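"""The motif graph-clustering cascade.

Input motifs from the footprinting ensemble are mostly spurious; true
motifs recur — across finders on one sequence set and across related
sequence sets. The cascade therefore filters instead of merely
partitioning:

A. two similarity graphs: G1 (loose cutoff α, keeps almost everything)
   and G2 (tight cutoff β, sparse enough to cluster); MCL cuts G2.
B. G3 re-links the G2 clusters and the motifs only present in G1, using
   mean G1 edge weight between groups; MCL cuts G3, and each G3 cluster
   induces a subgraph of G1.
C. quasi-cliques inside each induced subgraph pool their sites; a finder
   recovers one motif per quasi-clique; graph G4 over those at cutoff γ,
   cut by MCL.
D. sites of each G4 cluster are merged, padded and re-searched at a wider
   width ("extended motifs"); graph G5 at γ, cut by MCL.
E. each G5 cluster's sites are partitioned by genome; per genome-specific
   set a finder picks the best motif at an automatic width, and per-genome
   graphs at γ are cut by MCL.
F. each per-genome cluster is refined (several widths, overlapping calls
   merged into a unique site set) and ranked by its ClusterScore.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .ensemble import FinderAdapter, stable_seed
from .genome import Genome, Site
from .mcl import mcl
from .motifs import (
    DEFAULT_COLUMN_THRESHOLD,
    BackgroundModel,
    Motif,
    motif_similarity,
    pairwise_similarity,
)

__all__ = [
    "ClusteringConfig",
    "ScoredCluster",
    "build_similarity_graph",
    "graph_density",
    "autotune_cutoffs",
    "build_g3",
    "induce_subgraphs",
    "find_quasi_cliques",
    "merge_overlapping_sites",
    "quasi_clique_motif",
    "extend_and_refind",
    "genome_specific_stage",
    "refine_cluster",
    "cluster_score",
    "rank_clusters",
    "run_clustering_pipeline",
    "PipelineResult",
]

log = logging.getLogger(__name__)


@dataclass
class ClusteringConfig:
    """Cutoffs and stage parameters of the cascade.

    α and β are the loose/tight similarity cutoffs of G1 and G2 (α < β);
    γ, the cutoff for the later-stage graphs, defaults to β.
    """

    alpha: float = 0.30
    beta: float = 0.45
    gamma: float | None = None
    inflation: float = 2.0
    expansion: int = 2
    prune: float = 1e-5
    max_iter: int = 100
    tau: float = DEFAULT_COLUMN_THRESHOLD
    target_density_g1: float = 500.0
    target_density_g2: tuple[float, float] = (15.0, 20.0)
    overlap_merge: int = 8        # sites merge when they overlap MORE than this
    extension_pad: int = 10       # bases added on each side at stage D
    extended_width: int = 22
    refine_widths: tuple[int, int] = (8, 22)
    max_refine_motifs: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma is None:
            self.gamma = self.beta
        if not self.alpha < self.beta:
            raise ValueError("alpha must be smaller than beta")

    def _mcl(self, graph: nx.Graph):
        return mcl(graph, self.inflation, self.expansion, self.prune, self.max_iter)


@dataclass
class ScoredCluster:
    """A final per-genome predicted motif: its unique site set, best motif
    and ClusterScore."""

    id: str
    genome_id: str
    sites: list[Site]       # the unique merged site set (N sequences)
    best_motif: Motif       # best motif found in the cluster (n sites, width L)
    score: float
    rank: int = -1
    stage: str = "final"

    @property
    def n(self) -> int:
        return self.best_motif.n_sites

    @property
    def N(self) -> int:
        return len(self.sites)

    @property
    def L(self) -> int:
        return self.best_motif.width


# ---------------------------------------------------------------------------
# stage A: similarity graphs


def build_similarity_graph(
    motifs: list[Motif],
    cutoff: float,
    tau: float = DEFAULT_COLUMN_THRESHOLD,
    S: np.ndarray | None = None,
) -> nx.Graph:
    """Graph with an edge wherever S(M_x, M_y) > cutoff (weight = S).

    Only motifs incident to at least one edge become nodes — an isolated
    motif has no supporting recurrence and carries no information for the
    cascade. A precomputed all-pairs matrix ``S`` may be supplied.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    if S is None:
        S = pairwise_similarity(motifs, tau)
    g = nx.Graph()
    n = len(motifs)
    ii, jj = np.nonzero(np.triu(S, 1) > cutoff)
    for i, j in zip(ii, jj):
        g.add_edge(motifs[i].id, motifs[j].id, weight=float(S[i, j]))
    return g


def graph_density(g: nx.Graph) -> float:
    """Edges per node."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty node set")
    return g.number_of_edges() / g.number_of_nodes()


def _density_at(S: np.ndarray, cutoff: float) -> float:
    upper = np.triu(S, 1) > cutoff
    nodes = int((upper | upper.T).any(axis=0).sum())
    return upper.sum() / nodes if nodes else 0.0


def autotune_cutoffs(
    motifs: list[Motif],
    target_density_g1: float = 500.0,
    target_density_g2: tuple[float, float] = (15.0, 20.0),
    alpha_range: tuple[float, float] = (0.2, 0.3),
    beta_range: tuple[float, float] = (0.35, 0.45),
    tau: float = DEFAULT_COLUMN_THRESHOLD,
) -> tuple[float, float]:
    """Bisect the similarity cutoff against graph density to hit the target
    densities for G1 and G2, constrained to the usual working ranges; falls
    back to the range midpoints with a warning when a target is unattainable
    inside its range (density is monotone non-increasing in the cutoff)."""
    S = pairwise_similarity(motifs, tau)

    def tune(lo: float, hi: float, target: float) -> float | None:
        if _density_at(S, lo) < target or _density_at(S, hi) > target:
            return None
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if _density_at(S, mid) > target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    alpha = tune(*alpha_range, target_density_g1)
    if alpha is None:
        alpha = 0.5 * sum(alpha_range)
        warnings.warn("G1 target density unattainable in range; using midpoint alpha")
    g2_target = 0.5 * sum(target_density_g2)
    beta = tune(*beta_range, g2_target)
    if beta is None:
        beta = 0.5 * sum(beta_range)
        warnings.warn("G2 target density unattainable in range; using midpoint beta")
    return alpha, beta


# ---------------------------------------------------------------------------
# stage B: G3 over clusters + leftover nodes


def build_g3(
    g2_clusters: list[set[str]], g1: nx.Graph, alpha: float
) -> nx.Graph:
    """Graph over G2 clusters plus the motifs present only in G1.

    Node pair (u, v) is linked when the mean G1 edge weight between their
    member sets, w̄ = Σ w_xy / (|u|·|v|) over existing G1 edges, exceeds α.
    Nodes are sorted tuples of motif ids (deterministic independent of the
    process hash seed).
    """
    clustered = set().union(*g2_clusters) if g2_clusters else set()
    leftovers = sorted(v for v in g1.nodes if v not in clustered)
    groups = [tuple(sorted(c)) for c in g2_clusters] + [(v,) for v in leftovers]
    g3 = nx.Graph()
    g3.add_nodes_from(groups)
    for i, u in enumerate(groups):
        for v in groups[i + 1:]:
            total = 0.0
            for x in u:
                for y in v:
                    if g1.has_edge(x, y):
                        total += g1.edges[x, y]["weight"]
            wbar = total / (len(u) * len(v))
            if wbar > alpha:
                g3.add_edge(u, v, weight=wbar)
    return g3


def induce_subgraphs(g1: nx.Graph, g3_clusters: list[set[tuple]]) -> list[nx.Graph]:
    """For each G3 cluster, the G1 subgraph induced by all underlying
    motif ids (cluster-nodes expanded to their members)."""
    out = []
    for cluster in g3_clusters:
        members: set[str] = set()
        for node in cluster:
            members |= set(node)
        out.append(g1.subgraph(members).copy())
    return out


# ---------------------------------------------------------------------------
# stage C: quasi-cliques


def _greedy_clique(g: nx.Graph, start) -> set:
    clique = {start}
    neighbors = sorted(
        g[start].items(), key=lambda kv: (-kv[1].get("weight", 1.0), str(kv[0]))
    )
    for u, _ in neighbors:
        if all(g.has_edge(u, v) for v in clique if v != u):
            clique.add(u)
    return clique


def find_quasi_cliques(s: nx.Graph, majority: float = 0.5) -> list[set]:
    """Per-node greedy maximal cliques, transitively merged whenever two
    cliques share more than ``majority`` of the smaller one's nodes."""
    nodes = sorted(s.nodes, key=str)
    cliques = []
    seen = set()
    for v in nodes:
        c = frozenset(_greedy_clique(s, v))
        if c not in seen:
            seen.add(c)
            cliques.append(c)
    merge = nx.Graph()
    merge.add_nodes_from(range(len(cliques)))
    for i in range(len(cliques)):
        for j in range(i + 1, len(cliques)):
            shared = len(cliques[i] & cliques[j])
            if shared > majority * min(len(cliques[i]), len(cliques[j])):
                merge.add_edge(i, j)
    out = []
    for comp in nx.connected_components(merge):
        out.append(set().union(*(cliques[k] for k in comp)))
    return sorted(out, key=lambda qs: sorted(map(str, qs))[0])


def merge_overlapping_sites(
    sites: list[Site],
    genomes: dict[str, Genome],
    min_overlap_exclusive: int = 8,
) -> list[Site]:
    """Transitively merge same-genome, same-strand sites overlapping by MORE
    than ``min_overlap_exclusive`` bases into their union interval, with the
    sequence re-extracted from the genome. Duplicates collapse first."""
    unique = {}
    for s in sites:
        unique[(s.genome_id, s.start, s.end, s.strand)] = s
    by_group: dict[tuple[str, str], list[Site]] = {}
    for s in unique.values():
        by_group.setdefault((s.genome_id, s.strand), []).append(s)
    merged = []
    for (gid, strand), group in sorted(by_group.items()):
        group.sort(key=lambda s: (s.start, s.end))
        cur_start, cur_end = group[0].start, group[0].end
        for s in group[1:]:
            if min(cur_end, s.end) - max(cur_start, s.start) > min_overlap_exclusive:
                cur_end = max(cur_end, s.end)
                cur_start = min(cur_start, s.start)
            else:
                merged.append(_extract(gid, cur_start, cur_end, strand, genomes))
                cur_start, cur_end = s.start, s.end
        merged.append(_extract(gid, cur_start, cur_end, strand, genomes))
    merged.sort(key=lambda s: (s.genome_id, s.start, s.end, s.strand))
    return merged


def _extract(gid: str, start: int, end: int, strand: str, genomes: dict[str, Genome]) -> Site:
    return Site(genome_id=gid, start=start, end=end, strand=strand,
                seq=genomes[gid].slice(start, end, strand), source="merged")


def quasi_clique_motif(
    qc_sites: list[Site],
    finder: FinderAdapter,
    genomes: dict[str, Genome],
    width: int,
    seed: int,
    overlap_merge: int = 8,
) -> tuple[Motif | None, list[Site]]:
    """Pool a quasi-clique's sites, merge overlaps, and recover the single
    best motif from the merged set. Returns (motif, merged sequence set);
    degenerate sets (fewer than 2 merged sequences) pass the pooled sites
    through as a directly-built motif."""
    merged = merge_overlapping_sites(qc_sites, genomes, overlap_merge)
    if len(merged) < 2:
        usable = [s for s in qc_sites if "N" not in s.seq]
        if not usable:
            return None, merged
        w = min(len(s) for s in usable)
        trimmed = [
            s if len(s) == w else Site(s.genome_id, s.start, s.start + w, s.strand,
                                       genomes[s.genome_id].slice(s.start, s.start + w, s.strand),
                                       s.source)
            for s in usable
        ]
        bg = BackgroundModel.from_sequences([s.seq for s in trimmed])
        return Motif(id="qc", sites=trimmed, background=bg, origin=("quasi-clique",)), merged
    found = finder.find(merged, width, 1, seed)
    return (found[0] if found else None), merged


# ---------------------------------------------------------------------------
# stage D: extension


def extend_sites(
    sites: list[Site], genomes: dict[str, Genome], pad: int = 10
) -> list[Site]:
    """Pad each site by ``pad`` bases of flanking genome sequence on both
    ends, clipped at the sequence bounds."""
    out = []
    for s in sites:
        start = max(0, s.start - pad)
        end = min(len(genomes[s.genome_id]), s.end + pad)
        out.append(_extract(s.genome_id, start, end, s.strand, genomes))
    return out


def extend_and_refind(
    cluster_sites: list[Site],
    genomes: dict[str, Genome],
    finder: FinderAdapter,
    seed: int,
    pad: int = 10,
    width: int = 22,
    overlap_merge: int = 8,
) -> tuple[Motif | None, list[Site]]:
    """Merge a cluster's overlapping sites, extend them, and search for the
    best wide ("extended") motif; returns (motif, extended sequence set)."""
    merged = merge_overlapping_sites(cluster_sites, genomes, overlap_merge)
    extended = extend_sites(merged, genomes, pad)
    usable = [s for s in extended if len(s) >= width and "N" not in s.seq]
    if len(usable) < 2:
        return None, extended
    found = finder.find(usable, width, 1, seed)
    return (found[0] if found else None), extended


# ---------------------------------------------------------------------------
# stages E-F: genome-specific clustering, refinement, scoring


def genome_specific_stage(
    g5_cluster_sites: list[list[Site]],
    finder: FinderAdapter,
    genomes: dict[str, Genome],
    gamma: float,
    config: "ClusteringConfig",
) -> dict[str, list[list[Site]]]:
    """Partition each cluster's sites by genome, find one best motif per
    genome-specific set (automatic width), then per genome cluster those
    motifs at cutoff γ with MCL. Returns per-genome lists of site pools."""
    lo, hi = config.refine_widths
    per_genome_motifs: dict[str, list[tuple[Motif, list[Site]]]] = {}
    for ci, sites in enumerate(g5_cluster_sites):
        by_genome: dict[str, list[Site]] = {}
        for s in sites:
            by_genome.setdefault(s.genome_id, []).append(s)
        for gid, gsites in sorted(by_genome.items()):
            merged = merge_overlapping_sites(gsites, genomes, config.overlap_merge)
            usable = [s for s in merged if "N" not in s.seq]
            if len(usable) < 2:
                continue
            widths = range(lo, min(hi, min(len(s) for s in usable)) + 1)
            if not widths:
                continue
            seed = stable_seed(config.seed, "stageE", f"c{ci}", gid)
            # a coarse width scan is enough when only the best motif is kept
            found = finder.find_auto(usable, widths, 1, seed, width_step=2)
            if found:
                per_genome_motifs.setdefault(gid, []).append((found[0], merged))
    out: dict[str, list[list[Site]]] = {}
    for gid, pairs in sorted(per_genome_motifs.items()):
        motifs = [m for m, _ in pairs]
        pools = {m.id + f"#{k}": pool for k, (m, pool) in enumerate(pairs)}
        for k, m in enumerate(motifs):
            m.id = m.id + f"#{k}"
        if len(motifs) == 1:
            out[gid] = [pairs[0][1]]
            continue
        graph = build_similarity_graph(motifs, gamma, config.tau)
        clusters: list[set[str]] = list(config._mcl(graph)) if graph.number_of_nodes() else []
        clustered = set().union(*clusters) if clusters else set()
        for m in motifs:  # motifs isolated at γ keep their own cluster
            if m.id not in clustered:
                clusters.append({m.id})
        pools_out = []
        for cl in clusters:
            pool: list[Site] = []
            for mid in sorted(cl):
                pool.extend(pools[mid])
            pools_out.append(pool)
        out[gid] = pools_out
    return out


def refine_cluster(
    cluster_sites: list[Site],
    finder: FinderAdapter,
    genomes: dict[str, Genome],
    seed: int,
    width_range: tuple[int, int] = (8, 22),
    max_motifs: int = 15,
    overlap_merge: int = 8,
) -> tuple[list[Site], Motif | None]:
    """Refine one per-genome cluster into its final unique site set.

    Up to ``max_motifs`` motifs of different widths are found in the
    cluster's sequences; the sites they cover are merged (overlapping and
    redundant calls collapse) into the final predicted site set. The best
    motif is kept for scoring."""
    merged = merge_overlapping_sites(cluster_sites, genomes, overlap_merge)
    usable = [s for s in merged if "N" not in s.seq]
    if len(usable) < 2:
        return merged, None
    lo, hi = width_range
    widths = range(lo, min(hi, min(len(s) for s in usable)) + 1)
    found = finder.find_auto(usable, widths, max_motifs, seed)
    if not found:
        return merged, None
    covered = [s for m in found for s in m.sites]
    final_sites = merge_overlapping_sites(covered, genomes, overlap_merge)
    return final_sites, found[0]


def cluster_score(best_motif: Motif, n: int, N: int) -> float:
    """ClusterScore = (n/N) · (1/L) · Σ_i Σ_b p(b,i)·P(b,i).

    Coverage fraction of the cluster times the mean per-column information
    content of its best motif (bits); higher scores mark clusters more
    likely to be true motifs."""
    if N <= 0:
        raise ValueError("cluster with no sequences")
    L = best_motif.width
    ic = float((best_motif.p * best_motif.P).sum())
    return (n / N) * ic / L


def rank_clusters(scored: list[ScoredCluster]) -> list[ScoredCluster]:
    """Descending ClusterScore; ties broken by larger N, then cluster id."""
    out = sorted(scored, key=lambda c: (-c.score, -c.N, c.id))
    for r, c in enumerate(out, start=1):
        c.rank = r
    return out


# ---------------------------------------------------------------------------
# the full cascade


@dataclass
class PipelineResult:
    ranked: dict[str, list[ScoredCluster]]
    checkpoints: dict[str, dict] = field(default_factory=dict)

    def all_final_sites(self, genome_id: str | None = None) -> list[Site]:
        sites = []
        for gid, clusters in self.ranked.items():
            if genome_id is not None and gid != genome_id:
                continue
            for c in clusters:
                sites.extend(c.sites)
        return sites


def _cluster_site_pool(cluster_ids, motif_by_id) -> list[Site]:
    pool = []
    for mid in sorted(cluster_ids):
        pool.extend(motif_by_id[mid].sites)
    return pool


def run_clustering_pipeline(
    input_motifs: list[Motif],
    genomes: dict[str, Genome],
    finder: FinderAdapter,
    config: ClusteringConfig | None = None,
) -> PipelineResult:
    """Run stages A through F on a collection of input motifs."""
    config = config or ClusteringConfig()
    result = PipelineResult(ranked={})
    ck = result.checkpoints
    if not input_motifs:
        return result
    motif_by_id = {m.id: m for m in input_motifs}

    # A: G1/G2 and MCL on G2
    S = pairwise_similarity(input_motifs, config.tau)
    g1 = build_similarity_graph(input_motifs, config.alpha, config.tau, S=S)
    g2 = build_similarity_graph(input_motifs, config.beta, config.tau, S=S)
    ck["A"] = {"n_input": len(input_motifs),
               "g1_nodes": g1.number_of_nodes(), "g1_edges": g1.number_of_edges(),
               "g2_nodes": g2.number_of_nodes(), "g2_edges": g2.number_of_edges()}
    if g1.number_of_nodes() == 0:
        return result
    g2_clusters = list(config._mcl(g2)) if g2.number_of_nodes() else []

    # B: G3 and its clusters; induced subgraphs of G1
    g3 = build_g3(g2_clusters, g1, config.alpha)
    g3_clusters = list(config._mcl(g3)) if g3.number_of_nodes() else []
    subgraphs = [s for s in induce_subgraphs(g1, g3_clusters) if s.number_of_nodes()]
    ck["B"] = {"g3_nodes": g3.number_of_nodes(), "n_subgraphs": len(subgraphs)}

    # C: quasi-cliques -> quasi-clique-specific motifs -> G4
    qc_records = []  # (motif, merged site pool)
    for si, s in enumerate(subgraphs):
        for qi, qc in enumerate(find_quasi_cliques(s)):
            pool = _cluster_site_pool(qc, motif_by_id)
            seed = stable_seed(config.seed, "stageC", f"s{si}", f"q{qi}")
            m, merged = quasi_clique_motif(
                pool, finder, genomes, width=input_motifs[0].width,
                seed=seed, overlap_merge=config.overlap_merge,
            )
            if m is not None:
                m.id = f"qc_s{si}_q{qi}"
                m.origin = ("quasi-clique", si, qi)
                qc_records.append((m, merged))
    ck["C"] = {"n_quasi_cliques": len(qc_records)}
    if not qc_records:
        return result
    qc_motifs = [m for m, _ in qc_records]
    qc_pool = {m.id: merged for m, merged in qc_records}
    g4 = build_similarity_graph(qc_motifs, config.gamma, config.tau)
    g4_clusters = list(config._mcl(g4)) if g4.number_of_nodes() else []
    clustered = set().union(*g4_clusters) if g4_clusters else set()
    g4_clusters += [{m.id} for m in qc_motifs if m.id not in clustered]

    # D: extend and re-find at the wider width -> G5
    ext_records = []
    for ci, cl in enumerate(g4_clusters):
        pool = [s for mid in sorted(cl) for s in qc_pool[mid]]
        seed = stable_seed(config.seed, "stageD", f"c{ci}")
        m, extended = extend_and_refind(
            pool, genomes, finder, seed, pad=config.extension_pad,
            width=config.extended_width, overlap_merge=config.overlap_merge,
        )
        if m is not None:
            m.id = f"ext_c{ci}"
            m.origin = ("extended", ci)
            ext_records.append((m, extended))
    ck["D"] = {"n_extended": len(ext_records)}
    if not ext_records:
        return result
    ext_motifs = [m for m, _ in ext_records]
    g5 = build_similarity_graph(ext_motifs, config.gamma, config.tau)
    g5_clusters = list(config._mcl(g5)) if g5.number_of_nodes() else []
    clustered = set().union(*g5_clusters) if g5_clusters else set()
    g5_clusters += [{m.id} for m in ext_motifs if m.id not in clustered]

    # E: genome-specific partition and per-genome clustering
    ext_by_id = {m.id: m for m in ext_motifs}
    g5_site_pools = [
        [s for mid in sorted(cl) for s in ext_by_id[mid].sites] for cl in g5_clusters
    ]
    per_genome = genome_specific_stage(g5_site_pools, finder, genomes, config.gamma, config)
    ck["E"] = {gid: len(pools) for gid, pools in per_genome.items()}

    # F: refine, score, rank
    for gid, pools in sorted(per_genome.items()):
        scored = []
        for ci, pool in enumerate(pools):
            seed = stable_seed(config.seed, "stageF", gid, f"c{ci}")
            final_sites, best = refine_cluster(
                pool, finder, genomes, seed, width_range=config.refine_widths,
                max_motifs=config.max_refine_motifs, overlap_merge=config.overlap_merge,
            )
            if best is None or not final_sites:
                continue
            n = min(best.n_sites, len(final_sites))
            score = cluster_score(best, n, len(final_sites))
            scored.append(ScoredCluster(
                id=f"{gid}_c{ci}", genome_id=gid, sites=final_sites,
                best_motif=best, score=score,
            ))
        result.ranked[gid] = rank_clusters(scored)
    ck["F"] = {gid: len(cl) for gid, cl in result.ranked.items()}
    return result
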