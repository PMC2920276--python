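"""Orthology, operon clustering and upstream sequence extraction.

Orthologs between genome pairs come from bi-directional best hits (BDBH) on
protein-similarity tables. Each operon seeds a SCOOR (semi-cluster of operons
with orthologous relationships) by recruiting, from every other genome, the
operon that contains orthologs of at least half of the seed's genes. SCOORs
that mostly contain one another are connected, and each connected component
of that graph is a COOR — the unit from which one upstream inter-operonic
sequence set is extracted for motif finding.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .genome import Genome, Operon, Site

__all__ = [
    "read_hit_table",
    "bdbh_orthologs",
    "OrthologMap",
    "SCOOR",
    "COOR",
    "build_scoor",
    "scoor_graph",
    "coors_from_components",
    "extract_upstream",
    "SequenceSet",
    "build_sequence_sets",
    "write_sequence_set_fasta",
]

log = logging.getLogger(__name__)

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hit_table(path) -> pd.DataFrame:
    """Read a BLAST outfmt-6-like TSV ('#'-header); only qseqid, sseqid,
    evalue and bitscore are consumed downstream."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected '#'-prefixed header line")
        names = header.lstrip("#").strip().split("\t")
        df = pd.read_csv(io.StringIO(fh.read()), sep="\t", names=names, header=None)
    for col in ("qseqid", "sseqid", "evalue", "bitscore"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return df


class OrthologMap:
    """One-to-one cross-genome gene pairing from BDBH."""

    def __init__(self) -> None:
        self._pairs: set[frozenset[str]] = set()
        self._partner: dict[str, dict[str, str]] = {}  # gene -> {other fields}

    def add(self, a: str, b: str) -> None:
        self._pairs.add(frozenset((a, b)))

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def pairs(self) -> set[frozenset[str]]:
        return set(self._pairs)

    def partner_map(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for p in self._pairs:
            a, b = tuple(p)
            out.setdefault(a, set()).add(b)
            out.setdefault(b, set()).add(a)
        return out

    def update(self, other: "OrthologMap") -> None:
        self._pairs |= other._pairs


def _best_hits(df: pd.DataFrame, cutoff: float) -> dict[str, str]:
    """Best subject per query: min E-value, then max bitscore, then
    lexicographically smallest subject id."""
    kept = df[df["evalue"] <= cutoff]
    best: dict[str, tuple[float, float, str]] = {}
    for q, s, e, b in zip(kept["qseqid"], kept["sseqid"], kept["evalue"], kept["bitscore"]):
        key = (float(e), -float(b), str(s))
        if q not in best or key < best[q]:
            best[q] = key
    return {q: key[2] for q, key in best.items()}


def bdbh_orthologs(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame, evalue_cutoff: float = 1e-20
) -> OrthologMap:
    """Bi-directional best hits at an E-value cutoff applied in both
    directions. The resulting map is one-to-one within the genome pair."""
    ab = _best_hits(hits_ab, evalue_cutoff)
    ba = _best_hits(hits_ba, evalue_cutoff)
    out = OrthologMap()
    for a, b in ab.items():
        if ba.get(b) == a:
            out.add(a, b)
    return out


@dataclass
class SCOOR:
    """A seed operon plus at most one recruited orthologous operon per
    other genome."""

    seed_operon: str
    members: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.members.add(self.seed_operon)


@dataclass
class COOR:
    id: str
    operons: set[str]
    member_scoors: set[str]


def _ortholog_index(orthologs: OrthologMap) -> dict[str, set[str]]:
    return orthologs.partner_map()


def _syntenic_run(seed: Operon, candidate: Operon, partners: dict[str, set[str]]) -> int:
    """Length of the longest run of consecutive seed genes whose orthologs
    occupy consecutive positions of the candidate operon."""
    cand_pos = {g: i for i, g in enumerate(candidate.gene_ids)}
    best = run = 0
    prev_pos: int | None = None
    for g in seed.gene_ids:
        pos = None
        for p in partners.get(g, ()):
            if p in cand_pos:
                pos = cand_pos[p]
                break
        if pos is None:
            run, prev_pos = 0, None
            continue
        if prev_pos is not None and abs(pos - prev_pos) == 1:
            run += 1
        else:
            run = 1
        prev_pos = pos
        best = max(best, run)
    return best


def build_scoor(
    seed: Operon,
    operons_by_genome: dict[str, list[Operon]],
    orthologs: OrthologMap,
    min_frac: float = 0.5,
) -> SCOOR:
    """Recruit, from each other genome, the operon covering orthologs of at
    least ``min_frac`` of the seed's genes (ties: longest syntenic run, then
    lexicographic operon id)."""
    partners = _ortholog_index(orthologs)
    scoor = SCOOR(seed_operon=seed.id)
    gene_to_operon: dict[str, dict[str, Operon]] = {}
    for gid, ops in operons_by_genome.items():
        gene_to_operon[gid] = {}
        for op in ops:
            for g in op.gene_ids:
                gene_to_operon[gid][g] = op

    for genome_id, gmap in gene_to_operon.items():
        if genome_id == seed.genome_id:
            continue
        coverage: dict[str, set[str]] = {}  # operon id -> covered seed genes
        by_id = {op.id: op for op in operons_by_genome[genome_id]}
        for g in seed.gene_ids:
            for p in partners.get(g, ()):
                op = gmap.get(p)
                if op is not None:
                    coverage.setdefault(op.id, set()).add(g)
        candidates = [
            oid for oid, covered in coverage.items()
            if len(covered) >= min_frac * seed.n_genes
        ]
        if not candidates:
            continue
        candidates.sort(
            key=lambda oid: (
                -len(coverage[oid]),
                -_syntenic_run(seed, by_id[oid], partners),
                oid,
            )
        )
        scoor.members.add(candidates[0])
    return scoor


def scoor_graph(scoors: list[SCOOR], containment_frac: float = 0.7) -> nx.Graph:
    """Undirected graph over SCOORs: edge when the larger one contains at
    least ``containment_frac`` of the smaller one's operons."""
    g = nx.Graph()
    for s in scoors:
        g.add_node(s.seed_operon, members=frozenset(s.members))
    items = sorted(g.nodes(data="members"))
    for i, (u, mu) in enumerate(items):
        for v, mv in items[i + 1:]:
            small = min(len(mu), len(mv))
            if len(mu & mv) >= containment_frac * small:
                g.add_edge(u, v)
    return g


def coors_from_components(graph: nx.Graph) -> list[COOR]:
    """One COOR per connected component; ids are deterministic (sorted by the
    minimum member operon id)."""
    comps = []
    for comp in nx.connected_components(graph):
        operons: set[str] = set()
        for node in comp:
            operons |= set(graph.nodes[node]["members"])
        comps.append((min(sorted(operons)), comp, operons))
    comps.sort(key=lambda t: t[0])
    return [
        COOR(id=f"coor_{i:04d}", operons=operons, member_scoors=set(comp))
        for i, (_, comp, operons) in enumerate(comps)
    ]


def extract_upstream(
    operon: Operon, genome: Genome, max_len: int = 800
) -> Site | None:
    """Up-to-``max_len``-base upstream inter-operonic sequence of an operon.

    The region runs from the operon's transcription start back to the nearest
    annotated gene boundary on either strand (genes of the operon itself
    excluded), truncated to the ``max_len`` bases closest to the operon.
    Regions are clipped at the sequence origin/end — a ``Site`` interval is
    strictly linear — so an operon at position 0 has no upstream sequence
    even on a circular replicon. Returns None when empty.
    """
    member = set(operon.gene_ids)
    others = [g for g in genome.genes.values() if g.id not in member]
    L = len(genome)
    if operon.strand == "+":
        bounds = [g.end for g in others if g.end <= operon.start]
        boundary = max(bounds) if bounds else 0
        start = max(boundary, operon.start - max_len)
        end = operon.start
        strand = "+"
    else:
        bounds = [g.start for g in others if g.start >= operon.end]
        boundary = min(bounds) if bounds else L
        start = operon.end
        end = min(boundary, operon.end + max_len)
        strand = "-"
    if end - start <= 0:
        return None
    return Site(genome_id=genome.id, start=start, end=end, strand=strand,
                seq=genome.slice(start, end, strand), source=f"upstream:{operon.id}")


@dataclass
class SequenceSet:
    """The upstream sequences of one COOR's operons (≥3 for motif finding)."""

    coor_id: str
    entries: list[tuple[str, Site]]  # (operon id, upstream site)


def build_sequence_sets(
    coors: list[COOR],
    operons: dict[str, Operon],
    genomes: dict[str, Genome],
    min_seqs: int = 3,
    max_len: int = 800,
) -> list[SequenceSet]:
    """One sequence set per COOR with at least ``min_seqs`` non-empty
    upstream extracts; smaller COORs are dropped (logged)."""
    out = []
    for coor in coors:
        entries = []
        for oid in sorted(coor.operons):
            op = operons[oid]
            site = extract_upstream(op, genomes[op.genome_id], max_len=max_len)
            if site is not None:
                entries.append((oid, site))
        if len(entries) >= min_seqs:
            out.append(SequenceSet(coor_id=coor.id, entries=entries))
        else:
            log.info("dropping %s: only %d non-empty upstream sequences", coor.id, len(entries))
    return out


def write_sequence_set_fasta(path, ss: SequenceSet) -> None:
    with open(path, "w") as fh:
        for oid, site in ss.entries:
            fh.write(
                f">{site.genome_id}|{oid}|{site.start}-{site.end}({site.strand})\n{site.seq}\n"
            )
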