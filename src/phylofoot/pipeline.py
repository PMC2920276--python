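"""End-to-end convenience wrappers: bundle -> COORs -> motifs -> ranking."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .clustering import ClusteringConfig, PipelineResult, run_clustering_pipeline
from .ensemble import BuiltinGibbsSampler, EnsembleConfig, collect_input_motifs
from .genome import Genome, Operon
from .motifs import Motif
from .orthology import (
    OrthologMap,
    SequenceSet,
    bdbh_orthologs,
    build_scoor,
    build_sequence_sets,
    coors_from_components,
    scoor_graph,
)

log = logging.getLogger(__name__)


@dataclass
class CoorBuild:
    orthologs: OrthologMap
    coors: list
    sequence_sets: list[SequenceSet]


def build_coors(
    genomes: dict[str, Genome],
    operons_by_genome: dict[str, list[Operon]],
    hit_tables: dict[tuple[str, str], pd.DataFrame],
    evalue_cutoff: float = 1e-20,
    min_ortholog_frac: float = 0.5,
    containment_frac: float = 0.7,
    min_seqs: int = 3,
    upstream_len: int = 800,
) -> CoorBuild:
    """Orthology, SCOOR/COOR construction and upstream sequence extraction
    for a genome group."""
    orthologs = OrthologMap()
    ids = sorted(genomes)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if (a, b) in hit_tables and (b, a) in hit_tables:
                orthologs.update(
                    bdbh_orthologs(hit_tables[(a, b)], hit_tables[(b, a)], evalue_cutoff)
                )
    scoors = []
    for gid in ids:
        for op in operons_by_genome[gid]:
            scoors.append(build_scoor(op, operons_by_genome, orthologs, min_ortholog_frac))
    graph = scoor_graph(scoors, containment_frac)
    coors = coors_from_components(graph)
    all_operons = {op.id: op for ops in operons_by_genome.values() for op in ops}
    seq_sets = build_sequence_sets(coors, all_operons, genomes,
                                   min_seqs=min_seqs, max_len=upstream_len)
    return CoorBuild(orthologs=orthologs, coors=coors, sequence_sets=seq_sets)


def predict_group(
    genomes: dict[str, Genome],
    operons_by_genome: dict[str, list[Operon]],
    hit_tables: dict[tuple[str, str], pd.DataFrame],
    ensemble: EnsembleConfig | None = None,
    clustering: ClusteringConfig | None = None,
    seed: int = 0,
) -> tuple[PipelineResult, list[Motif], CoorBuild]:
    """Run the whole method on a genome group.

    Returns the per-genome ranked clusters, the input-motif collection and
    the COOR build (for evaluation against the upstream regions).
    """
    ensemble = ensemble or EnsembleConfig(seed=seed)
    clustering = clustering or ClusteringConfig(seed=seed)
    build = build_coors(genomes, operons_by_genome, hit_tables)
    log.info("%d COORs, %d sequence sets", len(build.coors), len(build.sequence_sets))
    input_motifs = collect_input_motifs(build.sequence_sets, ensemble)
    log.info("%d input motifs", len(input_motifs))
    finder = BuiltinGibbsSampler(name="stage-finder", restarts=2)
    result = run_clustering_pipeline(input_motifs, genomes, finder, clustering)
    return result, input_motifs, build
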