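"""Synthetic genome groups with planted regulatory motifs.

The generator emulates the statistical structure the method relies on:
a group of related genomes whose orthologous operons carry conserved
binding sites of a handful of regulators in their upstream inter-operonic
regions, embedded in i.i.d. background sequence. Every file format the
pipeline consumes is emitted, plus a ground-truth site table in the
known-site format so the evaluation stage runs unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    Gene,
    Genome,
    KnownSiteTable,
    Operon,
    Site,
    reverse_complement,
    write_known_sites,
    write_operon_table,
)

__all__ = ["FixtureConfig", "GroupBundle", "generate_group", "sample_pwm_site", "plant_site"]

BASES = "ACGT"


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic genome group.

    Defaults describe a small but fully structured group: five related
    genomes, sixty orthologous operon families (hence about sixty COORs),
    four planted motifs with near-consensus (2-bit) columns each regulating
    a quarter of the operons, and 5% per-base divergence of planted sites
    between genomes.
    """

    n_genomes: int = 5
    n_operons: int = 60
    genes_per_operon: tuple[int, int] = (1, 4)
    gene_length: tuple[int, int] = (300, 900)
    intergenic_length: tuple[int, int] = (250, 600)
    n_planted_motifs: int = 4
    motif_width: int = 16
    column_info_bits: float = 2.0
    coor_fraction: float = 0.25
    placement_margin: int = 20
    mutation_rate: float = 0.05
    gc_content: float = 0.5
    n_extra_tf_families: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation rate must be in [0, 1)")
        for name in ("n_genomes", "n_operons", "n_planted_motifs", "motif_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.intergenic_length[0] < self.motif_width + 2 * self.placement_margin:
            raise ValueError("intergenic space too small for the planted motif width")


@dataclass
class GroupBundle:
    """Everything a pipeline run needs, in memory."""

    genomes: dict[str, Genome]
    operons: dict[str, Operon]
    operons_by_genome: dict[str, list[Operon]]
    hit_tables: dict[tuple[str, str], pd.DataFrame]
    tf_table: pd.DataFrame
    truth: KnownSiteTable
    planted_pwms: dict[str, np.ndarray] = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for gid, genome in self.genomes.items():
            with open(out / f"{gid}.fa", "w") as fh:
                fh.write(f">{gid}\n")
                for i in range(0, len(genome.sequence), 70):
                    fh.write(genome.sequence[i: i + 70] + "\n")
            with open(out / f"{gid}.genes.tsv", "w") as fh:
                fh.write("#gene_id\tgenome_id\tstart\tend\tstrand\tprotein_id\n")
                for g in genome.genes.values():
                    fh.write(f"{g.id}\t{gid}\t{g.start + 1}\t{g.end}\t{g.strand}\t{g.protein_id}\n")
        write_operon_table(out / "operons.tsv", list(self.operons.values()))
        for (a, b), df in self.hit_tables.items():
            with open(out / f"hits_{a}_vs_{b}.tsv", "w") as fh:
                fh.write("#" + "\t".join(df.columns) + "\n")
                df.to_csv(fh, sep="\t", header=False, index=False)
        with open(out / "tf_families.tsv", "w") as fh:
            fh.write("#genome_id\ttf_family_id\n")
            self.tf_table.to_csv(fh, sep="\t", header=False, index=False)
        write_known_sites(out / "truth_sites.tsv", self.truth)


def sample_pwm_site(pwm: np.ndarray, rng: np.random.Generator) -> str:
    """Draw one site from a (4, w) column probability matrix."""
    cols = pwm / pwm.sum(axis=0, keepdims=True)
    return "".join(BASES[rng.choice(4, p=cols[:, i])] for i in range(pwm.shape[1]))


def plant_site(seq: str, site: str, position: int) -> str:
    """Substitute (not insert) ``site`` into ``seq`` at ``position``."""
    if position < 0 or position + len(site) > len(seq):
        raise ValueError("site does not fit at this position")
    return seq[:position] + site + seq[position + len(site):]


def _planted_pwm(width: int, info_bits: float, rng: np.random.Generator) -> np.ndarray:
    """A (4, width) PWM whose columns carry roughly ``info_bits`` bits:
    2-bit columns are consensus columns; lower values spread probability
    onto the non-consensus bases."""
    major = min(1.0, info_bits / 2.0) if info_bits < 2.0 else 1.0
    pwm = np.full((4, width), (1 - major) / 3)
    consensus = rng.integers(0, 4, size=width)
    pwm[consensus, np.arange(width)] = major
    return pwm


def _mutate(site: str, rate: float, rng: np.random.Generator) -> str:
    out = list(site)
    for i, c in enumerate(out):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in BASES if b != c])
    return "".join(out)


def generate_group(cfg: FixtureConfig) -> GroupBundle:
    """Generate a complete synthetic genome group; byte-identical given the
    same configuration (the seed is part of the configuration)."""
    rng = np.random.default_rng(cfg.seed)
    genome_ids = [f"g{i}" for i in range(cfg.n_genomes)]

    # shared operon templates: gene counts, lengths, strands, gaps
    ops_genes = [int(rng.integers(*cfg.genes_per_operon, endpoint=True))
                 for _ in range(cfg.n_operons)]
    ops_strand = [rng.choice(["+", "-"]) for _ in range(cfg.n_operons)]
    gene_lengths = [
        [int(rng.integers(*cfg.gene_length, endpoint=True)) for _ in range(k)]
        for k in ops_genes
    ]
    gaps = [int(rng.integers(*cfg.intergenic_length, endpoint=True))
            for _ in range(cfg.n_operons + 1)]

    # regulon structure: which operon templates carry which motif
    pwms = {
        f"motif_{m}": _planted_pwm(cfg.motif_width, cfg.column_info_bits, rng)
        for m in range(cfg.n_planted_motifs)
    }
    per_motif = max(1, int(round(cfg.coor_fraction * cfg.n_operons)))
    order = list(rng.permutation(cfg.n_operons))
    carriers: dict[int, list[str]] = {}
    pos = 0
    for name in pwms:
        for t in order[pos: pos + per_motif]:
            carriers.setdefault(t, []).append(name)
        pos += per_motif
        if pos >= cfg.n_operons:
            pos = 0  # regulons may overlap if fractions exceed the genome
    ancestral = {
        (name, t): sample_pwm_site(pwms[name], rng)
        for t, names in carriers.items() for name in names
    }

    genomes: dict[str, Genome] = {}
    operons: dict[str, Operon] = {}
    operons_by_genome: dict[str, list[Operon]] = {g: [] for g in genome_ids}
    truth = KnownSiteTable()
    p_bg = np.array([(1 - cfg.gc_content) / 2, cfg.gc_content / 2,
                     cfg.gc_content / 2, (1 - cfg.gc_content) / 2])

    for gid in genome_ids:
        # layout: [gap] genes [gap] genes ... [gap]; one operon per template
        parts: list[str] = []
        cursor = 0
        genes: list[Gene] = []
        op_records = []  # (template index, gene ids, strand, first_start, last_end)
        upstream_iv: dict[int, tuple[int, int]] = {}
        for t in range(cfg.n_operons):
            gap = gaps[t]
            bg = "".join(rng.choice(list(BASES), size=gap, p=p_bg))
            parts.append(bg)
            gap_start, gap_end = cursor, cursor + gap
            cursor += gap
            gene_ids = []
            first_start = cursor
            for slot in range(ops_genes[t]):
                glen = gene_lengths[t][slot]
                gene_seq = "".join(rng.choice(list(BASES), size=glen, p=p_bg))
                parts.append(gene_seq)
                gene_id = f"{gid}_op{t:03d}_{slot}"
                genes.append(Gene(id=gene_id, genome_id=gid, start=cursor,
                                  end=cursor + glen, strand=ops_strand[t],
                                  protein_id=gene_id))
                gene_ids.append(gene_id)
                cursor += glen
                if slot < ops_genes[t] - 1:
                    spacer = int(rng.integers(3, 20))
                    parts.append("".join(rng.choice(list(BASES), size=spacer, p=p_bg)))
                    cursor += spacer
            op_records.append((t, gene_ids, ops_strand[t], first_start, cursor))
            if ops_strand[t] == "+":
                upstream_iv[t] = (gap_start, gap_end)
        tail = gaps[cfg.n_operons]
        parts.append("".join(rng.choice(list(BASES), size=tail, p=p_bg)))
        trailing_start = cursor
        cursor += tail
        sequence = "".join(parts)

        # '-' operons read their upstream region from the following gap
        for k, (t, _, strand, _, last_end) in enumerate(op_records):
            if strand == "-":
                nxt = op_records[k + 1][3] if k + 1 < len(op_records) else cursor
                upstream_iv[t] = (last_end, nxt)

        # plant motif sites inside upstream regions (adjacent operons can
        # share a gap, so placement is checked genome-wide)
        placed: list[tuple[int, int]] = []
        for t in sorted(carriers):
            lo, hi = upstream_iv[t]
            for name in carriers[t]:
                site_seq = _mutate(ancestral[(name, t)], cfg.mutation_rate, rng)
                w = cfg.motif_width
                for _attempt in range(200):
                    p0 = int(rng.integers(lo + cfg.placement_margin,
                                          hi - w - cfg.placement_margin + 1))
                    if all(p0 + w <= a or p0 >= b for a, b in placed):
                        break
                else:
                    raise ValueError("infeasible packing: upstream region too crowded")
                placed.append((p0, p0 + w))
                strand = ops_strand[t]
                forward = site_seq if strand == "+" else reverse_complement(site_seq)
                sequence = plant_site(sequence, forward, p0)
                truth.rows.append((
                    name,
                    Site(genome_id=gid, start=p0, end=p0 + w, strand=strand,
                         seq=site_seq, source="planted"),
                ))

        genome = Genome(id=gid, sequence=sequence)
        for g in genes:
            genome.add_gene(g)
        genomes[gid] = genome
        for t, gene_ids, strand, first_start, last_end in op_records:
            ordered = gene_ids if strand == "+" else list(reversed(gene_ids))
            op = Operon(id=f"{gid}_op{t:03d}", genome_id=gid, gene_ids=ordered,
                        strand=strand, start=first_start, end=last_end)
            operons[op.id] = op
            operons_by_genome[gid].append(op)

    # hit tables consistent with the gene-family ground truth
    hit_tables = {}
    for a in genome_ids:
        for b in genome_ids:
            if a == b:
                continue
            rows = []
            for t in range(cfg.n_operons):
                for slot in range(ops_genes[t]):
                    qa, sb = f"{a}_op{t:03d}_{slot}", f"{b}_op{t:03d}_{slot}"
                    rows.append((qa, sb, 98.0, 300, 1, 0, 1, 300, 1, 300, 1e-50, 500.0))
                    # weak cross-family noise hit, never competitive
                    other = (t + 7) % cfg.n_operons
                    if slot < ops_genes[other]:
                        rows.append((qa, f"{b}_op{other:03d}_{slot}",
                                     30.0, 120, 60, 3, 1, 120, 1, 120, 1e-3, 45.0))
            hit_tables[(a, b)] = pd.DataFrame(rows, columns=[
                "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                "qstart", "qend", "sstart", "send", "evalue", "bitscore",
            ])

    # TF-presence table: the planted regulators (all genomes) plus extra
    # families whose presence decays with the genome's index distance
    tf_rows = []
    for name in pwms:
        for gid in genome_ids:
            tf_rows.append((gid, name))
    for j in range(cfg.n_extra_tf_families):
        anchor = j % cfg.n_genomes
        for i, gid in enumerate(genome_ids):
            if rng.random() < 0.9 ** (abs(i - anchor) + 1) + 0.05:
                tf_rows.append((gid, f"tf{j:02d}"))
    tf_table = pd.DataFrame(tf_rows, columns=["genome_id", "tf_family_id"])

    return GroupBundle(
        genomes=genomes, operons=operons, operons_by_genome=operons_by_genome,
        hit_tables=hit_tables, tf_table=tf_table, truth=truth, planted_pwms=pwms,
    )
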