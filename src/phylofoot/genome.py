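"""Core genomic data types and file I/O.

Internal coordinates are 0-based half-open throughout the package; every
on-disk table uses 1-based inclusive coordinates (the GFF/DOOR convention).
All TSV formats carry a header line beginning with ``#``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Genome",
    "Gene",
    "Operon",
    "Site",
    "KnownSiteTable",
    "reverse_complement",
    "read_genome_fasta",
    "read_annotation_table",
    "read_annotation_gff3",
    "read_operon_table",
    "write_operon_table",
    "read_known_sites",
    "write_known_sites",
]

_IUPAC = set("ACGTRYSWKMBDHVN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (N maps to N)."""
    return str(Seq(seq).reverse_complement())


@dataclass
class Gene:
    """An annotated gene: 0-based half-open interval on one strand."""

    id: str
    genome_id: str
    start: int
    end: int
    strand: str
    protein_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.id}: bad interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """A single replicon: uppercase DNA over {A,C,G,T,N}, linear by default."""

    id: str
    sequence: str
    topology: str = "linear"
    genes: dict[str, Gene] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"genome {self.id}: empty sequence")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"genome {self.id}: topology must be linear or circular")

    def __len__(self) -> int:
        return len(self.sequence)

    def add_gene(self, gene: Gene) -> None:
        if gene.id in self.genes:
            raise ValueError(f"duplicate gene id {gene.id} in genome {self.id}")
        if gene.end > len(self.sequence):
            raise ValueError(f"gene {gene.id} extends past genome {self.id} end")
        self.genes[gene.id] = gene

    def slice(self, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end); reverse-complemented when strand is '-'.

        On a circular genome the interval may wrap the origin (start > end).
        """
        if start <= end:
            s = self.sequence[start:end]
        else:
            if self.topology != "circular":
                raise ValueError("wrapping slice on a linear genome")
            s = self.sequence[start:] + self.sequence[:end]
        return reverse_complement(s) if strand == "-" else s


@dataclass
class Operon:
    """An ordered run of same-strand genes transcribed as one unit."""

    id: str
    genome_id: str
    gene_ids: list[str]
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"operon {self.id}: no genes")
        if self.strand not in "+-":
            raise ValueError(f"operon {self.id}: strand must be + or -")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class Site:
    """A located DNA segment (predicted or known TFBS).

    ``seq`` is the strand-oriented sequence: for strand '-' it equals the
    reverse complement of the genome slice [start, end).
    """

    genome_id: str
    start: int
    end: int
    strand: str
    seq: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq):
            raise ValueError("site length does not match its interval")
        if self.strand not in "+-":
            raise ValueError("site strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Site") -> int:
        """Bases of genomic overlap with another site (strand-agnostic)."""
        if self.genome_id != other.genome_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class KnownSiteTable:
    """Rows of (motif name, Site) — the evaluation reference."""

    rows: list[tuple[str, Site]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def motif_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for name, _ in self.rows:
            seen.setdefault(name)
        return list(seen)

    def sites_of(self, motif_name: str) -> list[Site]:
        return [s for n, s in self.rows if n == motif_name]

    def all_sites(self) -> list[Site]:
        return [s for _, s in self.rows]


def _clean_sequence(raw: str, where: str) -> str:
    seq = raw.upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"{where}: illegal characters {sorted(bad)}")
    # ambiguity codes other than N carry no information for motif finding
    return "".join(c if c in "ACGT" else "N" for c in seq)


def read_genome_fasta(path, multi: bool = False):
    """Read a genome FASTA file.

    One record per file by default; ``multi=True`` accepts a multi-record
    file and returns a list of Genomes.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    if len(records) > 1 and not multi:
        raise ValueError(
            f"{path}: {len(records)} records; pass multi=True to accept a multi-record file"
        )
    genomes = [
        Genome(id=r.id, sequence=_clean_sequence(str(r.seq), r.id)) for r in records
    ]
    return genomes if multi else genomes[0]


def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected '#'-prefixed header line")
        names = header.lstrip("#").strip().split("\t")
        df = pd.read_csv(
            io.StringIO(fh.read()), sep="\t", names=names, dtype=str, comment="#",
            header=None, skip_blank_lines=True,
        )
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_annotation_table(path, genome: Genome) -> None:
    """Load a PTT-like annotation TSV into ``genome`` (in place).

    Columns: gene_id, genome_id, start, end (1-based inclusive), strand,
    protein_id.
    """
    df = _read_tsv(path, ["gene_id", "genome_id", "start", "end", "strand", "protein_id"])
    for row in df.itertuples(index=False):
        if row.genome_id != genome.id:
            continue
        genome.add_gene(
            Gene(
                id=row.gene_id,
                genome_id=row.genome_id,
                start=int(row.start) - 1,
                end=int(row.end),
                strand=row.strand,
                protein_id=row.protein_id,
            )
        )


def read_annotation_gff3(path, genome: Genome) -> None:
    """Load gene features from a GFF3 file into ``genome`` (in place).

    Only ``gene``/``CDS`` lines are consumed; the ID attribute names the gene
    and protein_id (when present) names its product.
    """
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in ("gene", "CDS"):
                continue
            seqid, _, _, start, end, _, strand, _, attrs = parts[:9]
            if seqid != genome.id:
                continue
            kv = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            gid = kv.get("ID")
            if gid is None:
                raise ValueError(f"{path}: feature without ID attribute")
            if gid in genome.genes:
                continue
            genome.add_gene(
                Gene(
                    id=gid,
                    genome_id=seqid,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    protein_id=kv.get("protein_id", gid),
                )
            )


def operon_from_genes(op_id: str, genome: Genome, gene_ids: list[str], strand: str) -> Operon:
    """Build and validate an Operon from member gene ids."""
    genes = []
    for gid in gene_ids:
        if gid not in genome.genes:
            raise ValueError(f"operon {op_id}: gene {gid} absent from annotation of {genome.id}")
        genes.append(genome.genes[gid])
    strands = {g.strand for g in genes}
    if strands != {strand}:
        raise ValueError(f"operon {op_id}: mixed or mismatched strands {sorted(strands)}")
    start = min(g.start for g in genes)
    end = max(g.end for g in genes)
    coords = [g.start for g in genes]
    ordered = coords == sorted(coords) if strand == "+" else coords == sorted(coords, reverse=True)
    if not ordered:
        raise ValueError(f"operon {op_id}: gene order inconsistent with coordinates")
    return Operon(id=op_id, genome_id=genome.id, gene_ids=list(gene_ids), strand=strand,
                  start=start, end=end)


def read_operon_table(path, genomes: dict[str, Genome]) -> list[Operon]:
    """Read a DOOR-like operon TSV.

    Columns: operon_id, genome_id, gene_ids (comma-joined, transcription
    order), strand. Coordinates are resolved against the annotation.
    """
    df = _read_tsv(path, ["operon_id", "genome_id", "gene_ids", "strand"])
    operons = []
    for row in df.itertuples(index=False):
        if row.genome_id not in genomes:
            raise ValueError(f"{path}: unknown genome {row.genome_id}")
        operons.append(
            operon_from_genes(
                row.operon_id, genomes[row.genome_id], row.gene_ids.split(","), row.strand
            )
        )
    return operons


def write_operon_table(path, operons: list[Operon]) -> None:
    with open(path, "w") as fh:
        fh.write("#operon_id\tgenome_id\tgene_ids\tstrand\n")
        for op in operons:
            fh.write(f"{op.id}\t{op.genome_id}\t{','.join(op.gene_ids)}\t{op.strand}\n")


def read_known_sites(path, genomes: dict[str, Genome]) -> KnownSiteTable:
    """Read a known-TFBS TSV (motif_name, genome_id, start, end, strand,
    sequence; 1-based inclusive) and validate each site against its genome."""
    df = _read_tsv(path, ["motif_name", "genome_id", "start", "end", "strand", "sequence"])
    table = KnownSiteTable()
    for row in df.itertuples(index=False):
        if not row.motif_name:
            raise ValueError(f"{path}: empty motif name")
        genome = genomes[row.genome_id]
        start, end = int(row.start) - 1, int(row.end)
        expected = genome.slice(start, end, row.strand)
        if expected != row.sequence.upper():
            raise ValueError(
                f"{path}: sequence mismatch for {row.motif_name} at "
                f"{row.genome_id}:{start}-{end}({row.strand})"
            )
        table.rows.append(
            (row.motif_name,
             Site(genome_id=row.genome_id, start=start, end=end, strand=row.strand,
                  seq=expected, source="known"))
        )
    return table


def write_known_sites(path, table: KnownSiteTable) -> None:
    with open(path, "w") as fh:
        fh.write("#motif_name\tgenome_id\tstart\tend\tstrand\tsequence\n")
        for name, s in table.rows:
            fh.write(f"{name}\t{s.genome_id}\t{s.start + 1}\t{s.end}\t{s.strand}\t{s.seq}\n")
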