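"""Canonical in-memory genome model and readers/writers for external formats.

Coordinates are 1-based inclusive externally (GFF3 convention); gene *ranks*
(order indices along a chromosome) are 0-based internally.  All gene-distance
arithmetic downstream uses ranks, never base pairs, except co-localization
spans which are reported in bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "Gene",
    "Genome",
    "AnnotationTable",
    "OGCTable",
    "ScoredHit",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_hits_table",
    "write_hits_table",
    "read_cluster_table",
    "write_cluster_table",
    "read_annotation_table",
    "write_annotation_table",
    "trim_terminal_codon",
    "translate_cds",
]


@dataclass
class Gene:
    """One protein-coding gene with its coordinates and sequences.

    ``rank`` is the 0-based order index of the gene along its chromosome
    (by start position); it is assigned by :class:`Genome` construction,
    not read from any file.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    rank: int = -1
    cds: str = ""
    protein: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            logger.warning(
                "gene %s: unknown strand %r, treating as '+'",
                self.gene_id,
                self.strand,
            )
            self.strand = "+"

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def has_sequence(self) -> bool:
        return bool(self.cds)


@dataclass
class Genome:
    """An ordered collection of genes grouped by chromosome.

    ``group`` is a free-form label used for cluster classification
    (e.g. ``"cactus"`` / ``"noncactus"``).
    """

    species: str
    group: str = "default"
    chromosomes: dict[str, list[Gene]] = field(default_factory=dict)
    _index: dict[str, Gene] = field(default_factory=dict, repr=False)

    @classmethod
    def from_genes(cls, species: str, genes: Iterable[Gene], group: str = "default") -> "Genome":
        """Build a genome from an unordered gene list.

        Genes are sorted by (chromosome, start, end, gene_id) — ties in start
        broken by end then id for determinism — and ranks assigned 0..n-1
        per chromosome.
        """
        genome = cls(species=species, group=group)
        by_chrom: dict[str, list[Gene]] = {}
        for g in genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        for chrom in sorted(by_chrom):
            ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
            for rank, g in enumerate(ordered):
                g.rank = rank
            genome.chromosomes[chrom] = ordered
        genome._reindex()
        return genome

    def _reindex(self) -> None:
        self._index = {}
        for genes in self.chromosomes.values():
            for g in genes:
                if g.gene_id in self._index:
                    raise ValueError(f"duplicate gene id {g.gene_id} in genome {self.species}")
                self._index[g.gene_id] = g

    def genes(self) -> Iterator[Gene]:
        for chrom in self.chromosomes:
            yield from self.chromosomes[chrom]

    def __len__(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __getitem__(self, gene_id: str) -> Gene:
        try:
            return self._index[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id} in genome {self.species}") from None

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes()]


@dataclass
class AnnotationTable:
    """Functional-term assignments (GO or KEGG): gene_id -> set of terms."""

    namespace: str = "GO"
    assignments: dict[str, set[str]] = field(default_factory=dict)

    def terms_for(self, gene_id: str) -> set[str]:
        return self.assignments.get(gene_id, set())

    def add(self, gene_id: str, term: str) -> None:
        if not term:
            raise ValueError(f"empty term for gene {gene_id}")
        self.assignments.setdefault(gene_id, set()).add(term)


@dataclass
class OGCTable:
    """Orthologous gene clusters: cluster_id -> species -> member gene ids.

    ``species_groups`` labels each species with its comparison group.
    """

    clusters: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    species_groups: dict[str, str] = field(default_factory=dict)

    def members(self, cluster_id: str) -> list[str]:
        """All gene ids in a cluster, across species."""
        out: list[str] = []
        for genes in self.clusters[cluster_id].values():
            out.extend(genes)
        return out

    def species_present(self, cluster_id: str) -> set[str]:
        return {sp for sp, genes in self.clusters[cluster_id].items() if genes}

    def __len__(self) -> int:
        return len(self.clusters)

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for cid, per_sp in self.clusters.items():
            for genes in per_sp.values():
                for g in genes:
                    if g in seen:
                        raise ValueError(f"gene {g} assigned to clusters {seen[g]} and {cid}")
                    seen[g] = cid


@dataclass(frozen=True)
class ScoredHit:
    """One pairwise similarity hit (BLAST-tabular-compatible)."""

    query: str
    subject: str
    score: float
    identity: float = 0.0


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, nucleotide: bool = False) -> dict[str, str]:
    """Read a FASTA file into an order-preserving id -> sequence map.

    Ids are the first whitespace-delimited token of the header.  Sequences
    are uppercased; in nucleotide mode U is converted to T.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if nucleotide:
            seq = seq.replace("U", "T")
        if rec.id in out:
            raise ValueError(f"duplicate id {rec.id}")
        out[rec.id] = seq
    return out


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# CDS helpers

def trim_terminal_codon(cds: str) -> str:
    """Trim an incomplete terminal codon, and a terminal stop codon if present."""
    cds = cds[: len(cds) - len(cds) % 3]
    if len(cds) >= 3 and cds[-3:] in ("TAA", "TAG", "TGA"):
        cds = cds[:-3]
    return cds


def translate_cds(cds: str) -> str:
    """Translate a trimmed CDS with the standard code, up to the first stop.

    Internal stops are tolerated (annotation pipelines emit them); the
    protein is truncated there and the caller may flag the gene.
    """
    prot = str(Seq(cds).translate())
    stop = prot.find("*")
    return prot if stop < 0 else prot[:stop]


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(
    path: str | Path,
    cds_map: dict[str, str] | None = None,
    protein_map: dict[str, str] | None = None,
    species: str | None = None,
    group: str = "default",
    feature_types: tuple[str, ...] = ("gene", "mRNA"),
) -> Genome:
    """Read gene features from a GFF3 file into a :class:`Genome`.

    Genes are matched to CDS/protein sequences by their ``ID`` attribute.
    Records with start > end are dropped with a warning; genes lacking a CDS
    are retained sequence-less.  When both ``gene`` and ``mRNA`` features
    exist, ``gene`` features are preferred (mRNA ids would duplicate them).
    """
    from gffutils.iterators import DataIterator

    cds_map = cds_map or {}
    protein_map = protein_map or {}
    species = species or Path(path).stem

    raw: list[tuple[str, str, int, int, str]] = []
    seen_types: set[str] = set()
    n_dropped = 0
    for feat in DataIterator(str(path)):
        if feat.featuretype not in feature_types:
            continue
        seen_types.add(feat.featuretype)
        gid = feat.attributes.get("ID", [feat.id or ""])[0]
        if feat.start > feat.end:
            n_dropped += 1
            logger.warning("dropping record %s: start %d > end %d", gid, feat.start, feat.end)
            continue
        raw.append((feat.featuretype, gid, feat.start, feat.end, feat))
    if n_dropped:
        logger.warning("dropped %d records with start > end", n_dropped)

    use_type = "gene" if "gene" in seen_types else (next(iter(seen_types)) if seen_types else "gene")
    genes = []
    for ftype, gid, start, end, feat in raw:
        if ftype != use_type:
            continue
        cds = trim_terminal_codon(cds_map.get(gid, ""))
        protein = protein_map.get(gid, "") or (translate_cds(cds) if cds else "")
        genes.append(
            Gene(
                gene_id=gid,
                chromosome=feat.seqid,
                start=start,
                end=end,
                strand=feat.strand if feat.strand in ("+", "-") else "?",
                cds=cds,
                protein=protein,
            )
        )
    return Genome.from_genes(species, genes, group=group)


def write_gff3(path: str | Path, genome: Genome) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genome.genes():
            fh.write(
                f"{gene.chromosome}\tpaleodup\tgene\t{gene.start}\t{gene.end}"
                f"\t.\t{gene.strand}\t.\tID={gene.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

_BLAST6_NCOL = 12


def read_hits_table(path: str | Path) -> list[ScoredHit]:
    """Read a 12-column BLAST tabular file (outfmt 6 dialect).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Score is taken from the bitscore column,
    identity from pident (percent, converted to a fraction).
    """
    hits: list[ScoredHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _BLAST6_NCOL:
                raise ValueError(f"line {lineno}: expected {_BLAST6_NCOL} columns, got {len(parts)}")
            try:
                pident = float(parts[2])
                score = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            hits.append(ScoredHit(query=parts[0], subject=parts[1], score=score, identity=pident / 100.0))
    return hits


def write_hits_table(path: str | Path, hits: Iterable[ScoredHit]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.identity * 100:.2f}\t0\t0\t0\t0\t0\t0\t0\t0\t{h.score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Cluster table (TSV: cluster_id, then species:gene1,gene2 columns)

def read_cluster_table(path: str | Path, species_groups: dict[str, str] | None = None) -> OGCTable:
    table = OGCTable(species_groups=dict(species_groups or {}))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected cluster_id plus at least one species column")
            cid = parts[0]
            per_sp: dict[str, list[str]] = {}
            for col in parts[1:]:
                if not col:
                    continue
                if ":" not in col:
                    raise ValueError(f"line {lineno}: malformed species column {col!r}")
                sp, genes = col.split(":", 1)
                per_sp[sp] = [g for g in genes.split(",") if g]
            table.clusters[cid] = per_sp
    table.validate()
    return table


def write_cluster_table(path: str | Path, table: OGCTable) -> None:
    with open(path, "w") as fh:
        for cid in sorted(table.clusters):
            cols = [cid]
            for sp in sorted(table.clusters[cid]):
                genes = table.clusters[cid][sp]
                if genes:
                    cols.append(f"{sp}:{','.join(genes)}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Annotation table (gene_id \t term, one per row, or gene_id \t comma-list)

def read_annotation_table(path: str | Path, namespace: str = "GO") -> AnnotationTable:
    table = AnnotationTable(namespace=namespace)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 2 columns")
            gene, terms = parts
            for term in terms.split(","):
                term = term.strip()
                if term:
                    table.add(gene, term)
    return table


def write_annotation_table(path: str | Path, table: AnnotationTable) -> None:
    with open(path, "w") as fh:
        for gene in sorted(table.assignments):
            fh.write(f"{gene}\t{','.join(sorted(table.assignments[gene]))}\n")
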