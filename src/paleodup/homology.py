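"""Protein similarity, reciprocal-best-hit (RBH) homolog calling, and clustering.

The RBH rule: genes a (in genome A) and b (in genome B) form an ortholog
pair iff b is the top-scoring subject for query a among all of B, and a is
the top-scoring subject for b among all of A.  Applied within one genome
(self-hits removed) the same rule yields paralog pairs.  Ties at the top are
broken by higher identity, then lexicographic subject id, and logged.

Similarity is exact Smith–Waterman under BLOSUM62 with affine gaps
(open 11, extend 1), with an escape hatch for externally computed tabular
hits on large proteomes.  All-vs-all search uses a shared-k-mer seeding
prefilter so that only plausibly homologous pairs are aligned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import Genome, OGCTable, ScoredHit

logger = logging.getLogger(__name__)

__all__ = [
    "AlignConfig",
    "HomologPair",
    "align_score",
    "all_vs_all_hits",
    "rbh_orthologs",
    "rbh_paralogs",
    "top_hits_pairs",
    "build_ogcs",
]


@dataclass(frozen=True)
class HomologPair:
    """An unordered homolog pair; ``a < b`` lexicographically by convention."""

    a: str
    b: str
    kind: str = "paralog"  # {"paralog", "ortholog"}
    source: str = "rbh"  # {"rbh", "table", "tophit"}

    def __post_init__(self) -> None:
        if self.a > self.b:
            object.__setattr__(self, "a", self.b)
            object.__setattr__(self, "b", self.a)

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.a, self.b))


def make_pair(x: str, y: str, kind: str, source: str = "rbh") -> HomologPair:
    a, b = (x, y) if x <= y else (y, x)
    return HomologPair(a=a, b=b, kind=kind, source=source)


@dataclass
class AlignConfig:
    """Scoring configuration for protein similarity search."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_score: float = 50.0
    min_identity: float = 0.3
    seed_k: int = 4  # protein k-mer seed length
    seed_k_nuc: int = 12  # CDS k-mer seed length (second seeding track)
    nuc_seed_weight: float = 4.0  # nucleotide seeds are rarer by chance
    max_candidates: int = 12  # alignments per query, best-seeded first


def _build_aligner(config: AlignConfig, mode: str = "local") -> Align.PairwiseAligner:
    matrix = substitution_matrices.load(config.matrix)
    # Ambiguity code X scores 0 against everything.
    if "X" in matrix.alphabet:
        arr = matrix.copy()
        xi = matrix.alphabet.index("X")
        arr[xi, :] = 0.0
        arr[:, xi] = 0.0
        matrix = arr
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -abs(config.gap_open)
    aligner.extend_gap_score = -abs(config.gap_extend)
    return aligner


def _sanitize(seq: str, alphabet: str) -> str:
    return "".join(c if c in alphabet else "X" for c in seq.upper())


def align_score(seq1: str, seq2: str, config: AlignConfig | None = None) -> tuple[float, float]:
    """Local (Smith–Waterman) alignment score and identity of two proteins.

    Identity is the fraction of identical aligned columns over the local
    alignment length (gap columns included), as BLAST reports it.
    Symmetric in its arguments.
    """
    if not seq1 or not seq2:
        raise ValueError("empty sequence")
    config = config or AlignConfig()
    aligner = _build_aligner(config, "local")
    alphabet = str(aligner.substitution_matrix.alphabet)
    s1, s2 = _sanitize(seq1, alphabet), _sanitize(seq2, alphabet)
    alignments = aligner.align(s1, s2)
    score = alignments.score
    try:
        aln = alignments[0]
    except IndexError:
        return 0.0, 0.0
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / length if length else 0.0
    return float(score), float(identity)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def all_vs_all_hits(
    genome_a: Genome,
    genome_b: Genome | None = None,
    config: AlignConfig | None = None,
) -> list[ScoredHit]:
    """All-vs-all protein similarity hits between two genomes (or within one).

    A BLAST-like two-track seeding heuristic proposes candidate pairs:
    shared exact protein k-mers (``seed_k``) or shared CDS k-mers
    (``seed_k_nuc``, catching pairs whose protein similarity has eroded).
    Per query, the ``max_candidates`` best-seeded subjects are aligned
    exactly (Smith–Waterman, score first, traceback for identity only on
    hits passing ``min_score``); hits below ``min_score`` or
    ``min_identity`` are discarded.  Hits are emitted in both
    query/subject directions.  Self-hits excluded.
    """
    config = config or AlignConfig()
    intra = genome_b is None
    genome_b = genome_b or genome_a
    genes_a = [g for g in genome_a.genes() if g.protein]
    genes_b = [g for g in genome_b.genes() if g.protein]

    prot_index: dict[str, list[int]] = {}
    nuc_index: dict[str, list[int]] = {}
    for j, g in enumerate(genes_b):
        for kmer in _kmer_set(g.protein, config.seed_k):
            prot_index.setdefault(kmer, []).append(j)
        if g.cds:
            for kmer in _kmer_set(g.cds, config.seed_k_nuc):
                nuc_index.setdefault(kmer, []).append(j)

    aligner = _build_aligner(config, "local")
    alphabet = str(aligner.substitution_matrix.alphabet)
    sanitized_b = [_sanitize(g.protein, alphabet) for g in genes_b]
    hits: list[ScoredHit] = []
    attempted: set[frozenset[str]] = set()  # intra mode: each pair aligned once
    for ga in genes_a:
        shared: dict[int, float] = {}
        for kmer in _kmer_set(ga.protein, config.seed_k):
            for j in prot_index.get(kmer, ()):
                shared[j] = shared.get(j, 0.0) + 1.0
        if ga.cds:
            for kmer in _kmer_set(ga.cds, config.seed_k_nuc):
                for j in nuc_index.get(kmer, ()):
                    shared[j] = shared.get(j, 0.0) + config.nuc_seed_weight
        candidates = sorted(shared, key=lambda j: (-shared[j], genes_b[j].gene_id))
        sa = _sanitize(ga.protein, alphabet)
        n_done = 0
        for j in candidates:
            if n_done >= config.max_candidates:
                break
            gb = genes_b[j]
            if gb.gene_id == ga.gene_id:
                continue
            if intra:
                key = frozenset((ga.gene_id, gb.gene_id))
                if key in attempted:
                    continue
                attempted.add(key)
            n_done += 1
            score = float(aligner.score(sa, sanitized_b[j]))
            if score < config.min_score:
                continue
            alns = aligner.align(sa, sanitized_b[j])
            try:
                aln = alns[0]
            except IndexError:
                continue
            counts = aln.counts()
            length = counts.identities + counts.mismatches + counts.gaps
            identity = counts.identities / length if length else 0.0
            if identity < config.min_identity:
                continue
            hits.append(ScoredHit(ga.gene_id, gb.gene_id, score, identity))
            hits.append(ScoredHit(gb.gene_id, ga.gene_id, score, identity))
    return hits


def _best_subjects(
    hits: list[ScoredHit], queries: set[str], subjects: set[str]
) -> dict[str, str]:
    """Map each query to its unique best subject among ``subjects``.

    Best = highest score; ties broken by higher identity, then lexicographic
    subject id (tie events logged).
    """
    best: dict[str, ScoredHit] = {}
    n_ties = 0
    for h in sorted(hits, key=lambda h: (h.query, -h.score, -h.identity, h.subject)):
        if h.query not in queries or h.subject not in subjects or h.query == h.subject:
            continue
        cur = best.get(h.query)
        if cur is None:
            best[h.query] = h
        elif h.score == cur.score and h.identity == cur.identity and h.subject != cur.subject:
            n_ties += 1
    if n_ties:
        logger.info("broke %d top-hit ties by identity/lexicographic order", n_ties)
    return {q: h.subject for q, h in best.items()}


def rbh_orthologs(
    genome_a: Genome,
    genome_b: Genome,
    hits: list[ScoredHit] | None = None,
    config: AlignConfig | None = None,
) -> list[HomologPair]:
    """Reciprocal-best-hit ortholog pairs between two genomes."""
    if hits is None:
        hits = all_vs_all_hits(genome_a, genome_b, config)
    ids_a = set(genome_a.gene_ids())
    ids_b = set(genome_b.gene_ids())
    best_ab = _best_subjects(hits, ids_a, ids_b)
    best_ba = _best_subjects(hits, ids_b, ids_a)
    pairs = [
        make_pair(a, b, "ortholog")
        for a, b in best_ab.items()
        if best_ba.get(b) == a
    ]
    return sorted(pairs, key=lambda p: (p.a, p.b))


def rbh_paralogs(
    genome: Genome,
    hits: list[ScoredHit] | None = None,
    config: AlignConfig | None = None,
) -> list[HomologPair]:
    """Reciprocal-best-hit paralog pairs within one genome (self-hits excluded)."""
    if len(genome) < 2:
        return []
    if hits is None:
        hits = all_vs_all_hits(genome, None, config)
    ids = set(genome.gene_ids())
    best = _best_subjects(hits, ids, ids)
    pairs = {
        make_pair(a, b, "paralog").key: make_pair(a, b, "paralog")
        for a, b in best.items()
        if best.get(b) == a
    }
    return sorted(pairs.values(), key=lambda p: (p.a, p.b))


def top_hits_pairs(
    hits: list[ScoredHit],
    queries: set[str],
    subjects: set[str],
    n_top: int = 5,
    kind: str = "ortholog",
) -> list[HomologPair]:
    """Top-N hits per query as homolog pairs (MCScanX-style anchor source).

    RBH keeps one partner per gene, which hides one-to-many relationships
    such as the 2:1 gene depth left by a whole-genome duplication; synteny
    depth analysis therefore anchors on the top ``n_top`` hits per query.
    """
    by_query: dict[str, list[ScoredHit]] = {}
    for h in hits:
        if h.query in queries and h.subject in subjects and h.query != h.subject:
            by_query.setdefault(h.query, []).append(h)
    out: dict[frozenset[str], HomologPair] = {}
    for q, hs in by_query.items():
        hs.sort(key=lambda h: (-h.score, -h.identity, h.subject))
        for h in hs[:n_top]:
            p = make_pair(h.query, h.subject, kind, source="tophit")
            out[p.key] = p
    return sorted(out.values(), key=lambda p: (p.a, p.b))


def build_ogcs(genomes: list[Genome], pairs: list[HomologPair]) -> OGCTable:
    """Cluster genes into orthologous gene clusters (OGCs).

    Clusters are connected components of the homolog-pair graph
    (single-linkage); singleton genes are excluded.  Cluster ids are assigned
    deterministically in order of each component's smallest member gene id.
    """
    gene_species = {g.gene_id: gm.species for gm in genomes for g in gm.genes()}
    graph = nx.Graph()
    for p in pairs:
        graph.add_edge(p.a, p.b)
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph) if len(c) > 1),
        key=lambda c: c[0],
    )
    table = OGCTable(
        species_groups={gm.species: gm.group for gm in genomes},
    )
    for i, comp in enumerate(components):
        per_sp: dict[str, list[str]] = {}
        for gid in comp:
            sp = gene_species.get(gid, "unknown")
            per_sp.setdefault(sp, []).append(gid)
        table.clusters[f"OGC{i + 1:06d}"] = per_sp
    return table
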