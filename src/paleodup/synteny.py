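"""Collinearity analysis: block chaining, tandem classification, depth, spans.

A synteny block is a run of homolog anchors in conserved collinear order on
a chromosome pair — evidence that the two regions descend from one ancestral
segment.  Chaining is per-chromosome-pair dynamic programming maximizing
anchor count (a DAGchainer-like simplification of MCScanX): chains must be
strictly monotone on both rank axes (increasing, or decreasing on the second
axis for inverted blocks), with per-step rank gaps bounded by ``max_gap``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .genome_io import Gene, Genome
from .homology import HomologPair

logger = logging.getLogger(__name__)

__all__ = [
    "Anchor",
    "SyntenyBlock",
    "ColocalizationSpan",
    "anchors_from_pairs",
    "chain_blocks",
    "classify_tandem",
    "restrict_to_blocks",
    "synteny_depth",
    "colocalization_span",
    "dotplot_table",
]


@dataclass(frozen=True)
class Anchor:
    """One homolog pair projected to rank coordinates on a chromosome pair."""

    pair: HomologPair
    chrom1: str
    rank1: int
    chrom2: str
    rank2: int


@dataclass
class SyntenyBlock:
    block_id: str
    chrom1: str
    chrom2: str
    anchors: list[Anchor]
    orientation: str  # {"same", "inverted"}

    @property
    def score(self) -> int:
        return len(self.anchors)

    def rank_interval(self, axis: int) -> tuple[int, int]:
        ranks = [a.rank1 if axis == 1 else a.rank2 for a in self.anchors]
        return min(ranks), max(ranks)

    def pair_keys(self) -> set[frozenset[str]]:
        return {a.pair.key for a in self.anchors}


@dataclass
class ColocalizationSpan:
    chromosome: str
    gene_ids: list[str]
    span_bp: int
    n_genes: int
    primary: bool = False


def anchors_from_pairs(
    pairs: list[HomologPair],
    genome1: Genome,
    genome2: Genome | None = None,
    min_diagonal_distance: int = 10,
) -> list[Anchor]:
    """Project homolog pairs to rank anchors.

    Intragenome (``genome2`` omitted): each unordered pair becomes one
    anchor with the lower-(chromosome, rank) gene on axis 1, and — as in
    standard self-comparison collinearity practice — pairs on the same
    chromosome within ``min_diagonal_distance`` ranks of the self-diagonal
    are excluded: runs of tandem duplicates would otherwise chain into
    spurious near-diagonal "blocks".  Intergenome: gene of ``genome1`` on
    axis 1.  Pairs with a member absent from the genomes are skipped.
    """
    intra = genome2 is None
    genome2 = genome2 or genome1
    anchors = []
    for p in pairs:
        if p.a == p.b:
            continue
        if intra:
            if p.a not in genome1 or p.b not in genome1:
                continue
            ga, gb = genome1[p.a], genome1[p.b]
            if (
                ga.chromosome == gb.chromosome
                and abs(ga.rank - gb.rank) <= min_diagonal_distance
            ):
                continue
            if (gb.chromosome, gb.rank) < (ga.chromosome, ga.rank):
                ga, gb = gb, ga
        else:
            if p.a in genome1 and p.b in genome2:
                ga, gb = genome1[p.a], genome2[p.b]
            elif p.b in genome1 and p.a in genome2:
                ga, gb = genome1[p.b], genome2[p.a]
            else:
                continue
        anchors.append(Anchor(p, ga.chromosome, ga.rank, gb.chromosome, gb.rank))
    return anchors


# ---------------------------------------------------------------------------
# Block chaining


def _best_chain(
    anchors: list[Anchor], max_gap: int, direction: int
) -> tuple[list[int], int]:
    """Best monotone chain by DP: max length, ties by smaller total gap.

    ``direction`` +1 chains rank2 increasing, -1 decreasing; rank1 is always
    strictly increasing.  Returns (indices into ``anchors``, total_gap).
    """
    order = sorted(
        range(len(anchors)),
        key=lambda i: (anchors[i].rank1, direction * anchors[i].rank2),
    )
    n = len(order)
    length = [1] * n
    gap = [0] * n
    prev = [-1] * n
    for ii in range(n):
        ai = anchors[order[ii]]
        for jj in range(ii):
            aj = anchors[order[jj]]
            d1 = ai.rank1 - aj.rank1
            d2 = direction * (ai.rank2 - aj.rank2)
            if d1 <= 0 or d2 <= 0 or d1 > max_gap or d2 > max_gap:
                continue
            cand_len = length[jj] + 1
            cand_gap = gap[jj] + (d1 - 1) + (d2 - 1)
            if cand_len > length[ii] or (cand_len == length[ii] and cand_gap < gap[ii]):
                length[ii] = cand_len
                gap[ii] = cand_gap
                prev[ii] = jj
    best = max(range(n), key=lambda ii: (length[ii], -gap[ii]))
    chain = []
    ii = best
    while ii != -1:
        chain.append(order[ii])
        ii = prev[ii]
    chain.reverse()
    return chain, gap[best]


def chain_blocks(
    anchors: list[Anchor], max_gap: int = 25, min_block: int = 5
) -> list[SyntenyBlock]:
    """Chain anchors into synteny blocks per chromosome pair.

    Chains are extracted greedily: the longest admissible chain (ties by
    smaller total gap, then same orientation preferred) is removed and the
    search repeats until no chain reaches ``min_block`` anchors.  Each anchor
    belongs to at most one block.
    """
    by_pair: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        by_pair.setdefault((a.chrom1, a.chrom2), []).append(a)

    blocks: list[SyntenyBlock] = []
    counter = 0
    for chrom_pair in sorted(by_pair):
        remaining = sorted(
            by_pair[chrom_pair], key=lambda a: (a.rank1, a.rank2, a.pair.a, a.pair.b)
        )
        while len(remaining) >= min_block:
            fwd, fwd_gap = _best_chain(remaining, max_gap, +1)
            rev, rev_gap = _best_chain(remaining, max_gap, -1)
            if (len(fwd), -fwd_gap) >= (len(rev), -rev_gap):
                chain, orientation = fwd, "same"
            else:
                chain, orientation = rev, "inverted"
            if len(chain) < min_block:
                break
            counter += 1
            chosen = [remaining[i] for i in chain]
            blocks.append(
                SyntenyBlock(
                    block_id=f"B{counter:05d}",
                    chrom1=chrom_pair[0],
                    chrom2=chrom_pair[1],
                    anchors=chosen,
                    orientation=orientation,
                )
            )
            picked = set(chain)
            remaining = [a for i, a in enumerate(remaining) if i not in picked]
    return blocks


# ---------------------------------------------------------------------------
# Tandem classification


def classify_tandem(
    pairs: list[HomologPair], genome: Genome, window: int = 10
) -> dict[str, list[HomologPair]]:
    """Partition paralog pairs into tandem vs dispersed duplicates.

    A pair is tandem iff both genes lie on the same chromosome within
    ``window`` gene positions of each other (rank distance <= window,
    boundary inclusive); all other pairs are dispersed.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    out: dict[str, list[HomologPair]] = {"tandem": [], "dispersed": []}
    for p in pairs:
        ga, gb = genome[p.a], genome[p.b]
        if ga.chromosome == gb.chromosome and abs(ga.rank - gb.rank) <= window:
            out["tandem"].append(p)
        else:
            out["dispersed"].append(p)
    return out


# ---------------------------------------------------------------------------
# Block-restricted divergence


def restrict_to_blocks(table: pd.DataFrame, blocks: list[SyntenyBlock]) -> pd.DataFrame:
    """Rows of a divergence table whose pair anchors some synteny block."""
    anchored: set[frozenset[str]] = set()
    for b in blocks:
        anchored |= b.pair_keys()
    if table.empty:
        return table.copy()
    mask = [frozenset((a, b)) in anchored for a, b in zip(table["a"], table["b"])]
    return table[mask].copy()


# ---------------------------------------------------------------------------
# Synteny depth


def synteny_depth(
    blocks: list[SyntenyBlock], target_genome: Genome, axis: int = 2
) -> tuple[dict[str, int], dict[int, int], int]:
    """Per-gene block coverage depth on the target genome's axis.

    Depth of a gene = number of blocks whose rank interval on the target
    axis (with matching chromosome) covers the gene's rank.  Returns
    (per-gene depth, depth histogram, modal depth over covered genes).
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        chrom = b.chrom1 if axis == 1 else b.chrom2
        intervals.setdefault(chrom, []).append(b.rank_interval(axis))
    depth: dict[str, int] = {}
    for g in target_genome.genes():
        d = sum(
            lo <= g.rank <= hi for lo, hi in intervals.get(g.chromosome, ())
        )
        depth[g.gene_id] = d
    hist: dict[int, int] = {}
    for d in depth.values():
        hist[d] = hist.get(d, 0) + 1
    covered = {d: n for d, n in hist.items() if d > 0}
    modal = max(covered, key=lambda d: (covered[d], -d)) if covered else 0
    return depth, hist, modal


# ---------------------------------------------------------------------------
# Co-localization spans


def colocalization_span(gene_ids: list[str], genome: Genome) -> list[ColocalizationSpan]:
    """Base-pair span of a gene set per chromosome (e.g. a pathway's genes).

    The chromosome holding the most listed genes is flagged primary.
    """
    by_chrom: dict[str, list[Gene]] = {}
    for gid in gene_ids:
        g = genome[gid]  # raises KeyError naming the id if unknown
        by_chrom.setdefault(g.chromosome, []).append(g)
    spans = []
    for chrom in sorted(by_chrom):
        genes = by_chrom[chrom]
        start = min(g.start for g in genes)
        end = max(g.end for g in genes)
        spans.append(
            ColocalizationSpan(
                chromosome=chrom,
                gene_ids=sorted(g.gene_id for g in genes),
                span_bp=end - start + 1,
                n_genes=len(genes),
            )
        )
    if spans:
        primary = max(spans, key=lambda s: (s.n_genes, s.chromosome))
        primary.primary = True
    return spans


# ---------------------------------------------------------------------------
# Dot plot


def dotplot_table(anchors: list[Anchor], blocks: list[SyntenyBlock] | None = None) -> pd.DataFrame:
    """Plot-ready anchor table: (chrom1, rank1, chrom2, rank2, block_id)."""
    block_of: dict[tuple, str] = {}
    for b in blocks or []:
        for a in b.anchors:
            block_of[(a.chrom1, a.rank1, a.chrom2, a.rank2)] = b.block_id
    rows = [
        {
            "chrom1": a.chrom1,
            "rank1": a.rank1,
            "chrom2": a.chrom2,
            "rank2": a.rank2,
            "block_id": block_of.get((a.chrom1, a.rank1, a.chrom2, a.rank2), "none"),
        }
        for a in sorted(anchors, key=lambda a: (a.chrom1, a.rank1, a.chrom2, a.rank2))
    ]
    return pd.DataFrame(rows, columns=["chrom1", "rank1", "chrom2", "rank2", "block_id"])
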