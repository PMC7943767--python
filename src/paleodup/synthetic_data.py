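"""Genome-evolution simulator with ground truth for every pipeline stage.

The simulator grows a multi-species gene set from a single ancestral genome
along a ladder phylogeny:

* sequences evolve by a K80 (Kimura two-parameter) nucleotide substitution
  process — transition/transversion rate ratio ``kappa`` — with proposals
  that would create a stop codon rejected, so no CDS ever contains an
  internal stop.  The per-site substitution rate is ``synonymous_rate``
  (substitutions/site/year); with no selection in the model, the expected
  synonymous divergence of two copies separated ``t`` years ago is
  ``2 * synonymous_rate * t``, which is exactly what the truth table records;
* optional whole-genome duplications (WGD) duplicate every gene onto a
  mirrored set of new chromosomes preserving ancestral order (clean planted
  synteny blocks), each duplicate retained with ``retention_prob``;
* recent tandem duplications insert a copy at rank+1 at each tip;
* inversions and translocations fragment the planted collinearity;
* GO-style terms are assigned per ancestral family from a power-law
  frequency vocabulary, with planted terms oversampled by a configured fold
  in families destined for a target species group.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import AnnotationTable, Gene, Genome, OGCTable

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "PairTruth",
    "SimTruth",
    "simulate",
    "simulate_clusters",
    "truth_report",
    "depth_to_mya",
]

# base encoding A=0 C=1 G=2 T=3; transitions are b XOR 2 (A<->G, C<->T)
_BASES = "ACGT"
_STOPS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA TAG TGA
_TV = {0: (1, 3), 2: (1, 3), 1: (0, 2), 3: (0, 2)}

DEFAULT_RATE = 1.5e-8  # synonymous substitutions / site / year


def depth_to_mya(depth: float, rate: float = DEFAULT_RATE) -> float:
    """Event age (MYA) whose copies have the given pairwise synonymous depth."""
    return depth / (2.0 * rate) / 1e6


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults describe the benchmark scenario: a 500-gene, 5-chromosome
    genome of 300-codon genes carrying one clean WGD (all duplicates
    retained) at pairwise synonymous depth 0.5 — i.e. ~16.7 MYA at the
    dicot clock rate of 1.5e-8 synonymous substitutions/site/year.
    """

    seed: int = 1729
    n_genes: int = 500
    n_chromosomes: int = 5
    codons_per_gene: int = 300
    synonymous_rate: float = DEFAULT_RATE
    kappa: float = 2.0  # transition/transversion rate ratio
    #: (time_mya, retention_prob) per whole-genome duplication
    wgd_events: list[tuple[float, float]] = field(
        default_factory=lambda: [(depth_to_mya(0.5), 1.0)]
    )
    focal_species: str = "focal"
    #: other species -> split time (MYA) from the focal lineage
    speciation_times_mya: dict[str, float] = field(default_factory=dict)
    species_groups: dict[str, str] = field(default_factory=dict)
    #: probability an ancestral family is specific to one species group
    specific_fraction: float = 0.0
    tandem_rate: float = 0.0  # per-gene probability of a recent tandem copy
    tandem_depth: float = 0.05  # pairwise synonymous depth of tandem pairs
    n_inversions: int = 0
    n_translocations: int = 0
    go_vocab_size: int = 200
    terms_per_family: float = 2.0  # Poisson mean (plus one) of background terms
    planted_base_rate: float = 0.08
    #: (term, target_group, fold_enrichment)
    planted_terms: list[tuple[str, str, float]] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_chromosomes < 1 or self.codons_per_gene < 1:
            raise ValueError("n_genes, n_chromosomes, codons_per_gene must be >= 1")
        if self.synonymous_rate < 0 or self.kappa <= 0:
            raise ValueError("rates must be positive")
        for t, r in self.wgd_events:
            if t < 0 or not (0.0 < r <= 1.0):
                raise ValueError(f"invalid WGD event ({t}, {r}): retention must be in (0,1]")
        if any(t < 0 for t in self.speciation_times_mya.values()):
            raise ValueError("speciation times must be >= 0")
        if not (0.0 <= self.tandem_rate <= 1.0) or self.tandem_depth < 0:
            raise ValueError("invalid tandem parameters")
        if not (0.0 <= self.specific_fraction <= 1.0):
            raise ValueError("specific_fraction must be in [0,1]")


@dataclass(frozen=True)
class PairTruth:
    origin: str  # {"wgd", "tandem", "speciation"}
    divergence: float  # true pairwise synonymous depth
    species_a: str
    species_b: str


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated genomes."""

    pair_truth: dict[frozenset, PairTruth] = field(default_factory=dict)
    #: per species: (original chromosome, WGD-copy chromosome) pairings
    block_truth: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    #: family cluster id -> expected classification label value
    group_truth: dict[str, str] = field(default_factory=dict)
    enriched_terms: set[str] = field(default_factory=set)
    cluster_table: OGCTable = field(default_factory=OGCTable)

    def pairs_by_origin(self, origin: str, species: str | None = None) -> list[frozenset]:
        return [
            k
            for k, v in self.pair_truth.items()
            if v.origin == origin
            and (species is None or (v.species_a == species and v.species_b == species))
        ]


# ---------------------------------------------------------------------------
# sequence evolution


def _random_cds(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    """Random sense codons (no stops anywhere)."""
    codons = rng.integers(0, 4, (n_codons, 3))
    while True:
        is_stop = (codons[:, 0] == 3) & (
            ((codons[:, 1] == 0) & ((codons[:, 2] == 0) | (codons[:, 2] == 2)))
            | ((codons[:, 1] == 2) & (codons[:, 2] == 0))
        )
        bad = np.nonzero(is_stop)[0]
        if bad.size == 0:
            break
        codons[bad] = rng.integers(0, 4, (bad.size, 3))
    return codons.reshape(-1).astype(np.int8)


def _evolve(seq: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> None:
    """K80 substitution in place at expected ``d`` substitutions/site.

    Events are Poisson over the sequence; each picks a site, proposes a
    transition with probability kappa/(kappa+2) else one of the two
    transversions, and is rejected if the mutated codon would be a stop.
    """
    L = seq.size
    n_events = rng.poisson(d * L)
    if n_events == 0:
        return
    sites = rng.integers(0, L, n_events)
    kinds = rng.random(n_events)
    p_ts = kappa / (kappa + 2.0)
    s = seq  # local alias
    for site, u in zip(sites.tolist(), kinds.tolist()):
        b = int(s[site])
        if u < p_ts:
            nb = b ^ 2
        elif u < (1.0 + p_ts) / 2.0:
            nb = _TV[b][0]
        else:
            nb = _TV[b][1]
        c0 = 3 * (site // 3)
        codon = [int(s[c0]), int(s[c0 + 1]), int(s[c0 + 2])]
        codon[site - c0] = nb
        if tuple(codon) in _STOPS:
            continue  # stop-codon proposals rejected
        s[site] = nb


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[b] for b in seq)


# ---------------------------------------------------------------------------
# genome assembly during simulation


@dataclass
class _SimGene:
    copy_id: int
    family: int
    seq: np.ndarray
    strand: str

    def clone(self, copy_id: int | None = None) -> "_SimGene":
        return _SimGene(
            copy_id=self.copy_id if copy_id is None else copy_id,
            family=self.family,
            seq=self.seq.copy(),
            strand=self.strand,
        )


def _snapshot(chroms: dict[str, list[_SimGene]]) -> dict[str, list[_SimGene]]:
    return {c: [g.clone() for g in genes] for c, genes in chroms.items()}


def simulate(config: SimConfig) -> tuple[list[Genome], AnnotationTable, SimTruth]:
    """Run the simulator; returns (genomes, annotations, truth).

    Genomes are ordered focal species first, then the others by split time
    ascending.  Fully deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rate_per_my = config.synonymous_rate * 1e6
    truth = SimTruth()

    # ancestral genome, genes dealt round-robin onto chromosomes
    next_copy = 0
    chroms: dict[str, list[_SimGene]] = {
        f"chr{i + 1}": [] for i in range(config.n_chromosomes)
    }
    chrom_names = list(chroms)
    for fam in range(config.n_genes):
        g = _SimGene(
            copy_id=next_copy,
            family=fam,
            seq=_random_cds(config.codons_per_gene, rng),
            strand="+" if rng.random() < 0.5 else "-",
        )
        next_copy += 1
        chroms[chrom_names[fam % config.n_chromosomes]].append(g)

    # family destinies for group-specific clusters
    groups = sorted(set(config.species_groups.values()))
    destiny: dict[int, str | None] = {f: None for f in range(config.n_genes)}
    if config.specific_fraction > 0 and len(groups) >= 2:
        for fam in range(config.n_genes):
            if rng.random() < config.specific_fraction:
                destiny[fam] = groups[int(rng.integers(len(groups)))]

    # timeline: splits and WGDs, oldest first; at equal times splits first
    # (a species splitting exactly at a WGD does not inherit it)
    events: list[tuple[float, int, str, object]] = []
    for sp, t in config.speciation_times_mya.items():
        events.append((t, 0, "split", sp))
    wgd_pairs: list[tuple[int, int, float]] = []
    wgd_chrom_pairs: list[tuple[str, str]] = []
    for i, (t, retention) in enumerate(config.wgd_events):
        events.append((t, 1, "wgd", (i, retention)))
    events.sort(key=lambda e: (-e[0], e[1], e[2], str(e[3])))

    t_cur = events[0][0] if events else 0.0
    species_snapshots: dict[str, tuple[dict[str, list[_SimGene]], float]] = {}

    def evolve_backbone(d: float) -> None:
        if d <= 0:
            return
        for genes in chroms.values():
            for g in genes:
                _evolve(g.seq, d, config.kappa, rng)

    for t_ev, _, kind, payload in events:
        evolve_backbone(rate_per_my * (t_cur - t_ev))
        t_cur = t_ev
        if kind == "split":
            species_snapshots[str(payload)] = (_snapshot(chroms), rate_per_my * t_ev)
        else:
            wgd_idx, retention = payload  # type: ignore[misc]
            new_chroms: dict[str, list[_SimGene]] = {}
            for cname in list(chroms):
                copies = []
                for g in chroms[cname]:
                    if rng.random() <= retention:
                        copy = g.clone(copy_id=next_copy)
                        next_copy += 1
                        copies.append(copy)
                        wgd_pairs.append((g.copy_id, copy.copy_id, t_ev))
                if copies:
                    new_name = f"{cname}w{wgd_idx + 1}"
                    new_chroms[new_name] = copies
                    wgd_chrom_pairs.append((cname, new_name))
            chroms.update(new_chroms)
    evolve_backbone(rate_per_my * t_cur)
    species_snapshots[config.focal_species] = (chroms, 0.0)

    # finish each tip: branch evolution, family loss, tandems, rearrangements
    order = [config.focal_species] + sorted(
        config.speciation_times_mya, key=lambda s: (config.speciation_times_mya[s], s)
    )
    genomes: list[Genome] = []
    gene_len = 3 * config.codons_per_gene
    spacer = 500
    tandem_truth: list[tuple[str, int, int]] = []  # species, parent_copy, copy
    species_copies: dict[str, set[int]] = {}
    family_members: dict[int, dict[str, list[str]]] = {}

    for sp in order:
        tip_chroms, branch_d = species_snapshots[sp]
        sp_group = config.species_groups.get(sp)
        for cname in list(tip_chroms):
            kept = []
            for g in tip_chroms[cname]:
                dest = destiny[g.family]
                if dest is not None and dest != sp_group:
                    continue  # family destined specific to another group
                if branch_d > 0:
                    _evolve(g.seq, branch_d, config.kappa, rng)
                kept.append(g)
            tip_chroms[cname] = kept

        if config.tandem_rate > 0:
            for cname in list(tip_chroms):
                expanded: list[_SimGene] = []
                for g in tip_chroms[cname]:
                    expanded.append(g)
                    if rng.random() < config.tandem_rate:
                        copy = g.clone(copy_id=next_copy)
                        next_copy += 1
                        _evolve(copy.seq, config.tandem_depth, config.kappa, rng)
                        expanded.append(copy)
                        tandem_truth.append((sp, g.copy_id, copy.copy_id))
                tip_chroms[cname] = expanded

        _rearrange(tip_chroms, config.n_inversions, config.n_translocations, rng)

        genes = []
        copies_here: set[int] = set()
        for cname in sorted(tip_chroms):
            for pos, g in enumerate(tip_chroms[cname]):
                gid = f"{sp}_{g.copy_id:05d}"
                start = 1 + pos * (gene_len + spacer)
                cds = _decode(g.seq)
                genes.append(
                    Gene(
                        gene_id=gid,
                        chromosome=cname,
                        start=start,
                        end=start + gene_len - 1,
                        strand=g.strand,
                        cds=cds,
                    )
                )
                genes[-1].protein = _translate_int(g.seq)
                copies_here.add(g.copy_id)
                family_members.setdefault(g.family, {}).setdefault(sp, []).append(gid)
        species_copies[sp] = copies_here
        genomes.append(
            Genome.from_genes(sp, genes, group=sp_group or "default")
        )
        truth.block_truth[sp] = [
            (c1, c2)
            for c1, c2 in wgd_chrom_pairs
            if c1 in tip_chroms and c2 in tip_chroms
        ]

    # --- truth tables -------------------------------------------------
    split_of = dict(config.speciation_times_mya)
    split_of[config.focal_species] = 0.0

    # intragenome WGD sibling pairs
    for sp in order:
        have = species_copies[sp]
        for c1, c2, t_w in wgd_pairs:
            if c1 in have and c2 in have:
                key = frozenset((f"{sp}_{c1:05d}", f"{sp}_{c2:05d}"))
                truth.pair_truth[key] = PairTruth(
                    "wgd", 2.0 * config.synonymous_rate * t_w * 1e6, sp, sp
                )
    # tandem pairs
    for sp, parent, copy in tandem_truth:
        key = frozenset((f"{sp}_{parent:05d}", f"{sp}_{copy:05d}"))
        truth.pair_truth[key] = PairTruth("tandem", config.tandem_depth, sp, sp)
    # orthologs: same copy lineage across species
    for i, s1 in enumerate(order):
        for s2 in order[i + 1 :]:
            t_split = max(split_of[s1], split_of[s2])
            for c in species_copies[s1] & species_copies[s2]:
                key = frozenset((f"{s1}_{c:05d}", f"{s2}_{c:05d}"))
                truth.pair_truth[key] = PairTruth(
                    "speciation", 2.0 * config.synonymous_rate * t_split * 1e6, s1, s2
                )

    # family clusters + expected group labels
    truth.cluster_table = OGCTable(species_groups=dict(config.species_groups))
    for fam in sorted(family_members):
        cid = f"FAM{fam:06d}"
        truth.cluster_table.clusters[cid] = {
            sp: list(m) for sp, m in sorted(family_members[fam].items())
        }
        truth.group_truth[cid] = _expected_label(
            set(family_members[fam]), config.species_groups, groups
        )

    # annotations with planted enrichment
    annotations = _annotate_families(
        rng,
        config,
        destiny,
        family_members,
    )
    truth.enriched_terms = {t for t, _, _ in config.planted_terms}
    return genomes, annotations, truth


def _translate_int(seq: np.ndarray) -> str:
    from .genome_io import translate_cds

    return translate_cds(_decode(seq))


def _expected_label(
    present: set[str], species_groups: dict[str, str], groups: list[str]
) -> str:
    if len(groups) != 2:
        return "unclassified" if len(present) < 2 else "shared"
    a = {s for s in present if species_groups.get(s) == groups[0]}
    b = {s for s in present if species_groups.get(s) == groups[1]}
    if len(present) < 2:
        return "unclassified"
    if len(a) >= 2 and not b:
        return "specific_to_A"
    if len(b) >= 2 and not a:
        return "specific_to_B"
    if a and b:
        return "shared"
    return "unclassified"


def _rearrange(
    chroms: dict[str, list[_SimGene]],
    n_inversions: int,
    n_translocations: int,
    rng: np.random.Generator,
) -> None:
    names = sorted(chroms)

    def pick_chrom() -> str:
        sizes = np.array([len(chroms[c]) for c in names], dtype=float)
        if sizes.sum() == 0:
            return names[0]
        return names[int(rng.choice(len(names), p=sizes / sizes.sum()))]

    for _ in range(n_inversions):
        c = pick_chrom()
        genes = chroms[c]
        if len(genes) < 2:
            continue
        i, j = sorted(rng.integers(0, len(genes), 2).tolist())
        j = max(j, i + 1)
        seg = genes[i : j + 1][::-1]
        for g in seg:
            g.strand = "-" if g.strand == "+" else "+"
        chroms[c] = genes[:i] + seg + genes[j + 1 :]

    for _ in range(n_translocations):
        if len(names) < 2:
            break
        src = pick_chrom()
        genes = chroms[src]
        if not genes:
            continue
        i = int(rng.integers(0, len(genes)))
        j = min(len(genes) - 1, i + int(rng.integers(1, max(2, len(genes) // 4))))
        seg = genes[i : j + 1]
        chroms[src] = genes[:i] + genes[j + 1 :]
        others = [c for c in names if c != src]
        dst = others[int(rng.integers(len(others)))]
        at = int(rng.integers(0, len(chroms[dst]) + 1))
        chroms[dst] = chroms[dst][:at] + seg + chroms[dst][at:]


def _annotate_families(
    rng: np.random.Generator,
    config: SimConfig,
    destiny: dict[int, str | None],
    family_members: dict[int, dict[str, list[str]]],
) -> AnnotationTable:
    vocab = [f"GO:{i + 1:07d}" for i in range(config.go_vocab_size)]
    freqs = np.arange(1, config.go_vocab_size + 1, dtype=float) ** -1.5
    freqs /= freqs.sum()
    table = AnnotationTable(namespace="GO")
    planted = config.planted_terms
    for fam in sorted(family_members):
        n_terms = 1 + int(rng.poisson(config.terms_per_family))
        n_terms = min(n_terms, config.go_vocab_size)
        terms = set(
            rng.choice(config.go_vocab_size, size=n_terms, replace=False, p=freqs)
        )
        fam_terms = {vocab[i] for i in terms}
        for term, target_group, fold in planted:
            p = config.planted_base_rate
            if destiny.get(fam) == target_group:
                p = min(1.0, p * fold)
            if rng.random() < p:
                fam_terms.add(term)
            else:
                fam_terms.discard(term)
        for members in family_members[fam].values():
            for gid in members:
                for t in sorted(fam_terms):
                    table.add(gid, t)
    return table


# ---------------------------------------------------------------------------
# cluster/annotation-level simulation (no sequence evolution)


def simulate_clusters(
    n_clusters: int,
    species_groups: dict[str, str],
    seed: int = 1729,
    specific_fraction: float = 0.4,
    presence_prob: float = 0.75,
    go_vocab_size: int = 200,
    terms_per_cluster: float = 2.0,
    planted_base_rate: float = 0.08,
    planted_terms: list[tuple[str, str, float]] | None = None,
) -> tuple[OGCTable, AnnotationTable, dict[str, str], set[str]]:
    """Simulate cluster membership and annotations directly.

    Generates the statistical structure the enrichment stage consumes —
    species-presence patterns and term assignments with optional planted
    enrichment — without sequence evolution.  Per cluster: with probability
    ``specific_fraction`` the cluster is specific to one group (uniformly
    chosen; only that group's species may be present, at least two are);
    otherwise it is shared (at least one species per group).  Returns
    (table, annotations, expected labels, planted term set).
    """
    rng = np.random.default_rng(seed)
    planted_terms = planted_terms or []
    groups = sorted(set(species_groups.values()))
    if len(groups) != 2:
        raise ValueError("simulate_clusters needs exactly two species groups")
    by_group = {g: sorted(s for s, gg in species_groups.items() if gg == g) for g in groups}
    for g, sps in by_group.items():
        if len(sps) < 2:
            raise ValueError(f"group {g} needs >= 2 species")

    vocab = [f"GO:{i + 1:07d}" for i in range(go_vocab_size)]
    freqs = np.arange(1, go_vocab_size + 1, dtype=float) ** -1.5
    freqs /= freqs.sum()

    table = OGCTable(species_groups=dict(species_groups))
    annotations = AnnotationTable(namespace="GO")
    labels: dict[str, str] = {}

    for i in range(n_clusters):
        cid = f"C{i + 1:06d}"
        if rng.random() < specific_fraction:
            grp = groups[int(rng.integers(2))]
            pool = by_group[grp]
            while True:
                present = [s for s in pool if rng.random() < presence_prob]
                if len(present) >= 2:
                    break
            labels[cid] = "specific_to_A" if grp == groups[0] else "specific_to_B"
            destiny = grp
        else:
            while True:
                present = [s for s in sorted(species_groups) if rng.random() < presence_prob]
                got = {species_groups[s] for s in present}
                if len(got) == 2:
                    break
            labels[cid] = "shared"
            destiny = None
        table.clusters[cid] = {
            sp: [f"{sp}_{cid}_g{j}" for j in range(1 + int(rng.poisson(0.5)))]
            for sp in present
        }
        n_terms = min(1 + int(rng.poisson(terms_per_cluster)), go_vocab_size)
        chosen = rng.choice(go_vocab_size, size=n_terms, replace=False, p=freqs)
        terms = {vocab[j] for j in chosen}
        for term, target_group, fold in planted_terms:
            p = planted_base_rate
            if destiny == target_group:
                p = min(1.0, p * fold)
            if rng.random() < p:
                terms.add(term)
            else:
                terms.discard(term)
        for members in table.clusters[cid].values():
            for gid in members:
                for t in sorted(terms):
                    annotations.add(gid, t)
    return table, annotations, labels, {t for t, _, _ in planted_terms}


# ---------------------------------------------------------------------------
# recovery metrics


def truth_report(
    truth: SimTruth,
    estimates: pd.DataFrame | None = None,
    blocks=None,
    enrichment: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Recovery metrics of pipeline estimates against simulation truth.

    Rows (when the corresponding input is given): per-origin median bias and
    RMSE of Ks vs true divergence; synteny-block precision/recall over true
    WGD pairs; recall of planted enriched terms.
    """
    rows = []
    if estimates is not None and not estimates.empty:
        est_by_key = {
            frozenset((a, b)): ks
            for a, b, ks in zip(estimates["a"], estimates["b"], estimates["ks"])
        }
        by_origin: dict[str, list[tuple[float, float]]] = {}
        for key, pt in truth.pair_truth.items():
            if key in est_by_key and np.isfinite(est_by_key[key]):
                by_origin.setdefault(pt.origin, []).append((est_by_key[key], pt.divergence))
        for origin in sorted(by_origin):
            arr = np.array(by_origin[origin])
            err = arr[:, 0] - arr[:, 1]
            rows.append(
                {
                    "metric": f"ks_median_bias_{origin}",
                    "value": float(np.median(err)),
                    "n": len(err),
                }
            )
            rows.append(
                {
                    "metric": f"ks_rmse_{origin}",
                    "value": float(np.sqrt(np.mean(err**2))),
                    "n": len(err),
                }
            )
    if blocks is not None:
        anchored: set[frozenset] = set()
        for b in blocks:
            anchored |= b.pair_keys()
        true_wgd = set(truth.pairs_by_origin("wgd"))
        if anchored:
            precision = len(anchored & set(truth.pair_truth)) / len(anchored)
            rows.append({"metric": "block_precision", "value": precision, "n": len(anchored)})
        if true_wgd:
            recall = len(anchored & true_wgd) / len(true_wgd)
            rows.append({"metric": "block_recall_wgd", "value": recall, "n": len(true_wgd)})
    if enrichment is not None and truth.enriched_terms:
        sig = set(enrichment.loc[enrichment["significant"], "term"])
        recall = len(sig & truth.enriched_terms) / len(truth.enriched_terms)
        rows.append(
            {"metric": "planted_term_recall", "value": recall, "n": len(truth.enriched_terms)}
        )
    return pd.DataFrame(rows, columns=["metric", "value", "n"])
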