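# paleodup

Whole-genome duplication (WGD) detection and dating from the divergence
distributions of duplicated genes, with the comparative-genomics analyses
that accompany such a study: reciprocal-best-hit (RBH) homolog calling,
Ks and 4dTv estimation, mixture peak detection, collinearity (synteny)
block chaining, tandem-duplicate classification, orthologous gene cluster
(OGC) construction and classification, and cluster-level binomial
functional enrichment.  A genome-evolution simulator with full ground
truth is part of the package, so every stage can be validated end to end.

**Who it is for.** Researchers analyzing plant (or other) genomes for
paleopolyploidy: given per-species protein FASTA, CDS FASTA, and GFF3
gene coordinates — or simulated data — the pipeline answers: did this
lineage undergo a WGD, when, what fraction of recent duplicates are
tandem, what is the synteny depth against a relative, and which functions
are overrepresented in lineage-specific gene clusters?

## The statistics at the core

* **Ks** — synonymous substitutions per synonymous site, estimated by
  Nei–Gojobori counting with the Jukes–Cantor correction
  `Ks = −(3/4)·ln(1 − (4/3)·pS)`.  Multi-hit codons average over minimal
  mutational pathways, excluding pathways through stop codons.
* **4dTv** — the transversion fraction at fourfold-degenerate third codon
  positions (sites counted only when both codons share their first two
  bases and the family is fourfold degenerate); a slower-saturating
  divergence proxy.
* **Peaks** — genes duplicated together (a WGD) form a mode in the Ks or
  4dTv distribution of paralog pairs.  Modes are found by a Gaussian
  mixture (log scale for Ks) with the component count chosen by BIC, and
  labeled α/β/γ in ascending age.
* **Dating** — a Ks peak is converted to time with the molecular clock
  `T = Ks/(2r)`, `r = 1.5e-8` synonymous substitutions/site/year (dicots).
* **Synteny** — homolog pairs projected to gene-rank coordinates are
  chained per chromosome pair by dynamic programming (strictly monotone,
  gap ≤ 25 ranks, ≥ 5 anchors); paralogs within 10 gene positions on one
  chromosome are tandem duplicates.
* **Enrichment** — for each term, the exact binomial tail
  `P(X ≥ k_fg)`, `X ~ Binomial(n_fg, p_bg)` with the background rate
  `p_bg = k_bg/n_bg`, Benjamini–Hochberg adjusted; each cluster's term
  set is the deduplicated union over its member genes.

## Worked example

Simulate one genome carrying a clean WGD at synonymous depth 0.5
(≈ 16.7 MYA under the dicot clock), call paralogs, and date the peak:

```python
from paleodup.synthetic_data import SimConfig, simulate, depth_to_mya
from paleodup.homology import rbh_paralogs
from paleodup.divergence import divergence_table, detect_peaks, date_peak

cfg = SimConfig(seed=1, n_genes=200, n_chromosomes=4, codons_per_gene=300,
                wgd_events=[(depth_to_mya(0.5), 1.0)])
genomes, annotations, truth = simulate(cfg)
pairs = rbh_paralogs(genomes[0])
table = divergence_table(pairs, genomes)
print(f"paralog pairs: {len(pairs)}")
print(f"median Ks: {table['ks'].median():.3f}   median 4dTv: {table['fourdtv'].median():.3f}")
for peak in detect_peaks(table["ks"], "ks", seed=1729):
    dated = date_peak(peak, rate=1.5e-8)
    print(f"peak {peak.label or '-'}: mean Ks {peak.mean:.3f}, weight {peak.weight:.2f}, "
          f"T = {dated.time_mya:.1f} MYA")
```

prints

```
paralog pairs: 189
median Ks: 0.568   median 4dTv: 0.198
peak alpha: mean Ks 0.567, weight 1.00, T = 18.9 MYA
```

RBH recovers 189 of the 200 planted duplicate pairs; the mixture selects a
single component near the planted depth (Nei–Gojobori counting ignores the
transition bias of the substitution process, hence the characteristic
~10% overestimate of Ks and of the date — see `docs/methods.md`); the
4dTv mode sits at the K80 expectation for that depth.

The same analyses run from the shell via the `paleodup` CLI, driven by a
YAML config:

```bash
paleodup all --config run.yaml --outdir run/
```

with stages `simulate → homology → divergence → synteny → enrich`
exchanging plain TSVs and recording SHA-256 digests of every output in
`run/manifest.json` (two runs with the same config and seed are
byte-identical).

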