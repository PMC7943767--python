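# Methods

`paleodup` detects and dates whole-genome duplications (WGD) from the
divergence distributions of duplicated gene pairs, and carries the
downstream comparative analyses that usually accompany such a study:
collinearity (synteny) blocks, tandem-duplicate classification, orthologous
gene clusters (OGCs), and cluster-level functional enrichment.  This note
records the models, the parameters that matter, the numerical choices, and
what the bundled simulator does and does not emulate.

## Homolog calling

Paralogs (within a genome) and orthologs (between genomes) are called by
the reciprocal-best-hit (RBH) rule: a pair (a, b) is kept iff b is the
top-scoring subject for query a and a is the top-scoring subject for b.
Similarity is exact Smith–Waterman under BLOSUM62 with affine gaps (open
11, extend 1); the unknown residue X scores 0 against everything.  Ties at
the top are broken by higher identity, then lexicographic subject id, and
counted in the log — the RBH rule itself does not define tie handling, so
the tie-break is pinned here for reproducibility.  Reported hits require
score ≥ 50 and identity ≥ 0.3 (both configurable); externally computed
12-column tabular hit files are accepted in place of the built-in search
for large proteomes.

All-vs-all search at desk scale uses a two-track seeding heuristic before
any alignment: candidate subjects must share exact protein 4-mers or CDS
12-mers with the query; per query the 12 best-seeded candidates (CDS seeds
weighted 4×, being much rarer by chance) are aligned, score first and
traceback for identity only on hits passing the score threshold.  The
heuristic only decides which pairs are aligned; every reported score is an
exact Smith–Waterman score.

OGC construction is single-linkage: connected components of the
homolog-pair graph, singletons dropped, cluster ids assigned in order of
each component's smallest member id.  This is a deterministic, testable
stand-in for graph-clustering tools; externally produced cluster tables
can be supplied instead whenever their finer granularity matters.

## Ks: Nei–Gojobori with Jukes–Cantor correction

For each homolog pair the proteins are aligned globally (BLOSUM62, affine
gaps), the alignment is back-translated onto the coding sequences, and
columns with a gap, an ambiguous base, or a stop codon are dropped.  On the
remaining codon columns:

* Synonymous sites per codon: at each position, the fraction of the three
  single-base changes that preserve the amino acid; changes into stop
  codons count as nonsynonymous and stay in the denominator (so a
  fourfold-degenerate codon such as GGT contributes exactly one synonymous
  site).  `S` averages the two sequences; `N = 3·n_codons − S` holds to
  1e-9 by construction.
* Differences: codon pairs differing at one position are classified
  directly; pairs differing at 2–3 positions average the synonymous /
  nonsynonymous step counts over all orderings of the single-base steps,
  excluding pathways through stop codons (if every pathway is excluded,
  all are used).  Steps touching a stop codon count as nonsynonymous.
* Correction: `Ks = −(3/4)·ln(1 − (4/3)·pS)` with `pS = sd/S`; the pair is
  flagged SATURATED when the log argument is non-positive (`pS ≥ 3/4`),
  and saturated pairs are excluded from distribution fitting, as are
  values above a cap (default 5.0) where the correction explodes.

This estimator is used because it is closed-form and checkable against a
hand enumeration (the test suite verifies every per-codon count against an
independent pathway enumerator).  Its known bias matters for
interpretation: ignoring transition/transversion asymmetry inflates `pS`
when transitions dominate, so at a true synonymous distance of 0.5 with
ts/tv rate ratio κ = 2 the recovered peak sits near 0.55 (≈ +10%), which
propagates into dates.  The package reports the estimator name in its
outputs; dates inherit this bias and should be read accordingly.

## 4dTv

A third-codon-position site is eligible iff both codons belong to a
fourfold-degenerate family **and** their first two bases are identical;
4dTv is the fraction of eligible sites whose third bases differ by a
transversion (purine ↔ pyrimidine).  The statistic is undefined (flagged,
not zero) when a pair has no eligible site.  Raw 4dTv is the default; an
optional transversion-only multiple-hit correction
`−(1/2)·ln(1 − 2·4dTv)` — the transversion component of the K80/HKY model
under equal base frequencies — is available behind a flag, since published
4dTv values do not always state whether they are corrected.

## Peak detection and dating

Mixture peaks are found with a Gaussian mixture fitted for k = 1..4
components and selected by BIC (fixed random state, default 1729, three
initializations).  Ks is fitted on the log scale (components of a Ks
distribution are approximately log-normal) and peak locations
back-transformed as `exp(μ)`; 4dTv is fitted on the raw scale.  Peaks are
reported in ascending order and the three largest-weight components are
labeled α/β/γ by ascending mean, matching the usual naming of recent /
intermediate / ancient duplication modes.  Fewer than 30 usable values is
an error that points to the KDE fallback (Gaussian kernel, Silverman
bandwidth, local maxima; basin mass as weight).

A Ks peak is dated with the molecular clock `T = Ks/(2r)`, with `r`
defaulting to 1.5e-8 synonymous substitutions per site per year, the
conventional dicot rate.

## Synteny

Anchors are homolog pairs projected to gene *rank* coordinates (0-based
order along each chromosome); all distance logic is in ranks, never base
pairs, except co-localization spans, which report base pairs.  Chaining is
per-chromosome-pair dynamic programming maximizing anchor count, with ties
broken by smaller total rank gap: chains must be strictly monotone on both
axes (decreasing on the second axis for inverted blocks) with per-step
gaps ≤ `max_gap` (default 25); chains shorter than `min_block` (default 5)
are discarded; the best chain is removed and the search repeats, so each
anchor joins at most one block.  The defaults mirror common collinearity-
tool settings and are configurable; the DP is verified against an
exhaustive chain enumerator on small inputs.

Two practical rules around anchoring:

* In self-comparisons, same-chromosome pairs within 10 ranks of the
  diagonal are excluded before chaining.  Runs of tandem duplicates
  otherwise chain into spurious near-diagonal "blocks", which would
  contaminate the block-restricted divergence distribution.
* RBH keeps one partner per gene and therefore cannot exhibit the 2:1
  gene depth a WGD leaves against an unduplicated relative.  Synteny-depth
  analysis instead anchors on the top-N hits per query (default 5), the
  way collinearity tools consume BLAST lists.

A pair is a **tandem** duplicate iff both genes sit on the same chromosome
within 10 gene positions (inclusive; the boundary is pinned by test), else
dispersed.  Synteny depth of a gene is the number of blocks whose rank
interval on that genome's axis covers it; the modal depth over covered
genes summarizes duplication multiplicity (2 after a WGD).

## OGC classification and enrichment

With species assigned to two groups (e.g. cactus / noncactus), a cluster
is group-A-specific iff it contains ≥ 2 distinct A-species and no
B-species (symmetrically for B); shared iff it contains ≥ 1 of each;
clusters with < 2 distinct species are unclassified.  A cluster's term set
is the union of its member genes' GO/KEGG terms — a term occurring on
several members counts once.

Enrichment of a term in a foreground cluster set against a background set
uses the exact one-sided binomial tail `P(X ≥ k_fg)` with
`X ~ Binomial(n_fg, p_bg)` and `p_bg = k_bg/n_bg`; `n_fg`/`n_bg` count
annotated clusters only (a flag restores all-cluster counting), add-one
smoothing handles `k_bg = 0`, terms in fewer than 3 foreground clusters
are skipped, and Benjamini–Hochberg adjustment is applied across tested
terms (significance default α = 0.01).  For externally supplied expanded
cluster sets, the background is the conserved clusters containing ≥ 1
species from every clade, minus the expanded set.  The expansion analysis
itself (birth–death modeling) is out of scope; expanded sets are inputs.

## The simulator

`synthetic_data.simulate` grows multi-species gene sets from one ancestral
genome along a ladder phylogeny (each non-focal species branches off the
focal lineage at its configured split time; at equal times a split
precedes a WGD, so that species does not inherit it).

* **Sequences** evolve by K80 nucleotide substitution: events are Poisson
  with expectation `rate × time` per site; each event proposes a
  transition with probability κ/(κ+2) else one of the two transversions,
  and proposals creating a stop codon are rejected, so no CDS ever
  contains an internal stop.  With no selection in the model, every site
  is effectively synonymous-like, and the truth table records the exact
  expectation `2 × rate × elapsed_years` for every pair.  Stop rejection
  cannot affect fourfold third positions (no stop codon lies in a
  fourfold family), so the K80 closed form holds exactly there — the test
  suite checks realized substitution fractions against it within three
  standard errors.
* **WGD** duplicates every gene onto a mirrored set of new chromosomes
  preserving ancestral order (clean planted collinearity); each duplicate
  is retained with `retention_prob`, the original always kept.
* **Tandem duplications** insert a copy at rank+1 at each tip; the copy
  alone is evolved by `tandem_depth`, keeping ortholog truths exact at
  the cost of a slight asymmetry between the two copies.
* **Rearrangements**: inversions reverse a random rank interval (flipping
  strands); translocations move a random interval to another chromosome.
  Both fragment the planted collinearity controllably.
* **Annotations**: each ancestral family draws 1 + Poisson(2) terms from a
  200-term vocabulary with power-law frequencies (exponent 1.5, mimicking
  real GO skew); planted terms are attached independently at a base rate
  (default 0.08), multiplied by the configured fold in families destined
  for the target species group.  Group-specific families are created by
  deleting a configurable fraction of families from the other group's
  species.  `simulate_clusters` generates the cluster/annotation layer
  directly (no sequences) for enrichment studies at larger n.

Defaults describe the benchmark scenario used throughout the tests and
the acceptance script: 500 genes on 5 chromosomes, 300 codons per gene,
one clean WGD at pairwise synonymous depth 0.5 (≈ 16.7 MYA at the dicot
clock), κ = 2 (a typical plant nuclear ts/tv rate ratio), tandem rate 0.15
per gene at depth 0.05 where tandems are enabled.  The two-species depth
study places the sister split at depth 0.6, just older than the WGD:
under neutral evolution much older splits leave proteins unalignable,
which real purifying selection would prevent but this simulator does not
emulate.

**What passing tests do not show.** The simulator has no indels (so
back-translation columns drop only via substitution artifacts), no rate
variation across sites or lineages, no gene conversion, no selection
(protein divergence is much faster than in real proteomes at a given Ks),
uniform codon usage, and star-free ladder topologies.  Recovery rates
measured here are therefore upper bounds for real annotations, where
fragmented gene models and isoform handling dominate the error budget.

## Determinism

Every stochastic component takes an explicit seed (simulator configs,
mixture fitting default 1729); the pipeline writes plain TSVs with fixed
float formatting and a JSON manifest of SHA-256 digests per stage, and two
runs with the same config and seed are byte-identical — asserted in the
test suite.
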