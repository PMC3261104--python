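# Methods

This note records the scientific model behind `genesift`, the
parameters that matter, the numerical and design choices made where the
protocol left room, and what the synthetic fixtures do and do not show
about real data.

## Pipeline model and assumptions

The pipeline assumes GWAS association evidence arrives as per-marker
p-values (Cochran–Armitage-style trend tests summarised in a
PLINK-compatible `.assoc` table) and that causal genes reveal
themselves in two ways: their neighbourhood accumulates significant
SNPs, and they share biology — pathway membership or protein-domain
content — with genes near *other* associated loci or with known disease
genes. No linkage-disequilibrium structure is modelled anywhere;
physical distance is the only genomic prior, which is also why locus
clustering is a naive fixed-gap single linkage rather than an LD-aware
method.

### Significance tiers

Four tiers stratify evidence strength: WS (p ≤ 1e-3), MWS (p ≤ 1e-4),
MHS (p ≤ 1e-5) with inclusive comparison, and HS (p < 5e-7) with a
**strict** comparison. The asymmetry is deliberate and matters at
boundary values: a marker at exactly 5e-7 belongs to MHS but not HS.
Q-Q points use the rank/(n+1) plotting position — a conventional choice
that affects only the diagnostic, never predictions; ties in p are
ordered stably by SNP id.

### Locus clustering

`gap_bp` defaults to 50,000 (average haplotype-block scale). Distance
exactly equal to the gap merges ("within" read inclusively). Clustering
is transitive, so a chain of SNPs 40 kb apart forms one locus of
arbitrary span. The equivalence with a graph transitive-closure oracle
is asserted on randomized instances up to 1000 SNPs.

### Search spaces

Internally all coordinates are 0-based half-open (BED native);
1-based `.assoc` positions are converted on read. Distance is measured
from the SNP to the nearest gene boundary, strand ignored. Design
choices where the definitions were genuinely open:

- Bystander intervals are anchored per member SNP and unioned per
  locus. Under 50-kb clustering this equals widening the locus span for
  widths ≥ 0.1 Mbp and handles singleton loci identically.
- *adjacent* means the four genes nearest the SNP overall (residents
  count at distance 0), not two per side; ties break by
  (distance, smaller start, gene id) for determinism.
- *nearest* with an equidistant gene on each side keeps the gene with
  the smaller start coordinate (logged).
- A locus on a chromosome absent from the catalog maps to an empty gene
  list (logged) rather than erroring, so partial catalogs degrade
  gracefully.

Genome coverage treats every chip SNP as its own singleton locus and
reports the fraction of catalog genes capturable under each approach;
it is monotone in bystander width by construction.

### CPS contingency model

The unit-based 2×2 realises the rule that genes from one associated
region must not be counted multiple times. Associated units are loci
containing at least one annotated search-space gene (a locus is "in the
pathway" if any of its genes is), plus seed genes lying outside every
locus; seeds inside a locus merge into the locus unit rather than
double-counting. The non-associated side counts individual annotated
genome genes outside all loci and not seeds. The universe is
annotated genes only — unannotated genes carry no pathway or domain
evidence and can never be predicted, though they still count in
search-space sizes and validation denominators.

Sidedness defaults to the one-sided (greater) tail because CPS tests
over-representation; two-sided is available via `sided="two_sided"`.
No multiple-testing correction is applied across pathways by default
(raw p < 0.05); a Bonferroni option (`bonferroni=True`, dividing alpha
by the number of pathways tested) exists for stricter use. Degenerate
margins return p = 1 by convention. Ranks are dense ordinals: pathways
sorted by ascending p, equal p-values sharing a rank, and a gene in
several significant pathways inherits its best pathway's rank.

### CMP probability model

The pairwise similarity is a weighted Jaccard over domain multisets
(Σ min copies / Σ max copies): the simplest function satisfying the
printed anchors — 0 for disjoint domain sets, 1 for identical
signatures, a meaningful 0.4 threshold (read inclusively). It is a
stand-in for the original score whose formula is published elsewhere,
and is pluggable via the `similarity` argument of `cmp_seeded`.

For ab initio over-representation, with f(d) the fraction of annotated
genome genes carrying domain d:

- maximal correlation: p_corr = min_d f(d) (the combination occurs
  whenever its rarest domain does) → chi2_min;
- full independence counting copies: p_indep = Π_d f(d)^copies
  (duplicated domains drive it anomalously low) → chi2_max;
- independence ignoring copies: p_indep_unique = Π_d f(d) → the
  corrected chi2_max_unique.

p_indep ≤ p_indep_unique ≤ p_corr holds by construction (every factor
≤ 1); p_indep is computed as p_indep_unique times the extra copy
factors so the ordering is exact in floating point. Each chi-square is
(obs − n·p)²/(n·p), floored at 0 when obs ≤ expected: the
under-representation (lower) tail is computed in the sense of being
well-defined but never emits predictions. Matching a combination in
the search space ignores copy counts by default (making the
unique-variant correction meaningful); `match_copies=True` demands the
full multiset. Emission requires carriers in ≥ 2 distinct loci and the
conservative cutoffs chi2_max_unique ≥ 1e5 (multidomain) or
chi2_min ≥ 1e2 (single-domain), both inclusive as printed; 7.88 is kept
as the 0.005-level anchor constant for calibration checks.
Prioritisation is by descending chi2_min, the metric adopted as the
priority score; seeds are excluded from ab initio input.

### Random controls

Random SNP sets are drawn without replacement from the chip universe,
sized to the number of associated *loci* in the real data so that LD- or
association-driven clustering does not deflate the control. One draw per
replicate is shared across approaches and cells for comparability.
Defaults: 1000 replicates (scaled down in desk tests), occurrence
filter at 5 % of replicates with a strict `>` comparison (a gene at
exactly the threshold is kept), log prediction ratio in base 10 with a
0.5 pseudocount so (0, 0) maps to 0. The occurrence threshold, base
and pseudocount are package choices — the protocol names none — and are
configurable.

**Null emission rate.** The CPS calibration quantity is the
*unconditional* per-pathway emission probability: emissions divided by
(pathways × replicates). Conditioning on the ab-initio ≥ 2-loci gate
would select exactly the extreme hypergeometric tables (under the null
the expected locus-hit count is far below 1, so two hits *is* the tail
event) and the conditional rate would approach 1 for any correct exact
test; the unconditional rate is what the nominal alpha bounds.

### Validation

Confusion counts are taken over annotated search-space genes, with the
validation set restricted to that universe first (genes outside the
space, or unannotated, are not scoreable). sensitivity = tp/(tp+fn),
specificity = tn/(tn+fp), enrichment ratio = precision/prevalence; a
component with a zero denominator is reported as missing, never as 0.
LOOCV reruns seeded prediction with each in-space seed withheld and
records its recovered rank; ROC points sweep the rank cutoff and are
monotone in both coordinates.

## Synthetic data generator

The generator emulates the summary-statistic level only: a gene catalog
laid out per chromosome (log-normal lengths, median 20 kb, σ = 0.8,
clipped to [2, 300] kb; exponential intergenic gaps, mean 40 kb),
20,000 SNPs placed uniformly (≈1 per 6 kb, chip-like density relative
to the genome), uniform(0,1) background p-values, 200 pathways of 5–40
random members, and 250 domains assigned with a Zipf-like frequency
skew (40 % of genes multidomain, copy counts geometric and mostly 1;
85 % of genes domain-annotated).

The planted signal comprises five causal genes in five prospective
loci separated by ≥ 200 kb (≥ 4× the clustering gap, so they can never
merge): four of them form the causal pathway, and all five carry a
causal domain padded to genome frequency 0.005 with carriers outside
the loci. Each causal gene receives three SNPs within a 10-kb window
and p-values log-uniform on [1e-8, 1e-5], so the signal is present from
the MHS tier upward while the background contributes ≈0.2 SNPs at MHS —
recovery tests run on an almost-pure signal tier by design. The
fifth, pathway-free causal gene exists so that domain-based recovery is
tested over five loci while pathway-based recovery is tested over four.

What passing recovery tests does **not** show about real data: there is
no LD (so locus boundaries are sharper than reality), no correlation
between gene length and annotation, no overlapping genes, no population
stratification or case/control noise, and the planted effect is far
cleaner than typical complex-trait architecture. The generator
validates feasibility (genes must fit a fixed chromosome length if one
is given) before writing anything, and identical seeds produce
byte-identical bundles.

## Problem sizes in the checked runs

The automated checks use: all ≈46k 2×2 tables of total ≤ 30 for the
Fisher/enumeration agreement; 500 random clustering instances of up to
1000 SNPs; 100 random layouts for nesting; 100 generator replicates for
planted-pathway recovery; 200 replicates for the null calibration and
50 for the planted log-ratio control. These sizes give binomial
standard errors comfortably inside the asserted tolerances while
keeping a full run in tens of seconds.

## Known limitations

- The similarity and expectation formulas are principled stand-ins
  satisfying all printed constraints of the original system, not
  reconstructions of its unpublished internals.
- The unit-based CPS table mixes unit kinds (loci on the associated
  side, genes on the non-associated side); this is accepted as the
  concrete realisation of the locus-deduplication requirement.
- X/Y chromosomes are passed through as labels only; transcript-level
  isoforms, Pfam clans and LD-aware intervals are out of scope.
- With whole-genome-scale inputs the per-SNP nearest/adjacent queries
  scan each chromosome's gene array; this is fast at tens of thousands
  of SNPs but would deserve an indexed k-nearest query for chip-scale
  universes crossed with the full grid.
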