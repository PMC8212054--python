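# Methods

This note documents the models, conventions and numerical choices behind
`flavorhap`, and what the synthetic panel does and does not emulate.

## Coordinates and genotype conventions

All internal coordinates are 0-based half-open; VCF/GFF3 I/O converts at the
boundary. Genotypes are additive dosage codes (hom-ref 0, het 1, hom-alt 2,
missing), and phase is discarded everywhere — no stage uses it. Multiallelic
rows are split into biallelic records and indels left-aligned against the
reference; a genotype carrying a different alternate allele than the row being
emitted is unrepresentable in that row and becomes missing. A record is an SV
when declared by SVTYPE or when an allele is ≥ 100 bp, a SNP when both alleles
are single bases, an INDEL otherwise.

## Variant QC

SNP filters are KEEP conditions and INDEL filters are REMOVE conditions (the
conventional directions for the respective annotation sets); both are explicit
fields of `FilterSpec` rather than inferred, because upstream tools print them
in opposite senses. A record missing a required INFO field is dropped with
reason `missing_info` by default (configurable to pass-through). The
missingness ceiling has two profiles: 10% for a diverse panel, 50% for a
low-coverage cultivated set. MAC counts the minor allele over non-missing
genotypes only (het = 1, hom-alt = 2). SVs of identical type whose start *and*
end breakpoints lie within 500 bp are merged transitively; the merged record
takes the lower-median start, the allele of the record closest to it, and a
per-accession genotype union (any het → het, all hom-alt → hom-alt, mixed
hom calls → het). Thinning is greedy left-to-right with ≥ spacing, so exact
1000-bp spacing survives.

## Consequence annotation

Region classes are assigned by containment: strand-aware flanks (3 kb
upstream, 1 kb downstream by default), exon-minus-CDS as UTR (5′/3′ by
position relative to the CDS span and strand), introns, and a splice window
of 2 bp at each intron end (the canonical donor/acceptor dinucleotides; the
window is configurable). CDS SNPs are translated on the coding strand with
the standard code; CDS indels are frameshift unless the net length change is
a multiple of three. When a variant touches several features the most severe
class wins (start_lost > stop_gained > frameshift > splice_site >
inframe_indel > missense > synonymous > UTR > intronic > up/downstream). A SNP
that destroys the stop codon is reported as missense (the class enumeration
has no stop_lost; it is protein-changing either way, and the diversity fold
is unaffected). For diversity, missense/start_lost/stop_gained/splice_site
fold to non-synonymous, all region classes to non-coding. For haplotype
heatmaps, splice-site variants display as frameshift. The annotator is tested
exhaustively: every single-base substitution of a three-exon toy gene is
compared against an independent whole-protein translate-and-diff oracle, and a
minus-strand gene must classify identically to its reverse-complement mirror.

## Haplotype clustering

The dosage matrix covers SNPs and INDELs in the gene ± flanks (SVs are handled
separately — they are rare at locus scale and their genotypes are less
reliable). Distance is Manhattan on dosage with NA pairs omitted and the sum
rescaled by the fraction of jointly observed variants (dosage differences are
count-like, so city-block is the natural metric; Euclidean is available).
Clustering is the classical ward.D: the Ward Lance–Williams update applied to
the *raw* dissimilarity, not its square — scipy's `ward` implements the
squared variant, so the agglomeration loop is written out here and
cross-checked against an independent hierarchical-clustering implementation's
merge heights. Equal-distance merge candidates are broken by the
lexicographically smallest pair of cluster ids (id = smallest member index),
making the tree fully deterministic. The tree is cut at k = 6 by default
(configurable); labels I..VI are ordered by cluster size. Phenotype decile
classes use nearest-rank empirical deciles with ties sharing the lower decile:
deciles 1–5 are low, 6–8 medium, 9–10 high. Cluster–phenotype differences use
a one-way model with Tukey HSD; the compact letter display uses
insert-and-absorb, which guarantees exactly that two clusters share a letter
iff their adjusted p ≥ α. Clusters with fewer than two phenotyped members are
excluded with a warning; an all-constant phenotype yields a single shared
letter.

## Haplotype networks

Coding haplotypes substitute only homozygous-alternate CDS SNPs into the
reference CDS; heterozygous *and* missing genotypes stay reference (the
hom-alt-only substitution rule, extended to missing data). CDS indels are
excluded so Hamming distance is defined on equal-length sequences — the
synthetic setting builds all haplotypes on a shared reference, so they are
already aligned; gap-aware distance is an extension point. The epsilon = 0
network is the union of all minimum spanning trees, computed by processing
edges in weight classes over a disjoint-set forest: an edge is kept iff its
endpoints are unconnected by strictly lighter kept edges, with all edges of a
weight class tested before any is merged. A strict single-MST mode (Kruskal,
lexicographic tie-break) is also exposed. Note that the union of all MSTs may
contain *non-minimal* spanning trees assembled from edges of different MSTs;
correctness is therefore asserted as exact set equality with an
exhaustive-enumeration oracle on ≤ 7 nodes, not as "every contained tree is
minimal". An outgroup sequence (the reference CDS by default) is added as a
flagged node to root the network.

## Nucleotide diversity

π_site = ref·alt / C(n, 2) over the 2N chromosomes observed at the site
(heterozygotes contribute one of each allele, missing genotypes are excluded
site-wise). Windows of 1000 bp tile the flanked region from its left boundary;
window π divides the summed site values by the *window length*, not the
number of genotyped sites — matching the convention of the standard
command-line tool, and deflating π where data are sparse (documented because
it matters when comparing across coverage regimes). Only SNPs enter; classes
partition SNPs, so class-restricted π sums exactly to all-SNP π per window
(asserted). The gene-level summary is the mean over windows.

## Association

A single phenotype vector is "quantile normalized" as rank-based
inverse-normal with the Blom offset (r − 3/8)/(n + 1/4), average ranks for
ties, gated by Shapiro–Wilk at p < 0.01; missing values stay missing and
ranks are preserved. The scan is an ordinary per-variant linear model
phenotype ~ dosage with optional subpopulation indicator covariates — a
deliberate simplification of the original mixed-model machinery, whose fixed
significance thresholds are specific to a genome-wide test count; here
significance is per-run BH-FDR with tiers at q ≤ 0.05 and q ≤ 0.01. Dosage is
additive (het = 1); MAF is computed on dosages and floored at 2% (kept low to
retain rare alleles). PVE is the likelihood-ratio R² of the model with the
variant minus that of the model without it, R²_LR = 1 − exp(−(2/n)(ℓ − ℓ₀));
for the Gaussian model without covariates this equals OLS R² exactly
(asserted to 1e-10). LD r² is the squared Pearson correlation of dosage
vectors on their jointly observed entries.

## Duplication genotyping

Three evidence channels per accession: normalized coverage over the gene
(baseline = genome-wide depth, or the 3-kb + 1-kb flank mean where only local
depth exists — flanks match the gene's GC/mappability context), apparent
heterozygosity (fraction of in-gene variant sites called het, inflated when
paralogous reads mismap onto a single-copy reference), and presence of a
deletion when calling against an alternate assembly that carries both copies
(50% reciprocal overlap with the duplicated segment). A carrier must meet at
least two of: coverage ≥ 1.5× (midpoint of the one- and two-copy
expectations), het fraction ≥ 0.4, deletion absent. Thresholds are
configurable and echoed in the output metadata; the rule is monotone in all
three channels (property-tested).

## Synthetic panel

The generator is a founder-haplotype mosaic, not a coalescent: the downstream
stages need clustered haplotype structure, LD and planted effects, and a
mosaic provides all three at desk scale with full control. Defaults are the
study conditions: 166 accessions in the nine named subpopulations; six
founder haplotypes (founder 0 identical to the reference, as landraces tend
to be) derived from the ancestor by per-site mutations at rate 0.0045 over
the ~7.3-kb flanked region (≈ 33 mutations per founder, so founders are
separated by far more than 10 fixed differences); each subpopulation draws
its accessions predominantly from one founder (12% admixture probability,
92% selfing, matching a highly selfing crop), plus rare private mutations
(4 × 10⁻⁵ per site) and 2% missing genotypes. The default locus emits ~230
variants, inside the observed 100–450 per-locus range. Planted variants
guarantee at least one of every consequence class, including a 13-bp coding
duplication (frameshift) and a 15-bp deletion (in-frame, five codons).

Phenotypes are additive: y = μ + β·dosage + N(0, σ), with β solved from the
realized dosage standard deviation so the theoretical PVE matches the
configured fraction (0.15 by default — the magnitude of the reported top-SNP
PVEs at four of the five loci). Causal variants are chosen automatically
among intermediate-frequency sites closest to MAF 0.30. Sugar (SSC, °Bx,
baseline 5.0 ± 1.0) and malate (mg/g, 2.5 ± 0.6) are Gaussian; the two
volatiles (isobutyl acetate, (Z)-3-hexen-1-ol, ng/g) are log-normal with
log-scale means 2.5/2.8 and SDs 0.8/0.9 — real volatile panels span orders of
magnitude, the log-normal choice reproduces that skew, makes the Shapiro gate
fire (so the rank-normalization path is exercised end-to-end), and puts the
(Z)-3-hexen-1-ol scale near the reported ~16–26 ng/g group means. Duplication
evidence plants 28 carriers among the wild and Ecuadorian subpopulations with
coverage 2.0 ± 0.08 vs 1.0 ± 0.08 and het fraction 0.55 ± 0.05 vs
0.08 ± 0.05 — a ≥ 4-SD separation per channel. One RNG stream per component
(reference, founders, genotypes, phenotypes, missingness, evidence, QC
decoys) keeps components independently reproducible; the whole bundle is
byte-identical given the seed.

**What the generator does not emulate** — and therefore what passing tests do
not show about real data: read-level artifacts (mapping bias, allele balance,
base errors), recombination within the locus (accessions are founder mosaics
at the whole-locus level, so LD is block-like and stronger than real data),
site-frequency spectra under demography and selection, genotype-call
correlation between missingness and depth, and duplication evidence derived
from actual mismapped reads (the evidence table is simulated at the summary
level the genotyper consumes). Results on real panels depend on upstream
calling quality in ways these tests cannot certify.

## Numerical and design notes

- Problem sizes in tests and the acceptance script (e.g. 10–100 simulation
  seeds per check, 200–1000 variants per scan, ≤ 7 nodes for exhaustive tree
  enumeration) are chosen so each check carries clear statistical meaning
  while the whole suite stays desk-scale.
- The association power check simulates independent variants: top-rank
  recovery of the causal variant is a property of the scan, and in the
  LD-dense bundle the planted causal is typically tied with its perfect LD
  partners (the analysis scripts report the top hit's r² with the causal
  instead, which is ~1).
- Ties: ward.D merges lexicographically; thinning keeps the first variant per
  window; decile ties share the lower decile; MST ties are resolved
  lexicographically in strict mode and kept in full in the default network
  mode.
- Degenerate inputs fail fast with specific errors: empty haplotype matrix,
  constant phenotype, < 10 values for deciles, < 5 genotyped sites or
  non-positive baseline depth for duplication evidence, monomorphic causal
  variant for effect planting.
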