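# Methods

## Problem and pipeline

`growthnet` re-implements, as a tested pipeline, a candidate-gene discovery
analysis for idiopathic short stature (ISS) cohorts sequenced as trios
(affected child plus both parents) or as affected-only exomes. The pipeline
runs in five stages:

1. **Inheritance detection** — per family and gene, trio genotypes are
   screened for de novo, homozygous-recessive, compound-heterozygous and
   X-linked recessive patterns (plus a dominant-inherited catch-all).
2. **Variant classification** — each variant is placed on the five-class
   scale (I benign … V pathogenic) by a frequency-dominant rule table;
   classes I–II are excluded.
3. **Gene-level evidence and tiering** — surviving variants are aggregated
   per gene, merged with 8 boolean evidence categories into a combined score
   (1–4), and genes are tiered into high/medium confidence.
4. **Enrichment and clustering** — a growth-gene list is tested per
   annotation term (one-sided Fisher exact, BH FDR), and terms are fuzzily
   clustered by Cohen's kappa over shared genes.
5. **Candidate mapping and report** — candidates are mapped onto the
   clusters via member-term gene sets and a JSON/TSV report bundle is
   emitted, including a deterministic squarified treemap layout.

## Inheritance rules and their edge cases

A variant is *de novo* when the child carries an alternate allele absent
from both parents (heterozygous on autosomes, hemizygous alternate on the
male X); *homozygous* when the child is homozygous alternate and both
parents are heterozygous carriers; *X-linked recessive* when an X variant is
hemizygous alternate in a male child with a heterozygous mother and a
reference father. Compound heterozygosity requires at least two heterozygous
variants in one gene with opposite parental origin; origin is inferred from
parental genotypes only (no read-backed phasing), so a variant carried by
both parents is phase-unknown and never counts toward a compound pair.
Mendelian impossibilities (homozygous-alternate child with a parent lacking
the allele; homozygous-reference child with a homozygous-alternate parent;
heterozygous child with two homozygous-alternate parents) are flagged
`mendel_error` and excluded from pattern labels. Missing genotypes
invalidate pattern calls and fall through to `unresolved`. Pseudoautosomal
regions are ignored: every X variant is treated as hemizygous in males.
The implementation is verified against an independent brute-force
enumeration of all trio genotype combinations (autosome and X, both child
sexes).

## Classification rule table

The published analysis defers its exact thresholds to supplementary
material, so the default table is a deliberately simple ACMG-like,
frequency-dominant stand-in, fully configurable via YAML:

| condition | class |
|---|---|
| af ≥ 0.01 | I (benign) |
| 0.001 ≤ af < 0.01, not loss-of-function | II (likely benign) |
| LoF (nonsense/frameshift/splice) + de-novo-like pattern | V |
| LoF inherited, or missense de novo | IV |
| otherwise | III (VUS) |

Missing allele frequency is treated as 0 — absence from population controls
is the strongest rarity signal. The table is monotone: raising the allele
frequency can never move a variant toward pathogenic (property-tested). A
manual structural-override flag can raise class III to IV only, mirroring
how in-silico structure analysis was used for reclassification; structure
prediction itself is out of scope.

## Combined score and tiering

The per-family combined score merges the family's best surviving variant
class with the gene's evidence-category count:

    score = clamp(1 + (class − 3) + [categories ≥ 3] + [categories ≥ 6], 1, 4)

exposed as an explicit 3×9 lookup so the published decision table (also
supplement-only) can be dropped in. The formula reproduces the co-occurrence
visible in the published per-gene table (class V with 5 categories → 4;
class IV with moderate counts → 3; class III with few categories → 1–2) and
is monotone in both arguments (tested over the full grid). A gene reports
the min–max score range across families and tiers on the maximum: *high*
requires ≥ 2 independent families and a maximum score ≥ 3; otherwise a gene
with score ≥ 2 or any functional evidence is *medium*; the rest are
rejected. Tiering is idempotent.

## Enrichment statistics

For query list of size A against a background of size A+B, a term with a
in-list and b out-of-list genes is scored by the one-sided Fisher exact test
(the hypergeometric upper tail P(X ≥ a)), the odds ratio
(a/(A−a))/(b/(B−b)) with an infinity sentinel when A−a = 0 or b = 0, and
fold enrichment (a/A)/((a+b)/(A+B)). Benjamini–Hochberg step-up adjustment
is applied across terms; significance is FDR ≤ 0.05. An optional EASE-style
correction (one success removed before the tail) is available because the
original analysis routed through a DAVID-like tool; the classical test is
the default since EASE use is not stated. Gene identifiers are harmonised by
case-insensitive exact match only.

## Kappa fuzzy clustering

Term–term similarity is Cohen's kappa over the gene universe (2×2 agreement
table: both/one/neither annotate a gene). Pairs sharing fewer than
`min_gene_overlap = 5` genes are forced to 0; the published parameter
"kappa = 20" is read as a threshold of 0.20 (the source tool takes the value
×100; a raw 20 is outside kappa's range). Seeds grow around every term from
its ≥-threshold neighbours and are kept when they reach 5 members with at
least 50% of internal pairs tight; seeds merge while any two share ≥ 50% of
the smaller's members. The source heuristic is order-dependent, so a
deterministic merge order is imposed: highest sharing fraction first, ties
by smaller merged size, then lexicographically smallest member tuple —
clustering is therefore invariant under input permutation (tested). Raw
p-values drive clustering; members with FDR > 0.05 are pruned afterwards,
following the stated order of operations. Cluster summaries: representative
term = lowest raw p (ties: larger gene set, then lexicographic), enrichment
score = −log10 geometric mean of member raw p-values, mean fold enrichment =
arithmetic mean. The kappa universe defaults to the full background; a flag
restricts it to annotated genes.

## Synthetic-data generator

The generator's defaults encode the study conditions: 254 families with
69/254 ≈ 27% affected-only; inheritance mix {de novo 0.71, X-linked 0.17,
homozygous 0.06, compound het 0.06} (the published 71/17/11 splits the
recessive mass and is normalised to sum to 1); consequence mix
missense/nonsense/splice/in-frame = 0.78/0.15/0.06/0.01; causal allele
frequencies in [0, 1e-4] (25% reported as absent from controls) against 50
background variants per family drawn at common frequencies (0.01–0.2) with
Mendelian-consistent inherited genotypes. Compound-het families carry
exactly two causal variants in one gene, one per parent. The
background-variant burden per exome is a free parameter, not a published
value.

The annotation corpus plants blocks of correlated terms: each block is one
shared gene set (disjoint across blocks); with noise r each gene of a term
is swapped for an outside gene with probability r, so noiseless blocks have
pairwise kappa 1 and between-block kappa ≤ 0. Null terms are uniform random
gene sets. The growth-gene list includes each block gene with probability
`fold × L/N` and is filled to size L with non-block genes, so block terms
are enriched at approximately the configured fold. One root seed spawns
independent sub-streams per stage.

What the generator does **not** emulate: linkage disequilibrium, locus- or
gene-specific mutation rates, sequencing/genotyping error, annotation-term
nesting (GO hierarchy) and realistically long-tailed term-size
distributions. Passing recovery tests therefore demonstrate correctness of
the algorithms under idealised sampling, not calibrated performance on real
exome or annotation data.

## Operating-characteristic checks and problem sizes

Recovery tests run at desk scale: the global-null FDR check uses 200
replicate corpora of 200 terms over 1,000 genes (mean false-discovery
proportion ≤ 0.05 plus two Monte-Carlo standard errors). The planted-power
check uses 20 single-term planted blocks among 500 nulls over 4,000 genes
with a 400-gene list at fold 4 — an a-priori power computation (in-list
hits ~ Binomial(40, 0.4) against a BH cutoff near rank 20 of 520 tests)
gives per-term detection probability ≈ 0.97, so ≥ 18/20 recovered on
average, as required; 30 replicates bound the Monte-Carlo error. Block
recovery is exact (adjusted Rand index 1) on noiseless corpora and ≥ 0.8 on
average over 50 replicates at 20% annotation noise. Oracle equivalences are
exhaustive where cheap (all 2×2 tables with universe ≤ 25, all trio
genotype combinations) and seeded-random at larger sizes (300 tables up to
universe 200; >1,000 kappa pairs).

## Numerical and degenerate-input choices

Underflowed p-values are floored at the smallest positive double. Kappa is
defined as 0 with a warning when chance agreement Pe = 1 (constant
annotation vectors). Odds ratio is 0 when a = 0 and 0 (not ∞/∞) when every
non-list gene carries the term. Percentages round half-up at the printed
precision (integer for cohort fractions, one decimal for the
previously-reported fraction). Writers use fixed float formatting and sorted
orderings so a re-run with the same seed is byte-identical; the run manifest
records input checksums, a configuration hash, the seed and the package
version, and deliberately no timestamps.

## Known limitations

* The classification rule table and combined-score table are stand-ins for
  supplement-only published tables; both are configurable but the defaults
  have not been validated against the original per-variant calls.
* The published per-gene variant-class tallies are partly ambiguous in the
  source table; the shipped fixture marks those cells.
* The 50-gene medium-confidence roster is a synthetic stand-in (5 published
  previously-reported genes plus 45 synthetic single-family rows).
* Reproducing the published 29 annotation clusters would require the
  original annotation-database snapshot and the 1,025-gene query, both
  external and version-dependent; cluster counts are not asserted anywhere.
* Compound-het detection is restricted to parent-resolvable phase; true
  compound heterozygotes with both parents carrying are missed by design.
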