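# Methods

## The analysis

The pipeline asks whether trait groups — here five age-related disease
categories — share genetic architecture at the gene level and at the
pathway (GO term) level.

**Filtering.** Catalog rows are expanded to one record per rsid (multi-SNP
cells split on `;`/`,`). A trait survives when it has been examined in at
least `min_studies` (default 5) distinct studies, counted on the unfiltered
records; a SNP survives when its association p-value is strictly below
`p_max` (default 1 × 10⁻⁵). The strict inequality is deliberate and
configurable (`strict_less`): the inclusion rule is "less than" the
threshold, and boundary SNPs exist in real catalogs. "Independent GWAS" is
operationalised as distinct study identifiers per trait label; the catalog
does not expose cohort overlap, so this is a documented knob rather than a
claim about true independence.

**SNP→gene assignment.** A SNP maps to every gene whose interval contains
it (0-based half-open, BED convention; 1-based location tables are shifted
on read) and to every gene containing an LD partner with r² ≥ `r2_min`.
The default `r2_min = 0.8` is the conventional "high LD" cut-off; the
source analyses said only "high or complete LD", so the value is exposed.
LD is applied at depth 1 only — chaining r² through intermediate SNPs is
not transitive and would inflate assignments. Strand is ignored; gene-type
filtering (e.g. protein-coding only) is delegated to the supplied interval
table.

**Overlap and clustering.** Exact-k membership is computed by direct
enumeration of each item's category vector. Category similarity defaults to
|A ∩ B| / |universe| ("fraction of all genes"); per-pair Jaccard is the
selectable alternative — the two normalisations answer slightly different
questions and published "fraction shared" figures rarely say which was
used. Clustering is agglomerative on distance 1 − similarity, average
linkage by default (single/complete available); labels are sorted before
linkage so equal-height merges resolve lexicographically and dendrograms
are reproducible.

**GO term compilation.** Per-category term sets are the union of the direct
annotations of the category's genes. Ancestor propagation (is_a/part_of
closure) is off by default: with propagation every set converges onto the
upper ontology and the overlap statistics degenerate toward the roots; the
flag exists for sensitivity analysis, and namespace roots are always
excluded from compiled sets (they carry no information). Similarity analysis
is restricted to `biological_process` by default; cross-namespace term
pairs have no shared root and are an error unless explicitly allowed.

**Wang similarity.** S-values are computed by a reverse topological sweep
from the focal term over its ancestor closure, taking the max over child
edges; this equals per-path max enumeration (tested against that oracle on
random DAGs). Edge weights 0.8 (`is_a`) / 0.6 (`part_of`) are the standard
contribution factors for this measure. Tables are cached per term within
one engine, and results are independent of evaluation order.

**Overlap-vs-background test.** Within-set pairwise similarities of the
cross-category term overlap are compared to those of the background (all
unique terms across categories, overlap included by default; an exclusive
mode is available — the two choices differ negligibly when the overlap is
small) with a one-sided Wilcoxon rank-sum test, alternative "overlap
greater". For pooled samples up to `exact_limit` (default 10 000) the exact
distribution is used: scipy's exact method when there are no ties, full
enumeration of rank assignments (up to 3 × 10⁵ subsets) when there are.
Beyond that, the normal approximation with tie and continuity corrections.
Two all-tied samples are degenerate and report p = 1 with a flag.

**Fisher's combined probability.** X = −2 Σ ln pᵢ is referred to χ²(2k).
For even degrees of freedom the survival function is the closed series
exp(−X/2) Σ_{j<k} (X/2)ʲ/j!, evaluated via log-sum-exp so that combined
probabilities of 10⁻¹³–10⁻²⁰ (and far smaller) retain full relative
precision; `log_p_combined` is reported alongside, and only the final
exponentiation can underflow.

**Enrichment.** The two-unranked-lists analysis mode is represented by the
standard hypergeometric upper tail P(X ≥ k) per term over the supplied
background gene list (not the whole annotation corpus), with BH step-up
q-values. This is a deliberate methodological substitution for tools whose
internal statistic is the ranked mHG; for a fixed target/background split
the hypergeometric tail is the exact two-list probability.

## The synthetic generator

`simulate.generate` builds all seven inputs on one synthetic chromosome:
genes tiled every 10 kb (2 kb long), five categories of 30 exclusive genes
each, and 10 shared genes planted into exactly 3 categories chosen at
random per gene. Every gene carries `snps_per_gene = 2` significant SNPs
(p log-uniform on [10⁻¹², 10⁻⁶]); 30 % of assignments route through an LD
bridge (catalog SNP intergenic, partner on the gene, r² ∈ [0.8, 1]) and low
r² decoy pairs (≤ 0.6) exercise the threshold. Each trait has 5 studies;
distractor SNPs (p ∈ [10⁻⁴, 0.5]), an understudied trait (2 studies), a
longevity trait and a non-age trait exercise the filter and the category
side channel. The ontology is a complete 3-ary tree of depth 5 (364 terms)
plus part_of cross-edges on 10 % of terms so diamond paths exist. The
planted "aging pathway" is a connected 10-term subtree anchored at depth 2,
annotated to every shared gene; every gene additionally receives 2
uniform-noise annotations. These sizes keep a full pipeline run near 0.1 s
so replicate studies are cheap, while leaving every code path (LD bridges,
multi-SNP cells, diamonds, noise collisions) exercised.

What the generator does **not** emulate: realistic human LD block structure,
allele frequencies, gene length variation, GO term depth distribution, or
annotation bias toward well-studied genes. Passing recovery tests therefore
demonstrate correctness of the machinery under controlled conditions, not
performance on the real catalog.

## Replicate studies and a known limitation

`calibration.signal_recovery_study` (200 seeded bundles at generator
defaults) scores exact recovery of the planted shared genes by the
≥ 3-category overlap — 200/200 in the shipped configuration — and the power
of the similarity test run, as the pipeline does by default, on the
all-category term overlap (200/200 rejections at α = 0.05; the planted
module dominates that overlap because its terms are annotated to all shared
genes).

`calibration.null_calibration_study` (500 bundles with no planted
structure) probes the test where the overlap is pure annotation noise.
Because an all-category noise overlap is essentially always empty, the null
is probed at the ≥ 3-category depth. The measured type-I error at α = 0.05
is ≈ 0.15, not 0.05. This is a genuine property of the procedure, not an
implementation defect: the test treats all C(n, 2) pairwise similarities of
a term set as an i.i.d. sample, but pairs sharing a term are positively
dependent (a term's depth and position influence all of its pairs), so the
rank-sum variance is underestimated and the one-sided test is
anti-conservative under term-level resampling. The same test is correctly
calibrated when the two samples are genuinely exchangeable (verified by a
pair-level permutation check in the suite), and the exact small-sample path
matches full enumeration. Conclusions drawn from this test on real data
should therefore rest on p-values many orders of magnitude below α, or on a
term-level permutation null, never on marginal significance.

## Numerical and degenerate-input choices

* Outputs are sorted and ties break lexicographically everywhere
  (dendrograms, pair enumeration, table rows), so reruns are bit-identical.
* Obsolete ontology terms keep no analysis edges; annotations to them (or
  to unknown ids) are dropped with counts; `alt_id`s resolve to primaries.
* A trait set with no survivors, a category with no mapped genes, or a
  category of unannotated genes each degrade to empty results with counts,
  never silently.
* Filtering is idempotent; study counting is duplication-invariant; the
  universe always equals the union of per-category sets (validated at
  construction).
* Seeds derived for replicate studies stay below 2³¹.
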