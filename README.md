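# agepath

Joint analysis of GWAS-catalog associations across age-related disease
categories: do diseases of aging share genes, and — more powerfully — do
they share biological pathways?

`agepath` re-implements, as a tested and reusable pipeline, a catalog-mining
analysis over five broad age-related disease categories (cardiovascular,
metabolic, neurodegenerative, cancer, other age-related traits):

1. **Filtering** — keep traits examined in ≥ 5 independent GWAS reports and
   SNPs with association *P* < 1 × 10⁻⁵.
2. **SNP→gene mapping** — a SNP is assigned to every gene it lies on, and to
   every gene carrying an LD partner with *r*² ≥ 0.8 (depth-1 LD only).
3. **Multi-set overlap** — exact-*k* membership and ≥ *m*-category shared
   sets for genes and for GO terms; pairwise category similarity
   (|A ∩ B| / |universe| or Jaccard) with average-linkage clustering.
4. **GO semantic similarity** — Wang-method term similarity over the GO DAG:
   S_A(A) = 1, S_A(t) = max over children c on a path to A of w·S_A(c)
   (w = 0.8 for `is_a`, 0.6 for `part_of`), and
   sim(A,B) = Σ_{t ∈ anc(A)∩anc(B)} (S_A(t)+S_B(t)) / (SV(A)+SV(B)).
   The internal similarity of the cross-category term overlap is compared to
   the background term universe with a one-sided Wilcoxon rank-sum test
   (exact by full enumeration for small samples).
5. **Statistics** — Fisher's combined probability
   X = −2 Σ ln pᵢ ~ χ²(2k), evaluated through the even-df series in log
   space so values far below double underflow keep full precision;
   two-unranked-lists hypergeometric GO enrichment with Benjamini–Hochberg
   correction.
6. **Synthetic data** — a generator that emulates every input (catalog TSV,
   SNP locations, gene BED, LD pairs, OBO ontology, annotations, category
   map) with a planted core of genes shared by ≥ 3 categories annotated to a
   coherent GO subtree, so the whole pipeline is testable without downloads.

It is intended for researchers mining association catalogs for shared
architecture across trait groups, and as a reference implementation of the
Wang similarity + rank-sum overlap test.

## Worked example

Generate a synthetic bundle with a planted shared pathway and run the full
pipeline:

```bash
agepath simulate --seed 1 --out bundle/
agepath fisher -p 1e-5 -p 1e-5 -p 1e-5
```

The Fisher subcommand prints (three independent hits at the catalog
threshold):

```json
{"k": 3, "statistic": 69.077, "df": 6, "p_combined": 6.32e-13, ...}
```

i.e. a gene reaching *P* < 1 × 10⁻⁵ in three independent disease categories
is far beyond genome-wide chance. Running the pipeline on the bundle
(`agepath run --config config.yaml --out out/`, with the config pointing at
the seven files in `bundle/`) reports, for seed 1:

* gene universe 160, of which 10 genes sit in ≥ 3 categories — exactly the
  planted shared core (`manifest.json` lists it);
* term universe 226, 4.4 % shared by all five categories;
* Wang similarity of the all-category term overlap 0.63 ± 0.13 against a
  background of 0.20 ± 0.13, one-sided Wilcoxon p ≈ 1.6 × 10⁻²⁸ — the
  planted pathway is detected as a coherent cluster of related terms.

Stage tables (`category_genes.tsv`, `gene_overlap.tsv`, `term_similarity.tsv`,
dendrograms in newick, `enrichment.tsv`, `report.json`) are persisted per run
and reruns are bit-identical apart from the report timestamp.

To analyze real data, point the same config at an NHGRI-style catalog export,
a gene BED, SNP location and LD-pair tables, `go-basic.obo`, a GAF file, and
a trait→category map.

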