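# mirnome

A toolkit for integrative miRNome/transcriptome analysis of placental
count data. It re-implements, as tested and reusable components, a
complete analysis pipeline:

- **preprocess** — median-count filtering (strict `> 50` across all
  samples), median-of-ratios size factors, normalization, CPM.
- **diffexpr** — negative-binomial Wald differential expression between
  trimesters or clinical groups, with optional fetal-sex adjustment.
  A deliberately simple stand-in for full DESeq2-style machinery:
  method-of-moments dispersions with decile shrinkage, log-link NB GLM
  with size-factor offsets, per-contrast BH correction. Validated by
  simulation (type-I error, power), not by matching any reference
  implementation feature-for-feature.
- **dynamics** — the nine-pattern taxonomy of gestational expression
  dynamics (Up/Down/NoChange for each of the two trimester transitions),
  with cluster-wise (C19MC / C14MC / miR-371–373 / other) summaries.
- **correlation_landscape** — the full miRNA×gene Spearman correlation
  matrix, hierarchical grouping of miRNAs by their correlation profiles
  (G1..Gk), thresholded per-group correlated-gene lists
  (median |rho| > 0.3 and every-miRNA |rho| > 0.1), Kendall-based target
  sign-balance tests, and hypergeometric over-representation against a
  custom background (GMT input).
- **eqtl_association** — windowed cis miR-eQTL scan (±100 kb around each
  miRNA gene, MAF > 0.1, Hardy–Weinberg reported), linear regression of
  normalized expression on minor-allele dosage with fetal sex and
  gestational age as cofactors, SNV–trait association (linear/logistic
  additive models) and inverse-variance fixed-effect meta-analysis.
- **stats_core** — self-contained statistical primitives used by every
  stage: BH step-up, exact binomial/HWE tests, chi-square independence,
  Kruskal–Wallis, Spearman/Kendall, OLS and IRLS logistic regression,
  fixed-effect pooling.
- **synthetic_data** — a fully parameterized cohort simulator (NB counts
  over 3 trimesters + term clinical subgroups, planted dynamics patterns
  and PE shifts, clustered miRNA blocks, planted miRNA–gene
  correlations, HWE genotypes with additive cis effects, pregnancy
  traits) that ships ground truth for recovery testing.
- **io_formats / cli** — strict TSV/BED/GFF3/VCF/GMT readers and
  writers (internal coordinates 0-based half-open) and a `mirnome`
  command-line front end.

## CLI

```sh
# generate a synthetic cohort (TSV/BED/VCF + ground truth JSON)
mirnome simulate --seed 1 --out fixture/

# individual stages
mirnome preprocess --counts fixture/mirna_counts.tsv --out prep/
mirnome de --prep-dir prep/ --samples fixture/samples.tsv --contrast 1:2 --out de_t1_t2.tsv
mirnome dynamics --de-first de_t1_t2.tsv --de-second de_t2_term.tsv \
    --annotation fixture/mirna_annotation.bed --out dynamics/
mirnome correlate --mirna-expr prep/normalized_counts.tsv --gene-expr genes_norm.tsv --out corr/
mirnome enrich --query query.txt --gene-sets sets.gmt --background background.txt --out enrich.tsv
mirnome eqtl --expr prep/normalized_counts.tsv --genotypes fixture/genotypes.vcf \
    --samples fixture/samples.tsv --annotation fixture/mirna_annotation.bed --out eqtl.tsv
mirnome associate --genotypes fixture/genotypes.vcf --samples fixture/samples.tsv --out assoc.tsv
mirnome meta --cohort cohort_a.tsv --cohort cohort_b.tsv --out meta.tsv

# everything end-to-end on a simulated cohort, with a run manifest
mirnome run-all --seed 1 --out results_dir/
```

`run-all` writes `manifest.json` (seed, per-stage row counts, SHA-256
checksums of every output); reruns with the same seed and config are
byte-identical.

Contrasts are written `reference:comparison` and may name trimesters
(`1`, `2`, `term`) or clinical groups (`NORM`, `PE`, `GD`, `SGA`,
`LGA`); the reported log2 fold change is the change from reference to
comparison.

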