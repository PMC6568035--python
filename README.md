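# mircluster

Genomic clustering and co-expression analysis of miRNAs, built around a
question from alcohol-associated liver disease: when chronic ethanol exposure
dysregulates miRNAs in liver macrophages (Kupffer cells) and peripheral blood
mononuclear cells, are the affected miRNAs — in particular those tied to
M1/M2 macrophage polarization — organised into co-regulated genomic clusters?

The package is a reusable pipeline for anyone analysing small-RNA-seq count
matrices plus qPCR panels:

* **Genomic cluster detection** — a miRNA cluster is ≥ 4 annotated mature
  miRNAs (−5p and −3p arms counted separately) whose span fits in a 1 Mb
  window; greedy left-to-right chaining per chromosome, verified against a
  brute-force window-enumeration oracle. Each cluster is classified against
  gene annotation as *sense-intronic* (host gene), *antisense*, or
  *intergenic*.
* **Differential expression** — expression filter (> 0 reads in ≥ 1/4 of
  samples), TMM normalization (matches edgeR's `calcNormFactors` to 1e-6 on
  test fixtures), a common negative-binomial dispersion by Cox–Reid adjusted
  profile likelihood, and per-gene NB GLMs (log link, offsets
  `log(lib.size × TMM)`) with a likelihood-ratio test for the diet effect
  keeping LPS treatment as covariate: for gene *g*,
  `log μ_gj = β_0g + β_dg·diet_j + β_tg·LPS_j + o_j`, H0: `β_dg = 0`,
  `p` from χ²(1), Benjamini–Hochberg FDR with a deliberately lenient
  cutoff of 0.2.
* **Polarization enrichment** — one-sided Fisher exact (hypergeometric tail)
  test of a curated M1/M2 miRNA set against the DE list within the tested
  universe.
* **Co-expression** — all-pairs Pearson *r* with t-transform p-values on
  baseline samples (miRNAs detected in ≥ 5/6 of them), significance defined
  by the empirical 2.5% tails of the correlation distribution **and**
  p < 0.05, then a per-cluster 2×2 Fisher test of within-cluster versus
  background pair significance.
* **qPCR (ΔΔCt)** — `ΔCt = Ct(target) − Ct(reference)`, `ΔΔCt` relative to
  the control-group mean, fold = `2^(−ΔΔCt)`; Welch t-tests on log2 folds and
  cluster-annotated pairwise correlations of log2 qPCR expression.
* **Synthetic data** — a seeded generator producing annotations, NB count
  matrices with planted fold changes and latent-factor within-cluster
  correlation, and Ct tables, with ground truth, so the whole pipeline is
  testable without any download.

## Worked example

Generate a synthetic study (13 clusters, 3 of them co-regulated at ρ = 0.9,
10% of miRNAs differentially expressed, 2×2 diet × LPS design with 3 samples
per cell) and run the sequencing arm:

```bash
printf 'seed: 7\n' > sim.yaml
mircluster simulate --config sim.yaml --out simdata
cat > rat.yaml <<EOF
output_dir: ratout
annotation: simdata/annotation.tsv
counts: simdata/counts.tsv
metadata: simdata/metadata.tsv
polarization: simdata/polarization.tsv
genes: simdata/genes.gff3
seed: 7
EOF
mircluster rat --config rat.yaml
```

The summary printed (and written to `ratout/summary.json`) is:

```json
{
  "n_mirnas_input": 148,
  "n_mirnas_expressed": 143,
  "n_de_diet": 20,
  "n_de_diet_up": 4,
  "n_de_diet_down": 16,
  "n_de_treatment": 0,
  "n_clusters": 13,
  "n_de_in_clusters": 12,
  "n_coexpressed_clusters": 3,
  "coexpressed_cluster_ids": [8, 9, 13],
  "enrichment": {"k": 10, "K": 19, "n": 20, "N": 143,
                 "odds_ratio": 12.67, "p_value": 1.24e-05}
}
```

Reading it: of 148 simulated miRNAs, 143 pass the expression filter; 20 are
called differentially expressed by diet at FDR < 0.2 (the generator planted
~15, mostly downregulated) while the LPS contrast is null, as designed; all
13 planted genomic clusters are recovered, exactly the 3 co-regulated ones
are flagged as significantly co-expressed, and the polarization label set —
half of which was planted on DE miRNAs — is strongly enriched among the DE
calls (10 of 19 labelled miRNAs, Fisher p ≈ 1e-5).

Output files in `ratout/` include per-contrast DE tables, the cluster table
(TSV and JSON), the correlation matrix, the significant-pair edge list, the
per-cluster co-expression enrichment, and a run log with all parameters.

`mircluster qpcr --config ...` runs the ΔΔCt arm on a Ct table and emits
relative expression per target, Welch group comparisons, and the correlation
edge list.

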