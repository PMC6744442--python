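# famcontent

Comparing prokaryotic genomes by the protein families they encode.

The Candidate Phyla Radiation (CPR) is a vast group of mostly uncultivated
bacteria with small genomes. One way to ask whether the CPR really forms a
major subdivision of the bacterial domain — without relying on gene or
protein sequence phylogenies — is to compare genomes purely by *content*:
cluster millions of proteins into homologous families, record which genomes
carry which families, and analyze the resulting presence/absence matrix.
`famcontent` is a tested, reusable implementation of that pipeline for
microbial comparative genomicists:

- **two-step homology clustering** — subfamilies by greedy set cover on an
  e-value/coverage-filtered similarity graph (e ≤ 0.001, cov ≥ 0.5), then
  families by Markov clustering (inflation 2.0) of a profile-match network
  (probability ≥ 95%, coverage ≥ 0.50, edge weight = probability ×
  coverage);
- **genome QC** from single-copy genes (completeness > 70%, contamination
  < 10%), de-replication, and a genomes × families boolean matrix pruned
  to families in ≥ 5 genomes;
- **co-occurrence modules** — Louvain communities on a Jaccard network
  (J > 0.4), size filter (≥ 10 families), median-m taxonomy, and selection
  of modules widespread across ≥ 10 phyla of a superclade;
- **content dendrograms** — single/complete/average linkage on Jaccard
  distances, Newick import/export, cophenetic correlation against
  phylogenies, branch collapsing into wedges (< 0.25 of the maximum branch
  length), within-group similarity tests (Mann–Whitney U);
- **enrichment** — per-family two-sided Fisher exact tests of CPR vs
  non-CPR presence (explicit hypergeometric enumeration in log space),
  Benjamini–Hochberg correction, and the three-way enriched / depleted /
  equal categorization requiring q < 10⁻⁵ in two independent genome
  datasets;
- **a synthetic data generator** that plants all of this structure
  (superclades, phyla, universal/enriched/lineage-specific family modules,
  subfamily-structured sequences, draft-genome dropout) with ground-truth
  labels, so every stage is testable end to end without any download.

The statistic at the core of the enrichment stage: for a family present in
*a* of the CPR genomes and *c* of the non-CPR genomes (absent in *b* and
*d* respectively), the two-sided Fisher p-value sums hypergeometric point
probabilities P(X = k) = C(a+b, k)·C(c+d, n−k)/C(N, n) over all tables with
the observed margins whose probability does not exceed the observed
table's. A family is *enriched* iff its BH-adjusted p is below 10⁻⁵ in both
datasets and a/(a+b) > c/(c+d) in both.

## Worked example

Run the planted end-to-end demo (simulate → modules → dendrogram →
enrichment) and print the recovery report:

```sh
$ famcontent run-all --out demo/ --seed 1
{"enrichment_precision": 1.0, "enrichment_recall": 1.0, "module_ari": 1.0,
 "n_called_enriched": 40, "n_planted_enriched": 40, "superclade_ari": 1.0}
```

The scenario plants 200 genomes (100 CPR-like, 100 other bacteria, 10
phyla each) and 240 families; after the ≥ 5-genome prevalence filter, 237
families remain. The report says the Louvain modules reproduced the
planted family blocks exactly (`module_ari` 1.0, adjusted Rand index),
cutting the complete-linkage content dendrogram into two clusters
recovered the two superclades exactly (`superclade_ari` 1.0), and all 40
planted CPR-enriched families — and nothing else — were called enriched in
both simulated datasets (recall and precision 1.0).

`demo/` then contains the presence matrix, taxonomy, module membership and
summary tables, the dendrogram in Newick, the wedge report, the
per-family enrichment table, and `manifest.json` recording the seed and a
hash of every parameter: this run found 7 modules (modularity Q = 0.428),
of which 3 are widespread — the planted universal module (spanning all 20
phyla, m = 171), and the two superclade-specific modules (each spanning
the 10 phyla of its superclade).

Each stage is also available separately (`famcontent simulate | cluster |
matrix | modules | tree | enrich`, see `--help`), reading and writing
plain TSV/FASTA/Newick, and the same functionality is importable from
`famcontent.clustering`, `.presence`, `.modules`, `.trees`, `.enrich`,
`.synthetic` and `.pipeline`.

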