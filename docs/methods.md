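# Methods

`famcontent` implements a genome-content comparison pipeline for separating
the Candidate Phyla Radiation (CPR) from other bacteria by what their
genomes encode rather than by sequence phylogeny. This note documents the
models and procedures, the parameters that matter, what the synthetic data
generator does and does not emulate, and the numerical choices made where
the design was open.

## The pipeline

1. **Protein families** are built in two steps. An all-vs-all protein
   similarity search (consumed as a tabular m8-dialect file; the search
   itself is outside this package) is filtered at e-value ≤ 0.001 and
   coverage ≥ 0.5, and the resulting graph is partitioned into
   *subfamilies* by greedy set cover: repeatedly pick the protein whose
   closed neighborhood covers the most uncovered proteins; it becomes the
   representative of a subfamily made of itself and its uncovered
   neighbors. Subfamilies are then compared by profile–profile alignment
   (again consumed as a table of probability/coverage matches); matches
   with probability ≥ 95% and coverage ≥ 0.50 form a network weighted by
   probability × coverage, clustered into *families* by Markov clustering
   (MCL) at inflation 2.0. Both levels are exact partitions of the protein
   set and are asserted as such after every run.

2. **Genome QC.** Completeness = percentage of the group's single-copy
   gene (SCG) set present at least once (43 markers for CPR, 51 for
   non-CPR bacteria, 38 for archaea); contamination = percentage of the
   set present in more than one copy. Draft quality requires completeness
   strictly above 70% and contamination strictly below 10% (a 90% variant
   selects high-quality genomes). Replicate clusters (e.g. from ANI > 95%
   clustering, performed elsewhere) are reduced to the most complete
   member, ties broken by lower contamination then id.

3. **Presence/absence matrix.** Boolean genomes × families; a cell is true
   iff the genome encodes at least one family member. Families present in
   fewer than 5 distinct genomes are dropped.

4. **Co-occurrence modules.** Families are linked when the Jaccard index
   of their presence profiles strictly exceeds 0.4 (edges weighted by the
   index) and partitioned with Louvain modularity maximization. Partitions
   with ≥ 10 families count as modules; each module's taxonomy uses the
   median-m rule: m = median (lower median for even counts, since m indexes
   a number of genomes) of per-family genome counts; the m genomes carrying
   the most module families define the module's phylum distribution.
   Modules spanning ≥ 10 distinct phyla of either superclade are flagged
   *widespread*.

5. **Content dendrograms.** Genomes (or families) are clustered on Jaccard
   distances with single, complete or average linkage. Trees are compared
   by cophenetic correlation: Pearson correlation of leaf-pair distances,
   which are LCA merge heights for a dendrogram and patristic path lengths
   for an imported Newick phylogeny (raw vectors, no normalization —
   Pearson is scale-invariant, so the factor-of-two between ultrametric
   heights and patristic lengths is immaterial). Branch collapsing
   contracts every branch strictly shorter than a fraction (default 0.25)
   of the maximum branch length, where a dendrogram branch's length is
   parent height minus child height; the collapsed units ("wedges")
   partition the leaves, and a wedge counts toward every group present in
   it, with wedge purity reported alongside so stricter attributions can
   be recovered.

6. **Enrichment.** Per family, presence in CPR vs non-CPR bacteria
   (archaea excluded) is tested with a two-sided Fisher exact test,
   computed by explicit enumeration of the hypergeometric distribution in
   log space (point probabilities ≤ the observed one, within 1e-12
   relative tolerance, are summed; a degenerate margin yields p = 1 with a
   warning). P-values are Benjamini–Hochberg adjusted per dataset over all
   tested families. A family is *enriched* only when q < 1e-5 in **both**
   genome datasets with the CPR frequency above the non-CPR frequency in
   both; *depleted* symmetrically; anything else — including conflicting
   significant directions, which are flagged — is *equally distributed*.

## Parameters

| parameter | default | role |
|---|---|---|
| e-value ≤ | 0.001 | similarity-graph edge filter |
| coverage ≥ | 0.5 | min(query, target) coverage of a hit |
| profile probability ≥ | 95% | profile-match filter |
| profile coverage ≥ | 0.50 | profile-match filter |
| MCL inflation | 2.0 | cluster granularity (must be > 1) |
| prevalence ≥ | 5 genomes | family retention |
| Jaccard > | 0.4 | co-occurrence edge threshold (strict) |
| module size ≥ | 10 | module retention |
| widespread phyla ≥ | 10 | per-superclade breadth rule |
| completeness > / contamination < | 70% / 10% | draft-quality QC (strict) |
| collapse fraction | 0.25 | of maximum branch length (strict <) |
| alpha | 1e-5 | on BH-adjusted p, required in both datasets |

MCL internals (not fixed by the published parameterization, chosen as
standard practice): self-loop weight = each node's maximum incident weight
(1.0 for isolated nodes), prune threshold 1e-5, convergence tolerance 1e-8
on the max-norm change, at most 200 iterations, columns re-normalized after
every inflation and asserted stochastic to 1e-9. Disconnected components
are clustered independently (MCL never merges components), which keeps the
dense per-component implementation cheap. Non-convergence produces a
warning and the current matrix is interpreted. Hit coverage is read
conservatively as min(query coverage, target coverage).

The module-size rule is exposed as `--min-module-size` (default ≥ 10); the
widespread rule is the disjunction "≥ 10 distinct CPR phyla OR ≥ 10
distinct non-CPR bacterial phyla", a formalization of a selection that
real analyses make post hoc.

## The synthetic generator

The generator plants a two-superclade world whose structure the pipeline
must recover: by default 200 genomes (100 CPR-like, 100 non-CPR bacteria)
over 10 phyla per superclade, and 240 families in five classes — 40
universal (presence probability 0.95 everywhere), 40 enriched in each
superclade (0.9 at home, 0.05 elsewhere), four lineage-specific blocks of
15 (0.95 in one home phylum, 0.01 elsewhere), and 60 sparse background
families (0.05). Draft-genome incompleteness is emulated by thinning every
presence call at a per-genome dropout rate (default 0.1; a per-group
mapping expresses asymmetrically fragmentary CPR drafts, used for the
within-group similarity contrast at 0.3 vs 0.1). Sequence-level truth
generates families with subfamily divergence (subfamily seeds differing at
40% of sites, members mutated i.i.d. at 5%), plus matching similarity and
profile-match tables whose noise parameter removes true edges and adds
cross-family ones.

What it does **not** emulate: realistic amino-acid substitution processes
(substitutions are uniform over the alphabet — BLOSUM-style evolution is a
non-goal), e-values derived from actual alignments (hit tables carry
nominal scores that pass or fail the published thresholds by
construction), phylogenetic autocorrelation of gene content within phyla
(presence calls are independent given the class probabilities), gene gain/
loss along a tree, or annotation errors. Passing the planted-recovery
tests therefore shows the algorithms are implemented correctly and are
well-behaved at realistic signal strengths — not that the biological
conclusions would survive on any particular real dataset.

All generators draw from one `numpy` Generator stream seeded from the
config; fixed seeds make every artifact byte-reproducible, and ground-truth
labels are emitted alongside every artifact so ARI / precision / recall
are computable without re-deriving truth.

## Numerical and design choices

- **Greedy set-cover ties** (equal coverage gain) break to the
  lexicographically smallest protein id, making the partition invariant to
  edge input order. Representatives are chosen among uncovered nodes, so
  the representative is always a member of its subfamily.
- **Linkage and cophenetic distances** are computed with
  `scipy.cluster.hierarchy`; merge ties follow scipy's deterministic
  ordering. The often-quoted pairwise ordering "single ≤ average ≤
  complete" of cophenetic distances is **not** a theorem for average vs
  complete (differing topologies produce counterexamples); the package's
  tests assert the true properties — single-linkage cophenetic distances
  never exceed average- or complete-linkage ones (the subdominant
  ultrametric property) and root heights order single ≤ average ≤
  complete.
- **Branch collapsing** uses the strict "< fraction × max branch length"
  rule, so branches exactly at the cutoff survive.
- **Median for even counts** is the lower median: m indexes a number of
  genomes and must be attained.
- **Fisher direction** is defined by presence frequencies a/(a+b) vs
  c/(c+d), not odds ratios, which is robust to zero cells. BH correction
  is applied per dataset over all tested families (not pooled across
  datasets and not per module).
- **Annotation admixture** is computed over annotated members only and is
  *undefined* (None), not 0, for a family with no annotated member.
- **Degenerate inputs**: empty profiles get Jaccard distance 0 with a
  warning; zero-variance distance vectors make cophenetic correlation
  undefined (None) rather than NaN; a fully pruned MCL column falls back
  to self-assignment; SCG hits outside the marker set are ignored with a
  warning.
- **Mann–Whitney U** is exact for combined sample sizes ≤ 20 and uses the
  tie-corrected normal approximation otherwise; the within-group
  similarity samples are all unordered within-group genome pairs.

## Problem sizes

The shipped analyses run at desk scale: 200 genomes × 240 families for the
planted-recovery scenario, 48 proteins in 4 families × 2 subfamilies for
the sequence-level demonstration, 1000 families × 200 genomes × 100
replicate dataset pairs for the null calibration (call rate of the
enriched/depleted categories under no group effect, expected ≤ 1e-3 at
alpha 1e-5), and 12-genome random matrices for the linkage-ordering
property. These sizes were chosen so the statistics concentrate well while
the full suite remains fast to iterate on.

## Known limitations

- Louvain is a seeded heuristic: module boundaries on weak-signal networks
  can vary with the seed; the seed is recorded in all outputs.
- The independence of presence calls in the generator makes module
  recovery easier than on real data, where phylogenetic correlation blurs
  block boundaries.
- The contamination formula (fraction of the SCG set present in > 1 copy)
  is one reading of duplication-based contamination; an alternative (extra
  copies over total copies) is slightly less conservative.
- Cross-dataset family detection trusts the best-scoring subfamily hit;
  no calibration of profile scores across datasets is attempted.
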