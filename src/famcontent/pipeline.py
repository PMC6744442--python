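"""End-to-end orchestration of the genome-content comparison pipeline.

Stages run in order: simulate (or load) -> protein clustering -> QC +
presence matrix -> co-occurrence modules -> content dendrograms ->
enrichment.  Every stage is a pure function of (inputs, config, seed); a
manifest records the parameter hash so identical reruns are recognizably
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import enrich, io, modules, presence, synthetic, trees

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage thresholds, defaulting to the published parameterization."""

    evalue_max: float = 0.001
    cover_min: float = 0.5
    profile_prob_min: float = 95.0
    profile_cov_min: float = 0.5
    inflation: float = 2.0
    prevalence_min: int = 5
    jaccard_threshold: float = 0.4
    min_module_size: int = 10
    phylum_min: int = 10
    completeness_min: float = 70.0
    contamination_max: float = 10.0
    collapse_fraction: float = 0.25
    alpha: float = 1e-5
    linkage: str = "complete"
    seed: int = 1
    # synthetic scenario size
    n_cpr: int = 100
    n_bac: int = 100
    dropout: float = 0.1

    def validate(self) -> None:
        checks = [
            (self.evalue_max >= 0, "evalue_max must be >= 0"),
            (0 <= self.cover_min <= 1, "cover_min must lie in [0, 1]"),
            (0 <= self.profile_prob_min <= 100, "profile_prob_min must lie in [0, 100]"),
            (0 <= self.profile_cov_min <= 1, "profile_cov_min must lie in [0, 1]"),
            (self.inflation > 1, "inflation must be > 1"),
            (self.prevalence_min >= 1, "prevalence_min must be >= 1"),
            (0 <= self.jaccard_threshold < 1, "jaccard_threshold must lie in [0, 1)"),
            (self.min_module_size >= 1, "min_module_size must be >= 1"),
            (0 <= self.completeness_min <= 100, "completeness_min must lie in [0, 100]"),
            (0 <= self.contamination_max <= 100, "contamination_max must lie in [0, 100]"),
            (self.collapse_fraction >= 0, "collapse_fraction must be >= 0"),
            (0 < self.alpha < 1, "alpha must lie in (0, 1)"),
            (self.linkage in trees.LINKAGES, f"linkage must be one of {trees.LINKAGES}"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def parameter_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class PipelineResult:
    config: PipelineConfig
    matrix: pd.DataFrame
    taxonomy: pd.DataFrame
    partition: modules.ModulePartition
    kept_modules: dict
    unassigned: set
    taxonomies: list
    widespread: list
    tree: trees.LinkageTree
    wedges: trees.WedgeSummary
    enrichment: pd.DataFrame
    recovery: dict = field(default_factory=dict)


def run_synthetic_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> PipelineResult:
    """Generate the default planted scenario and run every stage on it.

    The recovery report compares each stage's output against the planted
    truth: ARI of the Louvain modules vs the planted blocks, ARI of the
    2-cut of the content dendrogram vs the superclades, and
    precision/recall of the enrichment calls vs the planted enriched class.
    """
    config.validate()
    truth = synthetic.default_truth(
        n_cpr=config.n_cpr, n_bac=config.n_bac, dropout=config.dropout, seed=config.seed
    )
    matrix, taxonomy = synthetic.generate_presence_matrix(truth)
    # an independent replicate emulating the second genome dataset
    truth2 = synthetic.default_truth(
        n_cpr=config.n_cpr, n_bac=config.n_bac, dropout=config.dropout,
        seed=config.seed + 10_000,
    )
    matrix2, taxonomy2 = synthetic.generate_presence_matrix(truth2)

    matrix = presence.filter_families_by_prevalence(matrix, config.prevalence_min)
    matrix2 = presence.filter_families_by_prevalence(matrix2, config.prevalence_min)

    partition, kept, unassigned, taxes, widespread = modules.detect_modules(
        matrix,
        taxonomy,
        jaccard_threshold=config.jaccard_threshold,
        min_module_size=config.min_module_size,
        phylum_min=config.phylum_min,
        seed=config.seed,
    )

    dist = trees.jaccard_distance_matrix(matrix, axis="rows")
    tree = trees.agglomerative(dist, method=config.linkage)
    groups = dict(zip(taxonomy["genome_id"], taxonomy["group"]))
    wedges = trees.collapse_and_count(tree, groups, fraction=config.collapse_fraction)

    enrichment = enrich.categorize(
        matrix, taxonomy, matrix2, taxonomy2, alpha=config.alpha
    )

    recovery = planted_recovery_metrics(
        truth, matrix, partition, kept, unassigned, tree, taxonomy, enrichment
    )

    result = PipelineResult(
        config=config,
        matrix=matrix,
        taxonomy=taxonomy,
        partition=partition,
        kept_modules=kept,
        unassigned=unassigned,
        taxonomies=taxes,
        widespread=widespread,
        tree=tree,
        wedges=wedges,
        enrichment=enrichment,
        recovery=recovery,
    )
    if outdir is not None:
        write_outputs(result, Path(outdir))
    return result


def planted_recovery_metrics(
    truth: synthetic.PangenomeTruth,
    matrix: pd.DataFrame,
    partition: modules.ModulePartition,
    kept: dict,
    unassigned: set,
    tree: trees.LinkageTree,
    taxonomy: pd.DataFrame,
    enrichment: pd.DataFrame,
) -> dict:
    """Recovery of the planted structure, as a flat dict of named metrics."""
    fam_info = truth.families.set_index("family_id")
    module_classes = {"universal", "bac_enriched", "cpr_enriched", "lineage_specific"}
    planted = [
        f for f in matrix.columns
        if fam_info.loc[f, "family_class"] in module_classes
    ]
    truth_blocks = [fam_info.loc[f, "block_id"] for f in planted]
    pred = []
    next_singleton = -1
    for f in planted:
        if f in unassigned or partition.assignment.get(f) is None:
            pred.append(next_singleton)
            next_singleton -= 1
        else:
            mod = partition.assignment[f]
            pred.append(mod if mod in kept else next_singleton)
            if mod not in kept:
                next_singleton -= 1
    module_ari = adjusted_rand_score(truth_blocks, pred)

    cut = tree.cut(2)
    group_of = dict(zip(taxonomy["genome_id"], taxonomy["group"]))
    genomes = tree.leaves
    superclade_ari = adjusted_rand_score(
        [group_of[g] for g in genomes], [cut[g] for g in genomes]
    )

    planted_enriched = set(
        truth.families.loc[
            truth.families["family_class"] == "cpr_enriched", "family_id"
        ]
    )
    called = set(enrichment.index[enrichment["category"] == enrich.CATEGORY_ENRICHED])
    tested = set(enrichment.index)
    planted_tested = planted_enriched & tested
    tp = len(called & planted_enriched)
    recall = tp / len(planted_tested) if planted_tested else float("nan")
    precis = tp / len(called) if called else float("nan")
    return {
        "module_ari": float(module_ari),
        "superclade_ari": float(superclade_ari),
        "enrichment_recall": float(recall),
        "enrichment_precision": float(precis),
        "n_planted_enriched": len(planted_tested),
        "n_called_enriched": len(called),
    }


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_matrix(result.matrix, outdir / "presence_matrix.tsv")
    io.write_taxonomy(result.taxonomy, outdir / "taxonomy.tsv")

    rows = [
        (fam, mod, "assigned" if mod in result.kept_modules else "unassigned")
        for fam, mod in sorted(result.partition.assignment.items())
    ]
    pd.DataFrame(rows, columns=["family_id", "module_id", "status"]).to_csv(
        outdir / "module_membership.tsv", sep="\t", index=False
    )
    widespread_ids = {t.module_id for t in result.widespread}
    mod_rows = []
    for mod, fams in sorted(result.kept_modules.items()):
        tax = next(t for t in result.taxonomies if t.module_id == mod)
        mod_rows.append(
            (
                mod,
                len(fams),
                tax.m,
                json.dumps(dict(tax.phylum_counts), sort_keys=True),
                mod in widespread_ids,
            )
        )
    pd.DataFrame(
        mod_rows, columns=["module_id", "size", "m", "phylum_distribution", "widespread"]
    ).to_csv(outdir / "module_summary.tsv", sep="\t", index=False)

    (outdir / "genome_tree.nwk").write_text(trees.to_newick(result.tree) + "\n")
    wedge_rows = [
        (i, len(w), json.dumps(dict(c), sort_keys=True))
        for i, (w, c) in enumerate(result.wedges.wedges)
    ]
    pd.DataFrame(wedge_rows, columns=["wedge_id", "size", "group_counts"]).to_csv(
        outdir / "wedges.tsv", sep="\t", index=False
    )
    result.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t")

    manifest = {
        "parameter_hash": result.config.parameter_hash(),
        "seed": result.config.seed,
        "config": asdict(result.config),
        "recovery": result.recovery,
        "n_genomes": int(result.matrix.shape[0]),
        "n_families": int(result.matrix.shape[1]),
        "n_modules": len(result.kept_modules),
        "n_widespread_modules": len(result.widespread),
        "modularity": result.partition.modularity,
        "n_wedges": result.wedges.n_wedges,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
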