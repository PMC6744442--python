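"""Genome QC and presence/absence matrix construction.

Completeness and contamination are estimated from single-copy gene (SCG)
hits: completeness is the percentage of the group's SCG set found at least
once, contamination the percentage found in more than one copy.  Genomes
with completeness > 70% and contamination < 10% count as draft quality;
near-identical genomes (replicate clusters, e.g. from ANI > 95% clustering)
are reduced to their most complete representative.  The genomes x families
boolean matrix is then built from family memberships and pruned to families
present in at least five distinct genomes.

A second, independently sampled genome dataset can be profiled against the
existing subfamilies via best-scoring profile-HMM hits (e-value <= 0.001,
HMM coverage > 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Number of single-copy genes used per group: 43 universal SCGs for CPR,
#: 51 for non-CPR bacteria, 38 for archaea.
DEFAULT_SCG_SIZES = {"CPR": 43, "BAC": 51, "ARC": 38}


def default_scg_config() -> dict[str, frozenset[str]]:
    """Synthetic SCG id sets of the standard sizes (43/51/38)."""
    return {
        grp: frozenset(f"{grp}_scg{i + 1:03d}" for i in range(n))
        for grp, n in DEFAULT_SCG_SIZES.items()
    }


@dataclass
class GenomeRecord:
    genome_id: str
    group: str
    phylum: str
    completeness: float = float("nan")
    contamination: float = float("nan")
    replicate_cluster: str | None = None

    def __post_init__(self):
        for v in (self.completeness, self.contamination):
            if not np.isnan(v) and not 0.0 <= v <= 100.0:
                raise ValueError("QC percentages must lie in [0, 100]")


def assess_genome(
    scg_hits: Iterable[str], scg_set: frozenset[str] | set[str]
) -> tuple[float, float]:
    """(completeness %, contamination %) from a multiset of SCG hits.

    completeness = 100 x |distinct SCGs present| / |SCG set|;
    contamination = 100 x |SCGs with multiplicity > 1| / |SCG set|.
    Hits outside the SCG set are ignored with a warning.
    """
    if not scg_set:
        raise ValueError("empty SCG set")
    counts: dict[str, int] = {}
    for h in scg_hits:
        if h not in scg_set:
            logger.warning("SCG hit %r outside the marker set — ignored", h)
            continue
        counts[h] = counts.get(h, 0) + 1
    present = len(counts)
    dup = sum(1 for c in counts.values() if c > 1)
    n = len(scg_set)
    return 100.0 * present / n, 100.0 * dup / n


def assess_genomes(
    scg_table: pd.DataFrame,
    scg_config: Mapping[str, frozenset[str]],
    taxonomy: pd.DataFrame,
) -> pd.DataFrame:
    """Vectorized QC over a hit table (genome_id, scg_id rows, one per copy)."""
    group_of = dict(zip(taxonomy["genome_id"], taxonomy["group"]))
    rows = []
    grouped = dict(tuple(scg_table.groupby("genome_id")["scg_id"]))
    for g in taxonomy["genome_id"]:
        hits = grouped.get(g, pd.Series([], dtype=object))
        comp, cont = assess_genome(hits, scg_config[group_of[g]])
        rows.append((g, comp, cont))
    return pd.DataFrame(rows, columns=["genome_id", "completeness", "contamination"])


def filter_draft_quality(
    genomes: Sequence[GenomeRecord],
    completeness_min: float = 70.0,
    contamination_max: float = 10.0,
) -> list[GenomeRecord]:
    """Keep genomes with completeness strictly above the minimum and
    contamination strictly below the maximum (70% / 10% by default; 90% for
    the high-quality variant)."""
    return [
        g
        for g in genomes
        if g.completeness > completeness_min and g.contamination < contamination_max
    ]


def dereplicate(genomes: Sequence[GenomeRecord]) -> list[GenomeRecord]:
    """One genome per replicate cluster: the most complete, ties broken by
    lower contamination then lexicographic id.  Genomes without a cluster id
    are their own cluster."""
    best: dict[str, GenomeRecord] = {}
    for g in genomes:
        key = g.replicate_cluster if g.replicate_cluster is not None else f"__self__{g.genome_id}"
        cur = best.get(key)
        if cur is None or (
            (-g.completeness, g.contamination, g.genome_id)
            < (-cur.completeness, cur.contamination, cur.genome_id)
        ):
            best[key] = g
    return sorted(best.values(), key=lambda g: g.genome_id)


def build_matrix(
    protein_to_family: Mapping[str, str],
    protein_to_genome: Mapping[str, str],
    genome_ids: Sequence[str],
    family_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Boolean genomes x families matrix: a cell is True iff the genome
    encodes at least one member of the family (presence, not count)."""
    known = set(genome_ids)
    if family_ids is None:
        family_ids = sorted(set(protein_to_family.values()))
    fam_index = {f: j for j, f in enumerate(family_ids)}
    gen_index = {g: i for i, g in enumerate(genome_ids)}
    cells = np.zeros((len(genome_ids), len(family_ids)), dtype=bool)
    for prot, fam in protein_to_family.items():
        genome = protein_to_genome.get(prot)
        if genome is None:
            raise KeyError(f"protein {prot} has no genome assignment")
        if genome not in known:
            continue  # proteins of genomes dropped by QC/dereplication
        if fam in fam_index:
            cells[gen_index[genome], fam_index[fam]] = True
    return pd.DataFrame(cells, index=list(genome_ids), columns=list(family_ids))


def filter_families_by_prevalence(
    matrix: pd.DataFrame, min_genomes: int = 5
) -> pd.DataFrame:
    """Keep families present in at least `min_genomes` distinct genomes."""
    keep = matrix.sum(axis=0) >= min_genomes
    return matrix.loc[:, keep]


def detect_in_second_dataset(
    hits: pd.DataFrame,
    subfamily_to_family: Mapping[str, str],
    protein_to_genome: Mapping[str, str],
    genome_ids: Sequence[str],
    family_ids: Sequence[str] | None = None,
    evalue_max: float = 0.001,
    coverage_min: float = 0.5,
) -> pd.DataFrame:
    """Family presence in a new genome set from profile-HMM search hits.

    `hits` columns: protein, subfamily, score, evalue, coverage.  Hits with
    e-value > `evalue_max` or coverage <= `coverage_min` are discarded; each
    protein is assigned to the subfamily of its best remaining score (ties
    to the lexicographically lower subfamily id) and contributes presence of
    that subfamily's family in its genome.
    """
    ok = (hits["evalue"] <= evalue_max) & (hits["coverage"] > coverage_min)
    passing = hits.loc[ok].copy()
    protein_to_family: dict[str, str] = {}
    if len(passing):
        passing = passing.sort_values(
            ["protein", "score", "subfamily"], ascending=[True, False, True]
        )
        best = passing.drop_duplicates(subset="protein", keep="first")
        for row in best.itertuples(index=False):
            fam = subfamily_to_family.get(row.subfamily)
            if fam is not None:
                protein_to_family[row.protein] = fam
    if family_ids is None:
        family_ids = sorted(set(subfamily_to_family.values()))
    return build_matrix(protein_to_family, protein_to_genome, genome_ids, family_ids)
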