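"""Co-occurrence modules of protein families.

Families sharing similar presence/absence profiles across genomes are linked
in a network whenever their Jaccard index exceeds 0.4 (edges weighted by the
index), and the network is partitioned with the Louvain modularity
heuristic.  Partitions of at least 10 families count as modules; each module
receives a taxonomic assignment by the median-m rule: m is the median number
of genomes per member family, and the phylum distribution of the m genomes
carrying the most module families defines the assignment.  Modules spanning
at least 10 distinct phyla of either superclade are flagged widespread.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


def family_jaccard_network(matrix: pd.DataFrame, threshold: float = 0.4) -> nx.Graph:
    """Weighted co-occurrence network over the matrix columns.

    J(f, g) = |genomes with both| / |genomes with either|; an edge is stored
    iff J strictly exceeds `threshold`.  Families present nowhere have an
    undefined index and stay isolated.
    """
    if matrix.size == 0:
        raise ValueError("empty presence matrix")
    B = matrix.to_numpy(dtype=bool)
    inter = (B.T.astype(np.int32) @ B.astype(np.int32)).astype(float)
    counts = B.sum(axis=0)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.maximum(union, 1), np.nan)
    g = nx.Graph()
    fams = list(matrix.columns)
    g.add_nodes_from(fams)
    ii, jj = np.nonzero(np.triu(np.nan_to_num(J, nan=0.0) > threshold, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(fams[i], fams[j], weight=float(J[i, j]))
    return g


@dataclass
class ModulePartition:
    """family -> module id mapping plus the partition's weighted modularity."""

    assignment: dict[str, int]
    modularity: float
    seed: int | None = None

    @property
    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for fam, mod in self.assignment.items():
            out.setdefault(mod, []).append(fam)
        for fams in out.values():
            fams.sort()
        return out

    def sizes(self) -> dict[int, int]:
        return {m: len(f) for m, f in self.modules.items()}


def louvain(network: nx.Graph, seed: int = 0, resolution: float = 1.0) -> ModulePartition:
    """Louvain community detection on the weighted co-occurrence network.

    Deterministic given the seed.  The reported Q is the final partition's
    weighted modularity; it is checked to be at least that of the two
    trivial partitions (all singletons and one block).
    """
    if network.number_of_nodes() == 0:
        return ModulePartition(assignment={}, modularity=0.0, seed=seed)
    if network.number_of_edges() == 0:
        assignment = {n: i for i, n in enumerate(sorted(network.nodes, key=str))}
        return ModulePartition(assignment=assignment, modularity=0.0, seed=seed)
    communities = nx.community.louvain_communities(
        network, weight="weight", resolution=resolution, seed=seed
    )
    communities = sorted((sorted(c, key=str) for c in communities), key=lambda c: c[0])
    q = nx.community.modularity(network, communities, weight="weight", resolution=resolution)
    q_singletons = nx.community.modularity(
        network, [{n} for n in network.nodes], weight="weight", resolution=resolution
    )
    q_block = nx.community.modularity(
        network, [set(network.nodes)], weight="weight", resolution=resolution
    )
    assert q >= max(q_singletons, q_block) - 1e-12, (
        "Louvain returned a partition worse than a trivial one"
    )
    assignment = {fam: i for i, comm in enumerate(communities) for fam in comm}
    assert set(assignment) == set(network.nodes), "partition must cover all nodes"
    return ModulePartition(assignment=assignment, modularity=q, seed=seed)


def filter_modules(
    partition: ModulePartition, min_size: int = 10
) -> tuple[dict[int, list[str]], set[str]]:
    """Modules with at least `min_size` families; smaller ones' families are
    returned as the unassigned set."""
    kept: dict[int, list[str]] = {}
    unassigned: set[str] = set()
    for mod, fams in partition.modules.items():
        if len(fams) >= min_size:
            kept[mod] = fams
        else:
            unassigned.update(fams)
    return kept, unassigned


@dataclass
class ModuleTaxonomy:
    module_id: int
    size: int
    m: int
    phylum_counts: Counter = field(default_factory=Counter)
    group_phyla: dict[str, set[str]] = field(default_factory=dict)

    def distinct_phyla(self, group: str) -> int:
        return len(self.group_phyla.get(group, ()))


def assign_module_taxonomy(
    module_id: int,
    families: list[str],
    matrix: pd.DataFrame,
    taxonomy: pd.DataFrame,
) -> ModuleTaxonomy:
    """Median-m taxonomic assignment of one module.

    m = median (lower median for even counts — m indexes a number of
    genomes) of the per-family genome counts; genomes are ranked by the
    number of module families they carry (descending, ties by genome id)
    and the top m genomes' phylum distribution is the assignment.
    """
    if not families:
        raise ValueError("empty module")
    sub = matrix[families]
    fam_counts = np.sort(sub.sum(axis=0).to_numpy())
    m = int(fam_counts[(len(fam_counts) - 1) // 2])  # lower median
    per_genome = sub.sum(axis=1)
    ranked = sorted(per_genome.items(), key=lambda kv: (-kv[1], kv[0]))
    top = [g for g, _ in ranked[:m]]
    tax = taxonomy.set_index("genome_id")
    phyla = Counter(tax.loc[g, "phylum"] for g in top)
    group_phyla: dict[str, set[str]] = {}
    for g in top:
        group_phyla.setdefault(tax.loc[g, "group"], set()).add(tax.loc[g, "phylum"])
    return ModuleTaxonomy(
        module_id=module_id,
        size=len(families),
        m=m,
        phylum_counts=phyla,
        group_phyla=group_phyla,
    )


def select_widespread_modules(
    taxonomies: list[ModuleTaxonomy], phylum_min: int = 10
) -> list[ModuleTaxonomy]:
    """Modules whose assignment spans at least `phylum_min` distinct CPR
    phyla or at least `phylum_min` distinct non-CPR bacterial phyla."""
    return [
        t
        for t in taxonomies
        if t.distinct_phyla("CPR") >= phylum_min or t.distinct_phyla("BAC") >= phylum_min
    ]


def detect_modules(
    matrix: pd.DataFrame,
    taxonomy: pd.DataFrame,
    jaccard_threshold: float = 0.4,
    min_module_size: int = 10,
    phylum_min: int = 10,
    seed: int = 0,
    resolution: float = 1.0,
) -> tuple[ModulePartition, dict[int, list[str]], set[str], list[ModuleTaxonomy], list[ModuleTaxonomy]]:
    """Full module stage: network -> Louvain -> size filter -> taxonomy ->
    widespread selection.

    Returns (partition, kept modules, unassigned families, taxonomies of
    kept modules, widespread module taxonomies).
    """
    net = family_jaccard_network(matrix, threshold=jaccard_threshold)
    partition = louvain(net, seed=seed, resolution=resolution)
    kept, unassigned = filter_modules(partition, min_size=min_module_size)
    taxonomies = [
        assign_module_taxonomy(mod, fams, matrix, taxonomy)
        for mod, fams in sorted(kept.items())
    ]
    widespread = select_widespread_modules(taxonomies, phylum_min=phylum_min)
    return partition, kept, unassigned, taxonomies, widespread
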