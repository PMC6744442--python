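"""Content-based genome dendrograms and tree comparison.

Genomes (or families) are hierarchically clustered on Jaccard distances
between presence/absence profiles, with single, complete or average
linkage.  Dendrograms can be exported to Newick, compared with each other
or with an imported phylogeny by cophenetic correlation, collapsed at a
fraction of the maximum branch length into wedges with per-group counts,
and within-group profile similarity distributions can be compared with a
two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, cut_tree, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu, pearsonr

LINKAGES = ("single", "complete", "average")


def jaccard_distance_matrix(matrix: pd.DataFrame, axis: str = "rows") -> pd.DataFrame:
    """Pairwise Jaccard distances between rows (genomes) or columns
    (families) of a boolean matrix: d = 1 - |a AND b| / |a OR b|, with the
    distance between two empty profiles defined as 0 (warned)."""
    B = matrix.to_numpy(dtype=bool)
    labels = list(matrix.index)
    if axis == "columns":
        B = B.T
        labels = list(matrix.columns)
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    if (B.sum(axis=1) == 0).any():
        warnings.warn("empty profiles present; their mutual distance is defined as 0")
    d = pdist(B, metric="jaccard")  # scipy: empty-vs-empty -> 0
    return pd.DataFrame(squareform(d), index=labels, columns=labels)


@dataclass
class LinkageTree:
    """Rooted ultrametric dendrogram: a scipy linkage matrix plus leaf ids.

    Internal node i (0-based, counting from n) merges at height Z[i, 2];
    leaves sit at height 0, and a branch's length is the height difference
    between its parent and child nodes.
    """

    Z: np.ndarray
    leaves: list[str]
    method: str = "complete"

    def __post_init__(self):
        if len(self.leaves) != self.Z.shape[0] + 1:
            raise ValueError("linkage matrix size does not match leaf count")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def heights(self) -> np.ndarray:
        """Height of every node (leaves first, then merges)."""
        return np.concatenate([np.zeros(self.n_leaves), self.Z[:, 2]])

    def cut(self, k: int) -> dict[str, int]:
        """Flat clustering into k clusters."""
        flat = cut_tree(self.Z, n_clusters=k).ravel()
        return dict(zip(self.leaves, (int(c) for c in flat)))


def agglomerative(
    distances: pd.DataFrame, method: str = "complete"
) -> LinkageTree:
    """Bottom-up hierarchical clustering of a square distance matrix.

    single: cluster distance = shortest point pair; complete: longest;
    average: mean over all cross pairs.
    """
    if method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if distances.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    condensed = squareform(distances.to_numpy(), checks=False)
    Z = linkage(condensed, method=method)
    return LinkageTree(Z=Z, leaves=list(distances.index), method=method)


# ---------------------------------------------------------------------------
# cophenetic comparison
# ---------------------------------------------------------------------------


def _pair_distances(tree) -> pd.Series:
    """Leaf-pair distances keyed by sorted (a, b) label pairs.

    For a :class:`LinkageTree` this is the cophenetic distance (merge height
    of the lowest common ancestor); for a phylogeny (dendropy Tree or a
    Newick string) the patristic path length.
    """
    if isinstance(tree, LinkageTree):
        coph = squareform(cophenet(tree.Z))
        labels = tree.leaves
        data = {
            tuple(sorted((labels[i], labels[j]))): coph[i, j]
            for i, j in combinations(range(len(labels)), 2)
        }
        return pd.Series(data)
    if isinstance(tree, str):
        tree = read_newick(tree)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    data = {
        tuple(sorted((a.label, b.label))): pdm.patristic_distance(a, b)
        for a, b in combinations(taxa, 2)
    }
    return pd.Series(data)


def cophenetic_correlation(tree_a, tree_b) -> float | None:
    """Pearson correlation between the two trees' leaf-pair distance
    vectors; None when either vector has zero variance (e.g. a star tree),
    for which the correlation is undefined."""
    da = _pair_distances(tree_a)
    db = _pair_distances(tree_b)
    if set(da.index) != set(db.index):
        raise ValueError("trees must share an identical leaf set")
    if len(da) < 3:
        raise ValueError("need at least 3 leaves")
    db = db.reindex(da.index)
    if np.ptp(da.to_numpy()) == 0 or np.ptp(db.to_numpy()) == 0:
        return None
    return float(pearsonr(da.to_numpy(), db.to_numpy())[0])


# ---------------------------------------------------------------------------
# branch collapsing and wedges
# ---------------------------------------------------------------------------


@dataclass
class WedgeSummary:
    """Wedges (leaf sets of collapsed subtrees) with per-group composition.

    ``group_wedge_counts`` counts a wedge toward every group present in it;
    ``purity`` is the fraction of wedges containing a single group.
    """

    wedges: list[tuple[frozenset[str], Counter]]
    group_wedge_counts: Counter = field(default_factory=Counter)

    @property
    def n_wedges(self) -> int:
        return len(self.wedges)

    @property
    def purity(self) -> float:
        if not self.wedges:
            return float("nan")
        return sum(1 for _, c in self.wedges if len(c) == 1) / len(self.wedges)


def collapse_and_count(
    tree: LinkageTree, groups: dict[str, str], fraction: float = 0.25
) -> WedgeSummary:
    """Contract branches shorter than `fraction` of the maximum branch
    length and count the resulting wedges per group.

    A branch's length is parent height minus child height.  A wedge is a
    maximal subtree all of whose internal branches are contracted; its leaf
    sets partition the genomes.  Each wedge counts toward every group
    appearing among its leaves (purity is reported alongside).
    """
    n = tree.n_leaves
    heights = tree.heights()
    children: dict[int, tuple[int, int]] = {
        n + i: (int(tree.Z[i, 0]), int(tree.Z[i, 1])) for i in range(len(tree.Z))
    }
    root = n + len(tree.Z) - 1 if len(tree.Z) else 0
    edge_len = {}
    for parent, (a, b) in children.items():
        for c in (a, b):
            edge_len[c] = heights[parent] - heights[c]
    if edge_len:
        l_max = max(edge_len.values())
        cutoff = fraction * l_max
    else:
        cutoff = 0.0
    contracted = {c: (length < cutoff) for c, length in edge_len.items()}

    # all_short[v]: every branch inside subtree(v) is contracted
    all_short: dict[int, bool] = {}
    leafset: dict[int, frozenset[str]] = {}
    for v in range(n):
        all_short[v] = True
        leafset[v] = frozenset([tree.leaves[v]])
    for parent in sorted(children):  # scipy guarantees children < parent id order
        a, b = children[parent]
        all_short[parent] = (
            all_short[a] and all_short[b] and contracted[a] and contracted[b]
        )
        leafset[parent] = leafset[a] | leafset[b]

    wedge_roots: list[int] = []

    def walk(v: int) -> None:
        if all_short[v]:
            wedge_roots.append(v)
            return
        a, b = children[v]
        walk(a)
        walk(b)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 2 * (n + len(tree.Z)) + 100))
    try:
        walk(root)
    finally:
        sys.setrecursionlimit(old)

    wedges = []
    counts: Counter = Counter()
    for v in wedge_roots:
        comp = Counter(groups[leaf] for leaf in leafset[v])
        wedges.append((leafset[v], comp))
        for grp in comp:
            counts[grp] += 1
    assert sum(len(w) for w, _ in wedges) == n, "wedges must partition the leaves"
    return WedgeSummary(wedges=wedges, group_wedge_counts=counts)


# ---------------------------------------------------------------------------
# within-group similarity comparison
# ---------------------------------------------------------------------------


@dataclass
class SimilarityTestResult:
    group_a: str
    group_b: str
    n_pairs_a: int
    n_pairs_b: int
    median_a: float
    median_b: float
    u_statistic: float
    p_value: float


def within_group_similarity_test(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    group_a: str,
    group_b: str,
) -> SimilarityTestResult:
    """Compare within-group profile similarities between two groups.

    Similarity of a genome pair = 1 - Jaccard distance of their family
    profiles; all within-group pairs form each sample, compared by a
    two-sided Mann-Whitney U test (exact when the combined sample size is
    <= 20, normal approximation with tie correction otherwise).
    """
    dist = jaccard_distance_matrix(matrix, axis="rows")
    samples = {}
    for grp in (group_a, group_b):
        ids = [g for g in matrix.index if groups.get(g) == grp]
        if len(ids) < 2:
            raise ValueError(f"group {grp} needs at least 2 genomes")
        sub = dist.loc[ids, ids].to_numpy()
        samples[grp] = 1.0 - sub[np.triu_indices(len(ids), k=1)]
    a, b = samples[group_a], samples[group_b]
    method = "exact" if len(a) + len(b) <= 20 else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return SimilarityTestResult(
        group_a=group_a,
        group_b=group_b,
        n_pairs_a=len(a),
        n_pairs_b=len(b),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# Newick import/export
# ---------------------------------------------------------------------------


def _needs_quoting(label: str) -> bool:
    return any(ch in label for ch in " \t()[]':;,")


def _quote(label: str) -> str:
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: LinkageTree, precision: int = 10) -> str:
    """Serialize a dendrogram to Newick; branch lengths are parent-minus-
    child heights, labels quoted when they contain metacharacters."""
    n = tree.n_leaves
    heights = tree.heights()

    def render(v: int, parent_height: float) -> str:
        bl = parent_height - heights[v]
        if v < n:
            return f"{_quote(tree.leaves[v])}:{bl:.{precision}g}"
        a, b = int(tree.Z[v - n, 0]), int(tree.Z[v - n, 1])
        inner = ",".join(render(c, heights[v]) for c in (a, b))
        return f"({inner}):{bl:.{precision}g}"

    if len(tree.Z) == 0:
        return f"{_quote(tree.leaves[0])}:0;"
    root = n + len(tree.Z) - 1
    a, b = int(tree.Z[root - n, 0]), int(tree.Z[root - n, 1])
    inner = ",".join(render(c, heights[root]) for c in (a, b))
    return f"({inner}):0;"


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a dendropy tree (error position reported
    by the parser on malformed input)."""
    return dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )
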