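"""Two-step homology clustering of protein sequences.

Step 1 — *subfamilies*: an undirected similarity graph is built from the
tabular output of an all-vs-all sequence search (m8 dialect with appended
query/target coverage columns), filtered at e-value <= 0.001 and coverage
>= 0.5, and partitioned by the greedy set-cover heuristic: repeatedly pick
the protein whose closed neighborhood covers the most still-uncovered
proteins; that protein becomes the representative of a new subfamily made of
itself plus its uncovered neighbors.

Step 2 — *families*: subfamilies are compared by profile-profile alignment
(consumed here as a tabular list of matches); matches with probability >=
95% and coverage >= 0.50 form a network weighted by probability x coverage,
which is clustered with the Markov Clustering algorithm (MCL, inflation 2.0).

Both levels are exact partitions of the protein set, asserted after every
run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Subfamily:
    id: str
    representative: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError("subfamily must have members")
        if self.representative not in self.members:
            raise ValueError("representative must be a member")


@dataclass(frozen=True)
class Family:
    id: str
    subfamilies: frozenset[str]
    proteins: frozenset[str]


@dataclass
class MclParams:
    """Markov clustering settings; inflation 2.0 is the pipeline default."""

    inflation: float = 2.0
    max_iterations: int = 200
    tolerance: float = 1e-8
    prune: float = 1e-5

    def __post_init__(self):
        if self.inflation <= 1.0:
            raise ValueError("inflation must be > 1")


def parse_m8(path) -> pd.DataFrame:
    """Read a 14-column m8-dialect table (12 standard columns + qcov, tcov).

    Malformed rows are skipped with a logged warning carrying the line
    number.
    """
    from .synthetic import M8_COLUMNS

    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(M8_COLUMNS):
                logger.warning("line %d: expected 14 fields, got %d — skipped",
                               lineno, len(parts))
                continue
            try:
                rows.append([
                    parts[0], parts[1], float(parts[2]), int(parts[3]),
                    int(parts[4]), int(parts[5]), int(parts[6]), int(parts[7]),
                    int(parts[8]), int(parts[9]), float(parts[10]),
                    float(parts[11]), float(parts[12]), float(parts[13]),
                ])
            except ValueError:
                logger.warning("line %d: unparseable numeric field — skipped", lineno)
    return pd.DataFrame(rows, columns=M8_COLUMNS)


def build_similarity_graph(
    hits: pd.DataFrame,
    evalue_max: float = 0.001,
    cover_min: float = 0.5,
    proteins=None,
) -> nx.Graph:
    """Protein similarity graph from an m8-dialect hit table.

    An edge is retained iff e-value <= `evalue_max` and coverage >=
    `cover_min`, where the coverage of a hit is the more conservative
    min(query coverage, target coverage).  Self-hits are dropped.  Proteins
    listed in `proteins` (or appearing in any hit) are kept as nodes even if
    they end up with no passing edge.
    """
    g = nx.Graph()
    if proteins is not None:
        g.add_nodes_from(proteins)
    for row in hits.itertuples(index=False):
        g.add_node(row.query)
        g.add_node(row.target)
        if row.query == row.target:
            continue
        cov = min(row.qcov, row.tcov)
        if row.evalue <= evalue_max and cov >= cover_min:
            g.add_edge(row.query, row.target)
    return g


def greedy_set_cover(graph: nx.Graph) -> list[Subfamily]:
    """Partition the similarity graph into subfamilies by greedy set cover.

    At each step the uncovered node with the largest number of uncovered
    nodes in its closed neighborhood is selected (ties broken by
    lexicographically smallest node id, making the result invariant to edge
    input order); it becomes the representative of a subfamily consisting of
    itself plus its uncovered neighbors.
    """
    uncovered = set(graph.nodes)
    subfamilies: list[tuple[str, frozenset[str]]] = []
    # gain of an uncovered node changes only when neighbors get covered, so a
    # simple recompute-on-demand loop is adequate at these sizes
    while uncovered:
        best = None
        best_gain = -1
        for node in uncovered:
            gain = 1 + sum(1 for nb in graph.neighbors(node) if nb in uncovered)
            if gain > best_gain or (gain == best_gain and str(node) < str(best)):
                best, best_gain = node, gain
        members = {best} | {nb for nb in graph.neighbors(best) if nb in uncovered}
        uncovered -= members
        subfamilies.append((best, frozenset(members)))
    # stable ids ordered by representative
    subfamilies.sort(key=lambda rm: str(rm[0]))
    out = [
        Subfamily(id=f"sub{i + 1:06d}", representative=rep, members=mem)
        for i, (rep, mem) in enumerate(subfamilies)
    ]
    _assert_partition([s.members for s in out], set(graph.nodes), "subfamilies")
    return out


def _assert_partition(parts, universe, label):
    union: set = set()
    total = 0
    for p in parts:
        union |= set(p)
        total += len(p)
    if union != set(universe) or total != len(universe):
        raise AssertionError(f"{label} do not partition the input set")


def filter_profile_matches(
    matches: pd.DataFrame,
    prob_min: float = 95.0,
    cov_min: float = 0.50,
    subfamilies=None,
) -> nx.Graph:
    """Weighted subfamily network from profile-profile matches.

    A match is kept iff probability >= `prob_min` (percent) and coverage >=
    `cov_min`; its weight is (probability / 100) x coverage, so weights lie
    in [0, 1].  Subfamilies without any retained match stay as isolated
    nodes.  Rows with probability outside [0, 100] or coverage outside
    [0, 1] are rejected.
    """
    g = nx.Graph()
    if subfamilies is not None:
        g.add_nodes_from(subfamilies)
    for row in matches.itertuples(index=False):
        p, c = float(row.probability), float(row.coverage)
        if not (0.0 <= p <= 100.0) or not (0.0 <= c <= 1.0):
            raise ValueError(
                f"invalid profile match {row.subfamily_a}-{row.subfamily_b}: "
                f"probability={p}, coverage={c}"
            )
        g.add_node(row.subfamily_a)
        g.add_node(row.subfamily_b)
        if row.subfamily_a == row.subfamily_b:
            continue
        if p >= prob_min and c >= cov_min:
            w = (p / 100.0) * c
            prev = g.get_edge_data(row.subfamily_a, row.subfamily_b)
            if prev is None or prev["weight"] < w:
                g.add_edge(row.subfamily_a, row.subfamily_b, weight=w)
    return g


def _mcl_dense(
    A: np.ndarray, params: MclParams, check_stochastic: bool = True
) -> list[set[int]]:
    """Run MCL on a dense non-negative adjacency matrix; returns clusters of
    row indices.

    Self-loops are set to each node's maximum incident weight (1.0 for
    isolated nodes) before column normalization.  Iteration alternates
    expansion (matrix squaring) and inflation (elementwise power, column
    re-normalization) with pruning of small entries, until the matrix
    changes by less than the tolerance.
    """
    n = A.shape[0]
    A = A.astype(float).copy()
    loop = A.max(axis=0)
    loop[loop <= 0] = 1.0
    np.fill_diagonal(A, loop)
    M = A / A.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(params.max_iterations):
        M2 = M @ M
        np.power(M2, params.inflation, out=M2)
        M2[M2 < params.prune] = 0.0
        colsum = M2.sum(axis=0, keepdims=True)
        # a fully pruned column falls back to staying put
        dead = colsum[0] == 0
        if dead.any():
            M2[np.argmax(M[:, dead], axis=0), np.nonzero(dead)[0]] = 1.0
            colsum = M2.sum(axis=0, keepdims=True)
        M2 /= colsum
        if check_stochastic:
            assert np.allclose(M2.sum(axis=0), 1.0, atol=1e-9), \
                "MCL columns must stay stochastic"
        diff = np.abs(M2 - M).max()
        M = M2
        if diff < params.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge; interpreting the current matrix")

    # attractors are rows with non-negligible diagonal mass; a cluster is an
    # attractor together with the columns that flow into it, overlapping
    # attractor systems merged
    eps = max(params.prune, 1e-9)
    attractors = np.nonzero(np.diag(M) > eps)[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    assigned = np.zeros(n, dtype=bool)
    for a in attractors:
        cols = np.nonzero(M[a] > eps)[0]
        for c in cols:
            union(a, c)
            assigned[c] = True
    for j in range(n):  # orphan columns: follow their largest flow
        if not assigned[j]:
            union(int(np.argmax(M[:, j])), j)
    clusters: dict[int, set[int]] = {}
    for j in range(n):
        clusters.setdefault(find(j), set()).add(j)
    return list(clusters.values())


def markov_cluster(
    network: nx.Graph,
    params: MclParams | None = None,
    subfamily_members: dict[str, frozenset[str]] | None = None,
) -> list[Family]:
    """Cluster the weighted subfamily network into families with MCL.

    Disconnected components are clustered independently (MCL never merges
    components, and per-component dense matrices keep this cheap); isolated
    subfamilies become singleton families.  If `subfamily_members` is given,
    each family also carries the union of its subfamilies' protein members.
    """
    params = params or MclParams()
    raw: list[frozenset[str]] = []
    for comp in nx.connected_components(network):
        nodes = sorted(comp, key=str)
        if len(nodes) == 1:
            raw.append(frozenset(nodes))
            continue
        A = nx.to_numpy_array(network.subgraph(nodes), nodelist=nodes, weight="weight")
        for cluster in _mcl_dense(A, params):
            raw.append(frozenset(nodes[i] for i in cluster))
    raw.sort(key=lambda c: min(str(x) for x in c))
    families = []
    for i, subs in enumerate(raw):
        prots: frozenset[str] = frozenset()
        if subfamily_members is not None:
            prots = frozenset().union(*(subfamily_members[s] for s in subs))
        families.append(Family(id=f"fam{i + 1:06d}", subfamilies=subs, proteins=prots))
    _assert_partition([f.subfamilies for f in families], set(network.nodes), "families")
    return families


def cluster_proteins(
    hits: pd.DataFrame,
    profiles: pd.DataFrame,
    evalue_max: float = 0.001,
    cover_min: float = 0.5,
    prob_min: float = 95.0,
    profile_cov_min: float = 0.50,
    mcl_params: MclParams | None = None,
    proteins=None,
) -> tuple[list[Subfamily], list[Family]]:
    """End-to-end two-step clustering: hit tables in, subfamilies+families out."""
    graph = build_similarity_graph(hits, evalue_max, cover_min, proteins=proteins)
    subfamilies = greedy_set_cover(graph)
    # the profile table must reference the recovered subfamily ids; tables
    # produced against another labelling are re-keyed with
    # remap_profile_table() first
    known = {s.id for s in subfamilies}
    table_ids = set(profiles["subfamily_a"]) | set(profiles["subfamily_b"])
    unknown = table_ids - known
    if unknown:
        raise ValueError(
            f"profile table references {len(unknown)} unknown subfamilies "
            f"(e.g. {sorted(unknown)[:3]}); re-key it with remap_profile_table()"
        )
    net = filter_profile_matches(
        profiles, prob_min, profile_cov_min, subfamilies=[s.id for s in subfamilies]
    )
    members = {s.id: s.members for s in subfamilies}
    families = markov_cluster(net, mcl_params, subfamily_members=members)
    return subfamilies, families


def remap_profile_table(
    profiles: pd.DataFrame,
    truth_members: dict[str, list[str]],
    subfamilies: list[Subfamily],
) -> pd.DataFrame:
    """Re-key a ground-truth profile table onto recovered subfamily ids.

    A truth subfamily maps to the recovered subfamily holding the plurality
    of its members (ties to the lexicographically smallest recovered id);
    rows whose two endpoints collapse onto the same recovered subfamily are
    dropped.
    """
    prot_to_sub = {p: s.id for s in subfamilies for p in s.members}
    mapping: dict[str, str] = {}
    for truth_id, prots in truth_members.items():
        counts: dict[str, int] = {}
        for p in prots:
            sid = prot_to_sub.get(p)
            if sid is not None:
                counts[sid] = counts.get(sid, 0) + 1
        if counts:
            best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            mapping[truth_id] = best
    out = profiles.assign(
        subfamily_a=profiles["subfamily_a"].map(mapping),
        subfamily_b=profiles["subfamily_b"].map(mapping),
    ).dropna(subset=["subfamily_a", "subfamily_b"])
    return out[out["subfamily_a"] != out["subfamily_b"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# annotation QC
# ---------------------------------------------------------------------------


def annotation_admixture(
    members, annotations: dict[str, str]
) -> float | None:
    """Percentage of annotated members disagreeing with the dominant label.

    Over annotated members only: ``100 * (1 - n_modal / n_annotated)``.
    Ties on the modal label are broken by lexicographic label order (the
    result is the same either way, since tied labels have equal counts).
    Returns None when no member is annotated — an undefined admixture is
    distinct from a perfectly homogeneous one.
    """
    labels = [annotations[p] for p in members if p in annotations]
    if not labels:
        return None
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    modal = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    return 100.0 * (1.0 - modal[1] / len(labels))


def best_family_per_annotation(
    families: list[Family], annotations: dict[str, str]
) -> dict[str, tuple[str, float]]:
    """For each annotation label, the family holding the largest share of
    that label's proteins (ties to the smaller family id)."""
    label_total: dict[str, int] = {}
    label_fam: dict[str, dict[str, int]] = {}
    fam_of = {p: f.id for f in families for p in f.proteins}
    for prot, lab in annotations.items():
        fid = fam_of.get(prot)
        label_total[lab] = label_total.get(lab, 0) + 1
        if fid is not None:
            label_fam.setdefault(lab, {}).setdefault(fid, 0)
            label_fam[lab][fid] += 1
    out: dict[str, tuple[str, float]] = {}
    for lab, per_fam in label_fam.items():
        fid, cnt = sorted(per_fam.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        out[lab] = (fid, 100.0 * cnt / label_total[lab])
    return out
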