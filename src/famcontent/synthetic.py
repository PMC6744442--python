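"""Synthetic pangenome data with planted structure.

Every downstream stage of the pipeline (homology clustering, presence/absence
matrix analysis, module detection, content dendrograms, enrichment tests) can
be exercised on data generated here, with ground-truth labels emitted
alongside every artifact so recovery metrics (ARI, precision/recall) are
computable without re-deriving the truth.

The generated world mimics a two-superclade prokaryotic dataset: a CPR-like
superclade and a non-CPR bacterial superclade, each with phylum substructure,
plus optionally a small archaeal outgroup.  Protein families fall into five
classes:

``universal``
    present in nearly every genome (the near-ubiquitous core module),
``bac_enriched`` / ``cpr_enriched``
    widespread in one superclade, rare in the other,
``lineage_specific``
    confined to a single phylum (blocks of co-occurring families),
``background``
    sparse, uncorrelated presence; these families should end up unassigned
    to any module.

Per-genome dropout emulates incomplete draft assemblies: every family call
is thinned uniformly at the genome's missingness rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("CPR", "BAC", "ARC")
FAMILY_CLASSES = (
    "universal",
    "bac_enriched",
    "cpr_enriched",
    "lineage_specific",
    "background",
)

#: Default presence probabilities per (family class, genome group).  The
#: enriched classes use 0.9 in their home superclade vs 0.05 in the other;
#: lineage-specific probabilities apply only within the family's home phylum
#: (elsewhere ``LINEAGE_FLOOR``).
DEFAULT_PRESENCE_PROB: dict[tuple[str, str], float] = {
    ("universal", "CPR"): 0.95,
    ("universal", "BAC"): 0.95,
    ("universal", "ARC"): 0.90,
    ("bac_enriched", "CPR"): 0.05,
    ("bac_enriched", "BAC"): 0.90,
    ("bac_enriched", "ARC"): 0.30,
    ("cpr_enriched", "CPR"): 0.90,
    ("cpr_enriched", "BAC"): 0.05,
    ("cpr_enriched", "ARC"): 0.05,
    ("lineage_specific", "CPR"): 0.95,
    ("lineage_specific", "BAC"): 0.95,
    ("lineage_specific", "ARC"): 0.95,
    ("background", "CPR"): 0.05,
    ("background", "BAC"): 0.05,
    ("background", "ARC"): 0.05,
}

#: Presence probability of a lineage-specific family outside its home phylum.
LINEAGE_FLOOR = 0.01

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class PangenomeTruth:
    """Ground truth for a planted presence/absence world.

    Attributes
    ----------
    genomes : pandas.DataFrame
        One row per genome: ``genome_id``, ``group`` (CPR/BAC/ARC),
        ``phylum``, ``dropout`` (per-genome missingness fraction).
    families : pandas.DataFrame
        One row per family: ``family_id``, ``family_class``, ``block_id``
        (ground-truth module label; background families get their own
        singleton block), ``home_phylum`` (lineage-specific only, else NA).
    presence_prob : dict
        ``(family_class, group) -> probability`` of presence before dropout.
    seed : int
        Seed of the RNG stream used by the generators.
    """

    genomes: pd.DataFrame
    families: pd.DataFrame
    presence_prob: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PRESENCE_PROB)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.genomes["genome_id"].duplicated().any():
            raise ValueError("genome ids must be unique")
        if self.families["family_id"].duplicated().any():
            raise ValueError("family ids must be unique")
        bad = set(self.families["family_class"]) - set(FAMILY_CLASSES)
        if bad:
            raise ValueError(f"unknown family classes: {sorted(bad)}")
        for p in self.presence_prob.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("presence probabilities must lie in [0, 1]")
        if ((self.genomes["dropout"] < 0) | (self.genomes["dropout"] > 1)).any():
            raise ValueError("dropout must lie in [0, 1]")


def default_truth(
    n_cpr: int = 100,
    n_bac: int = 100,
    n_arc: int = 0,
    phyla_per_group: int = 10,
    n_universal: int = 40,
    n_bac_enriched: int = 40,
    n_cpr_enriched: int = 40,
    lineage_blocks: int = 4,
    lineage_block_size: int = 15,
    n_background: int = 60,
    dropout: float | Mapping[str, float] = 0.1,
    presence_prob: Mapping[tuple[str, str], float] | None = None,
    seed: int = 0,
) -> PangenomeTruth:
    """The default two-superclade scenario.

    200 genomes (100 CPR-like, 100 non-CPR bacteria) spread over 10 phyla
    per superclade, with one universal module, one module widespread only in
    each superclade, four lineage-specific blocks and a pool of sparse
    background families; uniform per-genome dropout of 0.1 (pass a
    group -> fraction mapping for asymmetric incompleteness, e.g. more
    fragmentary CPR-like drafts).
    """
    rows = []
    for group, n in (("CPR", n_cpr), ("BAC", n_bac), ("ARC", n_arc)):
        drop = dropout.get(group, 0.0) if isinstance(dropout, Mapping) else dropout
        for i in range(n):
            phylum = f"{group}_p{(i % phyla_per_group) + 1:02d}" if group != "ARC" else "ARC_p01"
            rows.append((f"{group.lower()}_{i + 1:04d}", group, phylum, drop))
    genomes = pd.DataFrame(rows, columns=["genome_id", "group", "phylum", "dropout"])

    fam_rows: list[tuple[str, str, str, object]] = []

    def _add(n: int, cls: str, block: str, home: object = pd.NA) -> None:
        start = len(fam_rows)
        for i in range(n):
            fam_rows.append((f"fam{start + i + 1:06d}", cls, block, home))

    _add(n_universal, "universal", "block_universal")
    _add(n_bac_enriched, "bac_enriched", "block_bac")
    _add(n_cpr_enriched, "cpr_enriched", "block_cpr")
    # lineage blocks alternate between the two superclades' first phyla
    homes = []
    for b in range(lineage_blocks):
        group = "CPR" if b % 2 == 0 else "BAC"
        homes.append(f"{group}_p{b // 2 + 1:02d}")
    for b, home in enumerate(homes):
        _add(lineage_block_size, "lineage_specific", f"block_lineage_{b + 1}", home)
    start = len(fam_rows)
    for i in range(n_background):
        fam_rows.append(
            (f"fam{start + i + 1:06d}", "background", f"block_bg_{i + 1}", pd.NA)
        )
    families = pd.DataFrame(
        fam_rows, columns=["family_id", "family_class", "block_id", "home_phylum"]
    )
    prob = dict(DEFAULT_PRESENCE_PROB if presence_prob is None else presence_prob)
    truth = PangenomeTruth(genomes=genomes, families=families, presence_prob=prob, seed=seed)
    truth.validate()
    return truth


def generate_presence_matrix(
    truth: PangenomeTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the genome x family presence/absence matrix.

    Each cell is Bernoulli with probability
    ``presence_prob[class(f), group(g)] * (1 - dropout(g))``; for
    lineage-specific families the class probability applies only in the
    family's home phylum and :data:`LINEAGE_FLOOR` elsewhere.

    Returns
    -------
    (matrix, taxonomy)
        ``matrix`` is a boolean DataFrame (genomes as rows, families as
        columns); ``taxonomy`` has columns genome_id, group, phylum.
    """
    truth.validate()
    if len(truth.genomes) == 0 or len(truth.families) == 0:
        raise ValueError("need at least one genome and one family")
    rng = np.random.default_rng(truth.seed)

    n_g = len(truth.genomes)
    n_f = len(truth.families)
    prob = np.zeros((n_g, n_f))
    groups = truth.genomes["group"].to_numpy()
    phyla = truth.genomes["phylum"].to_numpy()
    for j, fam in enumerate(truth.families.itertuples(index=False)):
        cls = fam.family_class
        col = np.array([truth.presence_prob[(cls, g)] for g in groups])
        if cls == "lineage_specific" and not pd.isna(fam.home_phylum):
            col = np.where(phyla == fam.home_phylum, col, LINEAGE_FLOOR)
        prob[:, j] = col
    prob *= (1.0 - truth.genomes["dropout"].to_numpy())[:, None]
    cells = rng.random((n_g, n_f)) < prob
    matrix = pd.DataFrame(
        cells,
        index=truth.genomes["genome_id"].to_list(),
        columns=truth.families["family_id"].to_list(),
    )
    taxonomy = truth.genomes[["genome_id", "group", "phylum"]].copy()
    return matrix, taxonomy


# ---------------------------------------------------------------------------
# sequence-level truth: families with subfamily divergence structure
# ---------------------------------------------------------------------------


@dataclass
class SequenceTruth:
    """Planted protein families with subfamily structure.

    ``members`` maps family id -> subfamily id -> list of (protein_id,
    genome_id).  Subfamily seed sequences within one family diverge at
    ``seed_divergence`` of sites; each member differs from its subfamily
    seed by i.i.d. substitutions at ``member_rate`` (so within-subfamily
    identity exceeds between-subfamily identity whenever
    ``member_rate < seed_divergence / 2``).
    """

    members: Mapping[str, Mapping[str, Sequence[tuple[str, str]]]]
    member_rate: float = 0.05
    seed_divergence: float = 0.4
    length: int = 120
    seed: int = 0

    def validate(self) -> None:
        if not self.members:
            raise ValueError("empty family list")
        if not 0.0 <= self.member_rate <= 1.0:
            raise ValueError("member_rate must lie in [0, 1]")
        if not 0.0 <= self.seed_divergence <= 1.0:
            raise ValueError("seed_divergence must lie in [0, 1]")
        if self.length < 30:
            raise ValueError("sequence length must be >= 30")
        seen: set[str] = set()
        for fam in self.members.values():
            for prots in fam.values():
                for pid, _ in prots:
                    if pid in seen:
                        raise ValueError(f"duplicate protein id {pid}")
                    seen.add(pid)


def default_sequence_truth(
    n_families: int = 4,
    subfamilies_per_family: int = 2,
    members_per_subfamily: int = 6,
    n_genomes: int = 12,
    member_rate: float = 0.05,
    seed_divergence: float = 0.4,
    length: int = 120,
    seed: int = 0,
) -> SequenceTruth:
    """A small sequence world: members are dealt round-robin to genomes."""
    members: dict[str, dict[str, list[tuple[str, str]]]] = {}
    genome_ids = [f"g{i + 1:03d}" for i in range(n_genomes)]
    k = 0
    for f in range(n_families):
        fam_id = f"fam{f + 1:06d}"
        members[fam_id] = {}
        for s in range(subfamilies_per_family):
            sub_id = f"{fam_id}.sub{s + 1}"
            prots = []
            for _ in range(members_per_subfamily):
                prots.append((f"p{k + 1:05d}", genome_ids[k % n_genomes]))
                k += 1
            members[fam_id][sub_id] = prots
    return SequenceTruth(
        members=members,
        member_rate=member_rate,
        seed_divergence=seed_divergence,
        length=length,
        seed=seed,
    )


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently at `rate`, never to the same letter."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    if hit.any():
        shift = rng.integers(1, len(AMINO_ACIDS), size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % len(AMINO_ACIDS)
    return out


def generate_sequence_families(truth: SequenceTruth) -> list[tuple[str, str]]:
    """Generate protein sequences for every planted family member.

    Returns a list of ``(protein_id, sequence)`` in deterministic order
    (families, then subfamilies, then members, in insertion order).
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    records: list[tuple[str, str]] = []
    for fam_id in truth.members:
        base = rng.integers(0, len(AMINO_ACIDS), size=truth.length)
        for sub_id in truth.members[fam_id]:
            sub_seed = _mutate(base, truth.seed_divergence, rng)
            for pid, _genome in truth.members[fam_id][sub_id]:
                mem = _mutate(sub_seed, truth.member_rate, rng)
                records.append((pid, "".join(AMINO_ACIDS[i] for i in mem)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA via Biopython."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        (SeqRecord(Seq(s), id=pid, description="") for pid, s in records),
        str(path),
        "fasta",
    )


M8_COLUMNS = [
    "query", "target", "pident", "alnlen", "mismatch", "gapopen",
    "qstart", "qend", "tstart", "tend", "evalue", "bits", "qcov", "tcov",
]

PROFILE_COLUMNS = ["subfamily_a", "subfamily_b", "probability", "coverage"]


def _identity(a: str, b: str) -> float:
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def generate_hit_tables(
    truth: SequenceTruth,
    records: Sequence[tuple[str, str]] | None = None,
    noise: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulated all-vs-all search and profile-profile comparison tables.

    Within-subfamily protein pairs appear in the m8-style similarity table
    (e-value <= 1e-10, coverage >= 0.9); pairs of subfamilies of the same
    family appear in the profile-match table with probability >= 95% and
    coverage >= 0.5; cross-family pairs are absent.  ``noise`` removes that
    fraction of true similarity edges and adds the same number of random
    cross-family edges (which still pass the downstream thresholds, so they
    perturb the clustering).

    The m8 dialect is the standard 12-column tabular output plus two appended
    columns (query coverage, target coverage).
    """
    truth.validate()
    if records is None:
        records = generate_sequence_families(truth)
    seqs = dict(records)
    rng = np.random.default_rng(truth.seed + 1)

    prot_to_sub: dict[str, str] = {}
    prot_to_fam: dict[str, str] = {}
    for fam_id, subs in truth.members.items():
        for sub_id, prots in subs.items():
            for pid, _ in prots:
                prot_to_sub[pid] = sub_id
                prot_to_fam[pid] = fam_id

    m8_rows = []
    true_pairs: list[tuple[str, str]] = []
    for fam_id, subs in truth.members.items():
        for sub_id, prots in subs.items():
            pids = [p for p, _ in prots]
            for i in range(len(pids)):
                for j in range(i + 1, len(pids)):
                    true_pairs.append((pids[i], pids[j]))

    keep = np.ones(len(true_pairs), dtype=bool)
    if noise > 0 and true_pairs:
        n_drop = int(round(noise * len(true_pairs)))
        if n_drop:
            keep[rng.choice(len(true_pairs), size=n_drop, replace=False)] = False

    def _m8_row(q: str, t: str) -> list:
        pid = _identity(seqs[q], seqs[t])
        L = truth.length
        return [q, t, round(pid, 1), L, int(L * (100 - pid) / 100), 0,
                1, L, 1, L, 1e-30, 2.0 * L, 1.0, 1.0]

    for (q, t), k in zip(true_pairs, keep):
        if k:
            m8_rows.append(_m8_row(q, t))

    if noise > 0 and true_pairs:
        pids = sorted(prot_to_fam)
        n_add = int(round(noise * len(true_pairs)))
        added = 0
        while added < n_add:
            q, t = (pids[i] for i in rng.integers(0, len(pids), size=2))
            if q != t and prot_to_fam[q] != prot_to_fam[t]:
                m8_rows.append(_m8_row(q, t))
                added += 1

    profile_rows = []
    for fam_id, subs in truth.members.items():
        sub_ids = sorted(subs)
        for i in range(len(sub_ids)):
            for j in range(i + 1, len(sub_ids)):
                probability = 95.0 + 5.0 * rng.random()
                coverage = 0.6 + 0.4 * rng.random()
                profile_rows.append(
                    [sub_ids[i], sub_ids[j], round(probability, 2), round(coverage, 3)]
                )

    m8 = pd.DataFrame(m8_rows, columns=M8_COLUMNS)
    profiles = pd.DataFrame(profile_rows, columns=PROFILE_COLUMNS)
    return m8, profiles


def generate_scg_table(
    genome_ids: Sequence[str],
    scg_ids: Sequence[str],
    completeness: Mapping[str, float] | float = 1.0,
    duplication: Mapping[str, int] | int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulated single-copy-gene hit table (one row per hit copy).

    Per genome, ``floor(completeness * len(scg_ids))`` distinct SCGs are
    present and ``duplication`` of those are present in two copies.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in genome_ids:
        comp = completeness[g] if isinstance(completeness, Mapping) else completeness
        dup = duplication[g] if isinstance(duplication, Mapping) else duplication
        if not 0.0 <= comp <= 1.0:
            raise ValueError("completeness target must lie in [0, 1]")
        n_present = int(np.floor(comp * len(scg_ids)))
        if dup > n_present:
            raise ValueError(
                f"genome {g}: duplication count {dup} exceeds present count {n_present}"
            )
        present = rng.choice(len(scg_ids), size=n_present, replace=False)
        dupd = set(present[:dup].tolist())
        for idx in sorted(present.tolist()):
            rows.append((g, scg_ids[idx]))
            if idx in dupd:
                rows.append((g, scg_ids[idx]))
    return pd.DataFrame(rows, columns=["genome_id", "scg_id"])
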