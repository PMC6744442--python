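"""CPR vs non-CPR enrichment of protein families.

Each family's presence/absence is cross-tabulated against the CPR / non-CPR
bacteria split (archaea excluded) and tested with a two-sided Fisher's
exact test, computed by explicit enumeration of the hypergeometric
distribution in log space.  P-values are Benjamini-Hochberg adjusted per
dataset, and a family is called enriched (or depleted) only when its
adjusted p-value is below 1e-5 in *both* genome datasets with a consistent
direction of effect; everything else is equally distributed.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

CATEGORY_ENRICHED = "enriched"
CATEGORY_DEPLETED = "depleted"
CATEGORY_EQUAL = "equal"


@lru_cache(maxsize=200_000)
def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The p-value sums, over all tables with the observed margins, the
    hypergeometric point probabilities not exceeding that of the observed
    table (to within 1e-12 relative tolerance), evaluated in log space.
    A degenerate margin makes every table equally (un)informative: p = 1,
    with a warning.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    N = a + b + c + d
    K = a + b  # first-row margin
    n = a + c  # first-column margin
    if K == 0 or K == N or n == 0 or n == N:
        warnings.warn("degenerate margin in contingency table; p = 1")
        return 1.0
    lo = max(0, K + n - N)
    hi = min(K, n)
    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, N, n, K)
    log_obs = logpmf[a - lo]
    mask = logpmf <= log_obs + 1e-12  # relative 1e-12 on the pmf scale
    p = float(np.exp(logpmf[mask]).sum())
    return min(p, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), clipped at 1
    and returned in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contingency_counts(matrix: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Per-family 2x2 counts of presence in CPR vs non-CPR bacteria.

    Archaeal genomes are excluded from the test.  Columns: a (CPR with),
    b (CPR without), c (non-CPR with), d (non-CPR without).
    """
    group_of = dict(zip(taxonomy["genome_id"], taxonomy["group"]))
    cpr = [g for g in matrix.index if group_of.get(g) == "CPR"]
    bac = [g for g in matrix.index if group_of.get(g) == "BAC"]
    a = matrix.loc[cpr].sum(axis=0).astype(int)
    c = matrix.loc[bac].sum(axis=0).astype(int)
    out = pd.DataFrame(
        {"a": a, "b": len(cpr) - a, "c": c, "d": len(bac) - c},
        index=matrix.columns,
    )
    return out


def _dataset_stats(counts: pd.DataFrame) -> pd.DataFrame:
    p = np.array(
        [fisher_exact_two_sided(int(r.a), int(r.b), int(r.c), int(r.d))
         for r in counts.itertuples(index=False)]
    )
    q = bh_adjust(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_cpr = counts["a"] / (counts["a"] + counts["b"])
        f_bac = counts["c"] / (counts["c"] + counts["d"])
    out = counts.copy()
    out["p"] = p
    out["q"] = q
    out["freq_cpr"] = f_cpr
    out["freq_bac"] = f_bac
    return out


def categorize(
    matrix_1: pd.DataFrame,
    taxonomy_1: pd.DataFrame,
    matrix_2: pd.DataFrame,
    taxonomy_2: pd.DataFrame,
    alpha: float = 1e-5,
) -> pd.DataFrame:
    """Three-way family categorization over two genome datasets.

    A family is *enriched* iff its BH-adjusted p is strictly below `alpha`
    in both datasets and its CPR presence frequency exceeds the non-CPR
    frequency in both; *depleted* with the opposite direction in both;
    otherwise *equal*.  Families significant in both datasets but with
    conflicting directions are categorized equal and flagged.  Families
    absent from one dataset's matrix get zero presence counts there.
    """
    fams = sorted(set(matrix_1.columns) | set(matrix_2.columns))

    def _with_all(matrix: pd.DataFrame) -> pd.DataFrame:
        missing = [f for f in fams if f not in matrix.columns]
        if missing:
            pad = pd.DataFrame(False, index=matrix.index, columns=missing)
            matrix = pd.concat([matrix, pad], axis=1)
        return matrix[fams]

    s1 = _dataset_stats(contingency_counts(_with_all(matrix_1), taxonomy_1))
    s2 = _dataset_stats(contingency_counts(_with_all(matrix_2), taxonomy_2))

    rows = []
    for fam in fams:
        r1, r2 = s1.loc[fam], s2.loc[fam]
        sig = (r1["q"] < alpha) and (r2["q"] < alpha)
        dir1 = np.sign(r1["freq_cpr"] - r1["freq_bac"])
        dir2 = np.sign(r2["freq_cpr"] - r2["freq_bac"])
        conflict = False
        if sig and dir1 > 0 and dir2 > 0:
            cat = CATEGORY_ENRICHED
        elif sig and dir1 < 0 and dir2 < 0:
            cat = CATEGORY_DEPLETED
        else:
            cat = CATEGORY_EQUAL
            conflict = bool(sig)  # significant in both but directions disagree
        rows.append(
            {
                "family_id": fam,
                "a1": int(r1["a"]), "b1": int(r1["b"]),
                "c1": int(r1["c"]), "d1": int(r1["d"]),
                "p1": r1["p"], "q1": r1["q"],
                "a2": int(r2["a"]), "b2": int(r2["b"]),
                "c2": int(r2["c"]), "d2": int(r2["d"]),
                "p2": r2["p"], "q2": r2["q"],
                "category": cat,
                "direction_conflict": conflict,
            }
        )
    return pd.DataFrame(rows).set_index("family_id")
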