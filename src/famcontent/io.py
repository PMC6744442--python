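"""Plain-text I/O helpers: 0/1 matrices, taxonomy tables, membership tables."""

from __future__ import annotations

import pandas as pd


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a boolean matrix as TSV with 0/1 cells, genomes as rows."""
    matrix.astype(int).to_csv(path, sep="\t", index_label="genome_id")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(bool)


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "group", "phylum"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
    return df


def write_membership(subfamilies, families, path) -> None:
    """protein_id -> subfamily_id -> family_id table."""
    fam_of_sub = {s: f.id for f in families for s in f.subfamilies}
    rows = [
        (p, s.id, fam_of_sub.get(s.id, ""))
        for s in subfamilies
        for p in sorted(s.members)
    ]
    pd.DataFrame(rows, columns=["protein_id", "subfamily_id", "family_id"]).sort_values(
        "protein_id"
    ).to_csv(path, sep="\t", index=False)
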