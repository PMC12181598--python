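"""TSV readers for the pipeline's tabular interfaces."""

from __future__ import annotations

import pandas as pd

COHORT_COLUMNS = {"sample_id", "sex", "age_group", "age", "bmi", "fried_score"}


def read_cohort(path) -> pd.DataFrame:
    """Cohort metadata TSV -> DataFrame indexed by sample_id."""
    df = pd.read_csv(path, sep="\t")
    missing = COHORT_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"cohort table {path} missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dupes[:5]}")
    return df.set_index("sample_id")


def read_expression(path) -> pd.DataFrame:
    """Expression TSV (first column gene_id) -> genes x samples DataFrame."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ValueError(f"expression table {path} must start with a gene_id column")
    df = df.set_index("gene_id")
    if df.index.duplicated().any():
        raise ValueError(f"duplicate gene ids in {path}")
    return df


def read_serum(path) -> pd.DataFrame:
    """Serum concentration TSV (samples x markers) indexed by sample_id."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample_id":
        raise ValueError(f"serum table {path} must start with a sample_id column")
    return df.set_index("sample_id")
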