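"""Tabular formats: AIRR-style clonotype tables and raw UMI tables.

Clonotype tables are TSV with the column subset ``locus, v_call, j_call,
junction, duplicate_count, pgen, n_insertions_min, subset, productive``
(UTF-8, tab-separated, '.' decimal, empty field for missing optional
values); UMI tables are TSV with ``clonotype_key, umi, reads``.  Clonotype
identity is the (locus, V, J, junction-nucleotide) quadruple at gene level:
allele suffixes (``*01``) are stripped on read.  A "decombinator-like"
dialect maps the minimal column set of annotation-pipeline output onto the
same schema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClonotypeTable",
    "read_clonotype_table",
    "write_clonotype_table",
    "read_umi_table",
    "write_umi_table",
    "merge_memory_subsets",
    "filter_functional",
]

MANDATORY = ["locus", "v_call", "j_call", "junction", "duplicate_count"]
OPTIONAL = ["pgen", "n_insertions_min", "subset", "productive"]
DECOMBINATOR_MAP = {
    "v_gene": "v_call",
    "j_gene": "j_call",
    "cdr3nt": "junction",
    "frequency": "duplicate_count",
    "chain": "locus",
}
KEY_COLS = ["locus", "v_call", "j_call", "junction"]


@dataclass
class ClonotypeTable:
    """A clonotype table: unique (locus, V, J, junction) keys per subset."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
        counts = self.df["duplicate_count"]
        bad = self.df.index[(~np.isfinite(counts)) | (counts < 1)]
        if len(bad):
            raise ValueError(f"row {bad[0] + 2}: duplicate_count must be >= 1")
        if "pgen" in self.df:
            pg = self.df["pgen"].dropna()
            if ((pg < 0) | (pg > 1)).any():
                raise ValueError("pgen values must lie in [0, 1]")
        junk = self.df["junction"].str.fullmatch("[ACGT]+")
        if not junk.all():
            row = self.df.index[~junk][0]
            raise ValueError(f"row {row + 2}: junction must be over A/C/G/T")
        if self.keys().duplicated().any():
            raise ValueError("duplicated clonotype keys within one table")

    def keys(self) -> pd.Series:
        return self.df[KEY_COLS].agg("|".join, axis=1)

    @property
    def total_count(self) -> float:
        return float(self.df["duplicate_count"].sum())

    def __len__(self) -> int:
        return len(self.df)


def _strip_alleles(series: pd.Series) -> pd.Series:
    return series.str.split("*").str[0]


def read_clonotype_table(path, dialect: str = "airr-subset") -> ClonotypeTable:
    """Read a clonotype TSV.

    ``airr-subset`` expects the package's AIRR-style columns;
    ``decombinator-like`` maps a minimal annotation-pipeline header
    (v_gene, j_gene, cdr3nt, frequency, chain[, productive]).  Unknown
    columns are preserved as opaque annotations.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"junction": str}, float_precision="round_trip"
    )
    if dialect == "decombinator-like":
        df = df.rename(columns=DECOMBINATOR_MAP)
    elif dialect != "airr-subset":
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    cnt = pd.to_numeric(df["duplicate_count"], errors="coerce")
    bad = df.index[cnt.isna()]
    if len(bad):
        raise ValueError(f"{path}: row {bad[0] + 2}: non-numeric duplicate_count")
    df["duplicate_count"] = cnt.astype(np.int64) if (cnt % 1 == 0).all() else cnt
    df["junction"] = df["junction"].str.upper()
    df["v_call"] = _strip_alleles(df["v_call"].astype(str))
    df["j_call"] = _strip_alleles(df["j_call"].astype(str))
    if "productive" in df.columns:
        df["productive"] = df["productive"].map(
            {True: True, False: False, "T": True, "F": False, "true": True, "false": False}
        )
    return ClonotypeTable(df.reset_index(drop=True))


def write_clonotype_table(table: ClonotypeTable, path) -> None:
    # repr gives the shortest exact decimal, so floats round-trip bit-perfectly
    table.df.to_csv(
        path, sep="\t", index=False, float_format=lambda x: repr(float(x))
    )


def read_umi_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("clonotype_key", "umi", "reads"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column(s): {col}")
    if (df["reads"] < 1).any():
        raise ValueError(f"{path}: read counts must be >= 1")
    return df


def write_umi_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def merge_memory_subsets(tables: list[ClonotypeTable]) -> ClonotypeTable:
    """Combine memory subsets (CM/EM/EMRA) by summing the counts of
    identical (V, J, junction) sequences; total count is conserved."""
    if not tables:
        raise ValueError("no tables to merge")
    loci = {locus for t in tables for locus in t.df["locus"].unique()}
    if len(loci) > 1:
        raise ValueError(f"cannot merge mixed loci: {sorted(loci)}")
    frames = [t.df for t in tables]
    allrows = pd.concat(frames, ignore_index=True)
    agg = {"duplicate_count": "sum"}
    others = [c for c in allrows.columns if c not in KEY_COLS + ["duplicate_count"]]
    merged = allrows.groupby(KEY_COLS, as_index=False, sort=True).agg(
        {**agg, **{c: "first" for c in others}}
    )
    merged["subset"] = "memory"
    return ClonotypeTable(merged)


def filter_functional(table: ClonotypeTable) -> ClonotypeTable:
    """Keep records flagged productive whose generation probability is
    present and strictly positive."""
    df = table.df
    keep = pd.Series(True, index=df.index)
    if "productive" in df.columns:
        keep &= df["productive"].fillna(False).astype(bool)
    if "pgen" in df.columns:
        keep &= df["pgen"].notna() & (df["pgen"] > 0)
    else:
        keep &= False
    return ClonotypeTable(df[keep].reset_index(drop=True))
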