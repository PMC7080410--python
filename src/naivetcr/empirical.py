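"""Data-side summaries of subsampled repertoires.

Everything here operates on clonotype tables (one row per distinct
(locus, V, J, junction) with a UMI-derived molecule count) or on raw UMI
tables, and produces the comparison surfaces used against model
predictions: incidence across subsample replicates, the multi-mRNA
permutation test, memory-overlap cleaning, sort-contamination slope,
generation probability by abundance bin, zero-insertion fractions,
invariant-chain (NKT/MAIT) flags and cohort sharing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .prediction import IncidenceSummary

__all__ = [
    "incidence_summary",
    "PermutationResult",
    "permutation_test",
    "remove_memory_overlap",
    "contamination_slope",
    "median_pgen_by_log2bin",
    "zero_insertion_fraction",
    "invariant_chain_flags",
    "sharing_fraction",
]

KEY_COLS = ["locus", "v_call", "j_call", "junction"]


def _frame(table) -> pd.DataFrame:
    return table.df if hasattr(table, "df") else table


def _keys(df: pd.DataFrame) -> pd.Series:
    return df[KEY_COLS].agg("|".join, axis=1)


def incidence_table(tables: list) -> pd.DataFrame:
    """Per-sequence incidence across subsamples: one row per distinct key
    with its incidence (number of subsamples containing it) and the
    annotations of its first occurrence."""
    if len(tables) < 2:
        raise ValueError("incidence needs at least two subsamples")
    frames = []
    for i, t in enumerate(tables):
        df = _frame(t).copy()
        k = _keys(df)
        if k.duplicated().any():
            raise ValueError(
                f"subsample {i} has duplicated clonotype keys; collapse it first"
            )
        df["_key"] = k
        frames.append(df)
    allrows = pd.concat(frames, ignore_index=True)
    grouped = allrows.groupby("_key", sort=True)
    out = grouped.first().reset_index()
    out["incidence"] = grouped.size().to_numpy()
    out["total_count"] = grouped["duplicate_count"].sum().to_numpy()
    return out


def incidence_summary(tables: list, locus: str | None = None) -> IncidenceSummary:
    """Observed incidence summary: per-class sequence counts, median log10
    pgen and zero-insertion fraction."""
    inc = incidence_table(tables)
    if locus is None:
        locus = str(inc["locus"].iloc[0])
    n_sub = len(tables)
    counts, meds, zfrac = {}, {}, {}
    for cls in range(1, n_sub + 1):
        sub = inc[inc["incidence"] == cls]
        counts[cls] = float(len(sub))
        if len(sub) and "pgen" in sub and sub["pgen"].notna().any():
            meds[cls] = float(np.median(np.log10(sub["pgen"].dropna())))
        else:
            meds[cls] = np.nan
        if len(sub) and "n_insertions_min" in sub and sub["n_insertions_min"].notna().all():
            zfrac[cls] = float((sub["n_insertions_min"] == 0).mean())
        else:
            zfrac[cls] = np.nan
    return IncidenceSummary(locus, counts, meds, zfrac, repeats=1)


# ---------------------------------------------------------------------------
# permutation test for multi-mRNA inflation

@dataclass
class PermutationResult:
    observed_counts: dict[int, float]
    permuted_mean: dict[int, float]
    permuted_sd: dict[int, float]
    inflation: float  # pooled over incidence classes >= 2
    inflation_per_class: dict[int, float]
    reps: int


def _incidence_counts_from_matrix(mat: np.ndarray) -> dict[int, float]:
    inc = (mat > 0).sum(axis=1)
    n_sub = mat.shape[1]
    return {cls: float(np.sum(inc == cls)) for cls in range(1, n_sub + 1)}


def permutation_test(
    umi_counts: pd.DataFrame, reps: int, rng: np.random.Generator
) -> PermutationResult:
    """Estimate how much multi-incidence is explained by cells contributing
    multiple mRNA molecules.

    ``umi_counts`` has one row per sequence and one column per subsample
    holding its UMI (molecule) count there.  Each permutation pools every
    sequence's UMIs and reassigns each UMI independently and uniformly to
    one of the portions; in that setting molecules of one cell can spread
    over portions, so the permuted multi-incidence exceeds the observed one
    whenever cells contribute several molecules.  The inflation estimate per
    class is (permuted - observed) / permuted, averaged over repetitions.
    """
    mat = umi_counts.to_numpy()
    if mat.shape[1] < 2:
        raise ValueError("permutation test needs >= 2 subsamples")
    n_sub = mat.shape[1]
    observed = _incidence_counts_from_matrix(mat)
    totals = mat.sum(axis=1).astype(np.int64)
    per_rep = []
    for _ in range(reps):
        perm = rng.multinomial(totals, np.full(n_sub, 1.0 / n_sub))
        per_rep.append(_incidence_counts_from_matrix(perm))
    classes = range(1, n_sub + 1)
    perm_mean = {c: float(np.mean([r[c] for r in per_rep])) for c in classes}
    perm_sd = {c: float(np.std([r[c] for r in per_rep], ddof=1)) if reps > 1 else 0.0 for c in classes}
    multi = [c for c in classes if c >= 2]
    obs_multi = sum(observed[c] for c in multi)
    infl_per_class = {}
    for c in multi:
        infl_per_class[c] = (
            (perm_mean[c] - observed[c]) / perm_mean[c] if perm_mean[c] > 0 else np.nan
        )
    perm_multi = sum(perm_mean[c] for c in multi)
    inflation = (perm_multi - obs_multi) / perm_multi if perm_multi > 0 else np.nan
    return PermutationResult(observed, perm_mean, perm_sd, inflation, infl_per_class, reps)


def umi_count_matrix(umi_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-sequence UMI counts across subsample UMI tables (clonotype_key,
    umi, reads): distinct UMIs per key per subsample."""
    cols = {}
    for i, t in enumerate(umi_tables):
        cols[i] = t.groupby("clonotype_key")["umi"].nunique()
    return pd.DataFrame(cols).fillna(0).astype(int)


# ---------------------------------------------------------------------------
# cleaning and annotation summaries

def remove_memory_overlap(naive, memory):
    """Drop every naive record whose (locus, V, J, junction) key also occurs
    in the memory table."""
    ndf, mdf = _frame(naive), _frame(memory)
    if set(ndf["locus"].unique()) - set(mdf["locus"].unique()) and len(mdf):
        pass  # loci may legitimately differ in coverage; matching is by key
    shared = _keys(ndf).isin(set(_keys(mdf)))
    return ndf[~shared].reset_index(drop=True)


def contamination_slope(
    shared: pd.DataFrame, memory_threshold: float = 100.0
) -> float:
    """Least-squares slope of naive count on memory count over sequences
    with a memory count above the threshold: the estimated probability that
    a memory cell's sequence leaks into the naive sample."""
    sub = shared[shared["memory_count"] > memory_threshold]
    if len(sub) < 2:
        raise ValueError(
            f"need >= 2 sequences with memory count > {memory_threshold}"
        )
    if np.allclose(sub["naive_count"], 0):
        return 0.0
    res = stats.linregress(sub["memory_count"], sub["naive_count"])
    return float(res.slope)


def median_pgen_by_log2bin(table) -> tuple[pd.DataFrame, float]:
    """Median (and quartiles of) log10 pgen per log2 abundance bin
    (0,1], (1,2], (2,4], (4,8], ... -- intervals exclude the left edge and
    include the right -- plus the count-weighted least-squares slope of
    log10 pgen on the bin index."""
    df = _frame(table)
    counts = df["duplicate_count"].to_numpy()
    if np.any(counts < 1):
        raise ValueError("abundances must be >= 1")
    bin_idx = np.ceil(np.log2(counts)).astype(int)
    lp = np.log10(df["pgen"].to_numpy())
    rows = []
    for b in np.unique(bin_idx):
        sel = lp[bin_idx == b]
        rows.append(
            {
                "bin": int(b),
                "count_low": 0 if b == 0 else 2 ** (b - 1),
                "count_high": 2**b,
                "n_sequences": int(len(sel)),
                "median_log10_pgen": float(np.median(sel)),
                "q25": float(np.percentile(sel, 25)),
                "q75": float(np.percentile(sel, 75)),
            }
        )
    out = pd.DataFrame(rows)
    w = out["n_sequences"].to_numpy(float)
    x = out["bin"].to_numpy(float)
    y = out["median_log10_pgen"].to_numpy()
    if len(out) > 1:
        wm_x, wm_y = np.average(x, weights=w), np.average(y, weights=w)
        slope = np.sum(w * (x - wm_x) * (y - wm_y)) / np.sum(w * (x - wm_x) ** 2)
    else:
        slope = np.nan
    return out, float(slope)


def zero_insertion_fraction(incidence: pd.DataFrame) -> dict[int, float]:
    """Fraction of sequences with zero minimal N-additions per incidence
    class; requires the n_insertions_min annotation."""
    if "n_insertions_min" not in incidence or incidence["n_insertions_min"].isna().any():
        raise ValueError("minimal-insertion annotation missing")
    out = {}
    for cls, sub in incidence.groupby("incidence"):
        out[int(cls)] = float((sub["n_insertions_min"] == 0).mean())
    return out


def _strip_allele(call: str) -> str:
    return call.split("*")[0]


def _gene_match(call: str, target: str) -> bool:
    g = _strip_allele(call)
    return g == target or g.startswith(target + "-")


def invariant_chain_flags(locus: str, v_call: str, j_call: str | None = None):
    """(is_nkt_like, is_mait_like) by characteristic V/J usage:
    NKT: TRAV24-TRAJ18 (alpha), TRBV11 (beta);
    MAIT: TRAV1-2 with TRAJ33/TRAJ12/TRAJ20 (alpha), TRBV20 or TRBV6 (beta).
    """
    if locus == "alpha":
        nkt = _gene_match(v_call, "TRAV24") and j_call is not None and _gene_match(
            j_call, "TRAJ18"
        )
        mait = _strip_allele(v_call) == "TRAV1-2" and j_call is not None and any(
            _gene_match(j_call, t) for t in ("TRAJ33", "TRAJ12", "TRAJ20")
        )
    elif locus == "beta":
        nkt = _gene_match(v_call, "TRBV11")
        mait = _gene_match(v_call, "TRBV20") or _gene_match(v_call, "TRBV6")
    else:
        raise ValueError(f"unknown locus {locus!r}")
    return bool(nkt), bool(mait)


def sharing_fraction(
    query_sets: dict[int, set],
    cohort_tables: list,
    rng: np.random.Generator,
    downsample_reps: int = 10,
) -> pd.DataFrame:
    """Fraction of each incidence class's sequences found in each cohort
    repertoire.

    The (much larger) incidence-1 set is downsampled ``downsample_reps``
    times to the size of the largest multi-incidence set so the sharing
    fractions are comparable; its reported fraction is the mean over
    downsamples.
    """
    multi_sizes = [len(s) for c, s in query_sets.items() if c >= 2 and len(s)]
    target = max(multi_sizes) if multi_sizes else None
    rows = []
    for m, cohort in enumerate(cohort_tables):
        ckeys = set(_keys(_frame(cohort)))
        for cls, qset in query_sets.items():
            if not qset:
                continue
            if cls == 1 and target is not None and len(qset) > target:
                qlist = sorted(qset)
                fracs = []
                for _ in range(downsample_reps):
                    pick = rng.choice(len(qlist), size=target, replace=False)
                    sub = [qlist[i] for i in pick]
                    fracs.append(sum(k in ckeys for k in sub) / target)
                frac = float(np.mean(fracs))
            else:
                frac = sum(k in ckeys for k in qset) / len(qset)
            rows.append({"cohort": m, "incidence": cls, "sharing_fraction": frac})
    return pd.DataFrame(rows)
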