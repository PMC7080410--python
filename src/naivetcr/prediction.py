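"""In-silico subsample prediction from model clone-size distributions.

For a candidate clone-size distribution F the machinery simulates three
disjoint subsamples of cells, assigns an alpha and a beta chain only to the
clones that were actually sampled (drawn with replacement from a
post-selection chain pool, so identical rearrangements collide across
clones), collapses identical sequences, and scores each sequence's
*incidence* -- the number of subsamples it appears in.  Incidence is the
abundance proxy that is robust to multiple mRNA molecules per cell: a
sequence in two or three subsamples must come from at least two cells.

The comparison surface against observed data is the per-incidence sequence
count, median log10 P(sigma) and zero-insertion fraction; parameter sweeps
minimise a log-scale squared error on the incidence-2/3 counts and flag
whether the qualitative P(sigma) ordering (3 > 2 > 1 for alpha, 2 > 1 and
2 > 3 for beta) is reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clone_sizes import CloneSizeDistribution
from .sampling import _truncated_binomial

# Desk-scale study conditions: the full-scale system (N ~ 1e10-1e11 cells,
# 1e8 generated chains, samples of ~1e5-1e6 cells) is scaled down jointly so
# the governing ratios survive: the per-subsample sampled fraction n/N, the
# collision load per clone pair (set by the chain models' coincidence
# probability p2), and the recurrence rate of the highest-probability chains.
DESK_N = 8e6  # working pool size in cells
DESK_N_PER_SUBSAMPLE = 12_000  # cells per subsample (3 disjoint subsamples)
DESK_POOL_ALPHA = 300_000  # post-selection alpha chain pool entries
DESK_POOL_BETA = 2_000_000  # post-selection beta chain pool entries

__all__ = [
    "DESK_N",
    "DESK_N_PER_SUBSAMPLE",
    "DESK_POOL_ALPHA",
    "DESK_POOL_BETA",
    "ChainPool",
    "IncidenceSummary",
    "scale_distribution",
    "sample_clone_counts",
    "predict_subsamples",
    "qualitative_pgen_check",
    "goodness_of_fit",
    "parameter_sweep",
    "SweepResult",
    "predict_single_sample",
]


class ChainPool:
    """Post-selection chain pool prepared for fast incidence prediction.

    Wraps a chain DataFrame (``v_call, j_call, junction_nt, pgen,
    n_insertions_min``): entries are draws from the generative model, so
    sampling entry indices uniformly reproduces chain frequency proportional
    to P(sigma); distinct sequences are factorised once.
    """

    def __init__(self, chains: pd.DataFrame, locus: str):
        self.locus = locus
        key = chains["v_call"] + "|" + chains["j_call"] + "|" + chains["junction_nt"]
        self.entry_seq_id, uniques = pd.factorize(key)
        first = np.unique(self.entry_seq_id, return_index=True)[1]
        self.n_entries = len(chains)
        self.n_sequences = len(uniques)
        self.seq_log10_pgen = np.log10(chains["pgen"].to_numpy()[first])
        self.seq_zero_ins = chains["n_insertions_min"].to_numpy()[first] == 0
        # relative sequence frequencies in the pool (for diversity calibration)
        self.seq_weights = np.bincount(self.entry_seq_id) / self.n_entries


@dataclass
class IncidenceSummary:
    """Sequence counts and annotations per incidence class (1..n_subsamples)."""

    locus: str
    counts: dict[int, float]
    median_log10_pgen: dict[int, float]
    zero_insertion_fraction: dict[int, float]
    repeats: int = 1
    counts_sd: dict[int, float] = field(default_factory=dict)

    def classes(self):
        return sorted(self.counts)


def scale_distribution(
    dist: CloneSizeDistribution, n_target: float
) -> CloneSizeDistribution:
    """Scale a pool distribution down to ``n_target`` cells, preserving the
    clone sizes (the sampled statistics depend on s * clone size and the
    per-size sampling probabilities, which this keeps intact when the sample
    size n is scaled with the pool)."""
    factor = dist.N / n_target
    return CloneSizeDistribution(
        dist.sizes, dist.counts / factor, n_target, level=dist.level
    )


def sample_clone_counts(
    dist: CloneSizeDistribution,
    n_per_subsample: int,
    n_subsamples: int,
    rng: np.random.Generator,
):
    """Realise per-clone sampled-cell counts across disjoint subsamples.

    Returns ``(sizes, counts)`` for clones with at least one sampled cell:
    the clone's pool size and its cells per subsample (shape (M, S)).  At
    pool scale the draw is binomial: a clone of i cells contributes
    X ~ Binomial(i, S n/N) sampled cells in total (conditioned on >= 1 for
    the clones kept), uniformly partitioned over the S subsamples.
    """
    p_tot = n_subsamples * n_per_subsample / dist.N
    if p_tot > 1:
        raise ValueError("requested sample exceeds the pool")
    sizes_out = []
    totals = []
    for i, f in zip(dist.sizes, dist.counts):
        m = int(round(f))
        if m == 0:
            continue
        i = int(i)
        q = -np.expm1(i * np.log1p(-p_tot))
        k = rng.binomial(m, q)
        if k == 0:
            continue
        draws = _truncated_binomial(i, p_tot, k, rng)
        # a clone cannot contribute more cells than the draw holds
        draws = np.minimum(draws, n_subsamples * n_per_subsample)
        sizes_out.append(np.full(k, i, dtype=np.float64))
        totals.append(draws)
    if not sizes_out:
        return np.empty(0, np.float64), np.empty((0, n_subsamples), np.int64)
    sizes_out = np.concatenate(sizes_out)
    totals = np.concatenate(totals).astype(np.int64)
    # uniform partition over subsamples via sequential binomial thinning
    counts = np.empty((len(totals), n_subsamples), dtype=np.int64)
    left = totals.copy()
    for s in range(n_subsamples - 1):
        counts[:, s] = rng.binomial(left, 1.0 / (n_subsamples - s))
        left -= counts[:, s]
    counts[:, -1] = left
    return sizes_out, counts


def _incidence_one_repeat(
    dist: CloneSizeDistribution,
    pool: ChainPool,
    n_per_subsample: int,
    n_subsamples: int,
    rng: np.random.Generator,
):
    _, counts = sample_clone_counts(dist, n_per_subsample, n_subsamples, rng)
    m = len(counts)
    entry = rng.integers(0, pool.n_entries, m)
    sid = pool.entry_seq_id[entry]
    incidence = np.zeros(pool.n_sequences, dtype=np.int8)
    for s in range(n_subsamples):
        present = np.unique(sid[counts[:, s] > 0])
        incidence[present] += 1
    out = {}
    for cls in range(1, n_subsamples + 1):
        seqs = np.nonzero(incidence == cls)[0]
        if len(seqs):
            out[cls] = (
                len(seqs),
                float(np.median(pool.seq_log10_pgen[seqs])),
                float(np.mean(pool.seq_zero_ins[seqs])),
            )
        else:
            out[cls] = (0, np.nan, np.nan)
    return out


def predict_subsamples(
    dist: CloneSizeDistribution,
    pool: ChainPool,
    n_per_subsample: int,
    rng: np.random.Generator,
    n_subsamples: int = 3,
    repeats: int = 10,
) -> IncidenceSummary:
    """Predict the incidence summary for one locus, averaged over stochastic
    repeats of sampling and chain assignment."""
    per_class = {cls: [] for cls in range(1, n_subsamples + 1)}
    for _ in range(repeats):
        rep = _incidence_one_repeat(dist, pool, n_per_subsample, n_subsamples, rng)
        for cls, vals in rep.items():
            per_class[cls].append(vals)
    counts, meds, zfracs, sds = {}, {}, {}, {}
    for cls, vals in per_class.items():
        arr = np.array(vals, dtype=float)
        counts[cls] = float(arr[:, 0].mean())
        sds[cls] = float(arr[:, 0].std(ddof=1)) if repeats > 1 else 0.0
        with np.errstate(invalid="ignore"):
            meds[cls] = float(np.nanmean(arr[:, 1])) if np.any(~np.isnan(arr[:, 1])) else np.nan
            zfracs[cls] = float(np.nanmean(arr[:, 2])) if np.any(~np.isnan(arr[:, 2])) else np.nan
    return IncidenceSummary(pool.locus, counts, meds, zfracs, repeats, sds)


def qualitative_pgen_check(
    summary_alpha: IncidenceSummary, summary_beta: IncidenceSummary
) -> bool | None:
    """True iff median log10 P(sigma) orders 3 > 2 > 1 for alpha and
    2 > 1, 2 > 3 for beta; None (indeterminate) if a class is empty."""
    a = summary_alpha.median_log10_pgen
    b = summary_beta.median_log10_pgen
    needed = [a.get(1), a.get(2), a.get(3), b.get(1), b.get(2), b.get(3)]
    if any(v is None or np.isnan(v) for v in needed):
        return None
    return bool(a[3] > a[2] > a[1] and b[2] > b[1] and b[2] > b[3])


def goodness_of_fit(
    predicted: dict[str, IncidenceSummary],
    observed: dict[str, IncidenceSummary],
    classes: tuple[int, ...] = (2, 3),
) -> float:
    """Log-scale squared error on the multi-incidence sequence counts,
    summed over loci and incidence classes (symmetric in the arguments)."""
    d = 0.0
    for locus, pred in predicted.items():
        obs = observed[locus]
        for cls in classes:
            d += (
                np.log(pred.counts.get(cls, 0.0) + 1.0)
                - np.log(obs.counts.get(cls, 0.0) + 1.0)
            ) ** 2
    return float(d)


@dataclass(frozen=True)
class SweepResult:
    params: dict
    distance: float
    pgen_ordering_ok: bool | None


def parameter_sweep(
    dist_builder,
    grid: list[dict],
    observed: dict[str, IncidenceSummary],
    pools: dict[str, ChainPool],
    n_per_subsample: int,
    rng: np.random.Generator,
    repeats: int = 10,
    n_subsamples: int = 3,
) -> list[SweepResult]:
    """Score each grid point of a clone-size-distribution family.

    ``dist_builder(**params)`` must return a pool-level distribution at the
    working (scaled) N.  The distance at each point is computed from the
    repeat-averaged incidence summaries; the ordering flag is the majority
    vote of the qualitative P(sigma) check over repeats.
    """
    results = []
    for params in grid:
        dist = dist_builder(**params)
        singles = {
            locus: [
                predict_subsamples(dist, pool, n_per_subsample, rng, n_subsamples, 1)
                for _ in range(repeats)
            ]
            for locus, pool in pools.items()
        }
        # mean counts over repeats per locus, and a per-repeat ordering vote
        summaries = {}
        for locus, reps_list in singles.items():
            classes = range(1, n_subsamples + 1)
            counts = {
                c: float(np.mean([r.counts[c] for r in reps_list])) for c in classes
            }
            meds = {}
            for c in classes:
                vals = [
                    r.median_log10_pgen[c]
                    for r in reps_list
                    if not np.isnan(r.median_log10_pgen[c])
                ]
                meds[c] = float(np.mean(vals)) if vals else np.nan
            summaries[locus] = IncidenceSummary(locus, counts, meds, {}, repeats)
        votes = [
            qualitative_pgen_check(singles["alpha"][r], singles["beta"][r])
            for r in range(repeats)
        ]
        valid = [v for v in votes if v is not None]
        ordering = (sum(valid) > len(votes) / 2) if valid else None
        results.append(
            SweepResult(params, goodness_of_fit(summaries, observed), ordering)
        )
    return results


def best_sweep_point(results: list[SweepResult]) -> SweepResult:
    """Smallest distance among points with a correct P(sigma) ordering
    (falling back to the overall argmin when no point passes)."""
    ok = [r for r in results if r.pgen_ordering_ok]
    candidates = ok if ok else results
    return min(candidates, key=lambda r: r.distance)


def predict_single_sample(
    dist: CloneSizeDistribution,
    pool: ChainPool,
    mrna,
    n_cells: int,
    rng: np.random.Generator,
) -> pd.Series:
    """Predicted per-sequence molecule (UMI) abundances in one unsplit
    sample, including per-cell mRNA multiplicity: sampled cells contribute a
    random number of captured molecules each, and abundances sum over cells
    and over clones sharing a sequence."""
    sizes, counts = sample_clone_counts(dist, n_cells, 1, rng)
    cells = counts[:, 0]
    entry = rng.integers(0, pool.n_entries, len(cells))
    sid = pool.entry_seq_id[entry]
    mol_per_cell = mrna.draw_molecules(int(cells.sum()), rng)
    clone_of_cell = np.repeat(np.arange(len(cells)), cells)
    mols = np.bincount(clone_of_cell, weights=mol_per_cell, minlength=len(cells))
    abundance = np.bincount(sid, weights=mols, minlength=pool.n_sequences)
    abundance = abundance[abundance > 0]
    return pd.Series(abundance.astype(np.int64), name="abundance")
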