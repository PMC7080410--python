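"""Ground-truth synthetic repertoires and the sampling -> mRNA -> UMI -> read
measurement process.

The generator builds a naive pool from any clone-size distribution, assigns
every clone an independently generated, productive, selection-surviving
alpha and beta chain (identical chains in different clones arise naturally
from repeated recombination), splits a blood draw into disjoint subsamples
of cells, and converts sampled cells into molecule tables: each cell
contributes a random number of captured mRNA molecules, each molecule gets a
unique random 12-nt UMI and a read count, and per-read UMI errors can be
injected afterwards.  Every molecule is linked back to its source cell and
clone, so downstream estimates (UMI correction, incidence, inflation) can be
scored against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clone_sizes import CloneSizeDistribution
from .selection import SelectionModel, selection_mask
from .vdj import BASES, SyntheticVDJModel, generate_batch

__all__ = [
    "MRNAModel",
    "GroundTruthRepertoire",
    "realize_clone_sizes",
    "sample_chain_pool",
    "build_repertoire",
    "simulate_subsamples",
    "corrupt_umis",
]


@dataclass(frozen=True)
class MRNAModel:
    """Per-cell mRNA capture and sequencing model for one locus.

    ``mean_molecules`` is the expected number of mRNA molecules per cell
    (order 100 for alpha, 300 for beta); only a fraction
    ``capture_efficiency`` of them is captured and tagged with a UMI.  The
    captured count per cell is Poisson (or negative binomial with
    ``dispersion``) with mean ``mean_molecules * capture_efficiency``,
    optionally zero-truncated.  Reads per molecule are log-normal rounded up
    to >= 1 -- only relative read counts matter for UMI merge tie-breaks.
    """

    mean_molecules: float = 100.0
    capture_efficiency: float = 0.03
    reads_lognorm_mean: float = 1.0  # mean of log reads
    reads_lognorm_sigma: float = 0.7
    umi_length: int = 12
    umi_error_rate: float = 0.0
    family: str = "poisson"  # or "negbin" / "fixed"
    dispersion: float = 1.0  # negbin shape; larger = closer to Poisson
    zero_truncated: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.capture_efficiency <= 1:
            raise ValueError("capture_efficiency must be in (0, 1]")
        if not 0 <= self.umi_error_rate < 1:
            raise ValueError("umi_error_rate must be in [0, 1)")
        if self.family not in ("poisson", "negbin", "fixed"):
            raise ValueError(f"unknown molecule-count family {self.family!r}")

    @property
    def mean_captured(self) -> float:
        return self.mean_molecules * self.capture_efficiency

    def draw_molecules(self, n_cells: int, rng: np.random.Generator) -> np.ndarray:
        mu = self.mean_captured
        if self.family == "fixed":
            return np.full(n_cells, max(int(round(mu)), 1), dtype=np.int64)
        if self.family == "poisson":
            counts = rng.poisson(mu, n_cells)
        else:
            r = self.dispersion
            counts = rng.negative_binomial(r, r / (r + mu), n_cells)
        if self.zero_truncated:
            zero = counts == 0
            while zero.any():
                counts[zero] = (
                    rng.poisson(mu, int(zero.sum()))
                    if self.family == "poisson"
                    else rng.negative_binomial(
                        self.dispersion,
                        self.dispersion / (self.dispersion + mu),
                        int(zero.sum()),
                    )
                )
                zero = counts == 0
        return counts

    def draw_reads(self, n_molecules: int, rng: np.random.Generator) -> np.ndarray:
        raw = rng.lognormal(self.reads_lognorm_mean, self.reads_lognorm_sigma, n_molecules)
        return np.ceil(raw).astype(np.int64)


@dataclass
class GroundTruthRepertoire:
    """Explicit clone table: one row per clone with its size in cells and its
    alpha/beta chain annotations (v/j calls, junction, pgen, insertions)."""

    clones: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"clone_id", "size"}
        if not required <= set(self.clones.columns):
            raise ValueError("clone table needs clone_id and size columns")

    @property
    def n_cells(self) -> int:
        return int(self.clones["size"].sum())

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    def chain_key(self, locus: str) -> pd.Series:
        pre = locus[0]
        return (
            locus
            + "|"
            + self.clones[f"{pre}_v_call"]
            + "|"
            + self.clones[f"{pre}_j_call"]
            + "|"
            + self.clones[f"{pre}_junction"]
        )


def realize_clone_sizes(
    dist: CloneSizeDistribution, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Integer per-clone sizes from a (possibly fractional) distribution.

    Fractional clone counts are realised by a Bernoulli draw on the
    remainder, so the expected count per size class is exact.
    """
    if dist.sizes.max() >= 2**62:
        raise ValueError("explicit realization needs desk-scale clone sizes")
    sizes = []
    for i, f in zip(dist.sizes.astype(np.int64), dist.counts):
        m = int(np.floor(f))
        if rng is not None and rng.random() < f - m:
            m += 1
        if m > 0:
            sizes.append(np.full(m, i, dtype=np.int64))
    if not sizes:
        raise ValueError("distribution realises zero clones")
    return np.concatenate(sizes)


def sample_chain_pool(
    model: SyntheticVDJModel,
    selection: SelectionModel | None,
    n_chains: int,
    rng: np.random.Generator,
    batch: int = 200_000,
) -> pd.DataFrame:
    """Generate a pool of ``n_chains`` productive, selection-surviving chains.

    Chains are produced by rejection: raw rearrangements are filtered by the
    in-frame/stop-free rule and thinned by the selection model (memoized per
    distinct sequence).  Sampling clones from this pool with replacement
    reproduces chain frequency proportional to P(sigma) and lets identical
    rearrangements collide across clones.
    """
    parts = []
    got = 0
    # expected yield: ~28% productive, times the mean survival under selection
    yield_guess = 0.28 * (selection.overall_factor if selection is not None else 1.0)
    while got < n_chains:
        need = int((n_chains - got) / yield_guess * 1.25) + 2000
        df = generate_batch(model, min(batch, need), rng, productive_only=True)
        if selection is not None:
            seq = df["v_call"] + "|" + df["j_call"] + "|" + df["junction_nt"]
            keep = selection_mask(df["pgen"].to_numpy(), seq.to_numpy(), selection, rng)
            df = df[keep]
        parts.append(df)
        got += len(df)
    pool = pd.concat(parts, ignore_index=True).head(n_chains)
    pool.attrs["locus"] = model.locus
    return pool


def build_repertoire(
    dist: CloneSizeDistribution,
    alpha_model: SyntheticVDJModel,
    beta_model: SyntheticVDJModel,
    rng: np.random.Generator,
    alpha_selection: SelectionModel | None = None,
    beta_selection: SelectionModel | None = None,
    alpha_pool: pd.DataFrame | None = None,
    beta_pool: pd.DataFrame | None = None,
    pool_size: int = 200_000,
) -> GroundTruthRepertoire:
    """Build an explicit repertoire: clone sizes drawn from ``dist``, one
    alpha and one beta chain per clone drawn (with replacement) from
    productive post-selection chain pools."""
    if alpha_selection is not None and alpha_selection.locus != "alpha":
        raise ValueError("alpha selection model trained on the wrong locus")
    if beta_selection is not None and beta_selection.locus != "beta":
        raise ValueError("beta selection model trained on the wrong locus")
    sizes = realize_clone_sizes(dist, rng)
    n = len(sizes)
    if alpha_pool is None:
        alpha_pool = sample_chain_pool(
            alpha_model, alpha_selection, min(pool_size, 10 * n), rng
        )
    if beta_pool is None:
        beta_pool = sample_chain_pool(
            beta_model, beta_selection, min(pool_size, 10 * n), rng
        )
    ai = rng.integers(0, len(alpha_pool), n)
    bi = rng.integers(0, len(beta_pool), n)
    clones = pd.DataFrame({"clone_id": np.arange(n), "size": sizes})
    for pre, pool, idx in (("a", alpha_pool, ai), ("b", beta_pool, bi)):
        sub = pool.iloc[idx].reset_index(drop=True)
        clones[f"{pre}_v_call"] = sub["v_call"]
        clones[f"{pre}_j_call"] = sub["j_call"]
        clones[f"{pre}_junction"] = sub["junction_nt"]
        clones[f"{pre}_pgen"] = sub["pgen"]
        clones[f"{pre}_n_ins_min"] = sub["n_insertions_min"]
    return GroundTruthRepertoire(clones)


def _random_umis(n: int, length: int, rng: np.random.Generator) -> np.ndarray:
    codes = rng.integers(0, 4, size=(n, length), dtype=np.int8)
    return codes


def _decode(codes: np.ndarray) -> list[str]:
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return [bytes(row).decode() for row in lut[codes]]


def simulate_subsamples(
    rep: GroundTruthRepertoire,
    n_cells_per_subsample: int,
    mrna: MRNAModel,
    rng: np.random.Generator,
    locus: str = "alpha",
    n_subsamples: int = 3,
):
    """Split a blood draw into ``n_subsamples`` disjoint portions of cells and
    measure one locus.

    Cells are drawn without replacement from the pool (multivariate
    hypergeometric over clones) and partitioned disjointly, so one cell can
    appear in only one subsample.  Each sampled cell yields a random number
    of captured molecules; each molecule gets a fresh random UMI and a read
    count.  Returns ``(tables, truth)`` where ``tables`` is a list of
    per-subsample UMI tables (clonotype_key, umi, reads) and ``truth`` links
    every molecule to its subsample, clone and cell.
    """
    total = n_subsamples * n_cells_per_subsample
    if total > rep.n_cells:
        raise ValueError("subsamples exceed the pool size")
    clone_sizes = rep.clones["size"].to_numpy()
    remaining = clone_sizes.copy()
    keys = rep.chain_key(locus).to_numpy()

    mol_rows = []
    for sub in range(n_subsamples):
        take = rng.multivariate_hypergeometric(remaining, n_cells_per_subsample)
        remaining = remaining - take
        present = np.nonzero(take)[0]
        cells_clone = np.repeat(present, take[present])
        n_cells = len(cells_clone)
        mols_per_cell = mrna.draw_molecules(n_cells, rng)
        keep = mols_per_cell > 0
        cells_clone = cells_clone[keep]
        mols_per_cell = mols_per_cell[keep]
        n_mol = int(mols_per_cell.sum())
        mol_clone = np.repeat(cells_clone, mols_per_cell)
        mol_cell = np.repeat(np.arange(len(cells_clone)), mols_per_cell)
        umis = _decode(_random_umis(n_mol, mrna.umi_length, rng))
        reads = mrna.draw_reads(n_mol, rng)
        mol_rows.append(
            pd.DataFrame(
                {
                    "subsample": sub,
                    "clone_id": rep.clones["clone_id"].to_numpy()[mol_clone],
                    "cell_id": mol_cell,
                    "clonotype_key": keys[mol_clone],
                    "umi": umis,
                    "reads": reads,
                }
            )
        )
    truth = pd.concat(mol_rows, ignore_index=True)
    tables = []
    for sub in range(n_subsamples):
        t = truth[truth["subsample"] == sub]
        # distinct molecules may collide on the same UMI by chance
        t = (
            t.groupby(["clonotype_key", "umi"], as_index=False)["reads"]
            .sum()
            .sort_values(["clonotype_key", "umi"], ignore_index=True)
        )
        tables.append(t)
    return tables, truth


def corrupt_umis(
    table: pd.DataFrame, umi_error_rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Inject per-read UMI errors: every base of every read's UMI is
    substituted independently with probability ``umi_error_rate`` (uniform
    over the three alternatives), then reads are regrouped by the resulting
    UMI.  Total reads are conserved."""
    if not 0 <= umi_error_rate < 1:
        raise ValueError("umi_error_rate must be in [0, 1)")
    if umi_error_rate == 0 or len(table) == 0:
        return table.copy()
    reads = table["reads"].to_numpy()
    n_reads = int(reads.sum())
    length = len(table["umi"].iloc[0])
    # encode each read's UMI
    lut = {b: i for i, b in enumerate(BASES)}
    codes = np.array(
        [[lut[b] for b in u] for u in table["umi"]], dtype=np.int8
    )
    read_codes = np.repeat(codes, reads, axis=0)
    mutate = rng.random((n_reads, length)) < umi_error_rate
    # uniform over the 3 other bases: add 1..3 mod 4
    shift = rng.integers(1, 4, size=mutate.sum(), dtype=np.int8)
    flat = read_codes[mutate]
    read_codes[mutate] = (flat + shift) % 4
    out = pd.DataFrame(
        {
            "clonotype_key": np.repeat(table["clonotype_key"].to_numpy(), reads),
            "umi": _decode(read_codes),
            "reads": 1,
        }
    )
    return (
        out.groupby(["clonotype_key", "umi"], as_index=False)["reads"]
        .sum()
        .sort_values(["clonotype_key", "umi"], ignore_index=True)
    )
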