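"""Clone-size distributions of the naive T-cell pool.

The mechanistic model is a neutral birth-death-immigration process: a pool of
N cells in which every event removes one uniformly chosen cell, replaces it by
a peripheral division with probability 1 - theta, and otherwise advances a
thymic counter; after c division-free events the thymus releases a brand-new
clone of c cells.  All clones share per-capita birth and death rates, so the
steady-state clone-size distribution has a closed form:

    F_i = N (1 - (1-theta)^i) / (i c)            for 1 <= i <= c
    F_i = c F_c (1-theta)^(i-c) / i              for i > c

with richness R = theta N ln(theta) / (theta - 1) for c = 1 and Simpson
diversity S = 2 theta N / (2 + (c-1) theta).

Phenomenological alternatives (power law, log-normal, two-population mixture)
are provided on the same ``CloneSizeDistribution`` container; all of them are
normalised so that the total cell count sum_i i F_i equals N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import zeta

__all__ = [
    "CloneSizeDistribution",
    "NeutralParams",
    "PowerLawParams",
    "LogNormalParams",
    "MixtureParams",
    "neutral_steady_state",
    "neutral_richness",
    "simpson_diversity",
    "simulate_neutral",
    "powerlaw_distribution",
    "lognormal_distribution",
    "mixture_distribution",
]


@dataclass
class CloneSizeDistribution:
    """Mapping clone size i -> (expected) number of clones F_i.

    ``level`` distinguishes pool-level distributions (F) from sample-level
    ones (F-hat).  ``sizes`` is strictly increasing; entries with F_i = 0 may
    be omitted.
    """

    sizes: np.ndarray
    counts: np.ndarray
    N: float
    level: str = "pool"

    def __post_init__(self) -> None:
        # float sizes: condensed heavy tails use non-integer representative
        # sizes far beyond the int64 range
        self.sizes = np.asarray(self.sizes, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.sizes.shape != self.counts.shape:
            raise ValueError("sizes and counts must align")
        if np.any(self.counts < 0):
            raise ValueError("clone counts must be non-negative")
        if np.any(np.diff(self.sizes) <= 0):
            raise ValueError("sizes must be strictly increasing")

    @property
    def total_cells(self) -> float:
        return float(np.sum(self.sizes * self.counts))

    @property
    def richness(self) -> float:
        return float(np.sum(self.counts))

    @property
    def simpson(self) -> float:
        """Inverse Simpson index 1 / sum_i F_i (i/N)^2."""
        return 1.0 / float(np.sum(self.counts * (self.sizes / self.N) ** 2))

    def f(self, i: int) -> float:
        idx = np.searchsorted(self.sizes, i)
        if idx < len(self.sizes) and self.sizes[idx] == i:
            return float(self.counts[idx])
        return 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"clone_size": self.sizes, "n_clones": self.counts})


@dataclass(frozen=True)
class NeutralParams:
    theta: float  # thymic replacement probability per event
    c: int  # introduction size: cells per newly released clone
    N: float  # pool size in cells

    def __post_init__(self) -> None:
        if not 0 < self.theta <= 1:
            raise ValueError("theta must be in (0, 1]")
        if self.c < 1:
            raise ValueError("c must be a positive integer")
        if self.N <= self.c:
            raise ValueError("N must exceed c")


@dataclass(frozen=True)
class PowerLawParams:
    k: float  # slope; normalisable only for k > 2
    N: float

    def __post_init__(self) -> None:
        if self.k <= 2:
            raise ValueError("power-law slope k must exceed 2")


@dataclass(frozen=True)
class LogNormalParams:
    mu: float  # mean of log10 clone size
    sigma: float  # SD of log10 clone size
    N: float

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.sigma <= 0:
            raise ValueError("mu and sigma must be positive")


@dataclass(frozen=True)
class MixtureParams:
    phi: float  # fraction of cells in large clones
    M: int  # size of each large clone
    N: float

    def __post_init__(self) -> None:
        if not 0 <= self.phi < 1:
            raise ValueError("phi must be in [0, 1)")
        if self.M < 2:
            raise ValueError("large-clone size M must be >= 2")
        if self.phi > 0 and self.phi * self.N / self.M < 1:
            raise ValueError("phi N / M must be >= 1 (at least one large clone)")


# ---------------------------------------------------------------------------
# neutral model closed forms

def _neutral_f(params: NeutralParams, sizes: np.ndarray) -> np.ndarray:
    theta, c, N = params.theta, params.c, params.N
    f = np.empty(len(sizes))
    small = sizes <= c
    f[small] = N * (1.0 - (1.0 - theta) ** sizes[small]) / (sizes[small] * c)
    fc = N * (1.0 - (1.0 - theta) ** c) / (c * c)
    f[~small] = c * fc * (1.0 - theta) ** (sizes[~small] - c) / sizes[~small]
    return f


def _neutral_imax(params: NeutralParams) -> int:
    """Truncation size such that the analytic tail holds less than one cell.

    For i > c the cell mass i F_i is geometric with ratio (1 - theta), so the
    tail beyond i_max is bounded by c F_c (1-theta)^(i_max+1-c) / theta.
    """
    theta, c, N = params.theta, params.c, params.N
    if theta == 1.0:
        return c
    fc = N * (1.0 - (1.0 - theta) ** c) / (c * c)
    # c * fc * (1-theta)^(m+1-c) / theta < 1
    m = c + int(np.ceil(np.log(theta / (c * fc)) / np.log1p(-theta))) + 1
    return max(m, c + 1)


def neutral_steady_state(
    params: NeutralParams, i_max: int | None = None
) -> CloneSizeDistribution:
    """Steady-state clone-size distribution, truncated where the analytic
    tail mass drops below one cell (or at ``i_max`` if given)."""
    if i_max is None:
        i_max = _neutral_imax(params)
    sizes = np.arange(1, i_max + 1)
    return CloneSizeDistribution(sizes, _neutral_f(params, sizes), params.N)


def neutral_richness(params: NeutralParams) -> float:
    """Total number of distinct clones R = sum_i F_i.

    Closed form theta N ln(theta)/(theta - 1) for c = 1; numeric sum of the
    steady state otherwise.
    """
    if params.c == 1:
        if params.theta == 1.0:
            return float(params.N)
        return float(
            params.theta * params.N * np.log(params.theta) / (params.theta - 1.0)
        )
    return neutral_steady_state(params).richness


def simpson_diversity(params: NeutralParams) -> float:
    """Inverse Simpson diversity S = 2 theta N / (2 + (c-1) theta)."""
    return 2.0 * params.theta * params.N / (2.0 + (params.c - 1) * params.theta)


# ---------------------------------------------------------------------------
# explicit event-driven simulation

@njit(cache=True)
def _neutral_events(
    N, theta, c, burn_in, n_events, thin, n_batches, i_cap, seed, init_sizes
):  # pragma: no cover - numba kernel
    np.random.seed(seed)
    total = burn_in + n_events
    # expected thymic releases plus a 6-sigma fluctuation margin
    max_clones = (
        N + np.int64((theta * total + 6.0 * np.sqrt(theta * total + 1.0)) / c) + c + 64
    )
    size_of = np.zeros(max_clones, dtype=np.int64)
    cells = np.zeros(N + c + 2, dtype=np.int64)
    n_cells = 0
    F = np.zeros(i_cap + 1, dtype=np.int64)
    for k in range(len(init_sizes)):
        size_of[k] = init_sizes[k]
        for _ in range(init_sizes[k]):
            cells[n_cells] = k
            n_cells += 1
        if init_sizes[k] <= i_cap:
            F[init_sizes[k]] += 1
    n_clones = len(init_sizes)
    batch_sums = np.zeros((n_batches, i_cap + 1))
    batch_n = np.zeros(n_batches, dtype=np.int64)
    counter = 0
    for ev in range(total):
        # death: remove one uniformly random cell
        idx = np.random.randint(n_cells)
        jc = cells[idx]
        cells[idx] = cells[n_cells - 1]
        n_cells -= 1
        s = size_of[jc]
        size_of[jc] = s - 1
        if s <= i_cap:
            F[s] -= 1
        if 1 <= s - 1 <= i_cap:
            F[s - 1] += 1
        if np.random.random() < 1.0 - theta:
            # peripheral division of another uniformly random cell
            jd = cells[np.random.randint(n_cells)]
            cells[n_cells] = jd
            n_cells += 1
            s2 = size_of[jd]
            size_of[jd] = s2 + 1
            if 1 <= s2 <= i_cap:
                F[s2] -= 1
            if s2 + 1 <= i_cap:
                F[s2 + 1] += 1
        else:
            counter += 1
            if counter == c:
                counter = 0
                size_of[n_clones] = c
                for _ in range(c):
                    cells[n_cells] = n_clones
                    n_cells += 1
                n_clones += 1
                if c <= i_cap:
                    F[c] += 1
        if ev >= burn_in and (ev - burn_in) % thin == 0:
            b = (ev - burn_in) * n_batches // n_events
            batch_sums[b] += F
            batch_n[b] += 1
    return batch_sums, batch_n


@njit(cache=True)
def _neutral_events_ct(
    N, theta, c, burn_in, n_events, thin, n_batches, i_cap, seed, init_sizes
):  # pragma: no cover - numba kernel
    """Continuous-time (uncoupled) scheme: deaths, divisions and thymic
    introductions are independent Poisson processes; per-cell rates refer to
    the nominal pool size N, so each clone evolves independently and the
    stationary clone-size distribution equals the analytic steady state
    exactly.  Snapshots are weighted by the expected holding time."""
    np.random.seed(seed)
    total = burn_in + n_events
    max_clones = (
        N + np.int64((theta * total + 6.0 * np.sqrt(theta * total + 1.0)) / c) + c + 64
    )
    cap_cells = 4 * N + 64
    size_of = np.zeros(max_clones, dtype=np.int64)
    cells = np.zeros(cap_cells, dtype=np.int64)
    n_cells = 0
    F = np.zeros(i_cap + 1, dtype=np.int64)
    for k in range(len(init_sizes)):
        size_of[k] = init_sizes[k]
        for _ in range(init_sizes[k]):
            cells[n_cells] = k
            n_cells += 1
        if init_sizes[k] <= i_cap:
            F[init_sizes[k]] += 1
    n_clones = len(init_sizes)
    batch_sums = np.zeros((n_batches, i_cap + 1))
    batch_w = np.zeros(n_batches)
    for ev in range(total):
        r_death = n_cells / N
        r_div = n_cells * (1.0 - theta) / N
        r_thy = theta / c
        r_tot = r_death + r_div + r_thy
        u = np.random.random() * r_tot
        if u < r_death:
            idx = np.random.randint(n_cells)
            jc = cells[idx]
            cells[idx] = cells[n_cells - 1]
            n_cells -= 1
            s = size_of[jc]
            size_of[jc] = s - 1
            if s <= i_cap:
                F[s] -= 1
            if 1 <= s - 1 <= i_cap:
                F[s - 1] += 1
        elif u < r_death + r_div:
            jd = cells[np.random.randint(n_cells)]
            cells[n_cells] = jd
            n_cells += 1
            s2 = size_of[jd]
            size_of[jd] = s2 + 1
            if 1 <= s2 <= i_cap:
                F[s2] -= 1
            if s2 + 1 <= i_cap:
                F[s2 + 1] += 1
        else:
            size_of[n_clones] = c
            for _ in range(c):
                cells[n_cells] = n_clones
                n_cells += 1
            n_clones += 1
            if c <= i_cap:
                F[c] += 1
        if n_cells + c >= cap_cells or n_clones + 1 >= max_clones:
            # overflow guard; practically unreachable for theta >= 0.05
            break
        if ev >= burn_in and (ev - burn_in) % thin == 0:
            b = (ev - burn_in) * n_batches // n_events
            w = 1.0 / r_tot  # expected holding time in this state
            batch_sums[b] += F * w
            batch_w[b] += w
    return batch_sums, batch_w


def simulate_neutral(
    params: NeutralParams,
    n_events: int,
    burn_in: int,
    rng: np.random.Generator,
    thin: int = 97,
    n_batches: int = 16,
    i_cap: int = 3000,
    scheme: str = "discrete",
    init: str = "singletons",
):
    """Event-driven simulation of the neutral model.

    ``scheme="discrete"`` (default) couples cell exit with division or
    thymic counting within one event, as in the discrete formulation; its
    stationary law deviates from the analytic steady state by O(c/N).
    ``scheme="continuous"`` runs the uncoupled Poisson-process version of
    the dynamics, whose stationary clone-size distribution equals the
    closed forms exactly.

    Returns ``(dist, se)``: the time-averaged clone-size distribution after
    burn-in and the per-size Monte-Carlo standard error of those averages,
    estimated from ``n_batches`` batch means (batches are long relative to
    the relaxation time, which absorbs most autocorrelation).

    Snapshots are taken every ``thin`` events (a prime stride, so it cannot
    resonate with the thymic counter period).  ``i_cap`` bounds the sizes
    tracked; for theta >= 0.05 the stationary mass above it is negligible.
    """
    N = int(params.N)
    if N > 10**6:
        raise ValueError("explicit simulation is meant for small N (<= 1e6)")
    if scheme not in ("discrete", "continuous"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if init == "singletons":
        init_sizes = np.ones(N, dtype=np.int64)
    elif init == "stationary":
        # start from a realisation of the analytic steady state (shortens
        # the burn-in; the run then checks stationarity under the dynamics)
        ss = neutral_steady_state(params, i_max=i_cap)
        init_sizes = []
        total = 0
        for i, f in zip(ss.sizes.astype(np.int64), ss.counts):
            m = int(np.floor(f))
            if rng.random() < f - m:
                m += 1
            if m:
                init_sizes.append(np.full(m, i, dtype=np.int64))
                total += m * i
        pad = max(N - total, 0)
        if pad:
            init_sizes.append(np.ones(pad, dtype=np.int64))
        init_sizes = np.concatenate(init_sizes)
        while init_sizes.sum() > N:  # trim overshoot from the last class
            init_sizes = init_sizes[:-1]
    else:
        raise ValueError(f"unknown init {init!r}")
    kernel = _neutral_events if scheme == "discrete" else _neutral_events_ct
    seed = int(rng.integers(0, 2**31 - 1))
    batch_sums, batch_n = kernel(
        N,
        params.theta,
        params.c,
        int(burn_in),
        int(n_events),
        thin,
        n_batches,
        i_cap,
        seed,
        init_sizes,
    )
    means = batch_sums / batch_n[:, None]
    f_bar = means.mean(axis=0)
    # plain batch-means SE; batches must be long relative to the occupancy
    # autocorrelation time (roughly N c / theta events) for this to be honest
    se = means.std(axis=0, ddof=1) / np.sqrt(n_batches)
    sizes = np.arange(1, i_cap + 1)
    dist = CloneSizeDistribution(sizes, f_bar[1:], params.N)
    return dist, se[1:]


# ---------------------------------------------------------------------------
# phenomenological distributions

def powerlaw_distribution(
    params: PowerLawParams,
    i_max: int | None = None,
    tail_mass: float = 1e-4,
    dense_max: int = 10_000,
) -> CloneSizeDistribution:
    """F_i = N i^-k / zeta(k-1).

    Sizes up to ``dense_max`` are enumerated exactly.  Because the cell-mass
    tail sum_{i>m} i^(1-k) decays as m^(2-k), slopes near 2 need astronomical
    truncation points to conserve cells; beyond ``dense_max`` the support is
    therefore condensed onto geometrically spaced bins whose exact cell mass
    (by Hurwitz-zeta partial sums) is assigned to the bin's mean clone size,
    so sum_i i F_i matches N up to the requested relative ``tail_mass``
    (default 1e-4), which is the documented truncation error.  With
    ``i_max`` set, the support is simply cut there.
    """
    k, N = params.k, params.N
    z = zeta(k - 1)
    if i_max is not None:
        sizes = np.arange(1, i_max + 1)
        counts = N * sizes.astype(float) ** (-k) / z
        return CloneSizeDistribution(sizes, counts, N)
    # exact cell mass above m (in units of N): zeta(k-1, m+1) / zeta(k-1)
    tail_at = lambda m: zeta(k - 1, m + 1) / z
    if tail_at(dense_max) <= tail_mass:
        # dense region suffices; find the smallest adequate cutoff
        lo, hi = 1, dense_max
        while lo < hi:
            mid = (lo + hi) // 2
            if tail_at(mid) <= tail_mass:
                hi = mid
            else:
                lo = mid + 1
        sizes = np.arange(1, lo + 1)
        counts = N * sizes.astype(float) ** (-k) / z
        return CloneSizeDistribution(sizes, counts, N)
    sizes = [np.arange(1, dense_max + 1)]
    counts = [N * sizes[0].astype(float) ** (-k) / z]
    lo = dense_max + 1
    while tail_at(lo - 1) > tail_mass:
        hi = max(int(lo * 1.25), lo + 1)
        cells = N * (zeta(k - 1, lo) - zeta(k - 1, hi + 1)) / z  # sum i F_i, lo..hi
        clones = N * (zeta(k, lo) - zeta(k, hi + 1)) / z  # sum F_i, lo..hi
        if clones <= 0 or cells <= 0:
            break
        rep = int(round(cells / clones))
        rep = min(max(rep, lo), hi)
        sizes.append(np.array([rep]))
        counts.append(np.array([cells / rep]))
        lo = hi + 1
    return CloneSizeDistribution(np.concatenate(sizes), np.concatenate(counts), N)


def lognormal_distribution(
    params: LogNormalParams, n_clones: int, rng: np.random.Generator
) -> CloneSizeDistribution:
    """Clone sizes 10^Normal(mu, sigma), rounded and clipped to >= 1, then
    replicated by an integer factor (plus a remainder draw) so the total cell
    count equals N exactly while preserving the drawn shape."""
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    draws = np.round(10.0 ** rng.normal(params.mu, params.sigma, n_clones))
    draws = np.maximum(draws, 1.0).astype(np.int64)
    total = draws.sum()
    reps = int(params.N // total)
    remainder = params.N - reps * total
    sizes, counts = np.unique(draws, return_counts=True)
    counts = counts.astype(float) * max(reps, 1)
    if reps >= 1 and remainder > 0:
        # top up with singletons to conserve N exactly
        if sizes[0] == 1:
            counts[0] += remainder
        else:
            sizes = np.insert(sizes, 0, 1)
            counts = np.insert(counts, 0, float(remainder))
    elif reps == 0:
        # N smaller than one replicate: rescale counts fractionally
        counts = counts * (params.N / total)
    return CloneSizeDistribution(sizes, counts, params.N)


def mixture_distribution(params: MixtureParams) -> CloneSizeDistribution:
    """Two populations: (1-phi) N singleton cells and phi N cells in clones
    of exactly M cells."""
    if params.phi == 0:
        return CloneSizeDistribution([1], [params.N], params.N)
    f1 = (1.0 - params.phi) * params.N
    fM = params.phi * params.N / params.M
    return CloneSizeDistribution([1, params.M], [f1, fM], params.N)
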