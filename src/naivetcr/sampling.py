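"""Binomial subsampling of clone-size distributions.

A blood sample draws a fraction s of a large, well-mixed pool of N cells, so
the number of sampled cells from a clone of j cells is X_j ~ Binomial(j, s).
The induced sample-level distribution is

    F-hat_i = sum_{j >= i} F_j P(X_j = i)

with closed form F-hat_i = F_i (s / (s + (1-s) theta))^i for the neutral
steady state with introduction size c = 1 -- the per-unit-size attenuation
factor that makes even very large pool clones rare in realistic samples
(s / theta is of order 1e-5).  A clone of i cells is present at all in a
sample of n cells with probability p_i = 1 - (1 - i/N)^n.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .clone_sizes import CloneSizeDistribution, NeutralParams, neutral_steady_state

__all__ = [
    "presence_probability",
    "expected_sample_distribution",
    "neutral_sample_closed_form",
    "attenuation_factor",
    "draw_sample",
    "expected_distinct_clones",
    "calibrate_sample_size",
]


def presence_probability(i, n, N):
    """Probability that a clone of ``i`` cells contributes at least one cell
    to a sample of ``n`` cells from a pool of ``N``: 1 - (1 - i/N)^n."""
    i = np.asarray(i, dtype=float)
    if np.any(i < 1) or np.any(i > N):
        raise ValueError("clone size must satisfy 1 <= i <= N")
    if not 1 <= n <= N:
        raise ValueError("sample size must satisfy 1 <= n <= N")
    return 1.0 - (1.0 - i / N) ** n


def expected_sample_distribution(
    dist: CloneSizeDistribution, s: float, i_max: int | None = None
) -> CloneSizeDistribution:
    """Expected sample-level distribution F-hat under binomial sampling of a
    fraction ``s``: F-hat_i = sum_j F_j Binom(j, s).pmf(i)."""
    if dist.level != "pool":
        raise ValueError("expected a pool-level distribution")
    if not 0 < s <= 1:
        raise ValueError("sampled fraction s must be in (0, 1]")
    if i_max is None:
        i_max = int(dist.sizes.max())
    i = np.arange(1, i_max + 1)
    # pmf matrix over (sample size i, pool size j); vectorised over j
    pmf = stats.binom.pmf(i[:, None], dist.sizes[None, :], s)
    f_hat = pmf @ dist.counts
    return CloneSizeDistribution(i, f_hat, dist.N * s, level="sample")


def attenuation_factor(s: float, theta: float) -> float:
    """Per-unit-clone-size attenuation s / (s + (1-s) theta) of the neutral
    (c = 1) sample distribution relative to the pool distribution."""
    return s / (s + (1.0 - s) * theta)


def neutral_sample_closed_form(
    params: NeutralParams, s: float, i_max: int | None = None
) -> CloneSizeDistribution:
    """Closed-form sample distribution for the c = 1 neutral steady state:
    F-hat_i = F_i (s/(s + (1-s) theta))^i."""
    if params.c != 1:
        raise ValueError("closed form requires introduction size c = 1")
    pool = neutral_steady_state(params, i_max=i_max)
    a = attenuation_factor(s, params.theta)
    f_hat = pool.counts * a ** pool.sizes.astype(float)
    return CloneSizeDistribution(pool.sizes, f_hat, params.N * s, level="sample")


def draw_sample(dist: CloneSizeDistribution, n: int, rng: np.random.Generator):
    """Realise one sample of ``n`` cells from a pool-level distribution.

    Returns ``(clone_sizes, sampled_counts)`` for the clones with at least
    one sampled cell; per-clone counts are Binomial(i, n/N) (pool-scale
    approximation), drawn class-by-class.
    """
    if n > dist.N:
        raise ValueError("cannot sample more cells than the pool holds")
    p = n / dist.N
    out_sizes = []
    out_counts = []
    for i, f in zip(dist.sizes, dist.counts):
        m = int(np.floor(f))
        if rng.random() < f - m:  # unbiased realisation of fractional counts
            m += 1
        if m == 0:
            continue
        # number of clones present, then counts conditional on presence
        q = 1.0 - (1.0 - p) ** i
        k = rng.binomial(m, q)
        if k == 0:
            continue
        x = _truncated_binomial(int(i), p, k, rng)
        out_sizes.append(np.full(k, i, dtype=np.float64))
        out_counts.append(x)
    if not out_sizes:
        return np.empty(0, np.float64), np.empty(0, np.int64)
    return np.concatenate(out_sizes), np.concatenate(out_counts)


def _truncated_binomial(i: int, p: float, k: int, rng: np.random.Generator):
    """k draws from Binomial(i, p) conditioned on >= 1.

    Exact inverse-CDF for moderate i; Poisson/normal limits for very large
    clones, where enumerating the support would be infeasible.
    """
    mean = i * p
    if i > 100_000:
        if mean >= 50.0:
            # zero probability is negligible; normal limit of the binomial
            draws = np.rint(rng.normal(mean, np.sqrt(mean * (1.0 - p)), k))
            return np.maximum(draws, 1).astype(np.int64)
        # Poisson limit, zero-truncated via inverse CDF
        hi = max(8, int(stats.poisson.isf(1e-12, mean)) + 1)
        x = np.arange(1, hi + 1)
        w = stats.poisson.pmf(x, mean)
    else:
        hi = min(i, max(8, int(stats.binom.isf(1e-12, i, p)) + 1))
        x = np.arange(1, hi + 1)
        w = stats.binom.pmf(x, i, p)
    total = w.sum()
    if total <= 0:
        return np.ones(k, dtype=np.int64)
    return rng.choice(x, size=k, p=w / total)


# ---------------------------------------------------------------------------
# diversity-matched sample-size calibration

def expected_distinct_clones(dist: CloneSizeDistribution, n: int) -> float:
    """Expected number of distinct clones present in a sample of n cells."""
    p = presence_probability(dist.sizes, n, dist.N)
    return float(np.sum(dist.counts * p))


def expected_distinct_chains(
    dist: CloneSizeDistribution, n: int, chain_weights: np.ndarray
) -> float:
    """Expected number of distinct chain sequences among the sampled clones,
    after collapsing identical-recombination collisions.

    ``chain_weights`` are the relative frequencies of the distinct sequences
    in the (post-selection) chain pool clones draw from; with m sampled
    clones drawing independently, a sequence with weight q is seen with
    probability 1 - (1 - q)^m.
    """
    m = expected_distinct_clones(dist, n)
    q = np.asarray(chain_weights, dtype=float)
    q = q / q.sum()
    return float(np.sum(-np.expm1(m * np.log1p(-np.minimum(q, 1 - 1e-15)))))


def calibrate_sample_size(
    dist: CloneSizeDistribution,
    observed_distinct_chains: float,
    lower: int,
    upper: int,
    chain_weights: np.ndarray | None = None,
    rtol: float = 0.005,
    max_iter: int = 60,
) -> int:
    """Find the sample size n in [lower, upper] whose expected number of
    distinct chains matches the observation within ``rtol`` (0.5%).

    ``lower`` is naturally the observed distinct-chain count itself (one
    functional chain per cell) and ``upper`` the sorted cell count.  The
    expectation is strictly increasing in n, so integer bisection finds the
    unique root.  Without ``chain_weights`` each clone is assumed to carry a
    unique chain (no collisions) and the expectation reduces to the expected
    number of distinct sampled clones.
    """
    if lower > upper:
        raise ValueError("lower bound exceeds upper bound")

    def expected(n: int) -> float:
        if chain_weights is None:
            return expected_distinct_clones(dist, n)
        return expected_distinct_chains(dist, n, chain_weights)

    lo_val, hi_val = expected(lower), expected(upper)
    target = float(observed_distinct_chains)
    if not lo_val <= target <= hi_val:
        raise ValueError(
            f"target {target:.6g} outside attainable range "
            f"[{lo_val:.6g}, {hi_val:.6g}] for n in [{lower}, {upper}]"
        )
    lo, hi = lower, upper
    for _ in range(max_iter):
        mid = (lo + hi) // 2
        val = expected(mid)
        if abs(val - target) <= rtol * target:
            return mid
        if val < target:
            lo = mid + 1
        else:
            hi = mid - 1
        if lo > hi:
            break
    return (lo + hi + 1) // 2
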