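"""In-silico subsample incidence prediction and model-data fitting."""

import numpy as np
import pandas as pd
import pytest

from naivetcr.clone_sizes import CloneSizeDistribution
from naivetcr.prediction import (
    ChainPool,
    IncidenceSummary,
    best_sweep_point,
    goodness_of_fit,
    parameter_sweep,
    predict_single_sample,
    predict_subsamples,
    qualitative_pgen_check,
    sample_clone_counts,
    scale_distribution,
)
from naivetcr.synthetic import MRNAModel


def distinct_pool(n, locus="alpha"):
    """Collision-free pool: every entry a distinct sequence."""
    df = pd.DataFrame(
        {
            "v_call": "V1",
            "j_call": "J1",
            "junction_nt": [f"{i:012d}".replace("0", "A").replace("1", "C") + format(i, "012b").replace("0", "G").replace("1", "T") for i in range(n)],
            "pgen": np.full(n, 1e-8),
            "n_insertions_min": 1,
        }
    )
    return ChainPool(df, locus)


def single_sequence_pool(n, locus="alpha"):
    df = pd.DataFrame(
        {
            "v_call": "V1",
            "j_call": "J1",
            "junction_nt": "TGTGCAGCATTC",
            "pgen": np.full(n, 1e-4),
            "n_insertions_min": 0,
        }
    )
    return ChainPool(df, locus)


class TestSampleCloneCounts:
    def test_disjoint_subsample_totals(self):
        dist = CloneSizeDistribution([1, 10], [5000.0, 100.0], 6000)
        sizes, counts = sample_clone_counts(dist, 500, 3, np.random.default_rng(0))
        assert counts.min() >= 0
        assert (counts.sum(axis=1) >= 1).all()

    def test_oversampling_rejected(self):
        dist = CloneSizeDistribution([1], [100.0], 100)
        with pytest.raises(ValueError):
            sample_clone_counts(dist, 50, 3, np.random.default_rng(0))


class TestPredictSubsamples:
    def test_all_singletons_collision_free_never_multi_incidence(self):
        """Disjoint-partition guarantee: a singleton clone lands in exactly
        one subsample, so with chains unique per clone no sequence can reach
        incidence above 1."""
        dist = CloneSizeDistribution([1], [50_000.0], 50_000)
        rng = np.random.default_rng(1)
        for _ in range(5):
            _, counts = sample_clone_counts(dist, 500, 3, rng)
            assert ((counts > 0).sum(axis=1) == 1).all()
            # collision-free chains: one distinct sequence per sampled clone
            incidence = (counts > 0).sum(axis=1)
            assert (incidence == 1).all()

    def test_dominant_clone_reaches_every_subsample(self):
        N = 10**6
        dist = CloneSizeDistribution([1, N // 10], [9 * N // 10, 1.0], N)
        pool = distinct_pool(10_000)
        summ = predict_subsamples(dist, pool, 1000, np.random.default_rng(2), repeats=5)
        assert summ.counts[3] >= 1.0  # the big clone, every repeat

    def test_single_sequence_pool_collapses_everything(self):
        dist = CloneSizeDistribution([1], [10_000.0], 10_000)
        pool = single_sequence_pool(100)
        summ = predict_subsamples(dist, pool, 1000, np.random.default_rng(3), repeats=2)
        assert summ.counts[3] == 1.0
        assert summ.counts[1] == summ.counts[2] == 0.0

    def test_subsample_relabeling_invariance(self):
        """Incidence counts do not depend on subsample labels."""
        dist = CloneSizeDistribution([1, 50], [20_000.0, 100.0], 25_000)
        pool = distinct_pool(20_000)
        rng = np.random.default_rng(4)
        _, counts = sample_clone_counts(dist, 800, 3, rng)
        inc_a = np.sort((counts > 0).sum(axis=1))
        inc_b = np.sort((counts[:, ::-1] > 0).sum(axis=1))
        assert (inc_a == inc_b).all()


class TestGoodnessOfFit:
    def summary(self, locus, c1, c2, c3):
        return IncidenceSummary(locus, {1: c1, 2: c2, 3: c3}, {}, {})

    def test_identity_is_zero(self):
        s = {"alpha": self.summary("alpha", 100, 10, 1)}
        assert goodness_of_fit(s, s) == 0.0

    def test_doubling_increases_distance(self):
        obs = {"alpha": self.summary("alpha", 100, 10, 1)}
        near = {"alpha": self.summary("alpha", 100, 12, 1)}
        far = {"alpha": self.summary("alpha", 100, 24, 1)}
        assert 0 < goodness_of_fit(near, obs) < goodness_of_fit(far, obs)

    def test_symmetry(self):
        a = {"alpha": self.summary("alpha", 50, 20, 5)}
        b = {"alpha": self.summary("alpha", 80, 10, 2)}
        assert goodness_of_fit(a, b) == pytest.approx(goodness_of_fit(b, a))

    def test_incidence_one_excluded_by_default(self):
        a = {"alpha": self.summary("alpha", 10, 5, 2)}
        b = {"alpha": self.summary("alpha", 99999, 5, 2)}
        assert goodness_of_fit(a, b) == 0.0


class TestQualitativeCheck:
    def make(self, locus, m1, m2, m3):
        return IncidenceSummary(locus, {1: 1, 2: 1, 3: 1}, {1: m1, 2: m2, 3: m3}, {})

    def test_expected_pattern_true(self):
        a = self.make("alpha", -7, -6, -5)
        b = self.make("beta", -11, -10, -10.5)
        assert qualitative_pgen_check(a, b) is True

    def test_flat_alpha_false(self):
        a = self.make("alpha", -6, -6, -6)
        b = self.make("beta", -11, -10, -10.5)
        assert qualitative_pgen_check(a, b) is False

    def test_empty_class_indeterminate(self):
        a = self.make("alpha", -7, -6, np.nan)
        b = self.make("beta", -11, -10, -10.5)
        assert qualitative_pgen_check(a, b) is None


class TestSweep:
    def test_recovers_generating_point_of_synthetic_observation(self):
        rng = np.random.default_rng(5)
        pool = distinct_pool(50_000)
        pools = {"alpha": pool, "beta": distinct_pool(50_000, "beta")}
        N = 500_000

        def builder(phi):
            f1 = (1 - phi) * N
            return CloneSizeDistribution([1, 200], [f1, phi * N / 200], N)

        truth = builder(phi=0.04)
        obs = {
            locus: predict_subsamples(truth, pools[locus], 3000, rng, repeats=5)
            for locus in pools
        }
        grid = [{"phi": p} for p in (0.01, 0.02, 0.04, 0.08, 0.16)]
        results = parameter_sweep(builder, grid, obs, pools, 3000, rng, repeats=4)
        best = min(results, key=lambda r: r.distance)
        assert best.params["phi"] in (0.02, 0.04, 0.08)

    def test_identical_grid_points_have_similar_distance(self):
        rng = np.random.default_rng(6)
        pools = {"alpha": distinct_pool(20_000), "beta": distinct_pool(20_000, "beta")}
        dist = CloneSizeDistribution([1], [100_000.0], 100_000)
        obs = {
            locus: predict_subsamples(dist, pools[locus], 500, rng, repeats=3)
            for locus in pools
        }
        results = parameter_sweep(
            lambda: dist, [{}, {}], obs, pools, 500, rng, repeats=3
        )
        assert abs(results[0].distance - results[1].distance) < 0.5

    def test_best_point_prefers_correct_ordering(self):
        from naivetcr.prediction import SweepResult

        rs = [
            SweepResult({"k": 1}, 0.1, False),
            SweepResult({"k": 2}, 0.5, True),
        ]
        assert best_sweep_point(rs).params["k"] == 2


class TestSingleSample:
    def test_one_molecule_per_cell_matches_sampled_cells(self):
        dist = CloneSizeDistribution([1], [50_000.0], 50_000)
        pool = distinct_pool(40_000)
        mrna = MRNAModel(mean_molecules=1, capture_efficiency=1.0, family="fixed")
        ab = predict_single_sample(dist, pool, mrna, 500, np.random.default_rng(7))
        assert ab.sum() == pytest.approx(500, abs=1)

    def test_multiplicity_is_sole_source_of_abundance_for_singletons(self):
        dist = CloneSizeDistribution([1], [200_000.0], 200_000)
        pool = distinct_pool(60_000)
        mrna = MRNAModel(mean_molecules=100, capture_efficiency=0.03, zero_truncated=True)
        ab = predict_single_sample(dist, pool, mrna, 400, np.random.default_rng(8))
        assert (ab > 1).any()
        assert ab.mean() == pytest.approx(
            mrna.mean_captured / (1 - np.exp(-mrna.mean_captured)), rel=0.2
        )


def test_scale_distribution_preserves_shape():
    dist = CloneSizeDistribution([1, 100], [9e9, 1e7], 1e10)
    small = scale_distribution(dist, 1e6)
    assert small.N == 1e6
    assert small.total_cells == pytest.approx(1e6)
    assert (small.sizes == dist.sizes).all()
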