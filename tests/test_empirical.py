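"""Data-side summaries: incidence, permutation test, cleaning, binning,
invariant-chain flags, sharing."""

import numpy as np
import pandas as pd
import pytest

from naivetcr.empirical import (
    contamination_slope,
    incidence_summary,
    incidence_table,
    invariant_chain_flags,
    median_pgen_by_log2bin,
    permutation_test,
    remove_memory_overlap,
    sharing_fraction,
    umi_count_matrix,
    zero_insertion_fraction,
)


def table(junctions, counts, pgen=None, ins=None, locus="alpha"):
    df = pd.DataFrame(
        {
            "locus": locus,
            "v_call": "TRAV1",
            "j_call": "TRAJ1",
            "junction": junctions,
            "duplicate_count": counts,
        }
    )
    if pgen is not None:
        df["pgen"] = pgen
    if ins is not None:
        df["n_insertions_min"] = ins
    return df


class TestIncidence:
    def test_key_in_two_of_three_subsamples(self):
        t1 = table(["AAA", "CCC"], [1, 2])
        t2 = table(["GGG"], [1])
        t3 = table(["AAA"], [4])
        inc = incidence_table([t1, t2, t3])
        lookup = dict(zip(inc["junction"], inc["incidence"]))
        assert lookup == {"AAA": 2, "CCC": 1, "GGG": 1}
        assert inc.loc[inc["junction"] == "AAA", "total_count"].iloc[0] == 5

    def test_disjoint_tables_all_incidence_one(self):
        ts = [table([f"AA{b}"], [1]) for b in "ACG"]
        summ = incidence_summary(ts)
        assert summ.counts == {1: 3.0, 2: 0.0, 3: 0.0}

    def test_duplicated_keys_rejected(self):
        bad = pd.concat([table(["AAA"], [1]), table(["AAA"], [2])])
        with pytest.raises(ValueError, match="duplicated"):
            incidence_table([bad, table(["CCC"], [1])])

    def test_incidence_of_simulated_large_clone_matches_truth(
        self, alpha_model, beta_model
    ):
        from naivetcr.clone_sizes import CloneSizeDistribution
        from naivetcr.synthetic import MRNAModel, build_repertoire, simulate_subsamples

        rng = np.random.default_rng(0)
        dist = CloneSizeDistribution([1, 3000], [3000.0, 1.0], 6000)
        rep = build_repertoire(dist, alpha_model, beta_model, rng, pool_size=4000)
        mrna = MRNAModel(mean_molecules=2, capture_efficiency=1.0, zero_truncated=True)
        _, truth = simulate_subsamples(rep, 600, mrna, rng)
        big_id = rep.clones.loc[rep.clones["size"] == 3000, "clone_id"].iloc[0]
        assert truth[truth["clone_id"] == big_id]["subsample"].nunique() == 3


class TestPermutation:
    def test_all_single_umi_sequences_unchanged(self):
        mat = pd.DataFrame({0: [1, 0, 0], 1: [0, 1, 0], 2: [0, 0, 1]})
        res = permutation_test(mat, reps=5, rng=np.random.default_rng(0))
        assert res.observed_counts == {1: 3.0, 2: 0.0, 3: 0.0}
        assert res.permuted_mean[1] == 3.0

    def test_three_umis_from_one_cell_enumeration(self):
        """A sequence with 3 UMIs in one subsample: permutation spreads it
        over portions; the exact multi-incidence probability over the 27
        equally likely assignments is 24/27."""
        mat = pd.DataFrame({0: [3], 1: [0], 2: [0]})
        rng = np.random.default_rng(1)
        multi = []
        for _ in range(60):
            r = permutation_test(mat, reps=1, rng=rng)
            multi.append(r.permuted_mean[2] + r.permuted_mean[3])
        p = np.mean(multi)
        se = np.std(multi, ddof=1) / np.sqrt(len(multi))
        assert p == pytest.approx(24 / 27, abs=3 * se + 0.01)

    def test_umi_totals_conserved_per_sequence(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.integers(0, 6, size=(50, 3)))
        totals = mat.sum(axis=1).to_numpy()
        perm = rng.multinomial(totals, [1 / 3] * 3)
        assert (perm.sum(axis=1) == totals).all()

    def test_ground_truth_inflation_recovery(self, alpha_model, beta_model):
        """Cells contributing ~3 molecules inflate permuted multi-incidence;
        the estimator recovers the truth within 10 percentage points."""
        from naivetcr.clone_sizes import CloneSizeDistribution
        from naivetcr.synthetic import MRNAModel, build_repertoire, simulate_subsamples

        rng = np.random.default_rng(3)
        dist = CloneSizeDistribution([1], [30_000.0], 30_000)
        rep = build_repertoire(dist, alpha_model, beta_model, rng, pool_size=30_000)
        mrna = MRNAModel(mean_molecules=3, capture_efficiency=1.0, zero_truncated=True)
        tables, truth = simulate_subsamples(rep, 1500, mrna, rng)
        mat = umi_count_matrix(tables)
        res = permutation_test(mat, reps=10, rng=rng)
        # ground truth: scatter each molecule independently and re-score
        keys = truth["clonotype_key"]
        true_multi = []
        for _ in range(10):
            scattered = pd.crosstab(keys, rng.integers(0, 3, len(truth)))
            inc = (scattered > 0).sum(axis=1)
            true_multi.append((inc >= 2).sum())
        obs_multi = sum(res.observed_counts[c] for c in (2, 3))
        truth_inflation = (np.mean(true_multi) - obs_multi) / np.mean(true_multi)
        assert res.inflation == pytest.approx(truth_inflation, abs=0.10)
        assert res.permuted_mean[2] + res.permuted_mean[3] > obs_multi


class TestCleaningAndBinning:
    def test_remove_memory_overlap(self):
        naive = table(["AAA", "CCC", "GGG"], [1, 2, 3])
        memory = table(["CCC", "TTT"], [9, 9])
        out = remove_memory_overlap(naive, memory)
        assert set(out["junction"]) == {"AAA", "GGG"}
        assert len(remove_memory_overlap(naive, naive)) == 0

    def test_contamination_slope_exact_proportionality(self):
        shared = pd.DataFrame(
            {"memory_count": [200, 500, 1000, 4000], "naive_count": [2.0, 5.0, 10.0, 40.0]}
        )
        assert contamination_slope(shared) == pytest.approx(0.01)

    def test_contamination_slope_zero_when_naive_empty(self):
        shared = pd.DataFrame(
            {"memory_count": [200, 500, 1000], "naive_count": [0.0, 0.0, 0.0]}
        )
        assert contamination_slope(shared) == 0.0

    def test_contamination_slope_needs_points_above_threshold(self):
        shared = pd.DataFrame({"memory_count": [5, 50], "naive_count": [1, 2]})
        with pytest.raises(ValueError):
            contamination_slope(shared)

    def test_log2_binning_hand_example(self):
        t = table(
            ["A" * 3, "C" * 3, "G" * 3, "T" * 3, "ACT"],
            [1, 2, 3, 4, 8],
            pgen=[1e-5, 1e-6, 1e-7, 1e-8, 1e-9],
        )
        bins, slope = median_pgen_by_log2bin(t)
        by_bin = {int(b): n for b, n in zip(bins["bin"], bins["n_sequences"])}
        assert by_bin == {0: 1, 1: 1, 2: 2, 3: 1}  # {1},{2},(2,4],(4,8]
        assert np.isfinite(slope)

    def test_single_bin_median(self):
        t = table(["AAA", "CCC"], [1, 1], pgen=[1e-4, 1e-8])
        bins, slope = median_pgen_by_log2bin(t)
        assert len(bins) == 1
        assert bins["median_log10_pgen"].iloc[0] == pytest.approx(-6.0)
        assert np.isnan(slope)

    def test_zero_insertion_fractions(self):
        inc = pd.DataFrame(
            {"incidence": [1, 1, 2, 2, 3], "n_insertions_min": [0, 2, 0, 0, 1]}
        )
        out = zero_insertion_fraction(inc)
        assert out == {1: 0.5, 2: 1.0, 3: 0.0}
        with pytest.raises(ValueError):
            zero_insertion_fraction(inc.assign(n_insertions_min=[0, None, 1, 1, 1]))


class TestInvariantFlags:
    @pytest.mark.parametrize(
        "locus,v,j,nkt,mait",
        [
            ("alpha", "TRAV24", "TRAJ18", True, False),
            ("alpha", "TRAV1-2", "TRAJ33", False, True),
            ("alpha", "TRAV1-2", "TRAJ12", False, True),
            ("alpha", "TRAV1-2", "TRAJ20", False, True),
            ("alpha", "TRAV1-2", "TRAJ18", False, False),
            ("beta", "TRBV11", None, True, False),
            ("beta", "TRBV11-2", None, True, False),
            ("beta", "TRBV20", None, False, True),
            ("beta", "TRBV6-1", None, False, True),
            ("beta", "TRBV9", None, False, False),
        ],
    )
    def test_gene_usage_rules(self, locus, v, j, nkt, mait):
        assert invariant_chain_flags(locus, v, j) == (nkt, mait)


class TestSharing:
    def test_query_subset_of_cohort_fraction_one(self):
        cohort = table(["AAA", "CCC", "GGG"], [1, 1, 1])
        key = "alpha|TRAV1|TRAJ1|"
        qsets = {2: {key + "AAA", key + "CCC"}, 3: set()}
        out = sharing_fraction(qsets, [cohort], np.random.default_rng(0))
        assert out["sharing_fraction"].iloc[0] == 1.0

    def test_disjoint_sharing_zero(self):
        cohort = table(["TTT"], [1])
        qsets = {2: {"alpha|TRAV1|TRAJ1|AAA"}}
        out = sharing_fraction(qsets, [cohort], np.random.default_rng(0))
        assert out["sharing_fraction"].iloc[0] == 0.0

    def test_downsampled_class_one_mean_matches_full_fraction(self):
        rng = np.random.default_rng(1)
        juncs = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(400)]
        juncs = list(dict.fromkeys(juncs))
        cohort = table(juncs[: len(juncs) // 2], [1] * (len(juncs) // 2))
        key = "alpha|TRAV1|TRAJ1|"
        class1 = {key + j for j in juncs}
        class2 = {key + j for j in juncs[:20]}
        out = sharing_fraction({1: class1, 2: class2}, [cohort], rng, downsample_reps=40)
        full_frac = np.mean([k.split("|")[-1] in set(cohort["junction"]) for k in class1])
        got = out[out["incidence"] == 1]["sharing_fraction"].iloc[0]
        assert got == pytest.approx(full_frac, abs=0.12)
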