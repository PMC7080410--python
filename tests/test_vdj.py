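"""Generative recombination model: exact pgen, minimal insertions,
productivity."""

import numpy as np
import pytest
from scipy import stats

from naivetcr.vdj import (
    Segment,
    SyntheticVDJModel,
    default_model,
    generate_batch,
    generate_rearrangement,
    is_productive,
    min_insertions,
    pgen,
)


def brute_force_pgen(model, v_call, j_call, junction):
    """Independent oracle: enumerate every generative scenario (V, J,
    deletions, insertion length, inserted string) and accumulate the
    probability of those that produce the junction."""
    total = 0.0
    v = model.v(v_call)
    j = model.j(j_call)
    bases = "ACGT"
    for dv, p_dv in enumerate(model.deletion_probs):
        for dj, p_dj in enumerate(model.deletion_probs):
            for L, p_L in enumerate(model.insertion_probs):
                prefix = v.seq[: len(v.seq) - dv]
                suffix = j.seq[dj:]
                if len(prefix) + len(suffix) + L != len(junction):
                    continue
                mid = junction[len(prefix) : len(prefix) + L]
                if prefix + mid + suffix != junction:
                    continue
                p_mid = 1.0
                for b in mid:
                    p_mid *= model.base_probs[bases.index(b)]
                total += p_dv * p_dj * p_L * p_mid
    return v.prob * j.prob * total


def enumerate_all_sequences(model):
    """All reachable (v, j, junction) with their brute-force pgen."""
    bases = "ACGT"
    out = {}
    for v in model.v_segments:
        for j in model.j_segments:
            for dv in range(len(model.deletion_probs)):
                for dj in range(len(model.deletion_probs)):
                    for L in range(len(model.insertion_probs)):
                        def mids(length):
                            if length == 0:
                                yield ""
                                return
                            for head in mids(length - 1):
                                for b in bases:
                                    yield head + b

                        for mid in mids(L):
                            junction = (
                                v.seq[: len(v.seq) - dv] + mid + j.seq[dj:]
                            )
                            key = (v.label, j.label, junction)
                            if key not in out:
                                out[key] = brute_force_pgen(model, *key)
    return out


class TestPgen:
    def test_degenerate_single_scenario_model(self):
        m = SyntheticVDJModel(
            "alpha",
            [Segment("V1", "TGTGCA", 1.0)],
            [Segment("J1", "GCATTC", 1.0)],
            deletion_probs=[1.0],
            insertion_probs=[1.0],
        )
        assert pgen(m, "V1", "J1", "TGTGCAGCATTC") == pytest.approx(1.0)
        assert min_insertions(m, "V1", "J1", "TGTGCAGCATTC") == 0

    def test_inconsistent_junction_returns_zero(self, tiny_model):
        assert pgen(tiny_model, "V1", "J1", "AAAAAAAAAAAAAAAA") == 0.0
        with pytest.raises(ValueError):
            min_insertions(tiny_model, "V1", "J1", "AAAAAAAAAAAAAAAA")

    def test_matches_brute_force_scenario_enumeration(self, tiny_model):
        rng = np.random.default_rng(1)
        for _ in range(50):
            rec = generate_rearrangement(tiny_model, rng)
            expected = brute_force_pgen(
                tiny_model, rec.v_call, rec.j_call, rec.junction_nt
            )
            assert rec.pgen == pytest.approx(expected, rel=1e-12)

    def test_total_probability_sums_to_one(self, tiny_model):
        table = enumerate_all_sequences(tiny_model)
        assert sum(table.values()) == pytest.approx(1.0, abs=1e-9)

    def test_generated_sequences_have_positive_pgen(self, alpha_model):
        rng = np.random.default_rng(2)
        for _ in range(20):
            rec = generate_rearrangement(alpha_model, rng)
            assert rec.pgen > 0
            assert rec.n_insertions_min <= rec.n_insertions_true

    def test_empirical_frequency_matches_pgen(self, tiny_model):
        """Monte-Carlo draws hit each distinct sequence at its exact pgen
        (chi-square consistency over the full enumerated space)."""
        table = enumerate_all_sequences(tiny_model)
        keys = sorted(table)
        probs = np.array([table[k] for k in keys])
        rng = np.random.default_rng(3)
        df = generate_batch(tiny_model, 100_000, rng, annotate=False)
        seen = (df.v_call + "|" + df.j_call + "|" + df.junction_nt).value_counts()
        counts = np.array(
            [seen.get("|".join(k), 0) for k in keys], dtype=float
        )
        # merge tiny-probability cells for a valid chi-square
        big = probs * 100_000 >= 5
        obs, exp = counts[big], probs[big] * 100_000
        if (~big).any():
            obs = np.append(obs, counts[~big].sum())
            exp = np.append(exp, probs[~big].sum() * 100_000)
        chi = stats.chisquare(obs, exp)
        assert chi.pvalue > 1e-4


class TestMinInsertions:
    def test_zero_when_junction_explained_without_insertions(self, tiny_model):
        assert min_insertions(tiny_model, "V1", "J1", "TGTGCGGTTC") == 0

    def test_scenario_enumeration_oracle(self, tiny_model):
        rng = np.random.default_rng(4)
        for _ in range(50):
            rec = generate_rearrangement(tiny_model, rng)
            best = None
            for dv in range(len(tiny_model.deletion_probs)):
                for dj in range(len(tiny_model.deletion_probs)):
                    v = tiny_model.v(rec.v_call).seq
                    j = tiny_model.j(rec.j_call).seq
                    prefix, suffix = v[: len(v) - dv], j[dj:]
                    mid_len = len(rec.junction_nt) - len(prefix) - len(suffix)
                    if (
                        0 <= mid_len <= tiny_model.max_insertions
                        and rec.junction_nt.startswith(prefix)
                        and rec.junction_nt.endswith(suffix)
                    ):
                        if best is None or mid_len < best:
                            best = mid_len
            assert rec.n_insertions_min == best


class TestProductivity:
    @pytest.mark.parametrize(
        "junction,expected",
        [
            ("TGTGCTTTT", True),  # 9 nt, stop-free
            ("TGTTAATTT", False),  # in-frame TAA
            ("TGTGCTT", False),  # 7 nt, out of frame
            ("TGA", False),
            ("TTTGAT", True),  # TGA straddles codons, not in frame
        ],
    )
    def test_frame_and_stop_rule(self, junction, expected):
        assert is_productive(junction) is expected

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            is_productive("TGTNNA")
        with pytest.raises(ValueError):
            is_productive("")


class TestDefaults:
    def test_alpha_pgen_orders_of_magnitude_above_beta(
        self, alpha_model, beta_model
    ):
        rng = np.random.default_rng(5)
        da = generate_batch(alpha_model, 4000, rng, productive_only=True)
        db = generate_batch(beta_model, 4000, rng, productive_only=True)
        gap = np.median(np.log10(da.pgen)) - np.median(np.log10(db.pgen))
        assert gap >= 3.0

    def test_yaml_round_trip(self, alpha_model, tmp_path):
        path = tmp_path / "m.yaml"
        alpha_model.to_yaml(path)
        back = SyntheticVDJModel.from_yaml(path)
        assert back.to_dict() == alpha_model.to_dict()
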