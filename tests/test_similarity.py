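"""Alignment engine and fragmented translated similarity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dna
from oracles import dp_best_ungapped_score_both_strands
from phagekit.records import GenomeRecord
from phagekit.similarity import (
    NT_K,
    NT_LAMBDA,
    DistanceMatrix,
    SimilarityMatrix,
    fragmented_similarity,
    local_hsps,
    to_distance,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _mutate(seq: str, rate: float, seed: int) -> str:
    """Nested mutant: the same uniform draws decide hits at every rate."""
    rng = np.random.default_rng(seed)
    u = rng.random(len(seq))
    repl = rng.integers(1, 4, len(seq))
    out = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    idx = np.searchsorted(alphabet, out)
    hit = u < rate
    out[hit] = alphabet[(idx[hit] + repl[hit]) % 4]
    return out.tobytes().decode()


class TestLocalHsps:
    def test_identical_sequences_give_full_length_hsp(self):
        seq = random_dna(1000, seed=1)
        top = local_hsps(seq, seq)[0]
        assert (top.query_start, top.query_end) == (1, 1000)
        assert top.raw_score == 1000
        assert top.e_value < 1e-50

    def test_reverse_complement_hits_on_minus_strand_with_equal_score(self):
        seq = random_dna(800, seed=2)
        rc = seq.translate(_COMPLEMENT)[::-1]
        plus = local_hsps(seq, seq)[0]
        minus = local_hsps(rc, seq)[0]
        assert minus.strand == "-"
        assert minus.raw_score == plus.raw_score

    def test_unrelated_sequences_have_no_significant_hsp(self):
        a, b = random_dna(10000, seed=3), random_dna(10000, seed=4)
        assert local_hsps(a, b, e_ceiling=1e-5) == []
        # oracle: the best ungapped score anywhere falls below the threshold
        smin = np.log(NT_K * 1e4 * 1e4 / 1e-5) / NT_LAMBDA
        assert dp_best_ungapped_score_both_strands(a, b) < smin

    def test_p_value_equals_one_minus_exp_minus_e(self):
        a = random_dna(1500, seed=5)
        b = _mutate(a, 0.2, seed=6)
        hits = local_hsps(a, b, e_ceiling=10.0)
        assert hits
        for h in hits:
            assert h.p_value == pytest.approx(-np.expm1(-h.e_value), rel=1e-9)
            assert h.p_value <= h.e_value + 1e-15

    @pytest.mark.parametrize("rate", [0.0, 0.05, 0.10, 0.15])
    @pytest.mark.parametrize("length", [500, 2000])
    def test_top_score_matches_full_dp_oracle(self, rate, length):
        a = random_dna(length, seed=int(1000 * rate) + length)
        b = _mutate(a, rate, seed=int(1000 * rate) + length + 1)
        top = local_hsps(a, b, e_ceiling=10.0)[0]
        assert top.raw_score == dp_best_ungapped_score_both_strands(a, b)

    def test_translated_mode_finds_protein_level_similarity(self):
        a = random_dna(600, seed=7)
        hits = local_hsps(a, a, mode="translated", e_ceiling=1e-5)
        assert hits
        assert hits[0].query_frame == hits[0].target_frame

    def test_rejects_mostly_ambiguous_sequence(self):
        with pytest.raises(ValueError, match="ambiguity"):
            local_hsps("N" * 80 + "ACGT" * 5, random_dna(100, seed=8))

    def test_rejects_empty_sequence(self):
        with pytest.raises(ValueError, match="non-empty"):
            local_hsps("", "ACGT")


class TestFragmentedSimilarity:
    def test_self_similarity_is_100(self):
        genomes = [
            GenomeRecord(id="a", sequence=random_dna(2000, seed=1)),
            GenomeRecord(id="b", sequence=random_dna(2000, seed=2)),
        ]
        sim = fragmented_similarity(genomes)
        assert sim.loc("a", "a") == 100.0
        assert sim.loc("b", "b") == 100.0

    def test_subsequence_asymmetry(self):
        a = random_dna(2000, seed=3)
        b = a + random_dna(2000, seed=4)
        sim = fragmented_similarity(
            [GenomeRecord(id="A", sequence=a), GenomeRecord(id="B", sequence=b)]
        )
        assert sim.loc("A", "B") == pytest.approx(100.0, abs=3.0)
        assert sim.loc("B", "A") == pytest.approx(50.0, abs=6.0)

    def test_in_group_similarity_exceeds_between_group(self, community):
        picks = [g for g in community.genomes if g.id in
                 {"GA_1", "GA_2", "GB_1", "GB_2", "outgroup"}]
        sim = fragmented_similarity(picks)
        within = [sim.loc("GA_1", "GA_2"), sim.loc("GB_1", "GB_2")]
        between = [sim.loc("GA_1", "GB_1"), sim.loc("GA_1", "outgroup")]
        assert np.mean(within) > np.mean(between)
        assert min(within) > max(between)

    def test_similarity_non_increasing_in_substitution_rate(self):
        base = random_dna(1500, seed=9)
        rates = [0.0, 0.05, 0.1, 0.2, 0.4]
        sims = []
        for r in rates:
            pair = [
                GenomeRecord(id="a", sequence=base),
                GenomeRecord(id="b", sequence=_mutate(base, r, seed=10)),
            ]
            sims.append(fragmented_similarity(pair).loc("a", "b"))
        assert all(s1 >= s2 - 1e-9 for s1, s2 in zip(sims, sims[1:]))
        assert sims[0] == pytest.approx(100.0)
        assert sims[-1] < sims[0]

    def test_requires_two_genomes(self):
        with pytest.raises(ValueError, match="two genomes"):
            fragmented_similarity([GenomeRecord(id="a", sequence="ACGT" * 100)])


class TestToDistance:
    def test_identical_genomes_have_zero_distance(self):
        seq = random_dna(1500, seed=11)
        sim = fragmented_similarity(
            [GenomeRecord(id="a", sequence=seq), GenomeRecord(id="b", sequence=seq)]
        )
        d = to_distance(sim)
        assert d.loc("a", "b") == pytest.approx(0.0, abs=1e-9)

    def test_asymmetric_values_average(self):
        sim = SimilarityMatrix(
            labels=["A", "B"], values=np.array([[100.0, 100.0], [50.0, 100.0]])
        )
        d = to_distance(sim)
        assert d.loc("A", "B") == 25.0
        assert np.array_equal(d.values, d.values.T)

    @given(seed=st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_distance_from_any_similarity_is_a_valid_matrix(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        v = rng.uniform(0, 100, (n, n))
        np.fill_diagonal(v, 100.0)
        sim = SimilarityMatrix(labels=[f"g{i}" for i in range(n)], values=v)
        d = to_distance(sim)
        assert np.array_equal(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)
        assert np.all((d.values >= 0) & (d.values <= 100))

    def test_distance_matrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=["a", "b"], values=np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="NaN"):
            DistanceMatrix(
                labels=["a", "b"], values=np.array([[0.0, np.nan], [np.nan, 0.0]])
            )
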