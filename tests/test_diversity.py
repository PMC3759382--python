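"""Positional entropy, information content, and KL divergence."""

import math

import numpy as np
import pytest

from phagepan import (
    DegenerateCodonScheme,
    build_pfm,
    information_content,
    kl_divergence,
    kl_profile,
    shannon_entropy,
    theoretical_pfm,
)
from phagepan.diversity import DNA_ALPHABET, PositionFrequencyMatrix


def direct_entropy(p):
    """Oracle: literal direct summation of -sum p log2 p."""
    return -sum(x * math.log2(x) for x in p if x > 0)


def direct_kl(p, q):
    """Oracle: literal direct summation of sum p log2(p/q)."""
    return sum(x * math.log2(x / y) for x, y in zip(p, q) if x > 0)


def random_distribution(rng, k):
    p = rng.random(k) + 1e-6
    return p / p.sum()


def pfm_from_rows(rows, alphabet="dna", n=1000.0):
    return PositionFrequencyMatrix(
        alphabet=alphabet, freqs=np.array(rows), n_sequences=n, weighting="counts"
    )


class TestShannonEntropy:
    def test_uniform_four_bases_is_two_bits(self):
        assert shannon_entropy([0.25] * 4) == pytest.approx(2.0)

    def test_point_mass_is_zero(self):
        assert shannon_entropy([1.0, 0.0, 0.0]) == 0.0

    def test_half_quarter_quarter(self):
        # derived: -(1/2)log2(1/2) - 2*(1/4)log2(1/4) = 1.5
        assert shannon_entropy([0.5, 0.25, 0.25]) == pytest.approx(1.5)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([1.2, -0.2])

    def test_agrees_with_direct_summation(self, rng):
        for k in (2, 4, 20):
            for _ in range(100):
                p = random_distribution(rng, k)
                assert shannon_entropy(p) == pytest.approx(direct_entropy(p), abs=1e-12)


class TestInformationContent:
    def test_analytic_values_for_template_classes(self):
        pfm = pfm_from_rows(
            [
                [0.25, 0.25, 0.25, 0.25],  # N: IC = 0
                [0.0, 0.5, 0.5, 0.0],      # S: IC = 1
                [0.0, 0.0, 1.0, 0.0],      # fixed: IC = 2
            ]
        )
        profile = information_content(pfm)
        assert profile.s_max == 2.0
        assert profile.ic == pytest.approx([0.0, 1.0, 2.0])

    def test_bounds(self, rng):
        rows = [random_distribution(rng, 4) for _ in range(27)]
        profile = information_content(pfm_from_rows(rows))
        assert np.all(profile.s_obs >= 0) and np.all(profile.s_obs <= 2.0 + 1e-12)
        assert np.all(profile.ic >= -1e-12) and np.all(profile.ic <= 2.0)


class TestTheoreticalPfm:
    @pytest.mark.parametrize(
        "template,expected",
        [
            ("NNN", {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}),
            ("KKK", {"G": 0.5, "T": 0.5}),
            ("MMM", {"A": 0.5, "C": 0.5}),
        ],
    )
    def test_single_template_distributions(self, template, expected):
        scheme = DegenerateCodonScheme(codon_templates=(template,) * 9)
        pfm = theoretical_pfm(scheme)
        row = dict(zip(DNA_ALPHABET, pfm.freqs[0]))
        assert row == pytest.approx({b: expected.get(b, 0.0) for b in DNA_ALPHABET})

    def test_default_scheme_ic_profile_matches_enumeration(self, scheme):
        """The scheme's IC profile equals the profile derived by enumerating
        every concrete codon of each template (independent oracle)."""
        profile = information_content(theoretical_pfm(scheme))
        for codon_index in range(9):
            codons = scheme.codon_expansion(codon_index)
            for offset in range(3):
                counts = {b: 0 for b in DNA_ALPHABET}
                for codon in codons:
                    counts[codon[offset]] += 1
                p = [counts[b] / len(codons) for b in DNA_ALPHABET]
                expected_ic = 2.0 - direct_entropy(p)
                pos = codon_index * 3 + offset
                assert profile.ic[pos] == pytest.approx(expected_ic, abs=1e-12)


class TestKL:
    def test_identical_distributions_have_zero_divergence(self, rng):
        rows = [random_distribution(rng, 4) for _ in range(5)]
        pfm = pfm_from_rows(rows)
        profile = kl_profile(pfm, pfm, pseudocount=0.5)
        assert profile.d == pytest.approx([0.0] * 5, abs=1e-12)

    def test_point_mass_versus_uniform_is_one_bit(self):
        # derived: 1 * log2(1 / 0.5) = 1 bit
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0)

    def test_asymmetric_pair_hand_value(self):
        # derived: 0.75*log2(3) + 0.25*log2(1/3) = 0.5*log2(3)
        d = kl_divergence([0.75, 0.25], [0.25, 0.75])
        assert d == pytest.approx(0.5 * math.log2(3))

    def test_shared_zeros_contribute_nothing(self):
        d = kl_divergence([0.75, 0.25, 0.0], [0.25, 0.75, 0.0])
        assert d == pytest.approx(0.5 * math.log2(3))

    def test_zero_reference_on_support_is_an_error(self):
        with pytest.raises(ValueError, match="pseudocount"):
            kl_divergence([0.5, 0.5], [1.0, 0.0])

    def test_direct_summation_oracle(self, rng):
        for k in (2, 4, 20):
            for _ in range(100):
                p = random_distribution(rng, k)
                q = random_distribution(rng, k)
                d = kl_divergence(p, q)
                assert d == pytest.approx(direct_kl(p, q), abs=1e-12)
                assert d >= 0  # Gibbs inequality
        # and the positionwise profile agrees on full matrices
        rows_p = [random_distribution(rng, 4) for _ in range(27)]
        rows_q = [random_distribution(rng, 4) for _ in range(27)]
        profile = kl_profile(pfm_from_rows(rows_p), pfm_from_rows(rows_q), pseudocount=0.0)
        for pos in range(27):
            assert profile.d[pos] == pytest.approx(
                direct_kl(rows_p[pos], rows_q[pos]), abs=1e-12
            )

    def test_mismatched_shapes_rejected(self, rng):
        p = pfm_from_rows([random_distribution(rng, 4)])
        q = pfm_from_rows([random_distribution(rng, 4) for _ in range(2)])
        with pytest.raises(ValueError, match="share"):
            kl_profile(p, q)

    def test_zero_reference_requires_pseudocount(self):
        p = pfm_from_rows([[0.5, 0.5, 0.0, 0.0]])
        q = pfm_from_rows([[1.0, 0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="pseudocount"):
            kl_profile(p, q, pseudocount=0.0)
        assert kl_profile(p, q, pseudocount=0.5).d[0] > 0


class TestBuildPfm:
    def test_unique_set(self):
        pfm = build_pfm(["AAA", "AAC"], alphabet="dna", weighting="unique")
        assert dict(zip(DNA_ALPHABET, pfm.freqs[2])) == pytest.approx(
            {"A": 0.5, "C": 0.5, "G": 0.0, "T": 0.0}
        )

    def test_count_weighting(self):
        pfm = build_pfm({"AAA": 3, "AAC": 1}, alphabet="dna", weighting="counts")
        assert pfm.freqs[2][0] == pytest.approx(0.75)
        assert pfm.n_sequences == 4

    def test_unique_weighting_on_counted_input(self):
        pfm = build_pfm({"AAA": 3, "AAC": 1}, alphabet="dna", weighting="unique")
        assert pfm.freqs[2][0] == pytest.approx(0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            build_pfm(["AAA", "AAAA"], alphabet="dna")

    def test_bad_symbol_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            build_pfm(["AXA"], alphabet="dna")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_pfm([], alphabet="dna")

    def test_rows_sum_to_one(self, rng):
        seqs = {"ACGT": 5, "AAGT": 2, "ACGA": 1}
        pfm = build_pfm(seqs, alphabet="dna", weighting="counts")
        assert pfm.freqs.sum(axis=1) == pytest.approx([1.0] * 4)
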