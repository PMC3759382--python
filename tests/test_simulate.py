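"""Ground-truth pool construction, selection dynamics, and read emission."""

import numpy as np
import pytest
from scipy import stats

from phagepan import (
    DEFAULT_BARCODES,
    FitnessLandscape,
    PoolComposition,
    ReadEmissionConfig,
    SchemeError,
    apply_selection,
    emit_reads,
    emitted_counts,
    inject_anchor_failures,
    make_initial_pool,
    sample_counts,
    translate_hcdr3,
)
from phagepan.codons import revcomp


def closed_form_selection(pool, landscape, rounds):
    """Oracle: without a bottleneck, r rounds equal f * w^r, renormalized."""
    weights = {v: landscape.weight(translate_hcdr3(v)) for v in pool.variants}
    unnorm = {v: f * weights[v] ** rounds for v, f in pool.variants.items()}
    total = sum(unnorm.values())
    return {v: x / total for v, x in unnorm.items()}


class TestMakeInitialPool:
    def test_uniform_pool(self, scheme):
        pool = make_initial_pool(scheme, 100, rng_seed=1)
        assert len(pool.variants) == 100
        assert all(abs(f - 0.01) < 1e-12 for f in pool.variants.values())

    def test_single_variant(self, scheme):
        pool = make_initial_pool(scheme, 1, rng_seed=2)
        assert list(pool.variants.values()) == [1.0]

    def test_dominant_mass_is_shared_by_synonymous_encodings(self, scheme):
        pool = make_initial_pool(
            scheme, 50, ("YLLSPLLLA", "VQQVNNALA"), 0.967, rng_seed=3
        )
        peptides = pool.peptide_frequencies()
        dom = peptides["YLLSPLLLA"] + peptides["VQQVNNALA"]
        assert dom == pytest.approx(0.967, abs=1e-9)
        # each dominant peptide is carried by several nucleotide encodings
        for pep in ("YLLSPLLLA", "VQQVNNALA"):
            encodings = [
                v for v in pool.variants if translate_hcdr3(v) == pep
            ]
            assert len(encodings) > 1

    def test_frequencies_sum_to_one(self, scheme):
        pool = make_initial_pool(scheme, 33, ("YLLSPLLLA",), 0.4, rng_seed=4)
        assert sum(pool.variants.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unencodable_dominant_peptide_is_an_error(self, scheme):
        with pytest.raises(SchemeError, match="position 9"):
            make_initial_pool(scheme, 10, ("YLLSPLLLF",), 0.5, rng_seed=5)

    def test_composition_validation(self):
        with pytest.raises(ValueError, match="sum"):
            PoolComposition("p", {"A" * 27: 0.5, "C" * 27: 0.4})
        with pytest.raises(ValueError, match="positive"):
            PoolComposition("p", {"A" * 27: 1.5, "C" * 27: -0.5})


class TestSelection:
    def test_neutral_landscape_leaves_frequencies_unchanged(self, scheme):
        pool = make_initial_pool(scheme, 20, rng_seed=6)
        after = apply_selection(pool, FitnessLandscape(), rounds=5)
        for v, f in pool.variants.items():
            assert after.variants[v] == pytest.approx(f)

    def test_one_round_two_variant_arithmetic(self, scheme):
        a, b = "GCT" * 9, "TAT" * 9  # AAAAAAAAA vs YYYYYYYYY
        pool = PoolComposition("p", {a: 0.5, b: 0.5})
        landscape = FitnessLandscape({"A" * 9: 2.0, "Y" * 9: 1.0})
        after = apply_selection(pool, landscape, rounds=1)
        assert after.variants[a] == pytest.approx(2 / 3)
        assert after.variants[b] == pytest.approx(1 / 3)

    def test_three_rounds_compound_the_odds(self, scheme):
        # derived: after r rounds the odds update by w^r, so 2^3 = 8:1
        a, b = "GCT" * 9, "TAT" * 9
        pool = PoolComposition("p", {a: 0.5, b: 0.5})
        landscape = FitnessLandscape({"A" * 9: 2.0, "Y" * 9: 1.0})
        after = apply_selection(pool, landscape, rounds=3)
        assert after.variants[a] == pytest.approx(8 / 9)
        assert after.variants[b] == pytest.approx(1 / 9)

    def test_matches_closed_form_oracle_on_random_pools(self, scheme, rng):
        for trial in range(5):
            pool = make_initial_pool(scheme, 25, rng_seed=rng)
            peptides = sorted(pool.peptide_frequencies())
            landscape = FitnessLandscape(
                {p: float(2.0 ** rng.uniform(-2, 2)) for p in peptides}
            )
            rounds = int(rng.integers(1, 5))
            after = apply_selection(pool, landscape, rounds=rounds)
            oracle = closed_form_selection(pool, landscape, rounds)
            for v in pool.variants:
                assert after.variants[v] == pytest.approx(oracle[v], abs=1e-12)

    def test_bottleneck_resamples_and_renormalizes(self, scheme):
        pool = make_initial_pool(scheme, 50, rng_seed=8)
        after = apply_selection(
            pool, FitnessLandscape(), rounds=2, bottleneck=200, rng_seed=9
        )
        assert sum(after.variants.values()) == pytest.approx(1.0, abs=1e-9)
        assert set(after.variants) <= set(pool.variants)
        assert len(after.variants) <= 200

    def test_bottleneck_below_one_is_a_configuration_error(self, scheme):
        pool = make_initial_pool(scheme, 5, rng_seed=10)
        with pytest.raises(ValueError, match="bottleneck"):
            apply_selection(pool, FitnessLandscape(), rounds=1, bottleneck=0)


class TestEmission:
    def test_noiseless_reads_carry_barcode_and_valid_hcdr3(self, scheme):
        pool = make_initial_pool(scheme, 20, rng_seed=11)
        config = ReadEmissionConfig(barcode="ACGACG", depth=1000, error_rate=0.0, seed=12)
        pairs = emit_reads(pool, config, scheme)
        assert len(pairs) == 1000
        up, down = scheme.flank_upstream, scheme.flank_downstream
        for pair in pairs:
            assert pair.r1_seq.startswith("ACGACG" + up)
            start = 6 + len(up)
            insert = pair.r1_seq[start : start + 27]
            assert scheme.matches(insert)
            assert pair.r1_seq[start + 27 :] == down

    def test_noiseless_r2_is_reverse_complement_of_r1(self, scheme):
        pool = make_initial_pool(scheme, 5, rng_seed=13)
        config = ReadEmissionConfig(barcode="ACGACG", depth=200, error_rate=0.0, seed=14)
        for pair in emit_reads(pool, config, scheme):
            assert pair.r2_seq == revcomp(pair.r1_seq)

    def test_same_seed_gives_identical_reads(self, scheme):
        pool = make_initial_pool(scheme, 10, rng_seed=15)
        config = ReadEmissionConfig(barcode="ACGACG", depth=500, error_rate=0.02, seed=16)
        assert emit_reads(pool, config, scheme) == emit_reads(pool, config, scheme)

    def test_increasing_depth_appends_without_perturbing_earlier_reads(self, scheme):
        import dataclasses

        pool = make_initial_pool(scheme, 10, rng_seed=17)
        small = ReadEmissionConfig(barcode="ACGACG", depth=100, error_rate=0.02, seed=18)
        large = dataclasses.replace(small, depth=250)
        assert emit_reads(pool, large, scheme)[:100] == emit_reads(pool, small, scheme)

    def test_error_positions_get_the_low_quality_score(self, scheme):
        pool = make_initial_pool(scheme, 5, rng_seed=19)
        config = ReadEmissionConfig(
            barcode="ACGACG", depth=300, error_rate=0.05, seed=20,
            quality_high=40, quality_low=2,
        )
        pairs = emit_reads(pool, config, scheme)
        truth = {v: "ACGACG" + scheme.flank_upstream + v + scheme.flank_downstream
                 for v in pool.variants}
        n_err = 0
        for pair in pairs:
            clean = truth[pair.read_id.rsplit(":", 1)[1]]
            for base, true_base, q in zip(pair.r1_seq, clean, pair.r1_qual):
                if base != true_base:
                    assert q == chr(33 + 2)
                    n_err += 1
                else:
                    assert q == chr(33 + 40)
        assert n_err > 0  # the error model actually fired

    def test_empirical_frequencies_converge_to_pool(self, scheme):
        pool = make_initial_pool(scheme, 40, rng_seed=21)
        config = ReadEmissionConfig(barcode="ACGACG", depth=100_000, error_rate=0.0, seed=22)
        counts = emitted_counts(emit_reads(pool, config, scheme))
        observed = [counts.get(v, 0) for v in pool.variants]
        expected = [f * config.depth for f in pool.variants.values()]
        _, p_value = stats.chisquare(observed, expected)
        assert p_value > 0.001

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ReadEmissionConfig(barcode="ACG", depth=10)
        with pytest.raises(ValueError):
            ReadEmissionConfig(barcode="ACGT", depth=0)
        with pytest.raises(ValueError):
            ReadEmissionConfig(barcode="ACGT", depth=10, error_rate=0.6)


class TestSampleCounts:
    def test_counts_sum_to_depth(self, scheme):
        pool = make_initial_pool(scheme, 30, rng_seed=23)
        counts = sample_counts(pool, 5000, 24)
        assert sum(counts.values()) == 5000
        assert set(counts) <= set(pool.variants)

    def test_matches_noiseless_emission_semantics(self, scheme):
        # multinomial counts are what error-free emission + exact counting yield
        pool = make_initial_pool(scheme, 10, rng_seed=25)
        counts = sample_counts(pool, 20_000, 26)
        for v, f in pool.variants.items():
            se = (f * (1 - f) / 20_000) ** 0.5
            assert abs(counts.get(v, 0) / 20_000 - f) < 5 * se + 1e-3


def test_inject_anchor_failures_count_and_positions(scheme):
    from phagepan import make_initial_pool

    pool = make_initial_pool(scheme, 10, rng_seed=27)
    config = ReadEmissionConfig(barcode="ACGACG", depth=400, error_rate=0.0, seed=28)
    pairs = emit_reads(pool, config, scheme)
    broken, n_injected = inject_anchor_failures(pairs, 0.1, scheme, 6, rng_seed=29)
    assert n_injected == 40
    changed = [i for i, (a, b) in enumerate(zip(pairs, broken)) if a != b]
    assert len(changed) == 40
    for i in changed:
        assert broken[i].r2_seq == pairs[i].r2_seq  # R2 untouched
        assert scheme.flank_upstream not in broken[i].r1_seq
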