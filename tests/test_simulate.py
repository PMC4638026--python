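"""Synthetic virome generator: genome pools, evenness solver, read sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hvdi import (
    construct_abundance_profile,
    generate_genome_pool,
    geometric_proportions,
    sample_reads,
    shannon_index,
    stage_seed,
)
from hvdi._seq import revcomp


class TestGenomePool:
    def test_single_fixed_length_genome(self):
        pool = generate_genome_pool(1, (5000, 5000), gc_content=0.5, seed=7)
        assert len(pool) == 1
        assert pool[0].length == 5000

    def test_seed_determinism(self):
        a = generate_genome_pool(10, (5000, 20000), gc_content=0.455, seed=1)
        b = generate_genome_pool(10, (5000, 20000), gc_content=0.455, seed=1)
        assert [g.sequence for g in a.genomes] == [g.sequence for g in b.genomes]
        c = generate_genome_pool(10, (5000, 20000), gc_content=0.455, seed=2)
        assert [g.sequence for g in a.genomes] != [g.sequence for g in c.genomes]

    def test_gc_content_within_tolerance(self):
        pool = generate_genome_pool(50, (5000, 10000), gc_content=0.5, seed=3)
        assert abs(pool.gc_content() - 0.5) < 0.01

    def test_pool_genomes_are_well_separated(self):
        pool = generate_genome_pool(5, (5000, 5000), seed=9)
        assert pool.max_shared_kmer_fraction(k=25) < 0.001

    @pytest.mark.parametrize(
        "n,rng",
        [(0, (5000, 5000)), (3, (100, 5000)), (3, (9000, 6000)), (3, (5000, 10**6))],
    )
    def test_invalid_parameters_rejected(self, n, rng):
        with pytest.raises(ValueError):
            generate_genome_pool(n, rng, seed=0)


class TestEvennessSolver:
    def test_uniform_at_target_one(self):
        p = construct_abundance_profile(10, 1.0)
        np.testing.assert_allclose(p.proportions, 0.1)
        assert p.achieved_evenness == 1.0

    @pytest.mark.parametrize("target", [0.10, 0.33, 0.50, 0.67, 0.90])
    @pytest.mark.parametrize("S", [10, 50, 100, 500])
    def test_targets_hit_within_tolerance(self, S, target):
        p = construct_abundance_profile(S, target, tolerance=0.01)
        h = -(p.proportions * np.log(p.proportions)).sum()
        assert abs(h / np.log(S) - target) <= 0.01
        assert abs(p.proportions.sum() - 1.0) < 1e-9

    def test_achieved_evenness_matches_reported(self):
        p = construct_abundance_profile(100, 0.67)
        h = shannon_index(p.proportions)
        assert abs(h / np.log(100) - p.achieved_evenness) < 1e-9

    def test_single_genotype_is_domain_error(self):
        with pytest.raises(ValueError):
            construct_abundance_profile(1, 0.5)

    @pytest.mark.parametrize("target", [0.0, -0.1, 1.5])
    def test_target_out_of_range(self, target):
        with pytest.raises(ValueError):
            construct_abundance_profile(10, target)

    def test_seed_shuffles_rank_assignment_only(self):
        a = construct_abundance_profile(20, 0.5, seed=1)
        b = construct_abundance_profile(20, 0.5, seed=2)
        assert sorted(a.proportions) == sorted(b.proportions)
        assert not np.array_equal(a.proportions, b.proportions)

    def test_evenness_monotone_in_family_parameter(self):
        rs = np.linspace(0.01, 1.0, 25)
        evs = []
        for r in rs:
            p = geometric_proportions(40, r)
            p = p[p > 0]
            evs.append(-(p * np.log(p)).sum() / np.log(40))
        assert all(x < y + 1e-12 for x, y in zip(evs, evs[1:]))


class TestReadSampling:
    def test_zero_reads(self, small_pool):
        prof = construct_abundance_profile(5, 1.0, genotype_ids=small_pool.ids)
        v = sample_reads(small_pool, prof, 0, seed=0)
        assert len(v.reads) == 0
        assert sum(v.truth_spectrum.values()) == 0

    def test_reads_are_exact_substrings_with_correct_truth(self, small_pool):
        prof = construct_abundance_profile(5, 0.67, genotype_ids=small_pool.ids)
        v = sample_reads(small_pool, prof, 300, seed=4)
        genomes = {g.id: g.sequence for g in small_pool.genomes}
        for r in v.reads:
            frag = genomes[r.source_genotype_id][
                r.source_start : r.source_start + len(r.sequence)
            ]
            assert r.sequence == (frag if r.strand == "+" else revcomp(frag))
        assert sum(v.truth_spectrum.values()) == 300

    def test_length_law(self, small_pool):
        prof = construct_abundance_profile(5, 1.0, genotype_ids=small_pool.ids)
        v = sample_reads(small_pool, prof, 10_000, seed=8)
        lens = np.array([len(r.sequence) for r in v.reads])
        assert lens.min() >= 150 and lens.max() <= 250
        assert abs(lens.mean() - 200) < 2

    def test_truth_counts_follow_multinomial(self):
        pool = generate_genome_pool(10, (10_000, 10_000), seed=5)
        prof = construct_abundance_profile(10, 1.0, genotype_ids=pool.ids)
        v = sample_reads(pool, prof, 10_000, seed=5)
        sd = np.sqrt(10_000 * 0.1 * 0.9)
        for count in v.truth_spectrum.values():
            assert abs(count - 1000) <= 3 * sd

    def test_seed_reproducibility(self, small_pool):
        prof = construct_abundance_profile(5, 0.5, genotype_ids=small_pool.ids)
        a = sample_reads(small_pool, prof, 200, seed=3)
        b = sample_reads(small_pool, prof, 200, seed=3)
        assert [(r.id, r.sequence, r.strand) for r in a.reads] == [
            (r.id, r.sequence, r.strand) for r in b.reads
        ]

    def test_truth_shannon_converges_to_profile_shannon(self, small_pool):
        prof = construct_abundance_profile(5, 0.67, genotype_ids=small_pool.ids)
        v = sample_reads(small_pool, prof, 100_000, seed=9)
        h_truth = shannon_index(list(v.truth_spectrum.values()))
        assert abs(h_truth - prof.shannon()) / prof.shannon() < 0.02

    def test_substitution_errors_change_bases_at_rate(self, small_pool):
        prof = construct_abundance_profile(5, 1.0, genotype_ids=small_pool.ids)
        clean = sample_reads(small_pool, prof, 500, seed=6)
        noisy = sample_reads(small_pool, prof, 500, error_rate=0.02, seed=6)
        diff = total = 0
        for a, b in zip(clean.reads, noisy.reads):
            assert len(a.sequence) == len(b.sequence)
            diff += sum(x != y for x, y in zip(a.sequence, b.sequence))
            total += len(a.sequence)
        assert 0.012 < diff / total < 0.028

    def test_artifacts_exercise_qc(self, small_pool):
        from hvdi import filter_reads

        prof = construct_abundance_profile(5, 1.0, genotype_ids=small_pool.ids)
        v = sample_reads(
            small_pool, prof, 400,
            homopolymer_artifact_rate=0.1, ambiguous_artifact_rate=0.1, seed=7,
        )
        _kept, report = filter_reads(v.reads)
        assert report.removed_homopolymer > 0
        assert report.removed_ambiguous > 0

    def test_read_length_bounds_vs_genome_length(self, small_pool):
        prof = construct_abundance_profile(5, 1.0, genotype_ids=small_pool.ids)
        with pytest.raises(ValueError):
            sample_reads(small_pool, prof, 10, len_max=20_001, seed=0)


@settings(deadline=None, max_examples=20)
@given(st.integers(0, 2**31 - 1), st.integers(0, 10))
def test_stage_seed_is_deterministic_and_bounded(master, key):
    a = stage_seed(master, key)
    assert a == stage_seed(master, key)
    assert 0 <= a < 2**31
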