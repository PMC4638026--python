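"""Similarity search, genotype clustering and cross-virome sharing."""

import numpy as np
import pytest

from hvdi import (
    ContigSpectrum,
    construct_abundance_profile,
    contig_hit_profile,
    correct_contig_spectrum,
    cross_sample_shared_fraction,
    find_similarity_hits,
    generate_genome_pool,
    sample_reads,
    shannon_index,
)
from hvdi.similarity import SimilarityHit
from tests.conftest import random_seq


def _hit(q, s):
    return SimilarityHit(
        query_id=q, subject_id=s, strand="+", query_start=0, query_end=100,
        subject_start=0, subject_end=100, alignment_length=100, identity=1.0,
        score=100, bit_score=190.0, e_value=1e-50,
    )


class TestSimilaritySearch:
    def test_exact_copy_full_coverage_hit(self, rng):
        s = random_seq(rng, 1000)
        hits = find_similarity_hits([("a", s)], [("b", s)], e_value_max=1e-20)
        assert len(hits) == 1
        h = hits[0]
        assert h.identity == 1.0
        assert h.alignment_length == 1000
        assert h.e_value < 1e-100

    def test_unrelated_random_contigs_no_hit(self, rng):
        a, b = random_seq(rng, 1000), random_seq(rng, 1000)
        assert find_similarity_hits([("a", a)], [("b", b)], e_value_max=1e-20) == []

    def test_contained_contig_covered_fully(self, rng):
        big = random_seq(rng, 2000)
        small = big[700:1200]
        hits = find_similarity_hits([("small", small)], [("big", big)], 1e-20)
        assert len(hits) == 1
        assert hits[0].alignment_length == 500
        assert hits[0].subject_start == 700 and hits[0].subject_end == 1200

    def test_reverse_strand_hit_found(self, rng):
        from hvdi._seq import revcomp

        s = random_seq(rng, 800)
        hits = find_similarity_hits([("a", s)], [("b", revcomp(s))], 1e-20)
        assert len(hits) == 1
        assert hits[0].strand == "-"

    def test_self_hits_excluded_in_self_search(self, rng):
        pairs = [("a", random_seq(rng, 600)), ("b", random_seq(rng, 600))]
        assert find_similarity_hits(pairs, pairs, 1e-20) == []

    def test_coverage_of_shorter_required(self, rng):
        # 300-nt shared block between two 1-kb contigs: E-value passes but
        # covers only 30 % of the shorter contig
        block = random_seq(rng, 300)
        a = random_seq(rng, 350) + block + random_seq(rng, 350)
        b = random_seq(rng, 350) + block + random_seq(rng, 350)
        assert find_similarity_hits([("a", a)], [("b", b)], 1e-20) == []
        hits = find_similarity_hits([("a", a)], [("b", b)], 1e-20, min_frac_shorter=0.25)
        assert len(hits) == 1

    def test_substitutions_tolerated_in_extension(self, rng):
        s = random_seq(rng, 1000)
        mutated = list(s)
        for pos in range(50, 1000, 100):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        hits = find_similarity_hits([("a", s)], [("b", "".join(mutated))], 1e-20)
        assert len(hits) == 1
        assert 0.98 <= hits[0].identity < 1.0
        assert hits[0].alignment_length > 900

    def test_invalid_e_value(self, rng):
        with pytest.raises(ValueError):
            find_similarity_hits([("a", "ACGT" * 100)], [("b", "ACGT" * 100)], 0.0)


class TestCorrectedSpectrum:
    def test_no_hits_identity_correction(self):
        spec = ContigSpectrum(category_ids=["c1", "c2"], counts=np.array([5, 3]))
        corr = correct_contig_spectrum(spec, [])
        assert corr.counts.tolist() == [5, 3]
        assert corr.n_genotypes == 2

    def test_single_link_merges_counts(self):
        spec = ContigSpectrum(category_ids=["c1", "c2"], counts=np.array([5, 3]))
        corr = correct_contig_spectrum(spec, [_hit("c1", "c2")])
        assert corr.counts.tolist() == [8]

    def test_chain_is_transitively_merged(self):
        spec = ContigSpectrum(
            category_ids=["a", "b", "c"], counts=np.array([2, 2, 2])
        )
        corr = correct_contig_spectrum(spec, [_hit("a", "b"), _hit("b", "c")])
        assert corr.n_genotypes == 1
        assert corr.counts.tolist() == [6]

    def test_unknown_contig_id_rejected(self):
        spec = ContigSpectrum(category_ids=["a"], counts=np.array([1]))
        with pytest.raises(ValueError):
            correct_contig_spectrum(spec, [_hit("a", "zzz")])

    def test_count_conservation_and_shannon_monotonicity(self, uniform_analysis):
        raw = uniform_analysis.raw_spectrum
        corr = uniform_analysis.corrected
        assert corr.total_reads == raw.total_reads
        assert corr.n_genotypes <= len(raw.category_ids)
        assert shannon_index(corr.counts) <= shannon_index(raw.counts) + 1e-12

    def test_duplicate_contigs_from_same_genome_are_merged(self, rng):
        g = random_seq(rng, 3000)
        spec = ContigSpectrum(
            category_ids=["full", "dup", "other"], counts=np.array([10, 4, 2])
        )
        contigs = [("full", g), ("dup", g[500:2500]), ("other", random_seq(rng, 2000))]
        hits = find_similarity_hits(contigs, contigs, e_value_max=1e-20)
        corr = correct_contig_spectrum(spec, hits)
        assert corr.n_genotypes == 2
        assert corr.counts.tolist() == [14, 2]


@pytest.fixture(scope="module")
def shared_pools():
    """Two assembled viromes sharing exactly half of A's source genomes."""
    from hvdi import analyze_virome
    from hvdi.simulate import GenomePool

    big = generate_genome_pool(6, (10_000, 10_000), seed=51)
    out = {}
    for tag, genomes in (("a", big.genomes[:4]), ("b", big.genomes[2:6])):
        sub = GenomePool(genomes=tuple(genomes))
        prof = construct_abundance_profile(4, 1.0, genotype_ids=sub.ids)
        vir = sample_reads(sub, prof, 4000, seed=61 if tag == "a" else 62)
        res = analyze_virome(vir)
        out[tag] = [(c.id, c.sequence) for c in res.assembly.contigs]
    return out


class TestCrossSampleSharing:
    def test_identical_set_shares_everything(self, shared_pools):
        frac = cross_sample_shared_fraction(
            shared_pools["a"], shared_pools["a"], n_sampled=500, seed=1
        )
        assert frac == 1.0

    def test_disjoint_random_contigs_share_nothing(self, rng):
        a = [(f"a{i}", random_seq(rng, 2000)) for i in range(4)]
        b = [(f"b{i}", random_seq(rng, 2000)) for i in range(4)]
        assert cross_sample_shared_fraction(a, b, n_sampled=200, seed=2) == 0.0

    def test_half_shared_genomes_give_half_fraction(self, shared_pools):
        frac = cross_sample_shared_fraction(
            shared_pools["a"], shared_pools["b"], n_sampled=1000, seed=3
        )
        assert abs(frac - 0.5) <= 0.05

    def test_seed_reproducibility_and_range(self, shared_pools):
        f1 = cross_sample_shared_fraction(shared_pools["a"], shared_pools["b"], seed=9)
        f2 = cross_sample_shared_fraction(shared_pools["a"], shared_pools["b"], seed=9)
        assert f1 == f2
        assert 0.0 <= f1 <= 1.0

    def test_empty_virome_rejected(self, shared_pools):
        with pytest.raises(ValueError):
            cross_sample_shared_fraction([], shared_pools["a"])

    def test_hit_profile_matches_fraction_at_full_sampling(self, shared_pools):
        profile = contig_hit_profile(shared_pools["a"], shared_pools["b"])
        n = len(shared_pools["a"])
        frac = cross_sample_shared_fraction(
            shared_pools["a"], shared_pools["b"], n_sampled=n, seed=4
        )
        # sampling n of n without replacement is exhaustive
        assert frac == pytest.approx(profile.mean())
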