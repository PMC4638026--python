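"""Community comparison: permutation test, membership, Bray-Curtis, PCoA."""

import numpy as np
import pandas as pd
import pytest

from hvdi import (
    assemble,
    assembly_membership_matrix,
    bray_curtis_matrix,
    pcoa,
    permutation_shared_test,
)
from tests.conftest import random_seq


def _virome_contigs(rng, genomes, n_per=3, length=1500):
    """Contig sets built from slices of shared genome strings.

    Genomes are 2 kb so any two slices of one genome overlap by >= 1 kb,
    comfortably above the 50 %-of-shorter coverage rule.
    """
    out = []
    for gi, g in enumerate(genomes):
        for k in range(n_per):
            start = int(rng.integers(0, len(g) - length))
            out.append((f"g{gi}_c{k}_{rng.integers(1e6)}", g[start : start + length]))
    return out


class TestPermutationTest:
    def test_fully_separated_groups_give_zero_p(self, rng):
        genomes_a = [random_seq(rng, 2000) for _ in range(3)]
        genomes_b = [random_seq(rng, 2000) for _ in range(3)]
        group_a = [_virome_contigs(rng, genomes_a) for _ in range(2)]
        group_b = [_virome_contigs(rng, genomes_b) for _ in range(2)]
        res = permutation_shared_test(group_a, group_b, B=200, n_sampled=50, seed=1)
        assert res.p_value == 0.0
        assert res.observed_stat > 0.9
        assert float(np.mean(res.null_stats)) < 0.05

    def test_identical_viromes_in_both_groups_give_high_p(self, rng):
        genomes = [random_seq(rng, 2000) for _ in range(3)]
        viromes = [_virome_contigs(rng, genomes) for _ in range(2)]
        res = permutation_shared_test(viromes, viromes, B=200, n_sampled=50, seed=2)
        assert res.p_value > 0.4

    def test_subject_labels_leave_valid_pairs(self, rng):
        genomes = [random_seq(rng, 2000)]
        v = [_virome_contigs(rng, genomes) for _ in range(2)]
        res = permutation_shared_test(
            v, v, B=50, n_sampled=20,
            subject_labels_a=["s1", "s2"], subject_labels_b=["s3", "s4"],
            seed=0,
        )
        assert 0 <= res.p_value <= 1

    def test_all_between_pairs_excluded_is_error(self, rng):
        genomes = [random_seq(rng, 2000)]
        v = [_virome_contigs(rng, genomes) for _ in range(2)]
        with pytest.raises(ValueError):
            permutation_shared_test(
                v, v, B=10,
                subject_labels_a=["s1", "s1"], subject_labels_b=["s1", "s1"],
                seed=0,
            )

    def test_group_size_validation(self, rng):
        v = [_virome_contigs(rng, [random_seq(rng, 8000)])]
        with pytest.raises(ValueError):
            permutation_shared_test(v, v, B=10)

    def test_summary_fields(self, rng):
        genomes = [random_seq(rng, 2000) for _ in range(2)]
        v = [_virome_contigs(rng, genomes) for _ in range(2)]
        res = permutation_shared_test(v, v, B=100, n_sampled=20, seed=3)
        s = res.summary()
        assert set(s) >= {
            "observed_stat", "p_value", "within_mean", "between_mean",
            "null_quantiles",
        }
        assert res.B == 100 and len(res.null_stats) == 100


class TestMembershipMatrix:
    def _global_assembly(self, rng, sample_of_contig):
        g = random_seq(rng, 4000)
        contigs, labels = [], {}
        for cid, sample, seq in sample_of_contig(g):
            contigs.append((cid, seq))
            labels[cid] = sample
        return assemble(contigs, min_overlap_frac=0.5), labels

    def test_single_sample_gets_hundred_percent(self, rng):
        g = random_seq(rng, 4000)
        contigs = [("c1", g[:2500]), ("c2", g[1000:3500])]
        labels = {"c1": "day4", "c2": "day4"}
        res = assemble(contigs)
        m = assembly_membership_matrix(res, labels)
        assert m.percentages["day4"] == 100.0

    def test_identical_contig_sets_both_full(self, rng):
        g = random_seq(rng, 4000)
        contigs = [("t1_c", g[:3000]), ("t2_c", g[:3000])]
        res = assemble(contigs)
        m = assembly_membership_matrix(res, {"t1_c": "t1", "t2_c": "t2"})
        assert m.percentages["t1"] == 100.0
        assert m.percentages["t2"] == 100.0

    def test_persistent_samples_score_higher(self, rng):
        # persistent genome appears at every time point; transient ones do not
        persistent = random_seq(rng, 5000)
        contigs, labels = [], {}
        for t in range(5):
            cid = f"p_t{t}"
            contigs.append((cid, persistent[: 3000 + 10 * t]))
            labels[cid] = f"t{t}"
            cid2 = f"u_t{t}"
            contigs.append((cid2, random_seq(rng, 3000)))
            labels[cid2] = f"t{t}"
        res = assemble(contigs)
        m = assembly_membership_matrix(res, labels)
        # each time point contributed its persistent contig to the shared
        # assembly plus one private contig
        assert (m.percentages > 0).all()
        assert m.presence.shape[1] == 5

    def test_unlabeled_contig_rejected(self, rng):
        g = random_seq(rng, 4000)
        res = assemble([("c1", g[:2500]), ("c2", g[1000: 3500])])
        with pytest.raises(ValueError):
            assembly_membership_matrix(res, {"c1": "day4"})

    def test_membership_profiles_feed_bray_curtis(self, rng):
        from hvdi import membership_profiles

        g = random_seq(rng, 4000)
        contigs = [("a", g[:3000]), ("b", g[500:3500]), ("c", random_seq(rng, 2500))]
        res = assemble(contigs)
        m = assembly_membership_matrix(res, {"a": "s1", "b": "s2", "c": "s1"})
        profiles = membership_profiles(m)
        d = bray_curtis_matrix(profiles)
        assert d.shape == (2, 2)
        assert d.loc["s1", "s2"] < 1.0  # the shared assembly keeps them close

    def test_relabeling_equivariance(self, rng):
        g = random_seq(rng, 4000)
        contigs = [("a", g[:3000]), ("b", g[500:3500]), ("c", random_seq(rng, 2500))]
        res = assemble(contigs)
        m1 = assembly_membership_matrix(res, {"a": "s1", "b": "s2", "c": "s1"})
        m2 = assembly_membership_matrix(res, {"a": "s2", "b": "s1", "c": "s2"})
        assert m1.percentages["s1"] == m2.percentages["s2"]
        assert m1.percentages["s2"] == m2.percentages["s1"]


class TestBrayCurtis:
    def test_identical_profiles_distance_zero(self):
        p = pd.DataFrame([[3, 1, 0], [3, 1, 0]], index=["a", "b"])
        d = bray_curtis_matrix(p)
        assert d.loc["a", "b"] == 0.0

    def test_disjoint_support_distance_one(self):
        p = pd.DataFrame([[5, 0], [0, 7]], index=["a", "b"])
        assert bray_curtis_matrix(p).loc["a", "b"] == 1.0

    def test_frozen_example(self):
        p = pd.DataFrame([[1, 1, 0], [0, 1, 1]], index=["x", "y"])
        assert bray_curtis_matrix(p).loc["x", "y"] == pytest.approx(0.5)

    def test_symmetry_zero_diagonal_and_range(self, rng):
        p = pd.DataFrame(rng.integers(0, 50, size=(6, 12)))
        d = bray_curtis_matrix(p).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert ((d >= 0) & (d <= 1)).all()

    def test_all_zero_pair_flagged_nan(self):
        p = pd.DataFrame([[0, 0], [0, 0], [1, 2]], index=list("abc"))
        with pytest.warns(UserWarning):
            d = bray_curtis_matrix(p)
        assert np.isnan(d.loc["a", "b"])

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis_matrix(pd.DataFrame([[1, -1], [0, 1]]))


class TestPCoA:
    def test_all_zero_distances_collapse_to_origin(self):
        d = np.zeros((4, 4))
        coords, eigvals = pcoa(d, k=2)
        assert np.allclose(coords.to_numpy(), 0)

    def test_two_points_separate_by_distance(self):
        d = np.array([[0.0, 0.7], [0.7, 0.0]])
        coords, _ = pcoa(d, k=1)
        sep = abs(coords.iloc[0, 0] - coords.iloc[1, 0])
        assert sep == pytest.approx(0.7)

    def test_euclidean_distances_reproduced(self, rng):
        # full-rank Euclidean case: embedding must reproduce the input
        x = rng.normal(size=(6, 5))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x))
        coords, eigvals = pcoa(d, k=6)
        emb = squareform(pdist(coords.to_numpy()))
        assert np.abs(emb - d).max() < 1e-8

    def test_agrees_with_reference_implementation(self, rng):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        x = rng.normal(size=(7, 4))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x))
        ours_coords, ours_eig = pcoa(d, k=3)
        theirs = skbio_ord.pcoa(d, method="eigh")
        np.testing.assert_allclose(
            np.sort(ours_eig)[::-1][:3], theirs.eigvals.to_numpy()[:3], atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(ours_coords.to_numpy()),
            np.abs(theirs.samples.to_numpy()[:, :3]),
            atol=1e-6,
        )

    def test_negative_eigenvalues_reported_not_embedded(self):
        # a non-Euclidean (but metric) distance matrix
        d = np.array(
            [
                [0.0, 1.0, 1.0, 1.0],
                [1.0, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 1.9],
                [1.0, 1.0, 1.9, 0.0],
            ]
        )
        coords, eigvals = pcoa(d, k=4)
        assert eigvals.min() < -1e-6
        # the axis with negative eigenvalue carries zero coordinates
        assert np.allclose(coords.to_numpy()[:, -1], 0)

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError):
            pcoa(d)
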