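"""GCN data model, I/O, functional profiles, distances and descriptives."""

import numpy as np
import pandas as pd
import pytest

from gcnfr import (
    GCN,
    AlignmentError,
    GCNFormatError,
    TaxonomicProfile,
    align_profiles,
    degree_profiles,
    distance_histogram,
    functional_distance_matrix,
    functional_profile,
    load_gcn,
)

from conftest import random_gcn_matrix


class TestLoadGCN:
    def test_round_trip_identity(self, tmp_path):
        g = GCN(["a", "b"], ["x", "y"], np.eye(2, dtype=int))
        path = tmp_path / "g.tsv"
        g.write_tsv(path)
        g2 = load_gcn(path)
        assert g2.species == ["a", "b"]
        assert g2.genes == ["x", "y"]
        assert (g2.matrix == g.matrix).all()

    def test_negative_entry_rejected(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("species\tx\ty\na\t1\t0\nb\t0\t-1\n")
        with pytest.raises(GCNFormatError, match="non-negative"):
            load_gcn(path)

    def test_non_integer_entry_rejected(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("species\tx\ty\na\t1.5\t0\nb\t0\t1\n")
        with pytest.raises(GCNFormatError, match="integer"):
            load_gcn(path)

    def test_duplicate_label_rejected(self):
        with pytest.raises(GCNFormatError, match="duplicate"):
            GCN(["a", "a"], ["x", "y"], np.eye(2, dtype=int))

    def test_empty_column_pruned_when_flagged(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("species\tx\ty\tz\na\t1\t0\t0\nb\t0\t1\t0\n")
        g = load_gcn(path, prune_empty=True)
        assert g.n_genes == 2
        assert g.genes == ["x", "y"]
        with pytest.raises(GCNFormatError, match="no genome"):
            load_gcn(path, prune_empty=False)

    def test_empty_genome_rejected(self):
        with pytest.raises(GCNFormatError, match="empty genome"):
            GCN(["a", "b"], ["x", "y"], np.array([[1, 1], [0, 0]]))


class TestFunctionalProfile:
    def test_single_taxon_passthrough(self):
        g = GCN(["a", "b"], ["x", "y"], np.eye(2, dtype=int))
        f = functional_profile(TaxonomicProfile("s", np.array([1.0, 0.0])), g)
        assert np.allclose(f.abundances, [1.0, 0.0])

    def test_copy_number_weighting(self):
        g = GCN(["a", "b"], ["x", "y"], np.array([[2, 0], [0, 1]]))
        f = functional_profile(TaxonomicProfile("s", np.array([0.5, 0.5])), g)
        assert np.allclose(f.abundances, [2 / 3, 1 / 3])

    def test_shared_genome_gives_identical_functional_profiles(self):
        # all taxa carrying the same genome: every composition maps to the
        # same functional profile
        g = GCN(["a", "b", "c"], ["x", "y"], np.tile([2, 1], (3, 1)))
        rng = np.random.default_rng(0)
        refs = []
        for _ in range(5):
            p = rng.dirichlet(np.ones(3))
            refs.append(functional_profile(TaxonomicProfile("s", p), g).abundances)
        assert np.allclose(refs, refs[0])

    def test_sums_to_one_for_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            mat = random_gcn_matrix(rng)
            g = GCN([f"s{i}" for i in range(mat.shape[0])],
                    [f"g{a}" for a in range(mat.shape[1])], mat)
            p = rng.dirichlet(np.ones(g.n_species))
            f = functional_profile(TaxonomicProfile("s", p), g)
            assert f.abundances.sum() == pytest.approx(1.0, abs=1e-12)


class TestDistances:
    def test_identical_genomes_distance_zero(self):
        g = GCN(["a", "b"], ["x", "y"], np.array([[2, 1], [2, 1]]))
        for method in ("weighted_jaccard", "correlation", "sorensen"):
            d = functional_distance_matrix(g, method)
            assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_genomes_distance_one(self):
        g = GCN(["a", "b"], ["x", "y"], np.array([[3, 0], [0, 2]]))
        for method in ("weighted_jaccard", "correlation", "sorensen"):
            d = functional_distance_matrix(g, method)
            assert d.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_weighted_jaccard_hand_value(self):
        # rows (2,1,0) vs (1,1,1): 1 - (1+1+0)/(2+1+1) = 0.5
        g = GCN(["a", "b"], ["x", "y", "z"], np.array([[2, 1, 0], [1, 1, 1]]))
        d = functional_distance_matrix(g, "weighted_jaccard")
        assert d.values[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_invariants_on_random_gcns(self):
        # symmetry, zero diagonal, [0,1] range across many random matrices
        rng = np.random.default_rng(7)
        for trial in range(1000):
            mat = random_gcn_matrix(rng, max_n=6, max_m=6)
            g = GCN([f"s{i}" for i in range(mat.shape[0])],
                    [f"g{a}" for a in range(mat.shape[1])], mat)
            method = ("weighted_jaccard", "correlation", "sorensen")[trial % 3]
            d = functional_distance_matrix(g, method).values
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0.0)
            assert d.min() >= 0.0 and d.max() <= 1.0

    def test_jaccard_zero_iff_identical_one_iff_disjoint(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            mat = random_gcn_matrix(rng, max_n=5, max_m=5)
            g = GCN([f"s{i}" for i in range(mat.shape[0])],
                    [f"g{a}" for a in range(mat.shape[1])], mat)
            d = functional_distance_matrix(g, "weighted_jaccard").values
            for i in range(g.n_species):
                for j in range(i + 1, g.n_species):
                    identical = (mat[i] == mat[j]).all()
                    disjoint = not ((mat[i] > 0) & (mat[j] > 0)).any()
                    if identical:
                        assert d[i, j] == pytest.approx(0.0, abs=1e-12)
                    else:
                        assert d[i, j] > 0
                    if disjoint:
                        assert d[i, j] == pytest.approx(1.0, abs=1e-12)
                    else:
                        assert d[i, j] < 1


class TestDegrees:
    def test_identity_matrix(self):
        g = GCN(["a", "b"], ["x", "y"], np.eye(2, dtype=int))
        deg = degree_profiles(g)
        assert list(deg.species_unweighted) == [1, 1]
        assert list(deg.gene_unweighted) == [1, 1]

    def test_weighted_row_column_sums(self):
        g = GCN(["a", "b"], ["x", "y"], np.array([[2, 1], [0, 3]]))
        deg = degree_profiles(g)
        assert list(deg.species_weighted) == [3, 3]
        assert list(deg.gene_weighted) == [2, 4]
        assert list(deg.species_unweighted) == [2, 1]

    def test_all_ones(self):
        g = GCN([f"s{i}" for i in range(3)], [f"g{a}" for a in range(5)],
                np.ones((3, 5), dtype=int))
        deg = degree_profiles(g)
        assert (deg.species_unweighted == 5).all()
        assert (deg.gene_unweighted == 3).all()


class TestDistanceHistogram:
    def test_single_pair_placement(self):
        g = GCN(["a", "b"], ["x", "y", "z"], np.array([[2, 1, 0], [1, 1, 1]]))
        d = functional_distance_matrix(g, "weighted_jaccard")  # d12 = 0.5
        hist = distance_histogram(d, bin_width=0.02)
        hit = hist[hist["count"] > 0]
        assert len(hit) == 1
        assert hit["bin_left"].iloc[0] == pytest.approx(0.50)
        assert hit["count"].iloc[0] == 1

    def test_identical_genomes_all_in_first_bin(self):
        g = GCN(["a", "b", "c"], ["x", "y"], np.tile([1, 2], (3, 1)))
        d = functional_distance_matrix(g)
        hist = distance_histogram(d)
        assert hist["count"].iloc[0] == 3
        assert hist["count"].sum() == 3

    def test_pair_count_conserved(self, random_gcn):
        d = functional_distance_matrix(random_gcn)
        n = random_gcn.n_species
        for bw in (0.02, 0.07, 0.5):
            hist = distance_histogram(d, bin_width=bw)
            assert hist["count"].sum() == n * (n - 1) // 2

    def test_invalid_bin_width(self, random_gcn):
        d = functional_distance_matrix(random_gcn)
        with pytest.raises(ValueError):
            distance_histogram(d, bin_width=0.0)


class TestAlignment:
    def test_unmatched_species_raise_by_default(self, random_gcn):
        profiles = pd.DataFrame(
            [[0.5, 0.5]], index=["s1"], columns=[random_gcn.species[0], "ghost"]
        )
        with pytest.raises(AlignmentError):
            align_profiles(profiles, random_gcn)

    def test_drop_renormalizes(self, random_gcn):
        profiles = pd.DataFrame(
            [[0.5, 0.25, 0.25]],
            index=["s1"],
            columns=[random_gcn.species[0], random_gcn.species[1], "ghost"],
        )
        aligned = align_profiles(profiles, random_gcn, on_unmatched="drop")
        assert aligned.shape == (1, random_gcn.n_species)
        assert aligned.to_numpy().sum() == pytest.approx(1.0)
        assert aligned.iloc[0, 0] == pytest.approx(2 / 3)
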