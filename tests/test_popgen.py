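import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from slrkit import popgen
from slrkit.popgen import (DistanceMatrix, FstWindow, neighbor_joining, p_distance,
                           pca, region_fst_summary, wc_fst_components, wc_fst_windows)
from slrkit.regions import RegionMap


class TestPDistance:
    def test_identical_samples_zero(self):
        m = make_matrix(np.tile([0, 1, 2], (2, 1)).T, "FM")
        d = p_distance(m)
        assert d.values[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        g = np.column_stack([np.zeros(20), np.full(20, 2)]).astype(np.int8)
        m = make_matrix(g, "FM")
        assert p_distance(m).values[0, 1] == 1.0

    def test_all_nine_genotype_pairs(self):
        """Every diploid genotype pair at a single shared site follows
        |dosage_i - dosage_j| / 2."""
        for a, b in itertools.product([0, 1, 2], repeat=2):
            m = make_matrix(np.array([[a, b]]), "FM")
            assert p_distance(m).values[0, 1] == abs(a - b) / 2

    def test_missing_pairs_error_names_samples(self):
        g = np.array([[0, -1], [-1, 0]], dtype=np.int8)
        m = make_matrix(g, "FM")
        with pytest.raises(ValueError, match="s0 and s1"):
            p_distance(m)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        g = rng.choice([-1, 0, 1, 2], size=(100, 8), p=[0.05, 0.45, 0.3, 0.2])
        sexes = np.array(list("FM" * 4))
        base = p_distance(make_matrix(g, sexes)).values
        perm = rng.permutation(8)
        shuffled = p_distance(make_matrix(g[:, perm], sexes[perm])).values
        assert np.allclose(shuffled, base[np.ix_(perm, perm)])


def _leaf_distances(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = pdm.distance(taxa[i], taxa[j])
    return [t.label for t in taxa], out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        t = neighbor_joining(DistanceMatrix(list("ABC"), D))
        labels, got = _leaf_distances(t.newick)
        assert labels == ["A", "B", "C"]
        assert np.allclose(got, D)

    def test_four_taxon_additive_recovery(self):
        # generated from tree ((A:1,B:2):1.5,(C:3,D:4)); an exact path-length
        # match on an additive matrix pins down the generating topology
        D = np.array([[0, 3, 5.5, 6.5],
                      [3, 0, 6.5, 7.5],
                      [5.5, 6.5, 0, 7],
                      [6.5, 7.5, 7, 0]], float)
        t = neighbor_joining(DistanceMatrix(list("ABCD"), D))
        labels, got = _leaf_distances(t.newick)
        assert np.allclose(got, D, atol=1e-10)
        assert "(A:1,B:2)" in t.newick.replace(" ", "")

    def test_matches_reference_nj_on_random_additive_matrices(self):
        """Path-length equivalence against scikit-bio's NJ on random additive
        distance matrices (independent oracle)."""
        import random

        import skbio

        r = random.Random(7)
        for rep in range(5):
            n = 6
            ids = [f"t{i}" for i in range(n)]
            # random additive matrix: join random subtrees with random lengths
            frags = list(ids)
            while len(frags) > 3:
                a, b = r.sample(frags, 2)
                frags.remove(a)
                frags.remove(b)
                frags.append(f"({a}:{r.uniform(0.5, 2.0):.4f},"
                             f"{b}:{r.uniform(0.5, 2.0):.4f})")
            newick = "(" + ",".join(f"{f}:{r.uniform(0.5, 2.0):.4f}"
                                    for f in frags) + ");"
            _, D = _leaf_distances(newick)
            sorted_ids = sorted(ids)
            ours = neighbor_joining(DistanceMatrix(sorted_ids, D))
            _, got = _leaf_distances(ours.newick)
            ref = skbio.tree.nj(skbio.DistanceMatrix(D, sorted_ids))
            ref_d = np.array([[ref.find(a).distance(ref.find(b)) for b in sorted_ids]
                              for a in sorted_ids])
            assert np.allclose(got, ref_d, atol=1e-8)

    def test_identical_rows_join_as_siblings(self):
        D = np.array([[0, 0, 4, 4], [0, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float)
        t = neighbor_joining(DistanceMatrix(list("ABCD"), D))
        labels, got = _leaf_distances(t.newick)
        i, j = labels.index("A"), labels.index("B")
        assert got[i, j] == 0.0

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(list("AB"), np.array([[0, 1], [2, 0]], float))


class TestPCA:
    def test_duplicated_sample_identical_coordinates(self):
        rng = np.random.default_rng(1)
        g = rng.choice([0, 1, 2], size=(200, 6)).astype(np.int8)
        g[:, 5] = g[:, 4]
        m = make_matrix(g, "FM" * 3)
        coords, frac = pca(m, n_components=3)
        assert np.allclose(coords[4], coords[5], atol=1e-8)
        assert (frac >= 0).all() and frac.sum() <= 1 + 1e-9

    def test_no_polymorphic_sites_errors(self):
        m = make_matrix(np.zeros((10, 4)), "FFMM")
        with pytest.raises(ValueError, match="polymorphic"):
            pca(m)


class TestWcFst:
    def test_fixed_difference_gives_one(self):
        g = np.zeros((5, 12), dtype=np.int8)
        g[:, 6:] = 2
        m = make_matrix(g, "FM" * 6, groups=["p1"] * 6 + ["p2"] * 6)
        windows = wc_fst_windows(m, "p1", "p2", window=100, step=100)
        assert all(w.fst == pytest.approx(1.0) for w in windows)

    def test_panmixia_near_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, 10_000)
        g = rng.binomial(2, p[:, None], size=(10_000, 100)).astype(np.int8)
        m = make_matrix(g, "FM" * 50, groups=["p1"] * 50 + ["p2"] * 50)
        windows = wc_fst_windows(m, "p1", "p2", window=1000, step=1000)
        assert abs(np.mean([w.fst for w in windows])) < 0.01

    def test_single_site_matches_hand_computation(self):
        """One site, hand-specified genotype counts: pop1 = 3/5/2 hom-ref/het/
        hom-alt, pop2 = 6/1/1; scalar Weir-Cockerham arithmetic gives
        a = 0.01902832, b = 0.05377604, c = 1/6, FST = 0.07945980."""
        g = np.array([[0] * 3 + [1] * 5 + [2] * 2 + [0] * 6 + [1] + [2]], dtype=np.int8)
        m = make_matrix(g, "FM" * 9, groups=["p1"] * 10 + ["p2"] * 8)
        comp = wc_fst_components(m, "p1", "p2")
        assert comp.loc[0, "a"] == pytest.approx(0.019028320312500003)
        assert comp.loc[0, "b"] == pytest.approx(0.05377604166666672)
        assert comp.loc[0, "c"] == pytest.approx(1 / 6)
        (w,) = wc_fst_windows(m, "p1", "p2", window=10, step=10)
        assert w.fst == pytest.approx(0.0794598011296056)

    def test_label_swap_symmetry_and_order_invariance(self):
        rng = np.random.default_rng(3)
        g = rng.choice([0, 1, 2, -1], size=(300, 40), p=[0.4, 0.3, 0.25, 0.05])
        m = make_matrix(g, "FM" * 20, groups=["p1", "p2"] * 20)
        fwd = wc_fst_windows(m, "p1", "p2", window=50, step=50)
        rev = wc_fst_windows(m, "p2", "p1", window=50, step=50)
        assert np.allclose([w.fst for w in fwd], [w.fst for w in rev])
        perm = rng.permutation(40)
        sexes = np.array(list("FM" * 20))[perm]
        groups = list(np.array(["p1", "p2"] * 20)[perm])
        m2 = make_matrix(g[:, perm], sexes, groups=groups)
        shuffled = wc_fst_windows(m2, "p1", "p2", window=50, step=50)
        assert np.allclose([w.fst for w in fwd], [w.fst for w in shuffled])

    def test_window_tiling(self):
        rng = np.random.default_rng(4)
        g = rng.choice([0, 1, 2], size=(2000, 20))
        m = make_matrix(g, "FM" * 10, groups=["p1"] * 10 + ["p2"] * 10,
                        pos=np.arange(1, 2001))
        windows = wc_fst_windows(m, "p1", "p2", window=500, step=100,
                                 chrom_length=2000)
        starts = [w.start for w in windows]
        assert all(b - a == 100 for a, b in zip(starts, starts[1:]))
        # interior sites contribute to window/step = 5 windows
        pos0 = 999
        n_covering = sum(w.start <= pos0 < w.end for w in windows)
        assert n_covering == 5

    def test_absent_population_errors(self):
        m = make_matrix(np.zeros((2, 4)), "FFMM", groups=["p1"] * 4)
        with pytest.raises(ValueError, match="absent"):
            wc_fst_windows(m, "p1", "p2")


class TestRegionFstSummary:
    RMAP = RegionMap.from_layout("chrY", [("PAR1", 1000), ("IV", 1000), ("YDR", 1000)])

    def windows(self, values, start=0, width=200):
        return [FstWindow("chrY", start + i * width, start + (i + 1) * width, v, 10)
                for i, v in enumerate(values)]

    def test_equal_windows_equal_means_p_one(self):
        w = self.windows([0.1] * 15)
        table, p = region_fst_summary(w, self.RMAP)
        assert (table["mean_fst"] == 0.1).all()
        assert p == 1.0

    def test_single_window_contrast_refuses(self):
        w = self.windows([0.1], start=0) + self.windows([0.2], start=1000) \
            + self.windows([0.2], start=2000)
        with pytest.raises(ValueError, match=">= 2 windows"):
            region_fst_summary(w, self.RMAP)

    def test_missing_region_errors(self):
        w = self.windows([0.1] * 5)  # PAR1 only
        with pytest.raises(ValueError, match="without windows"):
            region_fst_summary(w, self.RMAP)
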