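import itertools

import numpy as np
import pytest

from dompop import (
    DistanceMatrix,
    geographic_distances,
    haversine_km,
    mantel,
    nei_distance_matrix,
    nei_unbiased_distance,
    pcoa,
    upgma,
)
from dompop.core import PopulationSite
from dompop.datasets import load_nei_distances, load_sampling_sites


def random_distance_matrix(rng, n):
    pts = rng.random((n, 3)) * 10
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix([f"T{chr(65 + i)}" for i in range(n)], d)


class TestNeiDistance:
    def test_identical_frequencies_large_n_near_zero(self):
        q = np.array([0.3, 0.5, 0.7])
        d = nei_unbiased_distance(q, q, 10**6, 10**6)
        assert abs(d) < 1e-5

    def test_one_locus_direct_evaluation(self):
        # qX=0.6, qY=0.9, nX=nY=20: Jxy=0.58, Jx=19.8/39, Jy=31.8/39
        jxy = 0.4 * 0.1 + 0.6 * 0.9
        jx = (2 * 20 * (0.4**2 + 0.6**2) - 1) / 39
        jy = (2 * 20 * (0.1**2 + 0.9**2) - 1) / 39
        expected = -np.log(jxy / np.sqrt(jx * jy))
        got = nei_unbiased_distance(np.array([0.6]), np.array([0.9]), 20, 20)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.1037396, abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        qx, qy = rng.random(30), rng.random(30)
        assert nei_unbiased_distance(qx, qy, 15, 22) == pytest.approx(
            nei_unbiased_distance(qy, qx, 22, 15)
        )

    def test_matrix_from_simulation(self, small_sim):
        m, _ = small_sim
        d = nei_distance_matrix(m)
        assert (d.condensed() > 0).all()


class TestUpgma:
    def test_two_taxa(self):
        d = DistanceMatrix(["A", "B"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        tree = upgma(d)
        assert tree.root.height == 1.0
        assert tree.newick() == "(A:1,B:1);"

    def test_three_taxon_hand_trace(self):
        vals = np.array([[0, 2, 8], [2, 0, 6], [8, 6, 0]], dtype=float)
        tree = upgma(DistanceMatrix(["A", "B", "C"], vals))
        assert tree.merge_order == [("A", "B", 2.0), ("A", "C", 7.0)]
        assert tree.root.height == 3.5

    def test_matches_average_linkage_heights(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(11)
        for n in (4, 5, 6, 7):
            d = random_distance_matrix(rng, n)
            z = linkage(squareform(d.values), method="average")
            expected = sorted(z[:, 2])
            got = sorted(dist for _, _, dist in upgma(d).merge_order)
            assert np.allclose(got, expected)

    def test_ultrametric_and_newick_parses(self):
        import dendropy

        rng = np.random.default_rng(12)
        d = random_distance_matrix(rng, 6)
        tree = upgma(d)
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        depths = []
        for leaf in parsed.leaf_node_iter():
            depth = 0.0
            node = leaf
            while node.parent_node is not None:
                depth += node.edge.length or 0.0
                node = node.parent_node
            depths.append(depth)
        assert np.allclose(depths, depths[0])

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            d = random_distance_matrix(rng, rng.integers(3, 8))
            dists = [dist for _, _, dist in upgma(d).merge_order]
            assert all(a <= b + 1e-12 for a, b in zip(dists, dists[1:]))

    def test_tie_break_lexicographic(self):
        # B-C and A-D tie at distance 1; A-D merges first (A < B)
        labels = ["A", "B", "C", "D"]
        vals = np.full((4, 4), 5.0)
        np.fill_diagonal(vals, 0.0)
        vals[1, 2] = vals[2, 1] = 1.0
        vals[0, 3] = vals[3, 0] = 1.0
        tree = upgma(DistanceMatrix(labels, vals))
        assert tree.merge_order[0] == ("A", "D", 1.0)

    def test_study_fixture_three_groups(self):
        tree = upgma(load_nei_distances())
        groups = {frozenset(g) for g in tree.cut(3)}
        assert groups == {
            frozenset({"WZT"}),
            frozenset({"SDG", "SEG", "XV", "TF", "SP"}),
            frozenset({"YMF", "FHB"}),
        }


def tree_heights(d):
    return upgma(d).merge_order


class TestPcoa:
    def test_collinear_points_single_axis(self):
        pts = np.array([0.0, 1.0, 2.0])
        vals = np.abs(pts[:, None] - pts[None, :])
        res = pcoa(DistanceMatrix(["a", "b", "c"], vals))
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_square_corners_split_evenly(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        vals = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(list("abcd"), vals))
        assert res.percent_variance[0] == pytest.approx(50.0)
        assert res.percent_variance[1] == pytest.approx(50.0)

    def test_euclidean_embedding_reconstructs_distances(self):
        rng = np.random.default_rng(14)
        pts = rng.random((6, 2))
        vals = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"p{i}" for i in range(6)], vals))
        coords = res.coordinates
        rec = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        assert np.allclose(rec, vals, atol=1e-9)

    def test_percentages_sum_and_order(self):
        rng = np.random.default_rng(15)
        d = random_distance_matrix(rng, 7)
        res = pcoa(d)
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)
        assert (np.diff(res.percent_variance) <= 1e-9).all()

    def test_against_reference_implementation(self):
        import warnings

        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(16)
        d = random_distance_matrix(rng, 6)
        res = pcoa(d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = skbio_pcoa(d.values)
        ref_prop = np.asarray(ref.proportion_explained)[: len(res.percent_variance)]
        assert np.allclose(res.percent_variance / 100, ref_prop, atol=1e-8)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestGeographicDistances:
    def test_identical_points_zero_and_symmetry(self):
        sites = [
            PopulationSite(name="a", longitude=103.5, latitude=31.5),
            PopulationSite(name="b", longitude=103.5, latitude=31.5),
            PopulationSite(name="c", longitude=104.0, latitude=32.0),
        ]
        d = geographic_distances(sites)
        assert d[("a", "b")] == 0.0
        assert d[("a", "c")] == d[("c", "a")] > 0

    def test_against_law_of_cosines_oracle(self):
        # independent great-circle formula on the FHB-SDG site pair
        sites = {s.name: s for s in load_sampling_sites()}
        fhb, sdg = sites["FHB"], sites["SDG"]
        phi1, phi2 = np.radians(fhb.latitude), np.radians(sdg.latitude)
        dlam = np.radians(sdg.longitude - fhb.longitude)
        ang = np.arccos(
            np.sin(phi1) * np.sin(phi2) + np.cos(phi1) * np.cos(phi2) * np.cos(dlam)
        )
        expected = 6371.0088 * ang
        got = haversine_km(fhb.latitude, fhb.longitude, sdg.latitude, sdg.longitude)
        assert got == pytest.approx(expected, abs=1e-6)
        assert 5 < got < 12  # order of 8 km


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(17)
        d = random_distance_matrix(rng, 5)
        r, p = mantel(d, d, exhaustive=True)
        assert r == pytest.approx(1.0)

    def test_affine_invariance(self):
        # d2 = a + b*d1 (off-diagonal, b > 0) leaves r = 1
        rng = np.random.default_rng(18)
        d1 = random_distance_matrix(rng, 5)
        vals = 0.3 + 2.0 * d1.values
        np.fill_diagonal(vals, 0.0)
        d2 = DistanceMatrix(d1.labels, vals)
        r, _ = mantel(d1, d2, exhaustive=True)
        assert r == pytest.approx(1.0)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(19)
        d1 = random_distance_matrix(rng, 4)
        d2 = random_distance_matrix(rng, 4)
        d2 = DistanceMatrix(d1.labels, d2.values)
        r_obs, p = mantel(d1, d2)  # n=4 -> exhaustive automatically
        tri = np.tril_indices(4, k=-1)
        x = d1.values[tri]
        hits = 0
        for perm in itertools.permutations(range(4)):
            y = d2.values[np.ix_(perm, perm)][tri]
            if abs(np.corrcoef(x, y)[0, 1]) >= abs(r_obs) - 1e-12:
                hits += 1
        assert p == pytest.approx(hits / 24)

    def test_agrees_with_reference_statistic(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(20)
        d1 = random_distance_matrix(rng, 8)
        d2 = DistanceMatrix(d1.labels, random_distance_matrix(rng, 8).values)
        r, _ = mantel(d1, d2, n_perm=99, seed=1, exhaustive=False)
        r_ref, _, _ = skbio_mantel(
            SkbioDM(d1.values, d1.labels), SkbioDM(d2.values, d2.labels),
            permutations=0,
        )
        assert r == pytest.approx(r_ref, abs=1e-10)

    def test_joint_relabeling_invariance(self):
        rng = np.random.default_rng(21)
        d1 = random_distance_matrix(rng, 5)
        d2 = DistanceMatrix(d1.labels, random_distance_matrix(rng, 5).values)
        r1, _ = mantel(d1, d2, exhaustive=True)
        perm = rng.permutation(5)
        labels = [d1.labels[i] for i in perm]
        d1p = d1.reorder(labels)
        d2p = d2.reorder(labels)
        r2, _ = mantel(d1p, d2p, exhaustive=True)
        assert r1 == pytest.approx(r2, abs=1e-12)
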