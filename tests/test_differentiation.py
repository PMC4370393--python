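import numpy as np
import pytest

from dompop import (
    amova,
    gene_flow,
    gst,
    ld_percent,
    ld_screen,
    pairwise_fst,
    simulate,
)
from dompop.core import BinaryMarkerMatrix
from dompop.differentiation import gst_from_frequencies
from tests.conftest import random_matrix


def amova_oracle(calls: np.ndarray, groups: np.ndarray):
    """Independent AMOVA via the centroid (sum-of-squares) formulation.

    For squared Euclidean distances the pairwise-distance SSDs equal the
    deviations from (sub)centroids, so this avoids the implementation's
    pairwise route entirely.
    """
    x = calls.astype(float)
    n = x.shape[0]
    ssd_total = ((x - x.mean(axis=0)) ** 2).sum()
    ssd_within = 0.0
    sizes = []
    for g in np.unique(groups):
        sub = x[groups == g]
        sizes.append(len(sub))
        ssd_within += ((sub - sub.mean(axis=0)) ** 2).sum()
    sizes = np.array(sizes)
    n_pops = len(sizes)
    ssd_among = ssd_total - ssd_within
    df_a, df_w = n_pops - 1, n - n_pops
    ms_w = ssd_within / df_w
    n0 = (n - (sizes**2).sum() / n) / df_a
    sigma_a = (ssd_among / df_a - ms_w) / n0
    phi = sigma_a / (sigma_a + ms_w)
    return ssd_among, ssd_within, sigma_a, ms_w, phi


class TestGst:
    def test_identical_populations_zero(self):
        q = np.tile(np.array([0.3, 0.6, 0.9]), (4, 1))
        assert gst_from_frequencies(q) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_population_case(self):
        # q = 0.2 and 0.8: Hs = 0.32, Ht = 0.5 -> Gst = 0.36
        assert gst_from_frequencies(np.array([[0.2], [0.8]])) == pytest.approx(0.36)

    def test_fixed_opposite_alleles_maximal(self):
        assert gst_from_frequencies(np.array([[0.0], [1.0]])) == pytest.approx(1.0)

    def test_matrix_interface(self, small_sim):
        m, _ = small_sim
        assert 0.0 < gst(m) < 1.0


class TestAmova:
    def test_fully_differentiated_populations(self):
        calls = np.vstack([np.tile([1, 1, 0], (4, 1)), np.tile([0, 0, 1], (4, 1))])
        m = BinaryMarkerMatrix(
            calls=calls.astype(np.int8),
            individual_ids=[f"i{j}" for j in range(8)],
            populations=["A"] * 4 + ["B"] * 4,
            locus_ids=["x", "y", "z"],
        )
        res = amova(m, n_perm=0)
        assert res.percent_among == pytest.approx(100.0)
        assert res.phi_st == pytest.approx(1.0)

    def test_ssd_additivity_and_percent_sum(self, toy_matrix):
        res = amova(toy_matrix, n_perm=0)
        assert res.ssd_total == pytest.approx(res.ssd_among + res.ssd_within)
        assert res.percent_among + res.percent_within == pytest.approx(100.0)

    def test_matches_centroid_oracle_on_random_matrices(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            n_pops = rng.integers(2, 5)
            n_per = rng.integers(2, 6)
            n_loci = rng.integers(2, 9)
            m = random_matrix(rng, n_pops, n_per, n_loci)
            groups = np.array([int(p[1:]) for p in m.populations])
            if amova_oracle(m.calls, groups)[1] == 0:
                continue  # degenerate within-SSD; tested separately
            res = amova(m, n_perm=0)
            exp_among, exp_within, exp_sa, exp_sw, exp_phi = amova_oracle(
                m.calls, groups
            )
            assert res.ssd_among == pytest.approx(exp_among, abs=1e-9)
            assert res.ssd_within == pytest.approx(exp_within, abs=1e-9)
            assert res.sigma2_among == pytest.approx(exp_sa, abs=1e-9)
            assert res.sigma2_within == pytest.approx(exp_sw, abs=1e-9)
            assert res.phi_st == pytest.approx(exp_phi, abs=1e-9)

    def test_null_data_phi_near_zero(self):
        m, _ = simulate(4, 25, 80, theta=0.0, f=0.0, seed=21)
        res = amova(m, n_perm=199, seed=5)
        assert abs(res.phi_st) < 0.02
        assert res.p_value > 0.05

    def test_all_identical_individuals_undefined(self):
        m = BinaryMarkerMatrix(
            calls=np.ones((6, 3), dtype=np.int8),
            individual_ids=[f"i{j}" for j in range(6)],
            populations=["A"] * 3 + ["B"] * 3,
            locus_ids=["x", "y", "z"],
        )
        res = amova(m, n_perm=0)
        assert not res.defined

    def test_permutation_needs_seed(self, toy_matrix):
        with pytest.raises(ValueError, match="seed"):
            amova(toy_matrix, n_perm=10, seed=None)


class TestPairwiseFst:
    def test_single_population_split_near_zero(self):
        # two labels drawn from one panmictic pool should show no structure
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 2, (40, 60)).astype(np.int8)
        m = BinaryMarkerMatrix(
            calls=calls,
            individual_ids=[f"i{j}" for j in range(40)],
            populations=["A"] * 20 + ["B"] * 20,
            locus_ids=[f"l{j}" for j in range(60)],
        )
        fst, _ = pairwise_fst(m)
        assert abs(fst[("A", "B")]) < 0.05

    def test_pairwise_consistent_with_overall_differentiation(self):
        # band-state Phi-st sits somewhat above the allele-level theta under
        # dominance; pairwise and overall estimates must agree with each other
        m, _ = simulate(8, 50, 500, theta=0.2, f=0.0, seed=30)
        fst, _ = pairwise_fst(m)
        mean_off = fst.condensed().mean()
        overall = amova(m, n_perm=0).phi_st
        assert mean_off == pytest.approx(overall, abs=0.02)
        assert 0.15 < mean_off < 0.33


class TestGeneFlow:
    @pytest.mark.parametrize(
        "fst, nm", [(0.1897, 1.0678), (0.2, 1.0), (0.5, 0.25)]
    )
    def test_island_model_values(self, fst, nm):
        assert gene_flow(fst).nm == pytest.approx(nm, abs=1e-4)

    def test_strictly_decreasing_in_fst(self):
        grid = np.linspace(0.01, 0.99, 50)
        nms = [gene_flow(v).nm for v in grid]
        assert all(a > b for a, b in zip(nms, nms[1:]))

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            gene_flow(bad)


class TestLdScreen:
    def test_percent_arithmetic(self):
        assert ld_percent(745, 32400) == 2.3
        assert ld_percent(0, 100) == 0.0

    def test_duplicated_locus_detected(self):
        rng = np.random.default_rng(8)
        col = rng.integers(0, 2, 40).astype(np.int8)
        other = rng.integers(0, 2, (40, 3)).astype(np.int8)
        calls = np.column_stack([col, col, other])
        m = BinaryMarkerMatrix(
            calls=calls,
            individual_ids=[f"i{j}" for j in range(40)],
            populations=["P"] * 40,
            locus_ids=[f"l{j}" for j in range(5)],
        )
        res = ld_screen(m, alpha=0.05)
        assert res["n_significant"] >= 1

    def test_ordered_convention_denominator(self):
        m, _ = simulate(2, 10, 12, theta=0.0, f=0.0, seed=9, pi_range=(0.3, 0.7))
        res_u = ld_screen(m)
        res_o = ld_screen(m, pair_convention="ordered")
        n_poly = res_u["n_pairs_tested"]
        # unordered C(L,2) vs ordered L^2
        L = (1 + np.sqrt(1 + 8 * n_poly)) / 2
        assert res_o["n_pairs_tested"] == int(round(L)) ** 2
        assert res_o["n_significant"] == 2 * res_u["n_significant"]
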