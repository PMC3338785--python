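import itertools

import numpy as np
import pytest

from itsdiv.differentiation import (
    fst_from_distances,
    fst_permutation_test,
    pairwise_fst,
)
from itsdiv.errors import ParameterError
from itsdiv.partitions import Partition
from itsdiv.site_stats import raw_difference_matrix

from conftest import aln_from, two_haplotype_alignment


def amova_oracle(d, idx_a, idx_b):
    """Exhaustive SSD decomposition with explicit loops over all pairs."""
    n1, n2 = len(idx_a), len(idx_b)
    N = n1 + n2
    pooled = list(idx_a) + list(idx_b)
    ss_total = sum(d[i][j] for i, j in itertools.combinations(pooled, 2)) / N
    ss_a = sum(d[i][j] for i, j in itertools.combinations(idx_a, 2)) / n1
    ss_b = sum(d[i][j] for i, j in itertools.combinations(idx_b, 2)) / n2
    ss_within = ss_a + ss_b
    ss_among = ss_total - ss_within
    sigma_w = ss_within / (N - 2) if N > 2 else 0.0
    n_prime = N - (n1 ** 2 + n2 ** 2) / N
    sigma_a = (ss_among - sigma_w) / n_prime
    if sigma_a + sigma_w == 0:
        return 0.0
    return sigma_a / (sigma_a + sigma_w)


def two_pop_partition(aln, n1):
    return Partition("user", {"A": aln.ids[:n1], "B": aln.ids[n1:]})


class TestPointEstimates:
    @pytest.mark.parametrize("estimator", ["nei_ratio", "amova"])
    def test_monomorphic_distinct_populations_fixed(self, estimator):
        aln = two_haplotype_alignment((5, 3), n_tv=4, length=60)
        fm = pairwise_fst(aln, two_pop_partition(aln, 5), estimator)
        assert fm.pair("A", "B") == 1.0

    @pytest.mark.parametrize("estimator", ["nei_ratio", "amova"])
    def test_identical_populations_zero(self, estimator):
        aln = aln_from(["ACGTACGT"] * 6)
        fm = pairwise_fst(aln, two_pop_partition(aln, 3), estimator)
        assert fm.pair("A", "B") == 0.0

    def test_nei_ratio_engineered_distance_matrix(self):
        """pop A: pairwise diffs (0, 8, 8); pop B: 6/2 split at 8 columns;
        all cross pairs at 7 -> Fst = 1 - 4.381/7 = 0.374."""
        nA, nB = 3, 8
        d = np.full((nA + nB, nA + nB), 7.0)
        dA = np.array([[0, 8, 8], [8, 0, 0], [8, 0, 0]], dtype=float)
        d[:3, :3] = dA
        dB = np.zeros((8, 8))
        dB[:6, 6:] = 8.0
        dB[6:, :6] = 8.0
        d[3:, 3:] = dB
        np.fill_diagonal(d, 0.0)
        f, raw, _ = fst_from_distances(d, np.arange(3), np.arange(3, 11), "nei_ratio")
        hw = 0.5 * (16 / 3 + 8 * 12 / 28)
        assert f == pytest.approx(1 - hw / 7)
        assert f == pytest.approx(0.374, abs=5e-4)

    def test_amova_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(77)
        for trial in range(25):
            n = int(rng.integers(4, 13))
            n1 = int(rng.integers(2, n - 1))
            arr = rng.choice(list("ACGT"), size=(n, 30))
            for row in range(n):
                cols = rng.choice(30, size=rng.integers(0, 6), replace=False)
                for c in cols:
                    arr[row, c] = rng.choice(list("ACGT-"))
            aln = aln_from(["".join(r) for r in arr])
            _, d = raw_difference_matrix(aln)
            f, raw, _ = fst_from_distances(d, np.arange(n1), np.arange(n1, n), "amova")
            expected = amova_oracle(d.tolist(), list(range(n1)), list(range(n1, n)))
            assert raw == pytest.approx(expected, abs=1e-10)
            assert 0.0 <= f <= 1.0

    def test_estimators_agree_at_boundaries(self):
        distinct = two_haplotype_alignment((4, 4), n_tv=5, length=60)
        same = aln_from(["ACGTACGT"] * 8)
        for aln, expected in ((distinct, 1.0), (same, 0.0)):
            part = two_pop_partition(aln, 4)
            nei = pairwise_fst(aln, part, "nei_ratio").pair("A", "B")
            amova = pairwise_fst(aln, part, "amova").pair("A", "B")
            assert nei == amova == expected

    def test_negative_estimates_clamped_with_raw_retained(self):
        rng = np.random.default_rng(15)
        found = False
        for seed in range(40):
            rng = np.random.default_rng(seed)
            arr = rng.choice(list("ACGT"), size=(6, 25))
            for row in range(6):
                cols = rng.choice(25, size=4, replace=False)
                for c in cols:
                    arr[row, c] = rng.choice(list("ACGT"))
            aln = aln_from(["".join(r) for r in arr])
            fm = pairwise_fst(aln, two_pop_partition(aln, 3), "amova")
            if fm.fst_raw[0, 1] < 0:
                assert fm.pair("A", "B") == 0.0
                found = True
                break
        assert found, "no negative raw estimate encountered in 40 random datasets"

    def test_unknown_estimator_rejected(self):
        aln = aln_from(["ACGT"] * 4)
        with pytest.raises(ParameterError):
            pairwise_fst(aln, two_pop_partition(aln, 2), "weir")


class TestPermutationTest:
    def test_p_bounded_below_by_monte_carlo_floor(self):
        aln = two_haplotype_alignment((8, 8), n_tv=6, length=80)
        fm = fst_permutation_test(aln, two_pop_partition(aln, 8),
                                  n_permutations=50, seed=1)
        assert fm.p_value("A", "B") >= 1 / 51

    def test_two_vs_two_can_never_be_significant(self):
        # only 3 distinct splits of 4 individuals into 2+2 exist
        aln = two_haplotype_alignment((2, 2), n_tv=20, length=80)
        fm = fst_permutation_test(aln, two_pop_partition(aln, 2),
                                  n_permutations=110, seed=9)
        assert fm.p_value("A", "B") >= 1 / 3
        assert fm.p_value("A", "B") > 0.05

    def test_observed_zero_gives_p_one(self):
        aln = aln_from(["ACGTACGT"] * 10)
        fm = fst_permutation_test(aln, two_pop_partition(aln, 5),
                                  n_permutations=40, seed=2)
        assert fm.p_value("A", "B") == 1.0

    def test_deterministic_given_seed(self):
        aln = two_haplotype_alignment((6, 6), n_ts=3, n_tv=2, length=80)
        f1 = fst_permutation_test(aln, two_pop_partition(aln, 6),
                                  n_permutations=60, seed=11)
        f2 = fst_permutation_test(aln, two_pop_partition(aln, 6),
                                  n_permutations=60, seed=11)
        np.testing.assert_array_equal(f1.p_values, f2.p_values)

    def test_p_invariant_to_label_order(self):
        aln = two_haplotype_alignment((6, 6), n_ts=3, n_tv=2, length=80)
        pa = Partition("user", {"A": aln.ids[:6], "B": aln.ids[6:]})
        pb = Partition("user", {"B": aln.ids[6:], "A": aln.ids[:6]})
        f1 = fst_permutation_test(aln, pa, n_permutations=60, seed=13)
        f2 = fst_permutation_test(aln, pb, n_permutations=60, seed=13)
        assert f1.p_value("A", "B") == f2.p_value("A", "B")
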