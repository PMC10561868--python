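"""Unit tests for the spatial-entropy decomposition."""

import math

import numpy as np
import pytest

from spatent import (
    CellPattern,
    DegenerateInputError,
    DistanceBinning,
    PairHistogram,
    ValidationError,
    bin_pairs,
    compute_distance_breaks,
    diversity_baselines,
    enumerate_pair_categories,
    permutation_null_spi,
    residual_entropy_curve,
    shannon_entropy,
    spi_curve,
    spi_from_pattern,
)
from conftest import brute_force_median, brute_force_counts, make_csr_pattern


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "pmf, expected",
        [
            ((0.2, 0.2, 0.2, 0.2, 0.2), math.log(5)),
            ((1.0, 0.0, 0.0), 0.0),
            ((0.5, 0.25, 0.25), 0.5 * math.log(2) + 0.5 * math.log(4)),
        ],
    )
    def test_values(self, pmf, expected):
        assert shannon_entropy(pmf) == pytest.approx(expected, abs=1e-12)

    def test_uniform_is_maximal(self, rng):
        p = rng.dirichlet(np.ones(7))
        assert shannon_entropy(p) <= math.log(7) + 1e-12

    def test_base_conversion(self):
        assert shannon_entropy([0.5, 0.5], base=2) == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [(0.5, 0.6), (-0.1, 1.1), (0.9,)])
    def test_invalid_pmf_rejected(self, bad):
        with pytest.raises(ValidationError):
            shannon_entropy(bad)


class TestPairCategories:
    @pytest.mark.parametrize("J, R", [(1, 1), (2, 3), (5, 15)])
    def test_count(self, J, R):
        assert len(enumerate_pair_categories(J)) == R

    def test_canonical_order(self):
        assert enumerate_pair_categories(["B", "A"]) == [("A", "A"), ("A", "B"), ("B", "B")]

    def test_invalid(self):
        with pytest.raises(ValidationError):
            enumerate_pair_categories(0)


class TestDistanceBreaks:
    def test_single_bin_is_zero_to_median(self, rng):
        pat = make_csr_pattern(rng, 30)
        b = compute_distance_breaks(pat, 1)
        assert b.breaks[0] == 0.0
        assert b.d_max == pytest.approx(brute_force_median(pat.coords.tolist()), rel=1e-12)

    def test_collinear_median(self):
        pat = CellPattern("c", [(0, 0), (1, 0), (2, 0)], np.array(list("AAB")))
        b = compute_distance_breaks(pat, 2)
        assert b.d_max == pytest.approx(1.0)  # median of {1, 1, 2}

    def test_full_k_breaks_strictly_increasing_and_median_anchored(self, rng):
        pat = make_csr_pattern(rng, 300, 3)
        b = compute_distance_breaks(pat, 50)
        assert b.n_bins == 50
        assert np.all(np.diff(b.breaks) > 0)
        assert b.d_max == pytest.approx(brute_force_median(pat.coords.tolist()), rel=1e-12)

    def test_min_distance_floor_mode(self, rng):
        pat = make_csr_pattern(rng, 40)
        b = compute_distance_breaks(pat, 10, floor="min-distance")
        from scipy.spatial.distance import pdist

        assert b.breaks[1] == pytest.approx(pdist(pat.coords).min())

    def test_k_cap_enforced(self, rng):
        with pytest.raises(ValidationError, match="K <= 50"):
            compute_distance_breaks(make_csr_pattern(rng), 51)

    def test_coincident_cells_degenerate(self):
        pat = CellPattern("d", [(1, 1), (1, 1), (1, 1)], np.array(list("AAB")))
        with pytest.raises(DegenerateInputError):
            compute_distance_breaks(pat, 5)


class TestBinPairs:
    def test_two_cells_single_pair_in_last_bin(self):
        pat = CellPattern("p", [(0, 0), (1, 0)], np.array(["A", "B"]))
        binning = compute_distance_breaks(pat, 1)
        hist = bin_pairs(pat, binning)
        assert hist.n_pairs == 1
        r = hist.pair_categories.index(("A", "B"))
        assert hist.counts[r, -1] == 1

    def test_conservation(self, rng):
        from scipy.spatial.distance import pdist

        pat = make_csr_pattern(rng, 80, 4)
        binning = compute_distance_breaks(pat, 12)
        hist = bin_pairs(pat, binning)
        d = pdist(pat.coords)
        assert hist.n_pairs == int(np.sum((d > 0) & (d <= binning.d_max)))

    def test_matches_bruteforce_counts_first_bin_radius(self, rng):
        # 30 cells, 3 types, explicit first range (0, 0.25] as in the
        # worked-example construction with circles of radius 0.25
        pat = make_csr_pattern(rng, 30, 3, side=2.0)
        binning = compute_distance_breaks(pat, 4)
        breaks = np.array([0.0, 0.25, *binning.breaks[2:]])
        binning = DistanceBinning(np.sort(np.unique(breaks)))
        hist = bin_pairs(pat, binning)
        oracle = brute_force_counts(pat.coords.tolist(), pat.types.tolist(), binning.breaks.tolist())
        for r, pair in enumerate(hist.pair_categories):
            for k in range(binning.n_bins):
                assert hist.counts[r, k] == oracle.get((pair, k), 0)

    def test_duplicate_coordinates_excluded_with_warning(self):
        pat = CellPattern("dup", [(0, 0), (0, 0), (1, 0), (0, 1)], np.array(list("ABAB")))
        binning = compute_distance_breaks(pat, 2)
        with pytest.warns(UserWarning, match="distance 0"):
            hist = bin_pairs(pat, binning)
        assert hist.n_pairs < 6

    def test_pmf_consistency(self, rng):
        pat = make_csr_pattern(rng, 60, 2)
        hist = bin_pairs(pat, compute_distance_breaks(pat, 8))
        assert hist.p_joint.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(hist.p_joint.sum(axis=1), hist.p_z, atol=1e-15)
        cols = ~hist.empty_bins
        np.testing.assert_allclose(hist.p_z_given_w[:, cols].sum(axis=0), 1.0, atol=1e-12)


def _hist_from_counts(counts, labels=("A", "B", "C")):
    J = len(labels)
    counts = np.asarray(counts, dtype=np.int64)
    K = counts.shape[1]
    breaks = np.linspace(0, 1, K + 1)
    return PairHistogram(
        counts=counts,
        binning=DistanceBinning(breaks),
        pair_categories=tuple(enumerate_pair_categories(list(labels))),
        labels=tuple(labels),
    )


class TestDecomposition:
    def test_residual_entropy_single_category_bin(self):
        hist = _hist_from_counts(np.array([[5], [0], [0], [0], [0], [0]]))
        assert residual_entropy_curve(hist)[0] == pytest.approx(0.0)

    def test_residual_entropy_uniform_bin(self):
        hist = _hist_from_counts(np.full((6, 1), 3))
        assert residual_entropy_curve(hist)[0] == pytest.approx(math.log(6))

    def test_residual_entropy_toy_counts(self):
        hist = _hist_from_counts(np.array([[2], [1], [1], [0], [0], [0]]))
        assert residual_entropy_curve(hist)[0] == pytest.approx(1.0397207708399179)

    def test_spi_zero_when_conditional_equals_marginal(self):
        # counts proportional across bins -> p(z|w) == p(z) in every bin
        col = np.array([4, 2, 2, 1, 1, 0])
        hist = _hist_from_counts(np.column_stack([3 * col, col, 2 * col]))
        curve = spi_curve(hist)
        np.testing.assert_allclose(curve.spi, 0.0, atol=1e-12)
        assert curve.spatial_information == pytest.approx(0.0, abs=1e-12)

    def test_single_type_pattern_spi_zero(self, rng):
        pat = make_csr_pattern(rng, 40, 1)
        curve = spi_from_pattern(pat, 6)
        defined = ~curve.empty_bins
        np.testing.assert_allclose(curve.spi[defined], 0.0, atol=1e-12)

    def test_decomposition_identity_random_histograms(self, rng):
        """H(Z) = SPI(Z) + H^W(Z) plus bounds, over random histograms."""
        for _ in range(100):
            R, K = int(rng.integers(1, 16)), int(rng.integers(1, 21))
            counts = rng.integers(0, 30, size=(R, K))
            if counts.sum() == 0:
                counts[rng.integers(R), rng.integers(K)] = 1
            J = next(j for j in range(1, 10) if j * (j + 1) // 2 >= R)
            labels = [f"t{i}" for i in range(J)]
            pairs = enumerate_pair_categories(labels)[:R]
            hist = PairHistogram(
                counts=counts.astype(np.int64),
                binning=DistanceBinning(np.linspace(0, 1, K + 1)),
                pair_categories=tuple(pairs),
                labels=tuple(labels),
            )
            curve = spi_curve(hist)
            assert abs(
                curve.total_entropy - curve.spatial_information - curve.residual_entropy
            ) < 1e-10
            defined = ~curve.empty_bins
            assert np.all(curve.spi[defined] >= 0)
            assert 0 <= curve.residual_entropy <= curve.total_entropy + 1e-12
            assert curve.total_entropy <= math.log(R) + 1e-12

    def test_rigid_motion_invariance(self, rng):
        pat = make_csr_pattern(rng, 120, 3)
        base = spi_from_pattern(pat, 15)
        theta = 1.234
        rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
        for coords in (
            pat.coords + np.array([5.0, -3.0]),
            pat.coords @ rot.T,
            pat.coords * np.array([1.0, -1.0]),
        ):
            moved = spi_from_pattern(pat.with_coords(coords), 15)
            np.testing.assert_allclose(moved.spi, base.spi, atol=1e-9, equal_nan=True)
            assert moved.total_entropy == pytest.approx(base.total_entropy, abs=1e-9)


class TestPermutationNull:
    def test_identity_permutation_returns_observed(self, rng):
        pat = make_csr_pattern(rng, 50, 2)

        class IdentityRng(np.random.Generator):
            def __init__(self):
                super().__init__(np.random.PCG64(0))

            def permutation(self, x):  # noqa: A003 - stub
                return np.asarray(x)

        null = permutation_null_spi(pat, 6, n_perm=1, seed=IdentityRng())
        np.testing.assert_allclose(null.curves[0], null.observed, equal_nan=True)

    def test_reproducible_and_csr_mean_near_observed(self, rng):
        pat = make_csr_pattern(rng, 150, 3)
        a = permutation_null_spi(pat, 8, n_perm=50, seed=7)
        b = permutation_null_spi(pat, 8, n_perm=50, seed=7)
        np.testing.assert_array_equal(a.curves, b.curves)
        defined = ~np.isnan(a.observed)
        # labels of a CSR pattern are already exchangeable
        assert np.nanmax(np.abs(a.mean[defined] - a.observed[defined])) < 0.1

    def test_clustered_pattern_exceeds_envelope_at_short_range(self):
        from spatent import simulate_pattern

        pat = simulate_pattern("clustered", n_types=2, cells_per_type=150, seed=3)
        null = permutation_null_spi(pat, 10, n_perm=99, seed=11)
        assert null.observed[0] > null.upper[0]


class TestDiversityBaselines:
    def test_equal_counts(self, rng):
        pat = make_csr_pattern(rng, 100, 5)
        out = diversity_baselines(pat)
        assert out["shannon"] == pytest.approx(math.log(5))
        assert out["simpson"] == pytest.approx(0.8)

    def test_single_type(self, rng):
        pat = make_csr_pattern(rng, 20, 1)
        out = diversity_baselines(pat)
        assert out["shannon"] == 0.0
        assert out["simpson"] == 0.0

    def test_blind_to_spatial_rearrangement(self, rng):
        pat = make_csr_pattern(rng, 60, 4)
        shuffled = pat.with_coords(rng.permutation(pat.coords, axis=0) * 3.0 + 1.0)
        assert diversity_baselines(pat) == diversity_baselines(shuffled)
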