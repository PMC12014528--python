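"""Heterozygosity EM, downsampling calibration, correction, Kruskal-Wallis."""

import itertools

import numpy as np
import pytest

import erosionkit as ek
from erosionkit import hetcal, simdata


def _grid_oracle_phet(two_class, step=1e-4):
    """Brute-force maximization of the two-class mixture likelihood."""
    L = np.asarray(two_class, dtype=float)
    grid = np.arange(0.0, 1.0 + step, step)
    ll = [
        np.log(np.maximum(L[:, 0] * (1 - p) + L[:, 1] * p, 1e-300)).sum()
        for p in grid
    ]
    return grid[int(np.argmax(ll))]


class TestSiteHetLikelihood:
    @pytest.mark.parametrize(
        "triplet,expected",
        [
            ((1, 0, 0), (1, 0)),
            ((0.2, 0.9, 0.1), (0.2, 0.9)),
            ((1, 1, 1), (1, 1)),
        ],
    )
    def test_folding(self, triplet, expected):
        np.testing.assert_allclose(
            hetcal.site_het_likelihood(np.array(triplet)), expected
        )


class TestHeterozygosityEm:
    def test_all_hom_gives_zero(self):
        two = np.tile([1.0, 1e-9], (50, 1))
        assert hetcal.estimate_heterozygosity_em(two).p_het == pytest.approx(0, abs=1e-6)

    def test_sharp_likelihoods_reduce_to_counting(self):
        two = np.array([[1, 1e-9]] * 90 + [[1e-9, 1]] * 10)
        res = hetcal.estimate_heterozygosity_em(two)
        assert res.p_het == pytest.approx(0.10, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_grid_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        two = rng.random((50, 2)) + 1e-3
        res = hetcal.estimate_heterozygosity_em(two, tol=1e-12, max_iter=50_000)
        assert res.p_het == pytest.approx(_grid_oracle_phet(two), abs=2e-4)

    def test_flat_input_returns_initialization_with_flag(self):
        two = np.ones((20, 2))
        res = hetcal.estimate_heterozygosity_em(two)
        assert res.uninformative
        assert res.p_het == pytest.approx(0.001)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(9)
        two = rng.random((100, 2)) + 1e-3
        lls = []
        p = np.array([0.999, 0.001])
        L = two / two.max(axis=1, keepdims=True)
        for _ in range(30):
            mix = L @ p
            lls.append(np.log(mix).sum())
            r = L * p / mix[:, None]
            p = r.sum(axis=0) / L.shape[0]
        assert np.all(np.diff(lls) >= -1e-10)


class TestDownsample:
    def _pileup(self, seed=1):
        cfg = ek.SimConfig(n_sites=50_000, n_historic=1, n_contemporary=1, seed=seed)
        geno, _ = ek.simulate_genotypes(cfg)
        return simdata.simulate_reads(geno, 4.0, 0.001, seed=seed + 1)

    def test_fraction_one_is_identity(self):
        pile = self._pileup()
        ds = hetcal.downsample_pileup(pile, 1.0, seed=2)
        np.testing.assert_array_equal(ds.counts, pile.counts)

    @pytest.mark.parametrize("fraction", [0.0, -0.5, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        pile = self._pileup()
        with pytest.raises(ValueError):
            hetcal.downsample_pileup(pile, fraction)

    def test_retained_count_is_binomial(self):
        pile = self._pileup(seed=3)
        n = int(pile.counts.sum())
        ds = hetcal.downsample_pileup(pile, 0.5, seed=4)
        kept = int(ds.counts.sum())
        sigma = np.sqrt(n * 0.25)
        assert abs(kept - n / 2) < 3 * sigma

    def test_thinning_composes(self):
        """Expected depth after thinning equals fraction x original."""
        pile = self._pileup(seed=5)
        ds = hetcal.downsample_pileup(pile, 0.25, seed=6)
        assert ds.depth.mean() == pytest.approx(0.25 * pile.depth.mean(), rel=0.03)


@pytest.fixture(scope="module")
def calibration_setup():
    """12.3x reference individual plus a 3x sibling with known truth."""
    cfg = ek.SimConfig(
        n_historic=2, n_contemporary=1, n_sites=100_000, theta=0.01,
        n_scaffolds=2, scaffold_length=20_000_000, seed=11,
    )
    geno, truth = ek.simulate_genotypes(cfg)
    pile_hi = simdata.simulate_reads(geno, 12.3, 0.001, seed=12)
    curve = hetcal.build_calibration_curve(pile_hi, 0.001, seed=13, individual=0)
    pile_lo = simdata.simulate_reads(geno, 3.0, 0.001, seed=14)
    return geno, truth, pile_hi, pile_lo, curve


class TestCalibrationCurve:
    def test_default_design_has_fifteen_datasets(self, calibration_setup):
        *_, curve = calibration_setup
        assert len(curve.replicates) == 15
        assert curve.replicates.groupby("fraction").size().tolist() == [3] * 5

    def test_prediction_at_reference_coverage_is_one(self, calibration_setup):
        *_, curve = calibration_setup
        assert float(curve.predict(curve.reference_coverage)) == pytest.approx(1.0)

    def test_expanded_coefficients_agree_with_predict(self, calibration_setup):
        *_, curve = calibration_setup
        for cov in (3.0, 6.0, 9.0):
            assert np.polyval(curve.coefficients, cov) == pytest.approx(
                float(curve.predict(cov))
            )

    def test_curve_monotone_increasing_over_fitted_range(self):
        """Relative heterozygosity rises with coverage (bias shrinks)."""
        for seed in range(5):
            cfg = ek.SimConfig(
                n_historic=1, n_contemporary=1, n_sites=60_000, theta=0.01,
                n_scaffolds=2, scaffold_length=20_000_000, seed=100 + seed,
            )
            geno, _ = ek.simulate_genotypes(cfg)
            pile = simdata.simulate_reads(geno, 12.0, 0.001, seed=200 + seed)
            curve = hetcal.build_calibration_curve(pile, 0.001, seed=300 + seed)
            grid = np.linspace(curve.min_fitted_coverage, curve.reference_coverage, 50)
            pred = curve.predict(grid)
            # monotone up to least-squares noise wiggle, with a clear net rise
            assert np.all(np.diff(pred) > -0.01)
            assert pred[-1] - pred[0] > 0.05

    def test_single_fraction_design_rejected(self, calibration_setup):
        geno, truth, pile_hi, *_ = calibration_setup
        with pytest.raises(ValueError, match="distinct fractions"):
            hetcal.build_calibration_curve(pile_hi, 0.001, fractions=(0.5, 0.5))


class TestApplyCorrection:
    def test_identity_at_reference_coverage(self, calibration_setup):
        *_, curve = calibration_setup
        raw = 0.0007
        assert hetcal.apply_correction(raw, curve.reference_coverage, curve) == raw

    def test_division_by_prediction(self):
        curve = hetcal.CalibrationCurve(
            degree=1, coefficients=np.array([0.0, 0.5]), reference_coverage=10.0,
            replicates=__import__("pandas").DataFrame({"coverage": [5.0, 10.0]}),
            het_full=0.001,
        )
        assert hetcal.apply_correction(0.0007, 8.0, curve) == pytest.approx(0.0014)

    def test_extrapolation_guard_names_range(self, calibration_setup):
        *_, curve = calibration_setup
        with pytest.raises(ValueError, match="calibrated range"):
            hetcal.apply_correction(0.001, 100.0, curve)

    def test_parameter_recovery_at_low_coverage(self, calibration_setup):
        """Correction from a 12x sibling brings a 3x estimate within 15%
        relative of the true heterozygosity."""
        geno, truth, _, pile_lo, curve = calibration_setup
        two = hetcal.individual_site_likelihoods(pile_lo, 1, 0.001)
        raw = hetcal.estimate_heterozygosity_em(two).p_het
        cov = float(pile_lo.depth[1].mean())
        corrected = hetcal.apply_correction(raw, cov, curve)
        h = truth.true_het[1]
        assert abs(corrected - h) / h < 0.15
        # and the correction moves the estimate in the right direction
        assert abs(corrected - h) < abs(raw - h)


class TestWindowedHeterozygosity:
    def test_em_recovers_truth_at_high_coverage(self):
        """Error-free 20x estimates land within 5% relative of simulated truth."""
        cfg = ek.SimConfig(
            n_historic=1, n_contemporary=1, n_sites=100_000, theta=0.01,
            n_scaffolds=2, scaffold_length=20_000_000, seed=21,
        )
        geno, truth = ek.simulate_genotypes(cfg)
        pile = simdata.simulate_reads(geno, 20.0, 0.0, seed=22)
        for i in range(2):
            two = hetcal.individual_site_likelihoods(pile, i, 1e-6)
            est = hetcal.estimate_heterozygosity_em(two).p_het
            assert abs(est - truth.true_het[i]) / truth.true_het[i] < 0.05

    def test_windows_cover_all_individuals(self):
        from erosionkit import gl

        cfg = ek.SimConfig(n_sites=5_000, n_historic=3, n_contemporary=3,
                           n_scaffolds=2, scaffold_length=3_000_000, theta=0.01,
                           seed=23)
        geno, _ = ek.simulate_genotypes(cfg)
        pile = simdata.simulate_reads(geno, 10.0, 0.001, seed=24)
        gls = gl.call_genotype_likelihoods(pile, gl.ErrorModel(rate=0.001))
        win = hetcal.windowed_heterozygosity(gls)
        assert set(win["individual"]) == set(geno.samples)
        assert (win["end"] - win["start"] + 1 == 1_000_000).all()
        per_ind = hetcal.genomewide_heterozygosity(win)
        assert ((per_ind >= 0) & (per_ind <= 1)).all()


class TestKruskalWallis:
    def test_hand_example(self):
        h, p = hetcal.kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert round(h, 4) == 3.8571

    def test_identical_values_degenerate(self):
        h, p = hetcal.kruskal_wallis([[2, 2], [2, 2, 2]])
        assert (h, p) == (0.0, 1.0)

    def test_chi_square_p_close_to_exhaustive_permutation(self):
        """The chi-square approximation tracks the exact permutation
        distribution of H on small two-group instances."""
        rng = np.random.default_rng(5)
        for _ in range(3):
            vals = rng.normal(size=8)
            h_obs, p_chi = hetcal.kruskal_wallis([vals[:4], vals[4:]])
            count = 0
            total = 0
            for comb in itertools.combinations(range(8), 4):
                rest = [i for i in range(8) if i not in comb]
                h, _ = hetcal.kruskal_wallis([vals[list(comb)], vals[rest]])
                count += h >= h_obs - 1e-12
                total += 1
            p_exact = count / total
            assert abs(p_chi - p_exact) < 0.1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            hetcal.kruskal_wallis([[1, 2], []])
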