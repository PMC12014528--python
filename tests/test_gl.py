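"""Genotype likelihoods: error estimation, the GL formula, MAF EM, LRT, filters."""

import numpy as np
import pytest

import erosionkit as ek
from erosionkit import gl, simdata
from conftest import make_pileup_from_counts

A, C, G, T = 0, 1, 2, 3


def counts_for(base_lists):
    """(n_ind, n_sites, 4) counts from per-individual per-site base lists."""
    n_ind = len(base_lists)
    n_sites = len(base_lists[0])
    out = np.zeros((n_ind, n_sites, 4), dtype=np.int32)
    for i, sites in enumerate(base_lists):
        for s, bases in enumerate(sites):
            for b in bases:
                out[i, s, b] += 1
    return out


class TestErrorRate:
    def test_no_mismatch_gives_zero(self):
        pile = make_pileup_from_counts(counts_for([[[A] * 10] * 10]))
        model = gl.estimate_error_rate_from_haploid("A" * 10, pile)
        assert model.rate == 0.0

    def test_direct_count(self):
        # 100 bases over 10 sites, 2 mismatches
        sites = [[A] * 10 for _ in range(10)]
        sites[0] = [A] * 8 + [C, G]
        pile = make_pileup_from_counts(counts_for([sites]))
        model = gl.estimate_error_rate_from_haploid("A" * 10, pile)
        assert model.rate == pytest.approx(0.02)
        assert model.n_bases == 100

    def test_transversion_rate_scales_by_three_halves(self):
        # consensus A: A->G is a transition, A->C and A->T transversions
        sites = [[A] * 7 + [G, C, T] for _ in range(10)]
        pile = make_pileup_from_counts(counts_for([sites]))
        model = gl.estimate_error_rate_from_haploid("A" * 10, pile)
        assert model.rate == pytest.approx(0.3)
        assert model.tv_rate == pytest.approx(1.5 * 20 / 100)

    def test_low_quality_bases_rejected(self):
        pile = make_pileup_from_counts(counts_for([[[A] * 5] * 4]), quality=20.0)
        with pytest.raises(ValueError, match="quality"):
            gl.estimate_error_rate_from_haploid("A" * 4, pile, min_quality=30)


class TestCallGenotypeLikelihoods:
    def test_depth_one_matches_formula(self):
        # one read of the major allele at e = 0.01
        pile = make_pileup_from_counts(counts_for([[[A]], [[A]], [[C]]]))
        gls = gl.call_genotype_likelihoods(pile, gl.ErrorModel(rate=0.01))
        lin = gls.linear()[0, 0]  # individual 0, site 0
        expected = np.array([0.99, 0.496667, 0.003333])
        # expected values are printed to 6 decimals
        np.testing.assert_allclose(lin / lin[0] * 0.99, expected, atol=5e-7)

    def test_depth_zero_is_flat(self):
        pile = make_pileup_from_counts(counts_for([[[]], [[A, C]]]))
        gls = gl.call_genotype_likelihoods(pile, gl.ErrorModel(rate=0.01))
        np.testing.assert_allclose(gls.linear()[0, 0], [1.0, 1.0, 1.0])
        assert not gls.has_data[0, 0]

    def test_het_dominates_with_vanishing_error(self):
        pile = make_pileup_from_counts(counts_for([[[A, C]], [[A]], [[C]]]))
        gls = gl.call_genotype_likelihoods(pile, gl.ErrorModel(rate=1e-9))
        lin = gls.linear()[0, 0]
        assert lin[1] == 1.0
        assert lin[1] / max(lin[0], lin[2]) > 1e6

    def test_major_minor_by_counts_with_base_order_ties(self):
        # G and T tie at 2 each; A has 3 -> major A, minor G (base order)
        pile = make_pileup_from_counts(counts_for([[[A, A, A, G, G, T, T]]]))
        gls = gl.call_genotype_likelihoods(pile, gl.ErrorModel(rate=0.01))
        assert gls.major[0] == A
        assert gls.minor[0] == G

    def test_triplets_depend_only_on_base_counts(self):
        """Read order cannot matter: likelihood is a product over reads."""
        pile1 = make_pileup_from_counts(counts_for([[[A, C, A, C, G]]]))
        pile2 = make_pileup_from_counts(counts_for([[[G, C, C, A, A]]]))
        m = gl.ErrorModel(rate=0.02)
        np.testing.assert_allclose(
            gl.call_genotype_likelihoods(pile1, m).loglik,
            gl.call_genotype_likelihoods(pile2, m).loglik,
        )

    def test_error_free_calls_recover_simulated_truth(self):
        cfg = ek.SimConfig(theta=0.1, n_sites=3000, n_historic=5,
                           n_contemporary=5, seed=11)
        geno, _ = ek.simulate_genotypes(cfg)
        pile = simdata.simulate_reads(geno, 20.0, 0.0, 0.0, seed=12)
        gls = gl.call_genotype_likelihoods(pile, gl.ErrorModel(rate=1e-6))
        best = gls.loglik.argmax(axis=2).T  # minor dose call
        covered = pile.depth >= 2
        # map simulated alt dose onto major/minor orientation
        alt_is_minor = gls.minor == geno.alt
        alt_is_major = gls.major == geno.alt
        oriented = np.where(alt_is_minor, geno.genotypes, np.nan)
        oriented = np.where(alt_is_major, 2 - geno.genotypes, oriented)
        both = covered & ~np.isnan(oriented)
        # at hets both alleles must be sampled to be unambiguous
        sampled_both = (pile.counts > 0).sum(axis=2) >= 2
        unambiguous = both & (sampled_both | (oriented.astype(float) != 1))
        assert np.array_equal(best[unambiguous], oriented[unambiguous].astype(int))


def _grid_oracle_maf(lin_triplets, step=1e-4):
    """Brute-force MAF: grid over f, then a bounded local polish."""
    from scipy.optimize import minimize_scalar

    def ll(f):
        prior = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        return np.log(np.maximum(lin_triplets @ prior, 1e-300)).sum()

    grid = np.arange(0.0, 1.0 + step, step)
    vals = [ll(f) for f in grid]
    best = grid[int(np.argmax(vals))]
    lo, hi = max(0.0, best - 2 * step), min(1.0, best + 2 * step)
    res = minimize_scalar(lambda f: -ll(f), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    return (res.x, -res.fun) if -res.fun >= max(vals) else (best, max(vals))


def _sharp_gls(doses, scaffold="scaf1"):
    """GenotypeLikelihoods with near-certain triplets at the given minor doses."""
    doses = np.asarray(doses)
    n = doses.size
    ll = np.full((1, n, 3), np.log(1e-9))
    ll[0, np.arange(n), doses] = 0.0
    return gl.GenotypeLikelihoods(
        scaffolds=np.array([scaffold], dtype=object),
        positions=np.array([1]),
        major=np.array([A], dtype=np.int8),
        minor=np.array([C], dtype=np.int8),
        loglik=ll,
        samples=[f"i{k}" for k in range(n)],
    )


class TestMafEm:
    def test_all_hom_major_gives_zero(self):
        gls = _sharp_gls([0] * 12)
        assert gl.estimate_maf_em(gls)[0] == pytest.approx(0.0, abs=1e-6)

    def test_all_het_gives_half(self):
        gls = _sharp_gls([1] * 12)
        assert gl.estimate_maf_em(gls)[0] == pytest.approx(0.5, abs=1e-6)

    def test_balanced_homozygotes_match_grid_oracle(self):
        gls = _sharp_gls([0] * 10 + [2] * 10)
        f = gl.estimate_maf_em(gls, tol=1e-10)[0]
        assert f == pytest.approx(0.5, abs=1e-3)
        f_oracle, _ = _grid_oracle_maf(gls.linear()[0])
        assert f == pytest.approx(f_oracle, abs=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_instances_match_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        lin = rng.random((1, n, 3)) + 1e-3
        lin /= lin.max(axis=2, keepdims=True)
        gls = gl.GenotypeLikelihoods(
            scaffolds=np.array(["scaf1"], dtype=object), positions=np.array([1]),
            major=np.array([A], dtype=np.int8), minor=np.array([C], dtype=np.int8),
            loglik=np.log(lin), samples=[f"i{k}" for k in range(n)],
        )
        f = gl.estimate_maf_em(gls, tol=1e-12, max_iter=10_000)[0]
        f_oracle, _ = _grid_oracle_maf(lin[0])
        assert f == pytest.approx(f_oracle, abs=2e-4)

    def test_loglik_nondecreasing_across_iterations(self):
        rng = np.random.default_rng(3)
        lin = rng.random((5, 10, 3)) + 1e-3
        lin /= lin.max(axis=2, keepdims=True)
        gls = gl.GenotypeLikelihoods(
            scaffolds=np.array(["scaf1"] * 5, dtype=object),
            positions=np.arange(1, 6),
            major=np.full(5, A, dtype=np.int8), minor=np.full(5, C, dtype=np.int8),
            loglik=np.log(lin), samples=[f"i{k}" for k in range(10)],
        )
        prev = np.full(5, -np.inf)
        f = np.full(5, 0.2)
        for _ in range(50):
            ll = gl.sites_loglik(gls, f)
            assert np.all(ll >= prev - 1e-9)
            prev = ll
            # one EM sweep via the public API with max_iter=1 from current f
            lin_ = gls.linear()
            prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)
            w = lin_ * prior[:, None, :]
            w /= w.sum(axis=2, keepdims=True)
            f = (w @ np.array([0.0, 1.0, 2.0])).mean(axis=1) / 2


class TestSnpLrt:
    def test_monomorphic_gives_p_one(self):
        gls = _sharp_gls([0] * 10)
        f = gl.estimate_maf_em(gls)
        assert gl.snp_lrt(gls, f)[0] == 1.0

    def test_twenty_sharp_hets_highly_significant(self):
        gls = _sharp_gls([1] * 20)
        f = gl.estimate_maf_em(gls)
        assert gl.snp_lrt(gls, f)[0] < 1e-6

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_statistic_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        lin = rng.random((1, n, 3)) + 1e-2
        lin /= lin.max(axis=2, keepdims=True)
        gls = gl.GenotypeLikelihoods(
            scaffolds=np.array(["scaf1"], dtype=object), positions=np.array([1]),
            major=np.array([A], dtype=np.int8), minor=np.array([C], dtype=np.int8),
            loglik=np.log(lin), samples=[f"i{k}" for k in range(n)],
        )
        f = gl.estimate_maf_em(gls, tol=1e-12, max_iter=10_000)
        stat = 2 * (gl.sites_loglik(gls, f) - gl.sites_loglik(gls, np.zeros(1)))
        _, ll_best = _grid_oracle_maf(lin[0])
        ll0 = np.log(lin[0, :, 0]).sum()
        assert stat[0] == pytest.approx(2 * (ll_best - ll0), abs=1e-6)


class TestFilterSites:
    def _panel(self, seed=20):
        cfg = ek.SimConfig(theta=0.1, n_sites=100, n_historic=10,
                           n_contemporary=10, seed=seed)
        geno, _ = ek.simulate_genotypes(cfg)
        pile = simdata.simulate_reads(geno, 10.0, 0.002, seed=seed + 1)
        gls = gl.call_genotype_likelihoods(pile, gl.ErrorModel(rate=0.002))
        gls.maf = gl.estimate_maf_em(gls)
        return gls

    def test_transition_pairs_removed(self):
        gls = self._panel()
        kept = gl.filter_sites(gls, min_maf=0, snp_p=1.0, min_ind=1,
                               rm_transitions=True)
        for a, b in zip(kept.major, kept.minor):
            assert {int(a), int(b)} not in ({A, G}, {C, T})

    def test_low_maf_removed(self):
        gls = self._panel()
        kept = gl.filter_sites(gls, min_maf=0.05, snp_p=1.0, min_ind=1,
                               rm_transitions=False)
        assert np.all(kept.maf >= 0.05)

    def test_filters_match_naive_per_site_rules(self):
        """Surviving set equals an independent re-application of each rule."""
        gls = self._panel(seed=30)
        f = gls.maf
        p = gl.snp_lrt(gls, f)
        n_data = gls.has_data.sum(axis=1)
        expect = np.ones(gls.n_sites, dtype=bool)
        for s in range(gls.n_sites):
            if {int(gls.major[s]), int(gls.minor[s])} in ({A, G}, {C, T}):
                expect[s] = False
            if f[s] < 0.05 or p[s] > 1e-6 or n_data[s] < 15:
                expect[s] = False
        kept = gl.filter_sites(gls, min_maf=0.05, snp_p=1e-6, min_ind=15,
                               rm_transitions=True)
        got = {f"{s}_{pos}" for s, pos in zip(kept.scaffolds, kept.positions)}
        want = {
            f"{s}_{pos}"
            for s, pos, keep in zip(gls.scaffolds, gls.positions, expect)
            if keep
        }
        assert got == want

    def test_empty_result_warns_not_raises(self):
        gls = self._panel()
        with pytest.warns(UserWarning, match="no sites"):
            kept = gl.filter_sites(gls, min_maf=0.49999, snp_p=1e-300, min_ind=10**6)
        assert kept.n_sites == 0
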