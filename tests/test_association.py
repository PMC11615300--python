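"""Quantile normalization, kinship, mixed-model scan, permutations,
effective tests, cis/trans labels, locus merging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popepigen.association import (
    EmmaNull,
    LinearMixedScan,
    QuantileNormalizer,
    classify_cis_trans,
    compute_kinship,
    effective_tests,
    fit_null_lmm,
    gls_scan,
    lambda_gc,
    marker_r2,
    merge_lead_loci,
    permutation_empirical_p,
    quantile_normalize,
    structure_pcs,
)


class TestQuantileNormalize:
    def test_three_values_hand_oracle(self):
        out = quantile_normalize(np.array([3.0, 1.0, 2.0]))
        phi = stats.norm.ppf
        np.testing.assert_allclose(out, [phi(0.75), phi(0.25), phi(0.5)], atol=1e-12)
        assert out[0] == pytest.approx(0.67449, abs=1e-4)

    def test_ties_get_equal_scores(self):
        out = quantile_normalize(np.array([1.0, 1.0, 2.0]))
        assert out[0] == out[1]

    def test_missing_preserved(self):
        out = quantile_normalize(np.array([3.0, np.nan, 1.0, 2.0]))
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2, 3]]).all()

    def test_constant_vector_warns_zeros(self):
        with pytest.warns(UserWarning):
            out = quantile_normalize(np.ones(5))
        assert (out == 0).all()

    def test_large_sample_standardized(self, rng):
        out = quantile_normalize(rng.exponential(size=5000))
        assert abs(out.mean()) < 0.01 and abs(out.std() - 1) < 0.02

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.array([1.0, 2.0]))

    def test_transformer_columns(self, rng):
        X = rng.normal(size=(50, 3))
        T = QuantileNormalizer().fit(X).transform(X)
        for j in range(3):
            np.testing.assert_allclose(T[:, j], quantile_normalize(X[:, j]))


class TestKinship:
    def test_duplicate_accessions_match_diagonal(self):
        rng = np.random.default_rng(2)
        M = rng.binomial(2, 0.4, (5, 200)).astype(float)
        M[1] = M[0]
        K = compute_kinship(M)
        assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-12)

    def test_independent_markers_offdiag_vanishes(self):
        # centering forces mean offdiag ~ -1/(n-1); use n large enough
        rng = np.random.default_rng(3)
        M = rng.binomial(2, 0.3, (200, 5000)).astype(float)
        K = compute_kinship(M)
        off = K[np.triu_indices_from(K, 1)]
        assert abs(off.mean()) < 0.02

    def test_psd_and_diagonal_scale(self):
        rng = np.random.default_rng(4)
        M = rng.binomial(2, 0.4, (30, 500)).astype(float)
        K = compute_kinship(M)
        assert np.linalg.eigvalsh(K).min() >= -1e-8
        assert np.mean(np.diag(K)) == pytest.approx(1.0, abs=0.15)

    def test_missing_mean_imputed_and_monomorphic_dropped(self):
        rng = np.random.default_rng(5)
        M = rng.binomial(2, 0.4, (20, 100)).astype(float)
        M[:, 0] = 2.0  # monomorphic
        M[3, 5] = np.nan
        K = compute_kinship(M)
        assert np.isfinite(K).all()

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            compute_kinship(np.full((10, 5), 2.0))


class TestNullModel:
    def test_k_identity_scan_equals_ols(self, rng):
        n, m = 100, 25
        G = rng.integers(0, 3, (n, m)).astype(float)
        y = rng.normal(size=n)
        fitted = fit_null_lmm(y, np.eye(n))
        scan = gls_scan(fitted, G)
        for j in range(m):
            X = np.column_stack([np.ones(n), G[:, j]])
            bh = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ bh
            se = np.sqrt(resid @ resid / (n - 2) * np.linalg.inv(X.T @ X)[1, 1])
            p_ols = 2 * stats.t.sf(abs(bh[1] / se), n - 2)
            assert scan["p"].iloc[j] == pytest.approx(p_ols, abs=1e-10)

    def test_h2_recovered_on_simulated_kinship(self):
        rng = np.random.default_rng(11)
        hs = []
        for rep in range(10):
            M = rng.binomial(2, 0.3, (300, 600)).astype(float)
            K = compute_kinship(M)
            lam, U = np.linalg.eigh(K)
            u = U @ (np.sqrt(np.maximum(lam, 0)) * rng.normal(size=300))
            y = np.sqrt(0.5) * u / u.std() + np.sqrt(0.5) * rng.normal(size=300)
            hs.append(EmmaNull(K).fit(y).h2)
        assert 0.4 <= np.median(hs) <= 0.6

    def test_pure_noise_h2_near_zero(self):
        rng = np.random.default_rng(12)
        hs = []
        M = rng.binomial(2, 0.3, (300, 600)).astype(float)
        K = compute_kinship(M)
        null = EmmaNull(K)
        for rep in range(10):
            hs.append(null.fit(rng.normal(size=300)).h2)
        assert np.median(hs) < 0.1

    def test_non_psd_kinship_rejected(self):
        K = np.eye(10)
        K[0, 0] = -5
        with pytest.raises(ValueError):
            EmmaNull(K)

    def test_rank_deficient_covariates_rejected(self):
        C = np.ones((20, 2))  # duplicates the intercept
        with pytest.raises(ValueError):
            EmmaNull(np.eye(20), C)

    def test_estimator_interface(self, rng):
        X = rng.integers(0, 3, (60, 10)).astype(float)
        y = rng.normal(size=60)
        est = LinearMixedScan(kinship=np.eye(60))
        est.fit(X, y)
        assert len(est.results_) == 10
        assert 0 <= est.h2_ <= 1
        params = est.get_params()
        assert "kinship" in params and "covariates" in params

    def test_missing_dosages_mean_imputed(self, rng):
        n = 80
        G = rng.integers(0, 3, (n, 3)).astype(float)
        G[:5, 0] = np.nan
        y = rng.normal(size=n)
        scan = fit_null_lmm(y, np.eye(n)).scan(G)
        assert np.isfinite(scan["p"]).all()

    def test_monomorphic_marker_skipped(self, rng):
        n = 50
        G = np.column_stack([np.full(n, 2.0), rng.integers(0, 3, n)])
        scan = fit_null_lmm(rng.normal(size=n), np.eye(n)).scan(G)
        assert np.isnan(scan["p"].iloc[0]) and np.isfinite(scan["p"].iloc[1])


class TestPermutation:
    def _setup(self, rng, n=100, m=15):
        G = rng.integers(0, 3, (n, m)).astype(float)
        y = rng.normal(size=n)
        return fit_null_lmm(y, np.eye(n)), G

    def test_lower_bound_when_observed_beats_all(self, rng):
        n = 100
        G = rng.integers(0, 3, (n, 5)).astype(float)
        y = G[:, 2] + 0.01 * rng.normal(size=n)  # overwhelming signal
        fitted = fit_null_lmm(y, np.eye(n))
        res = permutation_empirical_p(fitted, G, n_perm=1000, seed=0)
        assert res["p_empirical"] == pytest.approx(1 / 1001)
        assert res["lead_idx"] == 2

    def test_seed_reproducibility_bit_exact(self, rng):
        fitted, G = self._setup(rng)
        a = permutation_empirical_p(fitted, G, n_perm=300, seed=9)
        b = permutation_empirical_p(fitted, G, n_perm=300, seed=9)
        assert a == b

    def test_single_marker_consistent_with_nominal(self):
        """With one marker the empirical p estimates the nominal p."""
        rng = np.random.default_rng(21)
        diffs = []
        for rep in range(30):
            n = 150
            g = rng.integers(0, 3, (n, 1)).astype(float)
            y = 0.15 * g[:, 0] + rng.normal(size=n)
            fitted = fit_null_lmm(y, np.eye(n))
            res = permutation_empirical_p(fitted, g, n_perm=500, seed=rep,
                                          beta_approx=False)
            diffs.append(res["p_empirical"] - res["p_nominal"])
        assert abs(np.mean(diffs)) < 0.03

    def test_beta_approximation_close_to_empirical(self, rng):
        fitted, G = self._setup(rng, n=120, m=30)
        res = permutation_empirical_p(fitted, G, n_perm=800, seed=3,
                                      beta_approx=True)
        assert res["p_beta"] == pytest.approx(res["p_empirical"], abs=0.1)

    def test_few_permutations_warn(self, rng):
        fitted, G = self._setup(rng)
        with pytest.warns(UserWarning):
            permutation_empirical_p(fitted, G, n_perm=50, seed=0)


class TestEffectiveTests:
    def test_independent_markers_meff_near_m(self, rng):
        X = rng.binomial(2, 0.4, (2000, 150)).astype(float)
        meff, thr = effective_tests(X)
        assert 0.85 * 150 <= meff <= 150.5
        assert thr == pytest.approx(0.05 / meff)

    def test_perfectly_correlated_meff_one(self):
        rng = np.random.default_rng(6)
        x = rng.binomial(2, 0.4, 200).astype(float)
        X = np.tile(x[:, None], (1, 30))
        meff, thr = effective_tests(X)
        assert meff == pytest.approx(1.0, abs=1e-6)
        assert thr == pytest.approx(0.05)

    def test_ar1_threshold_within_2x_of_permutation_oracle(self):
        """Li-Ji threshold vs the 5th-percentile permutation min-p."""
        rng = np.random.default_rng(13)
        n, m, rho = 400, 120, 0.9
        Z = np.empty((n, m))
        Z[:, 0] = rng.normal(size=n)
        for j in range(1, m):
            Z[:, j] = rho * Z[:, j - 1] + np.sqrt(1 - rho**2) * rng.normal(size=n)
        X = (Z > 0).astype(float) + (Z > 0.8)
        meff, thr = effective_tests(X)
        minp = []
        null = EmmaNull(np.eye(n))
        y = rng.normal(size=n)
        for b in range(1000):
            f = null.fit(rng.permutation(y))
            minp.append(np.nanmin(f.scan(X)["p"].to_numpy()))
        oracle = np.percentile(minp, 5)
        assert oracle / 2 <= thr <= oracle * 2


class TestCisTrans:
    @pytest.mark.parametrize("mchrom,mpos,tchrom,anchor,expect", [
        ("chr1", 500_000, "chr1", 1_000_000, "cis"),     # 500 kb
        ("chr1", 1, "chr2", 1, "trans"),                  # different chrom
        ("chr1", 2_000_000, "chr1", 1_000_000, "cis"),    # exactly 1 Mb: inclusive
        ("chr1", 2_000_001, "chr1", 1_000_000, "trans"),
    ])
    def test_labeling(self, mchrom, mpos, tchrom, anchor, expect):
        label, _ = classify_cis_trans(mchrom, mpos, tchrom, anchor)
        assert label == expect

    def test_interval_anchor_zero_inside(self):
        label, dist = classify_cis_trans("chr1", 5000, "chr1", 4000, 6000)
        assert label == "cis" and dist == 0

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            classify_cis_trans("", 1, "chr1", 1)


class TestMergeLoci:
    def _markers(self, rng, r2_high=True):
        x = rng.binomial(2, 0.5, 200).astype(float)
        if r2_high:
            y = x.copy()
            flip = rng.random(200) < 0.1
            y[flip] = rng.binomial(2, 0.5, flip.sum())
        else:
            y = rng.binomial(2, 0.5, 200).astype(float)
        M = np.vstack([x, y])
        idx = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [1000, 2000]})
        return M, idx

    def test_correlated_pair_merges(self, rng):
        M, idx = self._markers(rng, r2_high=True)
        assert marker_r2(M[0], M[1]) > 0.1
        res = pd.DataFrame({"marker_idx": [0, 1], "target_id": ["t", "t"],
                            "p": [1e-8, 1e-6]})
        loci = merge_lead_loci(res, M, idx, r2_threshold=0.1)
        assert len(loci) == 1
        assert loci[0].lead_marker == "0"  # smaller p leads

    def test_uncorrelated_pair_stays_split(self, rng):
        M, idx = self._markers(rng, r2_high=False)
        res = pd.DataFrame({"marker_idx": [0, 1], "target_id": ["t", "t"],
                            "p": [1e-8, 1e-6]})
        loci = merge_lead_loci(res, M, idx, r2_threshold=0.1)
        assert len(loci) == 2

    def test_singleton_locus(self, rng):
        M, idx = self._markers(rng)
        res = pd.DataFrame({"marker_idx": [0], "target_id": ["t"], "p": [1e-8]})
        loci = merge_lead_loci(res, M, idx)
        assert len(loci) == 1 and loci[0].members == ["0"]

    def test_order_invariance(self, rng):
        M, idx = self._markers(rng, r2_high=True)
        res = pd.DataFrame({"marker_idx": [0, 1], "target_id": ["t", "t"],
                            "p": [1e-8, 1e-6]})
        a = merge_lead_loci(res, M, idx)
        b = merge_lead_loci(res.iloc[::-1].reset_index(drop=True), M, idx)
        assert [(l.lead_marker, l.members) for l in a] == \
               [(l.lead_marker, l.members) for l in b]


def test_lambda_gc_uniform_pvalues_near_one(rng):
    assert lambda_gc(rng.uniform(size=20_000)) == pytest.approx(1.0, abs=0.05)


def test_structure_pcs_separate_subpops(small_cohort):
    pcs = structure_pcs(small_cohort.genotypes.dosage.T, 2)
    sub = small_cohort.truth.subpops
    # first PC should separate the two subpopulations
    r = np.corrcoef(pcs[:, 0], sub)[0, 1]
    assert abs(r) > 0.8
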