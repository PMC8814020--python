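"""GRM construction and the HE / REML / LDSC estimator stack."""

import numpy as np
import pytest

from amherit.estimators import (
    HERegression,
    LDScoreRegression,
    REML,
    compute_grm,
    he_regression,
    ld_scores,
    ldsc_regression,
    marginal_chi2,
    partition_snps,
    pc_covariates,
    reml_single,
    residualize,
)


def _reml_brute_force_loglik(A, y, h):
    """Full-matrix residual log-likelihood (intercept-only), independent oracle."""
    n = y.size
    X = np.ones((n, 1))
    V = h * A + (1 - h) * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    q = n - 1
    sig = float(y @ P @ y) / q
    _, ld = np.linalg.slogdet(V)
    _, ld2 = np.linalg.slogdet(XtViX)
    _, ld3 = np.linalg.slogdet(X.T @ X)
    # log det(A' V A) = log det V + log det(X' V^-1 X) - log det(X' X)
    return -0.5 * (ld + ld2 - ld3 + q * np.log(sig) + q + q * np.log(2 * np.pi))


class TestGRM:
    def test_hand_computed_three_by_two(self):
        G = np.array([[0, 2], [1, 1], [2, 0]])
        grm, Z = compute_grm(G)
        Zh = (G - 1.0) / np.sqrt(0.5)
        assert np.allclose(Z, Zh)
        assert np.allclose(grm.values, Zh @ Zh.T / 2)
        assert grm.m_used == 2

    def test_mean_diagonal_near_one(self, rng):
        G = rng.binomial(2, rng.uniform(0.1, 0.5, 2000), size=(1000, 2000))
        grm, _ = compute_grm(G)
        assert abs(np.diag(grm.values).mean() - 1.0) < 0.02

    def test_duplicated_individual_has_unit_relatedness(self, rng):
        G = rng.binomial(2, 0.3, size=(50, 500)).astype(float)
        G[1] = G[0]
        grm, _ = compute_grm(G)
        assert grm.values[0, 1] == pytest.approx(grm.values[0, 0], rel=1e-10)

    def test_monomorphic_columns_dropped_or_rejected(self):
        G = np.array([[0, 1], [0, 1], [0, 2]])
        grm, _ = compute_grm(G)
        assert grm.m_used == 1
        with pytest.raises(ValueError):
            compute_grm(np.ones((3, 2)))


class TestHERegression:
    def test_three_individual_oracle(self):
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 0.2
        A[0, 2] = A[2, 0] = 0.1
        A[1, 2] = A[2, 1] = -0.1
        y = np.array([1.0, -1.0, 0.5])
        fit = HERegression(standardize=False).fit(A, y)
        assert fit.h2_ == pytest.approx(-0.1 / 0.06, rel=1e-10)

    def test_orthogonal_products_give_zero(self):
        A = np.eye(4)
        A[0, 1] = A[1, 0] = 0.3
        A[2, 3] = A[3, 2] = -0.3
        y = np.array([1.0, 1.0, 1.0, 1.0])
        fit = HERegression(standardize=False).fit(A, y)
        assert fit.h2_ == pytest.approx(0.0, abs=1e-12)

    def test_intercept_free_vs_intercept_close_for_standardized_y(self, am_cohort):
        grm, _ = compute_grm(am_cohort.genotypes)
        a = HERegression(intercept=False).fit(grm, am_cohort.phenotypes).h2_
        b = HERegression(intercept=True).fit(grm, am_cohort.phenotypes).h2_
        assert abs(a - b) < 0.05

    def test_multi_component_sums_to_single(self, am_cohort):
        G = am_cohort.genotypes
        y = am_cohort.phenotypes
        half = G.shape[1] // 2
        g1, _ = compute_grm(G[:, :half])
        g2, _ = compute_grm(G[:, half:])
        multi = HERegression().fit([g1, g2], y)
        assert multi.estimate_.components is not None
        assert sum(multi.estimate_.components.values()) == pytest.approx(
            multi.h2_, rel=1e-10
        )
        single = he_regression(compute_grm(G)[0], y)
        assert abs(multi.h2_ - single.point) < 0.25

    def test_collinear_components_rejected(self, rng):
        A = rng.standard_normal((20, 20))
        A = A @ A.T / 20
        y = rng.standard_normal(20)
        with pytest.raises(ValueError, match="collinear"):
            HERegression().fit([A, A], y)

    def test_jackknife_se_tracks_replicate_spread(self, rng):
        # null GRM: estimates scatter around zero; jackknife se should be
        # the right order of magnitude relative to the empirical spread
        ests, ses = [], []
        for s in range(8):
            r = np.random.default_rng(s)
            G = r.binomial(2, 0.4, size=(150, 300))
            grm, _ = compute_grm(G)
            fit = HERegression().fit(grm, r.standard_normal(150))
            ests.append(fit.h2_)
            ses.append(fit.se_)
        spread = np.std(ests, ddof=1)
        assert 0.3 * spread < np.median(ses) < 3.0 * spread

    def test_grouped_jackknife_matches_delete_one(self, am_cohort):
        grm, _ = compute_grm(am_cohort.genotypes)
        y = am_cohort.phenotypes
        d1 = HERegression(block_threshold=5000).fit(grm, y).se_
        grouped = HERegression(block_threshold=10, n_blocks=100).fit(grm, y).se_
        assert grouped == pytest.approx(d1, rel=0.5)


class TestREML:
    def test_identity_grm_is_unidentifiable(self, rng):
        fit = REML().fit(np.eye(80), rng.standard_normal(80))
        assert not fit.fit_.identifiable
        assert np.isnan(fit.h2_)

    def test_matches_brute_force_grid(self, rng):
        n, m = 120, 240
        Z = rng.standard_normal((n, m))
        A = Z @ Z.T / m
        g = Z @ rng.normal(0, np.sqrt(0.4 / m), m)
        y = g + rng.normal(0, np.sqrt(0.6), n)
        fit = reml_single(A, y)
        grid = np.arange(0.0, 1.0, 0.002)
        vals = [_reml_brute_force_loglik(A, y, h) for h in grid]
        h_grid = grid[int(np.argmax(vals))]
        assert fit.h_sq == pytest.approx(h_grid, abs=0.002)
        # grid maximum sits just below the continuous optimum
        assert fit.loglik == pytest.approx(max(vals), abs=1e-4)
        assert fit.loglik >= max(vals) - 1e-12

    def test_recovers_heritability_with_tight_se(self, rng):
        n, m = 500, 250
        Z = rng.standard_normal((n, m))
        A = Z @ Z.T / m
        g = Z @ rng.normal(0, np.sqrt(0.5 / m), m)
        y = g + rng.normal(0, np.sqrt(0.5), n)
        fit = reml_single(A, y)
        assert abs(fit.h_sq - 0.5) < 3 * fit.se
        assert fit.sigma_g_sq >= 0 and fit.sigma_e_sq >= 0
        assert fit.h_sq == pytest.approx(
            fit.sigma_g_sq / (fit.sigma_g_sq + fit.sigma_e_sq)
        )

    def test_permuted_phenotype_estimates_near_zero(self, am_cohort, rng):
        grm, _ = compute_grm(am_cohort.genotypes)
        vals = []
        for s in range(5):
            y = np.random.default_rng(s).permutation(am_cohort.phenotypes)
            vals.append(REML().fit(grm, y).h2_)
        assert np.median(vals) < 0.15

    def test_covariate_projection_reduces_spectrum(self, am_cohort, rng):
        grm, _ = compute_grm(am_cohort.genotypes)
        C = rng.standard_normal((grm.n, 3))
        fit = REML().fit(grm, am_cohort.phenotypes, covariates=C)
        assert fit.fit_.n_eigen == grm.n - 4  # intercept + 3 covariates

    def test_rank_deficient_covariates_rejected(self, am_cohort):
        grm, _ = compute_grm(am_cohort.genotypes)
        C = np.ones((grm.n, 2))
        with pytest.raises(ValueError, match="rank"):
            REML().fit(grm, am_cohort.phenotypes, covariates=C)


class TestPCs:
    def test_orthonormal_and_sorted(self, am_cohort):
        grm, _ = compute_grm(am_cohort.genotypes)
        P = pc_covariates(grm, 10)
        assert np.allclose(P.T @ P, np.eye(10), atol=1e-8)
        lam = np.sort(np.linalg.eigvalsh(grm.values))[::-1]
        proj_var = np.array([(grm.values @ P[:, j]) @ P[:, j] for j in range(10)])
        assert np.allclose(proj_var, lam[:10], rtol=1e-8)

    def test_k_must_be_below_n(self):
        with pytest.raises(ValueError):
            pc_covariates(np.eye(5), 5)


class TestLDScores:
    def test_independent_snps_score_near_one(self, rng):
        n, p, w = 800, 200, 10
        Z = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        ell = ld_scores(Z, window_snps=w)
        expected = 1.0 + 2 * w / n  # self term plus the noise floor
        assert abs(ell.mean() - expected) < 0.02

    def test_duplicated_snp_scores_two(self, rng):
        Z = rng.binomial(2, 0.3, size=(500, 20)).astype(float)
        Z[:, 5] = Z[:, 4]
        ell = ld_scores(Z, window_snps=19)
        assert ell[4] == pytest.approx(2.0 + 18 * 2 / 500, abs=0.15)

    def test_map_window_membership_is_exact(self, rng):
        Z = rng.binomial(2, 0.4, size=(2000, 5)).astype(float)
        cm = np.array([0.0, 0.3, 0.6, 5.0, 9.0])
        ell = ld_scores(Z, map_cm=cm, window_cm=1.0)
        Zs = (Z - Z.mean(0)) / Z.std(0)
        r2 = (Zs.T @ Zs / 2000) ** 2
        # SNPs 0-2 form one window; 3 and 4 are isolated
        assert ell[0] == pytest.approx(r2[0, :3].sum(), abs=1e-12)
        assert ell[3] == pytest.approx(1.0, abs=1e-12)
        assert ell[4] == pytest.approx(1.0, abs=1e-12)

    def test_unmapped_snps_rejected(self, rng):
        Z = rng.binomial(2, 0.4, size=(50, 3)).astype(float)
        with pytest.raises(ValueError, match="unmapped|map"):
            ld_scores(Z, map_cm=np.array([0.0, np.nan, 1.0]))


class TestLDSC:
    def test_chi2_matches_hand_computation(self, rng):
        Z = rng.binomial(2, 0.5, size=(5, 2)).astype(float)
        y = np.array([0.1, -1.2, 0.7, 0.3, -0.5])
        chi2 = marginal_chi2(Z, y)
        for j in range(2):
            r = np.corrcoef(Z[:, j], y)[0, 1]
            assert chi2[j] == pytest.approx(5 * r**2, rel=1e-10)

    def test_null_trait_gives_unit_intercept(self, small_panel, rng):
        H = small_panel.haplotypes
        G = (H[0::2] + H[1::2]).astype(float)
        G = np.vstack([G, G[: G.shape[0] // 2]])  # enlarge a little
        y = rng.standard_normal(G.shape[0])
        keep = G.std(axis=0) > 0
        ell = ld_scores(
            G[:, keep],
            map_cm=small_panel.snp_cm[keep],
            chrom=small_panel.chrom[keep],
        )
        est = ldsc_regression(G[:, keep], y, ell)
        assert abs(est.intercept - 1.0) < 0.35
        assert abs(est.point) < 1.0

    def test_degenerate_scores_rejected(self, rng):
        Z = rng.binomial(2, 0.4, size=(50, 10)).astype(float)
        with pytest.raises(ValueError, match="degenerate"):
            LDScoreRegression().fit(Z, rng.standard_normal(50), np.ones(10))


class TestPartition:
    def test_partition_is_disjoint_and_exhaustive(self, rng):
        f = rng.uniform(0.05, 0.95, 101)
        ell = rng.uniform(1, 5, 101)
        sets = partition_snps(f, ell)
        allidx = np.concatenate(sets)
        assert allidx.size == 101
        assert np.unique(allidx).size == 101

    def test_constant_scores_warn_and_empty_bins(self, rng):
        f = rng.uniform(0.05, 0.5, 10)
        with pytest.warns(UserWarning, match="degenerate"):
            sets = partition_snps(f, np.ones(10))
        assert sets[1].size == 0 and sets[3].size == 0


class TestAMSignature:
    def test_am_inflates_the_outcome_not_the_grm(self, am_cohort, null_cohort, rng):
        """AM feeds the phenotypic outer product but leaves the GRM untouched.

        The outcome side of HE regression (pairwise phenotype products)
        absorbs the AM-induced cross-locus covariance, so the regression
        slope rises sharply; the predictor side (GRM entries, within-locus
        averages) is statistically indistinguishable between mating regimes.
        """
        from scipy import stats

        slopes, entries = {}, {}
        for tag, cohort in (("am", am_cohort), ("rm", null_cohort)):
            grm, _ = compute_grm(cohort.genotypes)
            slopes[tag] = HERegression().fit(grm, cohort.phenotypes).h2_
            iu = np.triu_indices(grm.n, 1)
            entries[tag] = grm.values[iu]
        assert slopes["am"] > slopes["rm"] + 0.1
        # subsample pairs so the two-sample test has calibrated, modest power
        a = rng.choice(entries["am"], 4000, replace=False)
        b = rng.choice(entries["rm"], 4000, replace=False)
        assert stats.ks_2samp(a, b).pvalue > 0.01


class TestResidualize:
    def test_intercept_only_is_centering(self, rng):
        y = rng.standard_normal(30) + 5.0
        y_adj, _ = residualize(y, None, np.ones((30, 1)))
        centered = (y - y.mean()) / y.std()
        assert np.allclose(y_adj, centered / centered.std())

    def test_residuals_orthogonal_to_covariates(self, rng):
        C = rng.standard_normal((100, 4))
        y = rng.standard_normal(100)
        G = rng.binomial(2, 0.3, size=(100, 6)).astype(float)
        y_adj, G_adj = residualize(y, G, C)
        assert np.abs(C.T @ y_adj).max() < 1e-8 * 100
        assert np.abs(C.T @ G_adj).max() < 1e-6

    def test_estimates_invariant_to_affine_covariate_transform(self, am_cohort, rng):
        grm, _ = compute_grm(am_cohort.genotypes)
        C = rng.standard_normal((grm.n, 3))
        T = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        a = HERegression().fit(grm, am_cohort.phenotypes, covariates=C).h2_
        b = HERegression().fit(grm, am_cohort.phenotypes, covariates=C @ T).h2_
        assert a == pytest.approx(b, rel=1e-8)

    def test_rank_deficient_rejected(self, rng):
        C = np.ones((20, 2))
        with pytest.raises(ValueError):
            residualize(rng.standard_normal(20), None, C)
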