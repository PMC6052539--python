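import numpy as np
import pytest

from shaperate.landmarks import ShapeMatrix
from shaperate.rates import (
    SingularCovarianceError,
    phylo_transform,
    rate_ratio,
    rate_ratio_test,
    sigma_mult,
    simulate_bm_tips,
)
from shaperate.trees import phylo_covariance, read_newick
from shaperate.synthetic import generate_chronogram

from conftest import random_chronogram


class TestPhyloTransform:
    def test_star_tree_reduces_to_arithmetic_mean(self):
        t = read_newick("(A:2,B:2,C:2,D:2);")
        cov = phylo_covariance(t, ["A", "B", "C", "D"])
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((4, 3))
        gls_mean, Yt = phylo_transform(Y, cov)
        np.testing.assert_allclose(gls_mean, Y.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(Yt, (Y - Y.mean(axis=0)) / np.sqrt(2.0), atol=1e-12)

    def test_identity_covariance_centers_exactly(self):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((5, 4))
        gls_mean, Yt = phylo_transform(Y, np.eye(5))
        np.testing.assert_allclose(Yt, Y - Y.mean(axis=0), atol=1e-12)

    def test_singular_covariance_raises(self):
        C = np.ones((3, 3))
        with pytest.raises(SingularCovarianceError):
            phylo_transform(np.zeros((3, 2)), C)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            phylo_transform(np.zeros((3, 2)), np.eye(4))

    def test_whitening_monte_carlo(self):
        # BM data on a random 20-tip chronogram: after whitening, the mean
        # per-trait second moment matches sigma2 * I within 5%
        tree = random_chronogram(20, 10.0, 123)
        cov = phylo_covariance(tree)
        sigma2 = 0.3
        X = simulate_bm_tips(cov, sigma2 * np.eye(4), seed=5, n_replicates=1000)
        from shaperate.rates import _covariance_roots

        inv_half, _, w = _covariance_roots(cov.C)
        a = np.einsum("i,mip->mp", w, X)
        Xt = inv_half @ (X - a[:, None, :])
        # GLS-mean removal costs one degree of freedom, hence n - 1
        n = cov.C.shape[0]
        per_trait = (Xt**2).sum(axis=1).mean(axis=0) / (n - 1)
        np.testing.assert_allclose(per_trait, sigma2, rtol=0.05)
        cross = np.einsum("mip,miq->pq", Xt, Xt) / (len(X) * (n - 1))
        off = cross - np.diag(np.diag(cross))
        assert np.abs(off).max() < 0.05 * sigma2


class TestSigmaMult:
    def test_one_trait_star_tree(self):
        t = read_newick("(A:1,B:1,C:1,D:1);")
        cov = phylo_covariance(t, ["A", "B", "C", "D"])
        Y = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        _, Yt = phylo_transform(Y, cov)
        by_group, overall = sigma_mult(Yt, ["A", "B", "C", "D"], {t: "g" for t in "ABCD"})
        assert overall == pytest.approx(1.0)
        assert by_group["g"] == pytest.approx(1.0)

    def test_scaling_data_scales_rates_quadratically(self):
        tree = random_chronogram(8, 5.0, 3)
        cov = phylo_covariance(tree)
        rng = np.random.default_rng(4)
        Y = rng.standard_normal((8, 6))
        _, Yt = phylo_transform(Y, cov)
        _, Yt3 = phylo_transform(3.0 * Y, cov)
        _, o1 = sigma_mult(Yt)
        _, o2 = sigma_mult(Yt3)
        assert o2 == pytest.approx(9.0 * o1)

    def test_unmapped_taxon(self):
        with pytest.raises(KeyError):
            sigma_mult(np.zeros((2, 2)), ["a", "b"], {"a": "g"})

    def test_rate_recovery_within_ten_percent(self):
        # parameter recovery: sigma2 = 5e-4 on a 46-tip chronogram
        tree = random_chronogram(46, 18.0, 77)
        cov = phylo_covariance(tree)
        sigma2 = 5e-4
        X = simulate_bm_tips(cov, sigma2 * np.eye(36), seed=8, n_replicates=200)
        from shaperate.rates import _covariance_roots

        inv_half, _, w = _covariance_roots(cov.C)
        a = np.einsum("i,mip->mp", w, X)
        Xt = inv_half @ (X - a[:, None, :])
        estimates = (Xt**2).sum(axis=(1, 2)) / (46 * 36)
        assert np.median(estimates) == pytest.approx(sigma2, rel=0.10)


class TestRateRatio:
    def test_trunk_row_worked_example(self):
        assert rate_ratio(1.397e-2, 5.567e-3) == pytest.approx(2.51, abs=5e-3)

    def test_modular_row_worked_example(self):
        assert rate_ratio(2.737e-3, 1.071e-3) == pytest.approx(2.556, abs=5e-4)

    def test_equal_rates(self):
        assert rate_ratio(0.7, 0.7) == 1.0

    def test_non_positive(self):
        with pytest.raises(ValueError):
            rate_ratio(0.0, 1.0)


class TestSimulateBMTips:
    def test_zero_rate_matrix(self, cherry_plus_outgroup):
        X = simulate_bm_tips(cherry_plus_outgroup, np.zeros((3, 3)), seed=0)
        np.testing.assert_array_equal(X, np.zeros((3, 3)))

    def test_determinism(self, cherry_plus_outgroup):
        X1 = simulate_bm_tips(cherry_plus_outgroup, np.eye(2), seed=42)
        X2 = simulate_bm_tips(cherry_plus_outgroup, np.eye(2), seed=42)
        np.testing.assert_array_equal(X1, X2)

    def test_non_psd_rejected(self, cherry_plus_outgroup):
        R = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError):
            simulate_bm_tips(cherry_plus_outgroup, R, seed=0)

    def test_tip_covariance_monte_carlo(self, cherry_plus_outgroup):
        X = simulate_bm_tips(
            cherry_plus_outgroup, np.eye(1), seed=11, n_replicates=2000
        )
        emp = np.einsum("mi,mj->ij", X[:, :, 0], X[:, :, 0]) / len(X)
        np.testing.assert_allclose(
            emp, [[2, 1, 0], [1, 2, 0], [0, 0, 2]], atol=0.2
        )


@pytest.fixture(scope="module")
def two_clade_small():
    tree, groups = generate_chronogram(10, 4, 18.02, (14.05, 6.88), seed=31)
    return tree, groups


class TestRateRatioTest:
    def test_determinism(self, two_clade_small):
        tree, groups = two_clade_small
        cov = phylo_covariance(tree)
        X = simulate_bm_tips(cov, 1e-4 * np.eye(8), seed=1)
        Y = ShapeMatrix(cov.taxa, X)
        r1 = rate_ratio_test(Y, tree, groups, nsim=199, seed=9)
        r2 = rate_ratio_test(Y, tree, groups, nsim=199, seed=9)
        assert r1.to_json() == r2.to_json()

    def test_result_structure(self, two_clade_small):
        tree, groups = two_clade_small
        cov = phylo_covariance(tree)
        X = simulate_bm_tips(cov, 1e-4 * np.eye(8), seed=2)
        Y = ShapeMatrix(cov.taxa, X)
        r = rate_ratio_test(Y, tree, groups, nsim=99, seed=3)
        assert r.ratio >= 1.0
        assert {r.ratio_numerator, r.ratio_denominator} == {"G", "E"}
        assert r.ratio == pytest.approx(
            r.sigma2_by_group[r.ratio_numerator] / r.sigma2_by_group[r.ratio_denominator]
        )
        assert 0 < r.p_value <= 1.0
        assert r.trait_dim == 8

    def test_taxon_reordering_invariance(self, two_clade_small):
        tree, groups = two_clade_small
        cov = phylo_covariance(tree)
        X = simulate_bm_tips(cov, 1e-4 * np.eye(6), seed=4)
        Y = ShapeMatrix(cov.taxa, X)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(cov.taxa))
        Yp = ShapeMatrix(tuple(cov.taxa[i] for i in perm), X[perm])
        r1 = rate_ratio_test(Y, tree, groups, nsim=99, seed=6)
        r2 = rate_ratio_test(Yp, tree, groups, nsim=99, seed=6)
        assert r1.sigma2_by_group == pytest.approx(r2.sigma2_by_group)

    def test_branch_scaling_divides_rates_leaves_ratio(self, two_clade_small):
        tree, groups = two_clade_small
        c = 3.0
        scaled = read_newick(
            __import__("re").sub(
                r":([0-9.eE+-]+)",
                lambda m: f":{float(m.group(1)) * c!r}",
                tree.to_newick(),
            )
        )
        cov = phylo_covariance(tree)
        X = simulate_bm_tips(cov, 1e-4 * np.eye(6), seed=7)
        Y = ShapeMatrix(cov.taxa, X)
        Ys = Y.reorder(scaled.tip_labels) if scaled.tip_labels != Y.taxa else Y
        r1 = rate_ratio_test(Y, tree, groups, nsim=99, seed=8)
        r2 = rate_ratio_test(Ys, scaled, groups, nsim=99, seed=8)
        for g in r1.sigma2_by_group:
            assert r2.sigma2_by_group[g] == pytest.approx(r1.sigma2_by_group[g] / c)
        assert r2.ratio == pytest.approx(r1.ratio)
        assert r2.p_value == r1.p_value

    def test_explicit_quadratic_form_oracle(self):
        # whitening-pipeline sigma2 equals the direct GLS quadratic form
        # computed with an explicit inverse, on small random trees
        for seed in range(5):
            n = int(np.random.default_rng(seed).integers(4, 9))
            tree = random_chronogram(n, 6.0, seed + 200)
            cov = phylo_covariance(tree)
            rng = np.random.default_rng(seed)
            Y = rng.standard_normal((n, 3))
            _, Yt = phylo_transform(Y, cov)
            _, overall = sigma_mult(Yt)
            Cinv = np.linalg.inv(cov.C)
            ones = np.ones(n)
            a = (ones @ Cinv @ Y) / (ones @ Cinv @ ones)
            resid = Y - a
            direct = np.trace(resid.T @ Cinv @ resid) / (n * 3)
            assert overall == pytest.approx(direct, abs=1e-10)

    def test_group_mismatch(self, two_clade_small):
        tree, groups = two_clade_small
        cov = phylo_covariance(tree)
        Y = ShapeMatrix(cov.taxa, np.random.default_rng(0).standard_normal((14, 4)))
        bad = dict(groups)
        bad.pop(cov.taxa[0])
        with pytest.raises(KeyError):
            rate_ratio_test(Y, tree, bad, nsim=99, seed=0)

    def test_nsim_validation(self, two_clade_small):
        tree, groups = two_clade_small
        cov = phylo_covariance(tree)
        Y = ShapeMatrix(cov.taxa, np.random.default_rng(0).standard_normal((14, 4)))
        with pytest.raises(ValueError):
            rate_ratio_test(Y, tree, groups, nsim=0, seed=0)

    def test_type_one_error_light(self):
        # light version of the calibration check: isotropic truth with the
        # matching isotropic null is exact by scale invariance
        from scipy.stats import binom

        tree, groups = generate_chronogram(40, 4, 18.02, (14.05, 6.88), seed=42)
        cov = phylo_covariance(tree)
        rng = np.random.default_rng(99)
        n_rep = 100
        rejections = 0
        for _ in range(n_rep):
            X = simulate_bm_tips(cov, 1e-5 * np.eye(12), seed=rng)
            Y = ShapeMatrix(cov.taxa, X)
            r = rate_ratio_test(
                Y, tree, groups, nsim=99, seed=int(rng.integers(2**31)),
                isotropic_null=True,
            )
            rejections += r.p_value <= 0.05
        lo, hi = binom.interval(0.99, n_rep, 0.05)
        assert lo <= rejections <= hi

    def test_ratio_recovery_light(self):
        # true ratio 2.0 at paper scale: median estimate lands in the band
        tree, groups = generate_chronogram(40, 4, 18.02, (14.05, 6.88), seed=17)
        cov = phylo_covariance(tree)
        mask_G = np.array([groups[t] == "G" for t in cov.taxa])
        scale = np.where(mask_G, np.sqrt(2e-5), np.sqrt(1e-5))
        rng = np.random.default_rng(55)
        ratios = []
        for _ in range(30):
            Z = simulate_bm_tips(cov, np.eye(36), seed=rng)
            X = scale[:, None] * Z  # clade-specific rates, shared tree signal
            Y = ShapeMatrix(cov.taxa, X)
            cov_o = phylo_covariance(tree, Y.taxa)
            _, Yt = phylo_transform(Y, cov_o)
            bg, _ = sigma_mult(Yt, Y.taxa, groups)
            ratios.append(bg["G"] / bg["E"])
        assert 1.6 <= np.median(ratios) <= 2.5
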