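import warnings

import numpy as np
import pytest
from scipy.integrate import quad
from sklearn.metrics import adjusted_rand_score

from ccast import (
    bandwidth_rule,
    hclust_labels,
    kmeans_init,
    npem_estep,
    npem_fit,
    npem_kde_step,
    npem_mstep,
)
from ccast.mixture_clustering import WeightedKDE

import oracles
from conftest import make_table


class TestKmeansInit:
    def test_recovers_two_blobs_vs_exhaustive_wcss(self):
        rng = np.random.default_rng(3)
        x = np.r_[rng.normal(0, 0.5, 5), rng.normal(20, 0.5, 5)]
        table = make_table([x])
        post = kmeans_init(table, m=2, seed=0)
        labels = post.argmax(axis=1)
        best = oracles.brute_best_wcss_2partition(x[:, None])
        same = (labels == best).all() or (labels == 1 - best).all()
        assert same

    def test_single_component_all_ones(self):
        post = kmeans_init(make_table([[1.0], [2.0]]), m=1, seed=0)
        np.testing.assert_array_equal(post, [[1.0], [1.0]])

    def test_deterministic_and_hard(self):
        rng = np.random.default_rng(5)
        table = make_table(rng.normal(size=(30, 2)))
        a = kmeans_init(table, 3, seed=11)
        b = kmeans_init(table, 3, seed=11)
        np.testing.assert_array_equal(a, b)
        assert set(np.unique(a)) == {0.0, 1.0} and (a.sum(axis=1) == 1).all()

    def test_too_many_components_errors(self):
        with pytest.raises(ValueError, match="exceed"):
            kmeans_init(make_table([[1.0], [2.0]]), m=3, seed=0)


class TestBandwidthRule:
    def test_value_on_1_to_100(self):
        table = make_table([np.arange(1.0, 101.0)])
        # direct evaluation: sigma=29.011, IQR/1.34=36.94, 100^(-1/5)=0.3981
        assert bandwidth_rule(table) == pytest.approx(10.3947, abs=1e-3)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(40, 2))
        h1 = bandwidth_rule(make_table(vals))
        h2 = bandwidth_rule(make_table(vals * 3.7))
        assert h2 == pytest.approx(3.7 * h1, rel=1e-12)

    def test_duplication_scales_by_pow(self):
        vals = np.arange(1.0, 21.0).reshape(-1, 1)
        h1 = bandwidth_rule(make_table(vals))
        h2 = bandwidth_rule(make_table(np.vstack([vals, vals])))
        # sigma/IQR essentially unchanged, N doubles => h shrinks by about
        # 2^(-1/5); the ddof=1 correction to sigma perturbs this slightly
        assert h2 / h1 == pytest.approx(2 ** (-0.2), rel=2e-2)

    def test_degenerate_data_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            bandwidth_rule(make_table([[2.0], [2.0], [2.0]]))


class TestNpemSteps:
    def test_mstep_matches_brute_force(self):
        rng = np.random.default_rng(0)
        post = rng.dirichlet(np.ones(4), size=15)
        np.testing.assert_allclose(
            npem_mstep(post), oracles.brute_mstep(post.tolist()), atol=1e-12
        )

    def test_mstep_degenerate_and_uniform(self):
        post = np.zeros((5, 3))
        post[:, 0] = 1.0
        np.testing.assert_array_equal(npem_mstep(post), [1.0, 0.0, 0.0])
        np.testing.assert_allclose(npem_mstep(np.full((6, 3), 1 / 3)), [1 / 3] * 3)

    def test_kde_one_point_is_normal_density(self):
        kde = WeightedKDE(np.array([2.0]), np.array([1.0]), bandwidth=0.5)
        u = np.linspace(0, 4, 9)
        expect = np.exp(-0.5 * ((u - 2.0) / 0.5) ** 2) / (0.5 * np.sqrt(2 * np.pi))
        np.testing.assert_allclose(kde(u), expect, atol=1e-12)

    def test_kde_two_points_value(self):
        kde = WeightedKDE(np.array([-1.0, 1.0]), np.array([0.5, 0.5]), 1.0)
        assert kde(0.0) == pytest.approx(0.2419707245, abs=1e-10)

    def test_kde_matches_brute_force(self):
        rng = np.random.default_rng(2)
        pts, w = rng.normal(size=12), rng.uniform(0.1, 1, 12)
        kde = WeightedKDE(pts, w, 0.7)
        for u in (-1.3, 0.0, 2.2):
            assert kde(u) == pytest.approx(
                oracles.brute_kde(pts.tolist(), w.tolist(), 0.7, u), abs=1e-12
            )

    def test_kde_integrates_to_one(self):
        rng = np.random.default_rng(4)
        kde = WeightedKDE(rng.normal(size=10), rng.uniform(0.2, 1, 10), 0.4)
        total, _ = quad(kde, -10, 10, limit=200)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_kde_uniform_weights_collapse_to_plain_kde(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=15)
        a = WeightedKDE(pts, np.full(15, 1.0), 0.5)
        b = WeightedKDE(pts, np.full(15, 0.25), 0.5)  # scale-free in weights
        u = np.linspace(-3, 3, 11)
        np.testing.assert_allclose(a(u), b(u), atol=1e-14)

    def test_estep_symmetry_and_derived_example(self):
        # equal densities, equal mixing -> (0.5, 0.5); the (0.8,0.2) x
        # (0.3,0.1) case gives (0.24,0.02)/0.26
        post = oracles.brute_estep([[0.3, 0.1]], [0.8, 0.2])
        np.testing.assert_allclose(post, [[0.24 / 0.26, 0.02 / 0.26]], atol=1e-15)
        table = make_table([[0.0]])
        spec = [
            [WeightedKDE(np.array([0.0]), np.array([1.0]), 1.0)],
            [WeightedKDE(np.array([0.0]), np.array([1.0]), 1.0)],
        ]
        np.testing.assert_allclose(
            npem_estep(table, np.array([0.5, 0.5]), spec), [[0.5, 0.5]], atol=1e-15
        )

    def test_estep_matches_brute_force(self):
        rng = np.random.default_rng(9)
        n, m = 18, 3
        table = make_table(rng.normal(size=(n, 2)))
        post0 = rng.dirichlet(np.ones(m), size=n)
        lam = npem_mstep(post0)
        h = bandwidth_rule(table)
        spec = npem_kde_step(table, post0, h)
        result = npem_estep(table, lam, spec)
        dens = [
            [
                np.prod(
                    [
                        oracles.brute_kde(
                            table.values[:, k].tolist(), post0[:, j].tolist(), h,
                            table.values[i, k],
                        )
                        for k in range(2)
                    ]
                )
                for j in range(m)
            ]
            for i in range(n)
        ]
        np.testing.assert_allclose(result, oracles.brute_estep(dens, lam), atol=1e-12)

    def test_estep_rows_sum_to_one_and_zero_density_excluded(self):
        table = make_table([[0.0], [100.0]])
        spec = [
            [WeightedKDE(np.array([0.0]), np.array([1.0]), 0.5)],
            [WeightedKDE(np.array([100.0]), np.array([1.0]), 0.5)],
        ]
        post = npem_estep(table, np.array([0.5, 0.5]), spec)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
        assert post[0, 1] < 1e-100 and post[1, 0] < 1e-100

    def test_kde_step_freezes_tiny_component(self):
        table = make_table(np.linspace(0, 1, 10)[:, None])
        post = np.column_stack([np.full(10, 0.99), np.full(10, 0.01)])
        with pytest.warns(RuntimeWarning, match="frozen"):
            spec = npem_kde_step(table, post, 0.3)
        assert spec[1] is None and spec[0] is not None


class TestNpemFit:
    def test_recovers_separated_components(self):
        rng = np.random.default_rng(12)
        x = np.r_[rng.normal(0, 1, 100), rng.normal(10, 1, 100)]
        truth = np.repeat([0, 1], 100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = npem_fit(make_table([x]), m=2, seed=0)
        assert adjusted_rand_score(truth, fit.hard_labels) == 1.0
        np.testing.assert_allclose(fit.mixing_proportions.sum(), 1.0, atol=1e-12)
        np.testing.assert_allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            fit.mixing_proportions, fit.posteriors.mean(axis=0), atol=1e-12
        )

    def test_deterministic(self):
        rng = np.random.default_rng(13)
        table = make_table(rng.normal(size=(60, 2)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = npem_fit(table, m=2, seed=3, max_iter=40)
            b = npem_fit(table, m=2, seed=3, max_iter=40)
        np.testing.assert_array_equal(a.posteriors, b.posteriors)
        np.testing.assert_array_equal(a.mixing_proportions, b.mixing_proportions)

    def test_overfit_single_mode_pools_to_plain_kde(self):
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, 150)
        table = make_table([x])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = npem_fit(table, m=2, seed=0)
        grid = np.linspace(-4, 4, 400)
        pooled = np.zeros_like(grid)
        for j, kdes in enumerate(fit.densities):
            if kdes is not None and fit.mixing_proportions[j] > 0:
                pooled += fit.mixing_proportions[j] * kdes[0](grid)
        plain = WeightedKDE(x, np.ones_like(x), fit.bandwidth)(grid)
        l1 = np.trapezoid(np.abs(pooled - plain), grid)
        assert l1 < 0.05

    def test_high_separation_ari_across_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = np.r_[rng.normal(0, 1, 75), rng.normal(10, 1, 75)]
            truth = np.repeat([0, 1], 75)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = npem_fit(make_table([x]), m=2, seed=seed)
            hits += adjusted_rand_score(truth, fit.hard_labels) >= 0.99
        assert hits == 20


class TestHclust:
    @pytest.mark.parametrize("linkage", ["ward", "average", "complete"])
    def test_separated_blobs_pure(self, two_blobs, linkage):
        table, truth = two_blobs
        labels = hclust_labels(table, m=2, linkage=linkage)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_full_cut(self):
        table = make_table(np.arange(5.0)[:, None])
        assert len(np.unique(hclust_labels(table, m=5))) == 5

    def test_errors(self, two_blobs):
        table, _ = two_blobs
        with pytest.raises(ValueError, match="linkage"):
            hclust_labels(table, 2, linkage="single")
        with pytest.raises(ValueError, match="exceeds"):
            hclust_labels(table, table.n_cells + 1)
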