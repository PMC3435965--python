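import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from biofilm_spatstat.geostatistics import (GeoSample, KrigingGrid,
                                            VariogramModel,
                                            empirical_variogram,
                                            fit_variogram, isopleth_contours,
                                            loo_cross_validation, morans_i,
                                            ordinary_kriging)
from biofilm_spatstat.point_pattern import neighbor_table
from biofilm_spatstat.synthetic_data import gen_thomas


def exp_field(n, window, a, seed, nugget=0.0):
    """Gaussian random field with exponential covariance, unit sill."""
    rng = np.random.default_rng(seed)
    loc = rng.uniform(0, window, (n, 2))
    cov = np.exp(-squareform(pdist(loc)) / a) * (1 - nugget)
    cov[np.diag_indices(n)] += nugget
    z = np.linalg.cholesky(cov + 1e-9 * np.eye(n)) @ rng.standard_normal(n)
    return GeoSample(loc, z)


class TestEmpiricalVariogram:
    def test_two_point_semivariance(self):
        v = empirical_variogram(GeoSample([(0, 0), (3, 4)], [0.0, 1.0]),
                                n_lags=1, active_lag_max=6.0)
        assert v.semivariance[0] == pytest.approx(0.5)
        assert v.pair_counts[0] == 1

    def test_constant_z_zero_everywhere(self, rng):
        g = GeoSample(rng.uniform(0, 50, (30, 2)), np.full(30, 3.3))
        v = empirical_variogram(g)
        assert np.nanmax(v.semivariance) == 0.0

    def test_matches_all_pairs_brute_force(self, rng):
        loc = rng.uniform(0, 80, (60, 2))
        z = rng.normal(size=60)
        n_lags, alm = 8, 50.0
        v = empirical_variogram(GeoSample(loc, z), n_lags=n_lags,
                                active_lag_max=alm)
        # independent O(n^2) oracle
        sums = np.zeros(n_lags)
        counts = np.zeros(n_lags, dtype=int)
        for i in range(60):
            for j in range(i + 1, 60):
                h = np.hypot(*(loc[i] - loc[j]))
                b = int(h // (alm / n_lags))
                if b < n_lags:
                    sums[b] += (z[i] - z[j]) ** 2
                    counts[b] += 1
        assert (v.pair_counts == counts).all()
        with np.errstate(invalid="ignore"):
            expect = np.where(counts > 0, sums / (2 * counts), np.nan)
        np.testing.assert_allclose(v.semivariance, expect, equal_nan=True)

    def test_iid_z_flat_at_sample_variance(self, rng):
        g = GeoSample(rng.uniform(0, 100, (400, 2)),
                      rng.normal(size=400))
        v = empirical_variogram(g)
        usable = v.pair_counts > 50
        np.testing.assert_allclose(v.semivariance[usable],
                                   v.sample_variance, rtol=0.25)


class TestFitVariogram:
    def test_exponential_effective_range_is_3a(self):
        # noiseless variogram sampled from the model itself
        h = np.linspace(2, 60, 12)
        model_true = VariogramModel("exponential", 0.0, 1.0, 10.0, 0.0, 1.0)
        gamma = 0.0 + 1.0 * (1 - np.exp(-h / 10.0))
        from biofilm_spatstat.geostatistics import Variogram
        v = Variogram(h, gamma, np.full(12, 100), 60.0, 12, 1.0)
        m = fit_variogram(v, families=("exponential",))
        assert m.effective_range == pytest.approx(10 * np.log(20), rel=1e-3)
        assert m.fit_r2 > 0.999
        del model_true

    def test_pure_nugget_flagged_no_structure(self, rng):
        g = GeoSample(rng.uniform(0, 100, (200, 2)), rng.normal(size=200))
        m = fit_variogram(empirical_variogram(g))
        assert m.no_structure
        assert m.effective_range == 0.0

    def test_spherical_95_point(self):
        h = np.linspace(1, 40, 16)
        x = np.minimum(h / 20.0, 1)
        gamma = 1.5 * x - 0.5 * x ** 3
        from biofilm_spatstat.geostatistics import Variogram
        v = Variogram(h, gamma, np.full(16, 50), 40.0, 16, 1.0)
        m = fit_variogram(v, families=("spherical",))
        # root of 1.5x - 0.5x^3 = 0.95 is ~0.8109
        assert m.effective_range == pytest.approx(20 * 0.81094, rel=1e-2)

    def test_too_few_lags_rejected(self):
        from biofilm_spatstat.geostatistics import Variogram
        v = Variogram(np.array([1.0, 2, 3]), np.array([0.1, 0.2, 0.3]),
                      np.array([5, 5, 5]), 3.0, 3, 0.2)
        with pytest.raises(ValueError, match="4 usable lags"):
            fit_variogram(v)

    def test_effective_range_grows_with_thomas_cluster_radius(self):
        # the mechanism separating weakly vs strongly clustered biofilms;
        # min_separation emulates the physical exclusion between cell bodies
        sigmas = [1.0, 2.0, 4.0, 8.0]
        effs = []
        for i, s in enumerate(sigmas):
            vals = []
            for r in range(8):
                p = gen_thomas(1e-4, 20, s, (500, 500),
                               seed=[17, 1000 * i + r], min_separation=1.0)
                tab = neighbor_table(p)
                g = GeoSample(p.points, tab["cluster_index"].to_numpy())
                v = empirical_variogram(g, n_lags=16, active_lag_max=40.0)
                vals.append(fit_variogram(v).effective_range)
            effs.append(np.median(vals))
        assert np.all(np.diff(effs) > 0)
        rho = spearmanr(sigmas, effs).statistic
        assert rho > 0.8


class TestMoransI:
    @staticmethod
    def _oracle(loc, z):
        n = len(z)
        d = squareform(pdist(loc))
        w = np.zeros_like(d)
        nz = d > 0
        w[nz] = 1.0 / d[nz]
        dev = z - z.mean()
        num = sum(w[i, j] * dev[i] * dev[j]
                  for i in range(n) for j in range(n) if i != j)
        return (n / w.sum()) * num / np.sum(dev ** 2)

    def test_matches_double_sum_oracle(self, rng):
        loc = rng.uniform(0, 10, (25, 2))
        z = rng.normal(size=25)
        res = morans_i(GeoSample(loc, z))
        assert res["I"] == pytest.approx(self._oracle(loc, z), rel=1e-10)

    def test_checkerboard_negative(self):
        xs, ys = np.meshgrid(np.arange(6.0), np.arange(6.0))
        loc = np.column_stack([xs.ravel(), ys.ravel()])
        z = ((xs + ys) % 2).ravel().astype(float)
        res = morans_i(GeoSample(loc, z), weights="binary", bandwidth=1.0)
        assert res["I"] < -0.9  # rook neighbors always opposite color
        assert res["verdict"] == "dispersed"

    def test_gradient_strongly_positive(self):
        xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
        loc = np.column_stack([xs.ravel(), ys.ravel()])
        res = morans_i(GeoSample(loc, xs.ravel()))
        assert res["I"] > 0
        assert res["z_score"] > 3
        assert res["verdict"] == "autocorrelated"

    def test_iid_matches_null_expectation(self, rng):
        vals = []
        for _ in range(100):
            g = GeoSample(rng.uniform(0, 50, (40, 2)), rng.normal(size=40))
            vals.append(morans_i(g)["I"])
        assert np.mean(vals) == pytest.approx(-1 / 39, abs=0.01)

    def test_constant_z_rejected(self, rng):
        g = GeoSample(rng.uniform(0, 10, (12, 2)), np.ones(12))
        with pytest.raises(ValueError, match="zero variance"):
            morans_i(g)


class TestKriging:
    def _sample_and_model(self, seed=0):
        g = exp_field(150, 100.0, a=10.0, seed=seed)
        m = fit_variogram(empirical_variogram(g),
                          families=("exponential", "spherical"))
        return g, m

    def test_exact_at_data_nodes_with_zero_nugget(self, rng):
        loc = np.array([[10.0, 10.0], [30.0, 20.0], [20.0, 40.0],
                        [40.0, 40.0], [15.0, 30.0]])
        z = rng.normal(size=5)
        model = VariogramModel("exponential", 0.0, 1.0, 8.0,
                               8 * np.log(20), 1.0)
        kg = ordinary_kriging(GeoSample(loc, z), model, grid_spacing=5.0,
                              window=(50, 50), neighborhood=5)
        for (x, y), val in zip(loc, z):
            ix = int(round(x / 5.0))
            iy = int(round(y / 5.0))
            assert kg.z[iy, ix] == pytest.approx(val, abs=1e-8)
            assert kg.variance[iy, ix] == pytest.approx(0.0, abs=1e-8)

    def test_far_node_tends_to_local_mean_and_sill(self, rng):
        # lattice data with all pairs beyond the range: equal kriging
        # weights, so the far-field prediction is the neighborhood mean
        xs, ys = np.meshgrid(np.arange(5) * 2.0, np.arange(5) * 2.0)
        loc = np.column_stack([xs.ravel(), ys.ravel()])
        z = rng.normal(2.0, 1.0, 25)
        model = VariogramModel("exponential", 0.0, 1.5, 0.3,
                               0.3 * np.log(20), 1.0)
        kg = ordinary_kriging(GeoSample(loc, z), model, grid_spacing=10.0,
                              window=(100, 100), neighborhood=25)
        far = kg.z[-1, -1]  # node (100, 100), far beyond the range
        assert far == pytest.approx(z.mean(), abs=1e-3)
        assert kg.variance[-1, -1] >= 0.95 * model.sill

    def test_duplicate_locations_jittered_with_warning(self, rng):
        loc = np.vstack([[5.0, 5.0], [5.0, 5.0], rng.uniform(0, 10, (10, 2))])
        z = rng.normal(size=12)
        model = VariogramModel("exponential", 0.0, 1.0, 3.0, 9.0, 1.0)
        with pytest.warns(UserWarning, match="duplicate"):
            kg = ordinary_kriging(GeoSample(loc, z), model, grid_spacing=2.0,
                                  window=(10, 10))
        assert np.isfinite(kg.z).all()

    def test_cross_validation_msse_near_one(self):
        g, m = self._sample_and_model(seed=3)
        msse = loo_cross_validation(g, m)["msse"]
        assert msse == pytest.approx(1.0, abs=0.3)


class TestIsopleths:
    def _planar_grid(self):
        xs = np.linspace(0, 10, 21)
        ys = np.linspace(0, 10, 21)
        zz = np.tile(xs, (21, 1))  # z = x
        model = VariogramModel("linear", 0.0, 1.0, 10.0, 9.5, 1.0)
        return KrigingGrid(xs, ys, zz, np.zeros_like(zz), model)

    def test_planar_surface_gives_straight_vertical_contours(self):
        kg = self._planar_grid()
        contours = isopleth_contours(kg, levels=[2.5, 5.0, 7.5])
        assert len(contours) == 3
        for level, poly in contours:
            np.testing.assert_allclose(poly[:, 0], level, atol=1e-9)

    def test_radial_bump_gives_closed_contours(self):
        xs = ys = np.linspace(-5, 5, 41)
        xx, yy = np.meshgrid(xs, ys)
        zz = np.exp(-(xx ** 2 + yy ** 2) / 4)
        model = VariogramModel("gaussian", 0.0, 1.0, 2.0, 3.5, 1.0)
        kg = KrigingGrid(xs, ys, zz, np.zeros_like(zz), model)
        contours = isopleth_contours(kg, levels=[0.5])
        assert len(contours) == 1
        poly = contours[0][1]
        np.testing.assert_allclose(poly[0], poly[-1], atol=1e-9)  # closed

    def test_contour_count_monotone_in_levels(self):
        kg = self._planar_grid()
        n1 = len(isopleth_contours(kg, levels=[5.0]))
        n3 = len(isopleth_contours(kg, levels=[2.5, 5.0, 7.5]))
        assert n3 >= n1

    def test_constant_surface_no_contours(self):
        xs = ys = np.linspace(0, 1, 5)
        zz = np.ones((5, 5))
        model = VariogramModel("linear", 0.0, 1.0, 1.0, 0.95, 1.0)
        kg = KrigingGrid(xs, ys, zz, np.zeros_like(zz), model)
        assert isopleth_contours(kg, levels=[1.0]) == []
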