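"""Shape-on-size regression, CAC, module slopes, ANCOVA."""

import numpy as np
import pytest

from morphosig.align import gpa
from morphosig.allometry import (ShapeAllometry, compare_slopes_ancova,
                                 fit_shape_size_regression,
                                 module_size_allometry, cac_slope_per_module)
from morphosig.data import LandmarkConfiguration, SpecimenDataset, \
    ValidationError
from morphosig.simulate import make_scheme, make_truth, simulate_dataset


def linear_shape_data(n=15, k=9, seed=0, noise=0.0):
    """shape = consensus + (logCS - mean) * b, exactly linear."""
    rng = np.random.default_rng(seed)
    consensus = rng.standard_normal((k, 3))
    b = rng.standard_normal(3 * k)
    b /= np.linalg.norm(b)
    x = rng.uniform(-1, 1, n)
    Y = consensus.ravel()[None, :] + np.outer(x - x.mean(), 0.05 * b)
    if noise:
        Y = Y + noise * rng.standard_normal(Y.shape)
    return Y.reshape(n, k, 3), x, b


class TestShapeSizeRegression:
    def test_noiseless_linear_data_r2_one_and_cac_along_b(self):
        coords, x, b = linear_shape_data()
        res = fit_shape_size_regression(coords, log_sizes=x, n_perm=19)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        assert abs(res.cac @ b) == pytest.approx(1.0, abs=1e-10)

    def test_permuted_sizes_give_null_r2_and_uniformish_p(self):
        coords, x, _ = linear_shape_data(n=20)
        rng = np.random.default_rng(1)
        r2s, ps = [], []
        for _ in range(100):
            xp = rng.permutation(x)
            res = fit_shape_size_regression(coords, log_sizes=xp, n_perm=79,
                                            seed=int(rng.integers(2**31)))
            r2s.append(res.r_squared)
            ps.append(res.p_value)
        assert np.median(r2s) < 0.15
        # p approximately uniform: mean near 0.5, reasonable spread
        assert abs(np.mean(ps) - 0.5) < 0.12
        assert np.std(ps) > 0.15

    def test_generator_allometric_fraction_recovered(self):
        truth = make_truth(make_scheme(12, 5), seed=3)
        r2s = []
        for seed in range(5):
            ds, _ = simulate_dataset(truth, n_specimens=30, seed=seed)
            al = gpa(ds.complete_subset())
            r2s.append(fit_shape_size_regression(al, n_perm=1).r_squared)
        assert abs(np.median(r2s) - truth.allometric_fraction) < 0.1

    def test_cac_and_rsc_scores_exactly_uncorrelated(self, desk_aligned):
        res = ShapeAllometry(desk_aligned).fit(n_perm=9)
        s = res.cac_scores - res.cac_scores.mean()
        for j in range(res.rsc_scores.shape[1]):
            r = res.rsc_scores[:, j] - res.rsc_scores[:, j].mean()
            denom = np.linalg.norm(s) * np.linalg.norm(r)
            if denom > 0:
                assert abs(s @ r) / denom < 1e-8
        # residual directions orthonormal
        G = res.rsc_directions @ res.rsc_directions.T
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-8)

    def test_r2_invariant_to_rotation_of_aligned_data(self, desk_aligned):
        res1 = ShapeAllometry(desk_aligned).fit(n_perm=1)
        rng = np.random.default_rng(5)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        res2 = ShapeAllometry(desk_aligned.coords @ Q,
                              log_sizes=desk_aligned.log_sizes()).fit(n_perm=1)
        assert res1.r_squared == pytest.approx(res2.r_squared, abs=1e-12)

    def test_zero_size_variance_rejected(self):
        coords, x, _ = linear_shape_data()
        with pytest.raises(ValidationError, match="variance"):
            ShapeAllometry(coords, log_sizes=np.ones_like(x))


class TestAllometryCorrection:
    def test_noiseless_data_corrects_to_consensus(self):
        coords, x, _ = linear_shape_data()
        res = fit_shape_size_regression(coords, log_sizes=x, n_perm=1)
        corr = res.corrected()
        spread = corr.coords - corr.coords.mean(axis=0)
        assert np.max(np.abs(spread)) < 1e-12

    def test_refit_on_corrected_data_has_zero_r2(self, desk_aligned):
        res = ShapeAllometry(desk_aligned).fit(n_perm=1)
        corr = res.corrected()
        refit = ShapeAllometry(corr.coords,
                               log_sizes=desk_aligned.log_sizes()).fit(n_perm=1)
        assert refit.r_squared < 1e-10

    def test_corrected_variances_match_hand_computed_residuals(self):
        # 5-landmark toy: residual variance after removing the fitted
        # linear-in-size component, computed by hand
        rng = np.random.default_rng(6)
        n, k = 8, 5
        x = rng.uniform(0, 1, n)
        Y = rng.standard_normal((n, 3 * k)) * 0.01
        res = fit_shape_size_regression(Y.reshape(n, k, 3), log_sizes=x,
                                        n_perm=1)
        corr = res.corrected().coords.reshape(n, -1)
        xc = x - x.mean()
        b = (xc @ (Y - Y.mean(axis=0))) / (xc @ xc)
        expected = Y - np.outer(xc, b)
        np.testing.assert_allclose(corr, expected, atol=1e-12)


class TestPrediction:
    def test_mean_size_returns_consensus(self):
        coords, x, _ = linear_shape_data()
        res = fit_shape_size_regression(coords, log_sizes=x, n_perm=1)
        np.testing.assert_allclose(res.predict_shape_at_size(x.mean()),
                                   res.mean_shape, atol=1e-12)

    def test_noiseless_data_predicts_each_specimen(self):
        coords, x, _ = linear_shape_data()
        res = fit_shape_size_regression(coords, log_sizes=x, n_perm=1)
        for i in range(coords.shape[0]):
            np.testing.assert_allclose(res.predict_shape_at_size(x[i]),
                                       coords[i], atol=1e-10)

    def test_extrapolation_matches_hand_arithmetic(self):
        coords, x, _ = linear_shape_data(noise=1e-3, seed=7)
        res = fit_shape_size_regression(coords, log_sizes=x, n_perm=1)
        for q in (x.min() - 0.5, x.max() + 0.5):
            expect = (res.mean_shape.ravel()
                      + res.coef * (q - res.mean_log_size))
            np.testing.assert_allclose(res.predict_shape_at_size(q).ravel(),
                                       expect, atol=1e-12)


class TestModuleSizeAllometry:
    def _power_law_dataset(self, beta1, n=12, seed=0):
        """Two overlapping modules centered at the origin, so whole CS
        decomposes exactly: module 1's size is set to c * W^beta1 and
        module 2 absorbs the remainder of W."""
        from morphosig.data import FIXED, LandmarkScheme
        k1 = k2 = 6
        ids = tuple([f"a{i}" for i in range(k1)] + [f"b{i}" for i in range(k2)])
        scheme = LandmarkScheme(ids, (FIXED,) * (k1 + k2),
                                ("m1",) * k1 + ("m2",) * k2,
                                (False,) * (k1 + k2))
        rng = np.random.default_rng(seed)

        def unit_cluster(k):
            G = rng.standard_normal((k, 3))
            G -= G.mean(axis=0)
            return G / np.sqrt(np.sum(G ** 2))

        G1, G2 = unit_cluster(k1), unit_cluster(k2)
        W = np.exp(rng.uniform(-0.2, 0.2, n))
        c = 0.5
        configs = []
        for s in range(n):
            m1 = c * W[s] ** beta1
            m2 = np.sqrt(W[s] ** 2 - m1 ** 2)
            X = np.vstack([m1 * G1, m2 * G2])
            configs.append(LandmarkConfiguration(scheme, X, None, f"s{s}"))
        return SpecimenDataset(scheme, configs)

    def test_constructed_power_law_recovered_exactly(self):
        ds = self._power_law_dataset(1.5)
        tab = module_size_allometry(ds)
        assert tab.loc["m1", "slope"] == pytest.approx(1.5, abs=1e-8)

    def test_isometric_dataset_all_slopes_one(self):
        ds = self._power_law_dataset(1.0)
        tab = module_size_allometry(ds)
        np.testing.assert_allclose(tab["slope"].to_numpy(), 1.0, atol=1e-8)

    def test_slopes_invariant_to_common_rescaling(self, desk_dataset):
        ds, _ = desk_dataset
        sub = ds.complete_subset()
        tab1 = module_size_allometry(sub)
        scaled = SpecimenDataset(ds.scheme, [
            LandmarkConfiguration(ds.scheme, 3.7 * c.coords, None,
                                  c.specimen_id)
            for c in sub.configurations])
        tab2 = module_size_allometry(scaled)
        np.testing.assert_allclose(tab1["slope"], tab2["slope"], atol=1e-10)


class TestCACSlopes:
    def test_zero_shape_change_module_has_zero_slope(self):
        # module 0 carries no size-correlated shape change at all
        rng = np.random.default_rng(8)
        n, k = 14, 12
        x = rng.uniform(-1, 1, n)
        coords = np.zeros((n, k, 3))
        base = rng.standard_normal((k, 3))
        coords[:] = base
        b = np.zeros((k, 3))
        b[6:] = rng.standard_normal((6, 3))       # only module 1 changes
        coords += np.einsum("n,kd->nkd", x - x.mean(), b)
        from morphosig.align import AlignedDataset
        from morphosig.data import LandmarkScheme, FIXED
        scheme = LandmarkScheme(tuple(f"l{i}" for i in range(k)),
                                (FIXED,) * k,
                                ("m0",) * 6 + ("m1",) * 6, (False,) * k)
        al = AlignedDataset(scheme=scheme, coords=coords,
                            centroid_sizes=np.exp(x),
                            consensus=base, specimen_ids=[str(i) for i in
                                                          range(n)],
                            augmented=True)
        tab, _ = cac_slope_per_module(al)
        assert tab.loc["m0", "slope"] == pytest.approx(0.0, abs=1e-8)
        assert tab.loc["m1", "slope"] > 0.1

    def test_whole_slope_equals_coefficient_norm(self, desk_aligned):
        tab, _ = cac_slope_per_module(desk_aligned)
        res = ShapeAllometry(desk_aligned).fit(n_perm=1)
        assert tab.loc["whole", "slope"] == pytest.approx(
            np.linalg.norm(res.coef), rel=1e-10)

    def test_frill_analog_has_largest_cac_slope(self):
        wins = 0
        reps = 20
        truth = make_truth(make_scheme(12, 5), seed=9)
        for seed in range(reps):
            ds, _ = simulate_dataset(truth, n_specimens=30, seed=seed)
            al = gpa(ds.complete_subset())
            tab, _ = cac_slope_per_module(al)
            mods = tab.drop(index="whole")
            if mods["slope"].idxmax() == "frill":
                wins += 1
        assert wins >= int(0.9 * reps)


class TestANCOVA:
    def test_identical_groups_give_p_one(self):
        x = np.linspace(0, 1, 10)
        y = 2.0 * x + 0.3
        tab = compare_slopes_ancova(np.r_[x, x], np.r_[y, y],
                                    ["a"] * 10 + ["b"] * 10)
        assert tab.loc[0, "p"] == pytest.approx(1.0, abs=1e-9)

    def test_clearly_different_slopes_detected(self):
        rng = np.random.default_rng(10)
        x = np.linspace(0, 1, 25)
        y1 = 1.0 * x + 1e-7 * rng.standard_normal(25)
        y2 = 2.0 * x + 1e-7 * rng.standard_normal(25)
        tab = compare_slopes_ancova(np.r_[x, x], np.r_[y1, y2],
                                    ["a"] * 25 + ["b"] * 25)
        assert tab.loc[0, "p"] < 1e-6
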