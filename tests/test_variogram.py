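import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vsp.data import from_arrays
from vsp.errors import EmptyVariogramError, InsufficientDataError
from vsp.simulate import FieldSpec, simulate_field
from vsp.variogram import (VariogramModel, empirical_variogram, fit_variogram,
                           model_gamma, pairwise_semivariances)

from conftest import make_dataset


class TestPairwiseSemivariances:
    def test_three_four_five_triangle(self):
        ds = make_dataset([(3, 0.0, 0.2), (6, 0.4, 0.8)])
        pairs = pairwise_semivariances(ds)
        assert pairs.h[0] == pytest.approx(0.5)
        assert pairs.gamma[0] == pytest.approx(0.5 * 0.6**2)

    def test_equal_responses_give_zero_gamma(self):
        ds = make_dataset([(1, 0.0, 0.7), (5, 0.3, 0.7), (9, 0.8, 0.7)])
        pairs = pairwise_semivariances(ds)
        np.testing.assert_allclose(pairs.gamma, 0.0)

    def test_pair_count_is_n_choose_2(self, fixture_pair):
        ctl, _ = fixture_pair
        assert ctl.n == 48
        assert len(pairwise_semivariances(ctl)) == 48 * 47 // 2 == 1128

    def test_fewer_than_two_observations_rejected(self):
        ds = make_dataset([(1, 0.0, 0.5)])
        with pytest.raises(InsufficientDataError):
            pairwise_semivariances(ds)


class TestEmpiricalVariogram:
    def test_constant_field_has_zero_gamma_everywhere(self):
        rng = np.random.default_rng(1)
        ds = from_arrays(rng.uniform(0.1, 1, 20), rng.uniform(0, 1, 20),
                         np.full(20, 3.0))
        emp = empirical_variogram(pairwise_semivariances(ds), n_bins=5)
        np.testing.assert_allclose(emp.bin_gamma[emp.populated], 0.0)

    def test_two_bin_means_match_hand_enumeration(self, four_point_line):
        # pairs: h=0.1 x3 (gamma 0.5 each), h=0.2 x2 (gamma 0), h=0.3 (gamma 0.5);
        # the lag is set just past 0.3 so the farthest pair survives float round-off
        emp = empirical_variogram(pairwise_semivariances(four_point_line),
                                  n_bins=2, active_lag=0.305)
        np.testing.assert_allclose(emp.bin_gamma, [0.5, (0.0 + 0.0 + 0.5) / 3])
        np.testing.assert_array_equal(emp.bin_counts, [3, 3])

    def test_counts_never_exceed_total_pairs(self, random_dataset):
        pairs = pairwise_semivariances(random_dataset)
        emp = empirical_variogram(pairs, n_bins=8)
        n = random_dataset.n
        assert emp.bin_counts.sum() <= n * (n - 1) // 2
        assert np.all(np.isnan(emp.bin_gamma[~emp.populated]))

    def test_all_pairs_beyond_lag_is_error(self, four_point_line):
        pairs = pairwise_semivariances(four_point_line)
        with pytest.raises(EmptyVariogramError):
            empirical_variogram(pairs, n_bins=3, active_lag=0.01)

    def test_simulated_field_tracks_generating_model(self):
        # a single realisation fluctuates heavily (few independent correlation
        # patches), so average the empirical variogram over replicate fields
        model = VariogramModel("spherical", 0.0, 1.0, 0.3)
        acc = []
        for seed in range(20):
            ds = simulate_field(FieldSpec(model, 200, seed=seed))
            emp = empirical_variogram(pairwise_semivariances(ds), n_bins=10,
                                      active_lag=0.6)
            acc.append(emp.bin_gamma)
        mean_gamma = np.mean(acc, axis=0)
        expected = model_gamma(model, emp.bin_centers)
        assert np.all(np.abs(mean_gamma - expected) < 0.15 * model.sill)


class TestModelGamma:
    def test_zero_distance_convention(self, spherical_model):
        assert model_gamma(spherical_model, 0.0) == 0.0

    @pytest.mark.parametrize("family", ["spherical", "linear", "exponential", "gaussian"])
    def test_plateau_at_and_beyond_range(self, family):
        m = VariogramModel(family, 0.1, 0.9, 0.5)
        g = model_gamma(m, np.array([0.5, 1.0, 10.0]))
        if family in ("spherical", "linear"):
            np.testing.assert_allclose(g, m.sill)
        else:
            # practical range: ~95% of the sill at h = a, asymptotic beyond
            assert g[0] >= m.nugget + 0.95 * m.partial_sill - 1e-12
            assert np.all(g <= m.sill + 1e-12)

    def test_spherical_closed_form(self):
        m = VariogramModel("spherical", 0.0, 1.0, 1.0)
        assert model_gamma(m, 0.5) == pytest.approx(1.5 * 0.5 - 0.5 * 0.125)

    def test_negative_distance_rejected(self, spherical_model):
        with pytest.raises(ValueError):
            model_gamma(spherical_model, -0.1)

    @pytest.mark.parametrize("family", ["spherical", "linear", "exponential", "gaussian"])
    def test_covariance_nonnegative_and_vanishes_past_range(self, family):
        m = VariogramModel(family, 0.02, 0.08, 0.4)
        h = np.linspace(0, 2, 500)
        cov = m.covariance(h)
        assert np.all(cov >= -1e-12)
        if family == "spherical":
            np.testing.assert_allclose(cov[h >= m.range_], 0.0, atol=1e-15)


class TestFitVariogram:
    def test_noiseless_spherical_recovered_exactly(self, spherical_model):
        centers = np.linspace(0.02, 0.45, 12)
        d = centers[1] - centers[0]
        edges = np.concatenate([centers - d / 2, [centers[-1] + d / 2]])
        from vsp.variogram import EmpiricalVariogram
        emp = EmpiricalVariogram(edges, model_gamma(spherical_model, centers),
                                 np.full(12, 10), 0.47)
        fit = fit_variogram(emp, "spherical")
        assert fit.nugget == pytest.approx(0.01, rel=1e-6)
        assert fit.partial_sill == pytest.approx(0.04, rel=1e-6)
        assert fit.range_ == pytest.approx(0.19, rel=1e-6)

    def test_rss_beats_brute_force_grid(self, spherical_model):
        centers = np.linspace(0.02, 0.45, 12)
        d = centers[1] - centers[0]
        edges = np.concatenate([centers - d / 2, [centers[-1] + d / 2]])
        from vsp.variogram import EmpiricalVariogram
        gamma = model_gamma(spherical_model, centers)
        emp = EmpiricalVariogram(edges, gamma, np.full(12, 10), 0.47)
        fit = fit_variogram(emp, "spherical")

        # independent exhaustive grid search, resolution 1e-3
        c0s = np.arange(0.0, 0.021, 1e-3)
        cs = np.arange(0.03, 0.051, 1e-3)
        a_s = np.arange(0.15, 0.231, 1e-3)
        best = np.inf
        for c0 in c0s:
            for c in cs:
                curves = np.where(
                    centers[None, :] >= a_s[:, None],
                    c0 + c,
                    c0 + c * (1.5 * centers[None, :] / a_s[:, None]
                              - 0.5 * (centers[None, :] / a_s[:, None]) ** 3))
                best = min(best, float(((gamma - curves) ** 2).sum(axis=1).min()))
        assert fit.rss <= best + 1e-15

    def test_degenerate_constant_gamma_returns_pure_nugget(self):
        from vsp.variogram import EmpiricalVariogram
        emp = EmpiricalVariogram(np.linspace(0, 0.5, 6), np.full(5, 0.03),
                                 np.full(5, 4), 0.5)
        with pytest.warns(UserWarning, match="nugget"):
            fit = fit_variogram(emp)
        assert fit.partial_sill == 0.0
        assert fit.nugget == pytest.approx(0.03)


class TestInvariances:
    @given(st.floats(min_value=-5, max_value=5, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_translation_leaves_gammas_unchanged(self, shift):
        rng = np.random.default_rng(3)
        x, y, z = rng.uniform(0.1, 1, 15), rng.uniform(0, 1, 15), rng.normal(0, 1, 15)
        base = pairwise_semivariances(from_arrays(x, y, z))
        shifted = pairwise_semivariances(from_arrays(x, y, z + shift))
        np.testing.assert_allclose(shifted.gamma, base.gamma, rtol=0, atol=1e-9)

    @given(st.floats(min_value=0.1, max_value=10, allow_nan=False))
    @settings(max_examples=10, deadline=None)
    def test_scaling_z_scales_gamma_and_sill_not_range(self, s):
        rng = np.random.default_rng(4)
        x, y = rng.uniform(0.1, 1, 40), rng.uniform(0, 1, 40)
        z = np.sin(6 * x) + 0.3 * rng.normal(size=40)
        emp1 = empirical_variogram(pairwise_semivariances(from_arrays(x, y, z)), 8)
        emp2 = empirical_variogram(pairwise_semivariances(from_arrays(x, y, s * z)), 8)
        np.testing.assert_allclose(emp2.bin_gamma[emp2.populated],
                                   s**2 * emp1.bin_gamma[emp1.populated], rtol=1e-9)
        f1, f2 = fit_variogram(emp1), fit_variogram(emp2)
        assert f2.sill == pytest.approx(s**2 * f1.sill, rel=1e-3)
        assert f2.range_ == pytest.approx(f1.range_, rel=1e-3)
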