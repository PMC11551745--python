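import numpy as np
import pandas as pd
import pytest

from smmtracks import (TrackSet, d_from_msd, fit_gaussian_mixture,
                       fit_sqd_global, fit_sqd_mixture, frame_displacements,
                       msd, sigma_to_D, squared_displacements,
                       simulate_tracks)
from smmtracks.track_io import TRACK_COLUMNS

from conftest import free_config

DT = 0.030


def _make_trackset(trajs, delta_t=DT):
    rows = []
    for tid, xy in enumerate(trajs):
        for k, (x, y) in enumerate(xy):
            rows.append((0, tid, "green", k, x, y))
    return TrackSet(pd.DataFrame(rows, columns=TRACK_COLUMNS), delta_t)


class TestDisplacements:
    def test_stationary_track_gives_zeros(self):
        ts = _make_trackset([[(1.0, 2.0)] * 6])
        d = frame_displacements(ts)
        assert len(d) == 10
        assert np.all(d == 0.0)

    def test_constant_x_stepping(self):
        xy = [(0.1 * k, 0.0) for k in range(6)]
        ts = _make_trackset([xy])
        d = np.sort(frame_displacements(ts))
        np.testing.assert_allclose(d, [0.0] * 5 + [0.1] * 5, atol=1e-12)

    def test_no_pairs_raises(self):
        df = pd.DataFrame([(0, 0, "g", 0, 0.0, 0.0), (0, 0, "g", 5, 1.0, 1.0)],
                          columns=TRACK_COLUMNS)
        with pytest.raises(ValueError):
            frame_displacements(TrackSet(df, DT))

    def test_sample_variance_matches_analytic(self):
        D, sigma_loc = 0.12, 0.02
        cfg = free_config([1.0], [D], loc_noise_sigma=sigma_loc, n_cells=40,
                          n_molecules=20, n_frames=60, seed=4)
        tracks, _ = simulate_tracks(cfg)
        d = frame_displacements(tracks)
        assert len(d) >= 20_000
        expected = 2 * D * DT + 2 * sigma_loc**2
        assert np.var(d) == pytest.approx(expected, rel=0.05)

    def test_squared_displacement_345(self):
        ts = _make_trackset([[(0.0, 0.0), (0.3, 0.4)]])
        np.testing.assert_allclose(squared_displacements(ts), [0.25])

    def test_mean_squared_displacement_4ddt(self):
        D = 0.2
        cfg = free_config([1.0], [D], n_cells=40, n_molecules=20,
                          n_frames=60, seed=6)
        tracks, _ = simulate_tracks(cfg)
        r2 = squared_displacements(tracks)
        assert r2.mean() == pytest.approx(4 * D * DT, rel=0.05)


class TestSigmaToD:
    def test_zero(self):
        assert sigma_to_D(0.0, DT) == 0.0

    # inverting D = sigma^2 / (2 dt) at the two printed coefficients
    @pytest.mark.parametrize("sigma,expected", [(0.037147, 0.023),
                                                (0.087636, 0.128)])
    def test_printed_values(self, sigma, expected):
        assert sigma_to_D(sigma, DT) == pytest.approx(expected, abs=5e-5)

    def test_bad_delta_t(self):
        with pytest.raises(ValueError):
            sigma_to_D(0.1, 0.0)


class TestGaussianMixture:
    def test_all_zero_displacements(self):
        fit = fit_gaussian_mixture(np.zeros(100), K=2, delta_t=DT)
        assert fit.mixture.D[0] == 0.0
        assert "degenerate_sample" in fit.flags

    def test_two_component_fraction_recovery(self):
        # equal-weight mixture, sigma ratio 5
        rng = np.random.default_rng(12)
        n = 100_000
        s = np.where(rng.random(n) < 0.5, 0.02, 0.10)
        x = rng.normal(0.0, s)
        fit = fit_gaussian_mixture(x, K=2, delta_t=DT)
        assert fit.mixture.fractions[0] == pytest.approx(0.5, abs=0.03)
        np.testing.assert_allclose(fit.mixture.sigma, [0.02, 0.10], rtol=0.05)

    def test_single_component_identifiability(self):
        # K=2 on one-component data: either sigmas agree or one weight ~ 0
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 0.05, 20_000)
        fit = fit_gaussian_mixture(x, K=2, delta_t=DT)
        s = fit.mixture.sigma
        close = abs(s[1] - s[0]) / s[1] < 0.05
        tiny = fit.mixture.fractions.min() < 0.05
        assert close or tiny

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 0.05, 5000)
        fit = fit_gaussian_mixture(x, K=3, delta_t=DT)
        assert fit.mixture.fractions.sum() == pytest.approx(1.0, abs=1e-9)


class TestSqdMixture:
    def test_single_population_closed_form(self):
        # K=1: fitted CDF is 1 - exp(-u/4DΔt); D within 2% of moments
        rng = np.random.default_rng(17)
        D = 0.1
        r2 = rng.exponential(4 * D * DT, 10_000)
        fit = fit_sqd_mixture(r2, K=1, delta_t=DT)
        d_mom = r2.mean() / (4 * DT)
        assert fit.mixture.D[0] == pytest.approx(d_mom, rel=0.02)
        # fitted CDF functional form
        from smmtracks.diffusion import sqd_mixture_cdf
        u = np.linspace(0, 0.1, 50)
        np.testing.assert_allclose(
            sqd_mixture_cdf(u, [1.0], fit.mixture.D, DT),
            1 - np.exp(-u / (4 * fit.mixture.D[0] * DT)), atol=1e-12)

    def test_three_population_recovery(self):
        rng = np.random.default_rng(23)
        f = np.array([0.34, 0.36, 0.30])
        D = np.array([0.023, 0.128, 0.6])
        comp = rng.choice(3, 50_000, p=f)
        r2 = rng.exponential(4 * D[comp] * DT)
        fit = fit_sqd_mixture(r2, K=3, delta_t=DT)
        np.testing.assert_allclose(fit.mixture.D, D, rtol=0.10)
        np.testing.assert_allclose(fit.mixture.fractions, f, atol=0.05)

    def test_localization_term_recovers_true_D(self):
        rng = np.random.default_rng(29)
        D, s = 0.05, 0.03
        r2 = rng.exponential(4 * D * DT + 4 * s**2, 20_000)
        fit = fit_sqd_mixture(r2, K=1, delta_t=DT, loc_sigma=s)
        assert fit.mixture.D[0] == pytest.approx(D, rel=0.05)

    def test_fractions_sum_and_cdf_monotone(self):
        rng = np.random.default_rng(31)
        r2 = rng.exponential(0.01, 2000)
        fit = fit_sqd_mixture(r2, K=2, delta_t=DT)
        assert fit.mixture.fractions.sum() == pytest.approx(1.0, abs=1e-9)
        from smmtracks.diffusion import sqd_mixture_cdf
        u = np.linspace(0, 1.0, 500)
        cdf = sqd_mixture_cdf(u, fit.mixture.fractions, fit.mixture.D, DT)
        assert cdf[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(cdf) >= 0)
        assert cdf[-1] <= 1.0

    def test_component_order_invariant_to_permutation(self):
        rng = np.random.default_rng(37)
        comp = rng.choice(2, 20_000, p=[0.5, 0.5])
        r2 = rng.exponential(np.where(comp == 0, 0.003, 0.05))
        fit1 = fit_sqd_mixture(r2, K=2, delta_t=DT)
        fit2 = fit_sqd_mixture(r2[::-1].copy(), K=2, delta_t=DT)
        np.testing.assert_allclose(fit1.mixture.D, fit2.mixture.D, rtol=1e-6)
        assert np.all(np.diff(fit1.mixture.D) > 0)

    def test_degenerate_sample_flagged(self):
        fit = fit_sqd_mixture(np.full(100, 0.01), K=3, delta_t=DT)
        assert "degenerate_sample" in fit.flags
        assert fit.mixture.K == 1


class TestSqdGlobal:
    def test_identical_conditions_match_individual_fit(self):
        rng = np.random.default_rng(41)
        f = [0.4, 0.6]
        D = np.array([0.02, 0.3])
        samples = {}
        for c in ("a", "b"):
            comp = rng.choice(2, 15_000, p=f)
            samples[c] = rng.exponential(4 * D[comp] * DT)
        glob = fit_sqd_global(samples, K=2, delta_t=DT)
        solo = fit_sqd_mixture(samples["a"], K=2, delta_t=DT)
        np.testing.assert_allclose(glob["a"].mixture.D, solo.mixture.D,
                                   rtol=0.10)
        # shared D: both conditions report identical coefficients
        np.testing.assert_allclose(glob["a"].mixture.D, glob["b"].mixture.D)

    def test_condition_specific_fractions_recovered(self):
        rng = np.random.default_rng(43)
        D = np.array([0.02, 0.3])
        truth = {"ctrl": [0.3, 0.7], "target": [0.7, 0.3]}
        samples = {}
        for c, f in truth.items():
            comp = rng.choice(2, 10_000, p=f)
            samples[c] = rng.exponential(4 * D[comp] * DT)
        glob = fit_sqd_global(samples, K=2, delta_t=DT)
        for c, f in truth.items():
            np.testing.assert_allclose(glob[c].mixture.fractions, f,
                                       atol=0.05)
            np.testing.assert_allclose(glob[c].mixture.D, D, rtol=0.10)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            fit_sqd_global({"only": np.ones(100)}, K=2, delta_t=DT)


class TestMSD:
    def test_stationary_zero(self):
        ts = _make_trackset([[(0.5, 0.5)] * 10])
        curve = msd(ts, max_lag_frames=4)
        np.testing.assert_allclose(curve.msd, 0.0)

    def test_ballistic_closed_form(self):
        d = 0.05
        xy = [(d * k, 0.0) for k in range(12)]
        curve = msd(_make_trackset([xy]), max_lag_frames=5)
        np.testing.assert_allclose(curve.msd,
                                   (np.arange(1, 6) * d) ** 2, atol=1e-12)

    def test_pair_counts_non_increasing(self):
        cfg = free_config([1.0], [0.1], n_cells=5, n_molecules=10,
                          n_frames=40, seed=2)
        tracks, _ = simulate_tracks(cfg)
        curve = msd(tracks, max_lag_frames=8)
        assert np.all(np.diff(curve.n_pairs) <= 0)

    def test_brownian_slope_recovers_D(self):
        D = 0.15
        cfg = free_config([1.0], [D], n_cells=60, n_molecules=20,
                          n_frames=40, seed=10)
        tracks, _ = simulate_tracks(cfg)
        assert tracks.n_tracks >= 1000
        curve = msd(tracks, max_lag_frames=6)
        d_est, b, info = d_from_msd(curve, n_fit_points=4)
        assert d_est == pytest.approx(D, rel=0.05)
        assert abs(b) < 0.2 * 4 * D * DT

    def test_exact_linear_curve(self):
        lags = np.arange(1, 7) * DT
        curve_vals = 4 * 0.1 * lags
        from smmtracks.diffusion import MSDCurve
        curve = MSDCurve(lags_s=lags, msd=curve_vals,
                         n_pairs=np.full(6, 100), sem=np.full(6, 1e-4),
                         delta_t=DT)
        d_est, b, info = d_from_msd(curve, n_fit_points=6)
        assert d_est == pytest.approx(0.1, rel=1e-9)
        assert b == pytest.approx(0.0, abs=1e-12)
        assert info["r_squared"] == pytest.approx(1.0, abs=1e-9)

    def test_ballistic_flagged_by_low_r_squared(self):
        d = 0.05
        xy = [(d * k, 0.0) for k in range(30)]
        curve = msd(_make_trackset([xy]), max_lag_frames=20)
        _, _, info = d_from_msd(curve, n_fit_points=20)
        assert info["r_squared"] < 0.97  # quadratic growth fits a line badly

    def test_too_few_lags(self):
        ts = _make_trackset([[(0.0, 0.0)] * 10])
        curve = msd(ts, max_lag_frames=2)
        with pytest.raises(ValueError):
            d_from_msd(curve, n_fit_points=4)
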