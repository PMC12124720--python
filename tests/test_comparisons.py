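"""Comparison estimators: windowed averaging, tail fits, MSD/Einstein,
Nernst-Einstein and Yeh-Hummer."""

import numpy as np
import pytest

from gktransport import units
from gktransport.comparisons import (
    einstein_estimate,
    fit_exponential_tail,
    fit_stretched_tail,
    msd,
    nernst_einstein,
    windowed_average,
    yeh_hummer,
)
from gktransport.correlation import CAFResult, caf
from gktransport.estimator import RunningIntegral, running_integral
from gktransport.series import split_series
from gktransport.synthetic import brownian_trajectory, ou_series

from conftest import direct_msd


def make_ri(I, dt=1.0):
    I = np.atleast_2d(np.asarray(I, float))
    return RunningIntegral(I=I, u=np.ones_like(I), dt=dt,
                           lags=np.arange(1, I.shape[1] + 1), pairs=(("x", "x"),))


def analytic_caf(C, dt_fs):
    C = np.atleast_2d(np.asarray(C, float))
    return CAFResult(lags=np.arange(C.shape[1]), C=C,
                     u=np.full_like(C, 1e-6), M=2, N=C.shape[1],
                     dt=dt_fs, pairs=(("x", "x"),))


class TestWindowedAverage:
    def test_constant_integral_any_window(self):
        ri = make_ri(np.full(50, 4.2))
        for w in (2.0, 10.0, 30.0):
            np.testing.assert_allclose(windowed_average(ri, w), 4.2)

    def test_ramp_sliding_mean(self):
        ri = make_ri(np.arange(10.0))
        got = windowed_average(ri, 2.0)  # window of 2 dt -> mean of 3 points
        np.testing.assert_allclose(got[0], np.arange(1.0, 9.0))
        assert got.shape[1] == 8

    def test_window_too_large(self):
        ri = make_ri(np.arange(5.0))
        with pytest.raises(ValueError):
            windowed_average(ri, 5.0)

    def test_variance_decreases_with_window(self):
        series = ou_series(tau=1.0, sigma2=1.0, dt=10.0, n_steps=10**5,
                           n_components=1, seed=21)
        ri = running_integral(caf(split_series(series, 100e3)))
        variances = []
        for w_ps in (1.0, 5.0, 20.0):
            g = windowed_average(ri, w_ps * 1e3)
            variances.append(np.var(g[0, :2000]))
        assert variances[0] > variances[1] > variances[2]


class TestExponentialTailFit:
    def test_single_exponential_exact(self):
        t = np.arange(0, 30, 0.01)
        fit = fit_exponential_tail(analytic_caf(2 * np.exp(-t / 3.0), 10.0),
                                   k=1, switch_grid=[0.01])
        assert fit.params["A"][0] == pytest.approx(2.0, rel=1e-6)
        assert fit.params["tau"][0] == pytest.approx(3.0, rel=1e-6)
        assert fit.total_integral == pytest.approx(6.0, rel=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_biexponential_total_integral(self):
        t = np.arange(0, 50, 0.01)
        c = np.exp(-t / 1.0) + 0.5 * np.exp(-t / 5.0)
        fit = fit_exponential_tail(analytic_caf(c, 10.0), k=2)
        assert fit.total_integral == pytest.approx(3.5, rel=5e-3)

    def test_misspecified_single_exponential_biased(self):
        t = np.arange(0, 50, 0.01)
        c = np.exp(-t / 1.0) + 0.5 * np.exp(-t / 5.0)
        # while both relaxation processes are present a single
        # exponential cannot represent the decay
        fit = fit_exponential_tail(analytic_caf(c, 10.0), k=1, switch_grid=[0.05])
        assert abs(fit.total_integral - 3.5) / 3.5 > 0.005

    def test_r_squared_selects_among_candidates(self):
        t = np.arange(0, 50, 0.01)
        c = np.exp(-t / 1.0) + 0.5 * np.exp(-t / 5.0)
        fit = fit_exponential_tail(analytic_caf(c, 10.0), k=2)
        assert len(fit.candidates) > 1
        assert fit.r_squared >= max(r2 for _, r2, _ in fit.candidates) - 1e-12

    def test_invalid_k(self):
        t = np.arange(0, 5, 0.1)
        with pytest.raises(ValueError):
            fit_exponential_tail(analytic_caf(np.exp(-t), 100.0), k=0)


class TestStretchedTailFit:
    def test_alpha_one_reduces_to_exponential(self):
        t = np.arange(0, 20, 0.01)
        fit = fit_stretched_tail(analytic_caf(1.5 * np.exp(-t), 10.0),
                                 switch_grid=[0.5])
        assert fit.params["alpha"] == pytest.approx(1.0, rel=1e-5)
        # tail = a tau e^{-t_switch} with tau = 1
        assert fit.tail_part == pytest.approx(1.5 * np.exp(-0.5), rel=1e-5)

    def test_gaussian_tail_integral(self):
        t = np.arange(0, 6, 0.001)
        fit = fit_stretched_tail(analytic_caf(np.exp(-(t**2)), 1.0),
                                 switch_grid=[0.001])
        assert fit.params["alpha"] == pytest.approx(2.0, rel=1e-5)
        total = fit.total_integral
        assert total == pytest.approx(np.sqrt(np.pi) / 2, rel=1e-3)

    def test_parameter_recovery_within_one_percent(self):
        a, alpha = 0.8, 1.4
        t = np.arange(0, 10, 0.005)
        fit = fit_stretched_tail(analytic_caf(a * np.exp(-(t**alpha)), 5.0))
        assert fit.params["a"] == pytest.approx(a, rel=0.01)
        assert fit.params["alpha"] == pytest.approx(alpha, rel=0.01)


class TestMSD:
    def test_ballistic_motion_quadratic(self):
        t = np.arange(100.0)
        v = np.array([0.3, -0.1, 0.2])
        pos = t[:, None] * v[None, :]
        result = msd(pos, dt=1e3)  # 1 ps steps
        want = (v @ v) * result.times**2
        np.testing.assert_allclose(result.msd, want, rtol=1e-8, atol=1e-10)

    def test_stationary_particle_zero(self):
        result = msd(np.zeros((50, 3)), dt=1.0)
        np.testing.assert_allclose(result.msd, 0.0, atol=1e-12)

    def test_fft_matches_direct_oracle(self):
        rng = np.random.default_rng(31)
        x = np.cumsum(rng.standard_normal((300, 4, 3)), axis=0)
        result = msd(x, dt=1.0)
        np.testing.assert_allclose(result.msd, direct_msd(x), rtol=1e-8)

    def test_brownian_diffusion_recovery(self):
        d_true = 1e-7  # m^2/s -> 0.1 nm^2/ps
        pos = brownian_trajectory(d_true, dt=100.0, n_steps=20000,
                                  n_particles=50, seed=32)
        result = msd(pos, dt=100.0, max_lag=4000)
        est = einstein_estimate(result, (50.0, 300.0), "diffusion")
        assert est.value == pytest.approx(d_true, rel=0.05)

    def test_wrapped_input_rejected(self):
        with pytest.raises(ValueError, match="unwrap"):
            msd(np.zeros((10, 3)), dt=1.0, unwrapped=False)


class TestEinsteinEstimate:
    def test_exact_linear_msd_recovers_diffusion(self):
        d_nm2_ps = 0.25
        times = np.arange(200.0)
        from gktransport.comparisons import MSDResult
        result = MSDResult(times=times, msd=6 * d_nm2_ps * times)
        est = einstein_estimate(result, (20.0, 150.0), "diffusion")
        assert est.value == pytest.approx(d_nm2_ps * 1e-6, rel=1e-12)
        assert est.uncertainty == pytest.approx(0.0, abs=1e-15)

    def test_conductivity_prefactor_applied(self):
        from gktransport.comparisons import MSDResult
        times = np.arange(100.0)
        slope = 2.0  # (e nm)^2 / ps
        result = MSDResult(times=times, msd=slope * times)
        est = einstein_estimate(result, (10.0, 90.0), "conductivity",
                                volume_nm3=100.0, temperature=300.0)
        want = slope * units.einstein_prefactor("conductivity", 100.0, 300.0)
        assert est.value == pytest.approx(want, rel=1e-12)

    def test_window_outside_range(self):
        from gktransport.comparisons import MSDResult
        result = MSDResult(times=np.arange(10.0), msd=np.arange(10.0))
        with pytest.raises(ValueError, match="window"):
            einstein_estimate(result, (50.0, 60.0), "diffusion")


class TestNernstEinstein:
    def test_hand_value(self):
        kappa = nernst_einstein({"+": 1e-11, "-": 1e-11},
                                {"+": 1, "-": -1},
                                {"+": 500, "-": 500},
                                volume=1e-25, temperature=300.0)
        assert kappa == pytest.approx(0.6198, rel=1e-3)

    def test_zero_diffusion_zero_conductivity(self):
        assert nernst_einstein({"a": 0.0}, {"a": 2}, {"a": 10}, 1e-25, 300.0) == 0.0

    def test_volume_scaling(self):
        args = ({"a": 1e-11}, {"a": 1}, {"a": 100})
        assert nernst_einstein(*args, 2e-25, 300.0) == pytest.approx(
            nernst_einstein(*args, 1e-25, 300.0) / 2
        )

    def test_incongruent_species_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            nernst_einstein({"a": 1e-11}, {"b": 1}, {"a": 1}, 1e-25, 300.0)


class TestYehHummer:
    def test_hand_correction(self):
        corr = yeh_hummer(0.0, 298.15, 1e-3, 5e-9)
        assert corr == pytest.approx(1.2392e-10, rel=1e-3)

    def test_infinite_viscosity_limit(self):
        assert yeh_hummer(3e-11, 300.0, 1e6, 5e-9) == pytest.approx(3e-11, rel=1e-6)

    def test_inverse_box_length_scaling(self):
        c1 = yeh_hummer(0.0, 300.0, 1e-3, 4e-9)
        c2 = yeh_hummer(0.0, 300.0, 1e-3, 2e-9)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            yeh_hummer(1e-11, 300.0, -1.0, 5e-9)


class TestGkEinsteinConsistency:
    def test_conductivity_routes_agree_on_charged_random_walkers(self):
        """The dipole-MSD (Einstein) and current-CAF (GK) conductivities
        agree on the same synthetic data within combined uncertainties.

        The walkers are partitioned into independent groups acting as
        replicas: a single collective MSD has strongly correlated lag
        points, so its OLS slope stderr is not a usable uncertainty —
        the honest error bar is the scatter of the slope over groups.
        """
        from gktransport.pipeline import estimate_transport
        from gktransport.series import CurrentSeries

        rng = np.random.default_rng(33)
        n_steps, n_groups, per_group = 60_000, 8, 8
        n_walkers = n_groups * per_group
        d_nm2_ps = 0.05
        dt_fs = 10.0
        charges = np.array([1.0, -1.0] * (n_walkers // 2))
        steps = rng.standard_normal((n_steps - 1, n_walkers, 3)) * np.sqrt(
            2 * d_nm2_ps * dt_fs * 1e-3
        )
        pos = np.zeros((n_steps, n_walkers, 3))
        np.cumsum(steps, axis=0, out=pos[1:])
        dipoles = [
            np.einsum("k,tkd->td", charges[g::n_groups], pos[:, g::n_groups])
            for g in range(n_groups)
        ]
        v_nm3, t_k = 100.0, 300.0
        pref = units.einstein_prefactor("conductivity", v_nm3, t_k)

        slopes = []
        for dip in dipoles:
            result = msd(dip, dt=dt_fs, max_lag=20_000)
            sel = (result.times >= 50.0) & (result.times <= 150.0)
            slopes.append(np.polyfit(result.times[sel], result.msd[sel], 1)[0])
        kappa_msd = np.mean(slopes) * pref * n_groups  # groups add in parallel
        u_msd = np.std(slopes, ddof=1) / np.sqrt(n_groups) * pref * n_groups

        currents = [
            CurrentSeries((np.diff(dip, axis=0) / (dt_fs * 1e-3)).T,
                          dt=dt_fs, property_tag="electric_current")
            for dip in dipoles
        ]
        est_gk, _, _ = estimate_transport(
            currents, "conductivity", interval_length=100.0, max_lag=20.0,
            volume=v_nm3, temperature=t_k,
        )
        kappa_gk = est_gk.value * n_groups
        u_gk = est_gk.uncertainty * n_groups
        assert est_gk.converged
        assert abs(kappa_gk - kappa_msd) <= 3 * np.hypot(u_gk, u_msd)
        # both recover the analytic kappa = e^2 sum(q^2) D / (V kB T)
        d_si = d_nm2_ps * units.NM**2 / units.PS
        kappa_true = (units.E_CHARGE**2 * n_walkers * d_si
                      / (v_nm3 * units.NM**3 * units.KB * t_k))
        assert kappa_gk == pytest.approx(kappa_true, rel=0.2)
        assert kappa_msd == pytest.approx(kappa_true, rel=0.2)
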