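import numpy as np
import pytest
from scipy.integrate import quad

from efgrelax.core import CONSTANTS
from efgrelax.correlation import TensorACF, fit_acf
from efgrelax.synthetic import (TENSOR_BASIS, gen_brownian_walkers,
                                gen_maxwell_stress, gen_rotational_diffusion)
from efgrelax.transport import (DiffusiveRegimeError, OrientationSeries,
                                StressSeries, dipole_reorientation_time,
                                effective_sed_fit, green_kubo_viscosity,
                                msd, msd_diffusion, sed_time, stokes_radius,
                                stress_acf, structural_relaxation_time,
                                unwrap_trajectory, xi_cubic,
                                yeh_hummer_correct)

KB = CONSTANTS.k_B


def maxwell_acf(G, tau, dt, t_max):
    lags = np.arange(0.0, t_max + dt / 2, dt)
    vals = G * np.exp(-lags / tau)
    return TensorACF(lags=lags, values=vals, stderr=np.zeros_like(vals),
                     n_origins=np.ones_like(vals), dt=dt)


class TestStressACF:
    def test_pure_pressure_has_no_shear_signal(self):
        stress = 1e7 * np.tile(np.eye(3), (100, 1, 1))
        series = StressSeries(stress=stress, dt=1.0, volume=1e3,
                              temperature=300.0)
        acf = stress_acf(series, max_lag=20.0)
        assert np.allclose(acf.values, 0.0)

    def test_antisymmetric_part_ignored(self):
        rng = np.random.default_rng(0)
        sym = rng.standard_normal((200, 3, 3))
        sym = 0.5 * (sym + np.transpose(sym, (0, 2, 1)))
        anti = rng.standard_normal((200, 3, 3))
        anti = 0.5 * (anti - np.transpose(anti, (0, 2, 1)))
        a = stress_acf(StressSeries(sym, 1.0, 1e3, 300.0), max_lag=30.0)
        b = stress_acf(StressSeries(sym + anti, 1.0, 1e3, 300.0),
                       max_lag=30.0)
        assert np.allclose(a.values, b.values, rtol=1e-12)

    def test_isotropic_offset_invariance(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal((200, 3, 3))
        a = stress_acf(StressSeries(s, 1.0, 1e3, 300.0), max_lag=30.0)
        b = stress_acf(StressSeries(s + 5.0 * np.eye(3), 1.0, 1e3, 300.0),
                       max_lag=30.0)
        assert np.allclose(a.values, b.values, rtol=1e-12)

    def test_planted_ou_modes_variance(self):
        series, truth = gen_maxwell_stress(G=2e13, tau=300.0, volume=27e3,
                                           temperature=300.0, dt=5.0,
                                           n_frames=100_000, seed=3)
        acf = stress_acf(series, max_lag=50.0)
        assert acf.c0 == pytest.approx(truth["G"], rel=0.02)


class TestGreenKubo:
    def test_analytic_maxwell_closed_form(self):
        """eta = V G tau / (k_B T) when C_stress = G exp(-t/tau)."""
        G, tau, vol, T = 1e13, 500.0, 27e3, 300.0
        acf = maxwell_acf(G, tau, dt=1.0, t_max=10000.0)
        tail = fit_acf(acf, "exp", window=(0.0, 5000.0))
        res = green_kubo_viscosity(acf, vol, T, cutoff=10000.0,
                                   tail_fit=tail)
        expected = vol * 1e-30 * G * tau * 1e-15 / (KB * T)
        assert res.eta == pytest.approx(expected, rel=1e-4)

    def test_zero_stress(self):
        stress = np.zeros((100, 3, 3))
        acf = stress_acf(StressSeries(stress, 1.0, 1e3, 300.0), max_lag=20.0)
        res = green_kubo_viscosity(acf, 1e3, 300.0, cutoff=20.0)
        assert res.eta == 0.0

    def test_sampled_maxwell_recovery(self):
        series, truth = gen_maxwell_stress(G=1e13, tau=500.0, volume=27e3,
                                           temperature=298.15, dt=1.0,
                                           n_frames=500_000, seed=4)
        acf = stress_acf(series, max_lag=4000.0)
        res = green_kubo_viscosity(acf, series.volume, series.temperature,
                                   cutoff=3000.0)
        assert res.eta == pytest.approx(truth["eta"], rel=0.05)


class TestMSDDiffusion:
    def test_brownian_recovery_multirun(self):
        """Planted D recovered within 5% by the multi-run mean over
        independent 64-walker ensembles."""
        D = 1e-4
        estimates = []
        for seed in range(16):
            pos, truth = gen_brownian_walkers(D, 64, 10.0, 10_000, seed=seed)
            estimates.append(msd_diffusion(pos, 10.0).D)
        assert np.mean(estimates) == pytest.approx(truth["D_si"], rel=0.05)

    def test_static_particles(self):
        pos = np.zeros((1000, 8, 3))
        res = msd_diffusion(pos, 1.0)
        assert res.D == 0.0

    def test_ballistic_raises(self):
        t = np.arange(2000.0)
        pos = np.zeros((2000, 4, 3))
        pos[:, :, 0] = 0.01 * t[:, None]
        with pytest.raises(DiffusiveRegimeError):
            msd_diffusion(pos, 1.0)

    def test_msd_fft_matches_direct(self):
        rng = np.random.default_rng(5)
        pos = np.cumsum(rng.standard_normal((300, 3, 3)), axis=0)
        m = msd(pos)
        # direct multi-origin reference
        n = pos.shape[0]
        direct = np.zeros(n)
        for t in range(n):
            d = pos[t:] - pos[: n - t]
            direct[t] = np.mean(np.sum(d ** 2, axis=2))
        assert np.allclose(m, direct, rtol=1e-8, atol=1e-8)

    def test_unwrap_round_trip(self):
        rng = np.random.default_rng(6)
        true = np.cumsum(0.3 * rng.standard_normal((500, 4, 3)), axis=0)
        wrapped = np.mod(true, 5.0)
        unwrapped = unwrap_trajectory(wrapped, 5.0)
        # equal up to a constant offset per particle
        shifted = unwrapped - unwrapped[0] + true[0]
        assert np.allclose(shifted, true, atol=1e-9)


class TestYehHummer:
    def test_arithmetic_oracle(self):
        D, eta, T, L = 1.0e-9, 0.89e-3, 298.15, 3.1e-9
        res = yeh_hummer_correct(D, eta, T, L)
        corr = KB * T * res.xi / (6 * np.pi * eta * L)
        assert res.D_infinity == pytest.approx(D + corr, rel=1e-12)
        assert res.correction_fraction == pytest.approx(corr / D, rel=1e-12)

    def test_infinite_box_limit(self):
        res = yeh_hummer_correct(1e-9, 1e-3, 300.0, 1.0)   # L = 1 metre
        assert res.D_infinity == pytest.approx(1e-9, rel=1e-9)

    def test_construction_in_measured_band(self):
        """Inputs tuned for a 17-22% correction reproduce it exactly."""
        D, eta, T = 1.0e-9, 0.89e-3, 298.15
        xi = xi_cubic()
        frac = 0.20
        L = KB * T * xi / (6 * np.pi * eta * frac * D)
        res = yeh_hummer_correct(D, eta, T, L)
        assert res.correction_fraction == pytest.approx(frac, rel=1e-10)
        assert 0.17 <= res.correction_fraction <= 0.22


class TestXiCubic:
    def test_reference_value(self):
        assert xi_cubic() == pytest.approx(2.837297, abs=1e-6)

    def test_alpha_invariance(self):
        a = xi_cubic(alpha=np.sqrt(np.pi))
        b = xi_cubic(alpha=0.5 * np.sqrt(np.pi))
        assert a == pytest.approx(b, abs=1e-8)

    def test_underconvergence_flagged(self):
        xi, diag = xi_cubic(alpha=3.0, min_recip_shells=1,
                            return_diagnostics=True)
        assert not diag["converged"]
        assert abs(xi - 2.837297) > 1e-4
        with pytest.raises(RuntimeError):
            xi_cubic(alpha=3.0, min_recip_shells=1)


class TestStokesSED:
    def test_stokes_radius_arithmetic(self):
        D, eta, T = 1.33e-9, 0.89e-3, 298.15
        r0 = stokes_radius(D, eta, T)
        assert r0 == pytest.approx(KB * T / (6 * np.pi * eta * D), rel=1e-14)
        assert 1.5e-10 < r0 < 2.0e-10

    def test_doubling_eta_halves_radius(self):
        r1 = stokes_radius(1e-9, 1e-3, 300.0)
        r2 = stokes_radius(1e-9, 2e-3, 300.0)
        assert r2 == pytest.approx(r1 / 2.0, rel=1e-14)

    def test_sed_time_magnitude(self):
        tau = sed_time(0.89e-3, 2.0e-10, 298.15)
        assert tau == pytest.approx(7.2e-12, rel=0.01)

    def test_sed_cubic_scaling(self):
        t1 = sed_time(1e-3, 1e-10, 300.0)
        t8 = sed_time(1e-3, 2e-10, 300.0)
        assert t8 == pytest.approx(8 * t1, rel=1e-14)
        assert sed_time(1e-3, 1e-10, 600.0) == pytest.approx(t1 / 2,
                                                             rel=1e-14)

    def test_sed_stokes_round_trip_scaling(self):
        """tau_SED from the Stokes radius scales as eta^-2 D^-3."""
        def tau_of(D, eta, T=300.0):
            return sed_time(eta, stokes_radius(D, eta, T), T)
        base = tau_of(1e-9, 1e-3)
        assert tau_of(1e-9, 2e-3) == pytest.approx(base / 4, rel=1e-12)
        assert tau_of(2e-9, 1e-3) == pytest.approx(base / 8, rel=1e-12)


class TestEffectiveSEDFit:
    def test_noiseless_recovery_exact(self):
        """Data generated from r0_eff = 0.69 A, tau0 = 0.11 ps come back
        to machine precision."""
        r0, tau0 = 0.69e-10, 0.11e-12
        x = np.linspace(1e20, 4e20, 6)          # eta/kBT in s/m^3
        tau = 4 * np.pi * r0 ** 3 / 3 * x + tau0
        res = effective_sed_fit(tau, x)
        assert res.r0_eff == pytest.approx(r0, rel=1e-10)
        assert res.tau0_eff == pytest.approx(tau0, rel=1e-10)

    def test_zero_slope(self):
        x = np.linspace(1e20, 2e20, 5)
        tau = np.full(5, 3e-13)
        res = effective_sed_fit(tau, x)
        assert res.r0_eff == pytest.approx(0.0, abs=1e-12)
        assert res.tau0_eff == pytest.approx(3e-13, rel=1e-12)

    def test_negative_slope_flagged(self):
        x = np.linspace(1e20, 2e20, 5)
        res = effective_sed_fit(-1e-33 * x + 1e-12, x)
        assert res.flags and np.isnan(res.r0_eff)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            effective_sed_fit([1e-12, 2e-12], [1e20, 2e20])

    def test_noisy_monte_carlo_recovery(self):
        """10% multiplicative noise, 8 points: slope back within 2 SE in
        >= 90% of replicates."""
        r0, tau0 = 0.69e-10, 0.11e-12
        slope_true = 4 * np.pi * r0 ** 3 / 3
        x = np.linspace(1e20, 5e20, 8)
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            tau = (slope_true * x + tau0) * (1 + 0.1 * rng.standard_normal(8))
            res = effective_sed_fit(tau, x)
            if abs(res.slope - slope_true) <= 2 * res.slope_se:
                hits += 1
        assert hits / n_rep >= 0.9


class TestDipoleReorientation:
    def test_planted_rotational_diffusion(self):
        series, truth = gen_rotational_diffusion(D_r=1e-3, n_vectors=256,
                                                 dt=2.0, n_frames=6000,
                                                 seed=2)
        res = dipole_reorientation_time(series, max_lag=5000.0)
        assert res.tau_dip == pytest.approx(truth["tau_dip"], rel=0.03)

    def test_frozen_orientations_flagged(self):
        u = np.tile(np.array([0.0, 0.0, 1.0]), (500, 10, 1))
        res = dipole_reorientation_time(OrientationSeries(u, dt=1.0),
                                        max_lag=100.0)
        assert res.flags and not res.converged

    def test_memoryless_limit(self):
        rng = np.random.default_rng(7)
        u = rng.standard_normal((4000, 64, 3))
        u /= np.linalg.norm(u, axis=-1, keepdims=True)
        res = dipole_reorientation_time(OrientationSeries(u, dt=3.0),
                                        max_lag=300.0)
        assert res.tau_dip <= 3.0


class TestStructuralRelaxation:
    @staticmethod
    def _stretched_acf(tau_k, beta_k, dt=2.0, t_max=8000.0):
        lags = np.arange(0.0, t_max, dt)
        vals = np.exp(-np.power(lags / tau_k, beta_k, where=lags > 0,
                                out=np.zeros_like(lags)))
        return TensorACF(lags=lags, values=vals,
                         stderr=np.zeros_like(vals),
                         n_origins=np.ones_like(vals), dt=dt)

    def test_beta_one_reduces_to_exponential_mean(self):
        acf = self._stretched_acf(300.0, 1.0)
        res = structural_relaxation_time(acf, tail_start=0.0)
        assert res.tau_struct == pytest.approx(res.tau_K, rel=1e-6)

    def test_beta_half_doubles(self):
        acf = self._stretched_acf(200.0, 0.5, t_max=20000.0)
        res = structural_relaxation_time(acf, tail_start=0.0)
        assert res.tau_struct == pytest.approx(2 * res.tau_K, rel=1e-9)
        assert res.beta_K == pytest.approx(0.5, abs=0.01)

    def test_planted_water_like_tail(self):
        """(tau_K, beta_K) = (0.4 ps, 0.61): parameters recovered and the
        Gamma-formula mean time matches direct quadrature."""
        tau_k, beta_k = 400.0, 0.61
        acf = self._stretched_acf(tau_k, beta_k, t_max=30000.0)
        res = structural_relaxation_time(acf, tail_start=0.0)
        assert res.tau_K == pytest.approx(tau_k, rel=0.05)
        assert res.beta_K == pytest.approx(beta_k, rel=0.05)
        numeric, _ = quad(lambda t: np.exp(-(t / tau_k) ** beta_k),
                          0, np.inf)
        assert res.tau_struct == pytest.approx(numeric, rel=0.01)

    def test_default_tail_start_after_oscillation(self):
        """The automatic window skips an initial oscillatory transient."""
        lags = np.arange(0.0, 6000.0, 2.0)
        elastic = 0.3 * np.cos(lags / 20.0) * np.exp(-lags / 60.0)
        tail = 0.7 * np.exp(-np.power(lags / 400.0, 0.61, where=lags > 0,
                                      out=np.zeros_like(lags)))
        vals = elastic + tail
        acf = TensorACF(lags=lags, values=vals,
                        stderr=np.zeros_like(vals),
                        n_origins=np.ones_like(vals), dt=2.0)
        res = structural_relaxation_time(acf)
        assert res.fit_window[0] > 0.0
        assert res.beta_K < 1.0
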