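"""Transport coefficients and relaxation-model assessment.

Green-Kubo shear viscosity from the traceless symmetrized stress ACF,
mean-square-displacement diffusion with the Yeh-Hummer cubic finite-size
correction (xi ~ 2.837297, computed here from first principles), Stokes
radius and Stokes-Einstein-Debye (SED) rotational time, the effective-SED
fit with intercept, the water-dipole reorientation time from the P1
orientational ACF, and the structural relaxation time from the stretched
long-time tail of the stress ACF.

Unit conventions: stress in Pa, box volume in A^3, lengths in A, sampling
intervals in fs, temperatures in K.  Returned transport coefficients are
SI (eta in Pa s, D in m^2/s); times are reported in fs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import erfc, gamma as gamma_fn

from .core import CONSTANTS
from .correlation import (ACFFit, TensorACF, correlation_time, fit_acf,
                          stretched_mean_time, tensor_acf)

__all__ = [
    "StressSeries",
    "DiffusionResult",
    "SEDResult",
    "OrientationSeries",
    "StructuralRelaxResult",
    "stress_acf",
    "green_kubo_viscosity",
    "msd",
    "msd_diffusion",
    "yeh_hummer_correct",
    "xi_cubic",
    "stokes_radius",
    "sed_time",
    "effective_sed_fit",
    "dipole_reorientation_time",
    "structural_relaxation_time",
    "unwrap_trajectory",
]

A3_TO_M3 = 1e-30
FS_TO_S = 1e-15
A2_PER_FS_TO_M2_PER_S = 1e-5


class DiffusiveRegimeError(RuntimeError):
    """MSD is not linear over the fit window (ballistic/caged data)."""


@dataclass
class StressSeries:
    """Per-frame 3x3 stress tensors (Pa), uniform sampling (fs)."""

    stress: np.ndarray
    dt: float
    volume: float            # A^3
    temperature: float       # K

    def __post_init__(self) -> None:
        self.stress = np.asarray(self.stress, dtype=float)
        if self.stress.ndim != 3 or self.stress.shape[1:] != (3, 3):
            raise ValueError("stress must be (n_frames, 3, 3)")
        if not (self.dt > 0 and self.volume > 0 and self.temperature > 0):
            raise ValueError("dt, volume and temperature must be positive")

    def traceless_symmetrized(self) -> np.ndarray:
        """P_ab = (s_ab + s_ba)/2 - delta_ab tr(s)/3 per frame."""
        s = self.stress
        sym = 0.5 * (s + np.transpose(s, (0, 2, 1)))
        tr = np.trace(sym, axis1=1, axis2=2) / 3.0
        return sym - tr[:, None, None] * np.eye(3)


def stress_acf(series: StressSeries, max_lag: float | None = None,
               estimator: str = "fft") -> TensorACF:
    """C_stress(t) = (1/10) sum_ab <P_ab(t) P_ab(0)> of the traceless
    symmetrized stress (Pa^2)."""
    if series.stress.shape[0] < 2:
        raise ValueError("need at least 2 stress frames")
    P = series.traceless_symmetrized()
    return tensor_acf((P, series.dt), max_lag=max_lag, estimator=estimator,
                      prefactor=0.1)


@dataclass
class ViscosityResult:
    eta: float                     # Pa s
    cutoff: float                  # fs
    converged: bool
    running_lags: np.ndarray = field(repr=False, default=None)
    running_integral: np.ndarray = field(repr=False, default=None)


def green_kubo_viscosity(acf: TensorACF, volume: float, temperature: float,
                         cutoff="plateau", tail_fit: ACFFit | None = None,
                         ) -> ViscosityResult:
    """eta = V/(k_B T) * int_0^inf C_stress dt.

    Shares the plateau cutoff policy with the EFG correlation-time
    integral; a non-plateauing integral is returned flagged, never hidden.
    """
    if acf.c0 == 0.0:
        # no shear fluctuations at all (e.g. pure-pressure input)
        return ViscosityResult(eta=0.0, cutoff=0.0, converged=True,
                               running_lags=acf.lags,
                               running_integral=np.zeros_like(acf.lags))
    ct = correlation_time(acf, cutoff=cutoff, tail_fit=tail_fit)
    integral = ct.tau_c * acf.c0 * FS_TO_S              # Pa^2 s
    eta = volume * A3_TO_M3 / (CONSTANTS.k_B * temperature) * integral
    running = (ct.running_integral * acf.c0 * FS_TO_S
               * volume * A3_TO_M3 / (CONSTANTS.k_B * temperature))
    return ViscosityResult(eta=float(eta), cutoff=ct.cutoff,
                           converged=ct.converged,
                           running_lags=ct.running_lags,
                           running_integral=running)


# --------------------------------------------------------------------------
# Diffusion
# --------------------------------------------------------------------------

def unwrap_trajectory(wrapped: np.ndarray, box_edge: float) -> np.ndarray:
    """Undo periodic wrapping by accumulating minimum-image displacements."""
    disp = np.diff(wrapped, axis=0)
    disp -= box_edge * np.round(disp / box_edge)
    out = np.empty_like(wrapped)
    out[0] = wrapped[0]
    out[1:] = wrapped[0] + np.cumsum(disp, axis=0)
    return out


def msd(positions: np.ndarray) -> np.ndarray:
    """Multi-origin mean-square displacement via the FFT identity.

    positions: (n_frames, n_particles, 3), unwrapped.  Returns MSD(t)
    averaged over particles for t = 0..n_frames-1.
    """
    x = np.asarray(positions, dtype=float)
    if x.ndim == 2:
        x = x[:, None, :]
    n, npart, _ = x.shape
    # S1 part
    sq = np.einsum("tpa,tpa->tp", x, x)
    ssum = 2.0 * sq.sum(axis=0)
    s1 = np.empty((n, npart))
    run_head = 0.0
    run_tail = 0.0
    s1[0] = ssum / n
    for t in range(1, n):
        run_head += sq[t - 1]
        run_tail += sq[n - t]
        s1[t] = (ssum - run_head - run_tail) / (n - t)
    # S2 autocorrelation part
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    f = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft((f * f.conj()).real, n=nfft, axis=0)[:n]
    acf = acf.sum(axis=2) / (n - np.arange(n))[:, None]
    return (s1 - 2.0 * acf).mean(axis=1)


@dataclass
class DiffusionResult:
    D: float                       # m^2/s, finite box
    D_infinity: float | None      # corrected, m^2/s
    xi: float | None
    fit_window: tuple[float, float]
    r_squared: float
    correction_fraction: float | None = None
    slope_A2_fs: float = 0.0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be non-negative")


def msd_diffusion(positions: np.ndarray, dt: float,
                  fit_window: tuple[float, float] = (0.1, 0.5),
                  regime_tol: float = 0.1) -> DiffusionResult:
    """D = slope(MSD)/6 over a window in the diffusive regime.

    positions must be unwrapped (A); dt in fs.  The window is given as
    fractions of the trajectory length.  A local log-log MSD slope outside
    1 +- regime_tol over the window raises DiffusiveRegimeError (ballistic
    or caged input); static input returns D = 0.
    """
    m = msd(positions)
    n = m.size
    i0 = max(1, int(fit_window[0] * n))
    i1 = max(i0 + 2, int(fit_window[1] * n))
    t = np.arange(n) * dt
    tw, mw = t[i0:i1], m[i0:i1]
    if np.allclose(mw, 0.0):
        return DiffusionResult(D=0.0, D_infinity=None, xi=None,
                               fit_window=(tw[0], tw[-1]), r_squared=1.0)
    loglog = stats.linregress(np.log(tw), np.log(np.maximum(mw, 1e-300)))
    if abs(loglog.slope - 1.0) > regime_tol:
        raise DiffusiveRegimeError(
            f"local MSD exponent {loglog.slope:.2f} outside 1 +- {regime_tol}:"
            " window not diffusive")
    res = stats.linregress(tw, mw)
    slope = max(res.slope, 0.0)
    D = slope / 6.0 * A2_PER_FS_TO_M2_PER_S
    return DiffusionResult(D=float(D), D_infinity=None, xi=None,
                           fit_window=(float(tw[0]), float(tw[-1])),
                           r_squared=float(res.rvalue ** 2),
                           slope_A2_fs=float(slope))


def yeh_hummer_correct(D: float, eta: float, temperature: float,
                       box_edge_m: float, xi: float | None = None,
                       ) -> DiffusionResult:
    """Yeh-Hummer finite-size correction D_inf = D + k_B T xi / (6 pi eta L).

    All SI: D in m^2/s, eta in Pa s, L in metres.  The correction fraction
    (D_inf - D)/D is reported alongside.
    """
    if min(D, eta, temperature, box_edge_m) <= 0:
        if D == 0:
            pass
        else:
            raise ValueError("inputs must be positive")
    if xi is None:
        xi = xi_cubic()
    corr = CONSTANTS.k_B * temperature * xi / (6.0 * np.pi * eta * box_edge_m)
    frac = corr / D if D > 0 else np.inf
    return DiffusionResult(D=D, D_infinity=float(D + corr), xi=float(xi),
                           fit_window=(0.0, 0.0), r_squared=float("nan"),
                           correction_fraction=float(frac))


def xi_cubic(tolerance: float = 1e-8, alpha: float | None = None,
             min_real_shells: int | None = None,
             min_recip_shells: int | None = None,
             return_diagnostics: bool = False):
    """Self-interaction (Wigner) constant of a cubic lattice, xi ~ 2.837297.

    xi = -L * psi(0), where psi(0) is the periodic Coulomb self-potential of
    a unit point charge with uniform neutralizing background, evaluated via
    an Ewald split in a unit cube:

        psi(0) = sum_{n != 0} erfc(a|n|)/|n|
                 + (1/pi) sum_{m != 0} exp(-pi^2 m^2 / a^2)/m^2
                 - pi/a^2 - 2a/sqrt(pi).

    Shell counts are tolerance-driven; the value is invariant to the
    splitting parameter ``alpha`` within the tolerance.  Deliberately
    under-converged shell counts set converged=False in the diagnostics.
    """
    a = float(alpha) if alpha is not None else np.sqrt(np.pi)
    w = np.sqrt(max(-np.log(tolerance * 1e-2), 1.0))
    n_real = int(np.ceil(w / a)) + 1
    n_recip = int(np.ceil(w * a / np.pi)) + 1
    forced = False
    if min_real_shells is not None:
        forced = forced or min_real_shells < n_real
        n_real = min_real_shells
    if min_recip_shells is not None:
        forced = forced or min_recip_shells < n_recip
        n_recip = min_recip_shells

    def shell_sums(nmax):
        ax = np.arange(-nmax, nmax + 1)
        g = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3)
        g = g[np.any(g != 0, axis=1)].astype(float)
        return np.linalg.norm(g, axis=1)

    r = shell_sums(n_real)
    real = float(np.sum(erfc(a * r) / r))
    m = shell_sums(n_recip)
    m2 = m * m
    recip = float(np.sum(np.exp(-(np.pi ** 2) * m2 / (a * a)) / m2) / np.pi)
    psi0 = real + recip - np.pi / a ** 2 - 2.0 * a / np.sqrt(np.pi)
    xi = -psi0

    # convergence check: one more shell must not move the value
    r2 = shell_sums(n_real + 1)
    real2 = float(np.sum(erfc(a * r2) / r2))
    m2b = shell_sums(n_recip + 1)
    recip2 = float(np.sum(np.exp(-(np.pi ** 2) * m2b ** 2 / (a * a))
                          / m2b ** 2) / np.pi)
    xi2 = -(real2 + recip2 - np.pi / a ** 2 - 2.0 * a / np.sqrt(np.pi))
    converged = abs(xi2 - xi) < tolerance and not forced

    if return_diagnostics:
        return xi, {"converged": converged, "alpha": a,
                    "n_real_shells": n_real, "n_recip_shells": n_recip,
                    "shell_increment": abs(xi2 - xi)}
    if not converged:
        raise RuntimeError(
            f"xi_cubic under-converged (shell increment {abs(xi2 - xi):.1e})")
    return xi


# --------------------------------------------------------------------------
# Stokes / SED
# --------------------------------------------------------------------------

def stokes_radius(D: float, eta: float, temperature: float) -> float:
    """Hydrodynamic radius r0 = k_B T / (6 pi eta D), metres."""
    if min(D, eta, temperature) <= 0:
        raise ValueError("inputs must be positive")
    return CONSTANTS.k_B * temperature / (6.0 * np.pi * eta * D)


def sed_time(eta: float, r0: float, temperature: float) -> float:
    """Stokes-Einstein-Debye rotational time 4 pi eta r0^3 / (3 k_B T), s."""
    if min(eta, r0, temperature) <= 0:
        raise ValueError("inputs must be positive")
    return 4.0 * np.pi * eta * r0 ** 3 / (3.0 * CONSTANTS.k_B * temperature)


@dataclass
class SEDResult:
    r0_eff: float                  # m
    tau0_eff: float                # s
    slope: float                   # m^3
    slope_se: float
    intercept_se: float
    r_squared: float
    flags: list[str] = field(default_factory=list)


def effective_sed_fit(tau_c: np.ndarray, eta_over_kbt: np.ndarray,
                      ) -> SEDResult:
    """Fit tau_c = (4 pi / 3) [r0_eff]^3 (eta / k_B T) + tau0_eff.

    tau_c in seconds, eta/k_B T in s m^-3 across >= 3 state points.  The
    cube root of 3 slope / 4 pi gives the effective hydrodynamic radius; a
    negative slope has no real radius and is flagged.
    """
    tau_c = np.asarray(tau_c, dtype=float)
    x = np.asarray(eta_over_kbt, dtype=float)
    if tau_c.size < 3:
        raise ValueError("effective SED fit needs >= 3 state points")
    res = stats.linregress(x, tau_c)
    flags = []
    if res.slope < 0:
        flags.append("negative slope: no real effective radius")
        r0 = float("nan")
    else:
        r0 = (3.0 * res.slope / (4.0 * np.pi)) ** (1.0 / 3.0)
    return SEDResult(r0_eff=r0, tau0_eff=float(res.intercept),
                     slope=float(res.slope), slope_se=float(res.stderr),
                     intercept_se=float(res.intercept_stderr),
                     r_squared=float(res.rvalue ** 2), flags=flags)


# --------------------------------------------------------------------------
# Orientational and structural relaxation
# --------------------------------------------------------------------------

@dataclass
class OrientationSeries:
    """Per-frame unit vectors (HOH bisectors), (n_frames, n_molecules, 3)."""

    vectors: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim == 2:
            self.vectors = self.vectors[:, None, :]
        norms = np.linalg.norm(self.vectors, axis=-1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("orientation vectors must be unit length")
        if not self.dt > 0:
            raise ValueError("dt must be positive")


@dataclass
class DipoleTimeResult:
    tau_dip: float                 # fs
    cutoff: float
    converged: bool
    flags: list[str] = field(default_factory=list)


def dipole_reorientation_time(series: OrientationSeries,
                              max_lag: float | None = None,
                              cutoff="plateau") -> DipoleTimeResult:
    """tau_dip = int_0^inf <P1[u(0) . u(t)]> dt with P1(x) = x.

    The scalar orientational ACF is averaged over molecules and time
    origins; frozen (non-decaying) orientations are flagged as divergent.
    """
    u = series.vectors
    acf = tensor_acf((u.reshape(u.shape[0], u.shape[1], 3), series.dt),
                     max_lag=max_lag)
    cn = acf.normalized()
    flags = []
    if cn[-1] > 0.5:
        flags.append("ACF has not decayed: orientations frozen or window "
                     "too short; integral unreliable")
    ct = correlation_time(acf, cutoff=cutoff)
    converged = ct.converged and not flags
    return DipoleTimeResult(tau_dip=ct.tau_c, cutoff=ct.cutoff,
                            converged=converged, flags=flags)


@dataclass
class StructuralRelaxResult:
    tau_K: float                   # fs
    beta_K: float
    tau_struct: float              # fs
    fit_window: tuple[float, float]
    fit: ACFFit

    def __post_init__(self) -> None:
        expected = self.tau_K * gamma_fn(1.0 / self.beta_K) / self.beta_K
        if abs(self.tau_struct - expected) > 1e-10 * max(expected, 1.0):
            raise ValueError("tau_struct inconsistent with (tau_K, beta_K)")


def structural_relaxation_time(acf: TensorACF,
                               tail_start: float | None = None,
                               tail_end: float | None = None,
                               ) -> StructuralRelaxResult:
    """Stretched-exponential fit of the stress-ACF tail.

    tau_struct = tau_K Gamma(1/beta_K)/beta_K, the mean time of the fitted
    Kohlrausch decay.  The default tail window starts at the first local
    minimum of |C(t)| after the initial elastic/vibrational part.
    """
    cn = acf.normalized()
    lags = acf.lags
    if tail_start is None:
        absc = np.abs(cn)
        i = 1
        while i < cn.size - 1 and not (absc[i] <= absc[i - 1]
                                       and absc[i] <= absc[i + 1]):
            i += 1
        tail_start = float(lags[min(i, cn.size - 2)])
    if tail_end is None:
        tail_end = float(lags[-1])
    fit = fit_acf(acf, "stretched", window=(tail_start, tail_end))
    if not fit.converged:
        raise RuntimeError("stretched tail fit did not converge; "
                           f"diagnostics: {fit.diagnostics}")
    tau_K, beta_K = fit.params["tau"], fit.params["beta"]
    return StructuralRelaxResult(
        tau_K=tau_K, beta_K=beta_K,
        tau_struct=stretched_mean_time(tau_K, beta_K),
        fit_window=fit.window, fit=fit)
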