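"""Tensor autocorrelation functions, effective correlation times and decay
models.

The central quantity is the Frobenius autocorrelation of a stationary
tensor process,

    C(t) = sum_ab <X_ab(0) X_ab(t)>,

whose normalized time integral defines the effective correlation time

    tau_c = C(0)^-1 int_0^inf C(t) dt.

For the EFG at an ion site the decay is two-step: a fast (~60 fs)
exponential from librational/vibrational motion of the cage, and a slow
picosecond stretched-exponential (Kohlrausch) mode from collective
structural rearrangement, with a possible algebraic t^(-5/2) hydrodynamic
tail at long times.  This module provides multi-origin ACF estimators
(FFT and direct, agreeing to machine precision), plateau-detected
integration with optional fitted-tail extrapolation, nonlinear model fits
(exponential, two-exponential, stretched, fast-plus-stretched), the
slow-mode contribution to tau_c, and a power-law tail diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import gamma as gamma_fn, gammaincc

from .efg import EFGSeries

__all__ = [
    "TensorACF",
    "ACFFit",
    "CorrelationTime",
    "TailDiagnostic",
    "tensor_acf",
    "correlation_time",
    "fit_acf",
    "slow_mode_fraction",
    "tail_diagnostic",
    "stretched_mean_time",
]


def stretched_mean_time(tau: float, beta: float) -> float:
    """Mean relaxation time of exp(-(t/tau)^beta): tau * Gamma(1/beta)/beta."""
    if not (0 < beta <= 1):
        raise ValueError("beta must be in (0, 1]")
    return tau * gamma_fn(1.0 / beta) / beta


@dataclass
class TensorACF:
    """Multi-origin lagged Frobenius autocorrelation.

    ``values`` carries the unnormalized ACF (units of the squared signal,
    e.g. e^2/A^6 for EFG input); ``stderr`` is the standard error across
    independent series (zero when only one is available); ``n_origins`` the
    number of time origins contributing per lag.
    """

    lags: np.ndarray            # fs
    values: np.ndarray
    stderr: np.ndarray
    n_origins: np.ndarray
    dt: float
    n_series: int = 1

    def __post_init__(self) -> None:
        if self.values[0] < 0:
            raise ValueError("C(0) must be non-negative")

    @property
    def c0(self) -> float:
        return float(self.values[0])

    def normalized(self) -> np.ndarray:
        if self.c0 == 0:
            raise ValueError("cannot normalize an identically-zero ACF")
        return self.values / self.c0


def _acf_per_series_fft(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Multi-origin ACF summed over the trailing component axis via FFT.

    x: (n_frames, n_comp).  Returns C(t) for t = 0..n_lags-1 with the
    unbiased 1/(N-t) origin normalization.
    """
    n = x.shape[0]
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    f = np.fft.rfft(x, n=nfft, axis=0)
    raw = np.fft.irfft((f * f.conj()).real, n=nfft, axis=0)[:n_lags]
    counts = (n - np.arange(n_lags)).astype(float)
    return raw.sum(axis=1) / counts


def _acf_per_series_direct(x: np.ndarray, n_lags: int) -> np.ndarray:
    n = x.shape[0]
    out = np.empty(n_lags)
    for t in range(n_lags):
        out[t] = np.einsum("ij,ij->", x[: n - t], x[t:]) / (n - t)
    return out


def tensor_acf(series, max_lag: float | None = None,
               estimator: str = "fft", prefactor: float = 1.0) -> TensorACF:
    """Estimate the Frobenius ACF of a tensor (or vector) time series.

    Parameters
    ----------
    series : EFGSeries, or an array (n_frames, ..., 3, 3) of tensors, or
        (n_frames, n_series, n_comp) of flattened components, together with
        a uniform sampling interval; when an array is passed, wrap it as
        ``(data, dt)``.
    max_lag : largest lag in fs (default: half the series length).
    estimator : "fft" (default) or "direct"; the two agree to ~1e-10.
    prefactor : overall multiplier (e.g. 1/10 for the stress convention).

    All probes/series are averaged; per-lag standard errors come from the
    scatter across independent series.
    """
    if isinstance(series, EFGSeries):
        comps = series.components()        # (n_frames, n_probes, 9)
        dt = series.dt
    else:
        data, dt = series
        data = np.asarray(data, dtype=float)
        if data.ndim >= 3 and data.shape[-2:] == (3, 3):
            data = data.reshape(data.shape[0], -1, 9)
        elif data.ndim == 2:
            data = data[:, None, :]
        comps = data
    n_frames = comps.shape[0]
    if n_frames < 2:
        raise ValueError("ACF needs at least 2 frames")
    if max_lag is None:
        n_lags = max(2, n_frames // 2)
    else:
        n_lags = int(round(max_lag / dt)) + 1
        if n_lags > n_frames:
            raise ValueError("max_lag exceeds series length")
    n_series = comps.shape[1]
    per = np.empty((n_series, n_lags))
    fn = {"fft": _acf_per_series_fft, "direct": _acf_per_series_direct}[estimator]
    for s in range(n_series):
        per[s] = fn(comps[:, s, :], n_lags)
    values = prefactor * per.mean(axis=0)
    if n_series > 1:
        stderr = prefactor * per.std(axis=0, ddof=1) / np.sqrt(n_series)
    else:
        stderr = np.zeros(n_lags)
    lags = np.arange(n_lags) * dt
    n_origins = (n_frames - np.arange(n_lags)) * n_series
    return TensorACF(lags=lags, values=values, stderr=stderr,
                     n_origins=n_origins, dt=dt, n_series=n_series)


# --------------------------------------------------------------------------
# Correlation time
# --------------------------------------------------------------------------

@dataclass
class CorrelationTime:
    tau_c: float                 # fs
    cutoff: float                # fs
    method: str
    tail_correction: float       # fs
    error: float                 # fs
    running_lags: np.ndarray = field(repr=False, default=None)
    running_integral: np.ndarray = field(repr=False, default=None)
    converged: bool = True

    def __post_init__(self) -> None:
        if not self.tau_c > 0:
            raise ValueError("tau_c must be positive")


def _plateau_cutoff(lags: np.ndarray, running: np.ndarray, threshold: float,
                    window: float) -> tuple[int, bool]:
    """First lag index from which the running integral's mean slope over the
    trailing ``window`` stays below ``threshold`` times its peak slope.

    The slope of the running integral of the normalized ACF is the ACF
    itself, with peak slope 1 at t = 0; averaging it over the window makes
    the detector robust to estimator noise at long lags.
    """
    dt = lags[1] - lags[0] if lags.size > 1 else 1.0
    w = max(1, int(round(window / dt)))
    if running.size <= w + 1:
        return running.size - 1, False
    mean_slope = (running[w:] - running[:-w]) / (w * dt)
    ok = np.abs(mean_slope) < threshold
    idx = np.flatnonzero(ok[1:])
    if idx.size:
        return int(idx[0]) + 1, True
    return running.size - 1, False


def correlation_time(acf: TensorACF, cutoff="plateau",
                     tail_fit: "ACFFit | None" = None,
                     plateau_threshold: float = 1e-3,
                     plateau_window: float | None = None) -> CorrelationTime:
    """tau_c = C(0)^-1 int_0^cutoff C dt (trapezoid), with optional
    analytic tail extrapolation from a fitted model beyond the cutoff.

    cutoff="plateau" detects where the running integral has flattened
    (default window: 5 ps, shrunk to a fifth of the available span for
    short series); a float gives an explicit cutoff in fs.
    """
    cn = acf.normalized()
    lags = acf.lags
    running = np.concatenate(
        [[0.0], np.cumsum(0.5 * (cn[1:] + cn[:-1]) * np.diff(lags))])
    converged = True
    if cutoff == "plateau":
        if plateau_window is None:
            plateau_window = min(5000.0, lags[-1] / 5.0)
        i_cut, converged = _plateau_cutoff(lags, running, plateau_threshold,
                                           plateau_window)
        method = "plateau"
    else:
        t_cut = float(cutoff)
        if t_cut > lags[-1] + 1e-9:
            if tail_fit is None:
                raise ValueError("cutoff beyond data requires a tail model")
            t_cut = lags[-1]
        i_cut = int(np.searchsorted(lags, t_cut - 1e-9))
        method = "fixed"
    tau_c = float(running[i_cut])

    tail = 0.0
    if tail_fit is not None:
        tail = tail_fit.tail_integral(lags[i_cut])
        method += "+tail"
    err = float(np.sqrt(np.sum(((acf.stderr[1:i_cut + 1] / acf.c0)
                                * acf.dt) ** 2)))
    return CorrelationTime(tau_c=tau_c + tail, cutoff=float(lags[i_cut]),
                           method=method, tail_correction=tail, error=err,
                           running_lags=lags, running_integral=running,
                           converged=converged)


# --------------------------------------------------------------------------
# Model fits
# --------------------------------------------------------------------------

_MODELS = {
    "exp": ("a", "tau"),
    "double_exp": ("a1", "tau1", "a2", "tau2"),
    "stretched": ("a", "tau", "beta"),
    "fast_stretched": ("a_f", "tau_f", "a_s", "tau_s", "beta"),
}


def _model_eval(model: str, t: np.ndarray, p: dict[str, float]) -> np.ndarray:
    if model == "exp":
        return p["a"] * np.exp(-t / p["tau"])
    if model == "double_exp":
        return (p["a1"] * np.exp(-t / p["tau1"])
                + p["a2"] * np.exp(-t / p["tau2"]))
    if model == "stretched":
        return p["a"] * np.exp(-np.power(t / p["tau"],
                                         p["beta"], where=t > 0,
                                         out=np.zeros_like(t)))
    if model == "fast_stretched":
        slow = np.exp(-np.power(t / p["tau_s"], p["beta"], where=t > 0,
                                out=np.zeros_like(t)))
        return p["a_f"] * np.exp(-t / p["tau_f"]) + p["a_s"] * slow
    raise ValueError(f"unknown model {model!r}")


@dataclass
class ACFFit:
    """Nonlinear least-squares fit of a normalized ACF decay model."""

    model: str
    params: dict[str, float]
    errors: dict[str, float]
    covariance: np.ndarray
    window: tuple[float, float]
    residual_norm: float
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.params.items():
            if name.startswith("tau") and not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
            if name == "beta" and not (0 < v <= 1):
                raise ValueError(f"beta out of (0, 1]: {v}")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return _model_eval(self.model, np.asarray(t, dtype=float), self.params)

    def tail_integral(self, t_from: float) -> float:
        """Analytic integral of the fitted model from ``t_from`` to
        infinity (normalized-ACF units times fs)."""
        p = self.params
        total = 0.0
        if self.model == "exp":
            total = p["a"] * p["tau"] * np.exp(-t_from / p["tau"])
        elif self.model == "double_exp":
            total = (p["a1"] * p["tau1"] * np.exp(-t_from / p["tau1"])
                     + p["a2"] * p["tau2"] * np.exp(-t_from / p["tau2"]))
        elif self.model in ("stretched", "fast_stretched"):
            if self.model == "stretched":
                a, tau, beta = p["a"], p["tau"], p["beta"]
                total = a * _stretched_tail(tau, beta, t_from)
            else:
                total = (p["a_f"] * p["tau_f"] * np.exp(-t_from / p["tau_f"])
                         + p["a_s"] * _stretched_tail(p["tau_s"], p["beta"],
                                                      t_from))
        return float(total)


def _stretched_tail(tau: float, beta: float, t_from: float) -> float:
    """int_T^inf exp(-(t/tau)^beta) dt via the upper incomplete gamma."""
    x = (t_from / tau) ** beta
    return tau / beta * gamma_fn(1.0 / beta) * gammaincc(1.0 / beta, x)


def _initial_grids(model: str, t: np.ndarray) -> list[dict[str, float]]:
    """Multi-start grid: ~3 starting time constants per decade of window."""
    tmin = max(t[t > 0].min(), 1e-3)
    tmax = t.max()
    n_dec = max(1.0, np.log10(tmax / tmin))
    taus = np.geomspace(tmin, tmax, int(np.ceil(3 * n_dec)) + 1)
    taus_coarse = np.geomspace(tmin, tmax, int(np.ceil(1.5 * n_dec)) + 1)
    starts = []
    if model == "exp":
        starts = [{"a": 1.0, "tau": tv} for tv in taus]
    elif model == "stretched":
        starts = [{"a": 1.0, "tau": tv, "beta": b}
                  for tv in taus for b in (0.5, 0.8, 1.0)]
    elif model == "double_exp":
        for i, t1 in enumerate(taus_coarse):
            for t2 in taus_coarse[i + 1:]:
                if t2 < 5.0 * t1:
                    continue
                starts.append({"a1": 0.5, "tau1": t1, "a2": 0.5, "tau2": t2})
    elif model == "fast_stretched":
        for i, t1 in enumerate(taus_coarse):
            for t2 in taus_coarse[i + 1:]:
                if t2 < 5.0 * t1:
                    continue
                for b in (0.6, 0.9):
                    starts.append({"a_f": 0.5, "tau_f": t1,
                                   "a_s": 0.5, "tau_s": t2, "beta": b})
    return starts


def fit_acf(acf: TensorACF, model: str,
            window: tuple[float, float] | float | None = None,
            fix: dict[str, float] | None = None,
            seed: int = 0) -> ACFFit:
    """Fit a decay model to the normalized ACF on a time window.

    Multi-start nonlinear least squares (soft-l1-free, plain residuals);
    deterministic for a given grid and seed.  Non-convergence is flagged in
    the result, never silent.  ``fix`` pins parameters (e.g. beta=1 reduces
    the stretched model to an exponential).
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")
    fix = dict(fix or {})
    names = [n for n in _MODELS[model] if n not in fix]
    cn = acf.normalized()
    lags = acf.lags
    if window is None:
        lo, hi = 0.0, lags[-1]
    elif np.isscalar(window):
        lo, hi = 0.0, float(window)
    else:
        lo, hi = map(float, window)
    sel = (lags >= lo - 1e-9) & (lags <= hi + 1e-9)
    t, y = lags[sel], cn[sel]
    if t.size < 5 * len(names):
        raise ValueError(
            f"window holds {t.size} points; need >= {5 * len(names)} "
            f"for {len(names)} free parameters")
    if t.size > 600:
        # dense early lags plus log-spaced later ones: the information in a
        # smooth ACF is logarithmic in lag, and this keeps fits O(1)
        idx = np.unique(np.concatenate([
            np.arange(min(100, t.size)),
            np.geomspace(1, t.size - 1, 500).astype(int)]))
        t, y = t[idx], y[idx]

    lower = {"a": 0.0, "a1": 0.0, "a2": 0.0, "a_f": 0.0, "a_s": 0.0,
             "tau": 1e-6, "tau1": 1e-6, "tau2": 1e-6, "tau_f": 1e-6,
             "tau_s": 1e-6, "beta": 0.05}
    upper = {"a": 2.0, "a1": 2.0, "a2": 2.0, "a_f": 2.0, "a_s": 2.0,
             "tau": np.inf, "tau1": np.inf, "tau2": np.inf,
             "tau_f": np.inf, "tau_s": np.inf, "beta": 1.0}

    def residual(vec):
        p = dict(zip(names, vec));  p.update(fix)
        return _model_eval(model, t, p) - y

    best = None
    for start in _initial_grids(model, t):
        x0 = np.array([start[n] for n in names])
        try:
            res = optimize.least_squares(
                residual, x0,
                bounds=([lower[n] for n in names], [upper[n] for n in names]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all fit starts failed")

    params = dict(zip(names, best.x));  params.update(fix)
    n, k = t.size, len(names)
    dof = max(n - k, 1)
    s2 = 2.0 * best.cost / dof
    JTJ = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(JTJ) * s2
        errors = {nm: float(np.sqrt(max(cov[i, i], 0.0)))
                  for i, nm in enumerate(names)}
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        errors = {nm: float("nan") for nm in names}
    errors.update({nm: 0.0 for nm in fix})
    converged = bool(best.status > 0)
    resid = residual(best.x)
    diag = {"cost": float(best.cost), "status": int(best.status),
            "n_points": n}
    if resid.size > 2:
        r0, r1 = resid[:-1], resid[1:]
        denom = np.sqrt((r0 ** 2).sum() * (r1 ** 2).sum())
        diag["lag1_autocorr"] = float((r0 * r1).sum() / denom) if denom else 0.0
    # amplitude sanity: composite amplitudes should roughly sum to C(0)
    amp = sum(v for nm, v in params.items() if nm.startswith("a"))
    diag["amplitude_sum"] = float(amp)
    return ACFFit(model=model, params=params, errors=errors, covariance=cov,
                  window=(lo, hi), residual_norm=float(np.linalg.norm(resid)),
                  converged=converged, diagnostics=diag)


def slow_mode_fraction(fit: ACFFit) -> float:
    """Share of tau_c carried by the slow mode of a composite fit.

    fraction = a_slow T_slow / (a_fast T_fast + a_slow T_slow), with
    T = tau for an exponential and T = tau Gamma(1/beta)/beta for a
    stretched mode.
    """
    p = fit.params
    if fit.model == "double_exp":
        pairs = [(p["a1"], p["tau1"]), (p["a2"], p["tau2"])]
        pairs.sort(key=lambda ab: ab[1])
        (af, tf), (asl, tsl) = pairs
    elif fit.model == "fast_stretched":
        af, tf = p["a_f"], p["tau_f"]
        asl, tsl = p["a_s"], stretched_mean_time(p["tau_s"], p["beta"])
    else:
        raise ValueError("slow-mode fraction needs a composite (two-mode) fit")
    total = af * tf + asl * tsl
    if total == 0:
        return 0.0
    return float(asl * tsl / total)


# --------------------------------------------------------------------------
# Power-law tail diagnostic
# --------------------------------------------------------------------------

@dataclass
class TailDiagnostic:
    slope: float
    slope_se: float
    window: tuple[float, float]
    flatness: dict[float, float]
    best_exponent: float
    stable: bool
    window_shrunk: bool = False


def tail_diagnostic(acf: TensorACF,
                    exponents: Sequence[float] = (-1.5, -2.5),
                    window: tuple[float, float] | None = None,
                    ) -> TailDiagnostic:
    """Log-log slope of the ACF tail plus compensated-plateau scores.

    For each candidate exponent alpha, the flatness score is the variance
    of log(t^|alpha| C(t)) over the window (smaller = flatter).  Windows
    containing non-positive ACF values are shrunk to the positive part and
    flagged.  Stability compares the slopes of the two window halves.
    """
    lags, cn = acf.lags, acf.normalized()
    if window is None:
        window = (lags[-1] / 10.0, lags[-1])
    lo, hi = window
    sel = (lags >= lo) & (lags <= hi) & (lags > 0)
    shrunk = False
    t, y = lags[sel], cn[sel]
    if np.any(y <= 0):
        first_bad = np.argmax(y <= 0)
        t, y = t[:first_bad], y[:first_bad]
        shrunk = True
    if t.size < 4:
        raise ValueError("tail window too short after removing "
                         "non-positive values")
    logt, logy = np.log(t), np.log(y)
    res = stats.linregress(logt, logy)
    half = t.size // 2
    r1 = stats.linregress(logt[:half], logy[:half])
    r2 = stats.linregress(logt[half:], logy[half:])
    stable = abs(r1.slope - r2.slope) <= 2.0 * (r1.stderr + r2.stderr) + 1e-6
    flat = {}
    for a in exponents:
        comp = logy + abs(a) * logt
        flat[float(a)] = float(np.var(comp))
    best = min(flat, key=flat.get)
    return TailDiagnostic(slope=float(res.slope),
                          slope_se=float(res.stderr),
                          window=(float(t[0]), float(t[-1])),
                          flatness=flat, best_exponent=best,
                          stable=bool(stable), window_shrunk=shrunk)
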