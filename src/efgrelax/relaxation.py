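"""Quadrupolar NMR observables: QCC, longitudinal rate, narrowing check.

In the extreme-narrowing regime (omega_0 tau_c << 1) the longitudinal and
transverse quadrupolar rates of a spin-I nucleus coincide and read

    1/T1 = (2I+3) / (20 I^2 (2I-1)) * (eQ/hbar)^2 <V^2> tau_c,

with <V^2> the Frobenius variance of the EFG at the nucleus (SI, V^2 m^-4)
and tau_c the effective EFG correlation time.  With the quadrupolar
coupling constant C_Q^2 = (2/3) (eQ/hbar)^2 <V^2> this becomes, for
I = 3/2 (e.g. 23Na), exactly 1/T1 = C_Q^2 tau_c / 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CONSTANTS, efg_to_si

__all__ = [
    "RelaxationResult",
    "rate_prefactor",
    "quadrupolar_rate",
    "qcc",
    "narrowing_check",
]

_VALID_SPINS = (1.0, 1.5, 2.5, 3.5, 4.5)


def rate_prefactor(spin: float) -> float:
    """(2I+3) / (20 I^2 (2I-1)); equals 1/15 for I = 3/2."""
    if spin <= 0.5:
        raise ValueError("quadrupolar relaxation requires spin I > 1/2")
    if spin not in _VALID_SPINS:
        raise ValueError(f"spin must be one of {_VALID_SPINS}")
    return (2 * spin + 3) / (20.0 * spin ** 2 * (2 * spin - 1))


def qcc(variance_si: float, quadrupole_moment: float = CONSTANTS.Q_23Na,
        ) -> float:
    """Quadrupolar coupling constant C_Q = sqrt((2/3) (eQ/hbar)^2 <V^2>),
    rad/s, from the SI EFG variance (V^2 m^-4)."""
    if variance_si < 0:
        raise ValueError("variance must be non-negative")
    eq_hbar = CONSTANTS.e * quadrupole_moment / CONSTANTS.hbar
    return float(np.sqrt(2.0 / 3.0) * eq_hbar * np.sqrt(variance_si))


@dataclass
class RelaxationResult:
    rate: float                    # 1/T1, s^-1
    variance_si: float             # <V^2>, V^2 m^-4
    variance_eA3: float            # <V^2>, e^2 A^-6
    tau_c: float                   # s
    C_Q: float                     # rad/s
    spin: float
    quadrupole_moment: float       # m^2
    rate_se: float = 0.0
    narrowing_product_angular: float | None = None
    narrowing_product_linear: float | None = None
    narrowing_ok: bool | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")

    @property
    def T1(self) -> float:
        return np.inf if self.rate == 0 else 1.0 / self.rate


def quadrupolar_rate(variance_si: float, tau_c: float,
                     spin: float = CONSTANTS.I_23Na,
                     quadrupole_moment: float = CONSTANTS.Q_23Na,
                     variance_se: float = 0.0, tau_c_se: float = 0.0,
                     larmor_frequency: float | None = None,
                     provenance: dict | None = None) -> RelaxationResult:
    """Longitudinal quadrupolar rate 1/T1 from <V^2> (SI) and tau_c (s).

    The rate is linear in both inputs; their relative standard errors are
    propagated in quadrature.  When a Larmor frequency (Hz) is given, the
    extreme-narrowing product is evaluated under both the angular
    (omega_0 = 2 pi f) and the linear (omega_0 = f) convention.
    """
    if variance_si < 0 or tau_c < 0:
        raise ValueError("variance and tau_c must be non-negative")
    pref = rate_prefactor(spin)
    eq_hbar = CONSTANTS.e * quadrupole_moment / CONSTANTS.hbar
    rate = pref * eq_hbar ** 2 * variance_si * tau_c
    cq = qcc(variance_si, quadrupole_moment)
    rel = 0.0
    if variance_si > 0:
        rel += (variance_se / variance_si) ** 2
    if tau_c > 0:
        rel += (tau_c_se / tau_c) ** 2
    res = RelaxationResult(
        rate=float(rate), variance_si=variance_si,
        variance_eA3=float(variance_si / CONSTANTS.efg_si_per_eA3 ** 2),
        tau_c=tau_c, C_Q=cq, spin=spin,
        quadrupole_moment=quadrupole_moment,
        rate_se=float(rate * np.sqrt(rel)),
        provenance=dict(provenance or {}),
    )
    if larmor_frequency is not None:
        prod_ang, prod_lin, ok, _ = narrowing_check(tau_c, larmor_frequency)
        res.narrowing_product_angular = prod_ang
        res.narrowing_product_linear = prod_lin
        res.narrowing_ok = ok
    return res


def narrowing_check(tau_c: float, larmor_frequency: float,
                    threshold: float = 0.01,
                    ) -> tuple[float, float, bool, str]:
    """Extreme-narrowing products omega_0 tau_c under both frequency
    conventions.

    Returns (2 pi f tau_c, f tau_c, passes, message).  The angular
    convention decides the pass; a product exactly at the threshold passes
    with a boundary warning.
    """
    if tau_c < 0 or larmor_frequency <= 0:
        raise ValueError("inputs must be positive")
    prod_ang = 2.0 * np.pi * larmor_frequency * tau_c
    prod_lin = larmor_frequency * tau_c
    ok = prod_ang <= threshold
    msg = ""
    if ok and prod_ang == threshold:
        msg = "narrowing product exactly at threshold; treat with caution"
    elif not ok:
        msg = (f"omega_0 tau_c = {prod_ang:.3g} > {threshold}: outside the "
               "extreme-narrowing regime, Eq. rates unreliable")
    return float(prod_ang), float(prod_lin), bool(ok), msg


def rate_from_series_variance(variance_eA3: float, tau_c_fs: float,
                              gamma_factor: float = 0.0,
                              **kwargs) -> RelaxationResult:
    """Convenience wrapper: internal units in, SI rate out.

    Applies the electron-cloud correction (1 + gamma)^2 to the classical
    variance (e^2/A^6), converts to SI and evaluates the rate with tau_c
    given in fs.
    """
    var_total = (1.0 + gamma_factor) ** 2 * variance_eA3
    var_si = float(efg_to_si(1.0) ** 2 * var_total)
    prov = kwargs.pop("provenance", {})
    prov.update({"gamma_factor": gamma_factor,
                 "variance_ext_eA3": variance_eA3})
    return quadrupolar_rate(var_si, tau_c_fs * 1e-15, provenance=prov,
                            **kwargs)
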