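"""Electron-cloud (Sternheimer) calibration of classical EFGs.

The full EFG at a quadrupolar nucleus is enhanced relative to the external
point-charge EFG by polarization of the ion's electron cloud.  Two
effective enhancement factors are estimated from tables pairing ab initio
EFG components V_AI with classical ones V_ext on the same configurations:

* slope factor:     V_AI = (1 + gamma_eff) V_ext, intercept-free least
  squares over all pooled tensor components;
* variance factor:  (1 + gamma'_eff)^2 = <V_AI^2> / <V_ext^2>.

On noiseless proportional tables the two coincide; additive contributions
uncorrelated with V_ext inflate the variance ratio but not the slope, so
gamma'_eff >= gamma_eff is the expected ordering.  Uncertainties come from
bootstrap resampling of whole configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BootstrapResult, bootstrap

__all__ = [
    "COMPONENTS",
    "EFGPairTable",
    "SternheimerResult",
    "fit_gamma_slope",
    "fit_gamma_variance",
    "predict_total_variance",
]

COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")


@dataclass
class EFGPairTable:
    """Matched classical/ab-initio EFG component records.

    ``frame`` is a pandas DataFrame with columns config_id, probe_id, comp
    (one of xx|yy|zz|xy|xz|yz), v_ext, v_ai.  Units must be consistent
    between the two columns (e/A^3 or atomic units, declared in ``units``);
    both estimators are invariant under a global rescaling.
    """

    frame: pd.DataFrame
    units: str = "e/A^3"

    def __post_init__(self) -> None:
        required = {"config_id", "probe_id", "comp", "v_ext", "v_ai"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"pair table missing columns {sorted(missing)}")
        bad = set(self.frame["comp"].unique()) - set(COMPONENTS)
        if bad:
            raise ValueError(f"unknown tensor components {sorted(bad)}")
        if len(self.frame) < 10:
            raise ValueError(
                f"pair table needs >= 10 matched records, got {len(self.frame)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def config_ids(self) -> np.ndarray:
        return self.frame["config_id"].unique()


@dataclass
class SternheimerResult:
    gamma: float
    gamma_se: float
    kind: str                    # "slope" or "variance"
    n_records: int
    bootstrap: BootstrapResult | None = None
    r_squared: float = float("nan")
    intercept_diag: float = float("nan")
    flags: list[str] = field(default_factory=list)

    @property
    def enhancement(self) -> float:
        """The (1 + gamma) multiplier applied to classical EFGs."""
        return 1.0 + self.gamma


def _slope_through_origin(x: np.ndarray, y: np.ndarray) -> float:
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("zero variance of V_ext")
    return float(np.dot(x, y) / sxx)


def _per_config_resampler(table: EFGPairTable, reducer,
                          n_resamples: int, seed: int) -> BootstrapResult:
    """Bootstrap a scalar statistic by resampling whole configurations.

    Both estimators depend on the data only through the per-configuration
    sufficient statistics (sum x^2, sum x y, sum y^2), so the resampling
    is a vectorized sum over sampled group rows.
    """
    g = table.frame.groupby("config_id", sort=False)
    sxx = g.apply(lambda d: np.dot(d.v_ext, d.v_ext),
                  include_groups=False).to_numpy()
    sxy = g.apply(lambda d: np.dot(d.v_ext, d.v_ai),
                  include_groups=False).to_numpy()
    syy = g.apply(lambda d: np.dot(d.v_ai, d.v_ai),
                  include_groups=False).to_numpy()
    stats = np.column_stack([sxx, sxy, syy])
    n_groups = stats.shape[0]
    if n_groups < 2:
        raise ValueError("configuration bootstrap needs >= 2 configurations")
    rng = np.random.default_rng(seed)
    est = float(reducer(*stats.sum(axis=0)))
    idx = rng.integers(0, n_groups, size=(n_resamples, n_groups))
    sums = stats[idx].sum(axis=1)               # (n_resamples, 3)
    reps = reducer(sums[:, 0], sums[:, 1], sums[:, 2])
    se = float(np.std(reps, ddof=1))
    lo, hi = np.quantile(reps, [0.025, 0.975])
    return BootstrapResult(est, se, min(float(lo), est), max(float(hi), est),
                           0.95, n_resamples, seed)


def fit_gamma_slope(table: EFGPairTable, n_resamples: int = 1000,
                    seed: int = 0) -> SternheimerResult:
    """Intercept-free regression of V_AI on V_ext pooled over components.

    gamma_eff = slope - 1.  An ordinary-least-squares intercept is reported
    as a diagnostic only and never enters gamma_eff.
    """
    x = table.frame["v_ext"].to_numpy(float)
    y = table.frame["v_ai"].to_numpy(float)
    slope = _slope_through_origin(x, y)
    flags = []
    if np.allclose(y, 0.0):
        flags.append("degenerate: V_AI identically zero (gamma = -1)")
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    # intercept diagnostic from a one-degree-higher OLS fit
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    boot = None
    se = 0.0
    if len(table.config_ids) >= 2:
        boot = _per_config_resampler(
            table, lambda sxx, sxy, syy: sxy / sxx, n_resamples, seed)
        se = boot.std_error
    return SternheimerResult(gamma=slope - 1.0, gamma_se=se, kind="slope",
                             n_records=len(table), bootstrap=boot,
                             r_squared=r2, intercept_diag=float(coef[1]),
                             flags=flags)


def fit_gamma_variance(table: EFGPairTable, n_resamples: int = 1000,
                       seed: int = 0) -> SternheimerResult:
    """Variance-ratio estimator gamma'_eff = sqrt(sum V_AI^2 / sum V_ext^2) - 1.

    The pooled component sums of squares approximate the Frobenius
    variances <V^2> (all six independent components enter the table).
    """
    x = table.frame["v_ext"].to_numpy(float)
    y = table.frame["v_ai"].to_numpy(float)

    def ratio(xv, yv):
        sx = float(np.sum(xv ** 2))
        if sx == 0:
            raise ValueError("zero <V_ext^2>")
        return float(np.sqrt(np.sum(yv ** 2) / sx))

    g = ratio(x, y) - 1.0
    boot = None
    se = 0.0
    if len(table.config_ids) >= 2:
        boot = _per_config_resampler(
            table, lambda sxx, sxy, syy: np.sqrt(syy / sxx),
            n_resamples, seed)
        se = boot.std_error
    return SternheimerResult(gamma=g, gamma_se=se, kind="variance",
                             n_records=len(table), bootstrap=boot)


def predict_total_variance(v_ext_variance: float, gamma: float,
                           v_ext_variance_se: float = 0.0,
                           gamma_se: float = 0.0) -> tuple[float, float]:
    """Total EFG variance <V^2> = (1 + gamma)^2 <V_ext^2>.

    Returns (value, standard error); relative errors of the classical
    variance and of the (1+gamma)^2 factor are combined in quadrature.
    """
    if v_ext_variance < 0:
        raise ValueError("variance must be non-negative")
    factor = (1.0 + gamma) ** 2
    value = factor * v_ext_variance
    rel = 0.0
    if v_ext_variance > 0:
        rel += (v_ext_variance_se / v_ext_variance) ** 2
    if 1.0 + gamma != 0:
        rel += (2.0 * gamma_se / (1.0 + gamma)) ** 2
    return value, value * np.sqrt(rel)
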