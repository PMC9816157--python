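"""Shared domain types, unit conventions, physical constants and bootstrap
resampling.

Internal unit system
--------------------
Lengths in angstrom, times in femtoseconds, charges in units of the
elementary charge *e*, temperatures in kelvin.  Electric field gradients
(EFGs) are carried in e/A^3 throughout the analysis and converted to SI
(V/m^2) only inside the relaxation-rate formulas; this keeps tensor lattice
sums of order unity and avoids float underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "CONSTANTS",
    "PhysicalConstants",
    "Configuration",
    "StatePoint",
    "BootstrapResult",
    "bootstrap",
    "block_bootstrap",
    "efg_to_si",
    "efg_from_si",
]


class DegenerateInputError(ValueError):
    """Raised when an estimator receives statistically unusable input."""


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA constants plus the 23Na nuclear parameters.

    ``efg_au`` converts an EFG from e/A^3 to SI volts per square metre:
    e / (4 pi eps0 * 1e-30 m^3).
    """

    k_B: float = 1.380649e-23           # J/K
    hbar: float = 1.054571817e-34       # J s
    e: float = 1.602176634e-19          # C
    eps0: float = 8.8541878128e-12      # F/m
    Q_23Na: float = 104e-31             # m^2, quadrupole moment of 23Na
    I_23Na: float = 1.5                 # nuclear spin of 23Na

    @property
    def coulomb_constant(self) -> float:
        """1/(4 pi eps0) in SI."""
        return 1.0 / (4.0 * np.pi * self.eps0)

    @property
    def efg_si_per_eA3(self) -> float:
        """V/m^2 per (e/A^3)."""
        return self.e * self.coulomb_constant / 1e-30


CONSTANTS = PhysicalConstants()


def efg_to_si(value_eA3):
    """Convert EFG value(s) from e/A^3 to V/m^2."""
    return np.asarray(value_eA3, dtype=float) * CONSTANTS.efg_si_per_eA3


def efg_from_si(value_si):
    """Convert EFG value(s) from V/m^2 back to e/A^3."""
    return np.asarray(value_si, dtype=float) / CONSTANTS.efg_si_per_eA3


# --------------------------------------------------------------------------
# Configurations and state points
# --------------------------------------------------------------------------

@dataclass
class Configuration:
    """One periodic point-charge snapshot in a cubic box.

    Parameters
    ----------
    positions : (N, 3) array, angstrom.  May lie outside the box; they are
        wrappable into [0, L)^3 on demand.
    charges : (N,) array, units of e.
    box_edge : cubic box edge L in angstrom.
    species : N labels (defaults to "X").
    time : frame time in fs.
    """

    positions: np.ndarray
    charges: np.ndarray
    box_edge: float
    species: Sequence[str] | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        if self.positions.shape != (len(self.charges), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} inconsistent with "
                f"{len(self.charges)} charges"
            )
        if not self.box_edge > 0:
            raise ValueError("box_edge must be positive")
        if self.species is None:
            self.species = ["X"] * len(self.charges)
        elif len(self.species) != len(self.charges):
            raise ValueError("species length mismatch")

    def __len__(self) -> int:
        return len(self.charges)

    @property
    def n_particles(self) -> int:
        return len(self.charges)

    @property
    def volume(self) -> float:
        """Box volume in A^3."""
        return self.box_edge ** 3

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def is_neutral(self) -> bool:
        return abs(self.total_charge) <= 1e-9

    def wrapped(self) -> np.ndarray:
        """Positions wrapped into [0, L)^3."""
        return np.mod(self.positions, self.box_edge)

    def minimum_image(self, dr: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention to displacement vectors."""
        L = self.box_edge
        return dr - L * np.round(dr / L)


@dataclass(frozen=True)
class StatePoint:
    """Thermodynamic state: molality (mol/kg), temperature (K), density."""

    molality: float = 0.0
    temperature: float = 298.15
    density: float | None = None

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if self.molality < 0:
            raise ValueError("molality must be non-negative")


# --------------------------------------------------------------------------
# Bootstrap
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    std_error: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_resamples: int
    seed: int

    def __post_init__(self) -> None:
        if self.std_error < 0:
            raise ValueError("standard error must be non-negative")

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


def bootstrap(
    samples: Sequence[float] | np.ndarray,
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_resamples: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Resample independent per-run statistics with replacement.

    The unit of resampling is the independent simulation run.  Deterministic
    given ``seed``; the percentile confidence interval is widened (if needed)
    to contain the point estimate.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < 2:
        raise DegenerateInputError(
            f"bootstrap needs at least 2 independent samples, got {arr.size}"
        )
    rng = np.random.default_rng(seed)
    est = float(statistic(arr))
    idx = rng.integers(0, arr.size, size=(n_resamples, arr.size))
    reps = np.array([statistic(arr[row]) for row in idx], dtype=float)
    se = float(reps.std(ddof=1))
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    lo = min(float(lo), est)
    hi = max(float(hi), est)
    return BootstrapResult(est, se, lo, hi, ci_level, n_resamples, seed)


def block_bootstrap(
    series: Sequence[float] | np.ndarray,
    statistic: Callable[[np.ndarray], float] = np.mean,
    block_length: int | None = None,
    n_resamples: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Moving-block bootstrap for a single correlated time series.

    Use when only one run is available: contiguous blocks of
    ``block_length`` frames are drawn with replacement and concatenated,
    which respects temporal correlation up to the block length.  Callers
    that know a slow relaxation time should pass a block of ~10x that time
    in frames.
    """
    arr = np.asarray(series, dtype=float).ravel()
    if arr.size < 2:
        raise DegenerateInputError("block bootstrap needs at least 2 frames")
    if block_length is None:
        block_length = max(1, arr.size // 20)
    block_length = int(min(block_length, arr.size))
    n_blocks = int(np.ceil(arr.size / block_length))
    starts_max = arr.size - block_length + 1
    rng = np.random.default_rng(seed)
    est = float(statistic(arr))
    reps = np.empty(n_resamples)
    for k in range(n_resamples):
        starts = rng.integers(0, starts_max, size=n_blocks)
        pieces = [arr[s:s + block_length] for s in starts]
        reps[k] = statistic(np.concatenate(pieces)[: arr.size])
    se = float(reps.std(ddof=1))
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    lo = min(float(lo), est)
    hi = max(float(hi), est)
    return BootstrapResult(est, se, lo, hi, ci_level, n_resamples, seed)
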