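"""Specific energy and fluence-weighted yield computations.

Two quantities connect track-level physics to the damage and survival
models: the frequency-mean specific energy of a single charged-particle
traversal of a micrometre-scale water target,

    zF = 0.204 * LET / d**2     [Gy, LET in keV/um, d in um]

and the energy-fluence / stopping-power weighted mean of an
energy-dependent damage yield over a secondary-electron spectrum,

    Y = integral(Y(E) Phi(E) LET(E) dE) / integral(Phi(E) LET(E) dE).

The integral is evaluated by trapezoidal quadrature on the union of the
spectrum and yield-curve energy grids, with the yield interpolated
log-linearly in energy (yield curves are smooth and monotone over the
keV range of interest).  Extrapolating the yield curve outside its
tabulated range is an error, since the low-energy end dominates the
systematic uncertainty of the weighted yield.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FluenceSpectrum",
    "YieldCurve",
    "TargetGeometry",
    "frequency_mean_specific_energy",
    "dose_weighted_yield",
]

_ZBAR_COEFF = 0.204  # Gy um^2 / (keV/um) for a water sphere


def _check_grid(energies: np.ndarray, name: str) -> None:
    if energies.ndim != 1 or energies.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D energy grid")
    if np.any(np.diff(energies) <= 0):
        raise ValueError(f"{name} energies must be strictly increasing")
    if np.any(energies <= 0):
        raise ValueError(f"{name} energies must be positive")


@dataclass(frozen=True)
class FluenceSpectrum:
    """Secondary-electron spectrum: energy (keV), relative energy-fluence
    density and unrestricted stopping power LET (keV/um) on a common grid."""

    energy_kev: np.ndarray
    fluence: np.ndarray
    let_kev_um: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "energy_kev", np.asarray(self.energy_kev, float))
        object.__setattr__(self, "fluence", np.asarray(self.fluence, float))
        object.__setattr__(self, "let_kev_um", np.asarray(self.let_kev_um, float))
        _check_grid(self.energy_kev, "spectrum")
        if self.fluence.shape != self.energy_kev.shape or (
            self.let_kev_um.shape != self.energy_kev.shape
        ):
            raise ValueError("fluence and LET must match the energy grid")
        if np.any(self.fluence < 0) or np.any(self.let_kev_um < 0):
            raise ValueError("fluence and LET must be non-negative")
        if not np.any(self.fluence > 0):
            raise ValueError("spectrum must contain at least one point with fluence > 0")


@dataclass(frozen=True)
class YieldCurve:
    """Damage yield Y(E) (per Gy per Gbp) tabulated on an energy grid (keV)."""

    energy_kev: np.ndarray
    yield_per_gy_gbp: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "energy_kev", np.asarray(self.energy_kev, float))
        object.__setattr__(
            self, "yield_per_gy_gbp", np.asarray(self.yield_per_gy_gbp, float)
        )
        _check_grid(self.energy_kev, "yield curve")
        if self.yield_per_gy_gbp.shape != self.energy_kev.shape:
            raise ValueError("yields must match the energy grid")
        if np.any(self.yield_per_gy_gbp < 0):
            raise ValueError("yields must be non-negative")

    def interpolate(self, energy_kev: np.ndarray) -> np.ndarray:
        """Log-linear (in E) interpolation; extrapolation is refused."""
        e = np.asarray(energy_kev, float)
        lo, hi = self.energy_kev[0], self.energy_kev[-1]
        if np.any(e < lo * (1 - 1e-12)) or np.any(e > hi * (1 + 1e-12)):
            raise ValueError(
                f"requested energies outside tabulated range [{lo}, {hi}] keV; "
                "extrapolation of yield curves is not allowed"
            )
        return np.interp(np.log(e), np.log(self.energy_kev), self.yield_per_gy_gbp)


@dataclass(frozen=True)
class TargetGeometry:
    """Spherical water target; diameter in micrometres (default: V79 cell)."""

    diameter_um: float = 8.0

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("target diameter must be positive")


def frequency_mean_specific_energy(
    let_kev_um: float, geometry: TargetGeometry
) -> float:
    """Mean specific energy (Gy) per single traversal of the target."""
    if let_kev_um < 0:
        raise ValueError("LET must be non-negative")
    return _ZBAR_COEFF * let_kev_um / geometry.diameter_um**2


def dose_weighted_yield(curve: YieldCurve, spectrum: FluenceSpectrum) -> float:
    """Fluence- and LET-weighted mean damage yield over the spectrum.

    A single-point spectrum acts as a delta weight and returns Y at that
    energy.  Raises on zero total weight or if the spectrum's support
    lies outside the tabulated yield curve.
    """
    e_spec = spectrum.energy_kev
    if e_spec.size == 1:
        return float(curve.interpolate(e_spec)[0])

    grid = np.union1d(e_spec, curve.energy_kev)
    grid = grid[(grid >= e_spec[0]) & (grid <= e_spec[-1])]
    weight = np.interp(grid, e_spec, spectrum.fluence * spectrum.let_kev_um)
    denominator = np.trapezoid(weight, grid)
    if denominator <= 0:
        raise ValueError("spectrum has zero fluence*LET weight over its support")
    numerator = np.trapezoid(curve.interpolate(grid) * weight, grid)
    return float(numerator / denominator)
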