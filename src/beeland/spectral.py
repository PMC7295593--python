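"""Relative photon radiance and achromatic-system input from lamp spectra.

The bumblebee achromatic (motion/3D-vision) channel is driven chiefly by
green-sensitive photoreceptors. Its relative input under a lamp is modelled
as the trapezoid-rule integral of the lamp's relative photon radiance
multiplied pointwise by the achromatic spectral-sensitivity curve, after
resampling both onto the union wavelength grid of their overlap by linear
interpolation. Ratios of such integrals compare light conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DisjointSupportError(ValueError):
    """The two wavelength grids do not overlap."""


@dataclass(frozen=True)
class Spectrum:
    """A relative spectrum on a strictly increasing wavelength grid (nm)."""

    wavelength: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.shape != vals.shape:
            raise ValueError("wavelength and values must be matching 1D arrays")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(vals < 0):
            raise ValueError("spectral values must be non-negative")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "values", vals)

    def integral(self) -> float:
        """Trapezoid-rule area under the curve."""
        return float(np.trapezoid(self.values, self.wavelength))

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavelength, self.values * factor)

    def normalised(self) -> "Spectrum":
        """Peak-normalised copy (peak value 1)."""
        peak = self.values.max()
        if peak <= 0:
            raise ValueError("cannot normalise an all-zero spectrum")
        return self.scaled(1.0 / peak)


#: a sensitivity curve is a Spectrum whose values are relative sensitivities
SensitivityCurve = Spectrum


def _common_grid(a: Spectrum, b: Spectrum) -> np.ndarray:
    lo = max(a.wavelength[0], b.wavelength[0])
    hi = min(a.wavelength[-1], b.wavelength[-1])
    if lo >= hi:
        raise DisjointSupportError(
            f"wavelength supports [{a.wavelength[0]}, {a.wavelength[-1]}] and "
            f"[{b.wavelength[0]}, {b.wavelength[-1]}] do not overlap"
        )
    grid = np.union1d(a.wavelength, b.wavelength)
    return grid[(grid >= lo) & (grid <= hi)]


def resample(spec: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto ``grid`` (must lie inside the support)."""
    return Spectrum(grid, np.interp(grid, spec.wavelength, spec.values))


def photon_radiance_ratio(spec_a: Spectrum, spec_b: Spectrum) -> float:
    """Ratio of the areas under two radiance curves, a over b."""
    grid = _common_grid(spec_a, spec_b)
    ia = resample(spec_a, grid).integral()
    ib = resample(spec_b, grid).integral()
    if ib == 0:
        raise ValueError("denominator spectrum integrates to zero on the overlap")
    return ia / ib


def achromatic_input(spec: Spectrum, sens: SensitivityCurve) -> tuple[float, Spectrum]:
    """Relative achromatic-system input under one lamp.

    Returns the trapezoid integral of radiance x sensitivity on the common
    grid together with the per-wavelength product curve.
    """
    grid = _common_grid(spec, sens)
    product = Spectrum(
        grid, resample(spec, grid).values * resample(sens, grid).values
    )
    return product.integral(), product


def achromatic_input_ratio(
    spec_a: Spectrum, spec_b: Spectrum, sens: SensitivityCurve
) -> float:
    """Ratio of achromatic inputs of two lamps under one sensitivity curve."""
    ia, _ = achromatic_input(spec_a, sens)
    ib, _ = achromatic_input(spec_b, sens)
    if ib == 0:
        raise ValueError("denominator achromatic input is zero")
    return ia / ib


def synthetic_achromatic_sensitivity(grid: np.ndarray | None = None) -> SensitivityCurve:
    """Synthetic stand-in for the bumblebee achromatic sensitivity curve.

    A Gaussian green-receptor-like curve peaking at 540 nm with ~100 nm
    full width at half maximum, peak-normalised to 1. It is a synthetic
    placeholder with the qualitative shape of published green-receptor
    sensitivities, not a digitisation of any measured curve.
    """
    if grid is None:
        grid = np.arange(300.0, 701.0, 1.0)
    sigma = 100.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    values = np.exp(-((np.asarray(grid, dtype=float) - 540.0) ** 2) / (2.0 * sigma**2))
    return SensitivityCurve(np.asarray(grid, dtype=float), values)
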