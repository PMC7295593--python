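"""Convenience plots: per-condition kinematic bands and spectra."""

from __future__ import annotations

import numpy as np

from .kinematics import KinematicSeries
from .spectral import SensitivityCurve, Spectrum, achromatic_input

_COLOURS = {"white": "tab:green", "red_blue": "tab:purple"}


def plot_kinematic_bands(
    kins: list[KinematicSeries],
    conditions: list[str],
    field: str = "d_E",
    ax=None,
    t_min: float = -1.8,
):
    """Mean +/- s.e.m. band of one kinematic series per condition vs time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = np.arange(t_min, 0.0 + 1e-9, 0.01)
    for cond in sorted(set(conditions)):
        stack = []
        for kin, c in zip(kins, conditions):
            if c != cond:
                continue
            y = getattr(kin, field)
            stack.append(np.interp(grid, kin.t, y, left=np.nan, right=np.nan))
        arr = np.asarray(stack)
        mean = np.nanmean(arr, axis=0)
        sem = np.nanstd(arr, axis=0) / np.sqrt(np.sum(~np.isnan(arr), axis=0).clip(1))
        colour = _COLOURS.get(cond)
        ax.plot(grid, mean, color="black", lw=1)
        ax.fill_between(grid, mean - sem, mean + sem, alpha=0.4, color=colour, label=cond)
    ax.set_xlabel("time to touchdown (s)")
    ax.set_ylabel(field)
    ax.legend()
    return ax


def plot_spectra(
    white: Spectrum, red_blue: Spectrum, sensitivity: SensitivityCurve, axes=None
):
    """Lamp spectra with the sensitivity curve, and the achromatic products."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    ax0, ax1 = axes
    ax0.plot(white.wavelength, white.values, color="tab:green", label="white")
    ax0.plot(red_blue.wavelength, red_blue.values, color="tab:purple", label="red_blue")
    ax0b = ax0.twinx()
    ax0b.plot(sensitivity.wavelength, sensitivity.values, "k--", label="sensitivity")
    ax0.set_xlabel("wavelength (nm)")
    ax0.set_ylabel("relative photon radiance")
    ax0b.set_ylabel("relative sensitivity")
    ax0.legend()
    for spec, colour in ((white, "tab:green"), (red_blue, "tab:purple")):
        _, product = achromatic_input(spec, sensitivity)
        ax1.plot(product.wavelength, product.values, color=colour)
    ax1.set_xlabel("wavelength (nm)")
    ax1.set_ylabel("relative achromatic input")
    return axes
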