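"""Elastic Rayleigh peak integration in spectrofluorimeter emission spectra.

With emission scanned across the excitation wavelength, the band at
lambda_em = lambda_ex is elastically scattered light; its background-
subtracted area is proportional to the static scattering intensity of
the sample, so a plain spectrofluorimeter can stand in for a goniometer
in the two-extrusion concentration assay.  Only intensity *ratios* enter
the assay, so PMT voltage and slit settings drop out as long as the two
samples are measured identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .concentration import gamma_from_intensities

__all__ = ["EmissionSpectrum", "integrate_elastic_peak", "peak_areas_to_gamma"]


@dataclass(frozen=True)
class EmissionSpectrum:
    """An emission scan: wavelength grid (nm) vs detector counts (a.u.)."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    excitation_nm: float

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", it)
        if wl.ndim != 1 or wl.size != it.size:
            raise ValueError("wavelengths and intensities must be 1-D of equal length")
        if wl.size < 5:
            raise ValueError("spectrum needs at least 5 points")
        if not np.all(np.diff(wl) > 0):
            bad = int(np.flatnonzero(np.diff(wl) <= 0)[0]) + 1
            raise ValueError(f"wavelength grid must be strictly increasing (violation at point {bad})")
        if not np.all(np.isfinite(it)):
            raise ValueError("intensities contain non-finite values")
        if not self.excitation_nm > 0:
            raise ValueError("excitation wavelength must be positive")


def _interp(spec: EmissionSpectrum, x: np.ndarray) -> np.ndarray:
    return np.interp(x, spec.wavelengths_nm, spec.intensities)


def integrate_elastic_peak(
    spec: EmissionSpectrum,
    window_nm: float = 5.0,
    background: EmissionSpectrum | str | None = "flanking",
) -> float:
    """Background-subtracted area of the elastic peak, a.u. * nm.

    Integrates (trapezoid rule) the intensity over
    [lambda_ex - window_nm, lambda_ex + window_nm].  Background handling:

    * ``"flanking"`` (default): a straight baseline is fit to the two
      flanking bands of width ``window_nm`` just outside the window and
      subtracted, which also absorbs any constant offset;
    * an :class:`EmissionSpectrum`: an explicit buffer scan, interpolated
      onto the sample grid and subtracted;
    * ``None``: no subtraction.

    A net negative area is clipped to 0 with a warning.
    """
    if not window_nm > 0:
        raise ValueError("window_nm must be positive")
    lo = spec.excitation_nm - window_nm
    hi = spec.excitation_nm + window_nm
    wl = spec.wavelengths_nm
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(
            f"integration window [{lo:.1f}, {hi:.1f}] nm exceeds the spectrum "
            f"range [{wl[0]:.1f}, {wl[-1]:.1f}] nm"
        )

    inside = (wl >= lo) & (wl <= hi)
    # include the exact window edges by interpolation so the area does not
    # depend on how grid points straddle the window
    x = np.concatenate(([lo], wl[inside], [hi]))
    x = np.unique(x)
    y = _interp(spec, x)

    if background is None:
        base = np.zeros_like(x)
    elif isinstance(background, EmissionSpectrum):
        base = np.interp(x, background.wavelengths_nm, background.intensities)
    elif background == "flanking":
        flank = ((wl >= lo - window_nm) & (wl < lo)) | ((wl > hi) & (wl <= hi + window_nm))
        if flank.sum() < 2:
            raise ValueError("not enough points in the flanking bands to fit a baseline")
        coeffs = np.polyfit(wl[flank], spec.intensities[flank], 1)
        base = np.polyval(coeffs, x)
    else:
        raise ValueError(f"unknown background mode {background!r}")

    area = float(np.trapezoid(y - base, x))
    if area < 0:
        if area < -1e-9:  # beyond floating-point noise
            warnings.warn(
                f"net elastic-peak area {area:.4g} is negative (noise exceeds signal); "
                "clipped to 0",
                stacklevel=2,
            )
        area = 0.0
    return area


def peak_areas_to_gamma(a1: float, d1: float, a2: float, d2: float) -> float:
    """Concentration ratio gamma from elastic-peak areas A1, A2.

    The areas proxy the scattered intensities I1, I2, so
    gamma = (A1 d1)/(A2 d2) feeds the mass-closure solver unchanged.
    """
    return gamma_from_intensities(a1, d1, a2, d2)
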