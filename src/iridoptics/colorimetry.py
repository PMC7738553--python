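"""Spectral summaries: smoothing, peak, FWHM and CIE 1931 chromaticity.

Measured cell spectra in this pipeline follow the hyperspectral-imaging
convention of a running average over three data points before any
readout; :func:`peak_wavelength` therefore smooths (window 3) before
taking the argmax.  Chromaticity uses the CIE 1931 2-degree observer,
represented analytically as sums of piecewise Gaussians (the
Wyman-Sloan-Shirley multi-lobe fit, accurate to about 1% of peak),
area-normalised so that the equal-energy illuminant maps exactly to
(x, y) = (1/3, 1/3).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DataError, ParameterError
from .tmm import Spectrum

#: Wavelength support of the colour-matching functions (nm).
CMF_MIN_NM = 380.0
CMF_MAX_NM = 780.0

#: Peak/FWHM sentinel when a spectrum carries no peak.
NO_PEAK = float("nan")


def _piecewise_gaussian(x: np.ndarray, mu: float, s1: float, s2: float) -> np.ndarray:
    s = np.where(x < mu, s1, s2)
    return np.exp(-0.5 * ((x - mu) / s) ** 2)


def _cmf_raw(wl: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multi-lobe analytic fit to the CIE 1931 2-degree observer."""
    g = _piecewise_gaussian
    xbar = (
        1.056 * g(wl, 599.8, 37.9, 31.0)
        + 0.362 * g(wl, 442.0, 16.0, 26.7)
        - 0.065 * g(wl, 501.1, 20.4, 26.2)
    )
    ybar = 0.821 * g(wl, 568.8, 46.9, 40.5) + 0.286 * g(wl, 530.9, 16.3, 31.1)
    zbar = 1.217 * g(wl, 437.0, 11.8, 36.0) + 0.681 * g(wl, 459.0, 26.0, 13.8)
    return xbar, ybar, zbar


def _cmf_norms() -> tuple[float, float, float]:
    wl = np.arange(CMF_MIN_NM, CMF_MAX_NM + 0.5, 1.0)
    xb, yb, zb = _cmf_raw(wl)
    return tuple(float(np.trapezoid(c, wl)) for c in (xb, yb, zb))  # type: ignore[return-value]


_NORMS = _cmf_norms()


def color_matching_functions(wavelengths: np.ndarray) -> np.ndarray:
    """(3, n) array of x̄, ȳ, z̄ at the given wavelengths (nm).

    Each function is normalised to unit area over 380-780 nm, which
    pins the equal-energy white point at exactly (1/3, 1/3) — the
    defining property of the true 1931 observer, whose three areas are
    equal.
    """
    wl = np.asarray(wavelengths, dtype=float)
    xb, yb, zb = _cmf_raw(wl)
    return np.stack([xb / _NORMS[0], yb / _NORMS[1], zb / _NORMS[2]])


@dataclass(frozen=True)
class ChromaticityPoint:
    """CIE 1931 (x, y) chromaticity coordinates.

    Points computed from physical spectra satisfy x + y <= 1 (they lie
    inside the spectral locus); the container itself only requires each
    coordinate to be in [0, 1].
    """

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x <= 1.0 and 0.0 <= self.y <= 1.0):
            raise DataError("chromaticity coordinates must lie in [0, 1]")


def smooth(spectrum: Spectrum, window: int = 3) -> Spectrum:
    """Centered running average; edges use shrinking windows.

    The default window of three data points matches the smoothing
    applied to measured hyperspectral reflectance before plotting.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError("window must be odd and >= 1")
    n = len(spectrum)
    if window > n:
        raise ParameterError(f"window {window} exceeds spectrum length {n}")
    if window == 1:
        return spectrum
    kernel = np.ones(window)
    num = np.convolve(spectrum.reflectance, kernel, mode="same")
    den = np.convolve(np.ones(n), kernel, mode="same")
    return spectrum.with_reflectance(num / den, smoothed_window=window)


def peak_wavelength(spectrum: Spectrum, window: int = 3) -> float:
    """Wavelength (nm) of the global maximum of the smoothed spectrum.

    Ties (plateaus) break toward the shortest wavelength.  Returns the
    NO_PEAK sentinel (NaN) when the spectrum has no positive value.
    """
    if len(spectrum) == 0:
        raise DataError("empty spectrum")
    sm = smooth(spectrum, window) if window > 1 else spectrum
    r = sm.reflectance
    if not (r > 0).any():
        return NO_PEAK
    return float(sm.wavelengths[int(np.argmax(r))])


def fwhm(spectrum: Spectrum) -> tuple[float, bool]:
    """Full width at half maximum (nm) by linear interpolation.

    Returns ``(width, truncated)``; ``truncated`` is True when the
    half-maximum level is not crossed before a band edge, in which case
    the edge stands in for the missing crossing.  Width is NaN when the
    spectrum has no peak.
    """
    if len(spectrum) == 0:
        raise DataError("empty spectrum")
    wl = spectrum.wavelengths
    r = spectrum.reflectance
    if not (r > 0).any():
        return NO_PEAK, False
    i_pk = int(np.argmax(r))
    half = r[i_pk] / 2.0

    def _cross(side: int) -> tuple[float, bool]:
        # walk from the peak outward until r drops below half
        i = i_pk
        while 0 <= i + side < len(r) and r[i + side] >= half:
            i += side
        j = i + side
        if j < 0 or j >= len(r):
            return float(wl[i]), True
        # linear interpolation between (wl[i], r[i]) and (wl[j], r[j])
        frac = (r[i] - half) / (r[i] - r[j])
        return float(wl[i] + frac * (wl[j] - wl[i])), False

    lo, lo_trunc = _cross(-1)
    hi, hi_trunc = _cross(+1)
    return hi - lo, lo_trunc or hi_trunc


def _planckian(wl_nm: np.ndarray, temperature: float) -> np.ndarray:
    # Planck's law, arbitrary scale (chromaticity is scale-invariant)
    c2 = 1.4388e7  # nm*K, CIE value of the second radiation constant
    wl = wl_nm
    return wl**-5 / (np.exp(c2 / (wl * temperature)) - 1.0)


def cie_xy(
    spectrum: Spectrum,
    illuminant: Literal["equal_energy", "D65"] = "equal_energy",
) -> ChromaticityPoint:
    """CIE 1931 chromaticity of a reflectance spectrum.

    Tristimulus values integrate reflectance x illuminant against the
    2-degree colour-matching functions; the default equal-energy
    illuminant reports the intrinsic reflectance colour.  "D65" is
    approximated by a Planckian radiator at 6504 K.
    """
    wl = spectrum.wavelengths
    mask = (wl >= CMF_MIN_NM) & (wl <= CMF_MAX_NM)
    if mask.sum() < 2:
        raise DataError("spectrum does not overlap the 380-780 nm CMF support")
    wl = wl[mask]
    refl = spectrum.reflectance[mask]
    if illuminant == "equal_energy":
        s = np.ones_like(wl)
    elif illuminant == "D65":
        s = _planckian(wl, 6504.0)
        s = s / s.max()
    else:
        raise ParameterError(f"unknown illuminant {illuminant!r}")
    cmf = color_matching_functions(wl)
    xyz = np.trapezoid(cmf * (refl * s)[None, :], wl, axis=1)
    total = xyz.sum()
    if total <= 0:
        raise DataError("spectrum integrates to zero against the CMFs")
    return ChromaticityPoint(float(xyz[0] / total), float(xyz[1] / total))


def contrast(a: ChromaticityPoint, b: ChromaticityPoint) -> float:
    """Euclidean distance between two chromaticity points.

    Used as the stripe/interstripe colour-contrast metric.
    """
    return float(np.hypot(a.x - b.x, a.y - b.y))


def spectral_summary(spectrum_: Spectrum) -> dict:
    """JSON-ready summary: peak, FWHM (of the smoothed spectrum), CIE xy."""
    sm = smooth(spectrum_, 3) if len(spectrum_) >= 3 else spectrum_
    width, truncated = fwhm(sm)
    point = cie_xy(spectrum_)
    return {
        "peak_nm": peak_wavelength(spectrum_),
        "fwhm_nm": width,
        "truncated_fwhm": truncated,
        "cie_x": point.x,
        "cie_y": point.y,
    }
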