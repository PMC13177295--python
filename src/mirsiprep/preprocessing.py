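"""Per-spectrum preprocessing: rubberband baseline, SG derivative, Z-score.

The rubberband baseline is the lower convex hull of the (wavenumber,
absorbance) points, linearly interpolated between hull vertices; it
removes the broad scattering background while leaving band shapes
untouched.  Second derivatives are taken with a Savitzky-Golay filter
with respect to wavenumber (so units are absorbance * cm^2), and the
filter's edge-affected points are trimmed: one full window length per
side under the defaults (13 + 13 = 26 of the 426 axis points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectral import SpectralAxis

__all__ = [
    "CorrectedSpectrum",
    "SecondDerivSpectrum",
    "rubberband_baseline",
    "rubberband_correct_batch",
    "savgol_second_derivative",
    "zscore_normalize",
]


@dataclass(frozen=True)
class CorrectedSpectrum:
    """Baseline-corrected spectrum; ``values = raw - baseline`` >= 0."""

    values: np.ndarray
    baseline: np.ndarray


@dataclass(frozen=True)
class SecondDerivSpectrum:
    """Second derivative w.r.t. wavenumber on the edge-trimmed axis."""

    values: np.ndarray
    trimmed_axis: SpectralAxis


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> list[int]:
    # Andrew monotone chain, lower hull only.  Collinear middle points are
    # dropped (non-strict turn test), which keeps the baseline identical
    # and the vertex list minimal.  Robust for degenerate (all-collinear)
    # inputs, where a generic hull code fails.
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            cross = (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j])
            if cross <= 0:  # k is above or on the j->i chord
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def rubberband_baseline(spectrum: np.ndarray, axis: SpectralAxis) -> CorrectedSpectrum:
    """Subtract the lower-convex-hull ("rubberband") baseline.

    The first and last grid points are always hull vertices, so the
    corrected spectrum is exactly zero there and nonnegative everywhere.
    """
    y = np.asarray(spectrum, dtype=float)
    if y.ndim != 1:
        raise ValueError("rubberband_baseline expects a single spectrum")
    if y.size != len(axis):
        raise ValueError("spectrum length does not match axis")
    if y.size < 3:
        raise ValueError("need at least 3 points for a baseline")
    if not np.all(np.isfinite(y)):
        raise ValueError("spectrum contains NaN or infinite values")
    x = axis.values
    idx = _lower_hull_indices(x, y)
    baseline = np.interp(x, x[idx], y[idx])
    corrected = y - baseline
    # clip the ~1e-16 interpolation residue so the >= 0 contract is exact
    corrected[corrected < 0] = 0.0
    return CorrectedSpectrum(values=corrected, baseline=baseline)


def rubberband_correct_batch(spectra: np.ndarray, axis: SpectralAxis) -> np.ndarray:
    """Rubberband-correct each row of an (n, K) stack of spectra."""
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2:
        raise ValueError("expected a 2-D (n_spectra, n_wavenumbers) array")
    out = np.empty_like(spectra)
    for i in range(spectra.shape[0]):
        out[i] = rubberband_baseline(spectra[i], axis).values
    return out


def savgol_second_derivative(
    spectrum: np.ndarray,
    axis: SpectralAxis,
    window: int = 13,
    polyorder: int = 2,
    trim_per_side: int = 13,
) -> SecondDerivSpectrum:
    """Savitzky-Golay second derivative with edge trimming.

    Accepts a single spectrum or an (n, K) stack (derivative along the
    last axis).  The derivative is with respect to wavenumber (the axis
    step is passed as the filter ``delta``), and ``trim_per_side`` points
    are removed from each end; defaults reproduce the 426 -> 400 point
    reduction of the reference processing.
    """
    y = np.asarray(spectrum, dtype=float)
    k = y.shape[-1]
    if k != len(axis):
        raise ValueError("spectrum length does not match axis")
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if polyorder < 2:
        raise ValueError("second derivative needs polyorder >= 2")
    if trim_per_side < 0:
        raise ValueError("trim_per_side must be >= 0")
    if k <= window + 2 * trim_per_side:
        raise ValueError(
            f"spectrum too short ({k} points) for window {window} "
            f"and trim {trim_per_side} per side"
        )
    d2 = savgol_filter(
        y, window_length=window, polyorder=polyorder, deriv=2, delta=axis.step, axis=-1
    )
    if trim_per_side > 0:
        d2 = d2[..., trim_per_side:-trim_per_side]
    return SecondDerivSpectrum(values=d2, trimmed_axis=axis.trimmed(trim_per_side))


def zscore_normalize(spectrum: np.ndarray, per_wavenumber: bool = False) -> np.ndarray:
    """Z-score a spectrum (or each row of a stack) to mean 0, sd 1.

    By default each spectrum is standardised across its wavenumbers; with
    ``per_wavenumber=True`` a 2-D stack is standardised per wavenumber
    across spectra instead (population sd in both cases).
    """
    y = np.asarray(spectrum, dtype=float)
    axis = 0 if (per_wavenumber and y.ndim == 2) else -1
    mean = y.mean(axis=axis, keepdims=True)
    sd = y.std(axis=axis, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant spectrum cannot be Z-score normalized")
    return (y - mean) / sd
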