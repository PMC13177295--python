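"""Shared wavenumber-axis type for spectra and hyperspectral cubes.

Mid-IR fingerprint data in this package live on a uniform, ascending
wavenumber grid (cm^-1).  The instrument emulated here covers
950-1800 cm^-1 at 2 cm^-1 steps, a 426-point axis, but any uniform grid
is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectralAxis", "make_spectral_axis"]

_UNIFORMITY_TOL = 1e-9


@dataclass(frozen=True)
class SpectralAxis:
    """Ordered wavenumber grid in cm^-1, strictly increasing and uniform."""

    values: np.ndarray
    step: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("spectral axis needs at least two points")
        diffs = np.diff(values)
        if np.any(diffs <= 0):
            raise ValueError("spectral axis must be strictly increasing")
        if np.max(np.abs(diffs - self.step)) > _UNIFORMITY_TOL * max(1.0, abs(self.step)):
            raise ValueError(
                f"spectral axis spacing is not uniform at step={self.step}"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def min(self) -> float:
        return float(self.values[0])

    @property
    def max(self) -> float:
        return float(self.values[-1])

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the grid point closest to ``wavenumber``.

        Ties between two equidistant grid points resolve to the lower
        wavenumber.
        """
        d = np.abs(self.values - float(wavenumber))
        # argmin returns the first (lowest-wavenumber) minimiser on ties
        return int(np.argmin(d))

    def trimmed(self, per_side: int) -> "SpectralAxis":
        """Contiguous sub-axis with ``per_side`` points removed at each end."""
        if per_side < 0:
            raise ValueError("per_side must be >= 0")
        if 2 * per_side >= len(self):
            raise ValueError("trim removes every point of the axis")
        if per_side == 0:
            return self
        return SpectralAxis(self.values[per_side:-per_side].copy(), self.step)


def make_spectral_axis(min_wn: float, max_wn: float, step: float) -> SpectralAxis:
    """Build a uniform wavenumber axis from ``min_wn`` to ``max_wn`` inclusive.

    The range must be an integer multiple of ``step`` (within 1e-6 relative),
    so e.g. (950, 1800, 2) yields the instrument's 426-point axis.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if max_wn <= min_wn:
        raise ValueError("max_wn must exceed min_wn")
    span = max_wn - min_wn
    n_intervals = span / step
    if abs(n_intervals - round(n_intervals)) > 1e-6 * max(1.0, n_intervals):
        raise ValueError(
            f"range {min_wn}..{max_wn} cm^-1 is not divisible by step {step} cm^-1"
        )
    n_points = int(round(n_intervals)) + 1
    values = min_wn + step * np.arange(n_points, dtype=float)
    # pin the endpoint exactly to avoid accumulated rounding
    values[-1] = max_wn
    return SpectralAxis(values, float(step))
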