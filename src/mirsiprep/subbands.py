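"""Second-derivative sub-band statistics.

Absorbance maxima appear as *negative dips* of the second derivative, so
significance is one-sided: a local minimum is significant when its value
falls below -3 sigma, with sigma taken from the background model.  Band
occurrence counts, per pixel and per ROI, how often a reference band has
a significant dip within +-2 cm^-1; band "intensity" is quantified by
composite-Simpson integration of the *negated* second derivative over a
window around each reference center (positive for absorbance peaks).
The FF-vs-FFPE effect size is the percent reduction
100 * (I_FF - I_FFPE) / I_FF of a band integral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.optimize import least_squares

from .preprocessing import SecondDerivSpectrum
from .spectral import SpectralAxis

__all__ = [
    "PeakCall",
    "BandWindow",
    "GaussianFit",
    "GaussianFitError",
    "default_band_windows",
    "load_band_table",
    "save_band_table",
    "detect_significant_dips",
    "occurrence_counts",
    "integrate_band",
    "integrate_bands",
    "percent_reduction",
    "fit_gaussian_subbands",
    "summarize_bands",
]

logger = logging.getLogger(__name__)

SIGMA_MULTIPLIER = 3.0
OCCURRENCE_TOLERANCE_CM = 2.0
DEFAULT_WINDOW_HALF_WIDTH_CM = 8.0
EDGE_EXCLUSION_CM = 10.0

# Reference band centers (cm^-1) for the fingerprint region, including the
# fixation-associated ~1026 cm^-1 feature seen only in formalin-fixed tissue.
DEFAULT_BAND_CENTERS: tuple[tuple[str, float], ...] = (
    ("DNA", 966.0),
    ("Fixation", 1026.0),
    ("Glycogen", 1030.0),
    ("DNA", 1035.0),
    ("DNA", 1082.0),
    ("Glycogen", 1154.0),
    ("Proteins", 1168.0),
    ("Amide III", 1238.0),
    ("Amide III", 1308.0),
    ("Proteins", 1400.0),
    ("Proteins", 1448.0),
    ("Lipids", 1462.0),
    ("Amide II", 1516.0),
    ("Amide II", 1546.0),
    ("Amide I", 1658.0),
    ("Lipids", 1744.0),
)


@dataclass(frozen=True)
class PeakCall:
    """One local minimum of a second-derivative spectrum."""

    position: float  # cm^-1, on the trimmed grid
    depth: float  # second-derivative value (negative for real bands)
    significant: bool
    edge_flagged: bool = False


@dataclass(frozen=True)
class BandWindow:
    """A reference band with its integration bounds."""

    label: str
    center: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.center < self.hi:
            raise ValueError(
                f"band {self.label}: need lo < center < hi, got "
                f"{self.lo}, {self.center}, {self.hi}"
            )

    @property
    def key(self) -> str:
        return f"{self.label}~{self.center:g}"


@dataclass(frozen=True)
class GaussianFit:
    """Sum-of-Gaussians fit of a mean absorbance spectrum."""

    params: pd.DataFrame  # columns: center, fwhm, amplitude
    residual_norm: float
    success: bool


class GaussianFitError(RuntimeError):
    """Raised when the sub-band fit fails; carries the best-so-far fit."""

    def __init__(self, message: str, best: GaussianFit):
        super().__init__(message)
        self.best = best


def default_band_windows(
    half_width: float = DEFAULT_WINDOW_HALF_WIDTH_CM,
    centers: Sequence[tuple[str, float]] = DEFAULT_BAND_CENTERS,
) -> list[BandWindow]:
    """Reference band table with symmetric ``center +- half_width`` windows."""
    return [BandWindow(lab, c, c - half_width, c + half_width) for lab, c in centers]


def load_band_table(path: str | Path) -> list[BandWindow]:
    """Load a band table CSV with columns label, center, lo, hi."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"band table not found: {path}")
    df = pd.read_csv(path)
    required = {"label", "center", "lo", "hi"}
    if not required.issubset(df.columns):
        raise ValueError(f"band table {path} must have columns {sorted(required)}")
    return [
        BandWindow(str(r.label), float(r.center), float(r.lo), float(r.hi))
        for r in df.itertuples()
    ]


def save_band_table(bands: Sequence[BandWindow], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(b.label, b.center, b.lo, b.hi) for b in bands],
        columns=["label", "center", "lo", "hi"],
    ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Dip detection and occurrence
# ---------------------------------------------------------------------------

def detect_significant_dips(
    d2: SecondDerivSpectrum,
    sigma: float,
    multiplier: float = SIGMA_MULTIPLIER,
    edge_exclusion: float = EDGE_EXCLUSION_CM,
) -> list[PeakCall]:
    """All local minima of a second-derivative spectrum, flagged by the
    3-sigma rule (significant iff value < -multiplier * sigma).

    Plateau minima report their leftmost point.  Calls within
    ``edge_exclusion`` cm^-1 of the trimmed-axis ends carry an edge flag
    (near-edge features are detectable but not interpretable, like the
    weak ~1788 cm^-1 carbonyl-region artifact).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    v = np.asarray(d2.values, dtype=float)
    if v.ndim != 1:
        raise ValueError("detect_significant_dips expects a single spectrum")
    x = d2.trimmed_axis.values
    threshold = -multiplier * sigma
    calls: list[PeakCall] = []
    n = v.size
    i = 1
    while i < n - 1:
        if v[i] < v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[j]:
                j += 1
            if j < n - 1 and v[j + 1] > v[j]:
                pos = float(x[i])  # leftmost point of a plateau minimum
                near_edge = (
                    pos - x[0] < edge_exclusion or x[-1] - pos < edge_exclusion
                )
                calls.append(
                    PeakCall(
                        position=pos,
                        depth=float(v[i]),
                        significant=bool(v[i] < threshold),
                        edge_flagged=bool(near_edge),
                    )
                )
            i = j + 1
        else:
            i += 1
    return calls


def occurrence_counts(
    calls_per_pixel: Sequence[Sequence[PeakCall]],
    bands: Sequence[BandWindow],
    tolerance: float = OCCURRENCE_TOLERANCE_CM,
    axis_step: float = 2.0,
) -> pd.DataFrame:
    """Per-band occurrence over a set of pixel spectra.

    A pixel counts toward a band when it has at least one *significant*
    call with |position - center| <= tolerance (closed interval); each
    pixel contributes at most once per band.  A call matching several
    overlapping windows is assigned to the nearest center (ties to the
    lower wavenumber), with a warning.
    """
    if tolerance < axis_step / 2:
        raise ValueError(
            f"tolerance {tolerance} cm^-1 is below half the axis step"
        )
    centers = np.array([b.center for b in bands])
    order = np.argsort(centers, kind="stable")
    hit = np.zeros((len(calls_per_pixel), len(bands)), dtype=bool)
    overlap_warned = False
    for p, calls in enumerate(calls_per_pixel):
        for call in calls:
            if not call.significant:
                continue
            dists = np.abs(centers - call.position)
            matches = np.flatnonzero(dists <= tolerance)
            if matches.size == 0:
                continue
            if matches.size > 1 and not overlap_warned:
                logger.warning(
                    "call at %.1f cm^-1 falls in %d overlapping band windows; "
                    "assigning to the nearest center",
                    call.position, matches.size,
                )
                overlap_warned = True
            # nearest center; ties resolve to the lower wavenumber
            best = min(matches, key=lambda m: (dists[m], centers[m]))
            hit[p, best] = True
    n_pixels = len(calls_per_pixel)
    return pd.DataFrame(
        {
            "band_label": [bands[i].label for i in order],
            "center": centers[order],
            "count": hit.sum(axis=0)[order],
            "n_pixels": n_pixels,
        }
    )


# ---------------------------------------------------------------------------
# Band integrals
# ---------------------------------------------------------------------------

def integrate_band(d2: SecondDerivSpectrum, window: BandWindow) -> float:
    """Composite-Simpson integral of -d2 over the band window.

    On an odd number of grid points this is plain composite Simpson
    (exact for cubics); an even count is handled as Simpson over the
    first n-1 points plus a trapezoid on the last interval.  Positive for
    absorbance peaks by the sign convention.
    """
    x = d2.trimmed_axis.values
    eps = 1e-9
    if window.lo < x[0] - eps or window.hi > x[-1] + eps:
        raise ValueError(
            f"band {window.label} window [{window.lo}, {window.hi}] lies "
            f"outside the trimmed axis [{x[0]}, {x[-1]}]"
        )
    i0 = int(np.searchsorted(x, window.lo - eps, side="left"))
    i1 = int(np.searchsorted(x, window.hi + eps, side="right"))
    if i1 - i0 < 3:
        raise ValueError(
            f"band {window.label}: fewer than 3 grid points in the window"
        )
    xs = x[i0:i1]
    ys = -np.asarray(d2.values, dtype=float)[i0:i1]
    n = xs.size
    if n % 2 == 1:
        return float(simpson(ys, x=xs))
    head = float(simpson(ys[: n - 1], x=xs[: n - 1]))
    tail = 0.5 * (ys[-2] + ys[-1]) * (xs[-1] - xs[-2])
    return head + float(tail)


def bands_within(
    d2: SecondDerivSpectrum, bands: Sequence[BandWindow]
) -> list[BandWindow]:
    """Bands whose integration window lies on the trimmed axis.

    Edge trimming can push a reference window off the analysable range
    (e.g. the 966 cm^-1 window under the default 13-point-per-side trim);
    such bands are dropped with a warning rather than integrated.
    """
    x = d2.trimmed_axis.values
    kept, dropped = [], []
    for b in bands:
        (kept if (b.lo >= x[0] - 1e-9 and b.hi <= x[-1] + 1e-9) else dropped).append(b)
    if dropped:
        logger.warning(
            "band windows outside the trimmed axis [%g, %g] skipped: %s",
            x[0], x[-1], ", ".join(f"{b.label}~{b.center:g}" for b in dropped),
        )
    return kept


def integrate_bands(
    d2: SecondDerivSpectrum, bands: Sequence[BandWindow]
) -> pd.DataFrame:
    rows = [
        (b.label, b.center, integrate_band(d2, b)) for b in bands
    ]
    return pd.DataFrame(rows, columns=["band_label", "center", "integral"])


def percent_reduction(integral_ff: float, integral_ffpe: float) -> float:
    """100 * (I_FF - I_FFPE) / I_FF."""
    if integral_ff <= 0:
        raise ValueError("FF band integral must be positive")
    return 100.0 * (integral_ff - integral_ffpe) / integral_ff


# ---------------------------------------------------------------------------
# Gaussian sub-band fitting
# ---------------------------------------------------------------------------

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _sum_of_gaussians(x: np.ndarray, params: np.ndarray) -> np.ndarray:
    amps = params[0::3]
    centers = params[1::3]
    fwhms = params[2::3]
    s = fwhms * _FWHM_TO_SIGMA
    return (amps[None, :] * np.exp(-0.5 * ((x[:, None] - centers[None, :]) / s) ** 2)).sum(axis=1)


def fit_gaussian_subbands(
    mean_spectrum: np.ndarray,
    axis: SpectralAxis,
    init_centers: Sequence[float],
    center_bound: float = 5.0,
    init_fwhm: float = 20.0,
    max_nfev: int = 20_000,
) -> GaussianFit:
    """Nonlinear least-squares fit of a sum of Gaussians to a mean
    absorbance spectrum.

    Initial centers come from significant second-derivative dips; fitted
    centers are bounded to init +- ``center_bound`` cm^-1 and amplitudes
    to >= 0.  Raises :class:`GaussianFitError` (carrying the best-so-far
    parameters) if the optimiser does not converge.
    """
    y = np.asarray(mean_spectrum, dtype=float)
    if y.size != len(axis):
        raise ValueError("spectrum length does not match axis")
    if len(init_centers) == 0:
        raise ValueError("need at least one initial center")
    x = axis.values
    p0, lo, hi = [], [], []
    for c in init_centers:
        a0 = max(float(y[axis.nearest_index(c)]), 1e-6)
        p0 += [a0, float(c), init_fwhm]
        lo += [0.0, float(c) - center_bound, 2.0 * axis.step]
        hi += [np.inf, float(c) + center_bound, (axis.max - axis.min)]
    res = least_squares(
        lambda p: _sum_of_gaussians(x, p) - y,
        x0=np.asarray(p0), bounds=(np.asarray(lo), np.asarray(hi)),
        max_nfev=max_nfev,
    )
    params = pd.DataFrame(
        {
            "amplitude": res.x[0::3],
            "center": res.x[1::3],
            "fwhm": res.x[2::3],
        }
    )[["center", "fwhm", "amplitude"]]
    fit = GaussianFit(
        params=params,
        residual_norm=float(np.linalg.norm(res.fun)),
        success=bool(res.status > 0),
    )
    if res.status <= 0:
        raise GaussianFitError(
            f"sub-band fit did not converge within {max_nfev} evaluations", fit
        )
    return fit


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _box_stats(counts: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(counts, [25, 50, 75])
    iqr = q3 - q1
    in_lo = counts[counts >= q1 - 1.5 * iqr]
    in_hi = counts[counts <= q3 + 1.5 * iqr]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(in_lo.min()) if in_lo.size else float(q1),
        "whisker_hi": float(in_hi.max()) if in_hi.size else float(q3),
    }


def summarize_bands(
    occurrence: pd.DataFrame, integrals: pd.DataFrame
) -> pd.DataFrame:
    """Per-(sample type, band) summaries across ROIs.

    Occurrence: mean, sample sd (ddof=1) and box-plot statistics (median,
    quartiles, whiskers at 1.5 IQR).  Integrals: mean and sample sd.
    Both inputs are tidy tables with sample_type, roi_id and band_label
    columns; at least two ROIs are required.
    """
    for name, df in (("occurrence", occurrence), ("integrals", integrals)):
        required = {"sample_type", "roi_id", "band_label"}
        if not required.issubset(df.columns):
            raise ValueError(f"{name} table must have columns {sorted(required)}")
        if df.groupby("sample_type")["roi_id"].nunique().min() < 2:
            raise ValueError("need at least 2 ROIs per sample type")
    occ_rows = []
    for (stype, band), g in occurrence.groupby(["sample_type", "band_label"]):
        counts = g["count"].to_numpy(dtype=float)
        row = {
            "sample_type": stype,
            "band_label": band,
            "occurrence_mean": float(counts.mean()),
            "occurrence_sd": float(counts.std(ddof=1)),
        }
        row.update({f"occurrence_{k}": v for k, v in _box_stats(counts).items()})
        occ_rows.append(row)
    occ_summary = pd.DataFrame(occ_rows)
    int_summary = (
        integrals.groupby(["sample_type", "band_label"])["integral"]
        .agg(integral_mean="mean", integral_sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    return occ_summary.merge(int_summary, on=["sample_type", "band_label"], how="outer")
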