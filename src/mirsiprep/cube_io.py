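"""Hyperspectral cube I/O, tissue masking, and the background noise model.

Cubes are (rows, cols, K) absorbance stacks tied to a shared wavenumber
axis.  Tissue/background segmentation follows the reference workflow:
Otsu thresholding of the single-band image at 1608 cm^-1 (amide I
region, the strongest feature in tissue spectra).  The discarded
off-tissue pixels define the background model: their mean spectrum, and
the noise scale sigma = population standard deviation of its
Savitzky-Golay second derivative over the trimmed spectral range.  That
sigma anchors the 3-sigma significance rule downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .preprocessing import savgol_second_derivative
from .spectral import SpectralAxis

__all__ = [
    "HyperspectralCube",
    "TissueMask",
    "BackgroundModel",
    "PixelSpectrumSet",
    "read_cube",
    "write_cube",
    "write_mask",
    "otsu_threshold",
    "make_tissue_mask",
    "compute_background",
    "sample_pixels",
]

MASK_BAND_CM = 1608.0  # amide I region image used for segmentation
MIN_BACKGROUND_PIXELS = 50


@dataclass(frozen=True)
class HyperspectralCube:
    """Absorbance image stack with its axis and provenance labels."""

    data: np.ndarray
    axis: SpectralAxis
    tissue: str = ""
    preparation: str = ""
    roi_id: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x wavenumbers")
        if self.data.shape[2] != len(self.axis):
            raise ValueError(
                f"cube has {self.data.shape[2]} channels but axis has "
                f"{len(self.axis)} points"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class TissueMask:
    mask: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        if self.mask.dtype != bool or self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D boolean image")


@dataclass(frozen=True)
class BackgroundModel:
    """Mean off-tissue spectrum and its second-derivative noise scale."""

    mean_spectrum: np.ndarray
    sigma: float
    n_pixels: int


@dataclass(frozen=True)
class PixelSpectrumSet:
    """Sampled tissue-pixel spectra with their coordinates."""

    roi_id: str
    coords: np.ndarray  # (n, 2) row/col
    spectra: np.ndarray  # (n, K)
    axis: SpectralAxis
    seed: int | None = None

    def __len__(self) -> int:
        return int(self.coords.shape[0])

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{wn:g}" for wn in self.axis.values]
        df = pd.DataFrame(self.spectra, columns=cols)
        df.insert(0, "col", self.coords[:, 1])
        df.insert(0, "row", self.coords[:, 0])
        df.insert(0, "roi_id", self.roi_id)
        return df


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cube(cube: HyperspectralCube, path: str | Path) -> Path:
    """Write a cube to HDF5 (datasets /cube float32, /wavenumbers float64)
    or to multi-page TIFF (pages = wavenumbers) with a CSV axis sidecar,
    chosen by file suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("cube", data=cube.data.astype(np.float32))
            f.create_dataset("wavenumbers", data=cube.axis.values.astype(np.float64))
            d.attrs["tissue"] = cube.tissue
            d.attrs["preparation"] = cube.preparation
            d.attrs["roi_id"] = cube.roi_id
    elif suffix in (".tif", ".tiff"):
        # pages are per-wavenumber images
        tifffile.imwrite(path, np.moveaxis(cube.data.astype(np.float32), 2, 0))
        sidecar = path.with_suffix(".wavenumbers.csv")
        with open(sidecar, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["wavenumber_cm-1"])
            for wn in cube.axis.values:
                w.writerow([repr(float(wn))])
    else:
        raise ValueError(f"unsupported cube format {suffix!r} (use .h5 or .tiff)")
    return path


def read_cube(path: str | Path) -> HyperspectralCube:
    """Read a cube written by :func:`write_cube` (HDF5 or TIFF + sidecar)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cube file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "cube" not in f or "wavenumbers" not in f:
                raise ValueError(f"{path} lacks /cube or /wavenumbers datasets")
            data = f["cube"][()]
            wns = f["wavenumbers"][()]
            attrs = dict(f["cube"].attrs)
        axis = SpectralAxis(np.asarray(wns, float), float(np.diff(wns).mean()))
        return HyperspectralCube(
            data=data,
            axis=axis,
            tissue=str(attrs.get("tissue", "")),
            preparation=str(attrs.get("preparation", "")),
            roi_id=str(attrs.get("roi_id", "")),
        )
    if suffix in (".tif", ".tiff"):
        sidecar = path.with_suffix(".wavenumbers.csv")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"wavenumber sidecar missing for {path}: expected {sidecar}"
            )
        pages = tifffile.imread(path)
        with open(sidecar, newline="") as f:
            rows = list(csv.reader(f))
        wns = np.array([float(r[0]) for r in rows[1:]])
        if pages.shape[0] != wns.size:
            raise ValueError(
                f"{path}: {pages.shape[0]} TIFF pages but {wns.size} wavenumbers"
            )
        axis = SpectralAxis(wns, float(np.diff(wns).mean()))
        return HyperspectralCube(data=np.moveaxis(pages, 0, 2), axis=axis)
    raise ValueError(f"unsupported cube format {suffix!r}")


def write_mask(mask: TissueMask, path: str | Path) -> Path:
    """Write a tissue mask as single-page uint8 TIFF (255 = tissue)."""
    path = Path(path)
    tifffile.imwrite(path, (mask.mask.astype(np.uint8) * 255))
    return path


# ---------------------------------------------------------------------------
# Masking and background
# ---------------------------------------------------------------------------

def otsu_between_class_variance(
    values: np.ndarray, threshold: float, nbins: int = 256
) -> float:
    """Between-class variance of the two-class split at ``threshold``
    (histogram formulation, for checking threshold optimality)."""
    hist, edges = np.histogram(np.asarray(values, float).ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    lo = centers <= threshold
    w0, w1 = hist[lo].sum(), hist[~lo].sum()
    if w0 == 0 or w1 == 0:
        return 0.0
    m0 = (hist[lo] * centers[lo]).sum() / w0
    m1 = (hist[~lo] * centers[~lo]).sum() / w1
    return float(w0 * w1 * (m0 - m1) ** 2)


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold of an intensity image/array on an ``nbins`` histogram.

    Maximizes between-class variance over all candidate bin thresholds.
    When a range of thresholds ties (an empty gap between two well
    separated modes), the midpoint of the maximizing plateau is returned,
    so the cut falls centrally in the gap rather than at its edge.
    """
    values = np.asarray(values, dtype=float).ravel()
    if np.unique(values).size < 2:
        raise ValueError("Otsu threshold undefined for a constant image")
    hist, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    w0 = np.cumsum(hist)[:-1]
    w1 = hist.sum() - w0
    csum = np.cumsum(hist * centers)[:-1]
    total = (hist * centers).sum()
    valid = (w0 > 0) & (w1 > 0)
    variance = np.zeros(nbins - 1)
    m0 = np.divide(csum, w0, out=np.zeros_like(csum, dtype=float), where=valid)
    m1 = np.divide(total - csum, w1, out=np.zeros_like(csum, dtype=float),
                   where=valid)
    variance[valid] = (w0 * w1)[valid] * (m0 - m1)[valid] ** 2
    best = variance.max()
    if best <= 0:
        raise ValueError("Otsu threshold undefined: no valid class split")
    ties = np.flatnonzero(variance >= best * (1 - 1e-12))
    # candidate threshold i separates bins <= i from bins > i
    return float(centers[ties].mean())


def make_tissue_mask(
    cube: HyperspectralCube,
    band_wn: float = MASK_BAND_CM,
    invert: bool = False,
) -> TissueMask:
    """Segment tissue from background on the single-band image at ``band_wn``.

    The nearest grid point to ``band_wn`` is used (ties toward the lower
    wavenumber).  By convention tissue is the high-absorbance class; pass
    ``invert=True`` for inverted-contrast data where tissue is darker.
    """
    idx = cube.axis.nearest_index(band_wn)
    image = cube.data[:, :, idx]
    thr = otsu_threshold(image)
    mask = image > thr
    if invert:
        mask = ~mask
    return TissueMask(mask=mask, threshold_used=thr)


def compute_background(
    cube: HyperspectralCube,
    mask: TissueMask,
    window: int = 13,
    polyorder: int = 2,
    trim_per_side: int = 13,
) -> BackgroundModel:
    """Background model from the off-tissue pixels.

    The mean of the off-mask pixel spectra is the background spectrum;
    sigma is the population standard deviation of its SG second
    derivative over the trimmed range.  Sigma sets the 3-sigma
    significance threshold for dip detection.
    """
    if mask.mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match cube")
    off = ~mask.mask
    n_off = int(off.sum())
    if n_off == 0:
        raise ValueError("mask complement is empty; no background pixels")
    if n_off < MIN_BACKGROUND_PIXELS:
        raise ValueError(
            f"only {n_off} background pixels (< {MIN_BACKGROUND_PIXELS}); "
            "use a larger ROI or check the mask"
        )
    mean_spectrum = cube.data[off].mean(axis=0).astype(float)
    d2 = savgol_second_derivative(
        mean_spectrum, cube.axis, window=window, polyorder=polyorder,
        trim_per_side=trim_per_side,
    )
    sigma = float(np.std(d2.values))  # population std; trimmed range is large
    if sigma == 0.0:
        raise ValueError("degenerate noise: background second derivative is constant")
    return BackgroundModel(mean_spectrum=mean_spectrum, sigma=sigma, n_pixels=n_off)


def sample_pixels(
    cube: HyperspectralCube,
    mask: TissueMask,
    n: int = 2000,
    seed: int | None = None,
) -> PixelSpectrumSet:
    """Sample ``n`` tissue pixels uniformly without replacement (seeded)."""
    if mask.mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match cube")
    flat = np.flatnonzero(mask.mask)
    if flat.size < n:
        raise ValueError(
            f"requested {n} tissue pixels but the mask holds only {flat.size}"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(flat, size=n, replace=False))
    rows, cols = np.unravel_index(chosen, mask.mask.shape)
    coords = np.stack([rows, cols], axis=1)
    spectra = cube.data[rows, cols, :].astype(float)
    return PixelSpectrumSet(
        roi_id=cube.roi_id, coords=coords, spectra=spectra, axis=cube.axis, seed=seed
    )
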