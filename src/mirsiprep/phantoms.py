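"""Synthetic hyperspectral phantoms with known ground truth.

The generators here emulate QCL mid-infrared absorbance images of tissue
sections prepared fresh-frozen (FF) or formalin-fixed paraffin-embedded
(FFPE), at a level of realism sufficient to exercise every downstream
stage of the pipeline: tissue masks with FF-style holes, smooth scattering
baselines, Gaussian vibrational bands from per-sample-type libraries,
multiplicative per-pixel intensity jitter, and detector noise with both a
common-mode (shared across pixels) and an iid component.

Every phantom carries a :class:`PhantomTruth` with the planted mask, band
parameters, analytic second-derivative depths and band integrals, so that
parameter-recovery tests need no real tissue data.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .spectral import SpectralAxis, make_spectral_axis
from .cube_io import HyperspectralCube, write_cube

__all__ = [
    "BandSpec",
    "BaselineParams",
    "MaskParams",
    "PhantomConfig",
    "PhantomTruth",
    "StudyConfig",
    "make_spectral_axis",
    "default_band_library",
    "default_baseline",
    "gaussian_profile",
    "gaussian_d2_center_depth",
    "gaussian_band_integral",
    "synthesize_pixel_spectrum",
    "generate_roi",
    "generate_study",
    "derive_seed",
]

TISSUES = ("kidney", "liver")
PREPARATIONS = ("FF", "FFPE")

#: Amide-I band-integral reduction fractions planted in FFPE phantoms,
#: relative to the paired FF phantom (study conditions for each tissue).
AMIDE1_REDUCTION = {"kidney": 0.663, "liver": 0.462}

#: Attenuation applied to non-amide-I FFPE band amplitudes (free parameter;
#: only the amide-I ratio is pinned by the study conditions).
FFPE_RETENTION = 0.80

#: Default common-mode noise amplitude relative to the iid pixel noise.
#: The common mode dominates the second-derivative noise budget (as for
#: a coherent-source instrument), which is what makes the background
#: spectrum's sigma a meaningful per-pixel detection threshold.
COMMON_NOISE_FACTOR = 10.0

#: Common-mode realizations are redrawn until their second-derivative
#: excursions stay within this many sigma of their own spread: the
#: emulated instrument background is structured but stable, without
#: heavy-tailed spikes that would defeat any fixed significance rule.
COMMON_MODE_EXCURSION_CAP = 2.2

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class BandSpec:
    """One vibrational band: a Gaussian in absorbance over wavenumber.

    ``presence`` is the fraction of tissue pixels carrying the band
    (1.0 = ubiquitous); it models features detected only in part of a
    section, such as the fixation band partially present in FFPE kidney.
    """

    label: str
    center: float
    fwhm: float
    amplitude: float
    presence: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"band {self.label}: fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"band {self.label}: amplitude must be >= 0")
        if not 0.0 <= self.presence <= 1.0:
            raise ValueError(f"band {self.label}: presence must be in [0, 1]")

    @property
    def sigma(self) -> float:
        return self.fwhm * _FWHM_TO_SIGMA


@dataclass(frozen=True)
class BaselineParams:
    """Smooth scattering baseline: low-order polynomial plus broad sigmoid.

    The polynomial is evaluated in the normalised coordinate
    u = (nu - nu_min)/(nu_max - nu_min) so coefficients are absorbance
    units regardless of the axis range.  Order <= 3.
    """

    poly: tuple[float, ...] = (0.06, 0.03, -0.01)
    sigmoid_amplitude: float = 0.02
    sigmoid_center: float = 1400.0
    sigmoid_width: float = 150.0

    def __post_init__(self) -> None:
        if len(self.poly) > 4:
            raise ValueError("baseline polynomial order must be <= 3")
        if self.sigmoid_width <= 0:
            raise ValueError("sigmoid width must be > 0")

    def on_axis(self, axis: SpectralAxis) -> np.ndarray:
        u = (axis.values - axis.min) / (axis.max - axis.min)
        out = np.zeros_like(u)
        for p, c in enumerate(self.poly):
            out += c * u**p
        if self.sigmoid_amplitude != 0.0:
            out += self.sigmoid_amplitude / (
                1.0 + np.exp(-(axis.values - self.sigmoid_center) / self.sigmoid_width)
            )
        return out


@dataclass(frozen=True)
class MaskParams:
    """Tissue-mask geometry: union of random ellipses, optional holes.

    ``hole_fraction`` is the fraction of the initial tissue area carved
    out by random disks (FF sections show holes and fractures; FFPE
    sections are intact, fraction 0).
    """

    n_ellipses_range: tuple[int, int] = (3, 5)
    semiaxis_frac_range: tuple[float, float] = (0.18, 0.38)
    hole_fraction: float = 0.0
    hole_radius_range: tuple[int, int] = (3, 8)

    def __post_init__(self) -> None:
        if not 0.0 <= self.hole_fraction <= 1.0:
            raise ValueError("hole_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PhantomConfig:
    tissue: str
    preparation: str
    roi_shape: tuple[int, int] = (96, 96)
    band_library: tuple[BandSpec, ...] | None = None
    baseline: BaselineParams = field(default_factory=BaselineParams)
    noise_sd: float = 0.001
    #: Common-mode (shared across all pixels of a cube) spectral noise:
    #: smooth fluctuations with Gaussian correlation length
    #: ``common_corr_cm``, emulating coherent source/detector drifts that
    #: pixel averaging does not remove.  ``None`` couples the amplitude
    #: to the iid noise as COMMON_NOISE_FACTOR * noise_sd.
    common_noise_sd: float | None = None
    common_corr_cm: float = 14.0
    jitter_sd: float = 0.10
    mask_params: MaskParams | None = None
    seed: int = 0
    axis: SpectralAxis | None = None
    #: Broad envelope of unresolved protein absorbance carried by every
    #: tissue pixel.  It gives the 1608 cm^-1 masking image its tissue
    #: contrast (as in real amide-region images for both preparations)
    #: while being far too broad and shallow to produce a significant
    #: second-derivative dip of its own.
    pedestal: BandSpec | None = field(
        default_factory=lambda: BandSpec("Amide envelope", 1580.0, 260.0, 0.12)
    )

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.preparation not in PREPARATIONS:
            raise ValueError(f"unknown preparation {self.preparation!r}")
        if self.roi_shape[0] <= 0 or self.roi_shape[1] <= 0:
            raise ValueError("roi_shape must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.common_noise_sd is not None and self.common_noise_sd < 0:
            raise ValueError("common_noise_sd must be >= 0")

    def resolved_common_sd(self) -> float:
        if self.common_noise_sd is not None:
            return self.common_noise_sd
        return COMMON_NOISE_FACTOR * self.noise_sd

    def resolved_axis(self) -> SpectralAxis:
        return self.axis if self.axis is not None else make_spectral_axis(950.0, 1800.0, 2.0)

    def resolved_bands(self) -> tuple[BandSpec, ...]:
        if self.band_library is not None:
            return tuple(self.band_library)
        return tuple(default_band_library(self.tissue, self.preparation))

    def resolved_mask_params(self) -> MaskParams:
        if self.mask_params is not None:
            return self.mask_params
        hole = 0.15 if self.preparation == "FF" else 0.0
        return MaskParams(hole_fraction=hole)


@dataclass
class PhantomTruth:
    """Planted ground truth for one generated ROI."""

    mask: np.ndarray
    bands: tuple[BandSpec, ...]
    baseline_spectrum: np.ndarray
    common_mode: np.ndarray
    d2_center_depths: dict[str, float]
    band_integrals: dict[str, float]
    jitter_sd: float
    noise_sd: float
    common_noise_sd: float
    seed: int


# ---------------------------------------------------------------------------
# Band libraries
# ---------------------------------------------------------------------------

# Reference band table for the 950-1800 cm^-1 fingerprint region:
# (label, center cm^-1).  FF libraries of each tissue draw 13 of these.
_REFERENCE_BANDS = (
    ("DNA", 966.0),
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

# (center -> (fwhm, FF amplitude)) per tissue.  Amplitudes are plausible
# absorbance scales for 10 um sections; amide I dominates, fingerprint
# bands are weaker but all sit far above the 3-sigma detection floor.
_FF_KIDNEY = {
    966.0: (16.0, 0.10),
    1082.0: (18.0, 0.14),
    1154.0: (12.0, 0.10),
    1168.0: (12.0, 0.12),
    1238.0: (22.0, 0.16),
    1308.0: (20.0, 0.12),
    1400.0: (20.0, 0.18),
    1448.0: (12.0, 0.16),
    1462.0: (12.0, 0.12),
    1516.0: (20.0, 0.20),
    1546.0: (34.0, 0.35),
    1658.0: (50.0, 0.60),
    1744.0: (20.0, 0.15),
}
_FF_LIVER = {
    966.0: (16.0, 0.08),
    1030.0: (18.0, 0.16),
    1082.0: (18.0, 0.12),
    1154.0: (12.0, 0.12),
    1238.0: (22.0, 0.14),
    1308.0: (20.0, 0.10),
    1400.0: (20.0, 0.16),
    1448.0: (12.0, 0.14),
    1462.0: (12.0, 0.18),
    1516.0: (20.0, 0.18),
    1546.0: (34.0, 0.33),
    1658.0: (50.0, 0.62),
    1744.0: (20.0, 0.25),
}
# FFPE retains the protein/amide skeleton; DNA, glycogen and lipid bands
# are extracted or fall below detectability during fixation/dewaxing.
_FFPE_KEPT = {
    "kidney": (1168.0, 1238.0, 1308.0, 1400.0, 1448.0, 1516.0, 1546.0, 1658.0),
    "liver": (1238.0, 1308.0, 1400.0, 1448.0, 1516.0, 1546.0, 1658.0),
}
#: Fixation-induced band observed only in FFPE sections.
FIXATION_BAND_CENTER = 1026.0
_FIXATION_BAND = {
    "kidney": BandSpec("Fixation", FIXATION_BAND_CENTER, 16.0, 0.07, presence=0.55),
    "liver": BandSpec("Fixation", FIXATION_BAND_CENTER, 16.0, 0.10, presence=1.0),
}


def default_band_library(
    tissue: str,
    preparation: str,
    amide1_reduction: float | None = None,
) -> list[BandSpec]:
    """Band library for one sample type.

    FF libraries hold 13 reference bands.  FFPE libraries hold the
    protein/amide subset of the paired FF library (8 bands for kidney, 7
    for liver) with amide I attenuated by ``amide1_reduction`` (default:
    the per-tissue study value) and the remaining bands attenuated by
    ``FFPE_RETENTION``, plus the ~1026 cm^-1 fixation band.
    """
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue {tissue!r}")
    if preparation not in PREPARATIONS:
        raise ValueError(f"unknown preparation {preparation!r}")
    ff_params = _FF_KIDNEY if tissue == "kidney" else _FF_LIVER
    labels = {c: lab for lab, c in _REFERENCE_BANDS}
    if preparation == "FF":
        return [
            BandSpec(labels[c], c, fwhm, amp)
            for c, (fwhm, amp) in sorted(ff_params.items())
        ]
    f = AMIDE1_REDUCTION[tissue] if amide1_reduction is None else amide1_reduction
    bands = []
    for c in sorted(_FFPE_KEPT[tissue]):
        fwhm, amp = ff_params[c]
        scale = (1.0 - f) if c == 1658.0 else FFPE_RETENTION
        bands.append(BandSpec(labels[c], c, fwhm, amp * scale))
    bands.insert(0, _FIXATION_BAND[tissue])
    return bands


def default_baseline() -> BaselineParams:
    return BaselineParams()


# ---------------------------------------------------------------------------
# Gaussian band model and analytic truths
# ---------------------------------------------------------------------------

def gaussian_profile(wavenumbers: np.ndarray, band: BandSpec) -> np.ndarray:
    """Absorbance profile A * exp(-(nu - c)^2 / (2 s^2)) on the grid."""
    x = np.asarray(wavenumbers, dtype=float) - band.center
    return band.amplitude * np.exp(-0.5 * (x / band.sigma) ** 2)


def gaussian_d2_center_depth(band: BandSpec) -> float:
    """Analytic second derivative at the band center: -A * 8 ln2 / fwhm^2."""
    return -band.amplitude * 8.0 * np.log(2.0) / band.fwhm**2


def gaussian_band_integral(band: BandSpec, lo: float, hi: float) -> float:
    """Analytic integral of the *negated* second derivative over [lo, hi].

    Since -d2G integrates to -G', the value is G'(lo) - G'(hi); positive
    for any window containing the center.
    """

    def d1(x: float) -> float:
        z = x - band.center
        s2 = band.sigma**2
        return -band.amplitude * z / s2 * np.exp(-0.5 * z**2 / s2)

    return float(d1(lo) - d1(hi))


def synthesize_pixel_spectrum(
    axis: SpectralAxis,
    bands: Sequence[BandSpec],
    baseline: BaselineParams | None,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One pixel spectrum: sum of Gaussian bands + baseline + iid noise.

    Nonnegativity is not enforced; noise may dip below zero.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for b in bands:
        if not (axis.min <= b.center <= axis.max):
            raise ValueError(f"band {b.label} at {b.center} cm^-1 is off-axis")
    out = np.zeros(len(axis))
    if baseline is not None:
        out += baseline.on_axis(axis)
    for b in bands:
        out += gaussian_profile(axis.values, b)
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# ROI generation
# ---------------------------------------------------------------------------

def _random_ellipse_mask(shape: tuple[int, int], params: MaskParams,
                         rng: np.random.Generator) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    lo_f, hi_f = params.semiaxis_frac_range
    for _ in range(50):
        mask = np.zeros(shape, dtype=bool)
        n = rng.integers(params.n_ellipses_range[0], params.n_ellipses_range[1] + 1)
        for _ in range(n):
            cy = rng.uniform(0.25 * rows, 0.75 * rows)
            cx = rng.uniform(0.25 * cols, 0.75 * cols)
            a = rng.uniform(lo_f * rows, hi_f * rows)
            b = rng.uniform(lo_f * cols, hi_f * cols)
            theta = rng.uniform(0.0, np.pi)
            y = rr - cy
            x = cc - cx
            u = y * np.cos(theta) + x * np.sin(theta)
            v = -y * np.sin(theta) + x * np.cos(theta)
            mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
        frac = mask.mean()
        if 0.25 <= frac <= 0.90:
            return mask
    raise RuntimeError("could not draw a non-degenerate tissue mask in 50 attempts")


def _carve_holes(mask: np.ndarray, params: MaskParams,
                 rng: np.random.Generator) -> np.ndarray:
    if params.hole_fraction <= 0:
        return mask
    mask = mask.copy()
    rows, cols = mask.shape
    target = params.hole_fraction * mask.sum()
    rr, cc = np.mgrid[0:rows, 0:cols]
    carved = 0
    r_lo, r_hi = params.hole_radius_range
    for _ in range(10_000):
        if carved >= target:
            break
        true_idx = np.flatnonzero(mask)
        if true_idx.size == 0:
            break
        pick = true_idx[rng.integers(true_idx.size)]
        cy, cx = divmod(pick, cols)
        r = rng.integers(r_lo, r_hi + 1)
        disk = (rr - cy) ** 2 + (cc - cx) ** 2 <= r**2
        carved += int((mask & disk).sum())
        mask &= ~disk
    return mask


def _draw_common_mode(
    config: PhantomConfig, axis: SpectralAxis, rng: np.random.Generator
) -> np.ndarray:
    """Smooth common-mode spectral noise shared by all pixels of a cube.

    A white draw convolved with a Gaussian kernel (correlation length
    ``common_corr_cm``, unit-variance normalisation), redrawn until the
    second-derivative excursions stay within COMMON_MODE_EXCURSION_CAP
    standard deviations of their own spread.
    """
    from scipy.signal import savgol_filter

    common_sd = config.resolved_common_sd()
    k = len(axis)
    if common_sd <= 0:
        return np.zeros(k)
    ell = config.common_corr_cm / axis.step
    half = int(np.ceil(4 * ell))
    t = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (t / ell) ** 2)
    kernel /= np.sqrt((kernel**2).sum())
    for _ in range(500):
        white = rng.normal(0.0, 1.0, size=k + 2 * half)
        common = common_sd * np.convolve(white, kernel, mode="valid")
        d2 = savgol_filter(common, 13, 2, deriv=2, delta=axis.step)[13:-13]
        if np.max(np.abs(d2)) <= COMMON_MODE_EXCURSION_CAP * np.std(d2):
            return common
    raise RuntimeError("could not draw a bounded common-mode realization")


def generate_roi(config: PhantomConfig) -> tuple[HyperspectralCube, PhantomTruth]:
    """Generate one phantom ROI and its ground truth.

    On-mask pixels carry the band library with per-pixel multiplicative
    log-normal intensity jitter (a thickness/path-length proxy) and
    per-band presence draws; off-mask pixels carry only the baseline and
    noise.  Noise has a common-mode component shared by all pixels of the
    cube (coherent source fluctuations) plus iid detector noise.
    Identical seeds produce bit-identical cubes.
    """
    axis = config.resolved_axis()
    bands = config.resolved_bands()
    for b in bands:
        if not (axis.min <= b.center <= axis.max):
            raise ValueError(f"band {b.label} at {b.center} cm^-1 is off-axis")
    mask_params = config.resolved_mask_params()
    rng = np.random.default_rng(config.seed)

    mask = _random_ellipse_mask(config.roi_shape, mask_params, rng)
    mask = _carve_holes(mask, mask_params, rng)
    if mask.all() or not mask.any():
        raise ValueError("degenerate tissue mask (all-on or all-off)")

    k = len(axis)
    rows, cols = config.roi_shape
    baseline = config.baseline.on_axis(axis)
    common = _draw_common_mode(config, axis, rng)

    n_tissue = int(mask.sum())
    jitter = np.exp(rng.normal(0.0, config.jitter_sd, size=n_tissue))
    presence = np.empty((n_tissue, len(bands)))
    for j, b in enumerate(bands):
        presence[:, j] = (
            (rng.random(n_tissue) < b.presence) if b.presence < 1.0 else 1.0
        )

    if bands:
        profiles = np.stack([gaussian_profile(axis.values, b) for b in bands])  # B x K
    else:
        profiles = np.zeros((0, k))
    cube = np.empty((rows, cols, k), dtype=np.float64)
    cube[:] = baseline + common
    if config.noise_sd > 0:
        cube += rng.normal(0.0, config.noise_sd, size=cube.shape)
    tissue_signal = (presence * jitter[:, None]) @ profiles  # n_tissue x K
    if config.pedestal is not None:
        tissue_signal += jitter[:, None] * gaussian_profile(
            axis.values, config.pedestal
        )[None, :]
    cube[mask] += tissue_signal

    half = 8.0  # default integration half-width used for the analytic truth
    truth = PhantomTruth(
        mask=mask,
        bands=bands,
        baseline_spectrum=baseline,
        common_mode=common,
        d2_center_depths={b.label: gaussian_d2_center_depth(b) for b in bands},
        band_integrals={
            b.label: gaussian_band_integral(b, b.center - half, b.center + half)
            for b in bands
        },
        jitter_sd=config.jitter_sd,
        noise_sd=config.noise_sd,
        common_noise_sd=config.resolved_common_sd(),
        seed=config.seed,
    )
    hcube = HyperspectralCube(
        data=cube.astype(np.float32),
        axis=axis,
        tissue=config.tissue,
        preparation=config.preparation,
        roi_id=f"{config.tissue}_{config.preparation}_seed{config.seed}",
    )
    return hcube, truth


# ---------------------------------------------------------------------------
# Study generation
# ---------------------------------------------------------------------------

def derive_seed(base_seed: int, *parts: str) -> int:
    """Deterministic sub-seed: base + crc32 of a stable identifier, < 2^31."""
    tag = "/".join(parts).encode()
    return int((int(base_seed) + zlib.crc32(tag)) % (2**31))


@dataclass(frozen=True)
class StudyConfig:
    """Layout of a synthetic FF/FFPE kidney/liver study."""

    tissues: tuple[str, ...] = TISSUES
    preparations: tuple[str, ...] = PREPARATIONS
    n_rois: int = 8
    roi_shape: tuple[int, int] = (96, 96)
    seed: int = 0
    noise_sd: float = 0.001
    common_noise_sd: float | None = None
    jitter_sd: float = 0.10
    amide1_reduction: dict[str, float] = field(
        default_factory=lambda: dict(AMIDE1_REDUCTION)
    )

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")


def generate_study(
    study: StudyConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Generate tissues x preparations x n_rois phantom ROIs.

    Returns a manifest dict with one record per cube: sample type, roi id,
    planted band parameters and analytic truths, plus the cube and truth
    objects under ``"cube"``/``"truth"``.  If ``out_dir`` is given, cubes
    are written as HDF5 and the manifest (without arrays) as
    ``manifest.json``.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    records = []
    for tissue in study.tissues:
        for prep in study.preparations:
            library = tuple(
                default_band_library(
                    tissue, prep, study.amide1_reduction.get(tissue)
                )
            )
            for i in range(study.n_rois):
                roi_id = f"{tissue}_{prep}_roi{i}"
                cfg = PhantomConfig(
                    tissue=tissue,
                    preparation=prep,
                    roi_shape=study.roi_shape,
                    band_library=library,
                    noise_sd=study.noise_sd,
                    common_noise_sd=study.common_noise_sd,
                    jitter_sd=study.jitter_sd,
                    seed=derive_seed(study.seed, roi_id),
                )
                cube, truth = generate_roi(cfg)
                cube = dataclasses.replace(cube, roi_id=roi_id)
                rec = {
                    "tissue": tissue,
                    "preparation": prep,
                    "roi_id": roi_id,
                    "seed": cfg.seed,
                    "bands": [dataclasses.asdict(b) for b in library],
                    "d2_center_depths": truth.d2_center_depths,
                    "band_integrals": truth.band_integrals,
                    "amide1_reduction": (
                        study.amide1_reduction.get(tissue) if prep == "FFPE" else None
                    ),
                    "cube": cube,
                    "truth": truth,
                }
                if out_path is not None:
                    try:
                        p = write_cube(cube, out_path / f"{roi_id}.h5")
                    except OSError as exc:
                        raise OSError(
                            f"failed writing cube {out_path / (roi_id + '.h5')}: {exc}"
                        ) from exc
                    rec["path"] = str(p)
                records.append(rec)
    manifest = {
        "n_rois": study.n_rois,
        "roi_shape": list(study.roi_shape),
        "seed": study.seed,
        "records": records,
    }
    if out_path is not None:
        slim = {
            **{k: manifest[k] for k in ("n_rois", "roi_shape", "seed")},
            "records": [
                {k: v for k, v in r.items() if k not in ("cube", "truth")}
                for r in records
            ],
        }
        (out_path / "manifest.json").write_text(json.dumps(slim, indent=1))
    return manifest
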