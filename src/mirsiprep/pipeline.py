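"""End-to-end pipeline: simulate -> mask -> preprocess -> peaks ->
integrate -> classify -> report.

Every stage reads its inputs from, and persists its outputs to, the run
directory, so stages can be re-run individually from intermediates.  A
master seed fans out deterministically to per-stage, per-ROI seeds
(base + crc32 of a stable stage/ROI tag), making a rerun with the same
config and seed byte-identical in every CSV output.

Defaults follow the reference acquisition/processing conditions: 8 ROIs
per sample type, Otsu masking at 1608 cm^-1, SG window 13 / order 2 with
13 points trimmed per side, the 3-sigma rule with a +-2 cm^-1 occurrence
tolerance, 2000 classification / 100 occurrence pixels per ROI, 5000
UMAP spectra per sample type, and top-40 logistic wavenumbers.
"""

from __future__ import annotations

import json
import logging
import os
import sys
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__ as _pkg_version
from .classification import (
    cluster_separation_metrics,
    logistic_feature_importance,
    pca_reduce,
    roi_correlation_matrix,
    umap_embed,
)
from .cube_io import (
    TissueMask,
    compute_background,
    make_tissue_mask,
    read_cube,
    sample_pixels,
    write_mask,
)
from .phantoms import StudyConfig, derive_seed, generate_study
from .preprocessing import (
    rubberband_correct_batch,
    savgol_second_derivative,
    zscore_normalize,
)
from .spectral import SpectralAxis
from .subbands import (
    bands_within,
    default_band_windows,
    detect_significant_dips,
    integrate_band,
    integrate_bands,
    load_band_table,
    occurrence_counts,
    percent_reduction,
    save_band_table,
    summarize_bands,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "StageError",
    "ConfigError",
    "validate_config",
    "run_pipeline",
    "recover_amide1_reduction",
    "subsample_per_type",
    "STAGES",
]

logger = logging.getLogger("mirsiprep")

STAGES = ("simulate", "mask", "preprocess", "peaks", "integrate", "classify", "report")


class ConfigError(ValueError):
    """Configuration file is invalid; message lists every violation."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    # study layout
    tissues: tuple[str, ...] = ("kidney", "liver")
    preparations: tuple[str, ...] = ("FF", "FFPE")
    n_rois: int = Field(8, ge=1)
    roi_shape: tuple[int, int] = (96, 96)
    # phantom generation
    noise_sd: float = Field(0.001, ge=0)
    common_noise_sd: float | None = Field(None, ge=0)
    jitter_sd: float = Field(0.10, ge=0)
    # masking / background
    mask_band_cm: float = 1608.0
    # derivative filter
    sg_window: int = Field(13, ge=3)
    sg_polyorder: int = Field(2, ge=2)
    trim_per_side: int = Field(13, ge=0)
    # dip detection / occurrence / integration
    sigma_multiplier: float = Field(3.0, gt=0)
    tolerance_cm: float = Field(2.0, gt=0)
    window_half_width_cm: float = Field(8.0, gt=0)
    band_table: str | None = None
    # sampling sizes
    n_pixels_classification: int = Field(2000, ge=1)
    n_pixels_occurrence: int = Field(100, ge=1)
    n_umap_per_type: int = Field(5000, ge=1)
    # classification
    pca_components: int = Field(20, ge=1)
    umap_n_neighbors: int = Field(15, ge=2)
    umap_min_dist: float = Field(0.1, ge=0)
    top_n: int = Field(40, ge=1)
    # reproducibility
    seed: int = Field(0, ge=0)


@dataclass
class RunReport:
    outputs: dict[str, str] = dc_field(default_factory=dict)
    params: dict = dc_field(default_factory=dict)
    versions: dict[str, str] = dc_field(default_factory=dict)
    wall_time_s: float = 0.0
    warnings: list[str] = dc_field(default_factory=list)


def validate_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML/JSON config; ``None`` or an empty file
    yields all defaults.  Schema violations are reported exhaustively."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file {path} is not parseable: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must hold a mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
            for e in exc.errors()
        ]
        raise ConfigError(
            f"invalid config {path} ({len(lines)} problems):\n" + "\n".join(lines)
        ) from exc


# ---------------------------------------------------------------------------
# Output helpers: stage outputs land as .partial files and are renamed on
# stage success, so an aborted stage leaves its partial outputs visible.
# ---------------------------------------------------------------------------

class _StageWriter:
    def __init__(self) -> None:
        self.pending: list[tuple[Path, Path]] = []

    def path(self, final: Path) -> Path:
        partial = final.with_name(final.name + ".partial")
        self.pending.append((partial, final))
        return partial

    def write_csv(self, df: pd.DataFrame, final: Path, **kw) -> None:
        df.to_csv(self.path(final), index=kw.pop("index", False), **kw)

    def finalize(self) -> list[Path]:
        done = []
        for partial, final in self.pending:
            if partial.exists():
                os.replace(partial, final)
                done.append(final)
        self.pending.clear()
        return done


def _setup_logging(out_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    have = {getattr(h, "_mirsiprep_tag", None) for h in logger.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        h._mirsiprep_tag = "stderr"
        logger.addHandler(h)
    logfile = out_dir / "run.log"
    for h in list(logger.handlers):
        if getattr(h, "_mirsiprep_tag", None) == "file":
            logger.removeHandler(h)
            h.close()
    fh = logging.FileHandler(logfile)
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
    fh._mirsiprep_tag = "file"
    logger.addHandler(fh)


def _load_manifest(out_dir: Path) -> dict:
    path = out_dir / "cubes" / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(
            f"study manifest not found at {path}; run the simulate stage first"
        )
    return json.loads(path.read_text())


def _resolve_bands(config: RunConfig):
    if config.band_table is not None:
        return load_band_table(config.band_table)
    return default_band_windows(half_width=config.window_half_width_cm)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, out_dir: Path) -> None:
    study = StudyConfig(
        tissues=config.tissues,
        preparations=config.preparations,
        n_rois=config.n_rois,
        roi_shape=tuple(config.roi_shape),
        seed=derive_seed(config.seed, "simulate"),
        noise_sd=config.noise_sd,
        common_noise_sd=config.common_noise_sd,
        jitter_sd=config.jitter_sd,
    )
    manifest = generate_study(study, out_dir / "cubes")
    logger.info("simulate: wrote %d cubes", len(manifest["records"]))


def stage_mask(config: RunConfig, out_dir: Path) -> None:
    manifest = _load_manifest(out_dir)
    w = _StageWriter()
    mask_dir = out_dir / "masks"
    mask_dir.mkdir(exist_ok=True)
    rows = []
    bg_spectra = []
    for rec in manifest["records"]:
        cube = read_cube(rec["path"])
        mask = make_tissue_mask(cube, band_wn=config.mask_band_cm)
        bg = compute_background(
            cube, mask,
            window=config.sg_window, polyorder=config.sg_polyorder,
            trim_per_side=config.trim_per_side,
        )
        write_mask(mask, mask_dir / f"{rec['roi_id']}.tif")
        rows.append(
            {
                "roi_id": rec["roi_id"],
                "tissue": rec["tissue"],
                "preparation": rec["preparation"],
                "threshold": mask.threshold_used,
                "n_tissue": int(mask.mask.sum()),
                "n_background": bg.n_pixels,
                "sigma": bg.sigma,
            }
        )
        bg_spectra.append(
            pd.Series(bg.mean_spectrum, index=[f"{v:g}" for v in cube.axis.values],
                      name=rec["roi_id"])
        )
    w.write_csv(pd.DataFrame(rows), out_dir / "backgrounds.csv")
    w.write_csv(
        pd.DataFrame(bg_spectra).rename_axis("roi_id").reset_index(),
        out_dir / "background_spectra.csv",
    )
    w.finalize()
    logger.info("mask: %d ROIs masked", len(rows))


def stage_preprocess(config: RunConfig, out_dir: Path) -> None:
    """Sample tissue pixels and rubberband-correct them, per ROI.

    Two independent seeded draws per ROI: the classification sample
    (default 2000 pixels) and the occurrence sample (default 100).
    Corrected spectra are persisted to spectra.h5.
    """
    import tifffile

    manifest = _load_manifest(out_dir)
    h5_partial = out_dir / "spectra.h5.partial"
    n_rows = 0
    with h5py.File(h5_partial, "w") as f:
        for rec in manifest["records"]:
            cube = read_cube(rec["path"])
            mask_img = tifffile.imread(out_dir / "masks" / f"{rec['roi_id']}.tif")
            mask = TissueMask(mask=mask_img > 0, threshold_used=float("nan"))
            grp = f.create_group(rec["roi_id"])
            for tag, n in (
                ("classification", config.n_pixels_classification),
                ("occurrence", config.n_pixels_occurrence),
            ):
                px = sample_pixels(
                    cube, mask, n=n,
                    seed=derive_seed(config.seed, "preprocess", tag, rec["roi_id"]),
                )
                corrected = rubberband_correct_batch(px.spectra, cube.axis)
                grp.create_dataset(f"{tag}/corrected", data=corrected)
                grp.create_dataset(f"{tag}/coords", data=px.coords)
                n_rows += n
            grp.attrs["tissue"] = rec["tissue"]
            grp.attrs["preparation"] = rec["preparation"]
        f.create_dataset("wavenumbers", data=read_cube(manifest["records"][0]["path"]).axis.values)
    os.replace(h5_partial, out_dir / "spectra.h5")
    logger.info("preprocess: corrected %d sampled spectra", n_rows)


def _open_spectra(out_dir: Path):
    path = out_dir / "spectra.h5"
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found; run the preprocess stage first"
        )
    return h5py.File(path, "r")


def _axis_from_h5(f: h5py.File) -> SpectralAxis:
    wns = f["wavenumbers"][()]
    return SpectralAxis(np.asarray(wns, float), float(np.diff(wns).mean()))


def stage_peaks(config: RunConfig, out_dir: Path) -> None:
    """Per-pixel dip detection and per-ROI band occurrence counts."""
    bands = _resolve_bands(config)
    sigmas = pd.read_csv(out_dir / "backgrounds.csv").set_index("roi_id")
    w = _StageWriter()
    tables = []
    with _open_spectra(out_dir) as f:
        axis = _axis_from_h5(f)
        for roi_id in sorted(k for k in f.keys() if k != "wavenumbers"):
            grp = f[roi_id]
            spectra = grp["occurrence/corrected"][()]
            d2 = savgol_second_derivative(
                spectra, axis, window=config.sg_window,
                polyorder=config.sg_polyorder, trim_per_side=config.trim_per_side,
            )
            sigma = float(sigmas.loc[roi_id, "sigma"])
            calls = [
                detect_significant_dips(
                    type(d2)(values=d2.values[i], trimmed_axis=d2.trimmed_axis),
                    sigma, multiplier=config.sigma_multiplier,
                )
                for i in range(spectra.shape[0])
            ]
            table = occurrence_counts(
                calls, bands, tolerance=config.tolerance_cm, axis_step=axis.step
            )
            table.insert(0, "roi_id", roi_id)
            table.insert(0, "sample_type",
                         f"{grp.attrs['tissue']}_{grp.attrs['preparation']}")
            tables.append(table)
    occurrence = pd.concat(tables, ignore_index=True)
    w.write_csv(occurrence, out_dir / "occurrence.csv")
    save_band_table(bands, w.path(out_dir / "band_table.csv"))
    w.finalize()
    logger.info("peaks: occurrence over %d ROI x band rows", len(occurrence))


def stage_integrate(config: RunConfig, out_dir: Path) -> None:
    """Band integrals of the ROI-mean second derivative, plus FF-vs-FFPE
    percent reductions per tissue and band."""
    bands = _resolve_bands(config)
    w = _StageWriter()
    tables = []
    with _open_spectra(out_dir) as f:
        axis = _axis_from_h5(f)
        for roi_id in sorted(k for k in f.keys() if k != "wavenumbers"):
            grp = f[roi_id]
            mean_spec = grp["occurrence/corrected"][()].mean(axis=0)
            d2 = savgol_second_derivative(
                mean_spec, axis, window=config.sg_window,
                polyorder=config.sg_polyorder, trim_per_side=config.trim_per_side,
            )
            table = integrate_bands(d2, bands_within(d2, bands))
            table.insert(0, "roi_id", roi_id)
            table.insert(0, "preparation", str(grp.attrs["preparation"]))
            table.insert(0, "tissue", str(grp.attrs["tissue"]))
            table.insert(0, "sample_type",
                         f"{grp.attrs['tissue']}_{grp.attrs['preparation']}")
            tables.append(table)
    integrals = pd.concat(tables, ignore_index=True)
    w.write_csv(integrals, out_dir / "integrals.csv")

    red_rows = []
    for (tissue, label, center), g in integrals.groupby(
        ["tissue", "band_label", "center"]
    ):
        ff = g.loc[g["preparation"] == "FF", "integral"]
        ffpe = g.loc[g["preparation"] == "FFPE", "integral"]
        if ff.empty or ffpe.empty or ff.mean() <= 0:
            continue
        red_rows.append(
            {
                "tissue": tissue,
                "band_label": label,
                "center": center,
                "integral_ff_mean": ff.mean(),
                "integral_ffpe_mean": ffpe.mean(),
                "percent_reduction": percent_reduction(ff.mean(), ffpe.mean()),
            }
        )
    w.write_csv(pd.DataFrame(red_rows), out_dir / "reductions.csv")

    occurrence = pd.read_csv(out_dir / "occurrence.csv")
    summary = summarize_bands(occurrence, integrals)
    w.write_csv(summary, out_dir / "band_summary.csv")
    w.finalize()
    logger.info("integrate: %d integral rows, %d reduction rows",
                len(integrals), len(red_rows))


def subsample_per_type(
    pools: dict[str, np.ndarray], n_per_type: int, seed: int
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw up to ``n_per_type`` spectra per sample type, seeded per type.

    Under the reference sizes (5000 per type, 4 types of 16 000 pooled
    spectra) this yields the 20 000-spectrum embedding input.
    """
    sampled, meta = [], []
    for stype in sorted(pools):
        pool = np.asarray(pools[stype])
        rng = np.random.default_rng(derive_seed(seed, "umap", stype))
        n = min(n_per_type, pool.shape[0])
        idx = np.sort(rng.choice(pool.shape[0], size=n, replace=False))
        sampled.append(pool[idx])
        tissue, prep = stype.rsplit("_", 1)
        meta.append(
            pd.DataFrame({"tissue": tissue, "preparation": prep}, index=range(n))
        )
    return np.concatenate(sampled, axis=0), pd.concat(meta, ignore_index=True)


def stage_classify(config: RunConfig, out_dir: Path) -> None:
    w = _StageWriter()
    with _open_spectra(out_dir) as f:
        axis = _axis_from_h5(f)
        roi_ids = sorted(k for k in f.keys() if k != "wavenumbers")
        means, labels, pools = [], [], {}
        for roi_id in roi_ids:
            grp = f[roi_id]
            spectra = grp["classification/corrected"][()]
            stype = f"{grp.attrs['tissue']}_{grp.attrs['preparation']}"
            means.append(spectra.mean(axis=0))
            labels.append(f"{stype}/{roi_id}")
            pools.setdefault(stype, []).append(spectra)

    corr = roi_correlation_matrix(np.asarray(means), labels=labels)
    w.write_csv(corr.rename_axis("roi"), out_dir / "correlation.csv", index=True)

    # per-type UMAP sample drawn from the pooled classification spectra
    flat_pools = {s: np.concatenate(v, axis=0) for s, v in pools.items()}
    sampled, meta_df = subsample_per_type(
        flat_pools, config.n_umap_per_type, config.seed
    )
    x = zscore_normalize(sampled)
    n_comp = min(config.pca_components, min(x.shape))
    scores, evr = pca_reduce(x, n_components=n_comp)
    embedding = umap_embed(
        scores,
        n_neighbors=config.umap_n_neighbors,
        min_dist=config.umap_min_dist,
        seed=derive_seed(config.seed, "umap"),
        labels=meta_df,
        pca_components=n_comp,
    )
    emb_df = meta_df.copy()
    emb_df.insert(0, "y", embedding.coords[:, 1])
    emb_df.insert(0, "x", embedding.coords[:, 0])
    w.write_csv(emb_df[["x", "y", "tissue", "preparation"]],
                out_dir / "embedding.csv")

    stype_labels = (meta_df["tissue"] + "_" + meta_df["preparation"]).to_numpy()
    metrics = cluster_separation_metrics(embedding, stype_labels)
    w.write_csv(metrics, out_dir / "separation.csv")

    # per-tissue FF-vs-FFPE feature importance on Z-scored pooled spectra
    for tissue in sorted({t for t in meta_df["tissue"]}):
        groups = [s for s in pools if s.startswith(f"{tissue}_")]
        spect = np.concatenate([np.concatenate(pools[s], axis=0) for s in groups])
        labs = np.concatenate(
            [np.repeat(s.rsplit("_", 1)[1], sum(len(a) for a in pools[s]))
             for s in groups]
        )
        ranking = logistic_feature_importance(
            zscore_normalize(spect), labs, axis.values,
            top_n=config.top_n, seed=derive_seed(config.seed, "logistic", tissue),
        )
        w.write_csv(ranking, out_dir / f"ranking_{tissue}.csv")
    w.finalize()
    logger.info("classify: embedded %d spectra (%d types)", len(emb_df),
                meta_df.groupby(["tissue", "preparation"]).ngroups)


def stage_report(config: RunConfig, out_dir: Path,
                 report: RunReport | None = None) -> RunReport:
    import sklearn
    import scipy
    import umap

    report = report or RunReport()
    expected = [
        "cubes/manifest.json", "backgrounds.csv", "background_spectra.csv",
        "occurrence.csv", "band_table.csv", "integrals.csv", "reductions.csv",
        "band_summary.csv", "correlation.csv", "embedding.csv", "separation.csv",
    ] + [f"ranking_{t}.csv" for t in config.tissues]
    for rel in expected:
        p = out_dir / rel
        if p.exists():
            report.outputs[rel] = str(p)
        else:
            report.warnings.append(f"expected output missing: {rel}")
    report.params = json.loads(config.model_dump_json())
    report.versions = {
        "mirsiprep": _pkg_version,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "umap-learn": umap.__version__,
    }
    payload = {
        "outputs": report.outputs,
        "params": report.params,
        "versions": report.versions,
        "wall_time_s": report.wall_time_s,
        "warnings": report.warnings,
    }
    (out_dir / "run_report.json").write_text(json.dumps(payload, indent=1))
    logger.info("report: %d outputs, %d warnings",
                len(report.outputs), len(report.warnings))
    return report


def recover_amide1_reduction(
    tissue: str,
    seed: int,
    n_rois: int = 8,
    roi_shape: tuple[int, int] = (96, 96),
    n_pixels: int = 100,
) -> float:
    """Run the full masking -> rubberband -> SG-derivative -> Simpson
    chain on paired FF/FFPE phantoms of one tissue and return the
    recovered amide-I percent reduction.

    This is the in-memory equivalent of the simulate/mask/preprocess/
    integrate stages restricted to the amide I band: per ROI, Otsu-mask
    the cube, sample ``n_pixels`` tissue pixels, rubberband-correct them,
    take the SG second derivative of their mean, Simpson-integrate the
    amide-I window, then average integrals per preparation.
    """
    study = StudyConfig(tissues=(tissue,), n_rois=n_rois, roi_shape=roi_shape,
                        seed=seed)
    manifest = generate_study(study)
    amide = [b for b in default_band_windows() if b.label == "Amide I"][0]
    integrals: dict[str, list[float]] = {"FF": [], "FFPE": []}
    for rec in manifest["records"]:
        cube = rec["cube"]
        mask = make_tissue_mask(cube)
        px = sample_pixels(
            cube, mask, n=n_pixels, seed=derive_seed(seed, "px", rec["roi_id"])
        )
        corrected = rubberband_correct_batch(px.spectra, cube.axis)
        d2 = savgol_second_derivative(corrected.mean(axis=0), cube.axis)
        integrals[rec["preparation"]].append(integrate_band(d2, amide))
    return percent_reduction(
        float(np.mean(integrals["FF"])), float(np.mean(integrals["FFPE"]))
    )


_STAGE_FUNCS: dict[str, Callable[[RunConfig, Path], None]] = {
    "simulate": stage_simulate,
    "mask": stage_mask,
    "preprocess": stage_preprocess,
    "peaks": stage_peaks,
    "integrate": stage_integrate,
    "classify": stage_classify,
}


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> RunReport:
    """Run the requested stages in order and return the run report.

    A stage failure aborts with :class:`StageError` naming the stage;
    that stage's partial outputs remain on disk with a .partial suffix.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    t0 = time.monotonic()
    report = RunReport()
    for stage in STAGES:
        if stage not in stages:
            continue
        if stage == "report":
            continue
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, out_dir)
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            raise StageError(stage, exc) from exc
    report.wall_time_s = time.monotonic() - t0
    if "report" in stages:
        try:
            report = stage_report(config, out_dir, report)
        except Exception as exc:
            raise StageError("report", exc) from exc
    return report
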