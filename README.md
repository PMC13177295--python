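# mirsiprep

Processing pipeline for quantum-cascade-laser (QCL) mid-infrared
hyperspectral images of tissue sections, built to quantify how tissue
preparation — fresh-frozen (FF) versus formalin-fixed paraffin-embedded
(FFPE) — changes the spectral information available in the
950–1800 cm⁻¹ fingerprint region. It is aimed at spectrochemical-imaging
groups who need a tested, seed-reproducible implementation of the
standard second-derivative band-statistics workflow, together with
synthetic phantoms that make every stage verifiable without access to
tissue data.

## What it computes

Given absorbance cubes A(x, y, ν) on a uniform wavenumber grid
(2 cm⁻¹ steps, 426 points):

- **Tissue masks** by Otsu thresholding of the 1608 cm⁻¹ (amide I
  region) image; the discarded off-tissue pixels define the background
  spectrum and the noise scale σ = std of its Savitzky–Golay second
  derivative (window 13, order 2, 13 points trimmed per side).
- **Significant absorption bands** per pixel as local minima of
  d²A/dν² below −3σ ("dips"), and per-ROI **occurrence counts** — how
  many of 100 sampled pixels show a band within ±2 cm⁻¹ of each
  reference center (DNA, glycogen, amide I/II/III, lipid bands, and the
  fixation-associated ~1026 cm⁻¹ feature).
- **Band integrals** ∫ −d²A/dν² dν over center ± 8 cm⁻¹ windows by the
  composite Simpson rule, and the preparation effect size
  100 · (I_FF − I_FFPE)/I_FF per band and tissue.
- **Gaussian sub-band fits** of ROI-mean spectra initialised at the
  detected dip positions.
- **Spectral classification**: ROI correlation heatmaps, Z-score → PCA →
  UMAP embedding of 5000 spectra per sample type, pairwise silhouettes,
  and top-40 discriminative wavenumbers from L2 logistic regression.

The synthetic-phantom module generates FF/FFPE kidney/liver ROIs with
known band amplitudes, masks (with FF-style holes), scattering
baselines and a calibrated noise model, so planted quantities — in
particular the amide-I integral reductions of 66.3% (kidney) and 46.2%
(liver) — can be recovered end-to-end. See `docs/methods.md` for the
model and its assumptions.

## Worked example

Recover the planted amide-I reductions through the full chain
(mask → rubberband baseline → SG second derivative → Simpson
integration, 8 FF + 8 FFPE ROIs of 96×96 pixels per tissue):

```python
from mirsiprep.pipeline import recover_amide1_reduction

for tissue, seed in (("kidney", 42), ("liver", 43)):
    r = recover_amide1_reduction(tissue, seed=seed)
    print(f"{tissue}: recovered amide I reduction = {r:.1f} %")
```

prints

```
kidney: recovered amide I reduction = 66.1 %
liver: recovered amide I reduction = 45.7 %
```

i.e. the pipeline recovers the planted 66.3% / 46.2% integral
reductions to within ~1 percentage point at this scale: FFPE phantoms
lose roughly two-thirds (kidney) and half (liver) of their amide-I band
integral relative to FF.

The same chain is available as a CLI over a run directory, each stage
re-runnable from persisted intermediates:

```sh
mirsiprep all --out results/run1 --seed 42            # full defaults
mirsiprep simulate --config run.yaml --out results/run1
mirsiprep classify --out results/run1 --seed 42
```

A run directory ends up with `occurrence.csv`, `integrals.csv`,
`reductions.csv`, `band_summary.csv`, `correlation.csv`,
`embedding.csv`, `separation.csv`, `ranking_<tissue>.csv` and
`run_report.json` (parameter echo, versions, output inventory).
Reruns with the same config and seed are byte-identical.

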