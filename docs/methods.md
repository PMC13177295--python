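# Methods

`mirsiprep` implements a processing chain for quantum-cascade-laser (QCL)
mid-infrared hyperspectral images of tissue sections, aimed at one
scientific question: how much spectral information survives
formalin-fixed paraffin-embedded (FFPE) processing compared with
fresh-frozen (FF) preparation, for rat kidney and liver. Because the
kind of data it consumes (480 × 480-pixel absorbance cubes over
950–1800 cm⁻¹) is not publicly archived, the package ships a synthetic
phantom generator with exact ground truth, and every quantitative claim
the test suite makes is a parameter-recovery statement on those
phantoms. This note records the model, the defaults, and the places
where the design was genuinely open.

## The processing chain

1. **Tissue masking.** Off-tissue pixels are identified by Otsu
   thresholding of the single-band image at 1608 cm⁻¹ (amide I region,
   where tissue absorbs strongly). The Otsu threshold is computed on a
   256-bin histogram by an exhaustive between-class-variance scan; when
   a range of thresholds ties (an empty gap between modes), the midpoint
   of the maximizing plateau is used, so the cut falls centrally in the
   gap. Tissue is the high-absorbance class; an `invert` flag covers
   inverted-contrast data.
2. **Background noise model.** The mean spectrum of the discarded
   off-tissue pixels is the background spectrum. Its Savitzky–Golay (SG)
   second derivative (window 13 points, polynomial order 2, derivative
   taken with respect to wavenumber, Δν = 2 cm⁻¹) is computed, the 13
   edge-affected points per side are trimmed, and σ is the population
   standard deviation of what remains. σ is the yardstick for all
   significance decisions; it is computed per ROI.
3. **Pixel sampling.** 2000 tissue pixels per ROI are drawn uniformly
   without replacement for classification work and an independent 100
   for band-occurrence statistics, each with a seed derived from the
   master seed (base + CRC32 of a stage/ROI tag, kept below 2³¹).
4. **Rubberband baseline.** Each sampled spectrum has its lower convex
   hull (computed by a monotone-chain algorithm, robust to collinear
   inputs) subtracted, removing broad scattering backgrounds. The
   corrected spectrum is zero at the endpoints and nonnegative
   everywhere; adding any linear function of wavenumber to the input
   leaves the output unchanged.
5. **Second-derivative band detection.** Absorbance maxima appear as
   negative dips of the SG second derivative. All strict local minima
   are found (plateau minima report their leftmost point) and flagged
   significant when the value falls below −3σ — one-sided, because only
   dips correspond to absorption. Calls within 10 cm⁻¹ of the trimmed
   axis ends carry an edge flag (mirroring the treatment of a weak
   carbonyl-region feature near 1788 cm⁻¹ that is detectable but not
   interpretable).
6. **Occurrence statistics.** A pixel counts toward a reference band
   when it has at least one significant dip within ±2 cm⁻¹ of the band
   center (closed interval), at most once per band. Calls matching
   several overlapping windows go to the nearest center, ties to the
   lower wavenumber, with a logged warning.
7. **Band integrals and percent reduction.** Per ROI, the 100 corrected
   occurrence-sample spectra are averaged, the SG second derivative of
   the mean is taken, and −d² is integrated over each band window by the
   composite Simpson rule (exact for cubics on odd point counts; even
   counts are handled as Simpson over the first n−1 points plus a
   trapezoid on the last interval). The sign convention makes peak
   integrals positive. The preparation effect is
   100 · (I_FF − I_FFPE)/I_FF on the per-preparation means over 8 ROIs.
8. **Gaussian sub-band fitting.** A sum of Gaussians is fitted to the
   mean absorbance spectrum by bounded nonlinear least squares, with
   significant-dip positions as initial centers (bounded to ±5 cm⁻¹),
   amplitudes ≥ 0. Non-convergence raises an error carrying the
   best-so-far parameters.
9. **Classification.** ROI-mean corrected spectra are compared by
   Pearson correlation. Pixel spectra are Z-scored per spectrum
   (see "Open choices"), reduced by PCA (20 components, sign-fixed so
   the largest-magnitude loading of each component is positive),
   embedded in 2-D by UMAP (n_neighbors 15, min_dist 0.1, fixed seed;
   5000 spectra per sample type → 20 000 total), and separation is
   quantified by pairwise silhouettes. Feature importance is the
   absolute coefficient of an L2-regularised logistic regression
   (C = 1) fitted on the Z-scored spectra — not on embedding
   coordinates — so that importances map back to wavenumbers; the top
   40 are reported per tissue (FF vs FFPE).

## Reference band table

The band table holds 16 centers: DNA ~966, the fixation-associated
~1026 (seen only in formalin-fixed tissue), glycogen ~1030, DNA ~1035
and ~1082, glycogen ~1154, proteins ~1168, amide III ~1238 and ~1308,
proteins ~1400 and ~1448, lipids ~1462, amide II ~1516 and ~1546,
amide I ~1658, lipids ~1744 cm⁻¹. Integration windows default to
center ± 8 cm⁻¹ — the table's source prints centers only, and ±8 cm⁻¹
spans typical condensed-phase half-widths without overlapping neighbors
at this spacing; windows are configurable per band via a CSV table.
Note that under the default trim the analysable range is 976–1774 cm⁻¹,
so the 966 cm⁻¹ window cannot be integrated and is dropped with a
warning; its occurrence count is structurally zero.

## The phantom generator

Each synthetic ROI is built as
`pixel(ν) = baseline(ν) + common(ν) + tissue(ν) + ε`, with:

- **Band libraries.** Gaussian bands (the sub-band model used for
  fitting). FF kidney and FF liver each carry 13 bands from the table
  above (kidney omits the glycogen 1030/DNA 1035 pair; liver omits
  1035 and 1168 — glycogen is a liver marker and is planted only in FF
  liver). FFPE libraries are the protein/amide subset of the paired FF
  library (8 bands kidney, 7 liver), all attenuated to 80% except
  amide I, which is attenuated by the planted reduction fraction
  (kidney 0.663, liver 0.462), plus the fixation band at 1026 cm⁻¹
  (full presence in liver, 55% pixel presence in kidney). Because the
  FFPE amide-I amplitude is (1−f) times the FF amplitude at equal
  width, the true band-integral reduction is exactly f — the quantity
  the recovery tests and the acceptance script measure. Only the
  amide-I ratio is pinned; other FF/FFPE amplitude ratios are free
  parameters of the generator.
- **Amide envelope pedestal.** A broad band (center 1580, fwhm 260,
  amplitude 0.12) carried by every tissue pixel in both preparations.
  It reproduces the strong tissue contrast of real 1608 cm⁻¹ images —
  without it, low-amide FFPE phantoms mask poorly and background
  leakage biases the recovered reduction — while being too broad and
  shallow (|d²| ≈ 0.1σ) to register as a band or shift integrals by
  more than ~0.3%.
- **Baseline.** An order-≤3 polynomial in normalised wavenumber plus an
  optional broad sigmoid, standing in for scattering backgrounds that
  the rubberband removes.
- **Noise.** Two components. (i) iid Gaussian detector noise, default
  σ = 1 mOD, typical of averaged QCL microscope scans. (ii) A
  common-mode spectral fluctuation shared by all pixels of a cube:
  white noise convolved with a Gaussian kernel (correlation length
  14 cm⁻¹), amplitude 10 × the iid sd, redrawn until its
  second-derivative excursions stay within 2.2 standard deviations of
  their own spread. The common mode is what makes the background
  spectrum's σ meaningful: averaging thousands of off-tissue pixels
  removes iid noise but not coherent source structure, so σ measured on
  the mean background matches the derivative noise an individual pixel
  actually faces. The excursion cap encodes the assumption — implicit
  in any fixed-multiple significance rule — that the instrument
  background is structured but stable, without heavy-tailed spikes.
  With these defaults the 3σ rule is calibrated: on band-free phantoms
  no band collects more than 5 of 100 pixels, and planted bands with
  ≥ 6σ center depth are detected in ≥ 95% of pixels within ±2 cm⁻¹.
- **Intensity jitter.** A single multiplicative log-normal factor per
  tissue pixel (sd 10%) applied to all bands and the pedestal, modeling
  thickness/path-length variation — the dominant mode of intra-ROI
  heterogeneity in this kind of data.
- **Masks.** Unions of 3–5 random ellipses (redrawn until the tissue
  fraction is 25–90%); FF masks then have random disks carved out until
  ~15% (configurable) of the tissue area is removed, emulating the
  holes and fractures of frozen sections. FFPE masks stay intact.
- **Geometry.** Default ROI size is 96 × 96 pixels rather than the
  instrument's 480 × 480 — integrals, occurrence fractions and
  classification operate per pixel or per ROI mean, so recovery
  accuracy depends on ROI count and pixel-sample sizes, not on the
  frame size; full size remains available through the config.

What the phantoms do *not* emulate: Mie/resonant-Mie scattering
distortions, water-vapour rotational lines, band asymmetry or Voigt
shapes, spatial texture (amplitudes are spatially uncorrelated within
the mask), and instrument drift between ROIs. Passing recovery tests
therefore demonstrates the correctness of the pipeline's arithmetic and
its statistical calibration under the stated noise model — not
robustness to every artefact of real measurements.

## Numerical choices

- Nearest-grid lookups resolve ties toward the lower wavenumber
  (1607 cm⁻¹ on an even grid resolves to 1606).
- σ uses the population (not sample) standard deviation; the trimmed
  range has 400 points, so the distinction is immaterial, but the
  convention is fixed.
- Z-scoring uses population sd and rejects constant inputs; PCA uses a
  full SVD with deterministic sign fixing; UMAP runs single-threaded
  with a fixed random state, which pins its output exactly for a given
  umap-learn version.
- The SG filter attenuates narrow bands: the realized dip depth of a
  Gaussian band reaches the analytic −A·8ln2/fwhm² only asymptotically
  (≈ 72% of it at fwhm 24 cm⁻¹, ≈ 97% at fwhm 120 cm⁻¹ for the
  13-point window). Detection thresholds and integral ratios are
  unaffected (attenuation cancels between preparations at equal width),
  but absolute depths must not be read as analytic values.
- Logistic feature importance at C = 1 with n ≈ p overfits random
  labels (a permutation null retains large coefficients); with
  pooled-sample sizes well above the 426 wavenumbers, or stronger
  regularisation, the null collapses. The ranking of a genuinely
  discriminative band is stable across this range; magnitude
  comparisons between runs of different size are not meaningful.

## Open choices, resolved

- Z-scoring per spectrum across wavenumbers (the alternative,
  per wavenumber across spectra, is available as a flag): the chain
  normalises each absorption spectrum before PCA, which makes the
  embedding insensitive to the per-pixel intensity jitter that
  dominates intra-ROI variation.
- Rubberband is applied after pixel sampling (identical result per
  pixel, far cheaper than correcting full cubes).
- Band integrals use the 100-pixel occurrence sample's mean spectrum;
  a 120-pixel variant is a config knob.
- Otsu runs per ROI, and σ is recomputed per ROI.
- Whether the regression should consume spectra or embedding
  coordinates was ambiguous; spectra were chosen because wavenumber
  importances cannot be recovered from 2-D embedding coordinates.

## Problem sizes in the shipped tests

The test suite and the acceptance script run the full chain at 8 + 8
ROIs of 96 × 96 pixels per tissue for reduction recovery (the package's
desk-scale default), 100-pixel occurrence samples, and reduced
pixel/embedding counts for classification property checks. These sizes
were chosen so the statistical criteria (± 5 percentage points on
reduction recovery; ≤ 5/100 false occurrence; ≥ 95% sensitivity) have
comfortable margins under the default noise model, as verified across
independent seeds during development.
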