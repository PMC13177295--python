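"""3-sigma dip detection, occurrence, Simpson integrals, Gaussian fits."""

import numpy as np
import pandas as pd
import pytest

from mirsiprep import (
    BandSpec,
    BandWindow,
    PeakCall,
    detect_significant_dips,
    fit_gaussian_subbands,
    integrate_band,
    make_spectral_axis,
    occurrence_counts,
    percent_reduction,
    summarize_bands,
)
from mirsiprep.preprocessing import SecondDerivSpectrum
from mirsiprep.phantoms import gaussian_profile
from mirsiprep.subbands import bands_within, default_band_windows


def d2_of(values, axis):
    return SecondDerivSpectrum(values=np.asarray(values, float), trimmed_axis=axis)


@pytest.fixture(scope="module")
def trimmed():
    # 400-point trimmed grid, like the default 426-point axis after trim
    return make_spectral_axis(976.0, 1774.0, 2.0)


class TestDetectDips:
    def test_noise_null_rate_below_one_call_per_spectrum(self, trimmed, rng):
        # one-sided 3-sigma tail x local-minima density keeps the
        # expected significant-call count per 400-point spectrum << 1
        sigma = 1.0
        counts = []
        for _ in range(1000):
            v = rng.normal(0, sigma, len(trimmed))
            calls = detect_significant_dips(d2_of(v, trimmed), sigma)
            counts.append(sum(c.significant for c in calls))
        assert np.mean(counts) < 1.0

    def test_planted_band_gives_one_significant_call_at_center(self, trimmed):
        sigma = 1.0
        band = BandSpec("t", 1400.0, 30.0, 1.0)
        depth = 10.0 * sigma
        x = trimmed.values
        s = band.sigma
        d2g = (1 - ((x - 1400.0) / s) ** 2) * np.exp(-0.5 * ((x - 1400.0) / s) ** 2)
        v = depth * d2g * -1.0 / 1.0  # dip of 10 sigma at the center
        calls = [c for c in detect_significant_dips(d2_of(v, trimmed), sigma)
                 if c.significant]
        assert len(calls) == 1
        assert abs(calls[0].position - 1400.0) <= 2.0

    def test_all_positive_has_no_significant_calls(self, trimmed):
        v = 1.0 + np.abs(np.sin(trimmed.values / 10.0))
        calls = detect_significant_dips(d2_of(v, trimmed), sigma=0.01)
        assert all(not c.significant for c in calls)

    def test_plateau_minimum_uses_leftmost_point(self, trimmed):
        v = np.zeros(len(trimmed))
        v[100:104] = -5.0  # flat-bottomed dip
        calls = detect_significant_dips(d2_of(v, trimmed), sigma=1.0)
        assert len(calls) == 1
        assert calls[0].position == trimmed.values[100]

    def test_near_edge_calls_are_flagged(self, trimmed):
        v = np.zeros(len(trimmed))
        v[2] = -5.0    # within the 10 cm^-1 edge-exclusion zone
        v[200] = -5.0  # interior
        calls = detect_significant_dips(d2_of(v, trimmed), sigma=1.0)
        flags = {c.position: c.edge_flagged for c in calls}
        assert flags[trimmed.values[2]] is True
        assert flags[trimmed.values[200]] is False

    def test_nonpositive_sigma_rejected(self, trimmed):
        with pytest.raises(ValueError):
            detect_significant_dips(d2_of(np.zeros(len(trimmed)), trimmed), 0.0)


class TestOccurrence:
    bands = [BandWindow("A", 1400.0, 1392.0, 1408.0),
             BandWindow("B", 1500.0, 1492.0, 1508.0)]

    def call(self, pos, significant=True):
        return PeakCall(position=pos, depth=-5.0, significant=significant)

    def test_every_pixel_at_center_counts_fully(self):
        calls = [[self.call(1400.0)] for _ in range(100)]
        t = occurrence_counts(calls, self.bands).set_index("band_label")
        assert t.loc["A", "count"] == 100 and t.loc["A", "n_pixels"] == 100
        assert t.loc["B", "count"] == 0

    def test_tolerance_boundary_is_closed(self):
        t = occurrence_counts([[self.call(1402.0)]], self.bands).set_index("band_label")
        assert t.loc["A", "count"] == 1
        t = occurrence_counts([[self.call(1402.1)]], self.bands).set_index("band_label")
        assert t.loc["A", "count"] == 0

    def test_pixel_contributes_at_most_once_per_band(self):
        calls = [[self.call(1399.0), self.call(1401.0)]]
        t = occurrence_counts(calls, self.bands).set_index("band_label")
        assert t.loc["A", "count"] == 1

    def test_insignificant_calls_ignored(self):
        t = occurrence_counts(
            [[self.call(1400.0, significant=False)]], self.bands
        ).set_index("band_label")
        assert t.loc["A", "count"] == 0

    def test_overlap_assigned_to_nearest_center_tie_to_lower(self):
        near = [BandWindow("lo", 1398.0, 1390.0, 1406.0),
                BandWindow("hi", 1402.0, 1394.0, 1410.0)]
        t = occurrence_counts([[self.call(1400.0)]], near).set_index("band_label")
        assert t.loc["lo", "count"] == 1 and t.loc["hi", "count"] == 0
        t = occurrence_counts([[self.call(1401.0)]], near).set_index("band_label")
        assert t.loc["hi", "count"] == 1

    def test_sub_step_tolerance_rejected(self):
        with pytest.raises(ValueError, match="tolerance"):
            occurrence_counts([[]], self.bands, tolerance=0.5, axis_step=2.0)

    def test_partial_presence_band_counted_binomially(self):
        # phantom band present in 60% of pixels at ~10 sigma depth:
        # mean occurrence over 8 ROIs tracks 60 of 100
        from mirsiprep import PhantomConfig, compute_background, generate_roi, sample_pixels
        from mirsiprep import TissueMask
        from mirsiprep.preprocessing import rubberband_correct_batch, savgol_second_derivative

        band = BandSpec("t", 1400.0, 20.0, 0.10, presence=0.6)
        window = [BandWindow("t", 1400.0, 1392.0, 1408.0)]
        counts = []
        for seed in range(8):
            cube, truth = generate_roi(
                PhantomConfig("liver", "FF", roi_shape=(64, 64),
                              band_library=(band,), pedestal=None, seed=seed)
            )
            mask = TissueMask(mask=truth.mask, threshold_used=0.0)
            bg = compute_background(cube, mask)
            px = sample_pixels(cube, mask, n=100, seed=seed)
            corr = rubberband_correct_batch(px.spectra, cube.axis)
            d2 = savgol_second_derivative(corr, cube.axis)
            calls = [
                detect_significant_dips(
                    SecondDerivSpectrum(d2.values[i], d2.trimmed_axis), bg.sigma
                )
                for i in range(100)
            ]
            counts.append(
                occurrence_counts(calls, window)["count"].iloc[0]
            )
        assert 50 <= np.mean(counts) <= 70


class TestIntegration:
    def test_constant_dip_integrates_to_window_width(self):
        ax = make_spectral_axis(1000.0, 1020.0, 2.0)
        w = BandWindow("c", 1010.0, 1005.0, 1015.0)
        # grid points 1006..1014 span 8 cm^-1... use lo/hi on grid
        w = BandWindow("c", 1009.0, 1004.0, 1014.0)
        val = integrate_band(d2_of(-np.ones(len(ax)), ax), w)
        assert val == pytest.approx(10.0, rel=1e-12)

    def test_simpson_exact_for_quadratic(self):
        ax = make_spectral_axis(0.0, 4.0, 1.0)
        c = 2.0
        v = -((ax.values - c) ** 2)
        w = BandWindow("q", c, 0.0, 4.0)
        assert integrate_band(d2_of(v, ax), w) == pytest.approx(16.0 / 3.0, rel=1e-12)

    def test_even_point_window_handled(self):
        ax = make_spectral_axis(0.0, 5.0, 1.0)  # 6 points
        w = BandWindow("e", 2.5, 0.0, 5.0)
        # -d2 = 1 everywhere -> integral = 5 regardless of parity handling
        assert integrate_band(d2_of(-np.ones(6), ax), w) == pytest.approx(5.0)

    def test_gaussian_band_matches_fine_grid_oracle(self, axis):
        band = BandSpec("t", 1400.0, 28.0, 0.7)
        from mirsiprep.phantoms import gaussian_band_integral

        trimmed = axis.trimmed(13)
        x = trimmed.values
        s = band.sigma
        d2 = (
            band.amplitude / s**2
            * (((x - 1400.0) / s) ** 2 - 1)
            * np.exp(-0.5 * ((x - 1400.0) / s) ** 2)
        )
        w = BandWindow("t", 1400.0, 1392.0, 1408.0)
        got = integrate_band(d2_of(d2, trimmed), w)
        assert got == pytest.approx(
            gaussian_band_integral(band, 1392.0, 1408.0), rel=0.05
        )

    def test_window_outside_axis_rejected(self, trimmed):
        w = BandWindow("DNA", 966.0, 958.0, 974.0)
        with pytest.raises(ValueError, match="outside"):
            integrate_band(d2_of(np.zeros(len(trimmed)), trimmed), w)

    def test_bands_within_drops_off_axis_windows(self, trimmed):
        kept = bands_within(d2_of(np.zeros(len(trimmed)), trimmed),
                            default_band_windows())
        centers = {b.center for b in kept}
        assert 966.0 not in centers
        assert 1658.0 in centers

    def test_integral_linear_in_amplitude(self, trimmed):
        w = BandWindow("t", 1400.0, 1392.0, 1408.0)
        x = trimmed.values
        s = BandSpec("t", 1400.0, 24.0, 1.0).sigma
        shape = (((x - 1400.0) / s) ** 2 - 1) * np.exp(-0.5 * ((x - 1400.0) / s) ** 2)
        amps = np.array([0.2, 0.5, 1.1])
        vals = np.array([integrate_band(d2_of(a / s**2 * shape, trimmed), w) for a in amps])
        slope = (amps * vals).sum() / (amps**2).sum()
        ss_res = ((vals - slope * amps) ** 2).sum()
        ss_tot = ((vals - vals.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot >= 0.99


class TestPercentReduction:
    @pytest.mark.parametrize("ff, ffpe, out", [(10, 10, 0.0), (10, 0, 100.0),
                                               (10, 5, 50.0)])
    def test_examples(self, ff, ffpe, out):
        assert percent_reduction(ff, ffpe) == pytest.approx(out)

    def test_nonpositive_ff_rejected(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 1.0)


class TestGaussianFit:
    def test_noiseless_single_band_exact(self, axis):
        band = BandSpec("t", 1400.0, 25.0, 0.6)
        y = gaussian_profile(axis.values, band)
        fit = fit_gaussian_subbands(y, axis, [1400.0])
        row = fit.params.iloc[0]
        assert row.center == pytest.approx(1400.0, abs=1e-6)
        assert row.amplitude == pytest.approx(0.6, abs=1e-6)
        assert row.fwhm == pytest.approx(25.0, abs=1e-4)
        assert fit.residual_norm < 1e-8

    @pytest.mark.parametrize("seed", range(20))
    def test_two_bands_recovered_under_noise(self, axis, seed):
        b1 = BandSpec("a", 1200.0, 30.0, 0.5)
        b2 = BandSpec("b", 1290.0, 30.0, 0.8)  # 3 x fwhm separation
        r = np.random.default_rng(seed)
        y = (gaussian_profile(axis.values, b1) + gaussian_profile(axis.values, b2)
             + r.normal(0, 0.008, len(axis)))
        fit = fit_gaussian_subbands(y, axis, [1200.0, 1290.0], init_fwhm=25.0)
        p = fit.params.sort_values("center").reset_index(drop=True)
        assert p.center[0] == pytest.approx(1200.0, abs=1.0)
        assert p.center[1] == pytest.approx(1290.0, abs=1.0)
        assert p.amplitude[0] == pytest.approx(0.5, rel=0.05)
        assert p.amplitude[1] == pytest.approx(0.8, rel=0.05)

    def test_far_init_flags_poor_residual(self, axis):
        band = BandSpec("t", 1400.0, 25.0, 0.6)
        r = np.random.default_rng(0)
        noise_sd = 0.003
        y = gaussian_profile(axis.values, band) + r.normal(0, noise_sd, len(axis))
        fit = fit_gaussian_subbands(y, axis, [1350.0])  # 50 cm^-1 off
        noise_floor = noise_sd * np.sqrt(len(axis))
        assert fit.residual_norm > 10 * noise_floor
        # bounded fit stays near its init
        assert abs(fit.params.iloc[0].center - 1350.0) <= 5.0


class TestSummaries:
    def make_tables(self, counts_by_roi):
        occ = pd.DataFrame(
            [("liver_FF", f"roi{i}", "Amide I", c, 100)
             for i, c in enumerate(counts_by_roi)],
            columns=["sample_type", "roi_id", "band_label", "count", "n_pixels"],
        )
        ints = pd.DataFrame(
            [("liver_FF", f"roi{i}", "Amide I", 0.02 + 0.001 * c)
             for i, c in enumerate(counts_by_roi)],
            columns=["sample_type", "roi_id", "band_label", "integral"],
        )
        return occ, ints

    def test_identical_rois_have_zero_sd(self):
        occ, ints = self.make_tables([55] * 8)
        s = summarize_bands(occ, ints).iloc[0]
        assert s.occurrence_sd == 0.0 and s.integral_sd == 0.0
        assert s.occurrence_mean == 55.0

    def test_known_counts_mean_and_sample_sd(self):
        occ, ints = self.make_tables(list(range(1, 9)))
        s = summarize_bands(occ, ints).iloc[0]
        assert s.occurrence_mean == pytest.approx(4.5)
        assert s.occurrence_sd == pytest.approx(np.std(range(1, 9), ddof=1))
        assert s.occurrence_median == pytest.approx(4.5)

    def test_box_stats_match_independent_recompute(self):
        counts = [12, 40, 43, 44, 47, 52, 55, 90]
        occ, ints = self.make_tables(counts)
        s = summarize_bands(occ, ints).iloc[0]
        q1, med, q3 = np.percentile(counts, [25, 50, 75])
        iqr = q3 - q1
        arr = np.array(counts)
        assert s.occurrence_q1 == pytest.approx(q1)
        assert s.occurrence_q3 == pytest.approx(q3)
        assert s.occurrence_median == pytest.approx(med)
        assert s.occurrence_whisker_lo == arr[arr >= q1 - 1.5 * iqr].min()
        assert s.occurrence_whisker_hi == arr[arr <= q3 + 1.5 * iqr].max()

    def test_single_roi_rejected(self):
        occ, ints = self.make_tables([5])
        with pytest.raises(ValueError, match="2 ROIs"):
            summarize_bands(occ, ints)
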