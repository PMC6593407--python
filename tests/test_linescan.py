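"""Line-scan extraction, Gaussian window fits and the distance statistic d."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from sporeloc import (
    DistanceMeasurement,
    ForesporeModel,
    ImagingConfig,
    LineScanProfile,
    LocusPlacementModel,
    extract_linescan,
    find_membrane_peak,
    fit_gaussian_window,
    measure_focus_membrane_distance,
    render_frame,
    simulate_field,
    summarize_distances,
)
from sporeloc.pipeline import measure_field, measure_image_pair


def gauss(x, A, a, b):
    return A * np.exp(-((x - a) ** 2) / (2 * b * b))


def profile_from(y, step=1.0):
    y = np.asarray(y, dtype=float)
    x = np.arange(len(y)) * step
    return LineScanProfile((0.0, 0.0), (0.0, float(len(y) - 1)), x, y, step)


def grid_search_fit(xs, ys, A0, a0, b0):
    """Independent coarse-to-fine least-squares grid search over (A, a, b)."""
    best = (np.inf, A0, a0, b0)
    spans = (0.5 * A0 + 1.0, 1.5, 1.0)
    center = [A0, a0, b0]
    for _ in range(5):  # refine to ~1e-3 of the initial span
        grids = [
            np.linspace(center[k] - spans[k], center[k] + spans[k], 21)
            for k in range(3)
        ]
        for A in grids[0]:
            if A <= 0:
                continue
            for a in grids[1]:
                for b in grids[2]:
                    if b <= 1e-3:
                        continue
                    ss = np.sum((gauss(xs, A, a, b) - ys) ** 2)
                    if ss < best[0]:
                        best = (ss, A, a, b)
        center = list(best[1:])
        spans = tuple(s / 10.0 for s in spans)
    return best[1:]


class TestExtractLinescan:
    def test_constant_image_gives_constant_profile(self):
        img = np.full((20, 20), 7.0)
        prof = extract_linescan(img, (3.0, 2.0), (10.0, 14.0))
        np.testing.assert_allclose(prof.y, 7.0)

    def test_bilinear_is_exact_on_a_ramp(self):
        # I(row, col) = col; horizontal scan returns the sampled col coords
        img = np.tile(np.arange(20.0), (20, 1))
        prof = extract_linescan(img, (5.0, 2.5), (5.0, 16.5), sampling_step=0.5)
        # x is the scan coordinate in pixels, so intensity = col0 + x
        np.testing.assert_allclose(prof.y, 2.5 + prof.x, atol=1e-12)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            extract_linescan(np.zeros((10, 10)), (1.0, 1.0), (1.0, 4.0))

    def test_diagonal_scan_peaks_at_projected_spot_center(self):
        # spot centre projected onto the scan line locates the profile peak
        rr, cc = np.meshgrid(np.arange(40.0), np.arange(40.0), indexing="ij")
        center = np.array([17.3, 21.6])
        img = gauss(np.hypot(rr - center[0], cc - center[1]), 100.0, 0.0, 2.0)
        p0, p1 = np.array([5.0, 8.0]), np.array([30.0, 33.0])
        u = (p1 - p0) / np.linalg.norm(p1 - p0)
        t_star = float(np.dot(center - p0, u))
        prof = extract_linescan(img, p0, p1, sampling_step=0.5)
        fit = fit_gaussian_window(prof, int(np.argmax(prof.y)), window_width=7)
        assert abs(fit.a - t_star) < 0.1 * prof.sampling_step


class TestFitGaussianWindow:
    def test_noiseless_window_recovered_to_1e6_relative(self):
        x = np.arange(9.0)
        y = gauss(x, 100.0, 3.0, 1.2)
        fit = fit_gaussian_window(profile_from(y), 3, subtract_baseline=False)
        assert fit.converged
        assert fit.A == pytest.approx(100.0, rel=1e-6)
        assert fit.a == pytest.approx(3.0, rel=1e-6)
        assert fit.b == pytest.approx(1.2, rel=1e-6)

    def test_symmetric_window_centers_exactly(self):
        y = np.array([0.0, 1.0, 5.0, 9.0, 5.0, 1.0, 0.0, 0.0])
        fit = fit_gaussian_window(profile_from(y), 3)
        assert fit.a == pytest.approx(3.0, abs=1e-9)

    def test_matches_grid_search_least_squares(self, rng):
        x = np.arange(11.0)
        for _ in range(5):
            A, a, b = 80 + 40 * rng.uniform(), 5 + rng.uniform(-1, 1), 1.0 + rng.uniform()
            y = gauss(x, A, a, b) + rng.normal(0, 3.0, size=x.size)
            fit = fit_gaussian_window(profile_from(y), 5, subtract_baseline=False)
            xs, ys = x[2:9], y[2:9]
            Ag, ag, bg = grid_search_fit(xs, ys, fit.A, fit.a, fit.b)
            assert abs(fit.a - ag) < 2e-3
            assert abs(fit.b - bg) < 2e-3
            assert abs(fit.A - Ag) < 2e-3 * max(1.0, fit.A)

    def test_flat_window_flags_non_convergence(self):
        fit = fit_gaussian_window(profile_from(np.full(9, 4.0)), 4)
        assert not fit.converged

    def test_window_at_profile_edge_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_window(profile_from(np.arange(8.0)), 1)

    def test_non_finite_window_rejected(self):
        y = np.arange(9.0)
        y[4] = np.nan
        prof = LineScanProfile((0, 0), (0, 8), np.arange(9.0), np.nan_to_num(y), 1.0)
        prof.y = y  # bypass constructor check to exercise the fit guard
        with pytest.raises(ValueError):
            fit_gaussian_window(prof, 4)

    def test_center_equivariant_under_index_translation(self, rng):
        y = gauss(np.arange(9.0), 50.0, 4.2, 1.1) + rng.normal(0, 1.0, 9)
        base = fit_gaussian_window(profile_from(y), 4)
        shifted = profile_from(y)
        shifted.x = shifted.x + 10.0
        moved = fit_gaussian_window(shifted, 4)
        assert moved.a - base.a == pytest.approx(10.0, abs=1e-6)


class TestFindMembranePeak:
    def test_single_peak_found(self):
        y = np.zeros(14)
        y[9] = 5.0
        assert find_membrane_peak(profile_from(y), focus_center=2.0) == 9

    def test_nearest_of_two_peaks_wins(self):
        y = np.zeros(15)
        y[6] = 5.0
        y[12] = 5.0
        assert find_membrane_peak(profile_from(y), focus_center=2.0) == 6

    def test_plateau_resolves_to_lower_index(self):
        y = np.zeros(14)
        y[7] = y[8] = 5.0
        assert find_membrane_peak(profile_from(y), focus_center=2.0) == 7

    def test_no_qualifying_peak_is_rejection_not_error(self):
        y = np.linspace(5.0, 0.0, 10)  # monotone decay: no local maximum
        assert find_membrane_peak(profile_from(y), focus_center=0.0) is None


def _measure_at(true_distance_nm, cfg, forespore):
    mem, loc = render_frame(forespore, (forespore.radius - true_distance_nm, 0, 0), cfg)
    out = measure_image_pair(mem, loc, cfg.pixel_size)
    assert len(out) == 1
    return out[0]


class TestMeasureDistance:
    def test_locus_on_the_membrane_measures_near_zero(self, forespore, noiseless_cfg):
        m = _measure_at(0.0, noiseless_cfg, forespore)
        assert m.accepted
        assert m.d_nm <= 20.0

    def test_matches_dense_rendering_oracle_at_100nm(self, forespore, noiseless_cfg):
        # oracle: same noiseless render, dense (0.01 px) radial profiles,
        # peak positions from direct dense least-squares Gaussian fits
        # (the oracle therefore includes the PSF-induced membrane-peak shift)
        from scipy.optimize import curve_fit

        cfg = noiseless_cfg
        m = _measure_at(100.0, cfg, forespore)
        assert m.accepted
        mem, loc = render_frame(forespore, (forespore.radius - 100.0, 0, 0), cfg)
        c = (mem.shape[0] - 1) / 2
        t = np.arange(0, 10, 0.01)
        rows, cols = np.full_like(t, c), c + t

        def dense_peak(img):
            prof = map_coordinates(img, np.vstack([rows, cols]), order=1)
            i = int(np.argmax(prof))
            w = slice(max(i - 350, 0), i + 350)  # +/- 3.5 px around the peak
            p, _ = curve_fit(gauss, t[w], prof[w], p0=[prof[i], t[i], 1.0])
            return p[1]

        oracle_d = abs(dense_peak(mem) - dense_peak(loc)) * cfg.pixel_size
        assert m.d_nm == pytest.approx(oracle_d, abs=0.25 * cfg.pixel_size)

    def test_rotating_the_scene_90deg_preserves_d(self, forespore, noiseless_cfg):
        cfg = noiseless_cfg
        r = forespore.radius - 83.0
        d_x = measure_image_pair(*render_frame(forespore, (r, 0, 0), cfg), cfg.pixel_size)
        d_y = measure_image_pair(*render_frame(forespore, (0, r, 0), cfg), cfg.pixel_size)
        assert d_x[0].accepted and d_y[0].accepted
        assert abs(d_x[0].d_nm - d_y[0].d_nm) <= 0.25 * cfg.pixel_size

    def test_mean_d_monotone_in_true_tether_distance(self, forespore):
        means = []
        for true_d in (0.0, 50.0, 100.0, 150.0, 200.0):
            placement = LocusPlacementModel(
                tether_distance_mean=true_d, tether_distance_sd=0.0
            )
            field = simulate_field(30, forespore, placement, ImagingConfig(rng_seed=31))
            d = [m.d_nm for m in measure_field(field) if m.accepted]
            assert len(d) >= 25
            means.append(np.mean(d))
        assert all(b >= a for a, b in zip(means, means[1:]))


class TestSummarizeDistances:
    def _meas(self, values):
        return [
            DistanceMeasurement(cell_id=i, d_nm=v, accepted=True)
            for i, v in enumerate(values)
        ]

    def test_single_measurement_convention(self):
        s = summarize_distances(self._meas([83.0]))
        assert (s.n, s.mean_nm, s.sd_nm) == (1, 83.0, 0.0)

    def test_mean_and_sd_arithmetic(self):
        s = summarize_distances(self._meas([80.0, 90.0, 100.0]))
        assert s.mean_nm == pytest.approx(90.0)
        assert s.sd_nm == pytest.approx(10.0)

    def test_histogram_uses_fixed_bin_width(self):
        s = summarize_distances(self._meas([10.0, 30.0, 60.0]), bin_width_nm=25.0)
        assert np.allclose(np.diff(s.bin_edges_nm), 25.0)
        assert s.counts.sum() == 3

    def test_no_accepted_measurements_is_an_error(self):
        rejected = [DistanceMeasurement(cell_id=0, d_nm=None, accepted=False)]
        with pytest.raises(ValueError):
            summarize_distances(rejected)
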