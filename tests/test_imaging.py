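"""dF/F0 quantification, transient detection, MIP and CaMPARI ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermofly.imaging import (
    RoiTrace,
    campari_ratio,
    compute_dff,
    detect_transients,
    extract_roi_traces,
    max_intensity_projection,
    ramp_response,
)
from thermofly.synthetic import (
    CalciumMovieConfig,
    CampariConfig,
    TemperatureRamp,
    generate_calcium_movie,
    generate_campari_stacks,
)


def _trace(values, times=None):
    values = np.asarray(values, float)
    if times is None:
        times = np.arange(len(values), dtype=float)
    return RoiTrace(roi_id="r", intensity=values, frame_times_s=times)


class TestRoiExtraction:
    def test_uniform_frame_yields_constant_trace(self):
        stack = np.full((7, 8, 8), 42.0)
        mask = np.zeros((8, 8), bool)
        mask[2:5, 2:5] = True
        (tr,) = extract_roi_traces(stack, {"a": mask})
        assert np.all(tr.intensity == 42.0)

    def test_single_pixel_mask_returns_pixel_series(self):
        rng = np.random.default_rng(0)
        stack = rng.random((10, 4, 4))
        mask = np.zeros((4, 4), bool)
        mask[1, 2] = True
        (tr,) = extract_roi_traces(stack, {"px": mask})
        assert np.array_equal(tr.intensity, stack[:, 1, 2])

    def test_two_blob_movie_matches_generator_truth(self):
        cfg = CalciumMovieConfig(n_cells=2, transient_amplitude_rel=0.8,
                                 onset_temp_c=(24.0, 31.0), noise_sd=0.0)
        stack, ramp, truth = generate_calcium_movie(cfg)
        traces = extract_roi_traces(
            stack, {f"c{i}": truth.masks[i] for i in range(2)}, truth.frame_times_s)
        for i, tr in enumerate(traces):
            dff = compute_dff(tr)
            assert np.max(dff.dff) == pytest.approx(truth.amplitude_dff[i])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_roi_traces(np.ones((3, 4, 4)), {"e": np.zeros((4, 4), bool)})


class TestDff:
    def test_constant_trace_has_zero_dff(self):
        dff = compute_dff(_trace([100.0] * 10))
        assert np.all(dff.dff == 0.0)

    def test_baseline_is_mean_of_first_five_frames(self):
        # first five frames average to 100, so frame at 200 gives dF/F0 = 1
        dff = compute_dff(_trace([98, 100, 102, 100, 100, 100, 200]))
        assert dff.f0 == pytest.approx(100.0)
        assert dff.dff[-1] == pytest.approx(1.0)

    def test_half_increase_reads_49_percent(self):
        dff = compute_dff(_trace([100] * 5 + [149]))
        assert dff.dff[-1] == pytest.approx(0.49)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            compute_dff(_trace([0.0] * 6))


class TestRampResponse:
    def test_zero_dff_gives_zero_response(self):
        cfg = CalciumMovieConfig(n_cells=1, transient_amplitude_rel=0.0)
        stack, ramp, truth = generate_calcium_movie(cfg)
        (tr,) = extract_roi_traces(stack, {"c": truth.masks[0]}, truth.frame_times_s)
        res = ramp_response(compute_dff(tr), ramp)
        assert res.peak_dff_pct == 0.0 and res.average_dff_pct == 0.0

    def test_configured_196_percent_peak_recovered(self):
        cfg = CalciumMovieConfig(n_cells=1, transient_amplitude_rel=1.96,
                                 onset_temp_c=(28.0,), noise_sd=0.0)
        stack, ramp, truth = generate_calcium_movie(cfg)
        (tr,) = extract_roi_traces(stack, {"c": truth.masks[0]}, truth.frame_times_s)
        res = ramp_response(compute_dff(tr), ramp)
        assert res.peak_dff_pct == pytest.approx(196.0)
        assert res.peak_dff_pct >= res.average_dff_pct

    def test_peak_temperature_near_onset(self):
        cfg = CalciumMovieConfig(n_cells=1, transient_amplitude_rel=1.0,
                                 onset_temp_c=(30.0,), noise_sd=0.0)
        stack, ramp, truth = generate_calcium_movie(cfg)
        (tr,) = extract_roi_traces(stack, {"c": truth.masks[0]}, truth.frame_times_s)
        res = ramp_response(compute_dff(tr), ramp)
        # peak sits on the plateau which begins shortly after the 30 degC
        # crossing during heating (0.125 degC/s)
        assert res.temp_at_peak_c == pytest.approx(30.0, abs=1.5)

    def test_grid_mismatch_rejected(self):
        dff = compute_dff(_trace([100] * 6, times=np.arange(6) + 1e4))
        ramp = TemperatureRamp.standard()
        with pytest.raises(ValueError, match="outside"):
            ramp_response(dff, ramp)


class TestTransients:
    def test_flat_trace_has_no_events(self):
        dff = compute_dff(_trace([100.0] * 20))
        assert detect_transients(dff, 0.1, 1.0) == []

    def test_threshold_above_max_has_no_events(self):
        dff = compute_dff(_trace([100] * 5 + [150] * 5))
        assert detect_transients(dff, 5.0, 1.0) == []

    def test_three_small_peaks_then_spike(self):
        """Sparse sub-threshold-onset peaks followed by one large spike: four
        events, the last carrying the maximum amplitude."""
        f = np.full(100, 100.0)
        for i, amp in zip((10, 30, 50), (0.2, 0.25, 0.3)):
            f[i:i + 3] = 100 * (1 + amp)
        f[70:76] = 100 * (1 + 2.0)
        dff = compute_dff(_trace(f))
        events = detect_transients(dff, 0.1, 2.0)
        assert len(events) == 4
        assert events[-1].amplitude_dff == max(e.amplitude_dff for e in events)


class TestMip:
    def test_single_slice_is_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(max_intensity_projection(img[None]), img)

    def test_disjoint_bright_pixels_union(self):
        a = np.zeros((4, 4)); a[0, 0] = 9.0
        b = np.zeros((4, 4)); b[3, 3] = 7.0
        mip = max_intensity_projection(np.stack([a, b]))
        assert mip[0, 0] == 9.0 and mip[3, 3] == 7.0

    def test_matches_bruteforce_and_is_idempotent(self):
        rng = np.random.default_rng(5)
        stack = rng.random((6, 5, 7))
        mip = max_intensity_projection(stack)
        brute = np.zeros((5, 7))
        for i in range(5):
            for j in range(7):
                brute[i, j] = max(stack[z, i, j] for z in range(6))
        assert np.array_equal(mip, brute)
        assert np.array_equal(max_intensity_projection(mip[None]), mip)


class TestCampari:
    def test_fixed_ratio_everywhere(self):
        g = np.full((4, 8, 8), 50.0)
        r = 0.16 * g
        roi = np.ones((8, 8), bool)
        assert campari_ratio(g, r, roi).ratio_pct == pytest.approx(16.0)

    def test_equal_channels_read_100(self):
        g = np.random.default_rng(1).random((3, 6, 6)) + 1.0
        assert campari_ratio(g, g, np.ones((6, 6), bool)).ratio_pct == pytest.approx(100.0)

    def test_mip_differs_from_slice_mean_for_single_bright_voxel(self):
        g = np.full((5, 4, 4), 10.0)
        r = np.zeros((5, 4, 4))
        r[2, 1, 1] = 10.0  # one bright voxel in one slice
        roi = np.zeros((4, 4), bool)
        roi[1, 1] = True
        res = campari_ratio(g, r, roi)
        assert res.ratio_pct == pytest.approx(100.0)  # MIP sees the voxel
        slice_mean_ratio = r[:, 1, 1].mean() / g[:, 1, 1].mean() * 100
        assert slice_mean_ratio == pytest.approx(20.0)  # averaging dilutes it

    def test_zero_green_rejected(self):
        with pytest.raises(ZeroDivisionError):
            campari_ratio(np.zeros((2, 4, 4)), np.ones((2, 4, 4)),
                          np.ones((4, 4), bool))

    @settings(deadline=None, max_examples=25)
    @given(st.floats(min_value=0.01, max_value=1000.0))
    def test_common_gain_leaves_ratio_unchanged(self, gain):
        g, r, truth = generate_campari_stacks(CampariConfig(
            red_green_ratio_true=0.42, noise_sd=0.0))
        base = campari_ratio(g, r, truth.roi_mask).ratio_pct
        scaled = campari_ratio(gain * g, gain * r, truth.roi_mask).ratio_pct
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_configured_ratio_ordering_recovered(self):
        """Baseline photoconversion levels 16% < 42% < 55% keep their order."""
        measured = []
        for ratio in (0.16, 0.42, 0.55):
            g, r, truth = generate_campari_stacks(CampariConfig(
                red_green_ratio_true=ratio, noise_sd=1.5, seed=int(ratio * 100)))
            measured.append(campari_ratio(g, r, truth.roi_mask).ratio_pct)
        assert measured[0] < measured[1] < measured[2]
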