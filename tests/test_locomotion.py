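"""Speed, activity classification, bout segmentation and session summaries."""

import numpy as np
import pytest

from thermofly.locomotion import (
    ActivityRaster,
    StimulusEvent,
    Trajectory,
    classify_activity,
    compute_speed,
    raster_matrix,
    segment_bouts,
    startle_response,
    summarize_session,
)

DT = 0.2


def _traj(x, y, stimulus=None):
    n = len(x)
    return Trajectory(
        fly_id="f0", t=np.arange(n) * DT, x=np.asarray(x, float),
        y=np.asarray(y, float), stimulus=stimulus,
    )


def _raster(active):
    return ActivityRaster(active=np.asarray(active, bool), dt=DT, threshold_mm_s=1.0)


class TestSpeed:
    def test_stationary_fly_has_zero_speed(self):
        traj = _traj(np.full(50, 3.0), np.full(50, -2.0))
        assert np.all(compute_speed(traj) == 0.0)

    def test_straight_walk_at_constant_speed(self):
        # 1.24 mm per 0.2-s step = 6.2 mm/s, the printed 25 degC walking speed
        x = np.arange(100) * 1.24
        speed = compute_speed(_traj(x, np.zeros_like(x)))
        assert speed == pytest.approx(6.2)

    def test_pythagorean_displacement(self):
        # 3 mm east and 4 mm north in one step: 5 mm / 0.2 s = 25 mm/s
        speed = compute_speed(_traj([0.0, 3.0], [0.0, 4.0]))
        assert speed == pytest.approx([25.0])

    def test_non_uniform_grid_rejected(self):
        traj = _traj(np.zeros(4), np.zeros(4))
        traj.t = np.array([0.0, 0.2, 0.5, 0.7])
        with pytest.raises(ValueError, match="non-uniform"):
            compute_speed(traj)


class TestClassify:
    def test_zero_threshold_marks_everything_active(self):
        raster = classify_activity(np.array([0.0, 0.1, 5.0]), DT, 0.0)
        assert raster.percent_active == 100.0

    def test_all_subthreshold_is_inactive(self):
        raster = classify_activity(np.full(10, 0.3), DT, 1.0)
        assert raster.percent_active == 0.0

    def test_first_sample_inherits_second(self):
        raster = classify_activity(np.array([5.0, 0.0, 0.0]), DT, 1.0)
        assert list(raster.active) == [True, True, False, False]

    def test_percent_active_monotone_in_threshold(self, wt25_cohort):
        speed = compute_speed(wt25_cohort.trajectories[0])
        percents = [
            classify_activity(speed, DT, thr).percent_active
            for thr in (0.0, 0.5, 1.0, 2.0, 5.0, 20.0)
        ]
        assert all(a >= b for a, b in zip(percents, percents[1:]))


class TestSegmentation:
    def test_strict_alternation_recovers_construction(self):
        # 2 s walk / 3 s pause repeated over 60 min
        cycle = [True] * 10 + [False] * 15
        seg = segment_bouts(_raster(cycle * 720))
        walks = seg.intervals("walk")
        pauses = seg.intervals("pause")
        assert len(walks) == 720
        assert all(b.duration_s == pytest.approx(2.0) for b in walks)
        assert all(b.duration_s == pytest.approx(3.0) for b in pauses)

    def test_fully_active_session(self):
        seg = segment_bouts(_raster([True] * 100))
        assert len(seg.bouts) == 1
        bout = seg.bouts[0]
        assert bout.kind == "walk" and bout.censored_start and bout.censored_end
        assert len(seg.ibis(include_censored=True)) == 0

    def test_short_runs_merged_into_flank(self):
        # single-sample pause inside a walk disappears at min_ibi = 0.4 s
        active = [True] * 10 + [False] + [True] * 10
        seg = segment_bouts(_raster(active), min_bout_s=0.4, min_ibi_s=0.4)
        assert len(seg.bouts) == 1 and seg.bouts[0].kind == "walk"

    def test_walk_priority_on_tied_short_runs(self):
        # equal-length sub-minimum walk and pause runs: the pause is absorbed
        # first, so walking wins the contested samples
        active = [False] * 10 + [True] * 2 + [False] * 2 + [True] * 10
        seg = segment_bouts(_raster(active), min_bout_s=0.6, min_ibi_s=0.6)
        kinds = [b.kind for b in seg.bouts]
        assert kinds == ["pause", "walk"]
        assert seg.bouts[1].duration_s == pytest.approx(14 * DT)

    def test_edges_are_censored(self):
        seg = segment_bouts(_raster([False] * 5 + [True] * 5 + [False] * 5))
        assert seg.bouts[0].censored_start and seg.bouts[-1].censored_end
        assert not seg.bouts[1].censored

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tiling_conservation(self, seed):
        rng = np.random.default_rng(seed)
        raster = _raster(rng.random(500) < 0.6)
        seg = segment_bouts(raster, min_bout_s=0.6, min_ibi_s=0.4)
        total = sum(b.duration_s for b in seg.bouts)
        assert total == pytest.approx(500 * DT)
        starts = [b.start_s for b in seg.bouts]
        assert starts == sorted(starts)
        kinds = [b.kind for b in seg.bouts]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_matches_run_length_oracle_without_merging(self):
        rng = np.random.default_rng(3)
        active = np.repeat(rng.random(40) < 0.5, rng.integers(2, 8, 40))
        seg = segment_bouts(_raster(active), min_bout_s=DT, min_ibi_s=DT)
        # brute-force run-length encoding
        runs = []
        start = 0
        for i in range(1, len(active) + 1):
            if i == len(active) or active[i] != active[start]:
                runs.append((start * DT, i * DT, "walk" if active[start] else "pause"))
                start = i
        assert [(b.start_s, b.end_s, b.kind) for b in seg.bouts] == [
            (pytest.approx(a), pytest.approx(b), k) for a, b, k in runs
        ]


class TestSummaries:
    def test_fully_paused_session(self):
        traj = _traj(np.full(100, 1.0), np.zeros(100))
        speed = compute_speed(traj)
        seg = segment_bouts(classify_activity(speed, DT))
        s = summarize_session(traj, seg, speed=speed)
        assert s.percent_active == 0.0
        assert s.initiation_rate_per_s == 0.0
        assert s.n_bouts == 0

    def test_parameter_recovery_against_generator_truth(self, wt25_cohort):
        """Cohort means of measured metrics sit within 10% of generator truth."""
        truth = wt25_cohort.truth
        measured = wt25_cohort.per_fly
        true_frac = np.mean([f.fraction_active for f in truth.flies]) * 100
        assert measured["percent_active"].mean() == pytest.approx(true_frac, rel=0.10)
        true_speed = np.mean([f.mean_speed_mm_s for f in truth.flies])
        assert measured["mean_speed_active_mm_s"].mean() == pytest.approx(true_speed, rel=0.10)
        true_bout = np.mean([f.bout_durations_s.mean() for f in truth.flies])
        assert measured["mean_bout_s"].mean() == pytest.approx(true_bout, rel=0.10)


class TestStartle:
    def test_no_speed_change_gives_zero(self):
        stim = StimulusEvent(onset_s=20.0)
        x = np.arange(300) * 1.0  # constant 5 mm/s throughout
        res = startle_response(_traj(x, np.zeros_like(x), stim), window_s=10.0)
        assert res.delta_speed_mm_s == pytest.approx(0.0)

    def test_missing_stimulus_rejected(self):
        with pytest.raises(ValueError, match="stimulus"):
            startle_response(_traj(np.zeros(100), np.zeros(100)), window_s=5.0)

    def test_positive_startle_recovered_from_generator(self):
        from thermofly.io import analyze_cohort
        from thermofly.synthetic import generate_locomotor_session, preset_config

        cfg = preset_config("wt25", n_flies=25, seed=42)
        trajs, _ = generate_locomotor_session(cfg)
        per_fly, _ = analyze_cohort(trajs)
        # configured startle is +2.4 mm/s (the printed 25 degC arousal)
        assert per_fly["startle_delta_mm_s"].mean() == pytest.approx(2.4, abs=0.6)

    def test_negative_startle_yields_negative_delta(self):
        from thermofly.io import analyze_cohort
        from thermofly.synthetic import generate_locomotor_session, preset_config

        cfg = preset_config("R59B10-shi31", n_flies=25, seed=43)
        trajs, _ = generate_locomotor_session(cfg)
        per_fly, _ = analyze_cohort(trajs)
        assert per_fly["startle_delta_mm_s"].mean() < 0


class TestRasterMatrix:
    def test_single_fully_active_fly(self):
        mat, mean = raster_matrix([_raster([True] * 8)])
        assert mat.shape == (1, 8) and np.all(mat)
        assert np.all(mean == 1.0)

    def test_complementary_rasters_average_to_half(self):
        a = _raster([True, False] * 6)
        b = _raster([False, True] * 6)
        _, mean = raster_matrix([a, b])
        assert np.all(mean == 0.5)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            raster_matrix([_raster([True] * 5), _raster([True] * 6)])

    def test_warm_cohort_curve_dominates_cool_cohort(self, wt25_cohort, wt31_cohort):
        from thermofly.locomotion import classify_activity, compute_speed

        def curve(cohort, n=30):
            rasters = []
            for traj in cohort.trajectories[:n]:
                rasters.append(classify_activity(compute_speed(traj), traj.dt))
            return raster_matrix(rasters)[1]

        cool, warm = curve(wt25_cohort), curve(wt31_cohort)
        # smooth to 1-min bins, then the 31 degC curve should dominate
        cool_b = cool[: len(cool) // 300 * 300].reshape(-1, 300).mean(axis=1)
        warm_b = warm[: len(warm) // 300 * 300].reshape(-1, 300).mean(axis=1)
        assert np.mean(warm_b > cool_b) >= 0.95
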