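"""Open-field locomotor analysis: activity classification, bout segmentation
and summary metrics for single-fly arena trajectories.

A trajectory is a uniformly sampled (default 0.2 s) position time series of one
fly in a circular arena. The analysis proceeds in four steps:

1. instantaneous speed from finite-difference displacement,
2. per-step active/inactive classification against a speed threshold,
3. run-length segmentation into alternating walking bouts and inter-bout
   intervals (IBIs), with edge intervals flagged as censored,
4. session summaries: percent time active, mean walking speed, action
   initiation rate (bout onsets per second of inactive time), mean bout and
   IBI durations, and the startle response to a mechanical stimulus.

The initiation rate is defined per second of *inactive* time, which makes it
the reciprocal of the mean IBI for a stationary two-state process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "StimulusEvent",
    "Trajectory",
    "ActivityRaster",
    "Bout",
    "BoutSegmentation",
    "LocomotorSummary",
    "StartleResult",
    "DEFAULT_ACTIVITY_THRESHOLD_MM_S",
    "DEFAULT_MIN_BOUT_S",
    "DEFAULT_MIN_IBI_S",
    "DEFAULT_STARTLE_WINDOW_S",
    "compute_speed",
    "classify_activity",
    "segment_bouts",
    "summarize_session",
    "startle_response",
    "raster_matrix",
    "analyze_trajectory",
]

#: Instantaneous speed (mm/s) at or above which a sample counts as active.
DEFAULT_ACTIVITY_THRESHOLD_MM_S = 1.0
#: Minimum run durations; one sample at 0.2-s sampling, i.e. no sub-resolution
#: merging by default.  See docs/methods.md for why this matters with
#: heavy-tailed pause distributions.
DEFAULT_MIN_BOUT_S = 0.2
DEFAULT_MIN_IBI_S = 0.2
#: Pre/post averaging window around the mechanical stimulus.
DEFAULT_STARTLE_WINDOW_S = 60.0

_REL_TOL = 1e-6


@dataclass(frozen=True)
class StimulusEvent:
    """Mechanical (vibration) stimulus: a train of pulses.

    Defaults follow the assay protocol: 5 pulses of 200 ms separated by
    800 ms gaps, delivered 30 min into the session.
    """

    onset_s: float = 1800.0
    n_pulses: int = 5
    pulse_ms: float = 200.0
    gap_ms: float = 800.0

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("stimulus onset must be non-negative")
        if self.n_pulses < 0:
            raise ValueError("n_pulses must be >= 0")

    @property
    def span_s(self) -> float:
        """Total duration of the pulse train (4.2 s for the defaults)."""
        if self.n_pulses == 0:
            return 0.0
        total_ms = self.n_pulses * self.pulse_ms + (self.n_pulses - 1) * self.gap_ms
        return total_ms / 1000.0

    @property
    def end_s(self) -> float:
        return self.onset_s + self.span_s


@dataclass
class Trajectory:
    """Position time series of one fly in a circular arena.

    ``t`` must be uniform; ``x``/``y`` are in mm with the arena center at the
    origin.
    """

    fly_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena_diameter_mm: float = 35.0
    stimulus: Optional[StimulusEvent] = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")

    @property
    def dt(self) -> float:
        if len(self.t) < 2:
            raise ValueError("need >= 2 samples to define a sampling step")
        return float(self.t[1] - self.t[0])

    @property
    def duration_s(self) -> float:
        return float(len(self.t)) * self.dt


@dataclass
class ActivityRaster:
    """Per-sample active/inactive flags aligned to a trajectory's time grid."""

    active: np.ndarray  # bool, same length as t
    dt: float
    threshold_mm_s: float

    def __len__(self) -> int:
        return len(self.active)

    @property
    def percent_active(self) -> float:
        return float(np.mean(self.active)) * 100.0


@dataclass
class Bout:
    start_s: float
    end_s: float
    kind: str  # "walk" | "pause"
    censored_start: bool = False
    censored_end: bool = False

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("bout must have positive duration")
        if self.kind not in ("walk", "pause"):
            raise ValueError("kind must be 'walk' or 'pause'")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def censored(self) -> bool:
        return self.censored_start or self.censored_end


@dataclass
class BoutSegmentation:
    """Alternating walk/pause intervals tiling the session, plus the raster
    they were derived from (after any short-run merging)."""

    bouts: list[Bout]
    raster: ActivityRaster

    def intervals(self, kind: str, censored: Optional[bool] = None) -> list[Bout]:
        out = [b for b in self.bouts if b.kind == kind]
        if censored is not None:
            out = [b for b in out if b.censored == censored]
        return out

    def ibis(self, include_censored: bool = False) -> np.ndarray:
        """Inter-bout-interval (pause) durations in seconds."""
        sel = self.intervals("pause", None if include_censored else False)
        return np.array([b.duration_s for b in sel], dtype=float)

    def bout_durations(self, include_censored: bool = False) -> np.ndarray:
        sel = self.intervals("walk", None if include_censored else False)
        return np.array([b.duration_s for b in sel], dtype=float)


@dataclass
class LocomotorSummary:
    fly_id: str
    percent_active: float
    mean_speed_active_mm_s: float
    initiation_rate_per_s: float  # NaN sentinel when pause time is zero
    mean_bout_s: float
    mean_ibi_s: float
    n_bouts: int
    condition: str = ""


@dataclass
class StartleResult:
    delta_speed_mm_s: float
    pre_window_s: float
    post_window_s: float
    pre_mean_mm_s: float
    post_mean_mm_s: float


def compute_speed(traj: Trajectory) -> np.ndarray:
    """Instantaneous speed (mm/s) from finite-difference displacement.

    Returns ``len(t) - 1`` values; entry ``i`` is the speed over the step from
    sample ``i`` to ``i + 1``.
    """
    if len(traj.t) < 2:
        raise ValueError("need at least 2 samples to compute speed")
    dts = np.diff(traj.t)
    dt = dts[0]
    if np.any(np.abs(dts - dt) > _REL_TOL * max(dt, 1.0)):
        raise ValueError("non-uniform timestamps; resample before analysis")
    disp = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return disp / dt


def classify_activity(
    speed: np.ndarray,
    dt: float,
    threshold_mm_s: float = DEFAULT_ACTIVITY_THRESHOLD_MM_S,
) -> ActivityRaster:
    """Threshold the speed series into a per-sample activity raster.

    Sample ``i`` (``i >= 1``) is active iff ``speed[i-1] >= threshold``; the
    first sample inherits the second sample's class since no displacement
    precedes it.
    """
    if threshold_mm_s < 0:
        raise ValueError("threshold must be >= 0")
    speed = np.asarray(speed, dtype=float)
    active = np.empty(len(speed) + 1, dtype=bool)
    active[1:] = speed >= threshold_mm_s
    active[0] = active[1] if len(speed) else False
    return ActivityRaster(active=active, dt=dt, threshold_mm_s=threshold_mm_s)


def _runs(active: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode a boolean array into (start, stop, value) triples."""
    edges = np.flatnonzero(np.diff(active.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [len(active)]))
    return [
        (int(bounds[i]), int(bounds[i + 1]), bool(active[bounds[i]]))
        for i in range(len(bounds) - 1)
    ]


def segment_bouts(
    raster: ActivityRaster,
    min_bout_s: float = DEFAULT_MIN_BOUT_S,
    min_ibi_s: float = DEFAULT_MIN_IBI_S,
) -> BoutSegmentation:
    """Segment the raster into alternating walk bouts and IBIs.

    Runs shorter than their minimum duration are merged into the flanking
    state, shortest first; on a duration tie a pause run is merged before a
    walk run (walk priority). The first and last intervals are flagged
    censored at the session edge.
    """
    if len(raster) == 0:
        raise ValueError("empty raster")
    dt = raster.dt
    runs = _runs(raster.active.copy())

    min_steps = {
        True: max(1, int(round(min_bout_s / dt))),
        False: max(1, int(round(min_ibi_s / dt))),
    }

    def too_short(run: tuple[int, int, bool]) -> bool:
        return (run[1] - run[0]) < min_steps[run[2]]

    while len(runs) > 1:
        short = [(r[1] - r[0], 0 if not r[2] else 1, i) for i, r in enumerate(runs) if too_short(r)]
        if not short:
            break
        # shortest first; ties resolved pause-first so short pauses are
        # absorbed into walking (walk priority)
        _, _, idx = min(short)
        start, stop, val = runs.pop(idx)
        merged = (start, stop, not val)
        runs.insert(idx, merged)
        # coalesce with equal-valued neighbours
        i = idx
        if i + 1 < len(runs) and runs[i + 1][2] == runs[i][2]:
            a, b = runs[i], runs.pop(i + 1)
            runs[i] = (a[0], b[1], a[2])
        if i - 1 >= 0 and runs[i - 1][2] == runs[i][2]:
            a, b = runs.pop(i - 1), runs[i - 1]
            runs[i - 1] = (a[0], b[1], a[2])

    active = np.empty(len(raster), dtype=bool)
    for start, stop, val in runs:
        active[start:stop] = val
    merged_raster = ActivityRaster(active=active, dt=dt, threshold_mm_s=raster.threshold_mm_s)

    bouts: list[Bout] = []
    for start, stop, val in runs:
        bouts.append(
            Bout(
                start_s=start * dt,
                end_s=stop * dt,
                kind="walk" if val else "pause",
                censored_start=start == 0,
                censored_end=stop == len(raster),
            )
        )
    return BoutSegmentation(bouts=bouts, raster=merged_raster)


def summarize_session(
    traj: Trajectory,
    segmentation: BoutSegmentation,
    speed: Optional[np.ndarray] = None,
) -> LocomotorSummary:
    """Session-level locomotor metrics from a trajectory and its segmentation.

    * percent_active: active samples / total samples x 100
    * mean_speed_active: mean instantaneous speed over active samples only
    * initiation_rate: uncensored walk-bout onsets per second of total pause
      time (NaN when there is no pause time)
    * mean_bout / mean_ibi exclude censored edge intervals
    """
    if speed is None:
        speed = compute_speed(traj)
    raster = segmentation.raster
    if len(raster) != len(traj.t):
        raise ValueError("segmentation does not match trajectory grid")

    percent_active = raster.percent_active
    active_steps = raster.active[1:]  # speed[i] describes the step ending at i+1
    mean_speed = float(np.mean(speed[active_steps])) if np.any(active_steps) else 0.0

    pause_time = sum(b.duration_s for b in segmentation.intervals("pause"))
    onsets = len([b for b in segmentation.intervals("walk") if not b.censored_start])
    if pause_time > 0:
        initiation_rate = onsets / pause_time
    elif onsets == 0:
        initiation_rate = 0.0 if percent_active == 0.0 else float("nan")
    else:
        initiation_rate = float("nan")

    bouts = segmentation.bout_durations()
    ibis = segmentation.ibis()
    return LocomotorSummary(
        fly_id=traj.fly_id,
        percent_active=percent_active,
        mean_speed_active_mm_s=mean_speed,
        initiation_rate_per_s=initiation_rate,
        mean_bout_s=float(np.mean(bouts)) if len(bouts) else 0.0,
        mean_ibi_s=float(np.mean(ibis)) if len(ibis) else 0.0,
        n_bouts=len(segmentation.intervals("walk")),
        condition=traj.condition,
    )


def startle_response(
    traj: Trajectory,
    window_s: float = DEFAULT_STARTLE_WINDOW_S,
    speed: Optional[np.ndarray] = None,
) -> StartleResult:
    """Mean-speed contrast across the mechanical stimulus.

    delta = mean speed over (stim_end, stim_end + window] minus mean speed
    over [stim_start - window, stim_start); the stimulus span itself is
    excluded.
    """
    if traj.stimulus is None:
        raise ValueError("trajectory has no stimulus event")
    stim = traj.stimulus
    if stim.onset_s - window_s < 0 or stim.end_s + window_s > traj.duration_s:
        raise ValueError("startle window does not fit within the session")
    if speed is None:
        speed = compute_speed(traj)
    # speed[i] covers [t[i], t[i+1]); use the step midpoint for window tests
    mid = traj.t[:-1] + traj.dt / 2.0
    pre = (mid >= stim.onset_s - window_s) & (mid < stim.onset_s)
    post = (mid > stim.end_s) & (mid <= stim.end_s + window_s)
    pre_mean = float(np.mean(speed[pre]))
    post_mean = float(np.mean(speed[post]))
    return StartleResult(
        delta_speed_mm_s=post_mean - pre_mean,
        pre_window_s=window_s,
        post_window_s=window_s,
        pre_mean_mm_s=pre_mean,
        post_mean_mm_s=post_mean,
    )


def raster_matrix(rasters: Sequence[ActivityRaster]) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-fly rasters into a fly x time boolean matrix.

    Returns the matrix and the per-step population activity fraction (column
    mean). All rasters must share length and sampling step.
    """
    if not rasters:
        raise ValueError("no rasters given")
    n = len(rasters[0])
    dt = rasters[0].dt
    for r in rasters:
        if len(r) != n or not math.isclose(r.dt, dt, rel_tol=_REL_TOL):
            raise ValueError("rasters do not share a common time grid")
    mat = np.stack([r.active for r in rasters])
    return mat, mat.mean(axis=0)


def analyze_trajectory(
    traj: Trajectory,
    threshold_mm_s: float = DEFAULT_ACTIVITY_THRESHOLD_MM_S,
    min_bout_s: float = DEFAULT_MIN_BOUT_S,
    min_ibi_s: float = DEFAULT_MIN_IBI_S,
    startle_window_s: float = DEFAULT_STARTLE_WINDOW_S,
) -> tuple[LocomotorSummary, BoutSegmentation, Optional[StartleResult]]:
    """Convenience wrapper: speed -> raster -> segmentation -> summaries."""
    speed = compute_speed(traj)
    raster = classify_activity(speed, traj.dt, threshold_mm_s)
    seg = segment_bouts(raster, min_bout_s, min_ibi_s)
    summary = summarize_session(traj, seg, speed=speed)
    startle = None
    if traj.stimulus is not None and traj.stimulus.n_pulses > 0:
        try:
            startle = startle_response(traj, startle_window_s, speed=speed)
        except ValueError:
            startle = None
    return summary, seg, startle
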