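"""Calcium-imaging quantification: GCaMP dF/F0 ramp responses and CaMPARI
red/green photoconversion ratios.

GCaMP movies are (frames, H, W) arrays with an accompanying temperature
trace. ROI mean-intensity traces are converted to dF/F0 with the baseline F0
taken as the mean of the first five frames (acquired before any temperature
change), and a ramp response is the peak and average dF/F0 over the
20->35->20 degC ramp, in percent.

CaMPARI stacks are paired green/red z-stacks; the readout is the red/green
ratio of ROI means on the maximum-intensity projection, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .synthetic import TemperatureRamp

__all__ = [
    "RoiTrace",
    "DffTrace",
    "RampResponse",
    "TransientEvent",
    "CampariResult",
    "DEFAULT_BASELINE_FRAMES",
    "extract_roi_traces",
    "compute_dff",
    "ramp_response",
    "detect_transients",
    "max_intensity_projection",
    "campari_ratio",
]

#: Number of initial frames averaged for the F0 baseline.
DEFAULT_BASELINE_FRAMES = 5


@dataclass
class RoiTrace:
    roi_id: str
    intensity: np.ndarray  # mean intensity per frame
    frame_times_s: np.ndarray


@dataclass
class DffTrace:
    f0: float
    dff: np.ndarray  # (F - F0)/F0
    frame_times_s: np.ndarray


@dataclass
class RampResponse:
    peak_dff_pct: float
    average_dff_pct: float
    temp_at_peak_c: float


@dataclass
class TransientEvent:
    onset_time_s: float
    onset_temp_c: float  # NaN when no ramp is supplied
    amplitude_dff: float


@dataclass
class CampariResult:
    ratio_pct: float
    roi_area_px: int


def extract_roi_traces(
    stack: np.ndarray,
    rois: dict[str, np.ndarray],
    frame_times_s: Optional[np.ndarray] = None,
) -> list[RoiTrace]:
    """Mean pixel intensity within each ROI mask, per frame."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, H, W)")
    n_frames = stack.shape[0]
    if frame_times_s is None:
        frame_times_s = np.arange(n_frames, dtype=float)
    traces = []
    for roi_id, mask in rois.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != stack.shape[1:]:
            raise ValueError(f"ROI {roi_id!r} does not match frame shape")
        if not mask.any():
            raise ValueError(f"ROI {roi_id!r} is empty")
        traces.append(RoiTrace(
            roi_id=roi_id,
            intensity=stack[:, mask].mean(axis=1),
            frame_times_s=np.asarray(frame_times_s, dtype=float),
        ))
    return traces


def compute_dff(trace: RoiTrace, n_baseline: int = DEFAULT_BASELINE_FRAMES) -> DffTrace:
    """dF/F0 with F0 the mean of the first ``n_baseline`` frames."""
    f = np.asarray(trace.intensity, dtype=float)
    if len(f) < n_baseline + 1:
        raise ValueError(f"need more than {n_baseline} frames")
    f0 = float(f[:n_baseline].mean())
    if f0 <= 0:
        raise ValueError(f"non-positive baseline F0 = {f0}")
    return DffTrace(f0=f0, dff=(f - f0) / f0, frame_times_s=trace.frame_times_s)


def _align_temp(ramp: TemperatureRamp, frame_times_s: np.ndarray) -> np.ndarray:
    """Nearest-time interpolation of the temperature trace onto frame times."""
    t = np.asarray(ramp.time_s, dtype=float)
    if len(t) == 0:
        raise ValueError("empty temperature trace")
    lo, hi = t[0], t[-1]
    ft = np.asarray(frame_times_s, dtype=float)
    if ft[0] < lo - 0.5 * max(1.0, hi - lo) or ft[-1] > hi + 0.5 * max(1.0, hi - lo):
        raise ValueError("frame times lie far outside the temperature trace")
    idx = np.clip(np.searchsorted(t, ft), 1, len(t) - 1)
    nearest = np.where(np.abs(t[idx - 1] - ft) <= np.abs(t[idx] - ft), idx - 1, idx)
    return ramp.temp_c[nearest]


def ramp_response(dff: DffTrace, ramp: TemperatureRamp) -> RampResponse:
    """Peak and average dF/F0 (percent) over the temperature ramp.

    The peak is the first maximum; its temperature is read from the ramp
    aligned to frame times by nearest-time interpolation.
    """
    temp = _align_temp(ramp, dff.frame_times_s)
    i_peak = int(np.argmax(dff.dff))
    return RampResponse(
        peak_dff_pct=float(dff.dff[i_peak]) * 100.0,
        average_dff_pct=float(np.mean(dff.dff)) * 100.0,
        temp_at_peak_c=float(temp[i_peak]),
    )


def detect_transients(
    dff: DffTrace,
    threshold: float,
    min_separation_s: float,
    ramp: Optional[TemperatureRamp] = None,
) -> list[TransientEvent]:
    """Upward threshold crossings of dF/F0 separated by >= min_separation_s.

    Each event reports its onset time, the bath temperature at onset (when a
    ramp is supplied) and the maximum dF/F0 reached before the trace next
    falls below threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    y = dff.dff
    t = dff.frame_times_s
    above = y >= threshold
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        onsets = np.concatenate(([0], onsets))
    temp = _align_temp(ramp, t) if ramp is not None else None

    events: list[TransientEvent] = []
    last_t = -np.inf
    for i in onsets:
        if t[i] - last_t < min_separation_s:
            continue
        last_t = t[i]
        j = i
        while j < len(y) and y[j] >= threshold:
            j += 1
        events.append(TransientEvent(
            onset_time_s=float(t[i]),
            onset_temp_c=float(temp[i]) if temp is not None else float("nan"),
            amplitude_dff=float(np.max(y[i:j])),
        ))
    return events


def max_intensity_projection(zstack: np.ndarray) -> np.ndarray:
    """Pixel-wise maximum over z-slices."""
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim == 2:  # a projection already
        return zstack
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ValueError("z-stack must be (slices, H, W) with >= 1 slice")
    return zstack.max(axis=0)


def campari_ratio(green: np.ndarray, red: np.ndarray, roi: np.ndarray) -> CampariResult:
    """Red/green photoconversion ratio (percent) on MIP ROI means."""
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape:
        raise ValueError("green and red stacks must share geometry")
    roi = np.asarray(roi, dtype=bool)
    g_mip = max_intensity_projection(green)
    r_mip = max_intensity_projection(red)
    if roi.shape != g_mip.shape:
        raise ValueError("ROI does not match projected frame shape")
    if not roi.any():
        raise ValueError("empty ROI")
    g_mean = float(g_mip[roi].mean())
    if g_mean <= 0:
        raise ZeroDivisionError("no green signal in ROI; ratio undefined")
    return CampariResult(
        ratio_pct=float(r_mip[roi].mean()) / g_mean * 100.0,
        roi_area_px=int(roi.sum()),
    )
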