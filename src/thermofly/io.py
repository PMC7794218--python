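"""File formats, configuration and the simulate -> analyze -> report pipeline.

Trajectories travel as long-form CSV with columns ``fly_id, t_s, x_mm, y_mm``
plus optional ``condition`` and ``stimulus_onset_s``; image stacks as
multi-page grayscale TIFF (one file per channel); results as CSV tables with
a JSON provenance block (config hash, seed, package version). Re-running the
pipeline with the same configuration and seed reproduces every output file
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .burstiness import InsufficientDataError, fit_weibull_cdf
from .gstats import GroupSample, compare_two, summary_table
from .locomotion import (
    DEFAULT_ACTIVITY_THRESHOLD_MM_S,
    DEFAULT_MIN_BOUT_S,
    DEFAULT_MIN_IBI_S,
    DEFAULT_STARTLE_WINDOW_S,
    StimulusEvent,
    Trajectory,
    analyze_trajectory,
)
from .synthetic import GroundTruth, generate_locomotor_session, preset_config

__all__ = [
    "AnalysisConfig",
    "ResultsBundle",
    "read_trajectories_csv",
    "write_trajectories_csv",
    "read_temperature_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "analyze_cohort",
    "run_pipeline",
    "write_results",
]

log = logging.getLogger("thermofly")

_REQUIRED_COLUMNS = ("fly_id", "t_s", "x_mm", "y_mm")
_REL_TOL = 1e-6

#: Locomotor metrics compared between conditions in the statistics stage.
_STAT_METRICS = (
    "percent_active",
    "mean_speed_active_mm_s",
    "initiation_rate_per_s",
    "mean_bout_s",
    "mean_ibi_s",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the pipeline needs; all defaults overridable."""

    presets: tuple[str, ...] = ("wt25", "wt31")
    n_flies: int = 100
    input_csv: Optional[str] = None
    activity_threshold_mm_s: float = DEFAULT_ACTIVITY_THRESHOLD_MM_S
    min_bout_s: float = DEFAULT_MIN_BOUT_S
    min_ibi_s: float = DEFAULT_MIN_IBI_S
    startle_window_s: float = DEFAULT_STARTLE_WINDOW_S
    baseline_frames: int = 5
    spike_threshold_mv: float = -20.0
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "thermofly_results"

    def __post_init__(self) -> None:
        if self.activity_threshold_mm_s < 0 or self.min_bout_s < 0 or self.min_ibi_s < 0:
            raise ValueError("thresholds must be >= 0")
        if self.baseline_frames < 1:
            raise ValueError("baseline_frames must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "presets" in raw:
            raw["presets"] = tuple(raw["presets"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["presets"] = list(self.presets)
        return d


@dataclass
class ResultsBundle:
    per_fly: pd.DataFrame
    conditions: pd.DataFrame
    stats: Optional[pd.DataFrame]
    provenance: dict


# ---------------------------------------------------------------------------
# trajectory CSV


def write_trajectories_csv(trajs: Sequence[Trajectory], path: str | Path) -> None:
    frames = []
    for traj in trajs:
        df = pd.DataFrame({
            "fly_id": traj.fly_id,
            "t_s": traj.t,
            "x_mm": traj.x,
            "y_mm": traj.y,
        })
        if traj.condition:
            df["condition"] = traj.condition
        if traj.stimulus is not None:
            df["stimulus_onset_s"] = traj.stimulus.onset_s
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories_csv(
    path: str | Path,
    arena_diameter_mm: float = 35.0,
) -> list[Trajectory]:
    """Read and validate a trajectory CSV into per-fly trajectories.

    Rows may arrive in any order; they are sorted by (fly_id, t_s). A
    non-uniform time grid raises a format error naming the offending row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV is missing columns: {', '.join(missing)}")
    df = df.sort_values(["fly_id", "t_s"], kind="stable")
    trajs = []
    for fly_id, sub in df.groupby("fly_id", sort=True):
        t = sub["t_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError(f"fly {fly_id!r}: need >= 2 samples")
        dts = np.diff(t)
        dt = dts[0]
        bad = np.flatnonzero(np.abs(dts - dt) > _REL_TOL * max(dt, 1.0))
        if len(bad):
            i = int(bad[0])
            raise ValueError(
                f"fly {fly_id!r}: non-uniform time grid at t_s={t[i + 1]:g} "
                f"(gap {dts[i]:g} s, expected {dt:g} s)"
            )
        stim = None
        if "stimulus_onset_s" in sub.columns and not sub["stimulus_onset_s"].isna().all():
            stim = StimulusEvent(onset_s=float(sub["stimulus_onset_s"].iloc[0]))
        condition = ""
        if "condition" in sub.columns and not sub["condition"].isna().all():
            condition = str(sub["condition"].iloc[0])
        trajs.append(Trajectory(
            fly_id=str(fly_id), t=t,
            x=sub["x_mm"].to_numpy(dtype=float),
            y=sub["y_mm"].to_numpy(dtype=float),
            arena_diameter_mm=arena_diameter_mm,
            stimulus=stim, condition=condition,
        ))
    return trajs


def read_temperature_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    for col in ("t_s", "temp_c"):
        if col not in df.columns:
            raise ValueError(f"temperature CSV is missing column {col!r}")
    return df["t_s"].to_numpy(dtype=float), df["temp_c"].to_numpy(dtype=float)


def write_stack_tiff(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_stack_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# pipeline


def analyze_cohort(
    trajs: Sequence[Trajectory],
    config: Optional[AnalysisConfig] = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-fly locomotor summaries plus pooled IBIs per condition."""
    cfg = config or AnalysisConfig()
    rows = []
    pooled: dict[str, list[np.ndarray]] = {}
    for traj in trajs:
        summary, seg, startle = analyze_trajectory(
            traj,
            threshold_mm_s=cfg.activity_threshold_mm_s,
            min_bout_s=cfg.min_bout_s,
            min_ibi_s=cfg.min_ibi_s,
            startle_window_s=cfg.startle_window_s,
        )
        rows.append({
            "fly_id": summary.fly_id,
            "condition": summary.condition,
            "percent_active": summary.percent_active,
            "mean_speed_active_mm_s": summary.mean_speed_active_mm_s,
            "initiation_rate_per_s": summary.initiation_rate_per_s,
            "mean_bout_s": summary.mean_bout_s,
            "mean_ibi_s": summary.mean_ibi_s,
            "n_bouts": summary.n_bouts,
            "startle_delta_mm_s": startle.delta_speed_mm_s if startle else np.nan,
        })
        pooled.setdefault(traj.condition, []).append(seg.ibis())
    per_fly = pd.DataFrame(rows).sort_values(["condition", "fly_id"],
                                             kind="stable").reset_index(drop=True)
    pooled_ibis = {
        cond: (np.concatenate(parts) if parts else np.array([]))
        for cond, parts in pooled.items()
    }
    return per_fly, pooled_ibis


def _condition_table(per_fly: pd.DataFrame,
                     pooled_ibis: dict[str, np.ndarray],
                     grid_s: Optional[float] = None) -> pd.DataFrame:
    rows = []
    for cond, sub in per_fly.groupby("condition", sort=True):
        row = {"condition": cond, "n_flies": len(sub)}
        for metric in _STAT_METRICS + ("startle_delta_mm_s",):
            row[metric] = float(np.nanmean(sub[metric]))
        ibis = pooled_ibis.get(cond, np.array([]))
        try:
            fit = fit_weibull_cdf(ibis, grid_s=grid_s)
            row.update(weibull_shape_k=fit.shape_k, weibull_scale_s=fit.scale_lambda,
                       n_ibis=fit.n_intervals, weibull_rmse=fit.rmse_cdf)
        except (InsufficientDataError, ValueError):
            row.update(weibull_shape_k=np.nan, weibull_scale_s=np.nan,
                       n_ibis=len(ibis), weibull_rmse=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: AnalysisConfig) -> ResultsBundle:
    """simulate (optional) -> locomotion -> burstiness -> statistics.

    With ``input_csv`` set, trajectories are read from disk; otherwise the
    named presets are simulated with ``n_flies`` flies each. Conditions after
    the first are compared against the first (reference) condition with
    two-sample tests per metric.
    """
    stage = "simulate"
    try:
        if config.input_csv:
            stage = "read"
            log.info("reading trajectories from %s", config.input_csv)
            trajs = read_trajectories_csv(config.input_csv)
        else:
            trajs = []
            for i, preset in enumerate(config.presets):
                cfg = preset_config(preset, n_flies=config.n_flies,
                                    seed=config.seed + i)
                log.info("simulating %s: %d flies, seed %d",
                         preset, cfg.n_flies, cfg.seed)
                cohort, _truth = generate_locomotor_session(cfg)
                trajs.extend(cohort)

        stage = "locomotion"
        per_fly, pooled_ibis = analyze_cohort(trajs, config)
        stage = "burstiness"
        grid_s = trajs[0].dt if trajs else None
        conditions = _condition_table(per_fly, pooled_ibis, grid_s=grid_s)

        stage = "statistics"
        stats_df = None
        cond_names = list(conditions["condition"])
        if len(cond_names) >= 2:
            ref = cond_names[0]
            results = []
            for other in cond_names[1:]:
                for metric in _STAT_METRICS:
                    a = per_fly.loc[per_fly["condition"] == ref, metric].dropna()
                    b = per_fly.loc[per_fly["condition"] == other, metric].dropna()
                    if len(a) < 3 or len(b) < 3:
                        continue
                    results.append(compare_two(
                        GroupSample(ref, a.to_numpy()),
                        GroupSample(other, b.to_numpy()),
                        metric=metric, alpha=config.alpha,
                    ))
            if results:
                stats_df = summary_table(results)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
    }
    return ResultsBundle(per_fly=per_fly, conditions=conditions,
                         stats=stats_df, provenance=provenance)


def write_results(bundle: ResultsBundle, outdir: str | Path) -> list[Path]:
    """Write CSV tables and the JSON provenance block; stable column order."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in (("per_fly", bundle.per_fly), ("conditions", bundle.conditions),
                     ("stats", bundle.stats)):
        if df is None or len(df) == 0:
            continue
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    prov = out / "provenance.json"
    with open(prov, "w", encoding="utf-8") as fh:
        json.dump(bundle.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(prov)
    return written
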