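"""Shared fixtures: simulated cohorts analyzed once per session.

The cohorts mirror the study conditions (100 flies, 60 min at 0.2-s
sampling) with the printed per-condition parameters; no mechanical stimulus
is included so that activity and initiation-rate recovery can be checked
against the pure two-state renewal process.
"""

from dataclasses import dataclass

import pandas as pd
import pytest

from thermofly.io import analyze_cohort
from thermofly.synthetic import GroundTruth, generate_locomotor_session, preset_config

N_FLIES = 100


@dataclass
class Cohort:
    trajectories: list
    truth: GroundTruth
    per_fly: pd.DataFrame
    pooled_ibis: dict


def _make_cohort(preset: str, seed: int) -> Cohort:
    cfg = preset_config(preset, n_flies=N_FLIES, seed=seed, stimulus=None)
    trajs, truth = generate_locomotor_session(cfg)
    per_fly, pooled = analyze_cohort(trajs)
    return Cohort(trajs, truth, per_fly, pooled)


@pytest.fixture(scope="session")
def wt31_cohort() -> Cohort:
    return _make_cohort("wt31", seed=310)


@pytest.fixture(scope="session")
def wt25_cohort() -> Cohort:
    return _make_cohort("wt25", seed=250)


@pytest.fixture(scope="session")
def eb1_cohort() -> Cohort:
    return _make_cohort("EB1-shi31", seed=311)
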