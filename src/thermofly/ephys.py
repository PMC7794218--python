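"""Current-clamp feature extraction and liquid-junction-potential calculation.

Spike detection is upward threshold crossing with a refractory lockout; a
sustained depolarized plateau therefore contributes a single crossing, which
matches the depolarization-block phenotype where spiking ceases. Passive
properties come from hyperpolarizing steps (resting membrane potential from
the pre-step baseline, input resistance from the Ohmic steady-state
deflection). Burst metrics group spikes by an inter-spike-interval gap.

The liquid junction potential between pipette and bath solutions is computed
with the generalized Henderson equation using a bundled table of limiting
ionic mobilities (relative to K+), the standard approach of junction
potential calculators. The returned value is the potential of the bath
relative to the pipette — the number to subtract from recorded membrane
voltages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .synthetic import VoltageStep

__all__ = [
    "SpikeTrain",
    "FICurve",
    "PassiveProperties",
    "BurstMetrics",
    "SolutionSpec",
    "ION_TABLE",
    "INTRACELLULAR_SOLUTION",
    "EXTRACELLULAR_SALINE",
    "detect_spikes",
    "fi_curve",
    "passive_properties",
    "burst_metrics",
    "henderson_ljp",
    "DEFAULT_SPIKE_THRESHOLD_MV",
    "DEFAULT_REFRACTORY_MS",
]

DEFAULT_SPIKE_THRESHOLD_MV = -20.0
DEFAULT_REFRACTORY_MS = 2.0

R_GAS = 8.314462618  # J / (mol K)
F_FARADAY = 96485.33212  # C / mol


@dataclass
class SpikeTrain:
    times_s: np.ndarray
    threshold_mv: float

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass
class FICurve:
    currents_pa: np.ndarray
    rates_hz: np.ndarray

    @property
    def max_rate_hz(self) -> float:
        return float(np.max(self.rates_hz)) if len(self.rates_hz) else 0.0


@dataclass
class PassiveProperties:
    rmp_mv: float
    rin_mohm: float  # NaN sentinel when no usable step was given


@dataclass
class BurstMetrics:
    burst_count: int
    burst_rate_hz: float
    mean_spikes_per_burst: float
    max_spikes_per_burst: int
    inst_freq_min_hz: float
    inst_freq_max_hz: float


def detect_spikes(
    trace: VoltageStep,
    threshold_mv: float = DEFAULT_SPIKE_THRESHOLD_MV,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> SpikeTrain:
    """Upward threshold crossings with refractory enforcement."""
    vm = np.asarray(trace.vm_mv, dtype=float)
    t = np.asarray(trace.time_s, dtype=float)
    if len(vm) != len(t):
        raise ValueError("time and voltage must have equal length")
    crossings = np.flatnonzero((vm[1:] >= threshold_mv) & (vm[:-1] < threshold_mv)) + 1
    refr = refractory_ms / 1000.0
    times = []
    last = -math.inf
    for i in crossings:
        if t[i] - last >= refr:
            times.append(t[i])
            last = t[i]
    return SpikeTrain(times_s=np.asarray(times), threshold_mv=threshold_mv)


def _spikes_in_step(trace: VoltageStep, **kwargs) -> int:
    spikes = detect_spikes(trace, **kwargs)
    t0, t1 = trace.step_start_s, trace.step_start_s + trace.step_dur_s
    return int(np.count_nonzero((spikes.times_s >= t0) & (spikes.times_s < t1)))


def fi_curve(traces: Sequence[VoltageStep], **spike_kwargs) -> FICurve:
    """Firing rate (spikes in the step / step duration) per current step."""
    if not traces:
        raise ValueError("no traces given")
    currents = []
    rates = []
    for tr in sorted(traces, key=lambda tr: tr.current_pa):
        if tr.step_dur_s is None or tr.step_dur_s <= 0:
            raise ValueError("trace lacks step-duration metadata")
        currents.append(tr.current_pa)
        rates.append(_spikes_in_step(tr, **spike_kwargs) / tr.step_dur_s)
    return FICurve(currents_pa=np.asarray(currents), rates_hz=np.asarray(rates))


def passive_properties(trace: VoltageStep, steady_frac: float = 0.2) -> PassiveProperties:
    """RMP and input resistance from a (hyperpolarizing) current step.

    RMP is the mean pre-step voltage; Rin is the steady-state deflection over
    the injected current, using the final ``steady_frac`` of the step where
    the exponential charging has settled. With a zero-current trace the RMP
    is still returned and Rin is NaN.
    """
    t = trace.time_s
    vm = trace.vm_mv
    pre = t < trace.step_start_s
    if pre.sum() * (t[1] - t[0]) < 0.1:
        raise ValueError("need >= 100 ms of pre-step baseline")
    rmp = float(np.mean(vm[pre]))
    if trace.current_pa == 0.0:
        return PassiveProperties(rmp_mv=rmp, rin_mohm=float("nan"))
    t_end = trace.step_start_s + trace.step_dur_s
    tail = (t >= t_end - steady_frac * trace.step_dur_s) & (t < t_end)
    deflection_mv = float(np.mean(vm[tail])) - rmp
    rin_mohm = deflection_mv / trace.current_pa * 1e3  # mV/pA = GOhm
    return PassiveProperties(rmp_mv=rmp, rin_mohm=rin_mohm)


def burst_metrics(
    spikes: SpikeTrain,
    isi_gap_ms: float = 100.0,
    total_duration_s: Optional[float] = None,
) -> BurstMetrics:
    """Group spikes into bursts by an ISI criterion.

    A burst is a maximal group of >= 2 spikes whose consecutive ISIs are all
    below ``isi_gap_ms``. Instantaneous frequency is 1/ISI within bursts.
    """
    t = np.asarray(spikes.times_s, dtype=float)
    if len(t) < 2:
        return BurstMetrics(0, 0.0, 0.0, 0, float("nan"), float("nan"))
    gap = isi_gap_ms / 1000.0
    isi = np.diff(t)
    in_burst = isi < gap
    # group boundaries where the ISI criterion breaks
    groups: list[int] = []
    freqs: list[float] = []
    count = 1
    for i, ok in enumerate(in_burst):
        if ok:
            count += 1
            freqs.append(1.0 / isi[i])
        else:
            if count >= 2:
                groups.append(count)
            count = 1
    if count >= 2:
        groups.append(count)
    if not groups:
        return BurstMetrics(0, 0.0, 0.0, 0, float("nan"), float("nan"))
    duration = total_duration_s if total_duration_s else float(t[-1] - t[0])
    rate = len(groups) / duration if duration > 0 else float("nan")
    return BurstMetrics(
        burst_count=len(groups),
        burst_rate_hz=rate,
        mean_spikes_per_burst=float(np.mean(groups)),
        max_spikes_per_burst=int(max(groups)),
        inst_freq_min_hz=float(np.min(freqs)),
        inst_freq_max_hz=float(np.max(freqs)),
    )


# ---------------------------------------------------------------------------
# liquid junction potential

#: Limiting ionic mobilities relative to K+ (u = lambda0/|z| scaled to
#: u(K+) = 1), JPCalc-style. Gluconate is a slow organic anion; EGTA and
#: HEPES are treated as effectively immobile/neutral at these pH values, and
#: sugars are neutral.
ION_TABLE: dict[str, tuple[int, float]] = {
    # ion: (valence, relative mobility)
    "K": (1, 1.0000),
    "Na": (1, 0.6820),
    "Li": (1, 0.5260),
    "Cs": (1, 1.0500),
    "H": (1, 4.7580),
    "NH4": (1, 1.0000),
    "Ca": (2, 0.4048),
    "Mg": (2, 0.3606),
    "Cl": (-1, 1.0388),
    "Br": (-1, 1.0630),
    "F": (-1, 0.7530),
    "HCO3": (-1, 0.6054),
    "H2PO4": (-1, 0.4898),
    "NO3": (-1, 0.9720),
    "SO4": (-2, 0.5443),
    "gluconate": (-1, 0.3300),
    "glutamate": (-1, 0.3500),
    "methanesulfonate": (-1, 0.6600),
    "acetate": (-1, 0.5564),
}

#: Salt -> ionic dissociation (ion: stoichiometry). Neutral species map to {}.
_SALTS: dict[str, dict[str, int]] = {
    "NaCl": {"Na": 1, "Cl": 1},
    "KCl": {"K": 1, "Cl": 1},
    "CaCl2": {"Ca": 1, "Cl": 2},
    "MgCl2": {"Mg": 1, "Cl": 2},
    "K-gluconate": {"K": 1, "gluconate": 1},
    "NaH2PO4": {"Na": 1, "H2PO4": 1},
    "NaHCO3": {"Na": 1, "HCO3": 1},
    "glucose": {},
    "sucrose": {},
    "EGTA": {},
    "HEPES": {},
}


@dataclass
class SolutionSpec:
    """Ionic composition of a solution: ion name -> concentration (mM)."""

    ions: dict[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        for ion, conc in self.ions.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {ion}")
            if ion not in ION_TABLE:
                raise KeyError(
                    f"no mobility entry for ion {ion!r}; add it to ION_TABLE"
                )

    @classmethod
    def from_salts(cls, salts: dict[str, float], name: str = "") -> "SolutionSpec":
        """Build the ionic composition from salt concentrations (mM).

        Unknown neutral components can be ignored by adding them to the salt
        table with an empty dissociation.
        """
        ions: dict[str, float] = {}
        for salt, conc in salts.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {salt}")
            try:
                parts = _SALTS[salt]
            except KeyError:
                raise KeyError(f"unknown salt {salt!r}") from None
            for ion, stoich in parts.items():
                ions[ion] = ions.get(ion, 0.0) + stoich * conc
        return cls(ions=ions, name=name)

    def charged_ions(self) -> list[tuple[str, int, float, float]]:
        """(ion, valence, mobility, concentration) for all charged species."""
        out = []
        for ion, conc in self.ions.items():
            z, u = ION_TABLE[ion]
            if z != 0 and conc > 0:
                out.append((ion, z, u, conc))
        return out


#: The study's pipette and bath solutions (mM).
INTRACELLULAR_SOLUTION = SolutionSpec.from_salts(
    {
        "K-gluconate": 102.0,
        "NaCl": 17.0,
        "EGTA": 0.94,
        "HEPES": 8.5,
        "CaCl2": 0.085,
        "MgCl2": 1.7,
    },
    name="intracellular",
)

EXTRACELLULAR_SALINE = SolutionSpec.from_salts(
    {
        "NaCl": 101.0,
        "CaCl2": 1.0,
        "MgCl2": 4.0,
        "KCl": 3.0,
        "glucose": 5.0,
        "NaH2PO4": 1.25,
        "NaHCO3": 20.7,
    },
    name="extracellular",
)


def henderson_ljp(
    internal: SolutionSpec,
    external: SolutionSpec,
    temp_c: float = 25.0,
) -> float:
    """Generalized Henderson liquid junction potential, in mV.

    Returns the potential of the external (bath) solution relative to the
    internal (pipette) solution, i.e. the value subtracted from recorded
    membrane potentials. Identical solutions give 0; swapping the arguments
    negates the result.
    """
    ions_p = {ion: (z, u, c) for ion, z, u, c in internal.charged_ions()}
    ions_s = {ion: (z, u, c) for ion, z, u, c in external.charged_ions()}
    if not ions_p or not ions_s:
        raise ValueError("each solution needs at least one charged species")

    names = sorted(set(ions_p) | set(ions_s))
    s1 = s2 = sp = ss = 0.0
    for ion in names:
        z, u = ION_TABLE[ion]
        cp = ions_p.get(ion, (z, u, 0.0))[2]
        cs = ions_s.get(ion, (z, u, 0.0))[2]
        s1 += z * u * (cs - cp)
        s2 += z * z * u * (cs - cp)
        sp += z * z * u * cp
        ss += z * z * u * cs
    rt_f = R_GAS * (temp_c + 273.15) / F_FARADAY  # volts
    if s2 == 0.0 or sp <= 0.0 or ss <= 0.0:
        return 0.0
    if math.isclose(sp, ss, rel_tol=1e-12) and math.isclose(s1, 0.0, abs_tol=1e-12):
        return 0.0
    e_volts = -rt_f * (s1 / s2) * math.log(ss / sp)
    return e_volts * 1000.0
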