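# Methods

## The locomotor model

A fly's open-field behavior is modeled as an alternating two-state renewal
process. Walking-bout durations follow an exponential distribution (a gamma
option exists for over-dispersed bouts); pause durations (inter-bout
intervals, IBIs) follow a Weibull distribution with shape κ and a scale set
by the requested mean. κ < 1 produces the bursty pausing seen in real
flies: many brief pauses punctuated by rare, very long ones. During a bout
the fly moves at a per-bout speed drawn from a normal distribution (clipped
at 2 mm/s so walking always clears the activity threshold) along a
persistent-random-walk heading with wrapped-Gaussian turning noise
(σ = 30°/step) and specular reflection at the arena wall; during a pause it
jitters by < 0.1 mm per sample around an anchor point. No locomotor metric
depends on the heading model; it exists so trajectories look and validate
like tracker output.

### Calibration to the measurement process

The per-condition parameters shipped in `preset_config` are printed values
from 60-minute recordings sampled at 0.2 s. Two deliberate calibration
stages make the generator reproduce them *as measured*:

1. **Grid quantization.** State switches are aligned to the 0.2-s sampling
   grid: each drawn duration is rounded to a whole number of samples
   (minimum one). The continuous scale is then solved (Brent root finding
   on E[max(1, round(D/dt))]) so that the quantized mean equals the
   configured mean. Without this, sub-sample pauses — the majority of draws
   at κ ≈ 0.2–0.3 — would silently vanish below the tracker's resolution
   and every recovered rate would drift from its nominal value.
2. **Session windowing.** For heavy-tailed pause distributions the
   unconditional mean is dominated by rare, very long pauses that a 60-min
   recording almost never samples, so a generator calibrated only to the
   unconditional mean yields measured IBIs that run short and initiation
   rates that run high (by 5–9% at κ ≤ 0.27). Since the target values are
   themselves 60-min measurements, the pause scale is rescaled by a short
   fixed-point iteration against an interval-level session simulation
   (1500 sessions per iteration, internal fixed seed, independent of user
   seeds) until the expected within-session initiation rate equals
   1/mean-IBI. Verified residual centering error is below 0.5% for all
   presets.

The startle stimulus (5 × 200-ms pulses, 800-ms gaps, default onset 30 min)
opens a 60-s window in which walking speed is offset by the condition's
startle delta; for positive deltas paused flies also move at the delta
speed, modeling arousal, which is what lets the analysis-side mean-speed
contrast recover the configured value. Negative deltas only slow walkers
(speed cannot go negative), so measured contrasts are attenuated in sign-
preserving fashion.

Two presets are under-determined by the published per-condition values:
`R78B06-shi31` (only speed 5.4 mm/s, bout 1.2 s and startle +0.8 printed;
IBI chosen as 0.36 s to keep activity at the 31 °C control level, κ set to
the control 0.45) and `c232-shi31` (only speed 8.7 and κ 0.26 printed;
bout/IBI taken from the 31 °C control since activity was unaffected).

## Locomotor analysis

Speed is the finite-difference displacement over one 0.2-s step. A sample
is active iff its speed is ≥ 1.0 mm/s — the threshold sits between the
pause-jitter ceiling (0.5 mm/s) and the slowest plausible walk, and percent
active is monotone in it. Bout segmentation run-length-encodes the raster;
runs shorter than a configurable minimum are merged into the flanking state
(shortest first, pauses absorbed before walks on ties). The default
minimum is one sample (0.2 s): with κ ≈ 0.2–0.3 pausing, a large fraction
of genuine IBIs are exactly one sample long, and any stricter minimum
merges them away, breaking the identity between initiation rate and
1/mean-IBI. First and last intervals are censored at the session edge and
excluded from duration means and onset counts (their time still counts
toward pause time). The initiation rate is uncensored walk-bout onsets per
second of pause time — the definition consistent with the published
rate/IBI pairs (0.3 ≈ 1/3.2, 1.1 ≈ 1/0.9). The startle response is the
post-window minus pre-window mean speed (default 60-s windows), excluding
the 4.2-s stimulus span. Cohort metrics are per-fly values averaged across
flies; IBIs are pooled across flies for the condition-level κ.

## Weibull burstiness fit

`empirical_ibi_cdf` uses median-rank plotting positions (i − 0.3)/(n + 0.4).
`fit_weibull_cdf` initializes κ, λ from the linearized Weibull plot
(regressing ln(−ln(1 − F)) on ln x) and refines them by bounded least
squares on CDF residuals. Two practical refinements matter for tracker
data:

* ties (values within 1e-9 relative distance, which also absorbs float
  jitter in grid-derived durations) are collapsed to their largest plotting
  position — otherwise resolution-limited samples stack most of their
  probability on the first grid value and the fit returns κ ≈ 1 regardless
  of the truth;
* an optional `grid_s` declares the sampling resolution, and each quantized
  value's cumulative fraction is matched to the model CDF at the bin's
  upper edge (a value of 0.2 s stands for all durations below 0.3 s). With
  it, pooled pipeline IBIs recover generating shapes of 0.22–0.45
  essentially exactly; without it they bias upward by ~30%.

`fit_weibull_mle` (scipy, location fixed at zero) is the validation
estimator; the two agree within 5% on uncensored samples of 10⁴. Samples
with zero variance are reported with a capped shape and a degenerate flag;
fewer than 10 intervals is an error, not a fit.

## Calcium imaging

ΔF/F₀ uses F₀ = mean of the first five frames (acquired before any
temperature change); traces are ROI mean intensities. The ramp response
reports peak and average ΔF/F₀ (in percent, first maximum on ties) with the
bath temperature at the peak read from the temperature trace aligned by
nearest-time interpolation. The synthetic movie embeds, per cell, a
transient (linear 2.5-s rise, 5-s plateau, 30-s exponential decay)
triggered when the ramp crosses the cell's onset temperature; the plateau
guarantees a frame sits exactly at the peak, so noiseless movies are
recovered with zero error. With pixel noise σ on an m-pixel ROI the peak
estimate is biased by at most ≈ 3σ/(F₀√m) (max-of-noise over the plateau
frames). CaMPARI scoring is the red/green ratio of ROI means on
maximum-intensity projections, ×100; no background subtraction is applied
(none was part of the protocol), and ROIs are supplied masks — ring
segmentation was manual in the assay and is out of scope.

## Electrophysiology

Spikes are upward crossings of −20 mV with a 2-ms refractory lockout, so a
depolarization-block plateau contributes one crossing and no spike train.
f–I curves count spikes within the step over its duration; the synthetic
cell fires at min(gain·I, 80 Hz) with evenly spaced spikes, enters block
above a configurable current, and charges exponentially (τ = 25 ms) toward
the Ohmic deflection on hyperpolarizing steps. During suprathreshold steps
the interspike baseline is capped at −40 mV — with GΩ-range input
resistances the raw Ohmic deflection would exceed spike threshold, which no
real neuron's interspike voltage does. Passive properties: RMP is the
pre-step mean; Rin the steady-state deflection (final 20% of the step) over
the injected current. Bursts are maximal groups of ≥ 2 spikes with ISIs
under a 100-ms gap; instantaneous frequency is 1/ISI within bursts.

The liquid junction potential uses the generalized Henderson equation with
a bundled table of limiting ionic mobilities relative to K⁺ (JPCalc-style;
gluconate 0.33, EGTA/HEPES/sugars treated as immobile or neutral). The
returned sign is the bath potential relative to the pipette — the value to
subtract from recorded voltages; the study's pipette/bath pair evaluates to
≈ 13.1 mV at 25 °C. Identical solutions give exactly 0, swapping arguments
negates the result, and for a single binary salt the implementation matches
the Lewis–Sargent closed form to < 0.01 mV. Exact agreement with any
particular published LJP value depends on the mobility set chosen; ±1 mV is
the realistic reproducibility across tables.

## Group statistics

Normality is tested per group (D'Agostino–Pearson for n ≥ 8, Shapiro–Wilk
below — the cut is where the kurtosis test becomes defined) at α = 0.05;
all groups normal selects the parametric branch. Parametric: one-way ANOVA
with Dunnett's test of the experimental group against its two parental
controls (Šidák-adjusted t-tests available as an option). Nonparametric:
Kruskal–Wallis with Dunn's rank z-test (tie-corrected, Bonferroni over the
two comparisons performed). The two-control rule — significant only if
both adjusted p-values fall below α — is conservative by construction; its
empirical type-I error under the global null is well below 0.05. Two-group
designs (25 vs 31 °C wild type) use a t-test or Mann–Whitney under the same
gate. No correction is applied across metrics by default, matching
per-metric reporting; Dunn's test is implemented in-package (the standard
mean-rank z formula) rather than pulled from a posthoc library.

## Problem sizes and determinism

Simulated cohorts used in the test suite and the acceptance script are 100
flies × 60 min at 0.2-s sampling — the study's recording geometry — which
keeps every check within desktop-scale runtimes (the full suite runs in
under a minute). All generators consume a single integer seed through
`numpy.random.SeedSequence` spawning, so identical configurations reproduce
outputs bit for bit, and the pipeline's provenance block (config hash,
seed, version) makes result tables byte-reproducible.

## Limitations

The synthetic walker does not emulate video artifacts (identity swaps,
reflections at the acrylic lid), thigmotaxis, circadian drift within the
hour, or genuine per-fly parameter heterogeneity beyond bout-speed
variation; passing recovery tests therefore demonstrates correctness of the
measurement pipeline under the stated renewal model, not robustness to raw
tracking noise. The Weibull fit deliberately excludes censored intervals
rather than modeling them (no censored-likelihood survival fitting), which
is adequate at thousands of pooled intervals but would bias small samples
with many edge intervals. The calcium generator uses piecewise-linear
ramps and noise-free temperature readout; the voltage generator is a
template model, not a conductance-based neuron.
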