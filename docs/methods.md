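# Methods

## Scope and design

`iglu` implements the computational side of single-synapse iGluSnFR
experiments: detecting quantal glutamate-release events in 50-Hz
fluorescence traces, estimating release probability by failure analysis,
normalizing and fitting FRAP recovery curves, modelling use-dependent
photobleaching of a membrane-tethered sensor, and characterizing the
spatial organization of probe localizations. Because raw recordings of this
kind are rarely shareable, validation is built on *parameter recovery*:
every estimator is exercised against the package's own synthetic-data
generators, whose ground truth is exact, and must return the generating
parameters within stated tolerances.

## Event detection

A raw ROI trace is first detrended by subtracting a single ordinary
least-squares line fitted to the whole trace. A global line was chosen over
rolling or piecewise detrending because it is deterministic, analytically
invertible, and makes detection provably invariant to any affine trend
added to the raw signal (a property test enforces this). The detectors
consume this background-subtracted trace.

Inside the detectors, threshold crossings are evaluated on a centred moving
mean of 3 (default) or 5 samples; shrunken windows are used at the edges so
no values are invented. The moving baseline at frame *i* is the mean of the
trailing `baseline_window` (default 4 s) strictly preceding *i*, so an
event cannot inflate its own baseline. The noise scale is a robust SD —
1.4826 × median absolute deviation — over the same trailing window of the
**unsmoothed** trace:

* The MAD is used because the trailing window may contain genuine events;
  a standard deviation would be inflated by them, a median-based scale is
  not.
* The SD is measured on the unsmoothed trace deliberately. A 3-SD threshold
  expressed in *smoothed*-noise units admits a false-event rate of roughly
  0.03–0.06 Hz on pure Gaussian noise at 50 Hz — several times the entire
  physiological spontaneous rate of ~0.01–0.02 Hz per synapse — because
  smoothed noise is strongly autocorrelated and its exceedances cluster.
  Expressing the same k = 3 threshold in raw-noise units makes the
  effective level on the smoothed series 3·√3 ≈ 5.2 smoothed SDs: the
  measured false rate drops below 0.002 Hz while sensitivity for
  SNR-8 quanta remains above 99% (the smoothed peak of an instantaneous-
  rise, 0.1-s-decay quantum at 50 Hz retains ≈ 0.61 of its amplitude,
  i.e. ≈ 4.9 raw SDs at SNR 8).

Spontaneous events: supra-threshold samples are grouped into runs, each run
yields one event at its smoothed maximum, and peaks closer than the
refractory interval (default 0.1 s) merge with the larger one kept.
Evoked events: for each stimulus, baseline and SD come from the trailing
window ending at the stimulus frame (the response window is excluded); a
success is a smoothed-trace crossing within the closed window
[stim, stim + 0.3 s]. The window includes the stimulus frame because with
an instantaneous-rise kernel the true peak falls exactly on it; excluding
it would bias amplitudes by one decay frame (~18% at 50 Hz). Stimulus
trains whose inter-stimulus interval is shorter than the response window
are rejected rather than disambiguated.

Amplitudes are always read off the *unsmoothed* trace (maximum over the run
or response window, ± half the smoothing width around the peak) minus the
local baseline, so on clean data amplitude error is limited to kernel
sampling at 50 Hz (< 2%). Reported amplitudes are in background-subtracted
arbitrary units, not ΔF/F.

Release probability is the exact ratio of detected successes to delivered
stimuli; spontaneous frequency is count/duration. Summary statistics
aggregate as unweighted per-coverslip means, since inference in this field
is done across coverslips, not across the (thousands of) individual
synapses. Pre/post comparisons report post/pre ratios per synapse; a
synapse with a zero pre-bleach value is flagged and excluded from that
ratio rather than producing an infinity.

## FRAP

Double normalization divides the background-subtracted ROI by its
pre-bleach mean and multiplies by the reference channel's pre-bleach mean
over its current value, cancelling any acquisition-bleach trend shared by
both channels. All pre-bleach frames enter the pre-bleach means; the bleach
scans themselves are not sampled. The recovery is fit by unweighted least
squares with F(t) = F∞ − (F∞ − F₀)·e^(−(t−t_b)/τ) on the post-bleach
samples, initialized at F₀ = first post-bleach sample, F∞ = mean of the
last 10% of samples, τ = (time to half recovery)/ln 2, with bounds
τ ∈ (0, 10 × span], F∞ ∈ [0, 1.5]. The mobile fraction is
(F∞ − F₀)/(1 − F₀) on the double-normalized scale and the immobile
fraction its complement — the gap between pre-bleach baseline and recovery
asymptote. Degenerate inputs are handled explicitly: a curve with no
recovery amplitude returns mobile fraction 0 with τ = ∞ (τ is
unidentifiable there); a "bleach" that did not reduce the signal is
rejected; a non-converging fit is returned flagged with the solver message
instead of raising. Quality metrics follow the standard definitions:
bleach depth 1 − F at the first post-bleach frame, gap ratio as the
post/pre ratio of background-subtracted reference totals.

## Use-dependent photobleaching model

Only fluorescent (glutamate-bound) probes can photobleach. The probe
population is split into three well-mixed compartments: `evoked_site`
(probes over the clustered, diffusion-restricted evoked release sites),
`synaptic_general` (the rest of the synaptic surface, where spontaneous
release lands), and an effectively infinite extrasynaptic `reservoir`.
Each compartment's unbleached fraction obeys

    du_c/dt = −k_bleach · I(t) · a_c(t) · u_c + (u_res − u_c)/τ_c .

Defaults and their rationale (all configurable):

| parameter | default | rationale |
|---|---|---|
| k_bleach | 0.14 s⁻¹ | activated-probe half-life ≈ 5 s at full intensity, so a 30-s bleach substantially depletes active pools |
| τ_exchange(synaptic_general) | 10 s | the FRAP-measured mobile-pool exchange time |
| τ_exchange(evoked_site) | 6 h | puts 90% recovery on the hours scale, with near-complete recovery within a day |
| a_tonic | 0.05 | tonic/ambient-glutamate activation; nonzero so prolonged full-power illumination bleaches even without release events |
| event_activation / event_duration | 0.3 / 0.1 s | fraction of a compartment activated per release event and for how long |
| imaging intensity | 0.02 | relative to bleaching power; imaging-induced bleaching is slow but nonzero |
| reservoir_exposure | 0.1 | share of the reservoir membrane inside the illuminated field |

`reservoir_exposure` is a deliberate refinement of the minimal three-pool
picture. If the entire reservoir were tonically bleached at full intensity,
after a 10-minute bleach the reservoir and the exchange-fed general pool
would both collapse to the same level as the evoked-site pool, erasing the
differential-bleaching effect entirely and predicting (contrary to
observation) that spontaneous events disappear after long bleaches. Most
of the membrane reservoir of a neuron lies outside the illuminated field,
so only a fraction of it is bleachable; 0.1 preserves the observed
orderings — evoked detection collapses within 5–10 min, spontaneous
detection survives 10–20 min bleaches, and bath glutamate perfusion (which
activates every probe, a_c = 1 everywhere) ablates spontaneous detection.

Integration freezes activation and the reservoir inflow within each step
and applies the exact exponential update for the then-linear ODE, giving
O(dt²) trajectories; step sizes default to min(τ)/10, tightened to half the
event duration inside stimulated segments (two-scale stepping). Halving dt
moves endpoint values by < 1e−4 (tested). u is asserted to stay in [0, 1]
at every step. Activation is deterministic: stimulation contributes a
pulse train at the segment's stimulus rate, spontaneous release its
duty-cycle mean (event_activation × rate × duration), keeping
`run_protocol` reports reproducible without sampling. "Recovery to 90%" is
measured against a compartment's own asymptote (τ·ln 10 closed form),
since the asymptote itself is the reservoir level, which may sit below 1
after a long bleach.

Detection coupling: the model maps pool states to observables by scaling
event amplitudes with the compartment's unbleached fraction; an event is
detectable when its scaled amplitude reaches k noise SDs, and with
lognormal amplitude variability the detection probability is the lognormal
survival function at that threshold. Feeding the end-of-protocol state back
into the trace simulator and rerunning the full detection pipeline
reproduces the model-level orderings end to end (tested).

## Synthetic data

The generators encode the study conditions rather than adjustable
conveniences: 50-Hz sampling; Bernoulli(Pr) fusion per stimulus with
stimuli at 0.2 Hz; spontaneous release as a homogeneous Poisson process at
0.015 Hz per synapse (midpoint of the 0.01–0.02 Hz literature range);
quantal transients with instantaneous rise and 0.1-s exponential decay
(plausible for this sensor at 50 Hz; the source recordings show kinetics
but publish no constants); lognormal amplitude variability with CV 0.25
truncated at zero (a parametric stand-in for the reported amplitude
distributions); white Gaussian camera noise plus a linear baseline; 0.2
µm/px, 0.5-µm Gaussian PSF movie rendering; FRAP triplets that invert the
double normalization exactly; Thomas-process point patterns with uniform
cluster centers and Gaussian offspring against a CSR background. A single
integer seed spawns one independent substream per synapse via
`numpy.random.SeedSequence`, so enlarging a scene never perturbs existing
synapses, and all generators are bit-reproducible.

What the generators do **not** emulate — and hence what passing recovery
tests cannot certify about real data: shot noise and EM-CCD gain
statistics, focal drift and photobleaching of the baseline during ordinary
imaging (beyond the linear trend), multivesicular release and glutamate
spillover between neighbouring synapses, sensor saturation, and the 3D
geometry of real neuropil. Recovery results bound estimator error under
the stated noise model only.

## Spatial statistics

DBSCAN uses the standard core-point definition (≥ min_pts neighbours
within eps, self included) with clusters as maximal density-connected
sets. The well-known ambiguity — a border point within eps of two clusters
— is resolved deterministically: the lowest-index core neighbour claims
it. The implementation is verified against a brute-force transitive-closure
oracle on random instances and against scikit-learn's DBSCAN on core-point
partitions.

The pair-correlation estimator is the classical center-referenced radial
distribution: counts in annuli around each reference center divided by the
annulus area clipped to the field rectangle and by the global density,
pooled over centers with area weighting. Annulus clipping uses an exact
closed-form circle–rectangle intersection area (verified against polygon
clipping); a Monte-Carlo fallback is unnecessary for rectangular fields.
Default bins are 10-nm rings out to 500 nm. Under CSR the estimator is
unbiased (mean 1 in every bin, tested over seeds) with variance shrinking
as point density grows. Because the commercial software used for such
analyses does not document its normalization, this estimator is defined
and documented here in full.

## Problem sizes and tolerances

Recovery runs use 636 synapses × 40 stimuli for release probability
(tolerance: 3 binomial standard errors of the mean), 100 synapses × 600 s
for spontaneous rates, 100–200 seeds for Monte-Carlo means (tolerance: 3
Monte-Carlo SEs), and noiseless FRAP round trips fit to < 1e−6 relative
error. These sizes give stable statistics while keeping the full test
suite around a minute on one CPU.

## Known limitations

* Compartments are well-mixed; there is no spatially resolved
  reaction–diffusion treatment of probe exchange, and evoked/spontaneous
  compartments are fully disjoint by assumption.
* The bleaching model's activation parameters (a_tonic, event_activation)
  are order-of-magnitude choices; the model is used for orderings and
  qualitative recovery behaviour, not fitted to measured bleaching curves.
* The evoked detector requires a full baseline window before the first
  stimulus and non-overlapping response windows.
* FRAP fitting covers the single-exponential model only (no
  reaction-dominant or double-exponential variants).
* Localization inputs are consumed as given point patterns; localization
  fitting, drift correction and channel alignment are out of scope.
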