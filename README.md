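# iglu

Analysis tools for single-synapse imaging with the fluorescent glutamate
sensor iGluSnFR, built for experiments that use **use-dependent
photobleaching** to probe how evoked and spontaneous neurotransmitter
release are organized within a synapse.

The package is aimed at cellular neuroscientists analysing 50-Hz
epifluorescence movies of sparsely transfected neuronal cultures. It covers
the complete workflow:

- **Event detection and failure analysis** (`iglu.pipeline`) — circular ROIs
  (2 µm) around fluorescence maxima, per-ROI traces, linear background
  subtraction, 3/5-point smoothing, spontaneous events as threshold
  crossings k·SD above a trailing 4-s moving baseline, evoked successes
  time-locked within 0.3 s of each field stimulus. Release probability is
  the failure-analysis estimate Pr = (detected responses)/(stimulations);
  spontaneous frequency is events per second; statistics aggregate per
  coverslip.
- **FRAP** (`iglu.frap`) — double normalization
  F(t) = [⟨ref′⟩_pre/ref′(t)]·[roi′(t)/⟨roi′⟩_pre] and single-exponential
  fitting F(t) = F∞ − (F∞ − F₀)·e^(−t/τ), with the immobile fraction
  1 − (F∞ − F₀)/(1 − F₀), plus bleach-depth and gap-ratio quality metrics.
- **Photobleaching model** (`iglu.bleach`) — a three-compartment ODE for the
  unbleached probe fraction u under the rule that only activated
  (glutamate-bound) probes can bleach:
  du_c/dt = −k_bleach·I(t)·a_c(t)·u_c + (u_res − u_c)/τ_c.
  Diffusion-restricted evoked-site probes (τ ≈ hours) bleach fast and
  recover slowly; the general synaptic pool (τ ≈ 10 s) is continuously
  replenished from the membrane reservoir, reproducing the differential
  bleaching and recovery of the two release modes.
- **Spatial statistics** (`iglu.spatial`) — DBSCAN clustering of
  super-resolution localizations with a deterministic border-point rule, and
  a cluster-center-referenced pair correlation g(r) with exact analytic
  clipping of annuli to the field boundary (g ≡ 1 under complete spatial
  randomness).
- **Synthetic data** (`iglu.synth`) — generators with exact ground truth for
  every stage: Bernoulli-per-stimulus and Poisson spontaneous quantal
  events, Gaussian camera noise, Gaussian-PSF movies, FRAP triplets, Thomas
  process vs. CSR point patterns. Every estimator in the package is
  validated by parameter recovery against these generators.
- **I/O and orchestration** (`iglu.io`, `iglu` CLI) — TIFF stacks with JSON
  metadata sidecars, CSV traces/events/summaries, YAML protocols and
  configs, manifests with file hashes, and an end-to-end simulated
  pre-bleach/bleach/post-bleach experiment runner.

## Worked example

```python
from iglu import (SynapseConfig, RecordingProtocol, NoiseModel, generate_trace,
                  subtract_background, detect_evoked, detect_spontaneous,
                  release_probability, spontaneous_frequency,
                  generate_frap_curve, analyze_frap)

cfg = SynapseConfig(pr=0.49, spont_rate=0.015, quantal_amp=8.0, amp_cv=0.0)
noise = NoiseModel(sigma=1.0)          # SNR 8 recording

# evoked epoch: 40 APs at 0.2 Hz
stims = tuple(5.0 * (i + 1) for i in range(40))
ev_proto = RecordingProtocol(duration=205.0, stim_times=stims)
ev_trace, truth = generate_trace(cfg, ev_proto, noise, seed=42)
evoked = detect_evoked(subtract_background(ev_trace), stims)
print(f"true fusions: {(truth['kind'] == 'evoked').sum()}/40")
print(f"estimated Pr: {release_probability(evoked, stims):.3f}")

# spontaneous epoch: 10 min without stimulation
sp_proto = RecordingProtocol(duration=600.0)
sp_trace, sp_truth = generate_trace(cfg, sp_proto, noise, seed=43)
spont = detect_spontaneous(subtract_background(sp_trace))
print(f"spontaneous: {len(spont)} detected / {len(sp_truth)} true "
      f"-> {spontaneous_frequency(spont, sp_proto.duration):.4f} Hz")

# FRAP at the spinous-region group mean
curve = generate_frap_curve(tau=8.9, immobile_fraction=0.19, bleach_depth=0.8)
F, fit, qm = analyze_frap(curve)
print(f"FRAP: tau = {fit.tau:.2f} s, immobile fraction = {fit.immobile_fraction:.3f}, "
      f"bleach depth = {qm['bleach_depth']:.2f}")
```

prints

```
true fusions: 20/40
estimated Pr: 0.500
spontaneous: 5 detected / 5 true -> 0.0083 Hz
FRAP: tau = 8.90 s, immobile fraction = 0.190, bleach depth = 0.80
```

This synapse fused on 20 of 40 stimuli and the detector called every one of
them (Pr exactly 0.500); all five spontaneous quanta in the 10-minute epoch
were recovered with no false positives; and the noiseless FRAP round trip
returns the generating time constant and immobile fraction.

The same workflow is available from the shell:

```bash
iglu simulate --seed 3 --duration 600 --spont-rate 0.015 --quantal-amp 8 --sigma 1 --out sim/
iglu detect --trace sim/trace.csv --out detected/
iglu frap --in curve.csv --bleach-end 10
iglu spatial --in points.csv --eps 50 --min-pts 4 --out clusters/
iglu run --config experiment.yaml --seed 1 --out results/
```

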