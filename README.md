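# memprobe

Quantification toolkit for fluorescently labelled membrane-binding peptide
probes, built around the measurement chain used to characterize
sphingolipid-binding-domain (SBD) peptides on cell membranes:

* **FCS** — Brownian-dynamics simulation of confocal photon-count traces,
  multiple-tau autocorrelation, and nonlinear fitting of the standard 2D/3D,
  one/two-component, one-triplet ACF models;
* **aggregation classification** — intensity-spike counting, complex-ACF
  flagging, bound/unbound assignment from diffusion times, and cohort
  summaries (spike/complex overlap, bound percentages, τ_D histograms);
* **SPR** — sensorgram quantification (fraction binding / fraction bound
  with flow-cell immobilization normalization) against an exact 1:1
  Langmuir generator;
* **CD** — conversion of observed ellipticity to mean residue ellipticity
  and dye-absorbance concentration determination.

It is aimed at fluorescence-fluctuation spectroscopists who need a tested,
scriptable re-implementation of this analysis, with a synthetic-data module
standing in for instrument data.

## The model at the core

Intensity fluctuations of diffusing fluorophores in a 3D Gaussian confocal
volume are condensed into the normalized autocorrelation

    G(τ) = offset + (1/N) · T(τ) · D(τ)

with triplet factor `T(τ) = (1 − F_trip + F_trip e^{−τ/τ_trip})/(1 − F_trip)`
and diffusion factor

    2D:  D(τ) = F1 (1+τ/τ_D1)⁻¹ + (1−F1)(1+τ/τ_D2)⁻¹
    3D:  D(τ) = (1+τ/τ_D)⁻¹ (1+τ/(K²τ_D))⁻¹ᐟ²,   K = wz/w0

where `N` is the apparent particle number in the effective volume,
`τ_D = w0²/4D` the transit time, and `F1` the mole fraction of the slow
component (biased toward brighter species as `N q²`).  Membrane-bound probe
diffuses with τ_D ≈ 1–100 ms (2D), unbound probe in hundreds of µs, and
rare bright aggregates produce intensity spikes plus ACF distortions at
1–10 s lags — the two aggregation criteria the classifier implements.

See `docs/methods.md` for the full account (estimators, detector design,
study conditions, limitations).

## Worked example

```python
import numpy as np
from memprobe import fixtures
from memprobe.simulate import simulate_trace, expected_occupancy
from memprobe.correlate import autocorrelate_multitau
from memprobe.fcsmodels import FcsModelSpec, fit_curve

cfg = fixtures.solution_config(seed=3)        # tau_D = 0.5 ms probe, 20 s
trace = simulate_trace(cfg)
curve = autocorrelate_multitau(trace, m=16)
fit = fit_curve(curve.restrict(0, 1.0),
                FcsModelSpec("3D", 1, triplet=False, K=5.0))
print(f"N = {fit.N:.2f} (expected {expected_occupancy(cfg, 'solution_monomer'):.2f})")
print(f"tau_D = {fit.tau_d1*1e6:.0f} us (true 500 us)")
```

prints

```
N = 2.12 (expected 2.01)
tau_D = 473 us (true 500 us)
```

i.e. the fitted occupancy tracks `n·V_eff/V_box` (the small excess comes
from the uncorrelated background diluting the amplitude) and the fitted
transit time recovers the simulated `w0²/4D` within the documented ±15 %.

The same chain runs from the shell:

```bash
memprobe demo --seed 1 --out demo_out/      # good vs poor binder cohorts
memprobe simulate --config sim.yaml --out trace.txt
memprobe correlate trace.txt --out curve.txt
memprobe fit curve.txt --model 2d2p
```

`demo` prints one line per cohort (per-cent spiked traces, per-cent
complex ACFs, mean bound fraction) and writes per-trace tables, cohort
summaries, τ_D histograms and a run manifest.

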