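# Methods

## Scope

`memprobe` quantifies the behaviour of fluorescently labelled
membrane-binding peptide probes from four kinds of measurement:

1. confocal FCS intensity traces (simulation, correlation, model fitting),
2. per-measurement aggregation classification (intensity spikes and
   complex autocorrelation curves) and bound-fraction assignment,
3. SPR sensorgram statistics (fraction binding / fraction bound),
4. CD spectra (mean residue ellipticity, dye-absorbance concentration).

Because raw instrument data for this kind of study are rarely deposited,
the package carries a first-class synthetic-data generator whose output has
the statistical structure the analysis assumes, so every stage is testable
end to end.

## Photon-trace simulation

Particles perform Brownian dynamics in a periodic box and are detected
through a 3D Gaussian profile `W(r) = exp(-2(x²+y²)/w0² - 2z²/wz²)`.
Per time bin Δt each mobile coordinate gains a Gaussian step of standard
deviation `sqrt(2 D Δt)`; membrane species are confined to z = 0.  The
bin's photon count is Poisson with mean `(Σ_i q_i W(r_i) + background)·Δt`,
where `q_i` is the molecular brightness (counts/s at the volume centre) and
the sum runs over particles in the bright state.  The transit-time
convention is `τ_D = w0²/(4D)`.

Blinking is an exact two-state Markov chain propagated per bin with
equilibrium dark occupancy `F_trip` and relaxation time `τ_trip`
(transition probabilities `F_trip·(1−e^{−Δt/τ})` and
`(1−F_trip)·(1−e^{−Δt/τ})`).  Emission is masked for whole bins, so when
`Δt ≳ τ_trip` the recovered triplet amplitude is biased; the recovery
benchmark therefore samples at `Δt = 2 µs` against `τ_trip = 5 µs` and the
residual bias is absorbed by the documented (wide) tolerance.
Bleaching is an irreversible per-bin transition at rate `bleach_rate`,
used to model immobile aggregates that darken during a measurement.

Boundaries are periodic with the detection profile evaluated on
minimum-image coordinates: density stays exactly uniform and no boundary
layer forms.  The cost is that a particle leaving one side re-enters the
other, which adds (3D) or removes (2D mode truncation) correlation at lags
of order `(2·half-width)²/4D`.  Box sizes in the bundled study conditions
are chosen so this timescale sits far beyond the lags being interpreted;
the 3D solution condition uses a 4.5·w0 lateral half-width for this reason
(at the minimal 3·w0 box the fitted τ_D reads ~10 % low).

A guard rejects configurations whose RMS step exceeds `w0/2`: the
detection profile would be under-sampled and the effective τ_D distorted.

## Correlation

Both estimators use symmetric normalization,
`G(kΔt) = ⟨I_t I_{t+k}⟩ / (⟨I_t⟩_L ⟨I_{t+k}⟩_R) − 1`, with the left/right
means over exactly the pairs being averaged; this tolerates slow drift and
bleaching better than a global mean.  The brute-force estimator is O(N·K)
and serves as the oracle.  The multiple-tau scheme evaluates lags 1..2m on
the raw trace — arithmetic identical to the oracle, so the two agree to
floating-point resolution there — then halves the resolution per octave
(pairwise averaging) and evaluates lags (m+1)..2m per level, continuing
while at least one pair remains.  At rebinned levels the estimate is a
smoothed version of the underlying ACF and agrees with the oracle only
statistically.

Per-lag standard errors, when requested, come from cutting the trace into
≥10 segments and taking the standard error of the per-segment estimates;
only lags every segment reaches are returned.  Full-ladder curves carry no
stderr and are fitted unweighted; the quasi-logarithmic spacing keeps any
single timescale from dominating the least squares.

## ACF models and fitting

`G(τ) = offset + (1/N)·T(τ)·D(τ)` with the amplitude-preserving triplet
factor `T(τ) = (1 − F_trip + F_trip e^{−τ/τ_trip})/(1 − F_trip)` and
mole-fraction-weighted diffusion terms: `(1+τ/τ_D)^{-1}` in 2D and
`(1+τ/τ_D)^{-1}(1+τ/(K²τ_D))^{-1/2}` in 3D.  Two triplet conventions
coexist in the field; the amplitude-preserving form is used consistently,
and all recovery benchmarks run through the simulator, so the convention
choice cancels.  K = wz/w0 is a fixed calibration constant, never fitted
(it is not identifiable jointly with τ_D at realistic noise).

Fitting is `lmfit` Levenberg–Marquardt, weighted by 1/stderr² when the
curve carries errors.  Initialization: N from the early-lag amplitude,
τ from the half-decay lag; the two-component start splits that estimate
×10 and ÷10, with a three-point multi-start (×0.3, ×1, ×3) on the decay
scale before declaring non-convergence (returned as a flagged result, not
an exception).  Components are relabelled so τ_D1 ≥ τ_D2 with F1 the slow
fraction; parameters ending on a bound are flagged.  Default bounds:
fractions in [0,1]; diffusion times within a decade beyond the lag range;
τ_trip within two decades of the first lag (blinking slower than that is
not a triplet; faster is unobservable).

Because the ACF amplitude weighs each species by brightness squared, the
fitted mole fractions are biased: for occupancies N₁, N₂ and brightness
ratio q₂/q₁ the apparent fraction of species 2 converges to
`N₂q₂²/(N₁q₁² + N₂q₂²)`.  The benchmark at q₂/q₁ = 3 and N₁ = N₂ recovers
the predicted 0.9 and is the quantitative form of the caveat that
aggregate fractions are overestimated.

## Aggregation classification

**Spikes.** A spike is a sudden jump exceeding the baseline mean by more
than `multiplier` (default 5) times the highest-to-lowest fluctuation
range of the spike-free baseline.  The rule as stated is circular (a spike
inflates the range that defines it), so the implementation (i) smooths
with a short moving average, (ii) seeds the mask with a robust cut built
from the lower half of the smoothed distribution (median +
multiplier·2·(median − min)), (iii) dilates every masked run outward until
the trace returns to the baseline mean, so transit shoulders do not leak
into the range, and (iv) grows the mask monotonically to a unique fixed
point.  Contiguous masked runs count once.  Spike counting operates on
traces rebinned to 5 ms — the scale at which membrane intensity traces are
normally displayed — over a 20-s window; at much finer binning the
smoothed min-max range of a realistic few-particle baseline is so wide
that no physical aggregate can exceed five times it.

**Complex ACFs.** A curve is "complex" when it deviates from the fitted
normal model in the 1–10 s lag window: the mean absolute residual there
must exceed k (default 3) times the residual standard deviation at lags
below 100 ms (the well-fit region).  Two practical points matter.  First,
classification fits cap diffusion times at 1 s: the normal membrane model
spans ~0.1–100 ms, and an unbounded slow component will absorb any
aggregate shoulder into a nonphysical multi-second τ_D, defeating the
criterion.  Second, the statistic is noise-floor-limited when the flag
window is comparable to the trace length; classification measurements
therefore run 60 s (the spike window stays at 20 s).  At 60 s a clean
two-component membrane measurement flags in ~10 % of runs — consistent
with the low complex-ACF rates of well-behaved probes — while
bleaching-aggregate fixtures exceed the threshold by an order of
magnitude.

**Bound fraction.** Components with τ_D ≥ 1 ms are membrane-bound
(unbound probe diffuses in hundreds of µs; bound probe in 1–100 ms); the
bound fraction is the fitted mole fraction on bound components.  Cohort
bound percentages average only measurements that are neither spiked nor
complex: aggregate-contaminated fits carry the q² bias above and would
report inflated bound fractions.

## SPR quantification

Sensorgrams are re-baselined to the 10 s before injection.  Fraction
binding is the response at injection end minus the response at injection
start + 30 s (the exclusion removes the bulk refractive-index jump),
divided by the flow cell's normalized immobilization (cell RU over the
mean across cells).  Fraction bound is the re-baselined response after the
15-min dissociation over the same normalization.  The generator produces
exact 1:1 Langmuir kinetics — association
`Req(1−e^{−(konC+koff)t})`, `Req = Rmax·konC/(konC+koff)`; dissociation
`R_end e^{−koff t}` — plus an optional square bulk jump spanning the whole
injection, Gaussian noise, and linear drift, so every quantity has a
closed-form oracle.  The association "peak" is read at the injection end
point rather than as a global maximum, which is robust to bulk spikes on
monotone association curves.

## CD conversion

`[θ]_λ = θ_λ / (10·l·c·(n−1))` with θ in millidegrees, path length l in
cm, concentration c in mol/L and n residues; the factor 10 carries the
units into deg·cm²·dmol⁻¹.  Concentration comes from the label's
absorbance by Beer–Lambert (`ε = 90000 /M/cm at 556 nm` for TMR).
Baseline correction is element-wise blank subtraction; no smoothing.

## Study conditions (synthetic)

One fixed instrument-like parameter set: w0 = 0.25 µm, wz = 1.25 µm
(K = 5), monomer brightness 30 kcounts/s, background 500 counts/s.
Solution probe τ_D = 0.5 ms (3D); membrane mixtures pair a bound
population (50 ms, or 200 ms for the degraded "poor binder") with unbound
probe at 0.5 ms; aggregates are 50× brighter, either diffusing at
τ_D = 100 ms with 0.05 expected occupancy (spike production) or immobile
and bleaching at 0.05 /s (complex-ACF production; 12 particles, the
aggregate-dominated regime).  The poor-binder cohort draws per-spot
composition stochastically (60 % of spots contain the diffusing aggregate,
60 % the immobile cluster, independently), emulating spatial heterogeneity
of aggregation; the good binder is aggregate-free with bound fraction 0.5.

What the generator does **not** emulate: detector afterpulsing and dead
time, anomalous diffusion, membrane topography, explicit oligomerization
kinetics, multi-state photophysics, and optical aberrations.  Passing
benchmarks therefore demonstrate correctness of the estimators and
classifiers under the stated model, not robustness to every artifact of
real hardware.

## Problem sizes

Recovery benchmarks use 10–20 independent seeds per condition; detector
characteristics use 20 traces per arm; cohorts use 20 spots per binder.
Measurement lengths are 20 s for spike counting (and solution
measurements) and 60 s where ACF accuracy at second-scale lags matters
(two-component recovery, complex-ACF classification, cohorts).
Tolerances follow the weakest link in each chain: ±15 % on N and 3D τ_D
(finite-box and background biases of a few percent plus fit variance),
±25 % on two-component τ_Ds, ±0.10 on equal-brightness mole fractions,
±0.05 on the 20-seed mean of the brightness-bias law.

## Known limitations

* The multiple-tau estimate at deep levels is a triangularly smoothed
  ACF; fits of extremely stiff multi-decade curves should use the direct
  estimator or finer m.
* Mole fractions are brightness-squared weighted by construction; the
  package reports them as apparent fractions and does not attempt
  brightness deconvolution.
* The complex-ACF flag is a numeric surrogate for what was historically a
  visual judgement; its false-positive rate rises steeply when the trace
  length is within an order of magnitude of the flag window.
* Immobile bleaching emitters violate the stationarity the correlator
  assumes; that violation is exactly the signature the classifier uses,
  so their fitted parameters (when a fit converges) are not physical.
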