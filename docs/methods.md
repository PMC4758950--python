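# Methods

## The two-state model and its parameters

A microtubule plus end is modelled as a two-state continuous-time
process: in *growth* the length increases at v₊ (µm/min) and switches to
shrinkage with constant hazard f₊₋ (min⁻¹); in *shrinkage* it decreases
at v₋ and switches back with hazard f₋₊, or reaches the stabilized seed
(length 0) and renucleates.  Renucleation is instantaneous by default
(an optional exponential delay is available on the simulator).  With
constant hazards, the mean distance grown before a catastrophe is
v₊/f₊₋ (the *catastrophe distance*) and the mean distance shrunk before
a rescue is v₋/f₋₊ (the *rescue distance*).  Ignoring rescues and the
finite shrinkage time, the mean length at time t after seeding is the
renewal-age identity

    E[L(t)] = (v₊/f₊₋) · (1 − exp(−t·f₊₋)),

which the instant-reset Monte-Carlo simulator reproduces exactly (the
length is v₊ times the backward recurrence time of a Poisson process).
Note the model has no catastrophe aging: hazards are memoryless.  Real
microtubules show multi-step (gamma-like) catastrophe kinetics; all
error rules below assume the Poisson case and are therefore
conservative.

## The antenna positive-feedback model

Motor coupling is simulated mechanistically.  Motors in solution at
concentration c (nM) land anywhere on the lattice with rate
`landing_rate`·c per µm, walk toward the plus end at 2.1 µm/min (their
speed on a dynamic lattice), detach with rate velocity/run-length
(exponential run lengths, mean 4.1 µm), join a finite plus-end pool on
arrival (capacity 12 motors, matching the maximum accumulation seen by
fluorescence), and leave the pool with rate 60/30 s⁻¹.  The filament's
instantaneous rates are linear in the pool occupancy N:

    v = v₀ + (v_max − v₀)·N/N_sat      f = f₀ − (f₀ − f_min)·N/N_sat

with N_sat the pool capacity.  A catastrophe disperses the pool (the
growing-end structure is lost); a shrinking tip releases motors it
depolymerizes past; reaching the seed releases everything.  All waiting
times are sampled exactly (first-reaction scheme; the
length-proportional landing process by closed-form inversion of its
integrated rate), so there is no time-step error; populations stay
~10², so no approximate leaping is needed.

**Calibration.**  The coupling endpoints are taken from the reference
tables: v₀ = 0.294, v_max = 1.03 µm/min, f₀ = 0.166, f_min = 0.004
min⁻¹, with saturation constant A = 39.8 µm·nM from the length-binned
growth fit.  The landing rate (0.6 µm⁻¹nM⁻¹min⁻¹, the one unmeasured
parameter) is set so that the small-load antenna occupancy
J·τ_end ≈ N_sat·cL/A matches that A.  This calibration reproduces the
motor-free and 40 nM endpoints; at intermediate concentrations the
simulated feedback builds more slowly than the real 5 nM condition
(simulated mean length ≈ 1.9 µm at 10 min vs 5.3 µm measured), because
occupancy must bootstrap from short filaments.  Analyses that need
filaments above the 4 µm cutoff at 5 nM therefore use longer (30 min)
windows.

## The functional form of the length-dependent growth law

The growth law is taken as v(L, c) = v₀ + (v_max − v₀)·cL/(A + cL) —
the unique single-saturation-constant form consistent with A's units
(µm·nM) and with saturation in the antenna load cL.  The catastrophe
law mirrors it downward with the same A by default (only the endpoint
folds are constrained by measurement; f₀ and f_min are independently
configurable).  Both forms live in `model_core` as plain functions so
alternates can be swapped.

## What the synthetic data emulate — and what they do not

`generate_assay` samples exact event-driven trajectories at a fixed
frame interval (default 2 s) and adds i.i.d. Gaussian tip-localization
noise (default 0.05 µm, the diffraction-limited scale; both values are
assumptions recorded in every bundle manifest, as the originating
assays' acquisition parameters are unpublished).  Not emulated: images,
tracking failures, drift, length-dependent noise, catastrophe aging,
filament-filament interactions, or nucleotide-state (GTP-cap) dynamics.
Passing tests therefore demonstrate correctness of the estimators
against this generative model, not robustness to real-world imaging
artifacts.

Per-condition microtubule counts are sized so a 10-min assay yields
roughly the event counts printed in the reference tables (at least 20
microtubules).  The yeast table prints no shrinkage/rescue values;
bundles simulate those rows with a nominal v₋ = 25 µm/min and f₋₊ = 0,
and the porcine rows with unmeasured cells use 28 µm/min and 0.  The
generating parameters are written to `truth.json`, separate from
`manifest.json`; the analysis stage reads only the latter.

## Trace segmentation

Shrinkage is ~two orders of magnitude faster than growth, so the
segmenter works in two passes:

1. **Steep drops.**  Frame displacements below −max(4√2·σ̂, θ·Δt) are
   marked (σ̂ is a median-absolute-deviation noise estimate from second
   differences; θ = 0.1 µm/min is the slope threshold that keeps
   noiseless traces exact).  Consecutive marked displacements form
   candidate shrinkage windows, extended over residual sub-threshold
   drop from partial frames.
2. **Shallow resets.**  A catastrophe striking near the seed drops the
   tip by only ~1–3σ, but slow regrowth leaves a persistent level
   shift.  Trend-corrected before/after window means at widths 4–32
   frames flag these steps; a local step-plus-trend least-squares fit
   refines the changepoint.

Candidate windows whose denoised level drop (flanking growth lines) is
within noise are rejected as spikes.  Growth slopes are per-phase least
squares excluding one guard frame beside each event.  Shrinkage speed
is estimated per excursion by fitting the continuous piecewise-linear
model (fixed flanking growth lines, free catastrophe time and shrink
slope) to every frame in the window — an estimator with no selection on
the noise, hence unbiased; excursions with fewer than two fully
interior frames have unresolvable speed and are excluded from the
shrink-rate average (their durations still count).  A reversal is a
*rescue* only if the next growth line at the valley sits more than
max(4σ̂, 0.05 µm) above the seed; lower reversals are renucleations.

**Detection floor.**  Catastrophes whose excursion depth is below ~2×
the localization noise (≈0.1 µm at default noise) are physically
indistinguishable from noise at ±2-frame resolution; at the motor-free
porcine rates they are ~8 % of events, so the catastrophe frequency
carries a bias of that order — within 1 SE at the reference event
counts.  The false-rescue rate (seed reversals misread as rescues) is
2–5 % of reversals.  Both figures are measured against the generating
event log in the test suite.

## Estimation rules

Growth and shrinkage rates are means of per-phase slopes with SEs over
phases.  Switching frequencies divide event counts by the time spent in
the *source phase* (so that v₊/f̂₊₋ equals the mean growth excursion,
making the ratio identities exact by construction); a config switch
(`freq_denominator="total_time"`) implements the alternative
whole-observation-time convention.  Frequency SEs follow the Poisson
rule estimate/√n.  Mean length at harvest is the mean final tip
position across microtubules.  The short/long catastrophe-length
statistic sums growth distance below/above a 4 µm cutoff (optionally
adding a `seed_length` offset, default 0) and divides by the
catastrophes striking on that side.

Curve fits: exponential dwell/run distributions by maximum likelihood
with right-censoring (mean = total time / uncensored count; a
histogram least-squares mode with optional first-bin exclusion
replicates histogram-based practice); dose-response saturation and the
joint length law by (optionally SE-weighted) nonlinear least squares;
tubulin kinetics by SE-weighted linear regression, with the slope
converted to a per-dimer association rate via 1625 dimers/µm
(13 protofilaments × 125 dimers/µm).  A saturation fit whose half-max
SE exceeds the estimate is flagged `weakly_identified` rather than
rejected — the yeast growth column is the canonical example, where the
plateau is barely reached inside the measured range.  Note that the
SE-weighted and unweighted saturation fits of a dose-response can
differ materially when the plateau is unconstrained; the unweighted fit
of the porcine growth column places the half-max near 8 nM, the
weighted one near 16 nM.

## Numerical and reproducibility choices

Internal units are µm and minutes (dwell parameters in seconds at the
interface).  Unbounded excursion distances (zero event frequency) are a
tagged sentinel, printed as dashes, never `inf` from overflow.  All
randomness derives from one root seed via `SeedSequence.spawn`;
identical configuration ⇒ byte-identical bundles and analysis outputs.
Problem sizes in the tests and the acceptance script follow the
reference tables' printed event counts (10-min assays, 20–113
microtubules per condition; 10⁴–10⁵ draws for distributional checks).

## Known limitations

* No catastrophe aging, pause states, or GTP-cap kinetics.
* The occupancy→rate mapping and the landing rate are calibrated, not
  measured; intermediate-concentration kinetics are qualitative.
* Shrink-rate estimates use only excursions ≥ ~3 frames deep; at 2 s
  frames and motor-free excursion sizes this is a minority of events
  (unbiased, but with wider SEs than an idealized tracker could give).
* Statistical comparisons are reported as estimates ± SE only;
  hypothesis-test replication is out of scope.
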