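# kip2mt

Stochastic simulation and kymograph-style analysis of length-dependent
microtubule growth promotion by the budding-yeast kinesin Kip2.

## The problem

Microtubules switch stochastically between persistent growth and rapid
shrinkage (*dynamic instability*), characterised by four parameters: the
growth rate v₊, the catastrophe frequency f₊₋ (growth → shrinkage), the
shrinkage rate v₋, and the rescue frequency f₋₊ (shrinkage → growth).
The kinesin Kip2 is a processive, plus-end-directed motor that raises v₊
and suppresses f₊₋, and it does so *length-dependently*: motors land
along the filament lattice in proportion to its length (the filament
acts as an antenna), walk to the plus end faster than the end grows, and
accumulate there in a small pool whose occupancy sets the end's
behaviour.  Longer filaments therefore capture more motors, grow faster,
and catastrophe less — a mechanical positive-feedback loop that switches
filaments from a short to an effectively unbounded state.

`kip2mt` provides, for people modelling or analysing such assays:

* **Closed forms** (`kip2mt.model_core`): the expected length of a
  filament with instant post-catastrophe renucleation,
  L(t) = (v₊/f₊₋)(1 − e^(−t·f₊₋)); mean excursion distances v₊/f₊₋ and
  v₋/f₋₊; the length-dependent growth law
  v(L, c) = v₀ + (v_max − v₀)·cL/(A + cL) and its catastrophe mirror;
  the antenna end flux J = k_on·c·λ(1 − e^(−L/λ)); and the conversion
  between growth-rate slopes and per-dimer tubulin association rates.
* **Exact event-driven simulators** (`kip2mt.simulate`): the two-state
  dynamic-instability model; the coupled antenna model, in which motors
  land, walk, detach, pool at the plus end (capacity 12) and drive
  v and f through the pool occupancy; and single-molecule runs with
  exponential run lengths, Gaussian velocities, end residence, and
  competing photobleaching.
* **Assay emulation** (`kip2mt.synthetic`): sampled, noisy tip-position
  traces for every condition of the packaged porcine (12 µM tubulin) and
  yeast (4 µM) reference tables, plus single-molecule run tables with
  right-censoring.
* **The analysis pipeline** (`kip2mt.analysis`): kymograph-style phase
  segmentation of tip traces, catastrophe/rescue detection,
  per-condition statistics with Poisson (1/√n) errors, length-binned
  growth profiles, the short-vs-long catastrophe-length statistic
  (4 µm cutoff), and exponential / saturation / length-law / weighted
  linear fits.

## Worked example

Simulate a motor-free porcine assay (76 microtubules, 10 min, 2 s
frames, 0.05 µm localization noise) and re-estimate its parameters:

```python
import kip2mt as k

d = k.DynamicsParams(growth_rate=0.32, catastrophe_freq=0.166,
                     shrink_rate=27.6, rescue_freq=0.88)
cfg = k.AssayConfig(species="porcine", kip2_conc=0.0,
                    n_microtubules=76, seed=11)
traces = k.generate_assay(cfg, d)
res = k.MicrotubuleDynamics(traces).fit()
print(res.summary())
```

```
Microtubule dynamic instability
=======================================================
statistic                    estimate      SE     n
-------------------------------------------------------
growth rate (um/min)            0.325   0.006   185
shrinkage rate (um/min)        28.349   0.323    19
catastrophe freq (1/min)        0.144   0.014   109
rescue freq (1/min)             1.014   0.586     3
-------------------------------------------------------
catastrophe distance (um)   2.258782327249953
rescue distance (um)        27.95353240373877
mean final length (um)          1.821
```

The pipeline recovers the generating rates within statistical error:
growth 0.325 ± 0.006 vs 0.32; catastrophe 0.144 ± 0.014 vs 0.166 (109
events detected; catastrophes striking within ~0.1 µm of the seed are
below the localization noise and cannot be counted); shrinkage
28.3 ± 0.3 vs 27.6 from the 19 excursions deep enough to resolve the
shrink slope.  The derived catastrophe distance (growth rate divided by
catastrophe frequency, here 2.26 µm) is the mean length grown before a
catastrophe, and `k.expected_length(res.params(), 10.0)` → 1.72 µm
matches the measured mean final length 1.82 ± 0.26.

The same pipeline runs from the shell:

```bash
kip2mt simulate --seed 7 --out bundle      # all 12 table conditions
kip2mt analyze  --bundle bundle            # -> results/dynamics_estimates.csv
kip2mt report   --results bundle/results   # tables, fits, plots
```

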