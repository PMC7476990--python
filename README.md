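# egmorph

Automated morphology analysis of unipolar contact electrograms (EGMs) under
gap-junction uncoupling, with a mechanistic synthetic-study generator.

## The problem

During cardiac mapping, an electrode held against the myocardium records a
unipolar electrogram: a passing activation wavefront writes a biphasic
R-then-S deflection whose shape encodes the state of the local tissue.
Pharmacological gap-junction uncoupling (e.g. carbenoxolone) slows and
fragments conduction, and that shows up in the EGM as a longer stimulus-to-
(-dV/dt)max latency, a smaller (-dV/dt)max, deeper S waves and fractionated
(multi-deflection) complexes — a controllable stand-in for a pro-arrhythmic
substrate. `egmorph` is for electrophysiology researchers who want that
whole measurement chain as tested, reproducible code: simulate paced
multi-electrode recordings from a tissue sheet with tunable intercellular
coupling, extract 19 time-domain morphology features plus activation
latency for every beat, and compare baseline against drug with the standard
statistics.

## The model in brief

* **Propagation** — activation times on an `n × n` tissue lattice are exact
  shortest-path travel times (Dijkstra on the 8-connected graph), with
  nodewise conduction velocity `v = v₀√c · exp(g)` for coupling factor
  `c ∈ (0, 1]`, log-normal texture `g`, and millimetre-scale slow patches
  that emulate discontinuous conduction.
* **Forward model** — unipolar potentials from the current-source-density
  kernel `φₑ(t) = k Σᵢ ∇²Vmᵢ(t)/rᵢₑ` at a 4×4 grid catheter 0.5 mm above
  the sheet.
* **Features** — per beat: Q/R/S/endpoint amplitudes, intervals and widths,
  gradients, a fractionation index (count of distinct downstrokes),
  `(-dV/dt)max` and stimulus latency; definitions in `docs/methods.md`.
* **Statistics** — Welch two-sided t-tests per feature with percent change
  `100·(CBX − BL)/|BL|`, and a four-parameter logistic dose–response
  `L(d) = A + (B − A)/(1 + (d50/d)^h)` fitted to latency-vs-dose by
  multi-start weighted least squares.

## Worked example

Simulate a 16-site paired study (baseline vs uncoupler at the same sites),
extract every beat, and compare conditions:

```python
import numpy as np
from egmorph import (SimulationConfig, simulate_paired_study, extract_table,
                     ConditionComparison, DoseResponse, simulate_dose_response)

cfg = SimulationConfig(seed=7)            # defaults: 80x80 sheet, c_drug=0.4
recs = simulate_paired_study(cfg)         # 32 recordings, 16 sites x {BL, CBX}
table = extract_table(recs, heart_id="P01")
res = ConditionComparison(table).fit()    # Welch tests, all beats pooled
print(res.summary())
```

Selected rows of the output (BL mean (SD), CBX mean (SD), p, % change):

```
stim_to_dvdt_latency      48.37 ( 6.56)    76.19 (12.08)  p=0.00e+00   +57.52%
dvdt_max                   2.36 ( 0.07)     1.93 ( 0.31)  p=5.15e-240  -18.33%
s_point                   -5.81 ( 3.24)    -6.12 ( 3.32)  p=2.89e-02    -5.46%
fractionation_index        1.00 ( 0.00)     1.03 ( 0.16)  p=1.72e-07    +2.64%
amplitude                  6.52 ( 0.07)     7.35 ( 0.72)  p=8.73e-191  +12.82%
```

Uncoupling lengthens the stimulus-to-(-dV/dt)max latency (48 → 76 ms here),
lowers (-dV/dt)max, deepens the S wave and raises the fractionation index —
the qualitative signature reported for carbenoxolone in intact hearts.

The dose–response arm maps cumulative dose to coupling through a Hill
curve, simulates one recording per dose and fits the 4PL to the measured
latencies:

```python
doses = np.arange(0.0, 55.0, 5.0)
sim = simulate_dose_response(cfg, doses)
means, sds = zip(*((t.mean(), t.std(ddof=1)) for t in
                   (extract_table([r]).df["stim_to_dvdt_latency"]
                    for _, r in sim)))
print(DoseResponse(doses, means, sds).fit().summary())
```

```
Dose-response 4PL fit
  lower asymptote A :   49.076 ms
  upper asymptote B :   69.933 ms
  half-effect d50   :   26.790 ml
  rmse              :   1.9469 ms
```

i.e. the latency rises sigmoidally from its baseline asymptote to a
saturating value as the uncoupler accumulates.

There is also a CLI covering the same stages end to end:

```sh
egmorph run --out results/run1 --seed 7        # simulate→extract→compare→fit
egmorph compare results/run1/feature_table.csv --out comparison.csv
```

`run` writes 32 recording CSVs, the per-beat feature table, the comparison
table, the dose–response fit and a checksummed manifest; identical config
and seed reproduce identical bytes.

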