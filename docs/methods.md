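# Methods

`egmorph` models, measures and compares unipolar contact electrograms (EGMs)
recorded from paced cardiac tissue under gap-junction uncoupling. It has
three layers: a mechanistic tissue/electrode simulator, a deterministic
morphology feature extractor, and a statistical arm (condition comparison
and dose–response modelling). This note records the model, its assumptions,
the tunable parameters, and the design choices made where the design was
genuinely open.

## Tissue and propagation model

The tissue is a flat `grid_n × grid_n` sheet of nodes spaced `dx` mm apart
(default 80 × 80 at 0.5 mm, a 4 cm square of epicardium). Each node carries
a local conduction velocity (CV); activation spreads from a pacing node as
the single-source shortest-path travel time over the 8-connected lattice,
with edge cost equal to the Euclidean edge length divided by the harmonic
mean of the endpoint CVs. This eikonal-style treatment is exact (Dijkstra,
no heuristic), deterministic, and testable against an independent
exhaustive-relaxation oracle; it deliberately carries no ionic-current
dynamics, because only activation-time geometry is needed downstream.

Gap-junction coupling is a single factor `c ∈ (0, 1]`:

* **Conduction.** Ambient CV is `base_cv · √c` (continuous cable theory:
  macroscopic CV scales with the square root of intercellular conductance).
  Default `base_cv` = 0.6 mm/ms.
* **Upstroke.** The local upstroke time constant widens as
  `τ · c^(−upstroke_slowing_exponent)` with exponent 0.25 by default. The
  exponent is deliberately *below* 0.5: an uncoupler acts at junctions, not
  at sodium channels, so membrane kinetics slow less than propagation. A
  consequence worth stating explicitly is that the depolarisation
  wavelength `w = v·τ ∝ c^(0.5−β)` *shrinks* under uncoupling. Since the
  extracellular source density of a wavefront scales like 1/w while the
  temporal slope of the electrogram scales like 1/τ, this one choice makes
  the S wave deepen while (-dV/dt)max falls — the empirical signature of
  uncoupling — and any exponent in (0, 0.5) preserves both directions.
* **Disorder.** Uncoupled tissue is spatially disordered at two scales.
  Per-node i.i.d. log-normal CV texture with log-SD
  `heterogeneity_scale · (1 − c)` (0.17 by default) supplies fine-grained
  jitter. Contiguous **slow patches** — the upper `patch_scale · (1 − c)`
  areal fraction (0.4 by default) of an independent Gaussian random field
  smoothed to a 1 mm correlation length, with CV multiplied by
  `patch_slow_factor` = 0.2 — supply millimetre-scale conduction delays
  between bundles. The patch scale matters: disorder at the single-node
  (0.5 mm) scale is averaged away by path integration and by the 1/r
  electrode kernel and produces neither fractionation nor S-wave change,
  whereas bundle-scale delays split the wavefront into wavelets that arrive
  at an electrode as distinct deflections.

The drug condition uses `c_drug` (default 0.40). The dose→coupling map is a
Hill function `c(d) = 1 − (1 − c_drug)·d^h/(d50^h + d^h)` (defaults d50 =
25 ml, h = 3), chosen to produce the sigmoidal latency progression seen
during a constant-rate wash-in; no quantitative concentration–uncoupling
relation is claimed.

## Action potential and forward model

The action potential is phenomenological: rest −80 mV, a logistic upstroke
of 100 mV amplitude and duration ~τ (default 3 ms; maximum rate
≈ amplitude/τ), a plateau, and a smooth tanh repolarisation essentially
complete by the APD (250 ms ventricular, 150 ms atrial). τ = 3 ms keeps the
wavefront width v·τ ≈ 1.8 mm above the lattice resolution so the discrete
source density behaves continuously. Nodes whose travel time exceeds the
beat window never activate within the beat (functional block) and stay at
rest.

Electrode potentials follow the standard current-source-density model of
unipolar electrography: transmembrane current is proportional to the
Laplacian of the membrane potential (uniform intracellular conductivity),
and

    φ_e(t) = k · Σ_i ∇²Vm_i(t) / r_ie ,

with the 5-point discrete Laplacian (replicated-edge/Neumann boundaries)
and `r_ie` the 3D distance from electrode *e* (at `height` mm above the
sheet, default 0.5) to node *i*. The Laplacian sums to approximately zero
over the sheet, so charge conservation — and hence the biphasic R-then-S
morphology of a passing wavefront with near-zero DC content — is automatic
rather than imposed. The sign convention is fixed by the phenomenology that
an approaching wavefront reads positive. The gain `k` is calibrated at run
time so a homogeneous baseline beat has ≈ 6.5 mV median peak-to-peak
amplitude (`target_p2p`), matching the magnitude scale of intact-heart
epicardial recordings; the same `k` then applies to all conditions.

An earlier derivative-source formulation (`I_i ∝ dVm_i/dt` with an explicit
zero-sum correction) was implemented and rejected: its EGM amplitude is
proportional to the instantaneous activation rate and therefore to CV, so
*every* deflection shrinks under uncoupling and a deepening S wave is
unobtainable in principle. The Laplacian model keeps amplitude approximately
invariant under CV·τ-matched slowing and is the physically canonical choice.

## Study geometry and acquisition realism

A 4 × 4 electrode grid (3 mm pitch) is placed centrally over the sheet;
each of 16 recording sites gets an independent seeded placement jitter
(±3 mm translation, ±15° rotation), used identically for the baseline and
drug recordings of that site, mirroring a protocol in which drug recordings
revisit the baseline positions. Sites 1–12 use ventricular and 13–16 atrial
AP parameters. The pacing node sits near one corner, ~22 mm from the grid
centre, giving a baseline stimulus-to-(-dV/dt)max latency of ≈ 48 ms at
0.6 mm/ms. At the frozen defaults the uncoupled condition averages ≈ 78 ms;
the slow patches add conduction delay on top of the √c slowing, so the
shift overshoots a pure-velocity estimate. Pacing is steady at a fixed
cycle length (default 750 ms from the standard set {300, 400, 500, 660,
750, 1000, 1500}); one beat is synthesised and tiled `n_beats` times
(default 4), which is exact whenever activation + APD + repolarisation tail
fit inside one cycle (true for all defaults; very short cycles would
truncate the tail at beat boundaries).

Acquisition artefacts are added on top: a 2-sample biphasic stimulus
artefact (±8 mV) at each pacing time, white Gaussian noise (SD 0.03 mV),
and 0.5 Hz sinusoidal baseline wander (0.15 mV) with random phase per
channel — the low-frequency content a 0.3–500 Hz clinical band admits.

What the generator does *not* emulate: far-field signal from uninvolved
chambers, motion/contact artefacts, mains interference, repolarisation
(T-wave) morphology of real EGMs, 3D wall thickness, and re-entry. Passing
tests on synthetic studies therefore demonstrates that the *pipeline*
measures what the model produces, not that the model reproduces any
particular heart.

## Feature extraction

Recordings are zero-phase filtered (2nd-order Butterworth high-pass at
0.3 Hz, forward–backward, with padding spanning several filter time
constants; optional 50 Hz notch), resampled to 1 kHz if needed (rejected
below 600 Hz where the band cannot be honoured). Beats are cut at pacing
stimuli (metadata when present, otherwise artefact detection: samples where
|dV/dt| exceeds 10× the channel's median absolute derivative on at least
half the channels simultaneously, clustered within 5 ms); windows run
stimulus-to-stimulus and edge windows shorter than 50 ms are dropped.

Landmarks, per beat, after a 2 ms post-stimulus blanking (search only —
samples are retained):

* `act` — sample of the most negative central-difference derivative;
  `(-dV/dt)max` is its magnitude, and latency is `act` minus the stimulus
  time.
* `R` — maximum sample between onset and `act`; `S` — minimum within
  100 ms after `act`.
* onset — earliest sustained (≥ 2 ms) excursion of |dV/dt| above
  `max(5 × 1.4826·MAD of the derivative, 5% of (-dV/dt)max)` at or before
  `R`; the MAD term adapts to noise, the floor handles clean signals.
* `Q` — minimum between onset and `R` (coincides with onset on
  monotone-rising feet, the convention for monophasic complexes).
* end — earliest post-`S` time where |V| stays below 10% of the beat's
  peak-to-peak for ≥ 10 ms, else the window end.

Beats with peak-to-peak below 0.1 mV are flagged no-complex and excluded
from tables (not zero-filled, to avoid biasing means). Derivatives are
plain central differences at 1 kHz with no additional smoothing, so
fractionation detail is preserved. The fractionation index counts maximal
runs of dV/dt below −10% of (-dV/dt)max between onset and end, merging runs
separated by less than 1 ms; a clean biphasic complex scores exactly 1.
R/S widths are zero-crossing-bounded widths of the deflections containing
the R and S samples (minimum one sample). All thresholds are
`AnalysisConfig` parameters. These operational definitions are this
package's conventions; the ratio features are oriented as R/S amplitude
ratio and (r_width + s_width)/EGM-duration.

All landmark times are reported at sample resolution (no sub-sample
interpolation); on constructed piecewise-linear beats every landmark is
recovered within one sample, which is the tie-break-free accuracy the
definitions admit.

## Statistics

`ConditionComparison` pools all beats per condition (the per-beat pooling a
beat-count-style *n* implies) and runs per-feature two-sided tests —
Welch's unequal-variance t-test by default, since beats are not paired
one-to-one across conditions; Student and site/channel/beat-paired variants
are options. Sample SDs use the n−1 denominator. Percent change is
`100·(drug − baseline)/|baseline|`: the absolute-value denominator keeps
the sign interpretable for negative-baseline features (a deepening S wave
reads negative), and is the only orientation consistent with the published
table's negative-baseline rows. No multiple-testing correction is applied
by default, matching the comparison this package mirrors; Benjamini–
Hochberg is available as an option. Degenerate inputs follow fixed
conventions (two zero-variance equal-mean samples: p = 1; unequal means:
p = 0 with a warning).

`DoseResponse` fits the four-parameter logistic
`L(d) = A + (B − A)/(1 + (d50/d)^h)` — parameterized so `L(0) = A` exactly,
making the zero-dose point the baseline asymptote — by multi-start
least-squares (Levenberg–Marquardt from a grid of d50 quantiles × Hill
slopes {0.5, 1, 2, 3, 5}, log-parameterized so d50, h stay positive),
optionally inverse-SD weighted. On noiseless self-generated curves the
parameters are recovered to ~1e-15 relative error; a flat input yields
B ≈ A with ~zero RMSE.

## Problem sizes and numerical notes

The direction-of-effect and null-calibration suites each use 20 paired
16-site studies at the default configuration (≈ 2,000 beats per study); the
activation-solver oracle comparison uses 50 random 4×4–6×6 fields; landmark
recovery uses 200 constructed beats; the type-I-error check uses 2,000 null
simulations at n = 30 per arm. These sizes give stable study-level means
(direction margins several times their seed-to-seed spread) at desk-scale
runtimes.

Ties in argmin/argmax resolve to the earliest sample. The 0.3 Hz filter has
a seconds-long transient reach, so its idempotence holds in the steady-state
interior of a record, not at the edges. Velocity fields are floored at
`cv_floor` = 1e-3 mm/ms so travel times stay finite. All randomness flows
through one `numpy` Generator per study, seeded from the configuration, and
every artifact of a pipeline run is checksummed in a manifest so a re-run
with the same seed is verifiable byte-for-byte.

## Known limitations

* The simulator is 2D and monolayer-like; intact-heart far-field and
  transmural effects are absent, so absolute feature magnitudes (e.g. the
  fractionation means of real uncoupled hearts) are not reproduced — only
  the direction pattern is asserted.
* The latency shift at defaults (≈ 48 → 78 ms) overshoots a published
  47.9 → 67.2 ms shift; the coupling factor controls velocity while the
  patches add path delay, and no attempt is made to fit both knobs to one
  number.
* Percent change is undefined (NaN) for zero-baseline features.
* WFDB serialization is not provided; the CSV dialect is the interchange
  format.
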