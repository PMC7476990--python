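"""Synthetic paced unipolar-EGM generator.

The tissue is a square sheet of nodes with a nodewise conduction-velocity
(CV) field.  Gap-junction uncoupling is parameterized by a coupling factor
``c`` in (0, 1]: continuous cable theory gives CV proportional to the square
root of intercellular coupling, so ambient CV = ``base_cv * sqrt(c)``,
modulated by i.i.d. log-normal texture and by millimetre-scale "slow
patches" (contiguous regions at a fraction of the ambient CV) that emulate
discontinuous conduction between poorly coupled bundles.  The local
upstroke widens sub-proportionally to the conduction slowing (tau scaled by
``c**-beta`` with beta < 1/2): the uncoupler acts at junctions, not sodium
channels, so membrane kinetics slow less than propagation.  The
depolarisation wavelength v * tau therefore shrinks under uncoupling,
concentrating sources in space (deeper S waves) while (-dV/dt)max falls.

Activation times are exact single-source shortest-path travel times on the
8-connected node lattice (edge cost = Euclidean length / harmonic-mean CV of
the endpoints), computed with Dijkstra's algorithm.  Extracellular
potentials at each electrode follow the current-source-density forward
model of unipolar electrography: transmembrane current is proportional to
the Laplacian of the membrane potential, and

    phi_e(t) = k * sum_i [ laplacian(Vm)_i(t) / r_ie ],

with ``r_ie`` the 3D electrode-to-node distance (electrode height
included).  The Laplacian source sums to ~zero over the sheet (charge
conservation is automatic) and yields the classic biphasic R-then-S
deflection for a passing wavefront.  Nodes whose travel time exceeds the
beat window never activate within the beat (functional block) and stay at
rest.

Noise realism: a 2-sample biphasic stimulus artefact at each pacing time,
additive white Gaussian noise and 0.5 Hz sinusoidal baseline wander,
mimicking a 0.3-500 Hz / 1 kHz acquisition chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .config import ApParams, SimulationConfig, STANDARD_CYCLE_LENGTHS_MS
from .errors import ConfigError, SingularityError
from .io import EgmRecording, ElectrodeGrid, PacingProtocol

__all__ = [
    "ActivationMap",
    "build_velocity_field",
    "compute_activation_map",
    "ap_waveform",
    "forward_egm",
    "add_artifacts_and_noise",
    "calibrate_gain",
    "place_grid",
    "simulate_recording",
    "simulate_paired_study",
    "coupling_for_dose",
    "simulate_dose_response",
]


@dataclass(frozen=True)
class ActivationMap:
    """Per-node activation times (ms) from a single pacing site."""

    times: np.ndarray
    pacing_node: tuple[int, int]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if not np.isfinite(t).all():
            raise ValueError("activation times must be finite everywhere")
        if (t < 0).any():
            raise ValueError("activation times must be >= 0")
        if t[self.pacing_node] != 0.0:
            raise ValueError("activation time must be 0 at the pacing node")


def build_velocity_field(
    config: SimulationConfig,
    rng: np.random.Generator,
    coupling: float | None = None,
    heterogeneity_sd: float | None = None,
    patch_fraction: float | None = None,
) -> np.ndarray:
    """Draw a nodewise CV field (mm/ms) for a given coupling factor.

    CV = base_cv * sqrt(c) * exp(g) with g ~ N(0, sd^2) i.i.d. per node.
    A ``patch_fraction`` areal fraction of nodes — the upper tail of an
    independent Gaussian random field smoothed to ``patch_corr_mm``
    correlation length — is additionally multiplied by
    ``patch_slow_factor``, forming contiguous slow patches.  Draw order is
    fixed (texture first, then the patch field), so the stream layout is
    reproducible for a given seed.  All CVs are floored at ``cv_floor``.
    """
    c = config.coupling_factor if coupling is None else coupling
    if not (0.0 < c <= 1.0):
        raise ConfigError(f"coupling must be in (0, 1], got {c}")
    sd = config.resolved_heterogeneity_sd(c) if heterogeneity_sd is None else heterogeneity_sd
    pf = config.resolved_patch_fraction(c) if patch_fraction is None else patch_fraction
    n = config.grid_n
    g = rng.normal(0.0, sd, size=(n, n)) if sd > 0 else np.zeros((n, n))
    cv = config.base_cv * math.sqrt(c) * np.exp(g)
    if pf > 0:
        u = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, size=(n, n)),
            config.patch_corr_mm / config.dx,
            mode="nearest",
        )
        cv[u >= np.quantile(u, 1.0 - pf)] *= config.patch_slow_factor
    return np.maximum(cv, config.cv_floor)


# relative neighbour offsets defining the 8-connected lattice (one direction
# per undirected edge)
_EDGE_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def compute_activation_map(
    field: np.ndarray, pacing_node: tuple[int, int], dx: float
) -> ActivationMap:
    """Exact shortest-path activation times over the 8-connected lattice.

    Edge cost between neighbouring nodes a, b is the Euclidean edge length
    divided by the harmonic mean of their CVs; the map is the single-source
    Dijkstra solution from ``pacing_node`` (no heuristic).
    """
    field = np.asarray(field, dtype=float)
    nr, nc = field.shape
    i0, j0 = pacing_node
    if not (0 <= i0 < nr and 0 <= j0 < nc):
        raise IndexError(f"pacing_node {pacing_node} outside {nr}x{nc} grid")

    rows_l, cols_l, w_l = [], [], []
    idx = np.arange(nr * nc).reshape(nr, nc)
    for di, dj in _EDGE_OFFSETS:
        sl_a = (slice(max(0, -di), nr - max(0, di)),
                slice(max(0, -dj), nc - max(0, dj)))
        sl_b = (slice(max(0, di), nr - max(0, -di)),
                slice(max(0, dj), nc - max(0, -dj)))
        a = idx[sl_a].ravel()
        b = idx[sl_b].ravel()
        cv_a = field.ravel()[a]
        cv_b = field.ravel()[b]
        hmean = 2.0 * cv_a * cv_b / (cv_a + cv_b)
        dist = dx * math.hypot(di, dj)
        rows_l.append(a)
        cols_l.append(b)
        w_l.append(dist / hmean)
    rows = np.concatenate(rows_l)
    cols = np.concatenate(cols_l)
    weights = np.concatenate(w_l)
    graph = coo_matrix((weights, (rows, cols)), shape=(nr * nc, nr * nc))
    times = dijkstra(graph.tocsr(), directed=False, indices=i0 * nc + j0)
    return ActivationMap(times=times.reshape(nr, nc), pacing_node=(i0, j0))


def ap_waveform(t_since_activation: np.ndarray | float, ap: ApParams) -> np.ndarray:
    """Transmembrane potential (mV) as a function of time since activation.

    Resting potential before activation; a logistic upstroke of duration
    ~``upstroke_tau`` rising ``amplitude`` mV (max rate ~ amplitude / tau at
    t = 3 tau); a plateau followed by a smooth tanh repolarisation that is
    essentially complete by ``apd``.  Continuous everywhere; exactly at rest
    for t <= 0.
    """
    t = np.asarray(t_since_activation, dtype=float)
    scale = ap.upstroke_tau / 4.0
    tc = 3.0 * ap.upstroke_tau
    with np.errstate(over="ignore"):
        u = 1.0 / (1.0 + np.exp(-(t - tc) / scale))
    u0 = 1.0 / (1.0 + math.exp(tc / scale))
    u = (u - u0) / (1.0 - u0)
    w = 0.15 * ap.apd
    tr = ap.apd - 2.5 * w
    r = 0.5 * (1.0 + np.tanh((tr - t) / w))
    vm = ap.rest + ap.amplitude * u * r
    return np.where(t <= 0.0, ap.rest, vm)


def forward_egm(
    act_map: ActivationMap,
    ap: ApParams,
    grid: ElectrodeGrid,
    config: SimulationConfig,
    gain: float | None = None,
    duration_ms: float | None = None,
) -> EgmRecording:
    """Noise-free single-beat unipolar EGMs from an activation map.

    Returns an :class:`EgmRecording` spanning one cycle length (stimulus at
    t = 0).  Sources are the discrete 5-point Laplacian of the membrane
    potential (Neumann boundaries), weighted by the 1/r kernel.  Nodes
    whose activation time falls outside the beat window act as functional
    block and stay at rest.  ``gain`` defaults to ``config.gain`` (or 1.0).
    """
    if grid.height <= 0:
        raise SingularityError("electrode height must be > 0 for the 1/r kernel")
    k = gain if gain is not None else (config.gain if config.gain is not None else 1.0)
    duration = config.cycle_length if duration_ms is None else duration_ms
    fs = config.fs
    dt = 1000.0 / fs
    n_t = int(round(duration * fs / 1000.0))
    t = np.arange(n_t) * dt

    nr, nc = act_map.times.shape
    act = act_map.times

    vm = ap_waveform(t[None, None, :] - act[:, :, None], ap)
    vm[act >= duration, :] = ap.rest
    vp = np.pad(vm, ((1, 1), (1, 1), (0, 0)), mode="edge")
    lap = (
        vp[2:, 1:-1] + vp[:-2, 1:-1] + vp[1:-1, 2:] + vp[1:-1, :-2] - 4.0 * vm
    ) / config.dx ** 2
    sources = lap.reshape(nr * nc, n_t)

    jj, ii = np.meshgrid(np.arange(nc), np.arange(nr))
    node_xy = np.column_stack([jj.ravel() * config.dx, ii.ravel() * config.dx])
    elec = grid.positions()
    diff = elec[:, None, :2] - node_xy[None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=2) + elec[:, None, 2] ** 2)
    if np.min(r) < 1e-9:
        raise SingularityError("electrode coincides with a tissue node")

    samples = k * ((1.0 / r) @ sources)

    pacing = PacingProtocol(
        cycle_length=config.cycle_length,
        stimulus_times=(0.0,),
        enforce_standard_cycle=config.cycle_length in STANDARD_CYCLE_LENGTHS_MS,
    )
    return EgmRecording(samples=samples, fs=fs, grid=grid, pacing=pacing)


def add_artifacts_and_noise(
    rec: EgmRecording, config: SimulationConfig, rng: np.random.Generator
) -> EgmRecording:
    """Add stimulus artefacts, white noise and baseline wander to a recording.

    (i) a 2-sample biphasic artefact (+stim_amp then -stim_amp) at every
    stimulus time, (ii) i.i.d. Gaussian noise of SD ``noise_sd``, (iii) a
    ``wander_freq`` Hz sinusoid of amplitude ``wander_amp`` with a random
    phase per channel.  Phase draws precede the noise draw, so the stream is
    reproducible for a fixed config and seed.
    """
    s = rec.samples.copy()
    n_ch, n_t = s.shape
    for st in rec.pacing.stimulus_times:
        i = int(round(st * rec.fs / 1000.0))
        if 0 <= i < n_t:
            s[:, i] += config.stim_amp
        if 0 <= i + 1 < n_t:
            s[:, i + 1] -= config.stim_amp
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_ch)
    if config.wander_amp > 0:
        t_s = np.arange(n_t) / rec.fs
        s += config.wander_amp * np.sin(
            2.0 * np.pi * config.wander_freq * t_s[None, :] + phases[:, None]
        )
    if config.noise_sd > 0:
        s += rng.normal(0.0, config.noise_sd, size=s.shape)
    return rec.copy_with(s)


def place_grid(
    config: SimulationConfig,
    jitter_xy: tuple[float, float] = (0.0, 0.0),
    rotation_deg: float = 0.0,
) -> ElectrodeGrid:
    """Electrode grid centred on the tissue sheet, with optional offset/rotation."""
    centre = (config.grid_n - 1) * config.dx / 2.0
    span_x = (config.grid_cols - 1) * config.pitch / 2.0
    span_y = (config.grid_rows - 1) * config.pitch / 2.0
    th = math.radians(rotation_deg)
    # origin chosen so the grid's centroid lands at centre + jitter
    ox = centre + jitter_xy[0] - (span_x * math.cos(th) - span_y * math.sin(th))
    oy = centre + jitter_xy[1] - (span_x * math.sin(th) + span_y * math.cos(th))
    return ElectrodeGrid(
        rows=config.grid_rows,
        cols=config.grid_cols,
        pitch=config.pitch,
        height=config.height,
        origin=(ox, oy),
        rotation_deg=rotation_deg,
    )


def calibrate_gain(config: SimulationConfig) -> float:
    """Forward-model gain giving ~``target_p2p`` mV baseline peak-to-peak.

    Simulates one noise-free, homogeneous baseline beat (c = 1, centred
    grid) at unit gain and rescales the median per-channel peak-to-peak
    amplitude to the target.  Deterministic (no RNG involved).
    """
    field = np.full((config.grid_n, config.grid_n), config.base_cv)
    amap = compute_activation_map(field, config.pacing_node, config.dx)
    rec = forward_egm(amap, config.ventricular_ap, place_grid(config), config, gain=1.0)
    p2p = rec.samples.max(axis=1) - rec.samples.min(axis=1)
    med = float(np.median(p2p))
    if med <= 0:
        raise ConfigError("cannot calibrate gain: zero baseline amplitude")
    return config.target_p2p / med


def simulate_recording(
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    site_index: int,
    condition: str,
    coupling: float,
    grid: ElectrodeGrid | None = None,
    gain: float | None = None,
    dose_ml: float = 0.0,
    clean: bool = False,
) -> EgmRecording:
    """One multichannel, multi-beat recording at a site and coupling level.

    A single beat is synthesised from a freshly drawn CV field and tiled
    ``n_beats`` times (steady pacing at a fixed cycle length yields
    statistically identical beats); artefacts and noise are then applied
    over the full record unless ``clean``.
    """
    if grid is None:
        grid = place_grid(config)
    if gain is None:
        gain = config.gain if config.gain is not None else calibrate_gain(config)
    ap = config.ap_for_site(site_index)
    ap_eff = replace(
        ap,
        upstroke_tau=ap.upstroke_tau * coupling ** (-config.upstroke_slowing_exponent),
    )
    field = build_velocity_field(config, rng, coupling=coupling)
    amap = compute_activation_map(field, config.pacing_node, config.dx)
    beat = forward_egm(amap, ap_eff, grid, config, gain=gain)
    samples = np.tile(beat.samples, (1, config.n_beats))
    stim_times = tuple(i * config.cycle_length for i in range(config.n_beats))
    pacing = PacingProtocol(
        cycle_length=config.cycle_length,
        stimulus_times=stim_times,
        enforce_standard_cycle=beat.pacing.enforce_standard_cycle,
    )
    rec = EgmRecording(
        samples=samples,
        fs=config.fs,
        grid=grid,
        pacing=pacing,
        site_index=site_index,
        condition=condition,
        dose_ml=dose_ml,
    )
    if clean:
        return rec
    return add_artifacts_and_noise(rec, config, rng)


def simulate_paired_study(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[EgmRecording]:
    """A full 16-site baseline/uncoupled paired study (32 recordings).

    Sites 1-12 use ventricular AP parameters, 13-16 atrial.  Each site gets
    one randomly placed electrode grid used identically for its BL (c = 1)
    and CBX (c = ``c_drug``) recordings, mirroring a protocol where drug
    recordings are taken at the same positions as baseline.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gain = config.gain if config.gain is not None else calibrate_gain(config)
    recs: list[EgmRecording] = []
    for site in range(1, 17):
        jx, jy = rng.uniform(-config.site_jitter_mm, config.site_jitter_mm, size=2)
        rot = rng.uniform(-config.site_rotation_deg, config.site_rotation_deg)
        grid = place_grid(config, (jx, jy), rot)
        recs.append(
            simulate_recording(
                config, rng, site_index=site, condition="BL",
                coupling=1.0, grid=grid, gain=gain,
            )
        )
        recs.append(
            simulate_recording(
                config, rng, site_index=site, condition="CBX",
                coupling=config.c_drug, grid=grid, gain=gain, dose_ml=50.0,
            )
        )
    return recs


def coupling_for_dose(config: SimulationConfig, dose_ml: float) -> float:
    """Hill-type map from cumulative uncoupler dose (ml) to coupling factor.

    c(d) = 1 - (1 - c_drug) * d^h / (d50^h + d^h); c(0) = 1 and c tends to
    ``c_drug`` at saturating dose, giving the sigmoidal latency progression
    seen during drug wash-in.
    """
    if dose_ml < 0:
        raise ConfigError("dose must be >= 0")
    if dose_ml == 0:
        return 1.0
    h, d50 = config.hill_h, config.d50
    frac = dose_ml ** h / (d50 ** h + dose_ml ** h)
    return 1.0 - (1.0 - config.c_drug) * frac


def simulate_dose_response(
    config: SimulationConfig,
    doses_ml: Sequence[float],
    rng: np.random.Generator | None = None,
    clean: bool = False,
) -> list[tuple[float, EgmRecording]]:
    """One recording per dose at a fixed (centred) site.

    Doses must be non-negative and strictly increasing; dose 0 is the
    baseline condition.
    """
    doses = [float(d) for d in doses_ml]
    if any(d < 0 for d in doses) or any(b <= a for a, b in zip(doses, doses[1:])):
        raise ConfigError("doses must be non-negative and increasing")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gain = config.gain if config.gain is not None else calibrate_gain(config)
    grid = place_grid(config)
    out: list[tuple[float, EgmRecording]] = []
    for d in doses:
        c = coupling_for_dose(config, d)
        rec = simulate_recording(
            config, rng, site_index=1,
            condition="BL" if d == 0 else "CBX",
            coupling=c, grid=grid, gain=gain, dose_ml=d, clean=clean,
        )
        out.append((d, rec))
    return out
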