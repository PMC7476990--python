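"""Configuration objects for the simulator and the analysis pipeline.

Two dataclasses hold every tunable parameter: :class:`SimulationConfig` for
the synthetic tissue / electrode model and :class:`AnalysisConfig` for the
feature-extraction algorithm.  Units are mV, ms, mm and Hz throughout, which
matches clinical electrogram convention.  :func:`load_config` reads either a
YAML or a JSON document with optional ``simulation:`` and ``analysis:``
sections; absent keys take defaults, unknown keys and out-of-range values
raise :class:`~egmorph.errors.ConfigError`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError

#: Pacing cycle lengths (ms) used by the study protocol this package emulates.
STANDARD_CYCLE_LENGTHS_MS = (300.0, 400.0, 500.0, 660.0, 750.0, 1000.0, 1500.0)


@dataclass
class ApParams:
    """Action-potential waveform parameters.

    rest : resting membrane potential (mV)
    amplitude : upstroke amplitude (mV); rest + amplitude is the peak plateau
    upstroke_tau : characteristic upstroke duration (ms); the maximum
        depolarisation rate scales as amplitude / upstroke_tau
    apd : action-potential duration (ms); repolarisation completes near here
    """

    rest: float = -80.0
    amplitude: float = 100.0
    upstroke_tau: float = 3.0
    apd: float = 250.0

    def __post_init__(self) -> None:
        if self.upstroke_tau <= 0:
            raise ConfigError(f"upstroke_tau must be > 0, got {self.upstroke_tau}")
        if self.apd <= 0:
            raise ConfigError(f"apd must be > 0, got {self.apd}")
        if self.amplitude <= 0:
            raise ConfigError(f"amplitude must be > 0, got {self.amplitude}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic paced-EGM study.

    The tissue is a ``grid_n`` x ``grid_n`` sheet of nodes spaced ``dx`` mm
    apart.  Local conduction velocity is ``base_cv * sqrt(coupling_factor)``
    modulated by a log-normal heterogeneity field and, optionally, near-zero
    "block patches".  ``coupling_factor`` = 1 is the well-coupled baseline;
    values below 1 emulate progressive gap-junction uncoupling (the
    carbenoxolone condition uses ``c_drug``).

    Uncoupling also widens the local upstroke, but sub-proportionally to the
    conduction slowing (``tau`` scaled by ``c**-upstroke_slowing_exponent``
    with exponent < 0.5, since the uncoupler acts on junctions rather than
    sodium channels): the depolarisation wavelength v * tau therefore
    shrinks, concentrating extracellular sources in space — deeper, sharper
    S waves — while the temporal slope (-dV/dt)max still falls.

    When ``heterogeneity_sd`` / ``patch_fraction`` are ``None`` they are
    derived from the coupling factor as ``heterogeneity_scale * (1 - c)``
    and ``patch_scale * (1 - c)``: an uncoupled sheet is both slower and
    more spatially disordered.  Disorder enters at two scales — i.i.d.
    log-normal texture per node, and millimetre-scale "slow patches"
    (contiguous regions at ``patch_slow_factor`` x the ambient CV) that
    delay conduction between bundles and fractionate the electrogram, the
    signature of discontinuous conduction.
    """

    # tissue geometry / conduction
    grid_n: int = 80
    dx: float = 0.5                  # node spacing, mm
    base_cv: float = 0.6             # baseline conduction velocity, mm/ms
    coupling_factor: float = 1.0     # dimensionless, (0, 1]
    c_drug: float = 0.4              # coupling under the uncoupler
    upstroke_slowing_exponent: float = 0.25
    heterogeneity_sd: float | None = None
    heterogeneity_scale: float = 0.17
    patch_fraction: float | None = None
    patch_scale: float = 0.4
    patch_corr_mm: float = 1.0       # Gaussian correlation length of patches
    patch_slow_factor: float = 0.2   # CV multiplier inside slow patches
    cv_floor: float = 1e-3           # mm/ms, lower bound on any node's CV

    # action potentials (sites 1-12 ventricular, 13-16 atrial)
    ventricular_ap: ApParams = field(default_factory=ApParams)
    atrial_ap: ApParams = field(default_factory=lambda: ApParams(apd=150.0))

    # pacing / acquisition
    cycle_length: float = 750.0      # ms
    n_beats: int = 4
    fs: float = 1000.0               # Hz
    stim_amp: float = 8.0            # mV, biphasic stimulus artefact
    noise_sd: float = 0.03           # mV, additive white noise
    wander_amp: float = 0.15         # mV, sinusoidal baseline wander
    wander_freq: float = 0.5         # Hz
    pacing_node: tuple[int, int] = (8, 8)

    # electrode grid and per-site placement
    grid_rows: int = 4
    grid_cols: int = 4
    pitch: float = 3.0               # mm
    height: float = 0.5              # mm above tissue plane
    site_jitter_mm: float = 3.0
    site_rotation_deg: float = 15.0

    # forward-model gain: calibrated at run time unless given explicitly
    gain: float | None = None
    target_p2p: float = 6.5          # mV, baseline peak-to-peak calibration target

    # dose -> coupling map (Hill)
    d50: float = 25.0                # ml
    hill_h: float = 3.0

    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.coupling_factor <= 1.0):
            raise ConfigError(
                f"coupling_factor must be in (0, 1], got {self.coupling_factor}"
            )
        if not (0.0 < self.c_drug <= 1.0):
            raise ConfigError(f"c_drug must be in (0, 1], got {self.c_drug}")
        if self.base_cv <= 0:
            raise ConfigError(f"base_cv must be > 0, got {self.base_cv}")
        if self.grid_n < 3:
            raise ConfigError(f"grid_n must be >= 3, got {self.grid_n}")
        if self.dx <= 0:
            raise ConfigError(f"dx must be > 0, got {self.dx}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.heterogeneity_sd is not None and self.heterogeneity_sd < 0:
            raise ConfigError("heterogeneity_sd must be >= 0")
        if self.patch_fraction is not None and not (0.0 <= self.patch_fraction < 1.0):
            raise ConfigError(
                f"patch_fraction must be in [0, 1), got {self.patch_fraction}"
            )
        if not (0.0 < self.patch_slow_factor <= 1.0):
            raise ConfigError("patch_slow_factor must be in (0, 1]")
        if not (0.0 <= self.upstroke_slowing_exponent <= 0.5):
            raise ConfigError("upstroke_slowing_exponent must be in [0, 0.5]")
        if self.cv_floor <= 0:
            raise ConfigError("cv_floor must be > 0")
        if self.cycle_length <= 0 or self.fs <= 0:
            raise ConfigError("cycle_length and fs must be > 0")
        if self.n_beats < 1:
            raise ConfigError("n_beats must be >= 1")
        if self.height <= 0:
            raise ConfigError("electrode height must be > 0 (1/r kernel)")
        if isinstance(self.ventricular_ap, dict):
            self.ventricular_ap = ApParams(**self.ventricular_ap)
        if isinstance(self.atrial_ap, dict):
            self.atrial_ap = ApParams(**self.atrial_ap)
        if isinstance(self.pacing_node, list):
            self.pacing_node = tuple(self.pacing_node)

    def resolved_heterogeneity_sd(self, coupling: float | None = None) -> float:
        """Heterogeneity SD for a given coupling factor (explicit value wins)."""
        c = self.coupling_factor if coupling is None else coupling
        if self.heterogeneity_sd is not None:
            return self.heterogeneity_sd
        return self.heterogeneity_scale * (1.0 - c)

    def resolved_patch_fraction(self, coupling: float | None = None) -> float:
        """Areal fraction of slow patches for a given coupling factor."""
        c = self.coupling_factor if coupling is None else coupling
        if self.patch_fraction is not None:
            return self.patch_fraction
        return self.patch_scale * (1.0 - c)

    def ap_for_site(self, site_index: int) -> ApParams:
        """Ventricular AP for sites 1-12, atrial (shorter APD) for 13-16."""
        return self.ventricular_ap if site_index <= 12 else self.atrial_ap


@dataclass
class AnalysisConfig:
    """Parameters of the feature-extraction algorithm.

    Every operational threshold of the landmark detector is exposed here so
    alternative definitions can be tested without touching code.
    """

    highpass_hz: float = 0.3
    filter_order: int = 2
    notch_hz: float | None = None    # e.g. 50.0 to enable mains notch
    resample_to_hz: float = 1000.0
    min_fs_hz: float = 600.0         # below this the 0.3-500 Hz band is unattainable

    blank_ms: float = 2.0            # post-stimulus blanking for landmark search
    min_beat_ms: float = 50.0        # shorter edge beats are dropped

    stim_threshold_factor: float = 10.0  # x median |dV/dt| for stimulus detection
    stim_cluster_ms: float = 5.0

    onset_threshold_factor: float = 5.0  # x derivative noise (scaled MAD)
    onset_floor_frac: float = 0.05       # floor: fraction of (-dV/dt)max
    onset_sustain_ms: float = 2.0

    s_search_ms: float = 100.0       # S trough searched within act_t + this
    end_threshold_frac: float = 0.10  # |V| threshold as fraction of peak-to-peak
    end_sustain_ms: float = 10.0

    flat_threshold: float = 0.1      # mV peak-to-peak; below -> no-complex flag
    frac_threshold_frac: float = 0.10  # fraction of (-dV/dt)max
    frac_gap_ms: float = 1.0         # deflections closer than this merge

    def __post_init__(self) -> None:
        if self.highpass_hz <= 0:
            raise ConfigError("highpass_hz must be > 0")
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        for name in (
            "blank_ms", "min_beat_ms", "onset_sustain_ms", "s_search_ms",
            "end_sustain_ms", "frac_gap_ms", "stim_cluster_ms",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("onset_floor_frac", "end_threshold_frac", "frac_threshold_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.flat_threshold < 0:
            raise ConfigError("flat_threshold must be >= 0")


def _build(cls: type, payload: dict[str, Any], section: str) -> Any:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ConfigError(f"unknown {section} key(s): {sorted(unknown)}")
    try:
        return cls(**payload)
    except TypeError as exc:  # wrong type for a field
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> tuple[SimulationConfig, AnalysisConfig]:
    """Load a YAML/JSON config file into (SimulationConfig, AnalysisConfig).

    The document may contain ``simulation:`` and/or ``analysis:`` mappings;
    an empty document yields the full defaults.
    """
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    unknown = set(doc) - {"simulation", "analysis"}
    if unknown:
        raise ConfigError(f"unknown top-level section(s): {sorted(unknown)}")
    sim = _build(SimulationConfig, doc.get("simulation") or {}, "simulation")
    ana = _build(AnalysisConfig, doc.get("analysis") or {}, "analysis")
    return sim, ana


def config_snapshot(sim: SimulationConfig, ana: AnalysisConfig) -> dict[str, Any]:
    """Plain-dict snapshot of both configs (for run manifests)."""
    return {
        "simulation": dataclasses.asdict(sim),
        "analysis": dataclasses.asdict(ana),
    }
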