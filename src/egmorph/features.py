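"""Beat segmentation and time-domain morphology feature extraction.

For every paced activation on every channel this module locates the
canonical unipolar-EGM landmarks and derives the 19 morphology features
plus the stimulus-to-(-dV/dt)max latency:

* **act** — time of the most negative first derivative (central difference);
  the activation marker of a unipolar electrogram.
* **R / S** — the positive peak preceding and the negative trough following
  activation; a clean passing wavefront gives the classic biphasic RS.
* **onset / Q** — onset is the earliest sustained derivative excursion
  before R (the foot of the complex); Q is the minimum between onset and R
  and coincides with onset for monotone-rising feet.
* **end** — the earliest time after S at which the signal stays inside a
  small band around baseline, else the window end.

Fractionation is the count of distinct negative-going deflections (maximal
runs of dV/dt below a fraction of (-dV/dt)max) between onset and end — a
clean RS complex scores 1, wavefront breakup scores higher.

Operational thresholds are deliberate conventions of this package, each
exposed on :class:`~egmorph.config.AnalysisConfig`.  Derivatives use plain
central differences at 1 kHz with no extra smoothing so that fractionation
detail survives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .config import AnalysisConfig
from .errors import (
    NoComplexError,
    SamplingRateError,
    StimulusDetectionError,
)
from .io import EgmRecording, StudyTable

__all__ = [
    "BeatComplex",
    "Landmarks",
    "FeatureVector",
    "preprocess",
    "detect_stimuli",
    "segment_beats",
    "locate_landmarks",
    "dvdt_and_latency",
    "fractionation_index",
    "extract_features",
    "extract_table",
]


@dataclass
class BeatComplex:
    """One beat window on one channel; t = 0 at the pacing stimulus."""

    samples: np.ndarray
    fs: float
    channel: int
    beat_index: int
    stimulus_offset_ms: float = 0.0   # stimulus position within the window
    site_index: int = 0
    condition: str = "BL"
    heart_id: str = ""
    cycle_length: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs

    @property
    def duration_ms(self) -> float:
        return self.samples.size * self.dt_ms


@dataclass
class Landmarks:
    """Landmark times (ms, stimulus-referenced) and amplitudes (mV)."""

    onset_t: float
    q_t: float
    r_t: float
    s_t: float
    end_t: float
    q_amp: float
    r_amp: float
    s_amp: float
    end_amp: float
    act_t: float
    dvdt_max: float
    onset_idx: int = 0
    q_idx: int = 0
    r_idx: int = 0
    s_idx: int = 0
    end_idx: int = 0
    act_idx: int = 0

    def __post_init__(self) -> None:
        if not (self.onset_t <= self.q_t <= self.r_t <= self.s_t <= self.end_t):
            raise ValueError("landmark ordering violated")
        if not (self.r_t <= self.act_t <= self.s_t):
            raise ValueError("act_t must lie in [r_t, s_t]")
        if self.dvdt_max < 0:
            raise ValueError("dvdt_max is a magnitude, must be >= 0")


@dataclass
class FeatureVector:
    """The 19 morphology features plus stimulus latency for one beat.

    Intervals/widths in ms, amplitudes in mV, gradients in mV/ms; NaN marks
    a feature undefined for the beat (degenerate landmarks).
    """

    rs_interval: float
    qr_interval: float
    qs_interval: float
    egm_duration: float
    q_point: float
    r_point: float
    s_point: float
    endpoint_amplitude: float
    rs_gradient: float
    qr_gradient: float
    s_endpoint_gradient: float
    fractionation_index: float
    r_width: float
    s_width: float
    rs_ratio: float
    rs_width_ratio: float
    rs_width_over_duration: float
    dvdt_max: float
    amplitude: float
    stim_to_dvdt_latency: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def preprocess(rec: EgmRecording, cfg: AnalysisConfig | None = None) -> EgmRecording:
    """Zero-phase acquisition-band filtering (and resampling to 1 kHz).

    A forward-backward 2nd-order Butterworth high-pass at 0.3 Hz removes DC
    and baseline drift with no group delay; an optional mains notch can be
    enabled via ``notch_hz``.  Raises :class:`SamplingRateError` below
    600 Hz, where the 0.3-500 Hz band cannot be honoured.
    """
    cfg = cfg or AnalysisConfig()
    if rec.fs < cfg.min_fs_hz:
        raise SamplingRateError(
            f"fs = {rec.fs} Hz too low for the 0.3-500 Hz acquisition band"
        )
    samples = rec.samples
    fs = rec.fs
    if fs != cfg.resample_to_hz:
        up = int(round(cfg.resample_to_hz))
        down = int(round(fs))
        g = math.gcd(up, down)
        samples = sps.resample_poly(samples, up // g, down // g, axis=1)
        fs = cfg.resample_to_hz
    sos = sps.butter(cfg.filter_order, cfg.highpass_hz, btype="highpass", fs=fs,
                     output="sos")
    # pad across several filter time constants; the default padlen is far too
    # short for a 0.3 Hz corner and leaves edge transients
    padlen = min(samples.shape[1] - 2, int(3.0 * fs / cfg.highpass_hz))
    out = sps.sosfiltfilt(sos, samples, axis=1, padlen=max(padlen, 0))
    if cfg.notch_hz is not None:
        b, a = sps.iirnotch(cfg.notch_hz, Q=30.0, fs=fs)
        out = sps.filtfilt(b, a, out, axis=1)
    filtered = rec.copy_with(np.ascontiguousarray(out))
    filtered.fs = fs
    return filtered


# --------------------------------------------------------------------------
# stimulus detection and segmentation
# --------------------------------------------------------------------------

def detect_stimuli(rec: EgmRecording, cfg: AnalysisConfig | None = None) -> np.ndarray:
    """Stimulus times (ms): pacing metadata if present, else artefact search.

    Detection marks samples where |dV/dt| exceeds ``stim_threshold_factor``
    x the channel's median absolute derivative on at least half of the
    channels simultaneously, then clusters marks within ``stim_cluster_ms``
    and returns cluster centres.
    """
    cfg = cfg or AnalysisConfig()
    if rec.pacing.stimulus_times:
        return np.asarray(rec.pacing.stimulus_times, dtype=float)
    dt = 1000.0 / rec.fs
    d = np.gradient(rec.samples, dt, axis=1)
    ad = np.abs(d)
    med = np.median(ad, axis=1, keepdims=True)
    med = np.maximum(med, 1e-12)
    above = ad > cfg.stim_threshold_factor * med
    votes = above.sum(axis=0)
    candidates = np.flatnonzero(votes >= max(1, rec.n_channels // 2))
    if candidates.size == 0:
        raise StimulusDetectionError("no stimulus artefacts found")
    gap = int(round(cfg.stim_cluster_ms / dt))
    clusters: list[list[int]] = [[int(candidates[0])]]
    for c in candidates[1:]:
        if c - clusters[-1][-1] <= gap:
            clusters[-1].append(int(c))
        else:
            clusters.append([int(c)])
    centres = np.array([np.mean(cl) for cl in clusters]) * dt
    return centres


def segment_beats(
    rec: EgmRecording,
    stim_times_ms: Sequence[float] | None = None,
    cfg: AnalysisConfig | None = None,
    heart_id: str = "",
) -> list[BeatComplex]:
    """Cut each channel into per-stimulus beat windows.

    Windows run from each stimulus to the next (last beat: stimulus +
    cycle length, clipped to the record), tiling the paced portion of the
    recording without overlap.  Edge windows shorter than ``min_beat_ms``
    are dropped.
    """
    cfg = cfg or AnalysisConfig()
    if stim_times_ms is None:
        stim_times_ms = detect_stimuli(rec, cfg)
    stims = np.sort(np.asarray(stim_times_ms, dtype=float))
    if stims.size == 0:
        raise StimulusDetectionError("segmentation requires at least one stimulus")
    dt = 1000.0 / rec.fs
    n_t = rec.n_samples
    beats: list[BeatComplex] = []
    for b, s in enumerate(stims):
        start = int(round(s / dt))
        if b + 1 < stims.size:
            stop = int(round(stims[b + 1] / dt))
        else:
            stop = int(round((s + rec.pacing.cycle_length) / dt))
        start = max(0, start)
        stop = min(n_t, stop)
        if (stop - start) * dt < cfg.min_beat_ms:
            continue
        for ch in range(rec.n_channels):
            beats.append(
                BeatComplex(
                    samples=rec.samples[ch, start:stop],
                    fs=rec.fs,
                    channel=ch + 1,
                    beat_index=b,
                    stimulus_offset_ms=s - start * dt,
                    site_index=rec.site_index,
                    condition=rec.condition,
                    heart_id=heart_id,
                    cycle_length=rec.pacing.cycle_length,
                )
            )
    return beats


# --------------------------------------------------------------------------
# landmarks
# --------------------------------------------------------------------------

def _derivative(v: np.ndarray, dt_ms: float) -> np.ndarray:
    """Central-difference derivative in mV/ms (one-sided at the ends)."""
    return np.gradient(v, dt_ms)


def _sustained_runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True-runs of at least ``min_len`` samples."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]
    return [(int(a), int(b)) for a, b in zip(starts, stops) if b - a >= min_len]


def locate_landmarks(beat: BeatComplex, cfg: AnalysisConfig | None = None) -> Landmarks:
    """Locate onset/Q/R/S/end landmarks and the activation time of a beat.

    Raises :class:`NoComplexError` for flat beats (peak-to-peak below
    ``flat_threshold``) or fully degenerate geometry; such beats are
    excluded from feature tables rather than zero-filled.
    """
    cfg = cfg or AnalysisConfig()
    v = beat.samples
    dt = beat.dt_ms
    n = v.size
    stim_idx = int(round(beat.stimulus_offset_ms / dt))
    i0 = min(stim_idx + int(math.ceil(cfg.blank_ms / dt)), n - 2)

    seg = v[i0:]
    if seg.size < 3 or float(seg.max() - seg.min()) < cfg.flat_threshold:
        raise NoComplexError("flat beat: no activation complex detected")

    d = _derivative(v, dt)
    act_idx = i0 + int(np.argmin(d[i0:]))
    dvdt_max = float(-d[act_idx])
    if dvdt_max <= 0:
        raise NoComplexError("no negative deflection in beat")

    # preliminary R: maximum sample between blanking end and activation
    r_idx = i0 + int(np.argmax(v[i0:act_idx + 1]))

    # onset: earliest sustained |dV/dt| excursion at/before R (fallback:
    # before activation, covering monophasic negative complexes)
    noise = 1.4826 * float(np.median(np.abs(d - np.median(d))))
    theta_on = max(cfg.onset_threshold_factor * noise,
                   cfg.onset_floor_frac * dvdt_max)
    sustain = max(1, int(round(cfg.onset_sustain_ms / dt)))
    runs = _sustained_runs(np.abs(d[i0:]) >= theta_on, sustain)
    onset_idx = None
    for a, b in runs:
        if a + i0 <= r_idx:
            onset_idx = a + i0
            break
    if onset_idx is None:
        for a, b in runs:
            if a + i0 <= act_idx:
                onset_idx = a + i0
                break
    if onset_idx is None:
        onset_idx = i0

    # final R within [onset, act]; ties resolve to the earliest sample
    r_idx = onset_idx + int(np.argmax(v[onset_idx:act_idx + 1]))
    # Q: minimum between onset and R (equals onset when monotone rising)
    q_idx = onset_idx + int(np.argmin(v[onset_idx:r_idx + 1]))
    # S: minimum within a bounded window after activation
    s_stop = min(n, act_idx + int(round(cfg.s_search_ms / dt)) + 1)
    s_idx = act_idx + int(np.argmin(v[act_idx:s_stop]))
    if s_idx <= r_idx:
        raise NoComplexError("degenerate beat: R and S coincide")

    # end: earliest post-S time where |V| stays inside the baseline band
    p2p = float(seg.max() - seg.min())
    theta_end = cfg.end_threshold_frac * p2p
    hold = max(1, int(round(cfg.end_sustain_ms / dt)))
    below = np.abs(v) < theta_end
    end_idx = n - 1
    for a, b in _sustained_runs(below[s_idx:], hold):
        end_idx = s_idx + a
        break

    return Landmarks(
        onset_t=onset_idx * dt,
        q_t=q_idx * dt,
        r_t=r_idx * dt,
        s_t=s_idx * dt,
        end_t=end_idx * dt,
        q_amp=float(v[q_idx]),
        r_amp=float(v[r_idx]),
        s_amp=float(v[s_idx]),
        end_amp=float(v[end_idx]),
        act_t=act_idx * dt,
        dvdt_max=dvdt_max,
        onset_idx=onset_idx,
        q_idx=q_idx,
        r_idx=r_idx,
        s_idx=s_idx,
        end_idx=end_idx,
        act_idx=act_idx,
    )


def dvdt_and_latency(beat: BeatComplex, lm: Landmarks) -> tuple[float, float]:
    """((-dV/dt)max magnitude in mV/ms, stimulus-to-(-dV/dt)max latency in ms)."""
    return lm.dvdt_max, lm.act_t - beat.stimulus_offset_ms


def fractionation_index(
    beat: BeatComplex, lm: Landmarks, cfg: AnalysisConfig | None = None
) -> int:
    """Number of distinct negative-slope deflections between onset and end.

    Counts maximal runs of dV/dt < -``frac_threshold_frac`` x (-dV/dt)max;
    runs closer than ``frac_gap_ms`` merge into one deflection.  A clean
    biphasic RS complex scores exactly 1.
    """
    cfg = cfg or AnalysisConfig()
    dt = beat.dt_ms
    d = _derivative(beat.samples, dt)
    theta = cfg.frac_threshold_frac * lm.dvdt_max
    window = d[lm.onset_idx:lm.end_idx + 1]
    runs = _sustained_runs(window < -theta, 1)
    if not runs:
        return 1
    gap = cfg.frac_gap_ms / dt
    count = 1
    for (a1, b1), (a2, b2) in zip(runs, runs[1:]):
        if (a2 - b1) * 1.0 >= gap:
            count += 1
    return count


def _zero_crossing_width(
    v: np.ndarray, peak_idx: int, positive: bool, dt: float
) -> float:
    """Width (ms) of the deflection containing ``peak_idx``, bounded by the
    nearest baseline crossings (sample resolution, minimum one sample)."""
    n = v.size
    sign_ok = (v > 0) if positive else (v < 0)
    left = peak_idx
    while left > 0 and sign_ok[left - 1]:
        left -= 1
    right = peak_idx
    while right < n - 1 and sign_ok[right + 1]:
        right += 1
    return max(right - left, 1) * dt


def extract_features(
    beat: BeatComplex,
    lm: Landmarks | None = None,
    cfg: AnalysisConfig | None = None,
) -> FeatureVector:
    """Compute the full per-beat feature vector from landmarks.

    Interval identities hold exactly in samples (qs = qr + rs, amplitude =
    R - S).  Degenerate denominators yield NaN rather than raising.
    """
    cfg = cfg or AnalysisConfig()
    if lm is None:
        lm = locate_landmarks(beat, cfg)
    dt = beat.dt_ms
    v = beat.samples

    qr = lm.r_t - lm.q_t
    rs = lm.s_t - lm.r_t
    qs = lm.s_t - lm.q_t
    duration = lm.end_t - lm.q_t

    def _ratio(num: float, den: float) -> float:
        return num / den if den != 0 else float("nan")

    r_width = _zero_crossing_width(v, lm.r_idx, positive=True, dt=dt)
    s_width = _zero_crossing_width(v, lm.s_idx, positive=False, dt=dt)
    dvdt, latency = dvdt_and_latency(beat, lm)

    return FeatureVector(
        rs_interval=rs,
        qr_interval=qr,
        qs_interval=qs,
        egm_duration=duration,
        q_point=lm.q_amp,
        r_point=lm.r_amp,
        s_point=lm.s_amp,
        endpoint_amplitude=lm.end_amp,
        rs_gradient=_ratio(lm.s_amp - lm.r_amp, rs),
        qr_gradient=_ratio(lm.r_amp - lm.q_amp, qr),
        s_endpoint_gradient=_ratio(lm.end_amp - lm.s_amp, lm.end_t - lm.s_t),
        fractionation_index=float(fractionation_index(beat, lm, cfg)),
        r_width=r_width,
        s_width=s_width,
        rs_ratio=_ratio(lm.r_amp, lm.s_amp),
        rs_width_ratio=_ratio(r_width, s_width),
        rs_width_over_duration=_ratio(r_width + s_width, duration),
        dvdt_max=dvdt,
        amplitude=lm.r_amp - lm.s_amp,
        stim_to_dvdt_latency=latency,
    )


# --------------------------------------------------------------------------
# recording -> study table
# --------------------------------------------------------------------------

def extract_table(
    recordings: Iterable[EgmRecording],
    cfg: AnalysisConfig | None = None,
    heart_id: str = "H01",
    log: list[str] | None = None,
) -> StudyTable:
    """Run the full extraction pipeline over recordings into a StudyTable.

    Each recording is band-filtered, segmented on its pacing stimuli, and
    every beat is reduced to a feature vector.  Beats flagged as having no
    complex are skipped (and noted in ``log`` if provided).
    """
    cfg = cfg or AnalysisConfig()
    records: list[dict] = []
    for rec in recordings:
        clean = preprocess(rec, cfg)
        stims = detect_stimuli(clean, cfg)
        for beat in segment_beats(clean, stims, cfg, heart_id=heart_id):
            key = (f"site={beat.site_index} cond={beat.condition} "
                   f"ch={beat.channel} beat={beat.beat_index}")
            try:
                fv = extract_features(beat, cfg=cfg)
            except NoComplexError as exc:
                if log is not None:
                    log.append(f"SKIP {key}: {exc}")
                continue
            if log is not None:
                log.append(f"OK   {key}")
            row = {
                "heart_id": heart_id,
                "condition": beat.condition,
                "site_index": beat.site_index,
                "channel": beat.channel,
                "beat_index": beat.beat_index,
                "cycle_length": beat.cycle_length,
            }
            row.update(fv.as_dict())
            records.append(row)
    if not records:
        return StudyTable.empty()
    return StudyTable.from_records(records)
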