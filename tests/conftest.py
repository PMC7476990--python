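"""Shared fixtures: small simulation configs and constructed test beats."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from egmorph import AnalysisConfig, SimulationConfig
from egmorph.features import BeatComplex

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def ana_cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def sim_cfg() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture
def small_cfg() -> SimulationConfig:
    """Reduced tissue for fast unit tests (geometry scaled accordingly)."""
    return SimulationConfig(grid_n=40, n_beats=2, pacing_node=(4, 4))


def make_piecewise_beat(
    onset_ms: float = 30.0,
    q_ms: float | None = None,
    r_ms: float = 40.0,
    s_ms: float = 60.0,
    end_ms: float = 100.0,
    q_amp: float = 0.0,
    r_amp: float = 3.0,
    s_amp: float = -4.0,
    n_ms: int = 240,
    fs: float = 1000.0,
    **beat_kw,
) -> BeatComplex:
    """Piecewise-linear beat with known landmark geometry.

    Baseline 0 until ``onset``, optional dip to ``q_amp`` at ``q``, rise to
    ``r_amp`` at ``r``, fall to ``s_amp`` at ``s``, recovery to 0 at
    ``end``, flat afterwards.  All knots land exactly on samples.
    """
    t = np.arange(n_ms) * (1000.0 / fs)
    knots_t = [0.0, onset_ms]
    knots_v = [0.0, 0.0]
    if q_ms is not None:
        knots_t.append(q_ms)
        knots_v.append(q_amp)
    knots_t += [r_ms, s_ms, end_ms, n_ms - 1.0]
    knots_v += [r_amp, s_amp, 0.0, 0.0]
    v = np.interp(t, knots_t, knots_v)
    return BeatComplex(samples=v, fs=fs, channel=1, beat_index=0, **beat_kw)
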