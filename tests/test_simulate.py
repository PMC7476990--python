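"""Synthetic generator: velocity fields, activation maps, forward model."""

import math

import numpy as np
import pytest
from scipy import ndimage

from egmorph import (
    ActivationMap,
    SimulationConfig,
    add_artifacts_and_noise,
    ap_waveform,
    build_velocity_field,
    calibrate_gain,
    compute_activation_map,
    coupling_for_dose,
    forward_egm,
    simulate_dose_response,
    simulate_paired_study,
    write_recording,
)
from egmorph.config import ApParams
from egmorph.errors import ConfigError, SingularityError
from egmorph.io import EgmRecording, ElectrodeGrid, PacingProtocol
from egmorph.simulate import place_grid, simulate_recording
from egmorph.features import extract_table


# ---------------------------------------------------------------------------
# independent activation-time oracles
# ---------------------------------------------------------------------------

def _edges(field, dx):
    """All undirected lattice edges as (a, b, cost) with harmonic-mean CV."""
    nr, nc = field.shape
    out = []
    for i in range(nr):
        for j in range(nc):
            for di, dj in ((0, 1), (1, 0), (1, 1), (1, -1)):
                i2, j2 = i + di, j + dj
                if 0 <= i2 < nr and 0 <= j2 < nc:
                    hm = 2 * field[i, j] * field[i2, j2] / (field[i, j] + field[i2, j2])
                    out.append((i * nc + j, i2 * nc + j2,
                                dx * math.hypot(di, dj) / hm))
    return out


def bellman_ford_times(field, src, dx):
    """Exhaustive relaxation shortest-path oracle (no priority queue)."""
    nr, nc = field.shape
    n = nr * nc
    edges = _edges(field, dx)
    dist = [math.inf] * n
    dist[src[0] * nc + src[1]] = 0.0
    for _ in range(n):
        changed = False
        for a, b, w in edges:
            if dist[a] + w < dist[b]:
                dist[b] = dist[a] + w
                changed = True
            if dist[b] + w < dist[a]:
                dist[a] = dist[b] + w
                changed = True
        if not changed:
            break
    return np.array(dist).reshape(nr, nc)


def all_paths_times(field, src, dx):
    """True all-simple-paths enumeration (tractable only on tiny grids)."""
    nr, nc = field.shape
    adj = {}
    for a, b, w in _edges(field, dx):
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))
    best = {v: math.inf for v in range(nr * nc)}
    s = src[0] * nc + src[1]

    def dfs(v, cost, seen):
        if cost < best[v]:
            best[v] = cost
        for u, w in adj[v]:
            if u not in seen:
                dfs(u, cost + w, seen | {u})

    dfs(s, 0.0, {s})
    return np.array([best[v] for v in range(nr * nc)]).reshape(nr, nc)


class TestVelocityField:
    def test_homogeneous_baseline(self, sim_cfg):
        rng = np.random.default_rng(0)
        f = build_velocity_field(sim_cfg, rng, coupling=1.0,
                                 heterogeneity_sd=0.0, patch_fraction=0.0)
        assert np.allclose(f, sim_cfg.base_cv)

    def test_square_root_coupling_scaling(self, sim_cfg):
        rng = np.random.default_rng(0)
        f = build_velocity_field(sim_cfg, rng, coupling=0.25,
                                 heterogeneity_sd=0.0, patch_fraction=0.0)
        assert np.allclose(f, 0.5 * sim_cfg.base_cv)

    def test_matches_reference_rng_stream(self, sim_cfg):
        """Field equals an independent re-implementation of the generator spec."""
        seed, c, sd, pf = 77, 0.5, 0.3, 0.15
        got = build_velocity_field(sim_cfg, np.random.default_rng(seed),
                                   coupling=c, heterogeneity_sd=sd,
                                   patch_fraction=pf)
        rng = np.random.default_rng(seed)
        n = sim_cfg.grid_n
        g = rng.normal(0.0, sd, (n, n))
        cv = sim_cfg.base_cv * math.sqrt(c) * np.exp(g)
        u = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (n, n)),
                                    sim_cfg.patch_corr_mm / sim_cfg.dx,
                                    mode="nearest")
        cv[u >= np.quantile(u, 1 - pf)] *= sim_cfg.patch_slow_factor
        assert np.allclose(got, np.maximum(cv, sim_cfg.cv_floor))

    def test_invalid_coupling_rejected(self, sim_cfg):
        with pytest.raises(ConfigError):
            build_velocity_field(sim_cfg, np.random.default_rng(0), coupling=0.0)


class TestActivationMap:
    def test_uniform_corner_to_corner_diagonal(self):
        f = np.ones((3, 3))
        amap = compute_activation_map(f, (0, 0), dx=1.0)
        assert amap.times[0, 0] == 0.0
        assert np.isclose(amap.times[2, 2], 2.0 * math.sqrt(2.0))

    def test_halving_cv_doubles_times(self):
        rng = np.random.default_rng(3)
        f = np.exp(rng.normal(0, 0.2, (8, 8)))
        t1 = compute_activation_map(f, (2, 3), dx=0.5).times
        t2 = compute_activation_map(f / 2.0, (2, 3), dx=0.5).times
        assert np.allclose(t2, 2.0 * t1)

    def test_matches_relaxation_oracle_on_random_fields(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(4, 7))
            f = np.exp(rng.normal(0, 0.5, (n, n)))
            src = (int(rng.integers(n)), int(rng.integers(n)))
            got = compute_activation_map(f, src, dx=0.7).times
            exp = bellman_ford_times(f, src, dx=0.7)
            assert np.allclose(got, exp, atol=1e-10)

    def test_matches_all_paths_enumeration_on_3x3(self):
        rng = np.random.default_rng(5)
        f = np.exp(rng.normal(0, 0.6, (3, 3)))
        got = compute_activation_map(f, (1, 0), dx=1.0).times
        assert np.allclose(got, all_paths_times(f, (1, 0), dx=1.0), atol=1e-12)

    def test_pacing_node_out_of_bounds(self):
        with pytest.raises(IndexError):
            compute_activation_map(np.ones((4, 4)), (4, 0), dx=1.0)

    def test_map_invariants_enforced(self):
        with pytest.raises(ValueError):
            ActivationMap(times=np.ones((3, 3)), pacing_node=(0, 0))


class TestApWaveform:
    AP = ApParams()

    def test_resting_before_activation(self):
        assert ap_waveform(-5.0, self.AP) == self.AP.rest

    def test_returns_to_rest_after_apd(self):
        v = ap_waveform(self.AP.apd + 100.0, self.AP)
        assert abs(v - self.AP.rest) < 0.01

    def test_max_upstroke_rate_scales_inversely_with_tau(self):
        t = np.linspace(0, 30, 30001)
        rates = []
        for tau in (1.0, 2.0):
            v = ap_waveform(t, ApParams(upstroke_tau=tau))
            rates.append(np.max(np.diff(v)) / (t[1] - t[0]))
        assert rates[0] / rates[1] == pytest.approx(2.0, rel=0.02)
        # peak rate lands inside the upstroke window
        v = ap_waveform(t, self.AP)
        t_peak = t[np.argmax(np.diff(v))]
        assert 0 < t_peak < 6 * self.AP.upstroke_tau


class TestForwardModel:
    def _uniform_map(self, cfg):
        f = np.full((cfg.grid_n, cfg.grid_n), cfg.base_cv)
        return compute_activation_map(f, cfg.pacing_node, cfg.dx)

    def test_simultaneous_activation_gives_null_signal(self, small_cfg):
        amap = ActivationMap(times=np.zeros((small_cfg.grid_n,) * 2),
                             pacing_node=(0, 0))
        rec = forward_egm(amap, small_cfg.ventricular_ap, place_grid(small_cfg),
                          small_cfg, gain=1.0)
        assert np.max(np.abs(rec.samples)) < 1e-9

    def test_plane_wave_r_precedes_s(self, small_cfg):
        n = small_cfg.grid_n
        jj = np.meshgrid(np.arange(n), np.arange(n))[0]
        amap = ActivationMap(times=jj * small_cfg.dx / small_cfg.base_cv,
                             pacing_node=(0, 0))
        rec = forward_egm(amap, small_cfg.ventricular_ap, place_grid(small_cfg),
                          small_cfg, gain=1.0)
        for ch in rec.samples:
            assert ch.argmax() < ch.argmin()
            assert ch.max() > 0 > ch.min()

    def test_doubling_height_reduces_amplitude(self, small_cfg):
        amap = self._uniform_map(small_cfg)
        p2p = []
        for h in (0.5, 1.0):
            grid = ElectrodeGrid(rows=4, cols=4, pitch=3.0, height=h,
                                 origin=place_grid(small_cfg).origin)
            rec = forward_egm(amap, small_cfg.ventricular_ap, grid, small_cfg,
                              gain=1.0)
            p2p.append(np.median(rec.samples.max(1) - rec.samples.min(1)))
        assert p2p[1] < p2p[0]

    def test_zero_height_rejected(self, small_cfg):
        amap = self._uniform_map(small_cfg)
        grid = ElectrodeGrid(rows=4, cols=4, pitch=3.0, height=0.0)
        with pytest.raises(SingularityError):
            forward_egm(amap, small_cfg.ventricular_ap, grid, small_cfg)

    def test_gain_calibration_hits_target_p2p(self, sim_cfg):
        gain = calibrate_gain(sim_cfg)
        amap = self._uniform_map(sim_cfg)
        rec = forward_egm(amap, sim_cfg.ventricular_ap, place_grid(sim_cfg),
                          sim_cfg, gain=gain)
        p2p = np.median(rec.samples.max(1) - rec.samples.min(1))
        assert p2p == pytest.approx(sim_cfg.target_p2p, rel=1e-6)

    def test_output_finite_everywhere(self, small_cfg):
        rng = np.random.default_rng(9)
        f = build_velocity_field(small_cfg, rng, coupling=0.4,
                                 heterogeneity_sd=0.3, patch_fraction=0.2)
        amap = compute_activation_map(f, small_cfg.pacing_node, small_cfg.dx)
        rec = forward_egm(amap, small_cfg.ventricular_ap, place_grid(small_cfg),
                          small_cfg, gain=1.0)
        assert np.isfinite(rec.samples).all()


class TestArtifactsAndNoise:
    def _clean_rec(self, n_t=4000):
        grid = ElectrodeGrid(rows=1, cols=1)
        pacing = PacingProtocol(cycle_length=1000.0, stimulus_times=(100.0,))
        return EgmRecording(samples=np.zeros((1, n_t)), fs=1000.0, grid=grid,
                            pacing=pacing)

    def test_all_zero_settings_is_identity(self, sim_cfg):
        import dataclasses
        cfg = dataclasses.replace(sim_cfg, stim_amp=0.0, noise_sd=0.0,
                                  wander_amp=0.0)
        rec = self._clean_rec()
        out = add_artifacts_and_noise(rec, cfg, np.random.default_rng(0))
        assert np.array_equal(out.samples, rec.samples)

    def test_stimulus_artifact_is_two_sample_biphasic(self, sim_cfg):
        import dataclasses
        cfg = dataclasses.replace(sim_cfg, stim_amp=10.0, noise_sd=0.0,
                                  wander_amp=0.0)
        out = add_artifacts_and_noise(self._clean_rec(), cfg,
                                      np.random.default_rng(0))
        assert out.samples[0, 100] == pytest.approx(10.0)
        assert out.samples[0, 101] == pytest.approx(-10.0)
        assert np.count_nonzero(out.samples) == 2

    def test_noise_sd_matches_request(self, sim_cfg):
        import dataclasses
        cfg = dataclasses.replace(sim_cfg, stim_amp=0.0, noise_sd=0.05,
                                  wander_amp=0.0)
        rec = self._clean_rec(n_t=1_000_000)
        out = add_artifacts_and_noise(rec, cfg, np.random.default_rng(1))
        assert np.std(out.samples - rec.samples) == pytest.approx(0.05, rel=0.01)


class TestStudySimulation:
    def test_paired_study_structure(self, small_cfg):
        recs = simulate_paired_study(small_cfg)
        assert len(recs) == 32
        by_cond = {"BL": 0, "CBX": 0}
        for r in recs:
            by_cond[r.condition] += 1
        assert by_cond == {"BL": 16, "CBX": 16}
        # same electrode placement within a site, across conditions
        for site in range(1, 17):
            pair = [r for r in recs if r.site_index == site]
            assert pair[0].grid == pair[1].grid

    def test_same_seed_reproduces_bytes(self, small_cfg, tmp_path):
        a = simulate_paired_study(small_cfg)[0]
        b = simulate_paired_study(small_cfg)[0]
        pa = write_recording(a, tmp_path / "a.csv")
        pb = write_recording(b, tmp_path / "b.csv")
        assert pa.read_bytes() == pb.read_bytes()

    def test_latency_monotone_in_coupling_noise_free(self, small_cfg):
        """Slower coupling never shortens the farthest-electrode latency."""
        import dataclasses
        cfg = dataclasses.replace(small_cfg, heterogeneity_sd=0.0,
                                  patch_fraction=0.0)
        gain = calibrate_gain(cfg)
        lats = []
        for c in (0.3, 0.6, 1.0):
            rec = simulate_recording(cfg, np.random.default_rng(0), site_index=1,
                                     condition="BL", coupling=c, gain=gain,
                                     clean=True)
            tab = extract_table([rec])
            lats.append(tab.df["stim_to_dvdt_latency"].mean())
        assert lats[0] >= lats[1] >= lats[2]

    def test_far_electrode_later_than_near(self, small_cfg):
        import dataclasses
        cfg = dataclasses.replace(small_cfg, heterogeneity_sd=0.0,
                                  patch_fraction=0.0)
        rec = simulate_recording(cfg, np.random.default_rng(0), site_index=1,
                                 condition="BL", coupling=1.0, gain=1.0,
                                 clean=True)
        tab = extract_table([rec])
        lat = tab.df.groupby("channel")["stim_to_dvdt_latency"].mean()
        pace_xy = np.array(cfg.pacing_node[::-1]) * cfg.dx
        pos = rec.grid.positions()[:, :2]
        dist = np.linalg.norm(pos - pace_xy, axis=1)
        assert lat[int(np.argmax(dist)) + 1] > lat[int(np.argmin(dist)) + 1]


class TestDoseResponseSimulation:
    def test_zero_dose_is_baseline_coupling(self, sim_cfg):
        assert coupling_for_dose(sim_cfg, 0.0) == 1.0

    def test_hill_midpoint(self, sim_cfg):
        c = coupling_for_dose(sim_cfg, sim_cfg.d50)
        assert c == pytest.approx(1.0 - (1.0 - sim_cfg.c_drug) / 2.0)

    def test_latency_non_decreasing_in_dose_noise_free(self, small_cfg):
        import dataclasses
        cfg = dataclasses.replace(small_cfg, heterogeneity_sd=0.0,
                                  patch_fraction=0.0)
        out = simulate_dose_response(cfg, [0, 10, 20, 30, 40, 50],
                                     np.random.default_rng(0), clean=True)
        lats = [extract_table([rec]).df["stim_to_dvdt_latency"].mean()
                for _, rec in out]
        assert all(b >= a - 1e-9 for a, b in zip(lats, lats[1:]))

    def test_doses_must_increase(self, small_cfg):
        with pytest.raises(ConfigError):
            simulate_dose_response(small_cfg, [0, 10, 10])
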