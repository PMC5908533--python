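"""Pattern detection, tracking, MSD, afferent distances, reconstruction."""

import numpy as np
import pandas as pd
import pytest

from wavepatch import LatticeGeometry, ModelParameters, build_kernels
from wavepatch.fixtures import FixtureSpec, generate
from wavepatch.params import minimal_image_offsets
from wavepatch.patterns import (
    PatternTrack,
    afferent_spike_distances,
    detect_patterns,
    msd_exponent,
    mean_track_speed,
    reconstruct_conductance,
    spike_frames,
    track_patterns,
)

GEOM60 = LatticeGeometry(n=60)


def _frames_from_fixture(spec):
    spikes, truth = generate(spec)
    frames = spike_frames(spikes, spec.geometry.n, 0.0, spec.duration_ms)
    return spikes, truth, frames


class TestDetection:
    def test_single_blob_centroid_recovered(self):
        spec = FixtureSpec(kind="stationary_blob", geometry=GEOM60, duration_ms=30.0,
                           seed=1, start=(20.0, 40.0), blob_peak_rate_hz=2000.0)
        _, truth, frames = _frames_from_fixture(spec)
        comps = detect_patterns(frames)
        for frame_comps in comps:
            assert len(frame_comps) == 1
            d = minimal_image_offsets(frame_comps[0]["centroid"] - np.array([20.0, 40.0]), 60)
            assert np.linalg.norm(d) <= 1.0

    def test_empty_frames_give_no_components(self):
        frames = np.zeros((5, 60, 60), dtype=np.int32)
        assert detect_patterns(frames) == [[], [], [], [], []]

    def test_two_distant_blobs_detected_separately(self):
        geom = LatticeGeometry(n=150)
        s1 = FixtureSpec(kind="stationary_blob", geometry=geom, duration_ms=20.0,
                         seed=2, start=(25.0, 25.0))
        s2 = FixtureSpec(kind="stationary_blob", geometry=geom, duration_ms=20.0,
                         seed=3, start=(125.0, 125.0))
        spikes = pd.concat([generate(s1)[0], generate(s2)[0]], ignore_index=True)
        frames = spike_frames(spikes, 150, 0.0, 20.0)
        comps = detect_patterns(frames)
        assert all(len(c) == 2 for c in comps)

    def test_component_spans_periodic_seam(self):
        spec = FixtureSpec(kind="stationary_blob", geometry=GEOM60, duration_ms=20.0,
                           seed=4, start=(0.5, 30.0))
        _, _, frames = _frames_from_fixture(spec)
        comps = detect_patterns(frames)
        # the blob straddles the x seam but must be one component near x=0
        for frame_comps in comps:
            assert len(frame_comps) == 1
            cx = frame_comps[0]["centroid"][0]
            assert min(cx, 60 - cx) <= 2.0


class TestTracking:
    @pytest.mark.parametrize("speed", [10.0, 40.0, 80.0])
    def test_moving_blob_speed_recovered_within_5_percent(self, speed):
        spec = FixtureSpec(kind="moving_blob", geometry=LatticeGeometry(n=100),
                           duration_ms=300.0, seed=5, speed_mm_s=speed,
                           blob_peak_rate_hz=2000.0)
        _, truth, frames = _frames_from_fixture(spec)
        tracks = track_patterns(detect_patterns(frames), 100)
        assert len(tracks) == 1
        assert tracks[0].mean_speed == pytest.approx(speed, rel=0.05)
        assert tracks[0].label == "wave"

    def test_stationary_blob_labelled_patch_with_near_zero_speed(self):
        spec = FixtureSpec(kind="stationary_blob", geometry=GEOM60,
                           duration_ms=200.0, seed=6)
        _, _, frames = _frames_from_fixture(spec)
        tracks = track_patterns(detect_patterns(frames), 60)
        assert len(tracks) == 1
        assert tracks[0].label == "patch"
        assert tracks[0].mean_speed < 10.0

    def test_confined_wanderer_stays_patch(self):
        spec = FixtureSpec(kind="stationary_blob", geometry=GEOM60,
                           duration_ms=300.0, seed=7, confinement_radius=5.0)
        _, _, frames = _frames_from_fixture(spec)
        tracks = track_patterns(detect_patterns(frames), 60)
        assert all(t.label == "patch" for t in tracks)

    def test_speed_average_weights_by_track_length(self):
        a = PatternTrack(0, np.arange(3.0), np.zeros((3, 2)), "patch", 10.0)
        b = PatternTrack(1, np.arange(11.0), np.zeros((11, 2)), "wave", 40.0)
        assert mean_track_speed([a, b]) == pytest.approx((2 * 10 + 10 * 40) / 12)
        assert mean_track_speed([a, b], weight_by_length=False) == pytest.approx(25.0)


class TestMSD:
    def test_ballistic_track_has_exponent_two(self):
        t = np.arange(200.0)
        cen = np.column_stack([0.5 * t, 0.25 * t])
        track = PatternTrack(0, t, cen, "wave", 0.0)
        assert msd_exponent(track) == pytest.approx(2.0, abs=1e-9)

    def test_lattice_random_walk_has_exponent_near_one(self):
        rng = np.random.default_rng(8)
        steps = rng.choice([-1, 0, 1], size=(10_000, 2))
        cen = np.cumsum(steps, axis=0).astype(float)
        track = PatternTrack(0, np.arange(10_000.0), cen, "patch", 0.0)
        assert msd_exponent(track) == pytest.approx(1.0, abs=0.15)

    def test_short_track_rejected(self):
        track = PatternTrack(0, np.arange(10.0), np.zeros((10, 2)), "patch", 0.0)
        with pytest.raises(ValueError):
            msd_exponent(track)


class TestAfferentDistances:
    GEOM = LatticeGeometry(n=120)
    PARAMS = ModelParameters()

    def _series(self, spikes):
        return afferent_spike_distances(
            spikes, (60, 60), self.PARAMS, self.GEOM, t_start_ms=0.0, t_end_ms=10.0
        )

    def test_single_afferent_spike_distance_in_um(self):
        spikes = pd.DataFrame({"time_ms": [2.0], "x": [70], "y": [60]})
        s = self._series(spikes)
        assert list(s.event_distances_um) == [400.0]
        assert s.count.sum() == 1

    def test_spikes_beyond_cutoff_excluded(self):
        spikes = pd.DataFrame({"time_ms": [2.0, 3.0], "x": [91, 90], "y": [60, 60]})
        s = self._series(spikes)
        # (31, 0) is outside the 30-gridpoint cutoff; (30, 0) is included
        assert list(s.event_distances_um) == [1200.0]

    def test_all_distances_bounded_by_cutoff_range(self):
        rng = np.random.default_rng(9)
        spikes = pd.DataFrame({
            "time_ms": rng.uniform(0, 10, 200),
            "x": rng.integers(0, 120, 200),
            "y": rng.integers(0, 120, 200),
        })
        s = self._series(spikes)
        assert np.all(s.event_distances_um <= 1200.0)


class TestReconstruction:
    def test_no_spikes_pure_exponential_decay(self):
        geom, p = LatticeGeometry(n=20), ModelParameters(cutoff=5)
        kernels = build_kernels(p)
        empty = pd.DataFrame({"time_ms": [], "x": [], "y": []})
        t, g = reconstruct_conductance(empty, (10, 10), kernels, p, geom,
                                       t_end_ms=10.0, g0=2.0)
        expected = 2.0 * (1 - p.dt / p.tau_e) ** (t / p.dt)
        np.testing.assert_allclose(g, expected, rtol=1e-10)

    def test_single_spike_jumps_by_kernel_strength(self):
        geom, p = LatticeGeometry(n=20), ModelParameters(cutoff=5)
        kernels = build_kernels(p)
        spikes = pd.DataFrame({"time_ms": [3.0], "x": [13], "y": [10]})  # offset (3, 0)
        t, g = reconstruct_conductance(spikes, (10, 10), kernels, p, geom, t_end_ms=6.0)
        k = p.w_e * np.exp(-9.0 / (2 * p.sigma_e**2))
        decay = 1 - p.dt / p.tau_e
        assert g[t == 3.0][0] == 0.0  # jump lands on the step after the spike
        assert g[t == 4.0][0] == pytest.approx(k * decay ** (1.0 / p.dt), rel=1e-12)

    def test_reconstruction_matches_recorded_trace_to_round_off(self, small_probe_run):
        cfg, rec = small_probe_run
        kernels = build_kernels(cfg.params)
        t, g = reconstruct_conductance(
            rec.spikes, (30, 30), kernels, cfg.params, cfg.geometry,
            t_end_ms=cfg.duration_ms,
        )
        recorded = rec.probe_traces["g_e"][:, 0]
        assert len(rec.spikes) > 100  # the run is actually active
        np.testing.assert_allclose(g, recorded, rtol=1e-9, atol=1e-12)
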