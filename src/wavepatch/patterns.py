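"""Detection, tracking and classification of population activity patterns.

Activity patterns are detected per 1-ms spike frame by Gaussian-smoothing the
spike-count grid, thresholding at mean + k.std, and extracting periodic-aware
connected components. Components are linked frame-to-frame by nearest
centroid; a track whose net (unwrapped) displacement exceeds the RoI radius
is a propagating wave, otherwise a localized patch. The module also measures
mean-squared-displacement exponents of track trajectories, afferent spike
distances seen by a test neuron, and the offline reconstruction of its
excitatory conductance from the afferent spike record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .params import (
    ConnectivityKernels,
    LatticeGeometry,
    ModelParameters,
    minimal_image_offsets,
)

__all__ = [
    "PatternTrack",
    "DistanceSeries",
    "spike_frames",
    "detect_patterns",
    "track_patterns",
    "msd_exponent",
    "afferent_spike_distances",
    "reconstruct_conductance",
    "mean_track_speed",
]


@dataclass
class PatternTrack:
    """One tracked activity pattern.

    ``centroids`` are unwrapped across the periodic boundary (accumulated
    minimal-image frame displacements), so displacements and speeds can be
    read off directly; ``label`` is 'wave' if the net displacement over the
    track lifetime exceeds the classification radius, else 'patch'.
    ``mean_speed`` is in mm/s.
    """

    id: int
    times: np.ndarray  # ms
    centroids: np.ndarray  # (n_frames, 2), unwrapped gridpoints
    label: str
    mean_speed: float

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class DistanceSeries:
    """Per-ms afferent spike distances and counts for one test neuron.

    ``event_times_ms``/``event_distances_um`` list every afferent spike;
    ``times_ms``/``mean_distance_um``/``count`` give the 1-ms sliding-window
    mean distance (NaN where no afferent spiked) and spike count.
    """

    test_neuron: tuple[int, int]
    event_times_ms: np.ndarray
    event_distances_um: np.ndarray
    times_ms: np.ndarray
    mean_distance_um: np.ndarray
    count: np.ndarray


def spike_frames(
    spikes: pd.DataFrame,
    n: int,
    t_start_ms: float,
    t_end_ms: float,
    bin_ms: float = 1.0,
) -> np.ndarray:
    """Bin spike events into (n_frames, n, n) count grids of ``bin_ms`` width."""
    n_frames = int(round((t_end_ms - t_start_ms) / bin_ms))
    frames = np.zeros((n_frames, n, n), dtype=np.int32)
    t = spikes.time_ms.values
    sel = (t > t_start_ms) & (t <= t_end_ms)
    idx = np.ceil((t[sel] - t_start_ms) / bin_ms).astype(int) - 1
    np.add.at(frames, (idx, spikes.x.values[sel], spikes.y.values[sel]), 1)
    return frames


def _periodic_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Connected-component labelling with wrap-around adjacency."""
    labels, n_lab = ndimage.label(mask)
    if n_lab == 0:
        return labels, 0
    # merge labels that touch across each periodic seam
    parent = np.arange(n_lab + 1)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for edge_a, edge_b in ((labels[0, :], labels[-1, :]), (labels[:, 0], labels[:, -1])):
        both = (edge_a > 0) & (edge_b > 0)
        for a, b in zip(edge_a[both], edge_b[both]):
            union(a, b)
    remap = np.array([find(a) for a in range(n_lab + 1)])
    # compress to consecutive ids
    uniq = np.unique(remap[1:])
    lut = np.zeros(n_lab + 1, dtype=int)
    lut[uniq] = np.arange(1, len(uniq) + 1)
    return lut[remap[labels]], len(uniq)


def _periodic_centroid(coords: np.ndarray, n: int) -> np.ndarray:
    """Centroid of lattice points on a periodic lattice via circular means."""
    ang = coords * (2 * np.pi / n)
    c = np.arctan2(np.sin(ang).mean(axis=0), np.cos(ang).mean(axis=0))
    return (c * n / (2 * np.pi)) % n


def detect_patterns(
    frames: np.ndarray,
    sigma: float = 2.0,
    k: float = 2.0,
    min_size: int = 10,
) -> list[list[dict]]:
    """Per-frame list of detected components.

    Each frame's spike-count grid is smoothed with a periodic Gaussian of
    width ``sigma`` gridpoints, thresholded at mean + k.std of the smoothed
    frame, and segmented into periodic-aware connected components; components
    smaller than ``min_size`` gridpoints are discarded. Each component is a
    dict with keys 'centroid' (wrapped gridpoint coordinates), 'size' and
    'mass' (summed smoothed density).
    """
    out: list[list[dict]] = []
    n = frames.shape[1]
    for frame in frames:
        comps: list[dict] = []
        if frame.any():
            dens = ndimage.gaussian_filter(frame.astype(float), sigma, mode="wrap")
            thr = dens.mean() + k * dens.std()
            mask = dens > thr
            labels, n_lab = _periodic_label(mask)
            for lab in range(1, n_lab + 1):
                coords = np.argwhere(labels == lab)
                if len(coords) < min_size:
                    continue
                comps.append(
                    {
                        "centroid": _periodic_centroid(coords, n),
                        "size": len(coords),
                        "mass": float(dens[labels == lab].sum()),
                    }
                )
        out.append(comps)
    return out


def track_patterns(
    component_frames: list[list[dict]],
    n: int,
    frame_interval_ms: float = 1.0,
    spacing_um: float = 40.0,
    max_jump: float = 10.0,
    max_gap: int = 3,
    wave_radius: float = 15.0,
    min_length: int = 5,
    speed_lag: int = 10,
) -> list[PatternTrack]:
    """Link components into tracks by nearest centroid.

    Tracks are greedy nearest-neighbour links with per-frame jumps of at most
    ``max_jump`` gridpoints, terminated after ``max_gap`` frames without a
    match (no merging/splitting). Centroids are unwrapped by accumulating
    minimal-image displacements. A track is labelled 'wave' when its net
    unwrapped displacement exceeds ``wave_radius`` gridpoints, else 'patch'.

    ``mean_speed`` is the mean displacement over a ``speed_lag``-frame lag
    divided by the lag, converted to mm/s. The lag suppresses the spurious
    speed contributed by frame-to-frame centroid-localization jitter (which
    adds ~sqrt(2) x jitter per frame to a lag-1 estimate) while leaving true
    translocation unchanged; tracks shorter than ``speed_lag`` + 1 frames
    fall back to lag-1.
    """
    active: list[dict] = []
    done: list[dict] = []
    next_id = 0
    for fi, comps in enumerate(component_frames):
        cents = np.array([c["centroid"] for c in comps]) if comps else np.empty((0, 2))
        unmatched = set(range(len(comps)))
        # match existing tracks to nearest component
        for tr in active:
            if not len(cents):
                tr["miss"] += 1
                continue
            d = minimal_image_offsets(cents - tr["pos"][None, :], n)
            dist = np.hypot(d[:, 0], d[:, 1])
            order = np.argsort(dist)
            hit = next((j for j in order if j in unmatched and dist[j] <= max_jump), None)
            if hit is None:
                tr["miss"] += 1
            else:
                unmatched.discard(hit)
                tr["miss"] = 0
                tr["pos"] = cents[hit]
                tr["unwrapped"].append(tr["unwrapped"][-1] + d[hit])
                tr["times"].append(fi * frame_interval_ms)
        survivors: list[dict] = []
        for tr in active:
            (done if tr["miss"] > max_gap else survivors).append(tr)
        active = survivors
        for j in sorted(unmatched):
            active.append(
                {
                    "id": next_id,
                    "pos": cents[j],
                    "unwrapped": [cents[j].astype(float)],
                    "times": [fi * frame_interval_ms],
                    "miss": 0,
                }
            )
            next_id += 1
    done.extend(active)

    tracks: list[PatternTrack] = []
    for tr in done:
        cen = np.array(tr["unwrapped"])
        if len(cen) < min_length:
            continue
        disp = np.linalg.norm(cen[-1] - cen[0])
        times = np.array(tr["times"], dtype=float)
        lag = min(speed_lag, len(cen) - 1)
        steps = np.linalg.norm(cen[lag:] - cen[:-lag], axis=1)
        dt_ms = times[lag:] - times[:-lag]
        # gridpoints/ms * (um/gp) = um/ms = mm/s
        speed = float((steps / dt_ms).mean() * spacing_um)
        tracks.append(
            PatternTrack(
                id=tr["id"],
                times=np.array(tr["times"]),
                centroids=cen,
                label="wave" if disp > wave_radius else "patch",
                mean_speed=speed,
            )
        )
    return tracks


def mean_track_speed(tracks: list[PatternTrack], weight_by_length: bool = True) -> float:
    """Average propagation speed over tracks, in mm/s.

    Weighting by track length makes the average a per-frame displacement
    average over all tracked pattern motion rather than over track identities.
    """
    if not tracks:
        return float("nan")
    if weight_by_length:
        w = np.array([len(t) - 1 for t in tracks], dtype=float)
    else:
        w = np.ones(len(tracks))
    v = np.array([t.mean_speed for t in tracks])
    return float((v * w).sum() / w.sum())


def msd_exponent(track: PatternTrack, max_lag: int = 25) -> float:
    """Slope of log MSD vs log lag over lags 1..max_lag frames.

    ~1 for Brownian wandering (patches), ~2 for ballistic motion (waves).
    Requires at least 50 frames.
    """
    cen = track.centroids
    if len(cen) < 50:
        raise ValueError(f"track too short for MSD fit ({len(cen)} < 50 frames)")
    lags = np.arange(1, min(max_lag, len(cen) // 2) + 1)
    msd = np.array([((cen[lag:] - cen[:-lag]) ** 2).sum(axis=1).mean() for lag in lags])
    slope, _ = np.polyfit(np.log(lags), np.log(msd), 1)
    return float(slope)


def afferent_spike_distances(
    spikes: pd.DataFrame,
    test_neuron: tuple[int, int],
    params: ModelParameters,
    geometry: LatticeGeometry,
    t_start_ms: float = 0.0,
    t_end_ms: float | None = None,
    bin_ms: float = 1.0,
) -> DistanceSeries:
    """Distances and counts of spikes afferent to one test neuron.

    Every spike within minimal-image distance <= cutoff of the test neuron is
    an afferent event; the series reports the sliding 1-ms mean distance (um)
    and count. Spikes beyond the cutoff are excluded entirely.
    """
    t = spikes.time_ms.values
    if t_end_ms is None:
        t_end_ms = float(t.max()) if len(t) else t_start_ms
    sel = (t > t_start_ms) & (t <= t_end_ms)
    dx = minimal_image_offsets(spikes.x.values[sel] - test_neuron[0], geometry.n)
    dy = minimal_image_offsets(spikes.y.values[sel] - test_neuron[1], geometry.n)
    dist_gp = np.hypot(dx, dy)
    aff = (dist_gp > 0) & (dist_gp <= params.cutoff)
    ev_t = t[sel][aff]
    ev_d = dist_gp[aff] * geometry.spacing_um
    order = np.argsort(ev_t)
    ev_t, ev_d = ev_t[order], ev_d[order]

    n_bins = int(round((t_end_ms - t_start_ms) / bin_ms))
    times = t_start_ms + (np.arange(n_bins) + 1) * bin_ms
    idx = np.ceil((ev_t - t_start_ms) / bin_ms).astype(int) - 1
    count = np.bincount(idx, minlength=n_bins)
    dsum = np.bincount(idx, weights=ev_d, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_d = np.where(count > 0, dsum / np.maximum(count, 1), np.nan)
    return DistanceSeries(
        test_neuron=tuple(test_neuron),
        event_times_ms=ev_t,
        event_distances_um=ev_d,
        times_ms=times,
        mean_distance_um=mean_d,
        count=count,
    )


def reconstruct_conductance(
    spikes: pd.DataFrame,
    test_neuron: tuple[int, int],
    kernels: ConnectivityKernels,
    params: ModelParameters,
    geometry: LatticeGeometry,
    t_end_ms: float,
    g0: float = 0.0,
    sample_interval_ms: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Offline reconstruction of the g_E trace received by a test neuron.

    Evolves the conductance with the same explicit Euler scheme and
    conductance-jump convention as the simulator, adding K_E(dr) for every
    excitatory afferent spike (jump applied on the step after the spike,
    before the decay of that step). Given the complete afferent spike record
    it reproduces the simulator's recorded trace to floating-point round-off.

    Returns (times_ms, g_e) sampled every ``sample_interval_ms``.
    """
    n = geometry.n
    d = kernels.cutoff
    t = np.asarray(spikes.time_ms.values, dtype=float)
    xs = np.asarray(spikes.x.values, dtype=np.intp)
    ys = np.asarray(spikes.y.values, dtype=np.intp)
    dx = minimal_image_offsets(xs - test_neuron[0], n)
    dy = minimal_image_offsets(ys - test_neuron[1], n)
    # excitatory sources only: not both-odd coordinates
    is_exc = ~((xs % 2 == 1) & (ys % 2 == 1))
    r2 = dx**2 + dy**2
    aff = is_exc & (r2 > 0) & (r2 <= d * d)
    if aff.sum() and (np.abs(dx[aff]).max() > d or np.abs(dy[aff]).max() > d):
        raise ValueError("afferent offset outside kernel stencil")
    weights = kernels.patch_e[dx[aff] + d, dy[aff] + d]
    if np.any(weights <= 0):
        raise ValueError("missing kernel entry for an afferent offset")
    dt = params.dt
    n_steps = int(round(t_end_ms / dt))
    # jump lands on the step after the spike step
    jump_step = np.round(t[aff] / dt).astype(int) + 1
    jumps = np.zeros(n_steps + 2)
    np.add.at(jumps, np.clip(jump_step, 0, n_steps + 1), weights)

    stride = int(round(sample_interval_ms / dt))
    n_samples = n_steps // stride + 1
    out = np.empty(n_samples)
    out[0] = g0
    g = g0
    decay = 1.0 - dt / params.tau_e
    for i in range(1, n_steps + 1):
        g = (g + jumps[i]) * decay
        if i % stride == 0:
            out[i // stride] = g
    times = np.arange(n_samples) * sample_interval_ms
    return times, out
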