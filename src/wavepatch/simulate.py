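"""Euler integration of the conductance-based LIF lattice.

State advances in a fixed order each time step:

1. spikes fired on the previous step deposit kernel-weighted conductance
   increments on every neuron within the cutoff (translation-invariant patch
   accumulation, numerically identical to the pairwise afferent sum);
2. conductances decay by the explicit Euler factor (1 - dt/tau);
3. membrane potentials of non-refractory neurons advance one Euler step of
   the current-balance equation; refractory neurons are clamped at the reset
   potential and ignore synaptic input (their conductances still evolve);
4. neurons at or above threshold emit a spike, reset, and start the
   refractory countdown.

A presynaptic spike increments the target conductance by the kernel strength
K (nS) instantaneously (conductance-jump convention). Spikes take effect on
the next Euler step; there is no conduction delay.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .params import (
    ConnectivityKernels,
    LatticeGeometry,
    ModelParameters,
    StimulusProtocol,
    build_kernels,
    inhibitory_mask,
    stimulus_field,
)

__all__ = [
    "NetworkState",
    "TrialRecording",
    "SimulationConfig",
    "initialize_state",
    "step",
    "run_trial",
    "run_sweep",
]


class IntegrationError(RuntimeError):
    """Raised when the state develops NaN/Inf values."""


@dataclass
class NetworkState:
    """Gridded state of the lattice at one instant.

    ``v`` in mV, ``g_e``/``g_i`` in nS, ``refractory_remaining`` in ms,
    ``t`` in ms. ``pending_e``/``pending_i`` hold the coordinates of spikes
    fired on the previous step, which deposit conductance on the next one.
    """

    v: np.ndarray
    g_e: np.ndarray
    g_i: np.ndarray
    refractory_remaining: np.ndarray
    t: float
    pending_e: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.intp))
    pending_i: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.intp))


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one trial bit-for-bit (except the seed)."""

    geometry: LatticeGeometry = LatticeGeometry()
    params: ModelParameters = ModelParameters()
    protocol: StimulusProtocol = StimulusProtocol()
    duration_ms: float = 3500.0
    burn_in_ms: float = 1000.0
    sample_interval_ms: float = 1.0

    def digest(self) -> str:
        payload = json.dumps(
            {
                "geometry": vars(self.geometry) | {},
                "params": {k: v for k, v in vars(self.params).items()},
                "protocol": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(self.protocol).items()
                },
                "duration_ms": self.duration_ms,
                "burn_in_ms": self.burn_in_ms,
                "sample_interval_ms": self.sample_interval_ms,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TrialRecording:
    """Spike events and optional sampled traces from one trial.

    ``spikes`` is a DataFrame with columns time_ms, x, y. ``probe_traces``
    maps field name ('v', 'g_e', 'g_i') to an array of shape
    (n_samples, n_probes) sampled every ``sample_interval_ms``;
    ``probe_coords`` holds the probed gridpoints. ``lfp_frames`` optionally
    holds the synaptic-current LFP temporal component (pA, float32) on the
    full grid at the same sampling. Identical (config, seed) pairs produce
    bit-identical recordings.
    """

    spikes: pd.DataFrame
    config: SimulationConfig
    seed: int
    config_digest: str
    probe_coords: np.ndarray | None = None
    probe_traces: dict[str, np.ndarray] | None = None
    probe_times_ms: np.ndarray | None = None
    lfp_frames: np.ndarray | None = None

    @property
    def burn_in_ms(self) -> float:
        return self.config.burn_in_ms

    @property
    def duration_ms(self) -> float:
        return self.config.duration_ms

    def spikes_after_burn_in(self) -> pd.DataFrame:
        return self.spikes[self.spikes.time_ms.values > self.config.burn_in_ms]


def initialize_state(
    geometry: LatticeGeometry, params: ModelParameters, seed: int | np.random.Generator
) -> NetworkState:
    """Quiescent start: V i.i.d. uniform on [V_R, V_th), zero conductances."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = geometry.n
    v = rng.uniform(params.v_reset, params.v_th, size=(n, n))
    zeros = np.zeros((n, n))
    return NetworkState(
        v=v,
        g_e=zeros.copy(),
        g_i=zeros.copy(),
        refractory_remaining=np.zeros((n, n)),
        t=0.0,
    )


def _deposit(grid: np.ndarray, coords: np.ndarray, patch: np.ndarray, n: int) -> None:
    """Add the kernel stencil around each coordinate, with periodic wrap."""
    d = patch.shape[0] // 2
    ax = np.arange(-d, d + 1)
    if n >= patch.shape[0]:
        for x, y in coords:
            rows = (x + ax) % n
            cols = (y + ax) % n
            grid[np.ix_(rows, cols)] += patch
    else:
        # wrapped stencil overlaps itself; unbuffered add handles duplicates
        for x, y in coords:
            rows = (x + ax) % n
            cols = (y + ax) % n
            np.add.at(grid, (rows[:, None], cols[None, :]), patch)


def pairwise_increments(
    spike_coords_e: np.ndarray,
    spike_coords_i: np.ndarray,
    params: ModelParameters,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force pairwise conductance increments (reference implementation).

    For every target neuron, sums the kernel strength over its afferent
    offsets (each integer displacement with 0 < |dr| <= cutoff counts as one
    connection) whose source neuron spiked, directly from the model
    parameters. Exists to validate the stencil accumulation used by
    ``step``; O(offsets x n^2).
    """
    spiked_e = np.zeros((n, n), dtype=bool)
    spiked_i = np.zeros((n, n), dtype=bool)
    for coords, grid in ((spike_coords_e, spiked_e), (spike_coords_i, spiked_i)):
        for sx, sy in np.asarray(coords).reshape(-1, 2):
            grid[sx % n, sy % n] = True
    inc_e = np.zeros((n, n))
    inc_i = np.zeros((n, n))
    d = params.cutoff
    xt = np.arange(n)
    for dx in range(-d, d + 1):
        for dy in range(-d, d + 1):
            r2 = dx * dx + dy * dy
            if r2 == 0 or r2 > d * d:
                continue
            src = np.ix_((xt - dx) % n, (xt - dy) % n)
            inc_e += spiked_e[src] * (params.w_e * np.exp(-r2 / (2.0 * params.sigma_e**2)))
            inc_i += spiked_i[src] * params.w_i
    return inc_e, inc_i


def step(
    state: NetworkState,
    kernels: ConnectivityKernels,
    protocol: StimulusProtocol,
    params: ModelParameters,
    geometry: LatticeGeometry,
    *,
    stim_field: np.ndarray | None = None,
    spike_out: list | None = None,
) -> NetworkState:
    """Advance the state by one Euler step of ``params.dt`` (in place).

    ``stim_field`` may carry the precomputed spatial stimulus profile (nA);
    it is recomputed when omitted. Spike coordinates fired on this step are
    appended to ``spike_out`` as (t, x, y) when provided.
    """
    n = geometry.n
    dt = params.dt

    # 1. deposit conductance from spikes fired on the previous step
    if len(state.pending_e):
        _deposit(state.g_e, state.pending_e, kernels.patch_e, n)
    if len(state.pending_i):
        _deposit(state.g_i, state.pending_i, kernels.patch_i, n)

    # 2. Euler conductance decay
    state.g_e *= 1.0 - dt / params.tau_e
    state.g_i *= 1.0 - dt / params.tau_i

    # 3. membrane update for non-refractory neurons
    if stim_field is None:
        stim_field = stimulus_field(geometry, protocol)
    i_ext = protocol.i_background
    if state.t >= protocol.t_onset_ms and protocol.w_s > 0:
        syn = (
            -params.g_l * (state.v - params.v_leak)
            - state.g_e * (state.v - params.v_exc)
            - state.g_i * (state.v - params.v_inh)
        ) * 1e-3 + i_ext + stim_field
    else:
        syn = (
            -params.g_l * (state.v - params.v_leak)
            - state.g_e * (state.v - params.v_exc)
            - state.g_i * (state.v - params.v_inh)
        ) * 1e-3 + i_ext
    refractory = state.refractory_remaining > 0
    state.v += (dt / params.c_m) * syn
    state.v[refractory] = params.v_reset
    state.refractory_remaining[refractory] -= dt
    state.t += dt

    # 4. threshold crossing, reset, refractory countdown
    spiked = (~refractory) & (state.v >= params.v_th)
    if spiked.any():
        xs, ys = np.nonzero(spiked)
        state.v[xs, ys] = params.v_reset
        state.refractory_remaining[xs, ys] = params.tau_ref
        inh = (xs % 2 == 1) & (ys % 2 == 1)
        state.pending_e = np.column_stack([xs[~inh], ys[~inh]])
        state.pending_i = np.column_stack([xs[inh], ys[inh]])
        if spike_out is not None:
            t = state.t
            spike_out.extend((t, int(x), int(y)) for x, y in zip(xs, ys))
    else:
        state.pending_e = np.empty((0, 2), dtype=np.intp)
        state.pending_i = np.empty((0, 2), dtype=np.intp)

    if not np.isfinite(state.v).all():
        raise IntegrationError(f"non-finite membrane potential at t = {state.t:.2f} ms")
    return state


def run_trial(
    config: SimulationConfig,
    seed: int,
    *,
    probes: Sequence[tuple[int, int]] | np.ndarray | None = None,
    record_lfp: bool = False,
    kernels: ConnectivityKernels | None = None,
) -> TrialRecording:
    """Integrate one trial and return its recording.

    Spike events are always recorded. When ``probes`` is given, V, g_E and
    g_I at those gridpoints are sampled every ``config.sample_interval_ms``.
    ``record_lfp`` additionally stores the full-grid synaptic-current LFP
    temporal component |g_E (V - V_E)| + |g_I (V - V_I)| (pA, float32) at the
    same sampling, for downstream spatial convolution.
    """
    geometry, params, protocol = config.geometry, config.params, config.protocol
    if config.duration_ms < config.burn_in_ms:
        raise ValueError("duration must be at least the burn-in")
    if kernels is None:
        kernels = build_kernels(params)
    state = initialize_state(geometry, params, seed)
    stim = stimulus_field(geometry, protocol)
    n_steps = int(round(config.duration_ms / params.dt))
    stride = int(round(config.sample_interval_ms / params.dt))
    n_samples = n_steps // stride + 1

    probe_idx = None
    traces = None
    times = None
    if probes is not None:
        probe_coords = np.asarray(probes, dtype=np.intp)
        probe_idx = (probe_coords[:, 0], probe_coords[:, 1])
        traces = {
            "v": np.empty((n_samples, len(probe_coords))),
            "g_e": np.empty((n_samples, len(probe_coords))),
            "g_i": np.empty((n_samples, len(probe_coords))),
        }
        times = np.arange(n_samples) * config.sample_interval_ms
    lfp = (
        np.empty((n_samples, geometry.n, geometry.n), dtype=np.float32)
        if record_lfp
        else None
    )

    def sample(k: int) -> None:
        if traces is not None:
            traces["v"][k] = state.v[probe_idx]
            traces["g_e"][k] = state.g_e[probe_idx]
            traces["g_i"][k] = state.g_i[probe_idx]
        if lfp is not None:
            lfp[k] = (
                np.abs(state.g_e * (state.v - params.v_exc))
                + np.abs(state.g_i * (state.v - params.v_inh))
            ).astype(np.float32)

    spike_out: list[tuple[float, int, int]] = []
    sample(0)
    for i in range(1, n_steps + 1):
        step(
            state, kernels, protocol, params, geometry, stim_field=stim, spike_out=spike_out
        )
        if i % stride == 0:
            sample(i // stride)

    spikes = pd.DataFrame(spike_out, columns=["time_ms", "x", "y"])
    if spikes.empty:
        spikes = pd.DataFrame({"time_ms": pd.Series(dtype=float),
                               "x": pd.Series(dtype=int),
                               "y": pd.Series(dtype=int)})
    return TrialRecording(
        spikes=spikes,
        config=config,
        seed=seed,
        config_digest=config.digest(),
        probe_coords=None if probes is None else np.asarray(probes, dtype=np.intp),
        probe_traces=traces,
        probe_times_ms=times,
        lfp_frames=lfp,
    )


def run_sweep(
    config: SimulationConfig,
    strengths: Sequence[float],
    n_trials: int,
    seed_base: int,
    **trial_kwargs,
) -> dict[tuple[float, int], TrialRecording]:
    """Independent seeded trials for each stimulus strength.

    Trial (strength index j, trial index k) uses seed
    ``seed_base + j * n_trials + k``; the mapping (strength, trial) ->
    recording is returned as a dict and recorded in each recording's seed.
    """
    if not len(strengths):
        raise ValueError("strengths must be non-empty")
    from .params import with_updates

    kernels = build_kernels(config.params)
    out: dict[tuple[float, int], TrialRecording] = {}
    for j, w_s in enumerate(strengths):
        cfg = SimulationConfig(
            geometry=config.geometry,
            params=config.params,
            protocol=with_updates(config.protocol, w_s=float(w_s)),
            duration_ms=config.duration_ms,
            burn_in_ms=config.burn_in_ms,
            sample_interval_ms=config.sample_interval_ms,
        )
        for k in range(n_trials):
            out[(float(w_s), k)] = run_trial(
                cfg, seed_base + j * n_trials + k, kernels=kernels, **trial_kwargs
            )
    return out
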