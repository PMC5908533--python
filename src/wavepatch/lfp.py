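"""Synaptic-current LFP proxy, spike-triggered LFP, and space-constant fits.

The temporal LFP component at each lattice site is the sum of the magnitudes
of the excitatory and inhibitory synaptic currents,
|g_E (V - V_E)| + |g_I (V - V_I)| (pA); the spatial component is a
normalized periodic Gaussian convolution of width ``sigma_lfp`` gridpoints.
The spike-triggered LFP (stLFP) averages the LFP deflection around spikes
fired in the region of input, at electrodes placed at evenly spaced radial
distances from the RoI centre, and its amplitude-vs-distance curve is fit
with M exp(-d / lambda) + B to extract the space constant lambda (mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit

from .params import LatticeGeometry, StimulusProtocol, minimal_image_offsets

__all__ = [
    "LFPField",
    "StLFPCurve",
    "compute_lfp",
    "spike_triggered_lfp",
    "fit_space_constant",
]


@dataclass
class LFPField:
    """Gridded LFP (pA) over time, sampled every ``sample_interval_ms``."""

    frames: np.ndarray  # (n_frames, n, n)
    sample_interval_ms: float
    sigma_lfp: float
    t_start_ms: float = 0.0

    @property
    def n(self) -> int:
        return self.frames.shape[1]


@dataclass
class StLFPCurve:
    """stLFP amplitude vs distance, with the exponential fit when computed.

    ``distances_um`` starts at 0 and increases in steps of
    electrode_spacing x lattice spacing; ``fit`` holds (M, lambda_mm, B).
    """

    distances_um: np.ndarray
    amplitudes: np.ndarray
    n_triggers: int
    fit: tuple[float, float, float] | None = None
    residual_norm: float | None = None
    waveforms: np.ndarray | None = None  # (n_distances, n_lags) trigger-averaged LFP
    lags_ms: np.ndarray | None = None


def compute_lfp(
    temporal_frames: np.ndarray | None = None,
    sigma_lfp: float = 2.5,
    *,
    v: np.ndarray | None = None,
    g_e: np.ndarray | None = None,
    g_i: np.ndarray | None = None,
    v_exc: float = 0.0,
    v_inh: float = -80.0,
    sample_interval_ms: float = 1.0,
    t_start_ms: float = 0.0,
    signed: bool = False,
) -> LFPField:
    """Spatially filtered LFP from current frames or raw state frames.

    Either pass precomputed temporal-component frames (as recorded by the
    simulator with ``record_lfp=True``), or V/g_E/g_I frame stacks from
    which the synaptic currents are formed. ``signed=True`` selects the
    signed sum -(I_E + I_I) instead of the default sum of magnitudes. The
    spatial component is a periodic, normalized Gaussian of width
    ``sigma_lfp`` gridpoints. Linear in the underlying currents, so
    superposition holds exactly.
    """
    if temporal_frames is None:
        if v is None or g_e is None or g_i is None:
            raise ValueError(
                "need either temporal_frames or all of v, g_e, g_i; "
                "rerun the simulation with state capture enabled"
            )
        i_e = g_e * (v - v_exc)
        i_i = g_i * (v - v_inh)
        temporal_frames = -(i_e + i_i) if signed else np.abs(i_e) + np.abs(i_i)
    frames = np.asarray(temporal_frames, dtype=float)
    out = np.empty_like(frames)
    for k in range(frames.shape[0]):
        out[k] = ndimage.gaussian_filter(frames[k], sigma_lfp, mode="wrap")
    return LFPField(
        frames=out,
        sample_interval_ms=sample_interval_ms,
        sigma_lfp=sigma_lfp,
        t_start_ms=t_start_ms,
    )


def _electrode_rings(
    n: int, centre: tuple[int, int], spacing_gp: int, max_radius_gp: int
) -> list[np.ndarray]:
    """Index masks of lattice sites at each electrode distance from the centre.

    Ring k collects sites whose minimal-image distance rounds to
    k * spacing_gp within half a gridpoint, giving an isotropic average at
    each nominal electrode distance.
    """
    x = np.arange(n)
    dx = minimal_image_offsets(x[:, None] - centre[0], n)
    dy = minimal_image_offsets(x[None, :] - centre[1], n)
    dist = np.hypot(dx, dy)
    rings = []
    for k in range(max_radius_gp // spacing_gp + 1):
        rings.append(np.nonzero(np.abs(dist - k * spacing_gp) <= 0.5))
    return rings


def spike_triggered_lfp(
    lfp: LFPField,
    triggers_ms: np.ndarray,
    geometry: LatticeGeometry,
    protocol: StimulusProtocol,
    electrode_spacing: int = 5,
    max_radius_gp: int | None = None,
    window_ms: float = 50.0,
    baseline_ms: tuple[float, float] = (-50.0, -25.0),
) -> StLFPCurve:
    """Trigger-averaged LFP amplitude vs distance from the RoI centre.

    For every trigger time (spikes of RoI neurons, burn-in excluded), LFP
    traces are extracted at electrode rings spaced ``electrode_spacing``
    gridpoints apart, in a +/- ``window_ms`` window. The trigger average is
    baseline-subtracted (mean of the pre-trigger ``baseline_ms`` interval)
    and the amplitude at each distance is the maximum absolute deflection.
    """
    triggers_ms = np.asarray(triggers_ms, dtype=float)
    dt = lfp.sample_interval_ms
    if max_radius_gp is None:
        max_radius_gp = (geometry.n // 2) - electrode_spacing
    rings = _electrode_rings(lfp.n, protocol.centre, electrode_spacing, max_radius_gp)
    n_lag = int(round(window_ms / dt))
    lags = np.arange(-n_lag, n_lag + 1)
    n_frames = lfp.frames.shape[0]
    trig_idx = np.round((triggers_ms - lfp.t_start_ms) / dt).astype(int)
    trig_idx = trig_idx[(trig_idx - n_lag >= 0) & (trig_idx + n_lag < n_frames)]
    if len(trig_idx) == 0:
        raise ValueError("no usable trigger spikes within the recorded LFP range")

    ring_traces = np.stack([lfp.frames[:, r[0], r[1]].mean(axis=1) for r in rings])
    # (n_rings, n_frames) -> trigger-averaged (n_rings, n_lags)
    sta = np.zeros((len(rings), len(lags)))
    for ti in trig_idx:
        sta += ring_traces[:, ti - n_lag : ti + n_lag + 1]
    sta /= len(trig_idx)

    lag_ms = lags * dt
    base_sel = (lag_ms >= baseline_ms[0]) & (lag_ms <= baseline_ms[1])
    sta -= sta[:, base_sel].mean(axis=1, keepdims=True)
    amplitudes = np.abs(sta).max(axis=1)
    distances_um = np.arange(len(rings)) * electrode_spacing * geometry.spacing_um
    return StLFPCurve(
        distances_um=distances_um,
        amplitudes=amplitudes,
        n_triggers=len(trig_idx),
        waveforms=sta,
        lags_ms=lag_ms,
    )


def fit_space_constant(
    curve: StLFPCurve, amplitude_tolerance: float = 1e-12
) -> tuple[float, float, float]:
    """Nonlinear least-squares fit of M exp(-d / lambda) + B to the curve.

    Distances are converted to mm; returns (M, lambda_mm, B) and stores them
    with the residual norm on the curve. Initialization: M = amplitude
    range, B = min amplitude, lambda = distance at half range; lambda is
    bounded positive.
    """
    d_mm = np.asarray(curve.distances_um, dtype=float) / 1000.0
    a = np.asarray(curve.amplitudes, dtype=float)
    if len(d_mm) < 4:
        raise ValueError("need at least 4 distance points to fit a space constant")
    rng_a = a.max() - a.min()
    if rng_a < amplitude_tolerance:
        raise ValueError("flat stLFP curve: space constant unidentifiable")

    half = a.min() + rng_a / 2.0
    below = np.nonzero(a <= half)[0]
    lam0 = d_mm[below[0]] if len(below) and below[0] > 0 else (d_mm[1] if len(d_mm) > 1 else 0.1)
    lam0 = max(lam0, 1e-3)

    def model(d, m, lam, b):
        return m * np.exp(-d / lam) + b

    popt, _ = curve_fit(
        model,
        d_mm,
        a,
        p0=[rng_a, lam0, a.min()],
        bounds=([0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    m, lam, b = (float(p) for p in popt)
    curve.fit = (m, lam, b)
    curve.residual_norm = float(np.linalg.norm(model(d_mm, *popt) - a))
    return m, lam, b


def curve_to_frame(curve: StLFPCurve) -> pd.DataFrame:
    """Tabulate an stLFP curve (and its fit, if present) as a DataFrame."""
    df = pd.DataFrame(
        {"distance_um": curve.distances_um, "amplitude": curve.amplitudes}
    )
    if curve.fit is not None:
        m, lam, b = curve.fit
        df["fit"] = m * np.exp(-(df.distance_um / 1000.0) / lam) + b
    return df
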