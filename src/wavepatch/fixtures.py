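"""Synthetic spike fields with known ground truth.

Every analysis operation (pattern tracking, stLFP, rate and Fano statistics)
can be exercised against data whose true centroids, speeds, rates and labels
are known by construction, without running the network simulator. Blobs are
Gaussian rate envelopes thinned to spikes per millisecond; Poisson grids and
two-state rate-switching processes provide calibrated count statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .params import LatticeGeometry, minimal_image_offsets

__all__ = ["FixtureSpec", "generate"]


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of one synthetic recording.

    ``kind`` selects the generator; ``speed_mm_s`` (blobs), ``rate_hz``
    (Poisson / rate-switching) and ``switch_rate_hz``/``rate_hi_hz``
    (rate-switching) parameterize it. Output is reproducible from
    (spec, seed).
    """

    kind: Literal["moving_blob", "stationary_blob", "poisson_grid", "rate_switching"]
    geometry: LatticeGeometry = LatticeGeometry(n=60)
    duration_ms: float = 500.0
    seed: int = 0
    speed_mm_s: float = 40.0
    direction: tuple[float, float] = (1.0, 0.0)
    start: tuple[float, float] | None = None
    blob_sigma: float = 3.0
    blob_peak_rate_hz: float = 400.0
    rate_hz: float = 9.0
    rate_hi_hz: float = 36.0
    switch_rate_hz: float = 2.0
    confinement_radius: float = 0.0  # stationary blob jitter radius, gridpoints


def _thin_blob_frames(
    spec: FixtureSpec, centres: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Poisson-thin a Gaussian rate envelope moving along ``centres``."""
    n = spec.geometry.n
    x = np.arange(n)
    rows = []
    for fi, c in enumerate(centres):
        dx = minimal_image_offsets(x[:, None] - c[0], n)
        dy = minimal_image_offsets(x[None, :] - c[1], n)
        lam = spec.blob_peak_rate_hz / 1000.0 * np.exp(
            -(dx**2 + dy**2) / (2.0 * spec.blob_sigma**2)
        )
        counts = rng.poisson(lam)
        xs, ys = np.nonzero(counts)
        for sx, sy in zip(xs, ys):
            for _ in range(counts[sx, sy]):
                rows.append((fi + 1.0, sx, sy))
    return pd.DataFrame(rows, columns=["time_ms", "x", "y"])


def generate(spec: FixtureSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a synthetic spike table and its ground-truth record.

    Returns (spikes, truth); spikes has the simulator's event format
    (time_ms, x, y). The truth dict holds the generator's intent: true
    centroids and speed for blobs ('centroids_gp', 'speed_mm_s', 'label'),
    or true rates for the point-process kinds.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.geometry.n
    n_frames = int(round(spec.duration_ms))
    if spec.kind in ("moving_blob", "stationary_blob"):
        start = np.array(spec.start if spec.start is not None else (n / 2.0, n / 2.0))
        if spec.kind == "moving_blob":
            v_gp_per_ms = spec.speed_mm_s * 1000.0 / spec.geometry.spacing_um / 1000.0
            d = np.asarray(spec.direction, dtype=float)
            d = d / np.linalg.norm(d)
            centres = start[None, :] + np.arange(n_frames)[:, None] * v_gp_per_ms * d[None, :]
            label = "wave"
            speed = spec.speed_mm_s
        else:
            if spec.confinement_radius > 0:
                steps = rng.normal(0, 0.3, size=(n_frames, 2))
                walk = np.cumsum(steps, axis=0)
                r = np.linalg.norm(walk, axis=1, keepdims=True)
                walk = np.where(
                    r > spec.confinement_radius, walk * spec.confinement_radius / r, walk
                )
                centres = start[None, :] + walk
            else:
                centres = np.tile(start, (n_frames, 1))
            label = "patch"
            speed = 0.0
        spikes = _thin_blob_frames(spec, centres % n, rng)
        truth = {
            "centroids_gp": centres,
            "speed_mm_s": speed,
            "label": label,
            "blob_sigma": spec.blob_sigma,
        }
        return spikes, truth

    if spec.kind == "poisson_grid":
        lam = spec.rate_hz / 1000.0
        counts = rng.poisson(lam, size=(n_frames, n, n))
        fi, xs, ys = np.nonzero(counts)
        reps = counts[fi, xs, ys]
        spikes = pd.DataFrame(
            {
                "time_ms": np.repeat(fi + 1.0, reps),
                "x": np.repeat(xs, reps),
                "y": np.repeat(ys, reps),
            }
        )
        return spikes, {"rate_hz": spec.rate_hz}

    if spec.kind == "rate_switching":
        # Markov-modulated Poisson process, identical switching for the grid
        p_switch = spec.switch_rate_hz / 1000.0
        state = np.zeros(n_frames, dtype=bool)
        s = rng.random() < 0.5
        for i in range(n_frames):
            if rng.random() < p_switch:
                s = not s
            state[i] = s
        rate = np.where(state, spec.rate_hi_hz, spec.rate_hz) / 1000.0
        counts = rng.poisson(rate[:, None, None], size=(n_frames, n, n))
        fi, xs, ys = np.nonzero(counts)
        reps = counts[fi, xs, ys]
        spikes = pd.DataFrame(
            {
                "time_ms": np.repeat(fi + 1.0, reps),
                "x": np.repeat(xs, reps),
                "y": np.repeat(ys, reps),
            }
        )
        return spikes, {
            "rate_lo_hz": spec.rate_hz,
            "rate_hi_hz": spec.rate_hi_hz,
            "state": state,
        }

    raise ValueError(f"unsupported fixture kind: {spec.kind!r}")
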