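"""Membrane-potential, conductance and spike-count variability statistics.

Distribution-shape statistics (skewness of membrane potential and synaptic
conductance samples) distinguish the synchronous state — quiescence broken by
large, infrequent depolarizing excursions, hence positive skew — from the
asynchronous state of continuous near-threshold fluctuation, with skew near
zero. Spike-count statistics (sliding-window firing rates, raw and
mean-matched Fano factors) quantify trial-to-trial rate variability and its
stimulus-evoked decline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SkewnessSummary",
    "FanoResult",
    "skewness",
    "subthreshold_distance",
    "trial_statistic_summary",
    "firing_rate",
    "spike_counts",
    "fano_factor",
    "mean_matched_fano",
]


@dataclass
class SkewnessSummary:
    """Across-trial and across-neuron summary of per-trial skewness values.

    ``per_trial`` has shape (n_trials, n_neurons); ``median_across_trials``
    is per neuron; ``mean``/``sd`` summarize the per-neuron medians across
    neurons.
    """

    per_trial: np.ndarray
    median_across_trials: np.ndarray
    mean: float
    sd: float


@dataclass
class FanoResult:
    """Fano factor time series for one window size.

    ``raw_ff`` is the across-trial variance/mean of spike counts per neuron
    and window, averaged over neurons; ``mm_ff`` is the mean-matched version
    (NaN where matching was impossible) with standard error ``mm_se`` across
    resamples x neurons; ``window_ms`` and window-centre ``times_ms`` define
    the sliding windows.
    """

    window_ms: float
    times_ms: np.ndarray
    raw_ff: np.ndarray
    mm_ff: np.ndarray | None = None
    mm_se: np.ndarray | None = None
    n_resamples: int = 0
    mean_matched: bool = False


def skewness(sample: np.ndarray, axis: int = 0, bias: bool = True) -> np.ndarray:
    """Sample skewness: third standardized central moment.

    Bias-uncorrected by default; set ``bias=False`` for the adjusted
    (Fisher-Pearson corrected) estimator. Zero-variance samples are flagged
    as NaN rather than raising.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.shape[axis] < 3:
        raise ValueError("skewness needs at least 3 observations")
    with np.errstate(invalid="ignore", divide="ignore"):
        s = sps.skew(sample, axis=axis, bias=bias)
    return s


def subthreshold_distance(v_trace: np.ndarray, v_th: float, axis: int = 0) -> np.ndarray:
    """Time-averaged distance of the membrane potential below threshold, in mV.

    Positive for subthreshold-mean traces: <V_th - V> over time.
    """
    v_trace = np.asarray(v_trace, dtype=float)
    if v_trace.shape[axis] == 0:
        raise ValueError("empty membrane-potential trace")
    return v_th - v_trace.mean(axis=axis)


def trial_statistic_summary(per_trial: np.ndarray) -> SkewnessSummary:
    """Median across trials per neuron, then mean and s.d. across neurons.

    ``per_trial`` has shape (n_trials, n_neurons). NaN entries (flagged
    undefined statistics) are ignored in the medians.
    """
    per_trial = np.atleast_2d(np.asarray(per_trial, dtype=float))
    med = np.nanmedian(per_trial, axis=0)
    return SkewnessSummary(
        per_trial=per_trial,
        median_across_trials=med,
        mean=float(np.nanmean(med)),
        sd=float(np.nanstd(med)),
    )


def _window_starts(t_start: float, t_end: float, window: float, stride: float) -> np.ndarray:
    n = int(np.floor((t_end - t_start - window) / stride)) + 1
    if n < 1:
        raise ValueError("epoch shorter than the counting window")
    return t_start + np.arange(n) * stride


def spike_counts(
    spike_times_per_trial: list[np.ndarray],
    t_start_ms: float,
    t_end_ms: float,
    window_ms: float = 250.0,
    stride_ms: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window spike counts for one neuron across trials.

    Returns (window centre times, counts) with counts of shape
    (n_trials, n_windows); window (t, t + window] slides in ``stride_ms``
    increments.
    """
    starts = _window_starts(t_start_ms, t_end_ms, window_ms, stride_ms)
    counts = np.empty((len(spike_times_per_trial), len(starts)), dtype=float)
    for i, t in enumerate(spike_times_per_trial):
        t = np.asarray(t)
        counts[i] = np.searchsorted(t, starts + window_ms, side="right") - np.searchsorted(
            t, starts, side="right"
        )
    return starts + window_ms / 2.0, counts


def firing_rate(
    spike_times_ms: np.ndarray,
    t_start_ms: float,
    t_end_ms: float,
    window_ms: float = 250.0,
    stride_ms: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window firing rate (Hz) of one spike train."""
    times, counts = spike_counts([np.sort(np.asarray(spike_times_ms))],
                                 t_start_ms, t_end_ms, window_ms, stride_ms)
    return times, counts[0] / (window_ms / 1000.0)


def fano_factor(counts: np.ndarray) -> np.ndarray:
    """Across-trial variance/mean of spike counts, per window.

    ``counts`` has shape (n_trials, n_windows); needs >= 2 trials. Windows
    with zero mean count are flagged NaN.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("Fano factor needs counts from at least 2 trials")
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(mean > 0, var / mean, np.nan)
    return ff


def mean_matched_fano(
    counts_by_neuron: np.ndarray,
    n_resamples: int = 50,
    seed: int | np.random.Generator = 0,
    n_bins: int = 20,
) -> FanoResult:
    """Mean-matched Fano factor across neurons and time windows.

    ``counts_by_neuron`` has shape (n_neurons, n_trials, n_windows). For
    each window the per-neuron mean counts are histogrammed on common bin
    edges; the greatest common (element-wise floor) histogram across windows
    defines how many neurons per bin survive matching. At each window,
    neurons are randomly discarded to match that histogram, the Fano factors
    of the kept neurons are averaged, and the procedure is repeated
    ``n_resamples`` times. If the common histogram is empty the result falls
    back to the raw (unmatched) neuron-averaged Fano factor with
    ``mean_matched=False``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.asarray(counts_by_neuron, dtype=float)
    if counts.ndim != 3:
        raise ValueError("expected counts of shape (n_neurons, n_trials, n_windows)")
    n_neurons, n_trials, n_windows = counts.shape
    if n_windows < 2:
        raise ValueError("mean matching needs at least 2 time windows")
    means = counts.mean(axis=1)  # (n_neurons, n_windows)
    ffs = np.stack([fano_factor(counts[i]) for i in range(n_neurons)])  # (n_neurons, n_windows)
    raw = np.nanmean(ffs, axis=0)

    edges = np.histogram_bin_edges(means[np.isfinite(means)], bins=n_bins)
    hists = np.stack(
        [np.histogram(means[:, w], bins=edges)[0] for w in range(n_windows)]
    )  # (n_windows, n_bins)
    common = hists.min(axis=0)
    if common.sum() == 0:
        return FanoResult(
            window_ms=np.nan, times_ms=np.arange(n_windows, dtype=float),
            raw_ff=raw, mm_ff=raw.copy(), mm_se=np.full(n_windows, np.nan),
            n_resamples=0, mean_matched=False,
        )

    bin_of = np.clip(np.digitize(means, edges) - 1, 0, len(common) - 1)
    mm = np.empty((n_resamples, n_windows))
    for r in range(n_resamples):
        for w in range(n_windows):
            kept: list[int] = []
            for b in np.nonzero(common)[0]:
                members = np.nonzero(bin_of[:, w] == b)[0]
                take = common[b]
                kept.extend(rng.choice(members, size=take, replace=False))
            mm[r, w] = np.nanmean(ffs[kept, w])
    return FanoResult(
        window_ms=np.nan,
        times_ms=np.arange(n_windows, dtype=float),
        raw_ff=raw,
        mm_ff=mm.mean(axis=0),
        mm_se=mm.std(axis=0, ddof=1) / np.sqrt(n_resamples) if n_resamples > 1 else np.zeros(n_windows),
        n_resamples=n_resamples,
        mean_matched=True,
    )


def roi_spike_times(
    recordings: list,
    roi: np.ndarray,
) -> list[list[np.ndarray]]:
    """Per-neuron, per-trial spike-time lists for neurons in a boolean mask.

    Returns a list over RoI neurons (row-major order of True entries in
    ``roi``), each a list over trials of sorted spike-time arrays (ms).
    """
    coords = np.argwhere(roi)
    key = {(int(x), int(y)): i for i, (x, y) in enumerate(coords)}
    out: list[list[np.ndarray]] = [[] for _ in coords]
    for rec in recordings:
        sp = rec.spikes
        per_neuron: dict[int, list[float]] = {}
        xs, ys, ts = sp.x.values, sp.y.values, sp.time_ms.values
        inroi = roi[xs, ys]
        for x, y, t in zip(xs[inroi], ys[inroi], ts[inroi]):
            per_neuron.setdefault(key[(int(x), int(y))], []).append(t)
        for i in range(len(coords)):
            out[i].append(np.asarray(per_neuron.get(i, []), dtype=float))
    return out
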