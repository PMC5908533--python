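"""Top-level analysis workflows tying simulation to the analysis modules.

``reproduce`` runs the simulation protocol behind each headline analysis —
stLFP space constants, membrane-potential and conductance statistics,
afferent-distance series, firing-rate and Fano-factor analyses — at either
``desk`` scale (reduced lattice and trial counts, for a single workstation)
or ``full`` scale (the complete protocol: 300 x 300 lattice, 500 trials of
3.5 s), and writes the resulting tables plus a provenance manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import lfp as lfp_mod
from . import patterns as patterns_mod
from . import stats as stats_mod
from .params import (
    LatticeGeometry,
    ModelParameters,
    StimulusProtocol,
    build_kernels,
    roi_mask,
    with_updates,
)
from .simulate import SimulationConfig, run_trial

__all__ = ["ScalePreset", "DESK", "FULL", "reproduce", "REPRODUCIBLE_FIGURES"]

SPONT_EPOCH_MS = (1000.0, 2000.0)
EVOKED_EPOCH_MS = (2250.0, 3500.0)  # 250 ms settling after onset excluded
STRONG_STIMULUS_NA = 1.2


@dataclass(frozen=True)
class ScalePreset:
    """Problem sizes for one reproduction run."""

    name: str
    n: int
    n_trials: int
    duration_ms: float
    sweep_strengths: tuple[float, ...]
    probe_stride: int = 1  # keep every k-th RoI neuron as a probe


DESK = ScalePreset(
    name="desk",
    n=120,
    n_trials=4,
    duration_ms=3500.0,
    sweep_strengths=(0.0, 0.4, 0.8, 1.2),
    probe_stride=4,
)
FULL = ScalePreset(
    name="full",
    n=300,
    n_trials=500,
    duration_ms=3500.0,
    sweep_strengths=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2),
    probe_stride=1,
)

REPRODUCIBLE_FIGURES = ("1d", "1e", "2", "3", "4", "5a", "5b", "5c", "5d")


def _base_config(preset: ScalePreset, w_s: float = 0.0) -> SimulationConfig:
    geom = LatticeGeometry(n=preset.n)
    centre = (preset.n // 2, preset.n // 2)
    return SimulationConfig(
        geometry=geom,
        params=ModelParameters(),
        protocol=StimulusProtocol(centre=centre, w_s=w_s),
        duration_ms=preset.duration_ms,
        burn_in_ms=1000.0,
    )


def _epoch_slice(times_ms: np.ndarray, epoch: tuple[float, float]) -> np.ndarray:
    return (times_ms > epoch[0]) & (times_ms <= epoch[1])


def _roi_probes(cfg: SimulationConfig, stride: int) -> np.ndarray:
    return np.argwhere(roi_mask(cfg.geometry, cfg.protocol))[::stride]


def _simulate_pair(preset: ScalePreset, seed: int, **kw):
    """One spontaneous and one strongly stimulated trial per trial index."""
    cfg_s = _base_config(preset, w_s=0.0)
    cfg_e = _base_config(preset, w_s=STRONG_STIMULUS_NA)
    kernels = build_kernels(cfg_s.params)
    recs_s, recs_e = [], []
    probes_s = _roi_probes(cfg_s, preset.probe_stride)
    for k in range(preset.n_trials):
        recs_s.append(run_trial(cfg_s, seed + k, probes=probes_s, kernels=kernels, **kw))
        recs_e.append(
            run_trial(cfg_e, seed + 10_000 + k, probes=probes_s, kernels=kernels, **kw)
        )
    return cfg_s, cfg_e, recs_s, recs_e


def _stlfp_lambda(
    cfg: SimulationConfig, rec, epoch: tuple[float, float]
) -> tuple[lfp_mod.StLFPCurve, float]:
    field = lfp_mod.compute_lfp(
        rec.lfp_frames, sample_interval_ms=cfg.sample_interval_ms
    )
    rm = roi_mask(cfg.geometry, cfg.protocol)
    sp = rec.spikes
    sel = (
        _epoch_slice(sp.time_ms.values, epoch) & rm[sp.x.values, sp.y.values]
    )
    curve = lfp_mod.spike_triggered_lfp(
        field, sp.time_ms.values[sel], cfg.geometry, cfg.protocol
    )
    _, lam, _ = lfp_mod.fit_space_constant(curve)
    return curve, lam


def reproduce(
    figure_id: str,
    scale: str = "desk",
    seed: int = 0,
    out_dir: str | Path | None = None,
    preset: ScalePreset | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the workflow behind one headline analysis and return its tables.

    ``figure_id`` selects the analysis: '1d' stLFP curves and space
    constants (spontaneous vs strong stimulus); '1e' space constant vs
    stimulus strength; '2' membrane-potential statistics; '3' excitatory
    conductance statistics; '4' afferent spike distances, 1-ms count
    histogram and conductance reconstruction; '5a' firing rates; '5b'
    mean-matched Fano factor vs time; '5c' Fano factor vs window size;
    '5d' Fano factor vs stimulus strength. When ``out_dir`` is given, every
    table is written as CSV together with a provenance manifest.
    """
    if figure_id not in REPRODUCIBLE_FIGURES:
        raise ValueError(
            f"unknown figure id {figure_id!r}; choose from {REPRODUCIBLE_FIGURES}"
        )
    if preset is None:
        if scale not in ("desk", "full"):
            raise ValueError("scale must be 'desk' or 'full'")
        preset = DESK if scale == "desk" else FULL

    tables = _FIGURE_DISPATCH[figure_id](preset, seed)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import json

        for name, df in tables.items():
            df.to_csv(out_dir / f"fig{figure_id}_{name}.csv", index=False)
        manifest = {
            "figure": figure_id,
            "scale": preset.name,
            "seed": seed,
            "preset": {
                "n": preset.n,
                "n_trials": preset.n_trials,
                "duration_ms": preset.duration_ms,
            },
            "config_digest": _base_config(preset).digest(),
            "tables": sorted(f"fig{figure_id}_{k}.csv" for k in tables),
        }
        (out_dir / f"fig{figure_id}_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
    return tables


def _fig_1d(preset: ScalePreset, seed: int) -> dict[str, pd.DataFrame]:
    cfg_s = _base_config(preset, w_s=0.0)
    cfg_e = _base_config(preset, w_s=STRONG_STIMULUS_NA)
    kernels = build_kernels(cfg_s.params)
    rec_s = run_trial(cfg_s, seed, record_lfp=True, kernels=kernels)
    rec_e = run_trial(cfg_e, seed + 10_000, record_lfp=True, kernels=kernels)
    curve_s, lam_s = _stlfp_lambda(cfg_s, rec_s, SPONT_EPOCH_MS)
    curve_e, lam_e = _stlfp_lambda(cfg_e, rec_e, EVOKED_EPOCH_MS)
    out = {
        "stlfp_spont": lfp_mod.curve_to_frame(curve_s),
        "stlfp_evoked": lfp_mod.curve_to_frame(curve_e),
        "space_constants": pd.DataFrame(
            {
                "condition": ["spontaneous", "evoked"],
                "lambda_mm": [lam_s, lam_e],
                "n_triggers": [curve_s.n_triggers, curve_e.n_triggers],
            }
        ),
    }
    return out


def _fig_1e(preset: ScalePreset, seed: int) -> dict[str, pd.DataFrame]:
    rows = []
    for j, w_s in enumerate(preset.sweep_strengths):
        cfg = _base_config(preset, w_s=w_s)
        rec = run_trial(cfg, seed + j, record_lfp=True)
        epoch = SPONT_EPOCH_MS if w_s == 0 else EVOKED_EPOCH_MS
        _, lam = _stlfp_lambda(cfg, rec, epoch)
        rows.append({"w_s_na": w_s, "lambda_mm": lam})
    return {"space_constant_vs_strength": pd.DataFrame(rows)}


def _membrane_tables(preset: ScalePreset, seed: int, field: str):
    cfg_s, cfg_e, recs_s, recs_e = _simulate_pair(preset, seed)
    t = recs_s[0].probe_times_ms
    sl_s = _epoch_slice(t, SPONT_EPOCH_MS)
    sl_e = _epoch_slice(t, EVOKED_EPOCH_MS)
    skews = {}
    for label, recs, sl in (("spont", recs_s, sl_s), ("evoked", recs_e, sl_e)):
        per_trial = np.stack(
            [stats_mod.skewness(r.probe_traces[field][sl], axis=0) for r in recs]
        )
        skews[label] = stats_mod.trial_statistic_summary(per_trial)
    mean_trace = np.stack([r.probe_traces[field] for r in recs_e]).mean(axis=(0, 2))
    tables = {
        "trial_averaged_trace": pd.DataFrame({"time_ms": t, field: mean_trace}),
        "skewness": pd.DataFrame(
            {
                "condition": ["spontaneous", "evoked"],
                "mean_median_skew": [skews["spont"].mean, skews["evoked"].mean],
                "sd": [skews["spont"].sd, skews["evoked"].sd],
            }
        ),
    }
    return cfg_s, recs_s, recs_e, sl_s, sl_e, tables


def _fig_2(preset: ScalePreset, seed: int) -> dict[str, pd.DataFrame]:
    cfg_s, recs_s, recs_e, sl_s, sl_e, tables = _membrane_tables(preset, seed, "v")
    v_th = cfg_s.params.v_th
    rows = []
    for label, recs, sl in (("spontaneous", recs_s, sl_s), ("evoked", recs_e, sl_e)):
        per_trial = np.stack(
            [stats_mod.subthreshold_distance(r.probe_traces["v"][sl], v_th) for r in recs]
        )
        summ = stats_mod.trial_statistic_summary(per_trial)
        rows.append({"condition": label, "mean_median_dv_mv": summ.mean, "sd": summ.sd})
    tables["subthreshold_distance"] = pd.DataFrame(rows)
    return tables


def _fig_3(preset: ScalePreset, seed: int) -> dict[str, pd.DataFrame]:
    *_, tables = _membrane_tables(preset, seed, "g_e")
    return tables


def _fig_4(preset: ScalePreset, seed: int) -> dict[str, pd.DataFrame]:
    cfg = _base_config(preset, w_s=0.0)
    kernels = build_kernels(cfg.params)
    test_neuron = cfg.protocol.centre
    rec = run_trial(cfg, seed, probes=[test_neuron], kernels=kernels)
    series = patterns_mod.afferent_spike_distances(
        rec.spikes, test_neuron, cfg.params, cfg.geometry,
        t_start_ms=cfg.burn_in_ms, t_end_ms=cfg.duration_ms,
    )
    times, g_rec = patterns_mod.reconstruct_conductance(
        rec.spikes, test_neuron, kernels, cfg.params, cfg.geometry,
        t_end_ms=cfg.duration_ms,
    )
    counts, edges = np.histogram(series.count, bins=np.arange(series.count.max() + 2))
    return {
        "distance_series": pd.DataFrame(
            {
                "time_ms": series.times_ms,
                "mean_distance_um": series.mean_distance_um,
                "count": series.count,
            }
        ),
        "count_histogram": pd.DataFrame(
            {"spikes_per_ms": edges[:-1], "n_windows": counts}
        ),
        "conductance": pd.DataFrame(
            {
                "time_ms": times,
                "g_e_recorded": rec.probe_traces["g_e"][:, 0],
                "g_e_reconstructed": g_rec,
            }
        ),
    }


def _roi_counts(preset, recs, cfg, window_ms, epoch=None, stride_ms=50.0):
    rm = roi_mask(cfg.geometry, cfg.protocol)
    per_neuron = stats_mod.roi_spike_times(recs, rm)
    # keep every probe_stride-th RoI neuron to bound cost
    keep = range(0, len(per_neuron), preset.probe_stride)
    t0, t1 = (cfg.burn_in_ms, cfg.duration_ms) if epoch is None else epoch
    counts = []
    for i in keep:
        _, c = stats_mod.spike_counts(per_neuron[i], t0, t1, window_ms, stride_ms)
        counts.append(c)
    times, _ = stats_mod.spike_counts(per_neuron[0], t0, t1, window_ms, stride_ms)
    return times, np.stack(counts)  # (n_neurons, n_trials, n_windows)


def _fig_5a(preset: ScalePreset, seed: int) -> dict[str, pd.DataFrame]:
    cfg_s, cfg_e, recs_s, recs_e = _simulate_pair(preset, seed)
    times, counts = _roi_counts(preset, recs_e, cfg_e, 250.0)
    rates = counts / 0.250
    df = pd.DataFrame({"time_ms": times, "rate_hz_mean": rates.mean(axis=(0, 1))})
    for k in range(min(5, rates.shape[1])):
        df[f"rate_hz_trial{k}"] = rates[:, k, :].mean(axis=0)
    return {"firing_rate": df}


def _fig_5b(preset: ScalePreset, seed: int) -> dict[str, pd.DataFrame]:
    cfg_s, cfg_e, recs_s, recs_e = _simulate_pair(preset, seed)
    times, counts = _roi_counts(preset, recs_e, cfg_e, 250.0)
    res = stats_mod.mean_matched_fano(counts, seed=seed)
    return {
        "fano_vs_time": pd.DataFrame(
            {
                "time_ms": times,
                "raw_ff": res.raw_ff,
                "mm_ff": res.mm_ff,
                "mm_se": res.mm_se,
            }
        )
    }


def _fig_5c(preset: ScalePreset, seed: int) -> dict[str, pd.DataFrame]:
    cfg_s, cfg_e, recs_s, recs_e = _simulate_pair(preset, seed)
    rows = []
    for window in (150.0, 250.0, 400.0, 600.0):
        for label, recs, cfg, epoch in (
            ("spontaneous", recs_s, cfg_s, SPONT_EPOCH_MS),
            ("evoked", recs_e, cfg_e, EVOKED_EPOCH_MS),
        ):
            _, counts = _roi_counts(preset, recs, cfg, window, epoch=epoch)
            res = stats_mod.mean_matched_fano(counts, seed=seed)
            rows.append(
                {
                    "window_ms": window,
                    "condition": label,
                    "mm_ff": float(np.nanmean(res.mm_ff)),
                }
            )
    return {"fano_vs_window": pd.DataFrame(rows)}


def _fig_5d(preset: ScalePreset, seed: int) -> dict[str, pd.DataFrame]:
    rows = []
    for j, w_s in enumerate(preset.sweep_strengths):
        cfg = _base_config(preset, w_s=w_s)
        kernels = build_kernels(cfg.params)
        recs = [
            run_trial(cfg, seed + 100 * j + k, kernels=kernels)
            for k in range(preset.n_trials)
        ]
        epoch = EVOKED_EPOCH_MS
        _, counts = _roi_counts(preset, recs, cfg, 250.0, epoch=epoch)
        res = stats_mod.mean_matched_fano(counts, seed=seed)
        rows.append({"w_s_na": w_s, "mm_ff": float(np.nanmean(res.mm_ff))})
    return {"fano_vs_strength": pd.DataFrame(rows)}


_FIGURE_DISPATCH = {
    "1d": _fig_1d,
    "1e": _fig_1e,
    "2": _fig_2,
    "3": _fig_3,
    "4": _fig_4,
    "5a": _fig_5a,
    "5b": _fig_5b,
    "5c": _fig_5c,
    "5d": _fig_5d,
}
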