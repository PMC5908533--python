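"""Stimulus-evoked quenching of trial-to-trial rate variability.

Four stimulated trials; spike counts of RoI neurons in 250 ms sliding
windows. The mean-matched Fano factor (variance/mean of counts across
trials, computed on a rate-matched neuron subsample so rate changes cannot
masquerade as variability changes) is well above 1 during spontaneous
activity — slow switching between high- and low-rate states as patterns
wander — and drops at stimulus onset, when a pinned localized pattern holds
the RoI in a steady high-rate state.
"""

import numpy as np

from wavepatch import (
    LatticeGeometry,
    ModelParameters,
    SimulationConfig,
    StimulusProtocol,
    build_kernels,
    roi_mask,
    run_trial,
)
from wavepatch.stats import mean_matched_fano, roi_spike_times, spike_counts

n = 120
cfg = SimulationConfig(
    geometry=LatticeGeometry(n=n),
    params=ModelParameters(),
    protocol=StimulusProtocol(centre=(n // 2, n // 2), w_s=1.2),
    duration_ms=3500.0,
    burn_in_ms=1000.0,
)
kernels = build_kernels(cfg.params)
recs = [run_trial(cfg, seed, kernels=kernels) for seed in range(21, 25)]

rm = roi_mask(cfg.geometry, cfg.protocol)
per_neuron = roi_spike_times(recs, rm)
counts = []
for spikes_by_trial in per_neuron[::3]:
    _, c = spike_counts(spikes_by_trial, 1000.0, 3500.0, 250.0, 50.0)
    counts.append(c)
times, _ = spike_counts(per_neuron[0], 1000.0, 3500.0, 250.0, 50.0)

res = mean_matched_fano(np.stack(counts), n_resamples=20, seed=0)
pre = (times > 1125) & (times < 1875)
post = times > 2375
print(f"raw Fano factor: {np.nanmean(res.raw_ff[pre]):.2f} spontaneous -> "
      f"{np.nanmean(res.raw_ff[post]):.2f} evoked")
print(f"mean-matched FF: {np.nanmean(res.mm_ff[pre]):.2f} spontaneous -> "
      f"{np.nanmean(res.mm_ff[post]):.2f} evoked")
print("spontaneous values above 1 indicate doubly stochastic firing (slow rate "
      "fluctuations on top of irregular spiking); the drop at onset is the "
      "variability quench. With only four trials the raw contrast is the "
      "reliable one; the matched estimator needs tens of trials to resolve it.")
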