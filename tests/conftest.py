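"""Shared fixtures.

``stim_trials`` is the scaled-down reference protocol used by the
statistical tests: a 120 x 120 lattice (the full kernel cutoff fits four
times over), four seeded 3.5 s trials with the strong (1.2 nA) localized
stimulus switching on at t = 2 s. The pre-onset epoch (1.0-2.0 s, after
burn-in) is statistically identical to spontaneous activity because the
stimulus gate is exactly zero before onset, so one set of trials yields both
the spontaneous and the evoked condition, mirroring the before/after-onset
comparison the analyses are built around.
"""

from __future__ import annotations

import numpy as np
import pytest

from wavepatch import (
    LatticeGeometry,
    ModelParameters,
    SimulationConfig,
    StimulusProtocol,
    build_kernels,
    roi_mask,
    run_trial,
)

SPONT_EPOCH = (1000.0, 2000.0)
EVOKED_EPOCH = (2250.0, 3500.0)
N_TRIALS = 4
SEED_BASE = 101


@pytest.fixture(scope="session")
def stim_config() -> SimulationConfig:
    geom = LatticeGeometry(n=120)
    return SimulationConfig(
        geometry=geom,
        params=ModelParameters(),
        protocol=StimulusProtocol(centre=(60, 60), w_s=1.2),
        duration_ms=3500.0,
        burn_in_ms=1000.0,
    )


@pytest.fixture(scope="session")
def roi_probes(stim_config) -> np.ndarray:
    mask = roi_mask(stim_config.geometry, stim_config.protocol)
    return np.argwhere(mask)[::3]


@pytest.fixture(scope="session")
def stim_trials(stim_config, roi_probes):
    """Four stimulated trials; the first also records full-grid LFP frames."""
    kernels = build_kernels(stim_config.params)
    recs = []
    for k in range(N_TRIALS):
        recs.append(
            run_trial(
                stim_config,
                SEED_BASE + k,
                probes=roi_probes,
                record_lfp=(k == 0),
                kernels=kernels,
            )
        )
    return recs


@pytest.fixture(scope="session")
def small_probe_run():
    """A 60 x 60 spontaneous run with one probed neuron, for identity checks."""
    geom = LatticeGeometry(n=60)
    cfg = SimulationConfig(
        geometry=geom,
        params=ModelParameters(),
        protocol=StimulusProtocol(centre=(30, 30), w_s=0.0),
        duration_ms=600.0,
        burn_in_ms=0.0,
    )
    rec = run_trial(cfg, seed=7, probes=[(30, 30)])
    return cfg, rec
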