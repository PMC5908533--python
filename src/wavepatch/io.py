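"""Configuration files, recording I/O and run manifests.

Configurations are YAML mappings with sections ``geometry``, ``model``,
``stimulus`` and ``protocol``; unknown keys are rejected and every loaded
configuration is validated against the model invariants. Spike events are
stored as CSV (time_ms,x,y); probe traces and LFP frames go into an HDF5
container with units recorded as dataset attributes. A run manifest records
the configuration digest, seeds and per-trial file paths.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .params import (
    ConfigurationError,
    LatticeGeometry,
    ModelParameters,
    StimulusProtocol,
)
from .simulate import SimulationConfig, TrialRecording

__all__ = [
    "load_config",
    "save_config",
    "save_recording",
    "load_recording",
    "write_manifest",
    "load_manifest",
]

_SECTIONS = {
    "geometry": (LatticeGeometry, {"n", "spacing_um", "periodic"}),
    "model": (
        ModelParameters,
        {
            "g_l", "c_m", "v_leak", "v_exc", "v_inh", "v_th", "v_reset",
            "tau_ref", "tau_e", "tau_i", "w_e", "w_i", "sigma_e", "cutoff", "dt",
        },
    ),
    "stimulus": (
        StimulusProtocol,
        {"i_background", "w_s", "t_onset_ms", "centre", "sigma_s", "roi_radius"},
    ),
    "protocol": (None, {"duration_ms", "burn_in_ms", "sample_interval_ms"}),
}


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a simulation configuration from YAML.

    Unknown sections or keys raise a ``ConfigurationError`` naming the key.
    ``model.sigma_e`` must be stated explicitly: it is a calibrated quantity
    (default calibration: 4.0 gridpoints), not a measured one, so config
    files are required to own the choice.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration root must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigurationError(f"unknown configuration section(s): {sorted(unknown)}")
    kwargs = {}
    for section, (cls, allowed) in _SECTIONS.items():
        body = raw.get(section, {}) or {}
        bad = set(body) - allowed
        if bad:
            raise ConfigurationError(f"unknown key(s) in '{section}': {sorted(bad)}")
        kwargs[section] = body
    model = kwargs["model"]
    if "sigma_e" not in model:
        raise ConfigurationError(
            "model.sigma_e is required: it is a calibrated parameter "
            "(the package's calibrated default is 4.0 gridpoints = 160 um); "
            "state it explicitly in the configuration"
        )
    stim = dict(kwargs["stimulus"])
    if "centre" in stim:
        stim["centre"] = tuple(stim["centre"])
    return SimulationConfig(
        geometry=LatticeGeometry(**kwargs["geometry"]),
        params=ModelParameters(**model),
        protocol=StimulusProtocol(**stim),
        **kwargs["protocol"],
    )


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a configuration to YAML; round-trips through ``load_config``."""
    doc = {
        "geometry": asdict(config.geometry),
        "model": asdict(config.params),
        "stimulus": {
            **asdict(config.protocol),
            "centre": list(config.protocol.centre),
        },
        "protocol": {
            "duration_ms": config.duration_ms,
            "burn_in_ms": config.burn_in_ms,
            "sample_interval_ms": config.sample_interval_ms,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def save_recording(rec: TrialRecording, out_dir: str | Path, stem: str) -> dict[str, str]:
    """Write one trial: spikes to CSV, traces/frames to HDF5.

    Returns a dict of relative file paths, suitable for a manifest entry.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    spikes_path = out_dir / f"{stem}_spikes.csv"
    # %.17g guarantees float64 spike times round-trip through text
    rec.spikes.to_csv(spikes_path, index=False, float_format="%.17g")
    paths["spikes"] = spikes_path.name
    if rec.probe_traces is not None or rec.lfp_frames is not None:
        h5_path = out_dir / f"{stem}_traces.h5"
        with h5py.File(h5_path, "w") as f:
            f.attrs["seed"] = rec.seed
            f.attrs["config_digest"] = rec.config_digest
            f.attrs["burn_in_ms"] = rec.config.burn_in_ms
            f.attrs["duration_ms"] = rec.config.duration_ms
            if rec.probe_traces is not None:
                g = f.create_group("probes")
                g.create_dataset("coords", data=rec.probe_coords)
                g.create_dataset("times_ms", data=rec.probe_times_ms)
                units = {"v": "mV", "g_e": "nS", "g_i": "nS"}
                for name, arr in rec.probe_traces.items():
                    d = g.create_dataset(name, data=arr)
                    d.attrs["units"] = units.get(name, "")
            if rec.lfp_frames is not None:
                d = f.create_dataset("lfp_frames", data=rec.lfp_frames)
                d.attrs["units"] = "pA"
                d.attrs["sample_interval_ms"] = rec.config.sample_interval_ms
        paths["traces"] = h5_path.name
    return paths


def load_recording(
    out_dir: str | Path, stem: str, config: SimulationConfig, seed: int
) -> TrialRecording:
    """Load a trial written by ``save_recording``."""
    out_dir = Path(out_dir)
    spikes = pd.read_csv(out_dir / f"{stem}_spikes.csv", float_precision="round_trip")
    rec = TrialRecording(
        spikes=spikes, config=config, seed=seed, config_digest=config.digest()
    )
    h5_path = out_dir / f"{stem}_traces.h5"
    if h5_path.exists():
        with h5py.File(h5_path, "r") as f:
            if "probes" in f:
                g = f["probes"]
                rec.probe_coords = g["coords"][()]
                rec.probe_times_ms = g["times_ms"][()]
                rec.probe_traces = {
                    k: g[k][()] for k in g if k not in ("coords", "times_ms")
                }
            if "lfp_frames" in f:
                rec.lfp_frames = f["lfp_frames"][()]
    return rec


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(
    out_dir: str | Path,
    config: SimulationConfig,
    trials: list[dict],
) -> Path:
    """Write a run manifest listing per-trial seeds, files and file digests."""
    from . import __version__

    out_dir = Path(out_dir)
    entries = []
    for tr in trials:
        files = {
            role: {"path": name, "sha256_16": _file_digest(out_dir / name)}
            for role, name in tr["files"].items()
        }
        entries.append({**{k: v for k, v in tr.items() if k != "files"}, "files": files})
    doc = {
        "config_digest": config.digest(),
        "package_version": __version__,
        "trials": entries,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    return path


def load_manifest(out_dir: str | Path, verify: bool = True) -> dict:
    """Load a manifest; with ``verify`` check every file exists and matches."""
    out_dir = Path(out_dir)
    doc = json.loads((out_dir / "manifest.json").read_text())
    if verify:
        for tr in doc["trials"]:
            for role, info in tr["files"].items():
                p = out_dir / info["path"]
                if not p.exists():
                    raise FileNotFoundError(f"manifest references missing file {p}")
                if _file_digest(p) != info["sha256_16"]:
                    raise ValueError(f"digest mismatch for {p}")
    return doc
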