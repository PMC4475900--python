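"""Run configuration: defaults, YAML loading, validation, provenance.

A run is configured by three sections — ``simulate`` (latent dynamics
and emission), ``preprocess`` (smoothing, epoch, normalisation, PCA),
``shuffle`` (control kind and trial count) — plus a master ``seed``.
Values mirror the standard analysis parameters: 250 ms movement epoch,
Gaussian smoothing SD 25 ms, soft-normalisation constant 5 spikes/s,
top 6 PCs, 300 shuffle trials, 8 conditions.
"""

from __future__ import annotations

import copy
import hashlib
import json
import warnings

import yaml

__all__ = ["DEFAULTS", "load_config", "validate_config", "config_hash"]

DEFAULTS: dict = {
    "seed": 0,
    "simulate": {
        "n_dims": 4,
        "plane_frequencies_hz": [2.5, 1.0],
        "expansion_rates": [],
        "initial_state_spread": 1.0,
        "duration_ms": 250.0,
        "dt_ms": 10.0,
        "n_conditions": 8,
        "n_electrodes": 40,
        "baseline_hz": 20.0,
        "gain_hz": 10.0,
        "trials_per_condition": 100,
        "pre_epoch_ms": 300.0,
    },
    "preprocess": {
        "kernel_sd_ms": 25.0,
        "epoch_start_ms": None,
        "epoch_len_ms": 250.0,
        "soft_norm_constant_hz": 5.0,
        "n_pcs": 6,
        "pre_window_bins": 5,
        "channel_mask": None,
    },
    "shuffle": {
        "kinds": ["invert_half", "invert_all", "reassign"],
        "n_shuffles": 300,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid with a YAML file and then explicit overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        if not isinstance(user, dict):
            raise ValueError("config file must contain a mapping")
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    sim, pre, shuf = cfg["simulate"], cfg["preprocess"], cfg["shuffle"]
    positive = {
        "simulate.dt_ms": sim["dt_ms"],
        "simulate.duration_ms": sim["duration_ms"],
        "simulate.trials_per_condition": sim["trials_per_condition"],
        "preprocess.kernel_sd_ms": pre["kernel_sd_ms"],
        "preprocess.epoch_len_ms": pre["epoch_len_ms"],
        "preprocess.n_pcs": pre["n_pcs"],
        "shuffle.n_shuffles": shuf["n_shuffles"],
    }
    for name, value in positive.items():
        if value is None or value <= 0:
            raise ValueError(f"{name} must be positive (got {value})")
    if sim["n_dims"] < 2:
        raise ValueError("simulate.n_dims must be >= 2")
    if 2 * len(sim["plane_frequencies_hz"]) + len(sim["expansion_rates"]) != sim["n_dims"]:
        raise ValueError(
            "simulate: 2 * n_planes + n_expansion_dims must equal n_dims"
        )
    if pre["n_pcs"] % 2 == 1:
        warnings.warn("odd n_pcs leaves one unpaired (zero) eigenvalue")
    for kind in shuf["kinds"]:
        if kind not in ("invert_half", "invert_all", "reassign"):
            raise ValueError(f"unknown shuffle kind {kind!r}")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
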