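"""Structured configuration: every named model/controller/noise/experiment
constant in one mapping, loadable from YAML."""

from __future__ import annotations

import copy

import numpy as np
import yaml

from .noise import NoiseSpec
from .walker import WalkerParams

DEFAULT_CONFIG: dict = {
    "walker": {
        "leg_mass_fraction": 0.16,
        "pelvis_mass_fraction": 0.68,
        "leg_com_distance": 0.645,
        "leg_gyration_radius": 0.326,
        "foot_radius": 0.3,
        "leg_length": 1.0,
        "gravity": 1.0,
        "total_mass": 1.0,
        "scuff_threshold_fraction": 0.10,
    },
    "control": {
        "target_speed": 0.4,
    },
    "noise": {
        "process_sd": [0.015, 0.16],
        "sensor_sd": [0.1, 0.1],
        "sample_freq": 16.0,
        "truncation_sd": 3.0,
    },
    "experiments": {
        "rho_exponent_range": [-4.0, 0.8],
        "rho_grid_points": 13,
        "trials": 20,
        "steps": 100,
        "noise_conditions": {"low": 0.36, "medium": 1.15, "high": 2.06},
        "noise_sweep_sensor_mult": 1.15,
        "impulse_amplitude": 5.0,
        "impulse_phase": 0.15,
        "impulse_width": 0.0625,
        "fictive_gain_reduction": 0.5,
        "integrator_step": 2.0e-3,
        "nominal_integrator_step": 1.0e-3,
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path=None) -> dict:
    """Default configuration, optionally overridden (recursively) by a YAML
    file containing a subset of the keys."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}

    def merge(base, over, crumb=""):
        for k, v in over.items():
            if k not in base:
                raise KeyError(f"unknown config key: {crumb}{k}")
            if isinstance(v, dict):
                merge(base[k], v, crumb + k + ".")
            else:
                base[k] = v
    merge(cfg, user)
    return cfg


def walker_from_config(cfg: dict) -> WalkerParams:
    return WalkerParams(**cfg["walker"])


def noise_from_config(cfg: dict) -> NoiseSpec:
    n = cfg["noise"]
    return NoiseSpec(process_sd=tuple(n["process_sd"]),
                     sensor_sd=tuple(n["sensor_sd"]),
                     sample_freq=n["sample_freq"],
                     truncation_sd=n["truncation_sd"])


def rho_grid_from_config(cfg: dict) -> np.ndarray:
    lo, hi = cfg["experiments"]["rho_exponent_range"]
    return np.logspace(lo, hi, int(cfg["experiments"]["rho_grid_points"]))
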