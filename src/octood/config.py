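"""Run configuration: YAML with strict keys over study-condition defaults.

The default configuration embodies every fixed pipeline parameter
(corruption severities, resize target, K, learning rate, p-grid,
micrometers per pixel, dataset sizes); a YAML file overrides any subset
and unknown keys are rejected so typos cannot silently change a run.
"""

from __future__ import annotations

import copy
import hashlib
import json
import os

import yaml

__all__ = ["ConfigError", "default_config", "load_config", "config_hash"]


class ConfigError(ValueError):
    """Configuration file violates the schema."""


def default_config() -> dict:
    return {
        "data": {
            "P": 674,
            "T": 10,
            "n_train": 334,
            "n_test": 2000,
            "microns_per_pixel": 3.7,
            "phantom": {
                "vitreous_level": 20.0,
                "retina_level": 90.0,
                "rpe_level": 190.0,
                "ilm_mean_depth": 300.0,
                "ilm_jitter": 40.0,
                "drift_sigma": 2.0,
                "speckle_strength": 0.35,
                "rpe_offset": 120,
                "rpe_width": 14,
            },
        },
        "corruptions": {
            "noise_sigma": 50.0,
            "smoothing_sigma": 5.0,
            "contrast_factors": [0.1, 0.2, 0.3, 2.0, 3.0, 4.0],
            "intensity_range": [25.0, 50.0],
            "stripe_intensity_range": [100.0, 200.0],
            "rectangle_width_range": [6, 10],
            "rectangle_depth_range": [15, 30],
            "rectangle_intensity_range": [100.0, 200.0],
            "shift_range": [25.0, 100.0],
            "zoom_range": [1.5, 1.75],
        },
        "features": {
            "resize_height": 64,
            "resize_width": 224,
            "extractor": "random-pyramid",
            "extractor_seed": 0,
            "K": 9,
        },
        "mahaad": {"shrinkage": "ledoit-wolf", "eps": 1.0e-3, "tau": None},
        "retina": {
            "base_channels": 16,
            "sigma_gt": 3.0,
            "lr": 1.0e-4,
            "batch_size": 64,
            "max_epochs": 60,
            "patience": 10,
        },
        "baselines": {
            "supervised_hidden": 64,
            "supervised_max_iter": 500,
            "rawmaha_use_resized": False,
        },
        "evaluation": {
            "p_grid": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
            "per_corruption_p": 0.5,
        },
    }


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{here} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | os.PathLike | None = None) -> dict:
    """Load and validate a YAML config; missing file sections use defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        override = yaml.safe_load(fh)
    if override is None:
        return cfg
    if not isinstance(override, dict):
        raise ConfigError("top-level configuration must be a mapping")
    return _merge(cfg, override)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration for provenance logging."""
    blob = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
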