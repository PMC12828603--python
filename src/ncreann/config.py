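"""Run configuration: defaults for every stage, YAML loading with
unknown-key rejection, and a provenance hash."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["RunConfig", "DEFAULT_CONFIG", "load_config"]

#: Fully resolved default stage parameters.  The synthetic-data defaults
#: define the study conditions the pipeline is exercised under.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "results",
    "simulate": {
        "n_subjects": 10,
        "n_channels": 4,
        "order": 2,
        "n_trials": 1,
        "samples_per_trial": 1200,
        "sampling_rate": 256.0,
        "coupling": 0.35,          # planted cross-coupling strength
        "self_coupling": 0.45,
        "nonlinear_gain": 0.5,     # planted quadratic coupling gain
        "effect_scale": 0.5,       # active-condition scaling of the target coupling
        "flicker": {
            "n_subjects": 10, "n_trials": 20, "n_channels": 8,
            "flicker_freq": 4.5, "control_freq": 8.0, "amplitude": 0.6,
            "responsive_channels": [0, 1, 2],
        },
        "voxel_map": {"grid_spacing": 5.0},
    },
    "tagging": {
        "n_cycles": 5.0,
        "baseline": [-350.0, -150.0],
        "alpha": 0.05,
    },
    "roi": {
        "fraction": 0.03,
        "min_samples": 3,
        "temporal_split_y": -21.0,
    },
    "connectivity": {
        "order": None,             # None -> SBC selection over candidates
        "order_candidates": [1, 2, 3, 4, 5],
        "hidden": 6,
        "activation": "tanh",
        "learning_rate": 0.01,
        "momentum": 0.9,
        "max_epochs": 150,
        "patience": 15,
        "folds": 5,
        "phases": ["action_planning", "perception"],
        "conditions": ["sham", "active"],
    },
    "surrogate": {
        "n_surrogates": 100,
        "percentile": 95.0,
        "min_fraction_significant": 0.5,
    },
    "stats": {
        "alpha": 0.05,
    },
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise KeyError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = value
    return out


class RunConfig:
    """Resolved run configuration with stable provenance hash."""

    def __init__(self, overrides: dict | None = None) -> None:
        self._cfg = _merge(DEFAULT_CONFIG, overrides or {})

    def __getitem__(self, key: str):
        return self._cfg[key]

    @property
    def seed(self) -> int:
        return int(self._cfg["seed"])

    @seed.setter
    def seed(self, value: int) -> None:
        self._cfg["seed"] = int(value)

    @property
    def out_dir(self) -> Path:
        return Path(self._cfg["out_dir"])

    @out_dir.setter
    def out_dir(self, value) -> None:
        self._cfg["out_dir"] = str(value)

    def resolved(self) -> dict:
        return copy.deepcopy(self._cfg)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self._cfg, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def dump(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {"config_hash": self.config_hash, **self.resolved()}
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config over the defaults; unknown keys are rejected."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.pop("config_hash", None)  # provenance echo from a dumped config
    return RunConfig(raw)
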