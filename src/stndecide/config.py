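"""Study configuration: one YAML-serializable mapping drives the
end-to-end pipelines (simulate -> analyze -> report).

Unknown keys are rejected so that typos fail loudly; every default is
documented in :data:`DEFAULT_CONFIG`.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config", "config_hash"]

#: Full default configuration, with the study conditions of the
#: synthetic generators and the analysis settings of each stage.
DEFAULT_CONFIG = {
    "seed": 0,
    "behavior_study": {
        "n_sessions": 6,
        "n_per_cond": 60,  # trials per signed-coherence x stimulation cell
        "coherences": [0.032, 0.064, 0.128, 0.256, 0.512],
        "params": {  # base decision-model parameters
            "a": 1.1,
            "b_collapse": 1.5,
            "b_t": 0.35,
            "k": 6.0,
            "me": 0.0,
            "z": 0.0,
            "t0_contra": 0.32,
            "t0_ipsi": 0.30,
        },
        "effect": {  # additive deltas applied on stimulated trials
            "d_a": 0.0,
            "d_b_collapse": 0.0,
            "d_b_t": 0.0,
            "d_k": 0.0,
            "d_me": 0.0,
            "d_z": 0.0,
            "d_t0_contra": 0.0,
            "d_t0_ipsi": 0.0,
        },
        "psychometric_variants": ["NoLapse", "SymmetricLapse", "AsymmetricLapse"],
        "n_shuffles": 200,
        "run_ddm_compare": True,
    },
    "recording_study": {
        "n_per_cluster": 50,
        "trials_per_cond": 15,
        "separation": 1.0,
        "window_ms": 300,
        "step_ms": 100,
        "clustering": {
            "k": 4,
            "distance": "correlation",
            "representation": "raw30",
            "n_runs": 50,
            "n_reps": 100,
            "run_stability_grid": False,
        },
    },
}


def merge_config(overrides: dict | None, base: dict | None = None) -> dict:
    """Deep-merge ``overrides`` into the defaults, rejecting unknown keys."""
    base = copy.deepcopy(DEFAULT_CONFIG if base is None else base)
    if overrides is None:
        return base

    def _merge(dst, src, path):
        for key, val in src.items():
            if key not in dst:
                raise KeyError(f"unknown config key: {'.'.join(path + [key])}")
            if isinstance(dst[key], dict) and isinstance(val, dict):
                _merge(dst[key], val, path + [key])
            else:
                dst[key] = val

    _merge(base, overrides, [])
    return base


def load_config(path) -> dict:
    """Load a YAML config file and merge it over the defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return merge_config(data)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration, for report provenance."""
    blob = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
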