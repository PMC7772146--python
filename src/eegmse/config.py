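"""Structured configuration with YAML overrides.

``default_config()`` returns the full default tree; ``load_config``
deep-merges a YAML file over it.  Keys mirror the estimator parameters
(``filter.*``, ``entropy.*``, ``cnn.*``, ``hmm.*``, ``cv.*``).
"""

from __future__ import annotations

import copy

import yaml

__all__ = ["default_config", "load_config"]

_DEFAULTS = {
    "filter": {
        "order": 5,
        "bands": {
            "theta": [4.0, 7.0],
            "alpha": [8.0, 13.0],
            "beta": [14.0, 30.0],
            "gamma": [31.0, 45.0],
        },
        "zero_phase": True,
    },
    "entropy": {
        "m": 2,
        "r_factor": 0.2,
        "tau": 2,
        "coarse_grain_mode": "moving_average",
    },
    "cnn": {
        "conv_channels": [64, 128, 256, 64],
        "kernel_sizes": [[4, 4], [4, 4], [4, 4], [2, 2]],
        "fc_sizes": [1024, 512],
        "dropout": 0.5,
        "l2": 1e-4,
        "learning_rate": 0.01,
        "lr_decay": 10.0,
        "plateau_patience": 3,
        "batch_size": 128,
        "epochs": 50,
        "validation_fraction": 0.1,
    },
    "hmm": {
        "n_states": 3,
        "n_mix": 1,
        "max_iter": 1000,
        "tol": 0.01,
    },
    "cv": {
        "n_folds": 10,
        "unit": "trial",
    },
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _merge(base: dict, override: dict) -> dict:
    for key, value in override.items():
        if (
            key in base
            and isinstance(base[key], dict)
            and isinstance(value, dict)
        ):
            _merge(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path=None) -> dict:
    """Defaults, optionally deep-merged with a YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        _merge(cfg, override)
    return cfg


def tensorizer_kwargs(cfg: dict) -> dict:
    """EntropyTensorizer kwargs drawn from a config tree."""
    f, e = cfg["filter"], cfg["entropy"]
    return {
        "bands": {k: tuple(v) for k, v in f["bands"].items()},
        "filter_order": f["order"],
        "zero_phase": f["zero_phase"],
        "m": e["m"],
        "r_factor": e["r_factor"],
        "tau": e["tau"],
        "coarse_grain_mode": e["coarse_grain_mode"],
    }


def cnn_kwargs(cfg: dict) -> dict:
    c = cfg["cnn"]
    return {
        "conv_channels": tuple(c["conv_channels"]),
        "kernel_sizes": tuple(tuple(k) for k in c["kernel_sizes"]),
        "fc_sizes": tuple(c["fc_sizes"]),
        "dropout": c["dropout"],
        "l2": c["l2"],
        "learning_rate": c["learning_rate"],
        "lr_decay": c["lr_decay"],
        "plateau_patience": c["plateau_patience"],
        "batch_size": c["batch_size"],
        "epochs": c["epochs"],
        "validation_fraction": c["validation_fraction"],
    }


def hmm_kwargs(cfg: dict) -> dict:
    h = cfg["hmm"]
    return {
        "n_states": h["n_states"],
        "n_mix": h["n_mix"],
        "max_iter": h["max_iter"],
        "tol": h["tol"],
    }
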