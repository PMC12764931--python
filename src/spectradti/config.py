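"""YAML configuration: defaults, deep-merge loading, and content hashing.

Sections mirror the pipeline stages: data, spse, encoder, aggregator, train,
calibrate, synergy, eval.  Every CLI artifact embeds the hash of the resolved
configuration plus the seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .experiments import ExperimentConfig

DEFAULTS: dict = {
    "data": {
        "n_drugs": 300, "n_proteins": 40, "n_pathways": 12, "n_families": 5,
        "positive_rate": 0.2, "motif_snippet_rate": 0.3,
        "neg_ratio": 2.0, "max_pairs": 900, "split_mode": "unseen_protein", "k_folds": 5,
    },
    "spse": {"d_eig": 32, "t": 1.0, "operator_kind": "normalized_adjacency", "omega_mode": "uniform"},
    "encoder": {"d": 64, "use_subpocket_mask": True, "use_eig_bias": True,
                "fusion": "cross_attention", "k_local": 6},
    "aggregator": {"layers": 3, "heads": 4, "edge_drop": 0.1, "fan_out": 10,
                   "use_distance_features": True},
    "train": {"base_lr": 3e-3, "batch_size": 64, "max_epochs": 30, "steps_per_epoch": 8,
              "patience": 10, "beta": 0.5, "gamma": 0.3, "eta": 1e-3, "temperature": 0.07},
    "calibrate": {"grid": [0.0, 0.01, 0.05, 0.1, 0.2], "bins": 15},
    "synergy": {"w1": 0.4, "w2": 0.4, "w3": 0.2, "s_multi_rule": "min", "top_m": 5},
    "eval": {"threshold": 0.5},
}


def _merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in (over or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    cfg = DEFAULTS
    if path is not None:
        with open(path) as fh:
            cfg = _merge(DEFAULTS, yaml.safe_load(fh) or {})
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.md5(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def to_experiment_config(cfg: dict) -> ExperimentConfig:
    d, t, a = cfg["data"], cfg["train"], cfg["aggregator"]
    return ExperimentConfig(
        n_drugs=d["n_drugs"], n_proteins=d["n_proteins"], n_pathways=d["n_pathways"],
        n_families=d["n_families"], d=cfg["encoder"]["d"], layers=a["layers"],
        d_eig=cfg["spse"]["d_eig"], epochs=t["max_epochs"], batch_size=t["batch_size"],
        steps_per_epoch=t["steps_per_epoch"], neg_ratio=d["neg_ratio"],
        max_pairs=d["max_pairs"], k_folds=d["k_folds"], base_lr=t["base_lr"],
        split_mode=d["split_mode"],
    )
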