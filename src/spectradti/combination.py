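"""Checkpoint reconstruction for inference-time subcommands."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .experiments import ExperimentConfig, fit_fold, prepare_from_files

__all__ = ["rebuild_fit"]


def rebuild_fit(data_dir, model_dir, exp: ExperimentConfig, meta: dict):
    """Rebuild the trained model from a dataset directory and a checkpoint.

    The split, masked graph and spectral machinery are reconstructed
    deterministically from the stored seed/fold; the saved weights then
    replace the fresh initialization (no retraining: max_epochs is forced
    to zero-epoch equivalent by loading the checkpoint afterwards)."""
    from dataclasses import replace

    seed, fold, variant = meta["seed"], meta["fold"], meta.get("variant", "full")
    graph, pairs, tasks, truth, top = prepare_from_files(data_dir, exp, seed)
    quick = replace(exp, epochs=1, steps_per_epoch=1)
    fit = fit_fold(graph, pairs, tasks, quick, seed, variant=variant, fold=fold)
    weights = np.load(Path(model_dir) / "weights.npz")
    fit.model.load_state_dict({k: weights[k] for k in weights.files})
    return fit, pairs, tasks, top
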