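"""Self-describing artifact containers: datasets, models, run configs.

Every artifact is a numpy ``.npz`` archive next to a JSON sidecar
carrying labels/provenance (generator config, seed, schema version), so
any reported number is recomputable from the file alone.  Round-trips
are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple, Union

import numpy as np
import yaml

from .classifier import CNNClassifier
from .preprocess import Epoch
from .sim import SignalModelConfig, TrialSet

__all__ = ["save_dataset", "load_dataset", "save_model", "load_model",
           "load_run_config", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

PathLike = Union[str, Path]


def _check_schema(meta: dict, path: Path) -> None:
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"{path}: schema_version {version!r} not supported "
            f"(expected {SCHEMA_VERSION})"
        )


def save_dataset(trials: TrialSet, prefix: PathLike) -> Tuple[Path, Path]:
    """Write ``<prefix>.npz`` (trials × samples) and ``<prefix>.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    npz = prefix.with_suffix(".npz")
    sidecar = prefix.with_suffix(".json")
    np.savez(npz, X=trials.X)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "kind": "dataset",
        "labels": list(trials.labels),
        "subject_ids": list(trials.subject_ids),
        "label_space": list(trials.label_space),
        "channel": trials.channel,
        "config": trials.config.to_dict(),
        "seed": trials.seed,
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return npz, sidecar


def load_dataset(prefix: PathLike) -> TrialSet:
    """Inverse of :func:`save_dataset`; validates the schema version."""
    prefix = Path(prefix)
    npz = prefix.with_suffix(".npz")
    sidecar = prefix.with_suffix(".json")
    for p in (npz, sidecar):
        if not p.exists():
            raise FileNotFoundError(f"dataset file missing: {p}")
    meta = json.loads(sidecar.read_text())
    _check_schema(meta, sidecar)
    if meta.get("kind") != "dataset":
        raise ValueError(f"{sidecar}: not a dataset artifact ({meta.get('kind')!r})")
    with np.load(npz) as arch:
        X = arch["X"]
    if X.shape[0] != len(meta["labels"]):
        raise ValueError(
            f"{npz}: truncated or inconsistent archive — {X.shape[0]} trial "
            f"rows but {len(meta['labels'])} labels"
        )
    config = SignalModelConfig.from_dict(meta["config"])
    epochs = [
        Epoch(row, config.fs, label=lab, meta={"subject": sid})
        for row, lab, sid in zip(X, meta["labels"], meta["subject_ids"])
    ]
    return TrialSet(epochs, list(meta["labels"]), list(meta["subject_ids"]),
                    tuple(meta["label_space"]), config, meta["seed"],
                    meta.get("channel", "BIPOLAR"))


def save_model(model: CNNClassifier, prefix: PathLike) -> Tuple[Path, Path]:
    """Checkpoint a fitted classifier: parameter arrays + JSON manifest."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    npz = prefix.with_suffix(".npz")
    sidecar = prefix.with_suffix(".json")
    arrays = {k: getattr(model, k + "_") for k in model._PARAM_KEYS}
    np.savez(npz, **arrays)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "kind": "model",
        "hyperparameters": model.get_params(),
        "classes": [str(c) for c in model.classes_],
        "input_shape": list(model.input_shape_),
        "loss_history": list(model.loss_history_),
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return npz, sidecar


def load_model(prefix: PathLike) -> CNNClassifier:
    prefix = Path(prefix)
    npz = prefix.with_suffix(".npz")
    sidecar = prefix.with_suffix(".json")
    for p in (npz, sidecar):
        if not p.exists():
            raise FileNotFoundError(f"model file missing: {p}")
    meta = json.loads(sidecar.read_text())
    _check_schema(meta, sidecar)
    if meta.get("kind") != "model":
        raise ValueError(f"{sidecar}: not a model artifact ({meta.get('kind')!r})")
    model = CNNClassifier(**meta["hyperparameters"])
    with np.load(npz) as arch:
        for k in model._PARAM_KEYS:
            setattr(model, k + "_", arch[k])
    model.classes_ = np.asarray(meta["classes"])
    model.input_shape_ = tuple(meta["input_shape"])
    model.n_classes_ = len(meta["classes"])
    model.loss_history_ = list(meta["loss_history"])
    return model


_KNOWN_SECTIONS = {"sim", "filter", "stft", "cnn", "menu", "seed",
                   "schema_version"}


def load_run_config(path: PathLike) -> dict:
    """Load a YAML run configuration, rejecting unknown top-level keys."""
    path = Path(path)
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    unknown = set(data) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(
            f"{path}: unknown config keys {sorted(unknown)}; "
            f"known: {sorted(_KNOWN_SECTIONS)}"
        )
    return data
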