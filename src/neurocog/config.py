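"""Configuration loading, deterministic fixtures, and result reporting."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .accumulators import AccumulatorParams
from .assembly import ModelConfig
from .design import generate_study_list, generate_test_blocks
from .forward import HrfParams, RoiMap, default_roi_map
from .memory import MemoryScaleConfig
from .spa import Vocabulary

__all__ = ["RunConfig", "load_config", "config_hash", "make_fixtures",
           "report", "EmptyTrialSet"]


@dataclass
class RunConfig:
    """Top-level run description: model scale, seeds, design, ROI map."""

    model: ModelConfig = field(default_factory=ModelConfig)
    hrf: HrfParams = field(default_factory=HrfParams)
    roi_map: RoiMap = field(default_factory=default_roi_map)
    design_seed: int = 0
    network_seed: int = 0
    training_seed: int = 0
    n_trials: Optional[int] = None   # cap per participant (None = full)


_NESTED = {
    "model": ModelConfig,
    "memory": MemoryScaleConfig,
    "fam_acc": AccumulatorParams,
    "retr_acc": AccumulatorParams,
    "cmp_acc": AccumulatorParams,
    "hrf": HrfParams,
}


def _build_dataclass(cls, payload: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in payload.items():
        if key not in fields:
            raise ValueError(f"unknown config key {path}{key!r}")
        if key in _NESTED and isinstance(val, dict):
            kwargs[key] = _build_dataclass(_NESTED[key], val,
                                           f"{path}{key}.")
        elif key == "roi_map" and isinstance(val, dict):
            kwargs[key] = RoiMap(val)
        elif isinstance(val, list) and ("range" in key
                                        or "intercepts" in key):
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run config; unknown keys rejected.

    The ``scale: full`` preset inside the model section expands to the
    full-fidelity sizes before field overrides are applied.
    """
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    if not isinstance(payload, dict):
        raise ValueError("config root must be a mapping")
    model_section = payload.get("model", {})
    if isinstance(model_section, dict) and \
            model_section.get("scale") == "full":
        base = dataclasses.asdict(ModelConfig.full())
        base.update(model_section)
        payload = dict(payload, model=base)
    cfg = _build_dataclass(RunConfig, payload, "")
    cfg.model.validate()
    return cfg


def config_hash(cfg: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, RoiMap):
            return o.rois
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))
    blob = json.dumps(dataclasses.asdict(cfg), default=default,
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def make_fixtures(seed: int) -> dict:
    """Small deterministic objects for tests: a 16-D vocabulary, an 8-pair
    mini study list, a 20-neuron ensemble spec and a synthetic raster."""
    rng = np.random.default_rng(seed)
    vocab = Vocabulary(16, rng_seed=seed)
    vocab.make_pointer("ITEM1")
    vocab.make_pointer("ITEM2")
    study = generate_study_list(seed)
    mini_pairs = [p for p in study.pairs if p.fan == 1][:4] + \
                 [p for p in study.pairs if p.fan == 2][:4]
    raster = (rng.random((200, 20)) < 0.02).astype(float)
    from .core import Network
    net = Network(seed=seed)
    ens = net.ensemble("fixture", 20, 1)
    return {"vocab": vocab, "study_list": study, "mini_pairs": mini_pairs,
            "raster": raster, "network": net, "ensemble": ens}


class EmptyTrialSet(ValueError):
    """Raised by report() for an empty trial table (distinct exit path)."""


REQUIRED_COLUMNS = {"probe", "fan", "hand", "response", "rt_ms", "correct"}


def report(trials: pd.DataFrame):
    """Condition summaries from a trials table.

    Returns (rt_table, error_table): mean RT (correct, responded trials
    only) and error rate (timeouts count as errors) per probe x fan x hand,
    with SEM and trial counts.  Raises EmptyTrialSet for an empty table and
    ValueError for missing columns.
    """
    missing = REQUIRED_COLUMNS - set(trials.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(trials) == 0:
        raise EmptyTrialSet("no trials to report")
    t = trials.copy()
    t["error"] = ~t["correct"].astype(bool)
    t.loc[t["response"] == "none", "error"] = True
    keys = ["probe", "fan", "hand"]
    ok = t[(t["response"] != "none") & t["correct"].astype(bool)]
    rt = ok.groupby(keys)["rt_ms"].agg(
        mean_rt="mean", sem_rt=lambda x: x.std(ddof=1) / np.sqrt(len(x))
        if len(x) > 1 else 0.0, n="count").reset_index()
    err = t.groupby(keys)["error"].agg(
        error_rate="mean", n="count").reset_index()
    return rt, err
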