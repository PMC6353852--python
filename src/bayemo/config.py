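"""Configuration loading: flat YAML key/value files with one section per
module, merged over the package defaults.  CLI flags override file values.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .errors import ConfigurationError
from .experiment import ConditionMapping, ErpConfig, ExperimentConfig, LikertConfig
from .valence import ValenceParams

__all__ = [
    "default_config",
    "load_config",
    "valence_params_from",
    "mapping_from",
    "experiment_config_from",
]

_SECTIONS = ("model", "valence", "mapping", "likert", "erp", "experiment")


def default_config() -> dict[str, dict[str, Any]]:
    """The full default configuration as a plain nested dict."""
    return {
        "model": {
            "prior_mean": 0.0,
            "prior_variance": 1.0,
            "obs_mean": 0.0,
            "obs_variance": 0.1,
            "n": 1,
        },
        "valence": dataclasses.asdict(ValenceParams()),
        "mapping": dataclasses.asdict(ConditionMapping()),
        "likert": _plain(dataclasses.asdict(LikertConfig())),
        "erp": _plain(dataclasses.asdict(ErpConfig())),
        "experiment": {"n_subjects": 9, "n_sets": 20, "isi_min_ms": 1000.0, "isi_max_ms": 2000.0},
    }


def _plain(d: dict) -> dict:
    # tuples -> lists so the dict round-trips through YAML unchanged
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def load_config(path: Optional[str | Path] = None) -> dict[str, dict[str, Any]]:
    """Defaults, overlaid with the sections found in ``path`` (if given).

    Unknown sections or keys are rejected rather than ignored, so typos fail
    loudly.
    """
    cfg = default_config()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return cfg
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    for section, values in raw.items():
        if section not in _SECTIONS:
            raise ConfigurationError(
                f"unknown config section {section!r}; expected one of {_SECTIONS}"
            )
        if values is None:
            continue
        if not isinstance(values, Mapping):
            raise ConfigurationError(f"section {section!r} must be a mapping")
        for key, value in values.items():
            if key not in cfg[section]:
                raise ConfigurationError(
                    f"unknown key {key!r} in section {section!r}"
                )
            cfg[section][key] = value
    return cfg


def valence_params_from(cfg: Mapping[str, Any]) -> ValenceParams:
    return ValenceParams(**cfg["valence"])


def mapping_from(cfg: Mapping[str, Any]) -> ConditionMapping:
    return ConditionMapping(**cfg["mapping"])


def experiment_config_from(cfg: Mapping[str, Any]) -> ExperimentConfig:
    likert = {k: (tuple(v) if isinstance(v, list) else v) for k, v in cfg["likert"].items()}
    erp = {k: (tuple(v) if isinstance(v, list) else v) for k, v in cfg["erp"].items()}
    exp = cfg["experiment"]
    return ExperimentConfig(
        n_subjects=int(exp["n_subjects"]),
        n_sets=int(exp["n_sets"]),
        isi_range_ms=(float(exp["isi_min_ms"]), float(exp["isi_max_ms"])),
        mapping=mapping_from(cfg),
        likert=LikertConfig(**likert),
        erp=ErpConfig(**erp),
    )
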