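"""YAML/JSON (de)serialisation of scenario configurations."""

from __future__ import annotations

import dataclasses
import json
import pathlib

import yaml

from .datagen import ScenarioConfig, SurvivalSpec, WeightScheme

__all__ = ["scenario_to_dict", "scenario_from_dict", "load_scenario", "save_scenario"]


def scenario_to_dict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    d["omitted_features"] = list(config.omitted_features)
    d["models"] = list(config.models)
    d["weights"]["base_weights"] = dict(config.weights.base_weights)
    d["weights"]["male_cogstat"] = list(config.weights.male_cogstat)
    return d


def scenario_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    if "survival" in d and isinstance(d["survival"], dict):
        d["survival"] = SurvivalSpec(**d["survival"])
    if "weights" in d and isinstance(d["weights"], dict):
        w = dict(d["weights"])
        if "male_cogstat" in w:
            w["male_cogstat"] = tuple(w["male_cogstat"])
        d["weights"] = WeightScheme(**w)
    if "omitted_features" in d:
        d["omitted_features"] = tuple(d["omitted_features"])
    if "models" in d:
        d["models"] = tuple(d["models"])
    return ScenarioConfig(**d)


def load_scenario(path) -> ScenarioConfig:
    path = pathlib.Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return scenario_from_dict(data)


def save_scenario(config: ScenarioConfig, path) -> None:
    path = pathlib.Path(path)
    data = scenario_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
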