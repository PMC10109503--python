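"""Scenario configuration files and result export.

Scenario configurations round-trip through plain YAML mappings with
sections mirroring the dataclasses (``neuron``, ``cleft``, ``protocol``
plus top-level scenario keys).  Only keys that differ from the shipped
defaults need to be present.
"""

from __future__ import annotations

import json
from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .cleft import CleftParams
from .engine import ScenarioConfig, StimProtocol, SimulationResult
from .neuron import NeuronParams

__all__ = ["scenario_to_dict", "scenario_from_dict",
           "load_scenario", "save_scenario", "write_result"]

_SECTIONS = {"neuron": NeuronParams, "cleft": CleftParams,
             "protocol": StimProtocol}


def scenario_to_dict(config: ScenarioConfig) -> dict:
    d = asdict(config)
    return d


def scenario_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in d:
            sub = d.pop(name)
            valid = {f.name for f in fields(cls)}
            unknown = set(sub) - valid
            if unknown:
                raise ValueError(f"{name}: unknown keys {sorted(unknown)}")
            kwargs[name] = cls(**sub)
    valid = {f.name for f in fields(ScenarioConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown scenario keys {sorted(unknown)}")
    kwargs.update(d)
    return ScenarioConfig(**kwargs)


def load_scenario(path) -> ScenarioConfig:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def save_scenario(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(config), fh, sort_keys=False)


def write_result(result: SimulationResult, outdir, stem: str = "run") -> dict:
    """Write spike table, windup curve, traces and a manifest; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    table = result.spike_table()
    from .metrics import classify_spikes
    labeled = classify_spikes(table)
    paths["spikes"] = outdir / f"{stem}_spikes.csv"
    labeled.to_csv(paths["spikes"], index=False)
    curve = result.windup()
    import pandas as pd
    paths["windup"] = outdir / f"{stem}_windup.csv"
    pd.DataFrame({"stim_index": range(1, curve.n_stims + 1),
                  "n_spikes": curve.counts}).to_csv(paths["windup"], index=False)
    paths["trace"] = outdir / f"{stem}_trace.csv"
    result.trace.to_csv(paths["trace"], index=False)
    manifest = result.manifest()
    manifest["windup_auc"] = curve.auc
    manifest["windup_total"] = curve.total
    paths["manifest"] = outdir / f"{stem}_manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return {k: str(v) for k, v in paths.items()}
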