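"""Experiment configuration, presets, and manifest round-tripping.

A configuration is one flat key-value mapping (YAML on disk).  Unknown keys
are rejected so typos cannot silently change an experiment.  The presets
bundle the parameter sets of the reference experiments: a Donation Game
with Gaussian traits under imitation, equal-split Snowdrift Games under
death-birth at three selection intensities, and the fair-split (spatially
non-additive) Snowdrift Game under pairwise comparison.  At full scale the
parameters equal the published captions (N=500, k=3, 10^5 samples per bin);
the desk-scale default reduces to N=100 and 10^3 samples per bin.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import yaml

from . import __version__
from .engine import UpdateRule
from .games import (
    EcologicalField,
    donation_field,
    snowdrift_field,
)
from .networks import (
    ConstantTraits,
    GaussianTraits,
    InvalidParameterError,
    RegularGraph,
    TwoValuedCosts,
    VertexTraits,
    assign_traits,
    random_regular_graph,
)

__all__ = ["SimulationConfig", "ExperimentPreset", "PRESETS", "build_experiment"]

_FIELDS: dict[str, type] = {
    "game": str,            # donation | snowdrift-fair | snowdrift-half
    "rule": str,
    "beta": float,
    "n_vertices": int,
    "degree": int,
    "seed": int,
    "trait_scheme": str,    # gaussian | two-valued | constant | file
    "mean_b": float, "var_b": float, "mean_c": float, "var_c": float,
    "b": float, "c": float,
    "c1": float, "c2": float, "q": float,
    "min_samples_per_bin": int,
    "cycle_budget": int,
    "max_updates_per_cycle": int,
    "edgelist_file": str,
    "traits_file": str,
    "bd_constant": float,
}

_DEFAULTS: dict[str, Any] = {
    "degree": 3,
    "seed": 0,
    "min_samples_per_bin": 1000,
    "cycle_budget": 1_000_000,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Validated flat experiment configuration."""

    values: dict

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        unknown = set(raw) - set(_FIELDS)
        if unknown:
            raise InvalidParameterError(
                f"unknown configuration key(s): {', '.join(sorted(unknown))}"
            )
        vals = dict(_DEFAULTS)
        for key, value in raw.items():
            try:
                vals[key] = _FIELDS[key](value)
            except (TypeError, ValueError):
                raise InvalidParameterError(f"configuration key {key!r}: bad value {value!r}")
        for required in ("game", "rule", "beta"):
            if required not in vals:
                raise InvalidParameterError(f"missing configuration key {required!r}")
        if "edgelist_file" not in vals and "n_vertices" not in vals:
            raise InvalidParameterError("either n_vertices or edgelist_file is required")
        if vals.get("beta", 0.0) < 0:
            raise InvalidParameterError("beta must be non-negative")
        UpdateRule(vals["rule"])  # validates rule name
        if vals["game"] not in ("donation", "snowdrift-fair", "snowdrift-half"):
            raise InvalidParameterError(f"unknown game {vals['game']!r}")
        return cls(vals)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise InvalidParameterError("configuration must be a flat key-value document")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dict(self.values)

    def write_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def get(self, key: str, default=None):
        return self.values.get(key, default)

    def __getitem__(self, key: str):
        try:
            return self.values[key]
        except KeyError:
            raise InvalidParameterError(f"missing configuration key {key!r}")

    def replace(self, **overrides) -> "SimulationConfig":
        merged = {**self.values, **overrides}
        return SimulationConfig.from_dict(merged)

    def manifest(self, command: str) -> dict:
        return {
            "command": command,
            "config": self.to_dict(),
            "asymgames_version": __version__,
            "numpy_version": np.__version__,
        }

    def write_manifest(self, path: Union[str, Path], command: str) -> None:
        Path(path).write_text(json.dumps(self.manifest(command), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# presets


@dataclass(frozen=True)
class ExperimentPreset:
    """Named parameter bundle with a scale knob.

    At ``paper_scale`` the parameters equal the published captions exactly;
    the desk-scale default shrinks the network and the per-bin sample
    requirement so a profile completes in minutes.
    """

    name: str
    base: dict

    def config(self, paper_scale: bool = False, **overrides) -> SimulationConfig:
        vals = dict(self.base)
        if paper_scale:
            vals.update(n_vertices=500, min_samples_per_bin=100_000)
        else:
            vals.update(n_vertices=100, min_samples_per_bin=1_000)
        vals.update(overrides)
        return SimulationConfig.from_dict(vals)


_SNOWDRIFT_DB = {
    "game": "snowdrift-half",
    "rule": "death-birth",
    "degree": 3,
    "trait_scheme": "two-valued",
    "b": 5.0,
    "c1": 34.0 / 13.0,
    "c2": 70.0 / 13.0,
    "q": 0.5,
}

PRESETS: dict[str, ExperimentPreset] = {
    "fig1a": ExperimentPreset("fig1a", {
        "game": "donation",
        "rule": "imitation",
        "beta": 0.01,
        "degree": 3,
        "trait_scheme": "gaussian",
        "mean_b": 3.5, "var_b": 1.0, "mean_c": 0.5, "var_c": 0.25,
    }),
    "fig1b": ExperimentPreset("fig1b", {**_SNOWDRIFT_DB, "beta": 0.01}),
    "fig2": ExperimentPreset("fig2", {
        "game": "snowdrift-fair",
        "rule": "pairwise-comparison",
        "beta": 0.01,
        "degree": 3,
        "trait_scheme": "two-valued",
        "b": 4.0, "c1": 0.5, "c2": 5.5, "q": 0.5,
    }),
    "fig3a": ExperimentPreset("fig3a", {**_SNOWDRIFT_DB, "beta": 0.1}),
    "fig3b": ExperimentPreset("fig3b", {**_SNOWDRIFT_DB, "beta": 0.5}),
}


# ---------------------------------------------------------------------------
# experiment assembly


def _trait_scheme(config: SimulationConfig):
    name = config.get("trait_scheme")
    if name == "gaussian":
        return GaussianTraits(
            config["mean_b"], config["var_b"], config["mean_c"], config["var_c"]
        )
    if name == "two-valued":
        return TwoValuedCosts(config["c1"], config["c2"], config["q"], config["b"])
    if name == "constant":
        return ConstantTraits(config["b"], config["c"])
    raise InvalidParameterError(f"unknown trait scheme {name!r}")


def build_experiment(
    config: SimulationConfig,
) -> tuple[RegularGraph, VertexTraits, EcologicalField, UpdateRule]:
    """Construct graph, traits and payoff field from one configuration.

    One graph and one trait draw per experiment seed: sub-seeds for the
    graph and the traits are derived from ``seed`` with a seed sequence, so
    re-running the same configuration reproduces the experiment exactly.
    """
    seed = config["seed"]
    ss = np.random.SeedSequence(seed)
    graph_seed, trait_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    if config.get("edgelist_file"):
        graph = RegularGraph.read_edgelist(config["edgelist_file"])
    else:
        graph = random_regular_graph(config["n_vertices"], config["degree"], graph_seed)

    if config.get("traits_file"):
        traits = VertexTraits.read_tsv(config["traits_file"])
        if traits.n_vertices != graph.n_vertices:
            raise InvalidParameterError("trait table does not match the graph size")
    else:
        traits = assign_traits(graph, _trait_scheme(config), trait_seed)

    game = config["game"]
    if game == "donation":
        fld = donation_field(traits, graph)
    elif game == "snowdrift-fair":
        fld = snowdrift_field(traits, graph, "fair")
    else:
        fld = snowdrift_field(traits, graph, "half")
    return graph, traits, fld, UpdateRule(config["rule"])
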