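"""YAML run configurations and network serialization.

A run configuration names exactly one network source (a builder with its
parameters, or a serialized network file), an experiment description, the
engine settings and the output directory.  Unknown keys are rejected by
name; the seed is mandatory whenever component mismatch is enabled.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Dict, Mapping, Optional

import yaml

from .circuit import SCRDevice, SynapseSpec, UCNParams
from .network import Edge, Network, Port, build_network

__all__ = [
    "ConfigError",
    "SCHEMA_VERSION",
    "NetworkSource",
    "ExperimentConfig",
    "MismatchConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "network_to_dict",
    "network_from_dict",
    "save_network",
    "load_network",
]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Malformed or inconsistent run configuration."""


def _from_mapping(cls, data: Mapping[str, Any], where: str):
    """Build a dataclass from a mapping, rejecting unknown keys by name."""
    if not isinstance(data, Mapping):
        raise ConfigError(f"section {where!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown key {key!r} in section {where!r}")
    return cls(**data)


@dataclass(frozen=True)
class NetworkSource:
    """Either a builder (``jeffress`` / ``long_axon``) or a network file."""

    builder: Optional[str] = None
    file: Optional[str] = None
    n_side: int = 4
    n_segments: int = 7
    per_segment_delay_us: float = 20.0
    output_c_nf: float = 0.4

    def __post_init__(self) -> None:
        if (self.builder is None) == (self.file is None):
            raise ConfigError(
                "network source must set exactly one of 'builder' or 'file'"
            )
        if self.builder is not None and self.builder not in ("jeffress", "long_axon"):
            raise ConfigError(f"unknown builder {self.builder!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    kind: str = "sweep"  # axon | case | sweep | calibrate | tune
    itd_us: float = 0.0
    itd_min_us: float = -60.0
    itd_max_us: float = 60.0
    itd_step_us: float = 1.0
    target_delay_us: float = 22.22
    tuning_step: float = 0.02
    max_iterations: int = 200

    def __post_init__(self) -> None:
        if self.kind not in ("axon", "case", "sweep", "calibrate", "tune"):
            raise ConfigError(f"unknown experiment kind {self.kind!r}")


@dataclass(frozen=True)
class MismatchConfig:
    enabled: bool = False
    tolerance: float = 0.05


@dataclass(frozen=True)
class SimSettings:
    sample_interval_us: float = 0.5


@dataclass(frozen=True)
class RunConfig:
    network: NetworkSource = field(default_factory=lambda: NetworkSource(builder="jeffress"))
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    simulation: SimSettings = field(default_factory=SimSettings)
    mismatch: MismatchConfig = field(default_factory=MismatchConfig)
    output_dir: str = "out"
    seed: Optional[int] = None
    schema: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.mismatch.enabled and self.seed is None:
            raise ConfigError(
                "a seed is mandatory when component mismatch is enabled"
            )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" (line {mark.line + 1})" if mark is not None else ""
        raise ConfigError(f"cannot parse {path}{line}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"top level of {path} must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown top-level key {key!r}")
    schema = data.get("schema", SCHEMA_VERSION)
    if schema != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema version {schema}")
    return RunConfig(
        network=_from_mapping(NetworkSource, data.get("network", {"builder": "jeffress"}), "network"),
        experiment=_from_mapping(ExperimentConfig, data.get("experiment", {}), "experiment"),
        simulation=_from_mapping(SimSettings, data.get("simulation", {}), "simulation"),
        mismatch=_from_mapping(MismatchConfig, data.get("mismatch", {}), "mismatch"),
        output_dir=data.get("output_dir", "out"),
        seed=data.get("seed"),
        schema=schema,
    )


def save_config(cfg: RunConfig, path) -> None:
    """Write a configuration as YAML; ``load_config`` round-trips it."""
    data = asdict(cfg)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# network serialization


def _params_to_dict(p: UCNParams) -> Dict[str, Any]:
    d = asdict(p)
    return d


def _params_from_dict(d: Mapping[str, Any]) -> UCNParams:
    d = dict(d)
    scr = d.pop("scr", None)
    kwargs: Dict[str, Any] = dict(d)
    if scr is not None:
        kwargs["scr"] = SCRDevice(**scr)
    return UCNParams(**kwargs)


def network_to_dict(net: Network) -> Dict[str, Any]:
    return {
        "schema": SCHEMA_VERSION,
        "nodes": {n: _params_to_dict(p) for n, p in net.nodes.items()},
        "edges": [
            {"source": e.source, "target": e.target,
             "r_syn": e.synapse.r_syn, "label": e.synapse.label}
            for e in net.edges
        ],
        "ports": [
            {"name": p.name, "target": p.target,
             "r_syn": p.synapse.r_syn, "label": p.synapse.label}
            for p in net.ports
        ],
        "meta": {k: v for k, v in net.meta.items()},
    }


def network_from_dict(data: Mapping[str, Any]) -> Network:
    nodes = {n: _params_from_dict(p) for n, p in data["nodes"].items()}
    edges = [
        Edge(e["source"], e["target"], SynapseSpec(e["r_syn"], e.get("label", "axon_segment")))
        for e in data.get("edges", [])
    ]
    ports = [
        Port(p["name"], p["target"], SynapseSpec(p["r_syn"], p.get("label", "axon_segment")))
        for p in data.get("ports", [])
    ]
    meta = {
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in data.get("meta", {}).items()
    }
    if "pairs" in meta:
        meta["pairs"] = tuple(tuple(x) for x in meta["pairs"])
    return build_network(nodes, edges, ports, meta=meta)


def save_network(net: Network, path) -> None:
    Path(path).write_text(yaml.safe_dump(network_to_dict(net), sort_keys=False))


def load_network(path) -> Network:
    data = yaml.safe_load(Path(path).read_text())
    return network_from_dict(data)
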