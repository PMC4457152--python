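"""Run configuration files and run manifests.

Configs are YAML (JSON is a subset and also accepted).  Recognized keys
mirror :class:`~inspectgame.dynamics.SimulationConfig`; unknown keys are
rejected so typos fail loudly.  Defaults follow the study's
representative values: K = 0.5, alpha = 0.5.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import yaml

from . import __version__
from .core_model import PayoffParams, Strategy, get_variant
from .dynamics import DynamicsParams, SimulationConfig
from .lattice import InitialStateSpec

__all__ = ["load_config", "config_from_dict", "config_to_dict", "RunManifest"]

_TOP_KEYS = {
    "variant",
    "alpha",
    "beta",
    "gamma",
    "fine",
    "K",
    "L",
    "max_mcs",
    "sample_every",
    "relaxation_mcs",
    "seed",
    "replicates",
    "initial",
}
_INITIAL_KEYS = {"mode", "weights", "layout"}


def _parse_initial(raw: dict) -> InitialStateSpec:
    unknown = set(raw) - _INITIAL_KEYS
    if unknown:
        raise ValueError(f"unknown initial-state key(s): {sorted(unknown)}")
    weights = None
    if raw.get("weights") is not None:
        weights = {Strategy[k]: float(v) for k, v in raw["weights"].items()}
    layout = None
    if raw.get("layout") is not None:
        layout = tuple((Strategy[s], float(f)) for s, f in raw["layout"])
    return InitialStateSpec(
        mode=raw.get("mode", "uniform_random"), weights=weights, layout=layout
    )


def config_from_dict(raw: dict) -> SimulationConfig:
    """Build a validated SimulationConfig from a plain mapping."""
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    variant = get_variant(raw.get("variant", "three_strategy"))
    params = PayoffParams(
        alpha=float(raw.get("alpha", 0.5)),
        beta=float(raw.get("beta", 0.8)),
        gamma=float(raw.get("gamma", 0.8)),
        fine=float(raw.get("fine", 1.0)),
    )
    initial = (
        _parse_initial(raw["initial"])
        if raw.get("initial") is not None
        else InitialStateSpec()
    )
    if initial.weights is not None:
        for s in initial.weights:
            if s not in variant:
                raise ValueError(
                    f"initial weights name strategy {s.name} outside variant {variant.name!r}"
                )
    if initial.layout is not None:
        for s, _ in initial.layout:
            if s not in variant:
                raise ValueError(
                    f"initial layout names strategy {s.name} outside variant {variant.name!r}"
                )
    return SimulationConfig(
        variant=variant,
        params=params,
        dynamics=DynamicsParams(K=float(raw.get("K", 0.5))),
        L=int(raw.get("L", 100)),
        max_mcs=int(raw.get("max_mcs", 1000)),
        sample_every=int(raw.get("sample_every", 10)),
        relaxation_mcs=int(raw.get("relaxation_mcs", 0)),
        seed=int(raw.get("seed", 0)),
        initial=initial,
        replicates=int(raw.get("replicates", 1)),
    )


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML/JSON run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return config_from_dict(raw)


def config_to_dict(config: SimulationConfig) -> dict:
    """Plain-JSON-serializable view of a config (inverse of
    :func:`config_from_dict` up to defaults)."""
    init = {"mode": config.initial.mode}
    if config.initial.weights is not None:
        init["weights"] = {s.name: w for s, w in config.initial.weights.items()}
    if config.initial.layout is not None:
        init["layout"] = [[s.name, f] for s, f in config.initial.layout]
    return {
        "variant": config.variant.name,
        "alpha": config.params.alpha,
        "beta": config.params.beta,
        "gamma": config.params.gamma,
        "fine": config.params.fine,
        "K": config.dynamics.K,
        "L": config.L,
        "max_mcs": config.max_mcs,
        "sample_every": config.sample_every,
        "relaxation_mcs": config.relaxation_mcs,
        "seed": config.seed,
        "replicates": config.replicates,
        "initial": init,
    }


class RunManifest:
    """Resolved configuration + seeds + outputs of one CLI invocation.

    Written as JSON next to the outputs; its hash is embedded in PNG
    metadata so every figure is traceable to exactly one manifest.
    """

    def __init__(self, command: str, config: SimulationConfig, seeds: list[int]):
        self.data = {
            "command": command,
            "code_version": __version__,
            "config": config_to_dict(config),
            "seeds": seeds,
            "outputs": [],
            "complete": False,
        }

    def add_output(self, path: str | Path) -> None:
        self.data["outputs"].append(str(path))

    @property
    def hash(self) -> str:
        payload = {
            k: v
            for k, v in self.data.items()
            if k not in ("outputs", "complete", "manifest_hash")
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    def write(self, path: str | Path, complete: bool = True) -> None:
        self.data["complete"] = complete
        self.data["manifest_hash"] = self.hash
        Path(path).write_text(json.dumps(self.data, indent=2) + "\n")
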