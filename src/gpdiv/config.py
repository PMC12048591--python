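"""Run configuration: YAML loading with defaults materialized, and run metadata.

Every experiment kind has a complete default parameter set (the standard model
conditions); a user YAML may override any subset of keys, unknown keys are
rejected, and the fully resolved configuration is what gets saved into run
metadata so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from importlib import metadata as _im
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig", "RunMetadata", "defaults", "load_config", "save_metadata"]

_EDITING = dict(
    mode="editing",
    alpha=2.718281828459045,  # exp(1); optimal expression ln(P0_opt) = 1
    gamma0=1.0,
    gamma1=1.0,
    Q=1.0,
    C=1.0,
    epsilon=0.0,
    l=2,
    mu01=1e-9,
    mu10=1e-9,
    sigma=10.0,
    lam=1e-3,
    Ne=1e4,
    t=10**8,
)

_SPLICING = dict(
    mode="splicing",
    alpha=1.0,
    gamma0=0.0,
    gamma1=1.0,
    gamma2=20.0,
    Q=100.0,
    C=1.0,
    epsilon=0.0,
    l=10,
    mu01=1e-9,
    mu10=1e-9,
    sigma=10.0,
    lam=1e-3,
    Ne=1e4,
    t=10**8,
)

_COEVOLUTION = dict(
    Ne_grid=[1e2, 10**2.5, 1e3, 10**3.5, 1e4, 10**4.5, 1e5],
    l_grid=[2, 5, 10],
    sigma_Q_grid=[2.0, 20.0],
    n_genes=100,
    n_lineages=50,
    duration=10**8,
    alpha=1.0,
    gamma0=1.0,
    gamma1=1.0,
    C=1.0,
    epsilon=1e-3,
    sigma=10.0,
    lam=1e-3,
    Q_opt=2.0,
    U_Q=1e-8,
    S_Q=0.1,
    mu01=1e-9,
    mu10=1e-9,
)

_COLEOID = dict(
    n_neutral=10_000,
    n_deleterious=10_000,
    Ne=1e4,
    mu01=1e-9,
    mu10=1e-9,
    C_mean=0.1,
    l_max=10,
    tree=None,  # None -> built-in coleoid preset
)

_DEFAULTS: dict[str, dict[str, Any]] = {
    "editing": _EDITING,
    "splicing": _SPLICING,
    "coevolution": _COEVOLUTION,
    "coleoid": _COLEOID,
}


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved experiment configuration."""

    kind: str
    params: dict[str, Any]
    seed: int = 0

    def __getitem__(self, key: str) -> Any:
        return self.params[key]


@dataclass
class RunMetadata:
    """Everything needed to reproduce a run: config, seed, version, timing, warnings."""

    config: RunConfig
    wall_time_s: float = 0.0
    warnings: list[str] = field(default_factory=list)
    version: str = field(default_factory=lambda: _package_version())

    def to_dict(self) -> dict[str, Any]:
        return dict(
            kind=self.config.kind,
            params=self.config.params,
            seed=self.config.seed,
            version=self.version,
            wall_time_s=self.wall_time_s,
            warnings=self.warnings,
        )


def _package_version() -> str:
    try:
        return _im.version("gpdiv")
    except _im.PackageNotFoundError:
        return "unknown"


def defaults(kind: str) -> dict[str, Any]:
    """The complete default parameter set for an experiment kind."""
    if kind not in _DEFAULTS:
        raise ValueError(f"unknown experiment kind {kind!r}; choose from {sorted(_DEFAULTS)}")
    return dict(_DEFAULTS[kind])


def load_config(path: str | Path | None, kind: str, seed: int = 0) -> RunConfig:
    """Resolve a YAML config over the kind's defaults; unknown keys are rejected."""
    params = defaults(kind)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("config file must contain a mapping")
        user = dict(user)
        kind = user.pop("kind", kind)
        seed = user.pop("seed", seed)
        params = defaults(kind)
        unknown = sorted(set(user) - set(params))
        if unknown:
            raise ValueError(f"unknown config keys for kind {kind!r}: {unknown}")
        params.update(user)
    return RunConfig(kind=kind, params=params, seed=int(seed))


def save_metadata(meta: RunMetadata, path: str | Path) -> None:
    Path(path).write_text(json.dumps(meta.to_dict(), indent=2, default=float) + "\n")


def save_config_yaml(config: RunConfig, path: str | Path) -> None:
    """Round-trippable YAML dump of a resolved configuration."""
    doc = dict(kind=config.kind, seed=config.seed, **config.params)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
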