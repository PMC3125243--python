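"""Configuration files, tabular output, and run logging.

Configs are YAML (JSON is a subset and parses too) with four optional
blocks — ``sim``, ``focal``, ``competitor``, ``experiment`` — each
overriding the defaults of :class:`~netcomm.engine.SimConfig`,
:class:`~netcomm.engine.SpeciesParams` and :class:`ExperimentSpec`.
Unknown keys are an error; grid values outside the canonical experimental
sets are allowed but warned about.  All tabular output is CSV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import pandas as pd
import yaml

from netcomm.engine import (
    RunRecord,
    SimConfig,
    SpeciesParams,
)

__all__ = [
    "ExperimentSpec",
    "load_config",
    "dump_config",
    "write_outputs",
    "ConfigError",
]


class ConfigError(ValueError):
    """Malformed or invalid configuration file."""


#: canonical factor levels of the factorial design; other values warn
CANONICAL_LEVELS = {
    "competitor_n": {16, 64, 256},
    "competitor_topology": {"scale_free", "random"},
    "competitor_mu": {1e-3, 1e-4, 1e-5},
    "competitor_rec": {0.05, 0.5},
    "competitor_d": {0.1, 0.05, 0.01},
    "focal_d": {0.1, 0.05, 0.01},
}


@dataclass
class ExperimentSpec:
    """Factor grids, replication and output location for one experiment."""

    design: dict = field(default_factory=dict)
    replicates: int = 3
    master_seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        for factor, levels in self.design.items():
            if not isinstance(levels, (list, tuple)):
                raise ConfigError(f"design factor {factor!r} must list its levels")
            canon = CANONICAL_LEVELS.get(factor)
            if canon is None:
                continue
            off = [v for v in levels if v not in canon]
            if off:
                warnings.warn(
                    f"design factor {factor!r} includes non-canonical levels {off}",
                    stacklevel=2,
                )


def _build(cls, block: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where!r} block: {sorted(unknown)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {where!r} block: {exc}") from exc


def load_config(path) -> tuple[SimConfig, SpeciesParams, SpeciesParams, ExperimentSpec]:
    """Parse a YAML/JSON config into fully validated objects with defaults.

    An empty file yields pure defaults: the focal-species architecture for
    both species (competitor in patch 1) and the standard global constants.
    """
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark else ""
        raise ConfigError(f"cannot parse config {path}{line}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping of blocks")
    unknown = set(raw) - {"sim", "focal", "competitor", "experiment"}
    if unknown:
        raise ConfigError(f"unknown top-level blocks: {sorted(unknown)}")
    config = _build(SimConfig, dict(raw.get("sim") or {}), "sim")
    focal_block = {"name": "focal", "start_patch": 0, **(raw.get("focal") or {})}
    comp_block = {"name": "competitor", "start_patch": 1, **(raw.get("competitor") or {})}
    focal = _build(SpeciesParams, focal_block, "focal")
    competitor = _build(SpeciesParams, comp_block, "competitor")
    spec = _build(ExperimentSpec, dict(raw.get("experiment") or {}), "experiment")
    return config, focal, competitor, spec


def dump_config(
    config: SimConfig,
    focal: SpeciesParams,
    competitor: SpeciesParams,
    spec: ExperimentSpec,
    path,
) -> None:
    """Write a config snapshot that round-trips through :func:`load_config`."""
    blob = {
        "sim": _plain(asdict(config)),
        "focal": _plain(asdict(focal)),
        "competitor": _plain(asdict(competitor)),
        "experiment": _plain(asdict(spec)),
    }
    Path(path).write_text(yaml.safe_dump(blob, sort_keys=False))


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_outputs(
    records: list[RunRecord],
    summary: pd.DataFrame,
    out_dir,
    config: SimConfig | None = None,
    focal: SpeciesParams | None = None,
    competitor: SpeciesParams | None = None,
    spec: ExperimentSpec | None = None,
) -> dict[str, object]:
    """Write the standard output bundle for a batch of runs.

    Produces ``summary.csv`` (one row per run), ``run_<seed>.csv`` per run
    record, a ``config.yaml`` snapshot when the configuration objects are
    given, and ``run_log.json`` echoing seeds and termination causes.
    Re-running with the same inputs overwrites the same files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}
    summary.to_csv(out / "summary.csv", index=False)
    paths["summary"] = out / "summary.csv"
    run_paths = []
    log = []
    for rec in records:
        p = out / f"run_{rec.seed}.csv"
        rec.table.to_csv(p, index=False)
        run_paths.append(p)
        log.append(
            {
                "seed": rec.seed,
                "generations_run": rec.generations_run,
                "coexistence": rec.coexistence,
                "extinction_gen": rec.extinction_gen,
                "species": [_plain(asdict(sp)) for sp in rec.params],
            }
        )
    paths["runs"] = run_paths
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    paths["log"] = out / "run_log.json"
    if config is not None and focal is not None and competitor is not None:
        dump_config(config, focal, competitor, spec or ExperimentSpec(), out / "config.yaml")
        paths["config"] = out / "config.yaml"
    return paths
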