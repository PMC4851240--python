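"""CSV and YAML interfaces: interim datasets, study configs, result tables."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .params import EndpointParams, SimulationConfig, Stage1Data, TrialDesign, UNBOUNDED

__all__ = [
    "read_stage1_csv",
    "write_stage1_csv",
    "write_results_csv",
    "load_config",
    "ConfigError",
]

_FLOAT_FMT = "%.17g"  # round-trip exact for doubles


class ConfigError(ValueError):
    """Invalid or incomplete run configuration; message names the field."""


def read_stage1_csv(path, require_balanced: bool = False) -> Stage1Data:
    """Read a blinded interim dataset.

    Expected header: ``subject,x,y[,g][,block_id]`` (0-based subject index).
    With ``require_balanced`` the allocation column g, if present, must sum
    to n1/2 (the random-allocation invariant).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("subject", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    df = df.sort_values("subject")
    g = df["g"].to_numpy() if "g" in df.columns else None
    block_id = df["block_id"].to_numpy() if "block_id" in df.columns else None
    data = Stage1Data(
        x=df["x"].to_numpy(float), y=df["y"].to_numpy(float), g=g, block_id=block_id
    )
    if require_balanced and g is not None and int(g.sum()) != data.n1 // 2:
        raise ValueError(
            f"allocation column g sums to {int(g.sum())}, expected n1/2 = {data.n1 // 2}"
        )
    return data


def write_stage1_csv(data: Stage1Data, path) -> None:
    """Write a stage-1 dataset; inverse of :func:`read_stage1_csv`."""
    cols = {"subject": np.arange(data.n1), "x": data.x, "y": data.y}
    if data.g is not None:
        cols["g"] = data.g
    if data.block_id is not None:
        cols["block_id"] = data.block_id
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_results_csv(table: pd.DataFrame, path, config: Optional[dict] = None,
                      seed: Optional[int] = None) -> None:
    """Write a result table plus a reproducibility stanza.

    The stanza (``<path>.meta.json``) records the package version, the seed
    and a hash of the configuration that produced the table.
    """
    path = Path(path)
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)
    from . import __version__

    meta = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config or {}, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


_PARAM_KEYS = {"mu0", "mu1", "nu0", "nu1", "sigma", "rho"}
_DESIGN_KEYS = {"n1", "n2min", "n2max", "alpha", "scheme", "tau"}
_TOP_KEYS = {"params", "design", "n_runs", "seed"}


def _check_unknown(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def load_config(path) -> SimulationConfig:
    """Load and validate a study configuration from YAML.

    Defaults: ``alpha = 0.025``, ``n2min = 0``, ``n2max = inf`` (use the
    string ``"inf"`` or ``.inf`` for an explicitly unbounded second stage),
    ``scheme = random_allocation``, ``n_runs = 200000``, ``seed = 0``.
    Unknown keys are rejected; violations name the offending field.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    _check_unknown(raw, _TOP_KEYS, "top level")
    psec = raw.get("params")
    dsec = raw.get("design")
    if not isinstance(psec, dict):
        raise ConfigError("missing or invalid section `params`")
    if not isinstance(dsec, dict):
        raise ConfigError("missing or invalid section `design`")
    _check_unknown(psec, _PARAM_KEYS, "`params`")
    _check_unknown(dsec, _DESIGN_KEYS, "`design`")

    pdef = {"mu0": 0.0, "mu1": 0.0, "rho": 0.0}
    pargs = {**pdef, **psec}
    for k in ("nu0", "nu1", "sigma"):
        if k not in pargs:
            raise ConfigError(f"missing field `params.{k}`")
    ddef = {"n2min": 0.0, "n2max": UNBOUNDED, "alpha": 0.025,
            "scheme": "random_allocation", "tau": None}
    dargs = {**ddef, **dsec}
    if "n1" not in dargs:
        raise ConfigError("missing field `design.n1`")
    if isinstance(dargs["n2max"], str):
        if dargs["n2max"].lower() not in ("inf", "unbounded"):
            raise ConfigError("invalid `design.n2max`: use a number or 'inf'")
        dargs["n2max"] = UNBOUNDED
    try:
        params = EndpointParams(**{k: float(pargs[k]) for k in _PARAM_KEYS})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid `params`: {exc}") from exc
    try:
        design = TrialDesign(
            n1=int(dargs["n1"]),
            n2min=float(dargs["n2min"]),
            n2max=float(dargs["n2max"]),
            alpha=float(dargs["alpha"]),
            scheme=str(dargs["scheme"]),
            tau=None if dargs["tau"] is None else int(dargs["tau"]),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid `design`: {exc}") from exc
    try:
        return SimulationConfig(
            params=params,
            design=design,
            n_runs=int(raw.get("n_runs", 200_000)),
            seed=int(raw.get("seed", 0)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config: {exc}") from exc
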