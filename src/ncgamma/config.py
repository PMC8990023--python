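"""Run configuration and columnar file I/O.

The run config is a single YAML document with a versioned schema; unknown
keys are rejected so sweeps stay auditable.  Event, deposition and sweep
tables are exchanged as CSV with fixed headers (the canonical interchange
format of this package); round-trips preserve records to printed precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .beam import InvalidConfigError
from .detector import DEPOSITION_COLUMNS, MATERIALS, SHIELDS
from .discrimination import MASKS_NS, NCI_LINES_MEV
from .phase_space import EVENT_COLUMNS

__all__ = ["RunConfig", "load_config", "write_events", "read_events",
           "write_depositions", "read_depositions", "write_sweep", "logger"]

logger = logging.getLogger("ncgamma")

CONFIG_VERSION = 1

_SCENARIO_KEYS = {"nci", "beam", "total_ns", "n_primaries", "period_ns",
                  "on_ns", "yields", "gd_all_lines"}
_CRITERIA_KEYS = {"line_energy_MeV", "window_k_sigma", "window_lo_MeV",
                  "window_hi_MeV", "mask_ns"}
_TOP_KEYS = {"version", "seed", "scenario", "material", "shield", "criteria",
             "sweep_axes", "log_level"}


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    scenario: dict = field(default_factory=dict)
    material: str = "CdTe"
    shield: str = "none"
    criteria: dict = field(default_factory=dict)
    sweep_axes: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def scenario_kwargs(self) -> dict:
        kw = dict(self.scenario)
        kw.setdefault("nci", "B10")
        kw.setdefault("total_ns", 1e3)
        kw.setdefault("n_primaries", 1_000_000)
        kw["seed"] = self.seed
        return kw


def _reject_unknown(d: dict, allowed: set, where: str):
    unknown = set(d) - allowed
    if unknown:
        raise InvalidConfigError(
            f"unknown key(s) {sorted(unknown)} in config section '{where}'")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; errors name the offending key."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidConfigError(f"{path}: config must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "top level")
    version = raw.get("version", CONFIG_VERSION)
    if version != CONFIG_VERSION:
        raise InvalidConfigError(f"version: unsupported config version {version}")

    scenario = dict(raw.get("scenario") or {})
    _reject_unknown(scenario, _SCENARIO_KEYS, "scenario")
    nci = scenario.get("nci", "B10")
    if nci not in ("none", "B10", "Gd157"):
        raise InvalidConfigError(f"scenario.nci: unknown insert {nci!r}")
    period = float(scenario.get("period_ns", 200.0))
    on = float(scenario.get("on_ns", 11.0))
    if not 0 < on < period:
        raise InvalidConfigError("scenario.on_ns must satisfy 0 < on_ns < period_ns")

    material = raw.get("material", "CdTe")
    if material not in MATERIALS:
        raise InvalidConfigError(f"material: unknown detector material {material!r}")
    shield = raw.get("shield", "none")
    if shield not in SHIELDS:
        raise InvalidConfigError(f"shield: unknown shield material {shield!r}")

    criteria = dict(raw.get("criteria") or {})
    _reject_unknown(criteria, _CRITERIA_KEYS, "criteria")
    mask = float(criteria.get("mask_ns", 0.0))
    if mask < 0 or mask >= period:
        raise InvalidConfigError(
            f"criteria.mask_ns: mask {mask} must lie in [0, period_ns={period})")
    line = criteria.get("line_energy_MeV")
    if line is not None and nci in NCI_LINES_MEV and not np.isclose(
            float(line), NCI_LINES_MEV[nci]):
        logger.warning("criteria.line_energy_MeV %s does not match the %s capture line %s",
                       line, nci, NCI_LINES_MEV[nci])
        raise InvalidConfigError(
            f"criteria.line_energy_MeV: {line} mismatches the {nci} line "
            f"{NCI_LINES_MEV[nci]}")

    sweep_axes = dict(raw.get("sweep_axes") or {})
    for m in sweep_axes.get("mask_ns", []):
        if float(m) >= period:
            raise InvalidConfigError(
                f"sweep_axes.mask_ns: mask {m} >= period_ns {period}")

    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        scenario=scenario,
        material=material,
        shield=shield,
        criteria=criteria,
        sweep_axes=sweep_axes,
        log_level=str(raw.get("log_level", "INFO")),
    )
    logger.debug("loaded config %s (seed=%d)", path, cfg.seed)
    return cfg


# ---------------------------------------------------------------------------
# Columnar CSV interchange
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.9g"


def write_events(events: pd.DataFrame, path) -> None:
    events[EVENT_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"event_id": np.uint64})
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidConfigError(f"{path}: missing event columns {sorted(missing)}")
    return df[EVENT_COLUMNS]


def write_depositions(deps: pd.DataFrame, path) -> None:
    cols = DEPOSITION_COLUMNS + (["class"] if "class" in deps.columns else [])
    deps[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_depositions(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"event_id": np.uint64})
    missing = set(DEPOSITION_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidConfigError(f"{path}: missing deposition columns {sorted(missing)}")
    return df


def write_sweep(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)
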