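"""Sensitivity / selectivity metrics and the optimisation sweep.

True- and false-positive sensitivities are TP and FP counts divided by the
number of photons reaching the detector (neutrons excluded from the
denominator; shield-capture secondaries included — they do reach it).
Selectivity R_TF is the ratio TP:FP.  Uncertainties are reported as ±2σ
half-widths: binomial for the sensitivities, first-order propagation of
independent Poisson counts for R_TF, σ(R) = R·sqrt(1/TP + 1/FP).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beam import InvalidConfigError
from .detector import deposit, get_material, get_shield, shield_interact
from .discrimination import (
    MASKS_NS,
    NCI_LINES_MEV,
    AcceptanceCriteria,
    ClassificationCounts,
    classify_counts,
    energy_window_for,
)
from .phase_space import ScenarioConfig, generate_events, make_scenario

__all__ = [
    "Metrics",
    "SweepResult",
    "IRRADIATION_PERIODS_NS",
    "MATERIAL_AXES",
    "compute_metrics",
    "run_cell",
    "sweep_grid",
    "find_optimum",
]

#: Macroscopic irradiation periods evaluated: 1 µs, 10 µs, 1 ms, 10 ms, 100 ms.
IRRADIATION_PERIODS_NS = (1e3, 1e4, 1e6, 1e7, 1e8)

#: Candidate detector materials per insert: high-resolution materials for
#: the 478 keV line, high-density scintillators for the 7.94 MeV line.
MATERIAL_AXES = {"B10": ("LaBr3", "CdTe", "CZT"), "Gd157": ("BGO", "LSO", "PbWO4")}


@dataclass(frozen=True)
class Metrics:
    sens_tp: float
    sens_fp: float
    r_tf: float | None
    sens_tp_ci: float
    sens_fp_ci: float
    r_tf_ci: float | None

    def as_dict(self) -> dict:
        return {
            "sens_tp": self.sens_tp, "sens_fp": self.sens_fp,
            "r_tf": self.r_tf, "sens_tp_ci": self.sens_tp_ci,
            "sens_fp_ci": self.sens_fp_ci, "r_tf_ci": self.r_tf_ci,
        }


def compute_metrics(counts: ClassificationCounts) -> Metrics:
    """Sensitivities, selectivity and ±2σ intervals from class counts.

    R_TF is undefined (None) when FP = 0, never infinity.
    """
    n = counts.n_photons_at_detector
    if n <= 0:
        raise InvalidConfigError("metrics need n_photons_at_detector > 0")
    p_tp = counts.tp / n
    p_fp = counts.fp / n
    ci_tp = 2.0 * math.sqrt(max(p_tp * (1 - p_tp), 0.0) / n)
    ci_fp = 2.0 * math.sqrt(max(p_fp * (1 - p_fp), 0.0) / n)
    if counts.fp > 0 and counts.tp > 0:
        r = counts.tp / counts.fp
        r_ci = 2.0 * r * math.sqrt(1.0 / counts.tp + 1.0 / counts.fp)
    elif counts.fp > 0:
        r, r_ci = 0.0, None
    else:
        r, r_ci = None, None
    return Metrics(p_tp, p_fp, r, ci_tp, ci_fp, r_ci)


# ---------------------------------------------------------------------------
# Single pipeline cell
# ---------------------------------------------------------------------------


def run_cell(
    scenario: ScenarioConfig,
    material,
    shield="none",
    criteria: AcceptanceCriteria | None = None,
    mask_ns: float = 0.0,
    window_k_sigma: float = 3.0,
    events: pd.DataFrame | None = None,
):
    """Run phase space → shield → detector → classification for one cell.

    ``material`` / ``shield`` may be names or instances.  If ``criteria`` is
    omitted it is derived from the scenario's capture line, the material's
    resolution model (± k·σ) and ``mask_ns``.  A pre-generated ``events``
    stream may be passed to share one stream across mask/shield variants.
    Deterministic under a fixed scenario seed.
    """
    if isinstance(material, str):
        material = get_material(material)
    if isinstance(shield, str):
        shield = get_shield(shield)
    if criteria is None:
        line = scenario.nci_line_MeV
        if line is None:
            raise InvalidConfigError(
                "scenario without a capture insert needs explicit criteria")
        criteria = energy_window_for(line, material, k=window_k_sigma, mask_ns=mask_ns)
    if events is None:
        events = generate_events(scenario)
    at_detector = shield_interact(events, shield, seed=scenario.seed)
    n_photons = int((at_detector["species"] == "photon").sum())
    deps = deposit(at_detector, material, seed=scenario.seed)
    counts = classify_counts(deps, criteria, scenario.train, n_photons)
    return counts, compute_metrics(counts)


# ---------------------------------------------------------------------------
# Grid sweep
# ---------------------------------------------------------------------------

_SWEEP_AXES = ("material", "shield", "mask_ns", "total_ns", "nci", "beam")


@dataclass(frozen=True)
class SweepResult:
    axes: dict
    table: pd.DataFrame = field(repr=False)
    base_seed: int = 0

    def best(self, objective: str = "r_tf", tie_break: bool = True):
        return find_optimum(self, objective=objective)


def _cell_seed(base_seed: int, index: int) -> int:
    """Deterministic, well-separated per-cell seed below 2**31."""
    return (base_seed * 1_000_003 + index * 7919 + 17) % (2**31)


def sweep_grid(
    base_config: dict | None = None,
    axes: dict | None = None,
    n_primaries: int = 1_000_000,
    base_seed: int = 0,
    window_k_sigma: float = 3.0,
    share_stream_over_masks: bool = True,
) -> SweepResult:
    """Exhaustively evaluate the Cartesian product of the sweep axes.

    Axes: subsets of ``material``, ``shield``, ``mask_ns``, ``total_ns``,
    ``nci``, ``beam``; missing axes take single default values from
    ``base_config`` (nci B10, beam carbon, unshielded, 1 µs, mask 0).
    Per-cell seeds derive deterministically from ``base_seed`` and the
    (nci, beam) coordinates; all other axes — masks, materials, shields and
    irradiation periods — are evaluated with common random numbers, so
    within-sweep comparisons are paired and their differences are driven by
    the systematic effect rather than independent sampling noise.
    Independent replicates are obtained by varying ``base_seed``.
    """
    base = {"nci": "B10", "beam": "carbon", "material": "CdTe",
            "shield": "none", "mask_ns": 0.0, "total_ns": 1e3}
    if base_config:
        unknown = set(base_config) - set(base)
        if unknown:
            raise InvalidConfigError(f"unknown base_config keys: {sorted(unknown)}")
        base.update(base_config)
    axes = dict(axes or {})
    unknown = set(axes) - set(_SWEEP_AXES)
    if unknown:
        raise InvalidConfigError(f"unknown sweep axes: {sorted(unknown)}")
    grid = {k: tuple(axes.get(k, (base[k],))) for k in _SWEEP_AXES}
    for k, vals in grid.items():
        if len(vals) == 0:
            raise InvalidConfigError(f"sweep axis {k!r} is empty")

    outer_axes = [k for k in _SWEEP_AXES if k != "mask_ns"]
    rows = []
    scenario_coords = list(itertools.product(grid["nci"], grid["beam"]))
    outer_product = list(itertools.product(*(grid[k] for k in outer_axes)))
    for outer_vals in outer_product:
        cell = dict(zip(outer_axes, outer_vals))
        seed = _cell_seed(base_seed, scenario_coords.index((cell["nci"], cell["beam"])))
        scenario = make_scenario(
            nci=cell["nci"], total_ns=cell["total_ns"],
            n_primaries=n_primaries, seed=seed, beam=cell["beam"])
        events = generate_events(scenario) if share_stream_over_masks else None
        for mask in grid["mask_ns"]:
            counts, m = run_cell(
                scenario, cell["material"], cell["shield"],
                mask_ns=mask, window_k_sigma=window_k_sigma, events=events)
            rows.append({
                **cell, "mask_ns": mask, "seed": seed,
                "tp": counts.tp, "fp": counts.fp,
                "tn": counts.tn, "fn": counts.fn,
                "n_photons_at_detector": counts.n_photons_at_detector,
                **m.as_dict(),
            })
    table = pd.DataFrame(rows)
    return SweepResult(axes=grid, table=table, base_seed=base_seed)


_MASK_ORDER = {m: i for i, m in enumerate(MASKS_NS)}


def find_optimum(sweep: SweepResult, objective: str = "r_tf") -> pd.Series:
    """Arg-max cell of the sweep under the given objective.

    Cells with undefined R_TF are excluded when optimising it.  Ties are
    broken toward the smallest mask, then the shortest irradiation period,
    then material name order.
    """
    if objective not in ("r_tf", "sens_tp"):
        raise InvalidConfigError("objective must be 'r_tf' or 'sens_tp'")
    t = sweep.table
    valid = t[t[objective].notna()]
    if valid.empty:
        raise InvalidConfigError(f"no cell has a defined {objective}")
    best_val = valid[objective].max()
    ties = valid[valid[objective] == best_val]
    ties = ties.sort_values(["mask_ns", "total_ns", "material"], kind="stable")
    return ties.iloc[0]
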