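"""Acceptance criteria and ground-truth classification.

A detection is *accepted* when it falls outside the per-spill temporal mask
and inside the energy window around the capture line.  Against the
ground-truth origin this yields the four classes:

* TP — capture-in-insert event, accepted;
* FN — capture-in-insert event, rejected by mask or window;
* FP — any other event, accepted;
* TN — any other event, rejected.

Hydrogen-capture photons are physically neutron captures but are *not* the
capture of interest, so they count as background (FP when accepted).

The temporal mask runs from the start of each nano-spill; depositions after
the end of irradiation are always accepted, because spills — and therefore
masks — no longer occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beam import InvalidConfigError, PulseTrain, pulse_relative_time
from .detector import DetectorMaterial, sigma_at

__all__ = [
    "MASKS_NS",
    "AcceptanceCriteria",
    "ClassificationCounts",
    "energy_window_for",
    "apply_mask",
    "classify",
    "classify_counts",
]

#: The eight temporal masks swept in the optimisation: no mask, beam-on
#: only, and beam-on + prompt-emission + neutron margins up to 80 ns.
MASKS_NS = (0.0, 11.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)

#: Capture line per insert isotope.
NCI_LINES_MEV = {"B10": 0.478, "Gd157": 7.94}


@dataclass(frozen=True)
class AcceptanceCriteria:
    line_energy_MeV: float
    window_lo_MeV: float
    window_hi_MeV: float
    mask_ns: float
    window_k_sigma: float | None = None

    def __post_init__(self):
        # non-strict: a zero-resolution material yields the degenerate
        # window at the line energy (acceptance is inclusive at the edges)
        if not self.window_lo_MeV <= self.line_energy_MeV <= self.window_hi_MeV:
            raise InvalidConfigError("energy window must bracket the line energy")
        if self.mask_ns < 0:
            raise InvalidConfigError("mask must be non-negative")


@dataclass(frozen=True)
class ClassificationCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    n_photons_at_detector: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def energy_window_for(
    line_energy_MeV: float, material: DetectorMaterial, k: float = 3.0,
    mask_ns: float = 0.0,
) -> AcceptanceCriteria:
    """Symmetric window line ± k·σ(line) from the material's resolution model."""
    if k <= 0:
        raise InvalidConfigError("window width multiplier k must be positive")
    s = float(sigma_at(line_energy_MeV, material))
    return AcceptanceCriteria(
        line_energy_MeV=line_energy_MeV,
        window_lo_MeV=line_energy_MeV - k * s,
        window_hi_MeV=line_energy_MeV + k * s,
        mask_ns=0.0 if mask_ns is None else mask_ns,
        window_k_sigma=k,
    )


def apply_mask(depositions: pd.DataFrame, train: PulseTrain, mask_ns: float):
    """Partition depositions into (accepted, rejected) by the temporal mask.

    A deposition during irradiation is rejected iff its pulse-relative
    offset is below ``mask_ns`` (half-open: an offset exactly at the mask
    boundary is accepted).  Post-irradiation depositions are always
    accepted.  The partition is exhaustive and disjoint.
    """
    acc = accepted_mask(depositions["t_abs_ns"].to_numpy(dtype=float), train, mask_ns)
    return depositions.loc[acc], depositions.loc[~acc]


def accepted_mask(t_abs_ns: np.ndarray, train: PulseTrain, mask_ns: float) -> np.ndarray:
    """Boolean acceptance of the temporal mask for an array of times."""
    if mask_ns < 0:
        raise InvalidConfigError("mask must be non-negative")
    if mask_ns >= train.period_ns:
        raise InvalidConfigError(
            "mask covering a full period would reject everything during beam")
    _, offset, post = pulse_relative_time(t_abs_ns, train)
    return post | (offset >= mask_ns)


def classify(depositions: pd.DataFrame, criteria: AcceptanceCriteria,
             train: PulseTrain) -> pd.Series:
    """Classify each deposition as TP/FP/TN/FN against ground truth.

    Ground truth for "capture of interest" is ``origin == 'nci_capture'``.
    """
    if "origin" not in depositions:
        raise KeyError("depositions must carry a ground-truth 'origin' column")
    e = depositions["deposited_energy_MeV"].to_numpy(dtype=float)
    in_window = (e >= criteria.window_lo_MeV) & (e <= criteria.window_hi_MeV)
    acc = accepted_mask(depositions["t_abs_ns"].to_numpy(dtype=float),
                        train, criteria.mask_ns)
    is_capture = (depositions["origin"] == "nci_capture").to_numpy()
    positive = acc & in_window
    label = np.where(is_capture,
                     np.where(positive, "TP", "FN"),
                     np.where(positive, "FP", "TN"))
    return pd.Series(label, index=depositions.index, name="class")


def classify_counts(
    depositions: pd.DataFrame,
    criteria: AcceptanceCriteria,
    train: PulseTrain,
    n_photons_at_detector: int,
) -> ClassificationCounts:
    """Tally the four classes; the tally is a total partition of the stream."""
    labels = classify(depositions, criteria, train)
    c = labels.value_counts()
    return ClassificationCounts(
        tp=int(c.get("TP", 0)), fp=int(c.get("FP", 0)),
        tn=int(c.get("TN", 0)), fn=int(c.get("FN", 0)),
        n_photons_at_detector=int(n_photons_at_detector),
    )
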