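"""Pulsed ion-beam micro-structure.

A synchrotron-style treatment beam is modelled as a periodic train of
nano-spills: ``period_ns`` between spill starts, beam on for the first
``on_ns`` of each period (defaults 200 ns / 11 ns, i.e. a 5.5% duty cycle).
Primary ions are injected at a constant rate during each spill, over a
macroscopic irradiation lasting ``total_ns`` (1 µs up to 100 ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PulseTrain",
    "build_pulse_train",
    "pulse_relative_time",
    "InvalidConfigError",
]


class InvalidConfigError(ValueError):
    """Raised when beam/detector/criteria parameters are inconsistent."""


@dataclass(frozen=True)
class PulseTrain:
    """Timing structure of a pulsed irradiation.

    Attributes
    ----------
    period_ns : float
        Spill repetition period.
    on_ns : float
        Beam-on duration at the start of each period.
    total_ns : float
        Total macroscopic irradiation duration.
    n_primaries : int
        Number of primary ions injected over the whole irradiation.
    injection_times_ns : np.ndarray
        Sorted absolute injection time of every primary; each time falls
        within the beam-on window of its spill.
    """

    period_ns: float
    on_ns: float
    total_ns: float
    n_primaries: int
    injection_times_ns: np.ndarray = field(repr=False)

    @property
    def duty_cycle(self) -> float:
        return self.on_ns / self.period_ns

    @property
    def n_pulses(self) -> int:
        return math.ceil(self.total_ns / self.period_ns)

    def to_dict(self) -> dict:
        """Config-file representation (injection times are derived, not stored)."""
        return {
            "period_ns": self.period_ns,
            "on_ns": self.on_ns,
            "total_ns": self.total_ns,
            "n_primaries": self.n_primaries,
        }


def build_pulse_train(
    total_ns: float,
    period_ns: float = 200.0,
    on_ns: float = 11.0,
    n_primaries: int = 1,
    rng_seed: int | None = None,
    jitter: bool = False,
) -> PulseTrain:
    """Construct a pulse train with primaries spread across all spills.

    Primaries are divided as evenly as possible over the ``ceil(total/period)``
    spills, any remainder going to the earliest spills.  Within a spill the
    injections are placed at a constant stride through the beam-on window
    (offset ``(i + 0.5)/k * on_ns`` for the i-th of k injections), which makes
    the per-spill rate exactly constant and small cases reproducible without
    randomness.  With ``jitter=True`` offsets are instead drawn uniformly on
    ``[0, on_ns)``.

    Raises
    ------
    InvalidConfigError
        For non-positive durations, ``on_ns >= period_ns``,
        ``period_ns > total_ns`` or ``n_primaries < 1``.
    """
    if total_ns <= 0 or period_ns <= 0 or on_ns <= 0:
        raise InvalidConfigError("durations must be positive")
    if on_ns >= period_ns:
        raise InvalidConfigError("beam-on duration must be shorter than the period")
    if period_ns > total_ns:
        raise InvalidConfigError("total irradiation must cover at least one period")
    if n_primaries < 1:
        raise InvalidConfigError("need at least one primary")

    n_pulses = math.ceil(total_ns / period_ns)
    base, rem = divmod(n_primaries, n_pulses)
    counts = np.full(n_pulses, base, dtype=np.int64)
    counts[:rem] += 1  # remainder to the earliest spills

    pulse_starts = np.repeat(np.arange(n_pulses, dtype=np.float64) * period_ns, counts)
    if jitter:
        rng = np.random.default_rng(rng_seed)
        offsets = rng.uniform(0.0, on_ns, size=n_primaries)
        # sort within each pulse so the train is globally sorted
        order = np.lexsort((offsets, pulse_starts))
        times = (pulse_starts + offsets)[order]
    else:
        ranks = np.concatenate([np.arange(c, dtype=np.float64) for c in counts if c > 0]) \
            if n_primaries else np.empty(0)
        ks = np.repeat(counts[counts > 0].astype(np.float64), counts[counts > 0])
        offsets = (ranks + 0.5) / ks * on_ns
        times = pulse_starts + offsets

    times.setflags(write=False)
    return PulseTrain(
        period_ns=float(period_ns),
        on_ns=float(on_ns),
        total_ns=float(total_ns),
        n_primaries=int(n_primaries),
        injection_times_ns=times,
    )


def pulse_relative_time(t_abs_ns, train: PulseTrain):
    """Map absolute times to (pulse index, offset from spill start).

    During irradiation this is plain integer division by the period.  Times
    after ``total_ns`` (delayed capture / decay photons) keep the *last* spill
    as their reference, so their offset can exceed the period; a boolean
    post-beam flag marks them.  Scalar in, scalar out; array in, array out.

    Raises
    ------
    ValueError
        If any time is negative.
    """
    t = np.asarray(t_abs_ns, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("absolute times must be non-negative")
    idx = np.floor_divide(t, train.period_ns).astype(np.int64)
    last = train.n_pulses - 1
    post_beam = idx > last
    idx = np.minimum(idx, last)
    offset = t - idx * train.period_ns
    if np.ndim(t_abs_ns) == 0:
        return int(idx), float(offset), bool(post_beam)
    return idx, offset, post_beam
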