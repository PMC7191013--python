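"""Safety-behavior-sampling (SBS) design: sample size and observation schedule.

SBS is a work-sampling technique: instantaneous, randomized observations of
worker behavior classified as safe / unsafe.  It relies on the normal
approximation to the binomial, so the number of observations needed to pin
the unsafe proportion p down to a desired *relative* accuracy S with
confidence multiplier K (a standard-normal quantile) is

    n = K^2 (1 - p) / (S^2 p).

A pilot round estimates p = N1/N0.  With the customary K = 2 and S = 0.05 and
a pilot proportion of 0.45, this gives ~1956 observations, conventionally
rounded to the nearest ten (1960).  The absolute-precision variant
K^2 p(1-p)/S^2 is also exposed under a flag for completeness.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DesignError",
    "SampleSize",
    "SBSDesign",
    "ObservationSchedule",
    "estimate_p",
    "required_sample_size",
    "design",
    "build_schedule",
]

#: Conventional standard-normal multiplier (two-sided 95%, z ≈ 1.96 ≈ 2).
DEFAULT_K = 2.0
#: Conventional relative accuracy.
DEFAULT_S = 0.05


class DesignError(ValueError):
    """Invalid sampling-design inputs."""


@dataclass(frozen=True)
class SampleSize:
    """Required observation count: raw value, ceiling, and nearest-ten."""

    raw: float
    required: int
    nearest_ten: int


@dataclass(frozen=True)
class SBSDesign:
    """A complete sampling design derived from a pilot study."""

    n0: int
    n1: int
    p: float
    k: float
    s: float
    size: SampleSize

    @property
    def n_required(self) -> int:
        return self.size.required


def estimate_p(n1: int, n0: int) -> float:
    """Pilot estimate of the unsafe-behavior proportion, p = N1/N0."""
    if n0 <= 0:
        raise DesignError("empty pilot: N0 must be positive")
    if not 0 <= n1 <= n0:
        raise DesignError(f"N1 must lie in [0, N0]; got N1={n1}, N0={n0}")
    return n1 / n0


def required_sample_size(
    p: float,
    k: float = DEFAULT_K,
    s: float = DEFAULT_S,
    absolute_precision: bool = False,
) -> SampleSize:
    """Observations needed to estimate p to relative accuracy s.

    Uses the relative-precision work-sampling formula n = k²(1−p)/(s²p);
    with ``absolute_precision=True`` the half-width s is treated as absolute
    and n = k²p(1−p)/s² instead.  Returns the raw value, its ceiling, and a
    nearest-ten presentation rounding.
    """
    if not 0.0 < p < 1.0:
        raise DesignError(f"degenerate proportion p={p}; need 0 < p < 1")
    if k <= 0:
        raise DesignError("K must be positive")
    if not 0.0 < s < 1.0:
        raise DesignError("S must lie in (0, 1)")
    if absolute_precision:
        raw = k * k * p * (1.0 - p) / (s * s)
    else:
        raw = k * k * (1.0 - p) / (s * s * p)
    required = max(1, math.ceil(raw))
    nearest_ten = max(10, int(round(raw / 10.0)) * 10)
    return SampleSize(raw=raw, required=required, nearest_ten=nearest_ten)


def design(
    n0: int,
    n1: int,
    k: float = DEFAULT_K,
    s: float = DEFAULT_S,
    absolute_precision: bool = False,
) -> SBSDesign:
    """Full pilot-to-sample-size design in one call."""
    p = estimate_p(n1, n0)
    size = required_sample_size(p, k=k, s=s, absolute_precision=absolute_precision)
    return SBSDesign(n0=n0, n1=n1, p=p, k=k, s=s, size=size)


@dataclass(frozen=True)
class ObservationSchedule:
    """Randomized observation slots: ordered (weekday, 'HH:MM') entries."""

    entries: tuple[tuple[object, str], ...]
    seed: int

    def __len__(self) -> int:
        return len(self.entries)


def build_schedule(
    n: int,
    weekdays=range(7),
    hours=range(8, 18),
    seed: int = 0,
) -> ObservationSchedule:
    """Randomized observation schedule covering all weekdays and hours.

    Entries are a balanced randomized design over the (weekday × hour) grid:
    every cell is scheduled floor(n/G) times, the remaining n mod G slots are
    drawn without replacement, the order is shuffled, and minutes within each
    hour are uniform.  Deterministic for a given seed; every weekday and
    every whole hour is guaranteed to appear whenever n ≥ G (grid size).
    """
    weekdays = list(weekdays)
    hours = [int(h) for h in hours]
    if not weekdays or not hours:
        raise DesignError("weekday list and hour range must be non-empty")
    if n < 1:
        raise DesignError("schedule length n must be ≥ 1")
    rng = np.random.default_rng(seed)
    grid = [(d, h) for d in weekdays for h in hours]
    g = len(grid)
    cells = list(range(g)) * (n // g)
    rem = n % g
    if rem:
        cells.extend(rng.choice(g, size=rem, replace=False).tolist())
    order = rng.permutation(len(cells))
    minutes = rng.integers(0, 60, size=len(cells))
    entries = []
    for pos, m in zip(order, minutes):
        d, h = grid[cells[pos]]
        entries.append((d, f"{h:02d}:{int(m):02d}"))
    return ObservationSchedule(entries=tuple(entries), seed=seed)
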