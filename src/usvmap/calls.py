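"""Band classification of ultrasonic vocalizations (USVs).

Rat USVs carry affective valence: long, narrow-band "22-kHz" calls signal a
negative state, short "50-kHz" calls accompany approach and play.  Detected
calls are classified by the detector-reported principal frequency and call
duration into *aversive* (19-33 kHz, 0.5-5 s) and *pro-social* (40-60 kHz,
up to 1 s) categories; everything else is *other* and is reported separately
but excluded from the aversive/pro-social statistics.

All band bounds are inclusive; the pro-social duration interval is open at
zero.  Frequency modulation within a call is ignored — only the principal
frequency of the whole call is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .errors import ConfigError
from .io_formats import CallEvent

Category = Literal["aversive", "prosocial", "other"]
CATEGORIES: tuple[Category, ...] = ("aversive", "prosocial", "other")


@dataclass(frozen=True)
class BandCriteria:
    """Frequency (kHz) and duration (s) bands defining the two call classes.

    Intervals are (lo, hi) with inclusive bounds, except the pro-social
    duration where the lower bound 0 is exclusive.
    """

    aversive_freq: tuple[float, float] = (19.0, 33.0)
    aversive_dur: tuple[float, float] = (0.5, 5.0)
    prosocial_freq: tuple[float, float] = (40.0, 60.0)
    prosocial_dur: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("aversive_freq", "aversive_dur", "prosocial_freq", "prosocial_dur"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ConfigError(f"{name} must be a finite interval with lo < hi, got {(lo, hi)}")
        a, p = self.aversive_freq, self.prosocial_freq
        if max(a[0], p[0]) <= min(a[1], p[1]):
            raise ConfigError("aversive and prosocial frequency bands must be disjoint")


@dataclass(frozen=True)
class ClassifiedCall:
    """A call event with its valence category."""

    event: CallEvent
    category: Category


def classify_call(event: CallEvent, criteria: BandCriteria = BandCriteria()) -> Category:
    """Categorize one call from its principal frequency and duration.

    Total on valid events: aversive iff frequency and duration both fall in
    the aversive band, pro-social likewise (duration in (0, 1] by default),
    otherwise other.  Valid criteria make the categories mutually exclusive.
    """
    f, d = event.principal_freq, event.duration
    af, ad = criteria.aversive_freq, criteria.aversive_dur
    pf, pd = criteria.prosocial_freq, criteria.prosocial_dur
    if af[0] <= f <= af[1] and ad[0] <= d <= ad[1]:
        return "aversive"
    if pf[0] <= f <= pf[1] and pd[0] < d <= pd[1]:
        return "prosocial"
    return "other"


def classify_calls(
    events: Iterable[CallEvent], criteria: BandCriteria = BandCriteria()
) -> list[ClassifiedCall]:
    return [ClassifiedCall(e, classify_call(e, criteria)) for e in events]


@dataclass(frozen=True)
class CallAggregate:
    """Count and cumulative duration of one call category."""

    category: Category
    n_calls: int
    total_duration: float

    def __post_init__(self) -> None:
        if self.n_calls < 0 or self.total_duration < 0:
            raise ValueError("aggregate must be non-negative")
        if (self.n_calls == 0) != (self.total_duration == 0.0):
            raise ValueError("total_duration must be 0 iff n_calls is 0")


def aggregate_calls(classified: Sequence[ClassifiedCall]) -> list[CallAggregate]:
    """One aggregate per category present, in fixed category order."""
    out = []
    for cat in CATEGORIES:
        sel = [c for c in classified if c.category == cat]
        if sel:
            out.append(CallAggregate(cat, len(sel), sum(c.event.duration for c in sel)))
    return out


def overlap_fraction(classified: Sequence[ClassifiedCall]) -> float:
    """Fraction of calls whose time interval overlaps any other call's.

    Overlap requires positive-length intersection (intervals touching only
    at an endpoint do not overlap); the relation is symmetric, so both
    members of an overlapping pair are counted.  Calls are few per session,
    so the quadratic pairwise check is fine.
    """
    n = len(classified)
    if n == 0:
        return 0.0
    iv = [(c.event.t_start, c.event.t_end) for c in classified]
    overlapping = 0
    for i in range(n):
        a0, a1 = iv[i]
        for j in range(n):
            if j != i and iv[j][0] < a1 and a0 < iv[j][1]:
                overlapping += 1
                break
    return overlapping / n
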