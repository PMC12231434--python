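"""Locomotor metrics from a single-animal trajectory.

Provides position interpolation (the primitive that call localization
needs), total path length, freezing-episode detection, and region occupancy.

Freezing is operationalized as behavioral immobility: the centroid speed —
central-difference velocity smoothed by a moving average — stays below a
threshold for at least a minimum duration.  The tracker used in the original
workflow does this internally with unpublished constants, so all three
parameters are explicit and configurable here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .errors import ConfigError, InsufficientDataError
from .io_formats import Trajectory

if TYPE_CHECKING:  # pragma: no cover
    from .zoning import ArenaGeometry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FreezingParams:
    """Immobility detection constants.

    speed_threshold : cm/s
        Smoothed centroid speed below which the animal counts as immobile.
    min_duration : s
        Shortest immobile interval reported as a freezing episode.
    smoothing_window : s
        Width of the moving-average filter applied to instantaneous speed.
    """

    speed_threshold: float = 2.0
    min_duration: float = 1.0
    smoothing_window: float = 0.2

    def __post_init__(self) -> None:
        if min(self.speed_threshold, self.min_duration, self.smoothing_window) <= 0:
            raise ConfigError("freezing parameters must all be > 0")


@dataclass(frozen=True)
class FreezingEpisode:
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def position_at(traj: Trajectory, t: float) -> tuple[float, float]:
    """Linearly interpolated position at time ``t``.

    Exact at sample times; raises for ``t`` outside the track span (the
    caller decides the drop policy).
    """
    if not (traj.t[0] <= t <= traj.t[-1]):
        raise ValueError(f"t={t} outside track span [{traj.t[0]}, {traj.t[-1]}]")
    return (float(np.interp(t, traj.t, traj.x)), float(np.interp(t, traj.t, traj.y)))


def path_length(traj: Trajectory) -> float:
    """Total distance traveled: sum of straight segments between samples (cm)."""
    return float(np.sum(np.hypot(np.diff(traj.x), np.diff(traj.y))))


def speeds(traj: Trajectory, smoothing_window: float | None = None) -> np.ndarray:
    """Instantaneous centroid speed (cm/s) at each sample.

    Central differences in the interior, one-sided at the ends; optionally
    smoothed by a moving average of the given width (s).
    """
    if len(traj) < 2:
        raise InsufficientDataError("need at least 2 samples for speed")
    v = np.empty(len(traj))
    v[1:-1] = np.hypot(traj.x[2:] - traj.x[:-2], traj.y[2:] - traj.y[:-2]) / (traj.t[2:] - traj.t[:-2])
    v[0] = np.hypot(traj.x[1] - traj.x[0], traj.y[1] - traj.y[0]) / (traj.t[1] - traj.t[0])
    v[-1] = np.hypot(traj.x[-1] - traj.x[-2], traj.y[-1] - traj.y[-2]) / (traj.t[-1] - traj.t[-2])
    if smoothing_window is not None:
        dt = float(np.median(np.diff(traj.t)))
        k = max(1, int(round(smoothing_window / dt)))
        if k > 1:
            kernel = np.ones(k) / k
            # reflect-pad so the average stays unbiased at the edges
            pad = k // 2
            vp = np.pad(v, pad, mode="edge")
            v = np.convolve(vp, kernel, mode="same")[pad : pad + len(traj)]
    return v


def detect_freezing(traj: Trajectory, params: FreezingParams = FreezingParams()) -> list[FreezingEpisode]:
    """Maximal immobile intervals of at least ``min_duration`` seconds.

    Episodes are disjoint and sorted.  Requires the sampling rate to resolve
    the smoothing window (at least two samples per window).
    """
    if len(traj) < 2:
        return []
    rate = traj.nominal_rate or 1.0 / np.median(np.diff(traj.t))
    if rate < 2.0 / params.smoothing_window:
        raise ConfigError(
            f"sampling rate {rate:.3g} Hz too low for a {params.smoothing_window} s smoothing window"
        )
    v = speeds(traj, params.smoothing_window)
    below = v < params.speed_threshold
    episodes: list[FreezingEpisode] = []
    i = 0
    n = len(below)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            t0, t1 = float(traj.t[i]), float(traj.t[j])
            if t1 - t0 >= params.min_duration:
                episodes.append(FreezingEpisode(t0, t1))
            i = j + 1
        else:
            i += 1
    return episodes


def freezing_time(episodes: list[FreezingEpisode]) -> float:
    return float(sum(e.duration for e in episodes))


def occupancy(traj: Trajectory, geometry: "ArenaGeometry") -> dict[str, float]:
    """Sample-interval-weighted residence time (s) per compartment and zone.

    Each sample carries half the interval to each neighbour (midpoint rule),
    so compartment times sum exactly to the track span, and so do the
    near/distant zone times.  Out-of-arena samples (tracking glitches) are
    clamped to the boundary with a warning, preserving time conservation.
    """
    if geometry is None:
        raise ConfigError("geometry required for occupancy")
    if len(traj) < 2:
        raise InsufficientDataError("need at least 2 samples for occupancy")
    x, y = traj.x, traj.y
    inside = (
        (x >= geometry.arena.xmin)
        & (x <= geometry.arena.xmax)
        & (y >= geometry.arena.ymin)
        & (y <= geometry.arena.ymax)
    )
    if not inside.all():
        logger.warning(
            "%s: clamped %d out-of-arena samples", traj.session_id, int((~inside).sum())
        )
        x, y = geometry.clamp(x, y)

    dt = np.diff(traj.t)
    w = np.empty(len(traj))
    w[0] = dt[0] / 2
    w[-1] = dt[-1] / 2
    w[1:-1] = (dt[:-1] + dt[1:]) / 2

    comp = geometry.compartment_of(x, y)
    near = geometry.is_near(x, y)
    out: dict[str, float] = {}
    for c in geometry.compartments:
        out[c] = float(w[comp == c].sum())
    out["near"] = float(w[near].sum())
    out["distant"] = float(w[~near].sum())
    return out
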