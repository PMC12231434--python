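"""Arena geometry, near/distant zoning, and call-to-trajectory localization.

The three-chamber apparatus is a square arena split by two partition walls
into two stimulus chambers and a central corridor.  Each chamber holds a
perforated container that houses (or not) a stimulus animal.  The *near*
zone is the vicinity of either container — the container footprint expanded
by a configurable buffer distance (a Euclidean Minkowski expansion, boundary
inclusive); everything else inside the arena is the *distant* zone.

Coordinates are centimetres, origin at the arena's lower-left corner, y
increasing upward.  Times are seconds from session start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Literal, Sequence

import numpy as np

from .errors import ConfigError

if TYPE_CHECKING:  # pragma: no cover
    from .calls import ClassifiedCall
    from .io_formats import Trajectory

logger = logging.getLogger(__name__)

Zone = Literal["near", "distant"]
ZONES: tuple[Zone, ...] = ("near", "distant")

#: Arena side length (cm) of the apparatus the defaults model.
DEFAULT_ARENA_SIZE = 60.0
#: Stimulus-container footprint, width x height (cm).
DEFAULT_CONTAINER_SIZE = (15.0, 20.0)
#: Near-zone buffer around the container footprint (cm).
DEFAULT_NEAR_BUFFER = 10.0
#: Width of the central corridor between the two chambers (cm).
DEFAULT_CORRIDOR_WIDTH = 12.0


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in arena coordinates (cm)."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ConfigError(f"degenerate rectangle: {self}")

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.xmin + self.xmax), 0.5 * (self.ymin + self.ymax))

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    def contains(self, other: "Rect") -> bool:
        return (
            self.xmin <= other.xmin
            and self.ymin <= other.ymin
            and self.xmax >= other.xmax
            and self.ymax >= other.ymax
        )

    def distance(self, x, y):
        """Euclidean distance from point(s) to the rectangle (0 inside)."""
        dx = np.maximum(np.maximum(self.xmin - np.asarray(x), 0.0), np.asarray(x) - self.xmax)
        dy = np.maximum(np.maximum(self.ymin - np.asarray(y), 0.0), np.asarray(y) - self.ymax)
        return np.hypot(dx, dy)


@dataclass(frozen=True)
class ArenaGeometry:
    """Arena bounds, chamber partition, container footprints and near buffer.

    Invariants (checked at construction): each container lies inside a
    chamber; the two chambers plus the corridor tile the arena exactly;
    ``near_buffer >= 0``.
    """

    arena: Rect
    chambers: tuple[Rect, Rect]
    corridor: Rect
    containers: tuple[Rect, Rect]
    near_buffer: float = DEFAULT_NEAR_BUFFER

    def __post_init__(self) -> None:
        if self.near_buffer < 0:
            raise ConfigError("near_buffer must be >= 0")
        for c in self.containers:
            if not any(ch.contains(c) for ch in self.chambers):
                raise ConfigError(f"container {c} is not inside any chamber")
        tiles = [*self.chambers, self.corridor]
        area = sum(r.width * r.height for r in tiles)
        if abs(area - self.arena.width * self.arena.height) > 1e-6:
            raise ConfigError("chambers + corridor do not tile the arena")

    # -- point predicates ---------------------------------------------------

    def clamp(self, x, y):
        """Clip point(s) to the arena bounds."""
        return (
            np.clip(x, self.arena.xmin, self.arena.xmax),
            np.clip(y, self.arena.ymin, self.arena.ymax),
        )

    def is_near(self, x, y):
        """True where the point is within ``near_buffer`` of a container.

        Boundary inclusive: a point exactly at buffer distance is near.
        """
        d = np.minimum(self.containers[0].distance(x, y), self.containers[1].distance(x, y))
        return d <= self.near_buffer

    def compartment_of(self, x, y):
        """Compartment label(s): ``chamber_1`` / ``corridor`` / ``chamber_2``.

        The partition is by x only (the walls are vertical); boundaries are
        assigned left-to-right half-open so every point gets exactly one
        label.
        """
        x = np.asarray(x)
        out = np.where(
            x < self.chambers[0].xmax,
            "chamber_1",
            np.where(x < self.chambers[1].xmin, "corridor", "chamber_2"),
        )
        return out if out.ndim else str(out)

    @property
    def compartments(self) -> tuple[str, ...]:
        return ("chamber_1", "corridor", "chamber_2")


def default_geometry(
    arena_size: float = DEFAULT_ARENA_SIZE,
    corridor_width: float = DEFAULT_CORRIDOR_WIDTH,
    container_size: tuple[float, float] = DEFAULT_CONTAINER_SIZE,
    near_buffer: float = DEFAULT_NEAR_BUFFER,
    wall_inset: float = 2.0,
) -> ArenaGeometry:
    """Build the default apparatus: 60 x 60 cm arena, two 15 x 20 cm
    containers in diagonally opposite corners (stimulus 1 upper-left),
    central corridor, 10 cm near buffer."""
    w = h = float(arena_size)
    cw = float(corridor_width)
    x1 = (w - cw) / 2.0
    x2 = (w + cw) / 2.0
    bw, bh = container_size
    arena = Rect(0, 0, w, h)
    chambers = (Rect(0, 0, x1, h), Rect(x2, 0, w, h))
    corridor = Rect(x1, 0, x2, h)
    c1 = Rect(wall_inset, h - wall_inset - bh, wall_inset + bw, h - wall_inset)
    c2 = Rect(w - wall_inset - bw, wall_inset, w - wall_inset, wall_inset + bh)
    return ArenaGeometry(arena, chambers, corridor, (c1, c2), near_buffer)


def zone_of(p: tuple[float, float], geometry: ArenaGeometry) -> Zone:
    """Zone label of a single point: near iff within the buffered footprint
    of either container (boundary inclusive), else distant."""
    return "near" if bool(geometry.is_near(p[0], p[1])) else "distant"


# -- localization -----------------------------------------------------------


@dataclass(frozen=True)
class LocalizedCall:
    """A classified call placed on the test animal's trajectory.

    ``position``/``zone`` are present iff ``status == "ok"``.  Note the
    microphone records every animal in the room, so localization attributes
    each call to the *test* animal's position regardless of the true caller;
    calls emitted by stimulus animals are therefore mapped to wherever the
    test animal was at that moment.
    """

    call: "ClassifiedCall"
    position: tuple[float, float] | None
    zone: Zone | None
    localization_status: Literal["ok", "off_track_dropped"]

    def __post_init__(self) -> None:
        ok = self.localization_status == "ok"
        if ok != (self.position is not None) or ok != (self.zone is not None):
            raise ValueError("position/zone must be present iff status is ok")


def localize_calls(
    calls: Sequence["ClassifiedCall"],
    traj: "Trajectory",
    geometry: ArenaGeometry,
    sync_offset: float = 0.0,
) -> list[LocalizedCall]:
    """Assign each call to the track point at its onset time.

    The call onset ``t_start + sync_offset`` is linearly interpolated on the
    trajectory; onsets outside the track span are kept with status
    ``off_track_dropped`` (a status, not an error).  Output order matches
    input order.
    """
    out: list[LocalizedCall] = []
    t = np.asarray([c.event.t_start for c in calls], dtype=float) + sync_offset
    if len(calls) == 0:
        return out
    in_span = (t >= traj.t[0]) & (t <= traj.t[-1])
    xs = np.interp(t, traj.t, traj.x)
    ys = np.interp(t, traj.t, traj.y)
    near = geometry.is_near(xs, ys)
    n_dropped = 0
    for i, c in enumerate(calls):
        if in_span[i]:
            zone: Zone = "near" if near[i] else "distant"
            out.append(LocalizedCall(c, (float(xs[i]), float(ys[i])), zone, "ok"))
        else:
            out.append(LocalizedCall(c, None, None, "off_track_dropped"))
            n_dropped += 1
    if n_dropped:
        logger.warning(
            "%d of %d calls fell outside the track span and were dropped",
            n_dropped,
            len(calls),
        )
    return out


@dataclass
class ZonalSummary:
    """Per-(category, zone) call counts and cumulative durations (s) over
    status-ok localized calls, plus the number of dropped calls."""

    counts: dict[tuple[str, Zone], int] = field(default_factory=dict)
    durations: dict[tuple[str, Zone], float] = field(default_factory=dict)
    n_dropped: int = 0

    def count(self, category: str, zone: Zone) -> int:
        return self.counts.get((category, zone), 0)

    def duration(self, category: str, zone: Zone) -> float:
        return self.durations.get((category, zone), 0.0)

    def category_count(self, category: str) -> int:
        return sum(v for (c, _z), v in self.counts.items() if c == category)


def zonal_summary(localized: Iterable[LocalizedCall]) -> ZonalSummary:
    """Exact counts and duration sums per (category, zone) over ok calls."""
    s = ZonalSummary()
    for lc in localized:
        if lc.localization_status != "ok":
            s.n_dropped += 1
            continue
        key = (lc.call.category, lc.zone)
        s.counts[key] = s.counts.get(key, 0) + 1
        s.durations[key] = s.durations.get(key, 0.0) + lc.call.event.duration
    return s
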