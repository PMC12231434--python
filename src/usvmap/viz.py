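"""Composite track-overlay maps with valence-colored call pins.

Every session's track is drawn semi-transparently on the arena outline and
superimposed; each localized call puts a pin at its onset position —
blue for aversive, red for pro-social (gray for other).  Sessions where the
stimulus-1 container sat on the other side (sides are alternated between
animals) are mirrored — axis-aligned flips only, never rotation, so wall
identity is preserved — so that stimulus 1 always renders in the upper-left
quadrant before overlay.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from .errors import ConfigError
from .io_formats import Trajectory
from .zoning import ArenaGeometry, LocalizedCall, Rect

PIN_COLORS = {"aversive": "tab:blue", "prosocial": "tab:red", "other": "0.6"}


@dataclass(frozen=True)
class MapStyle:
    """Rendering style; track_alpha 0.25 reproduces the 25%-transparent
    overlay convention.  Stimulus 1 is normalized to the upper-left."""

    track_alpha: float = 0.25
    aversive_pin_color: str = PIN_COLORS["aversive"]
    prosocial_pin_color: str = PIN_COLORS["prosocial"]
    other_pin_color: str = PIN_COLORS["other"]
    pin_size: float = 18.0
    track_color: str = "0.2"
    dpi: int = 150

    def __post_init__(self) -> None:
        if not (0.0 < self.track_alpha <= 1.0):
            raise ConfigError("track_alpha must be in (0, 1]")

    def pin_color(self, category: str) -> str:
        return {
            "aversive": self.aversive_pin_color,
            "prosocial": self.prosocial_pin_color,
        }.get(category, self.other_pin_color)


@dataclass
class MapResult:
    figure: "plt.Figure"
    pin_counts: dict[str, int]
    flipped: list[tuple[bool, bool]]  # per-session (mirror_x, mirror_y)

    @property
    def n_pins(self) -> int:
        return sum(self.pin_counts.values())


def _flip_needed(stim1: Rect, arena: Rect) -> tuple[bool, bool]:
    cx, cy = stim1.center
    ax, ay = arena.center
    return (cx > ax, cy < ay)


def _mirror(vals, lo, hi, do):
    return (lo + hi) - vals if do else vals


def composite_track_map(
    sessions: Sequence[tuple[Trajectory, Sequence[LocalizedCall]]],
    geometry: ArenaGeometry,
    style: MapStyle = MapStyle(),
    out_png: str | Path | None = None,
    out_svg: str | Path | None = None,
    flip: bool = True,
    title: str | None = None,
) -> MapResult:
    """Overlay session tracks and call pins on the arena.

    A session's own stimulus-1 container index may be recorded in
    ``trajectory.meta["stim1_container"]`` (default 0); the session is
    mirrored horizontally/vertically as needed to bring that container to
    the upper-left quadrant.  Pins are drawn only for status-ok calls, one
    scatter collection per category, so the renderer's object counts are
    testable.  Output is deterministic for fixed inputs.
    """
    if len(sessions) == 0:
        raise ConfigError("composite_track_map needs at least one session")
    arena = geometry.arena
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.set_xlim(arena.xmin, arena.xmax)
    ax.set_ylim(arena.ymin, arena.ymax)
    ax.set_aspect("equal")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    if title:
        ax.set_title(title)

    for rect, ls in ((geometry.containers[0], "-"), (geometry.containers[1], "-")):
        ax.add_patch(
            Rectangle(
                (rect.xmin, rect.ymin), rect.width, rect.height,
                fill=False, edgecolor="k", linestyle=ls, linewidth=1.2,
            )
        )
    for ch in geometry.chambers:
        for xwall in (ch.xmin, ch.xmax):
            if arena.xmin < xwall < arena.xmax:
                ax.axvline(xwall, color="0.5", linewidth=0.8, linestyle=":")

    flips: list[tuple[bool, bool]] = []
    pins: dict[str, list[tuple[float, float]]] = {c: [] for c in PIN_COLORS}
    for traj, localized in sessions:
        stim1 = geometry.containers[int(traj.meta.get("stim1_container", 0))]
        fx, fy = _flip_needed(stim1, arena) if flip else (False, False)
        flips.append((fx, fy))
        xs = _mirror(traj.x, arena.xmin, arena.xmax, fx)
        ys = _mirror(traj.y, arena.ymin, arena.ymax, fy)
        ax.plot(xs, ys, color=style.track_color, alpha=style.track_alpha, linewidth=0.8)
        for lc in localized:
            if lc.localization_status != "ok":
                continue
            px = _mirror(lc.position[0], arena.xmin, arena.xmax, fx)
            py = _mirror(lc.position[1], arena.ymin, arena.ymax, fy)
            pins[lc.call.category].append((px, py))

    pin_counts: dict[str, int] = {}
    for cat, pts in pins.items():
        if not pts:
            continue
        ax.scatter(
            [p[0] for p in pts], [p[1] for p in pts],
            s=style.pin_size, c=style.pin_color(cat), marker="v",
            label=cat, zorder=3, edgecolors="none",
        )
        pin_counts[cat] = len(pts)
    if pin_counts:
        ax.legend(loc="lower left", fontsize=8)

    if out_png is not None:
        fig.savefig(out_png, dpi=style.dpi)
    if out_svg is not None:
        with plt.rc_context({"svg.hashsalt": "usvmap"}):
            fig.savefig(out_svg, metadata={"Date": None})
    return MapResult(fig, pin_counts, flips)
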