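"""Tabular and config I/O: track tables, call tables, arena geometry, summaries.

Dialects
--------
Video trackers and USV detectors export CSVs with tool-specific headers.
Column resolution goes through a *dialect*: an ordered list of candidate
header names per logical column, matched case-insensitively after stripping
whitespace.  Two presets ship — a tracker-style preset (time/x/y) and a
detector-style preset (begin/end/duration/principal frequency) — and both
are user-overridable, since export schemas vary between tool versions.

Conventions: CSV is RFC-4180 UTF-8 with "." decimal; coordinates are cm with
origin at the arena's lower-left corner, y up; times are seconds from
session start (default session length 600 s).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, InsufficientDataError
from .zoning import (
    DEFAULT_ARENA_SIZE,
    DEFAULT_CONTAINER_SIZE,
    DEFAULT_CORRIDOR_WIDTH,
    DEFAULT_NEAR_BUFFER,
    ArenaGeometry,
    Rect,
    default_geometry,
)

logger = logging.getLogger(__name__)

#: Default session length (s): each test session lasts 10 min.
DEFAULT_SESSION_LENGTH = 600.0


# -- domain types ------------------------------------------------------------


@dataclass(frozen=True)
class TrackSample:
    """One tracked position: time (s from session start), x and y (cm)."""

    t: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.t < 0 or not all(map(math.isfinite, (self.t, self.x, self.y))):
            raise ValueError(f"invalid track sample {self}")


@dataclass(frozen=True)
class LoadReport:
    """Row accounting for one table load; rows_in = rows_kept + rows_dropped."""

    rows_in: int
    rows_kept: int
    rows_dropped: int

    def __post_init__(self) -> None:
        if self.rows_in != self.rows_kept + self.rows_dropped:
            raise ValueError("load report does not reconcile")


@dataclass
class Trajectory:
    """Time-ordered positions of one animal for one session.

    Positions are stored as numpy arrays (``t`` strictly increasing); the
    ``samples`` property offers a record view.  ``meta`` carries optional
    provenance (e.g. the simulator records its generating freeze bouts).
    """

    session_id: str
    subject_id: str
    strain_label: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    nominal_rate: float | None = None
    meta: dict = field(default_factory=dict)
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) == 0:
            raise ValueError("empty trajectory")
        if np.any(~np.isfinite(self.t)) or np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y)):
            raise ValueError("non-finite values in trajectory")
        if self.t[0] < 0 or np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be non-negative and strictly increasing")
        if self.nominal_rate is None and len(self.t) > 1:
            self.nominal_rate = float(1.0 / np.median(np.diff(self.t)))

    def __len__(self) -> int:
        return len(self.t)

    @property
    def span(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def samples(self) -> list[TrackSample]:
        return [TrackSample(float(a), float(b), float(c)) for a, b, c in zip(self.t, self.x, self.y)]


@dataclass(frozen=True)
class CallEvent:
    """One detected USV: onset/offset (s), duration (s), principal frequency (kHz)."""

    call_id: str
    t_start: float
    t_end: float
    duration: float
    principal_freq: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError(f"call {self.call_id}: t_end must exceed t_start")
        if abs(self.duration - (self.t_end - self.t_start)) > 1e-3:
            raise ValueError(f"call {self.call_id}: duration inconsistent with onset/offset")
        if not self.principal_freq > 0:
            raise ValueError(f"call {self.call_id}: principal_freq must be > 0")


@dataclass(frozen=True)
class SucroseRecord:
    """One fluid-consumption measurement: rat x phase (day/night) x fluid."""

    rat_id: str
    strain_label: str
    phase: Literal["day", "night"]
    fluid: Literal["water", "sucrose"]
    volume: float

    def __post_init__(self) -> None:
        if self.phase not in ("day", "night") or self.fluid not in ("water", "sucrose"):
            raise ValueError(f"invalid phase/fluid in {self}")
        if self.volume < 0:
            raise ValueError("volume must be >= 0")


# -- session summary (serialized here; consumed by the statistics layer) -----

SUMMARY_CATEGORIES = ("aversive", "prosocial", "other")
SUMMARY_ZONES = ("near", "distant")


@dataclass
class SessionSummary:
    """Per-animal session aggregates feeding the statistical battery."""

    session_id: str
    subject_id: str
    strain_label: str
    distance_cm: float
    freezing_total_s: float
    freezing_n: int
    occupancy: dict[str, float]
    call_counts: dict[tuple[str, str], int]
    call_durations: dict[tuple[str, str], float]
    n_calls_dropped: int = 0

    def count(self, category: str, zone: str | None = None) -> int:
        if zone is None:
            return sum(v for (c, _z), v in self.call_counts.items() if c == category)
        return self.call_counts.get((category, zone), 0)

    def duration(self, category: str, zone: str | None = None) -> float:
        if zone is None:
            return sum(v for (c, _z), v in self.call_durations.items() if c == category)
        return self.call_durations.get((category, zone), 0.0)


# -- dialects ----------------------------------------------------------------


@dataclass(frozen=True)
class TrackDialect:
    """Candidate header names for the logical track columns."""

    time: tuple[str, ...] = ("time", "t", "time (s)", "time_s", "sec")
    x: tuple[str, ...] = ("x", "pos x", "x (cm)", "x_cm", "pos_x")
    y: tuple[str, ...] = ("y", "pos y", "y (cm)", "y_cm", "pos_y")


@dataclass(frozen=True)
class CallDialect:
    """Candidate header names for the logical call-table columns."""

    begin: tuple[str, ...] = ("begin time (s)", "begin_time", "begin", "start", "t_start", "start_time")
    end: tuple[str, ...] = ("end time (s)", "end_time", "end", "stop", "t_end", "stop_time")
    duration: tuple[str, ...] = ("call length (s)", "duration", "dur", "call_length")
    freq: tuple[str, ...] = (
        "principal frequency (khz)",
        "principal_frequency",
        "principal_freq",
        "freq_khz",
        "frequency",
    )


#: Tracker-style preset (time/x/y export).
TRACK_DIALECT = TrackDialect()
#: Detector-style preset (begin/end/length/principal-frequency export).
CALL_DIALECT = CallDialect()


def _resolve(columns: Sequence[str], candidates: Sequence[str], logical: str) -> str:
    norm = {str(c).strip().lower(): c for c in columns}
    for cand in candidates:
        if cand in norm:
            return norm[cand]
    raise FormatError(
        f"required column '{logical}' not found; tried {list(candidates)}, "
        f"table has {list(columns)}"
    )


def load_dialects(path: str | Path) -> tuple[TrackDialect, CallDialect]:
    """Load dialect overrides from a YAML file with ``track:``/``calls:`` keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    tr = {k: tuple(s.lower() for s in v) for k, v in (raw.get("track") or {}).items()}
    ca = {k: tuple(s.lower() for s in v) for k, v in (raw.get("calls") or {}).items()}
    try:
        return TrackDialect(**tr), CallDialect(**ca)
    except TypeError as exc:
        raise ConfigError(f"unknown dialect key in {path}: {exc}") from exc


# -- readers -----------------------------------------------------------------


def read_track_table(
    path: str | Path,
    dialect: TrackDialect = TRACK_DIALECT,
    session_id: str | None = None,
    subject_id: str = "",
    strain_label: str = "",
) -> Trajectory:
    """Read a tracker export into a Trajectory.

    Rows with non-finite coordinates (and rows duplicating an earlier
    timestamp) are dropped and counted in the attached load report; samples
    are returned sorted ascending in time.
    """
    path = Path(path)
    df = pd.read_csv(path)
    tc = _resolve(df.columns, dialect.time, "time")
    xc = _resolve(df.columns, dialect.x, "x")
    yc = _resolve(df.columns, dialect.y, "y")
    rows_in = len(df)
    sub = df[[tc, xc, yc]].apply(pd.to_numeric, errors="coerce")
    sub = sub.dropna()
    sub = sub[np.isfinite(sub).all(axis=1)]
    sub = sub.sort_values(tc, kind="mergesort")
    sub = sub[~sub[tc].duplicated(keep="first")]
    rows_kept = len(sub)
    if rows_kept < 2:
        raise InsufficientDataError(f"{path}: {rows_kept} valid rows; need at least 2")
    report = LoadReport(rows_in, rows_kept, rows_in - rows_kept)
    if report.rows_dropped:
        logger.warning("%s: dropped %d invalid track rows", path, report.rows_dropped)
    return Trajectory(
        session_id=session_id or path.stem,
        subject_id=subject_id,
        strain_label=strain_label,
        t=sub[tc].to_numpy(),
        x=sub[xc].to_numpy(),
        y=sub[yc].to_numpy(),
        load_report=report,
    )


def read_call_table(path: str | Path, dialect: CallDialect = CALL_DIALECT) -> list[CallEvent]:
    """Read a detector export into CallEvents sorted by onset time.

    Duration is reconciled from begin/end when both are present.  Rows with
    ``t_end <= t_start`` are rejected with a warning.  Frequencies are kHz;
    a table whose median frequency is below 1 almost certainly uses MHz and
    is refused outright rather than silently misclassified.
    """
    path = Path(path)
    df = pd.read_csv(path)
    bc = _resolve(df.columns, dialect.begin, "begin time")
    fc = _resolve(df.columns, dialect.freq, "principal frequency")
    cols = {str(c).strip().lower() for c in df.columns}
    ec = dc = None
    if any(c in cols for c in dialect.end):
        ec = _resolve(df.columns, dialect.end, "end time")
    if any(c in cols for c in dialect.duration):
        dc = _resolve(df.columns, dialect.duration, "duration")
    if ec is None and dc is None:
        raise FormatError(f"{path}: need an end-time or a duration column")

    begin = pd.to_numeric(df[bc], errors="coerce")
    freq = pd.to_numeric(df[fc], errors="coerce")
    if ec is not None:
        end = pd.to_numeric(df[ec], errors="coerce")
    else:
        end = begin + pd.to_numeric(df[dc], errors="coerce")
    valid_freq = freq[np.isfinite(freq)]
    if len(valid_freq) and float(np.median(valid_freq)) < 1.0:
        raise FormatError(
            f"{path}: median principal frequency {np.median(valid_freq):.4g} < 1; "
            "values look like MHz, expected kHz"
        )

    events: list[CallEvent] = []
    n_rejected = 0
    for i in range(len(df)):
        b, e, f = float(begin.iloc[i]), float(end.iloc[i]), float(freq.iloc[i])
        if not all(map(math.isfinite, (b, e, f))) or e <= b or f <= 0:
            n_rejected += 1
            logger.warning("%s row %d rejected (begin=%s end=%s freq=%s)", path, i, b, e, f)
            continue
        events.append(CallEvent(f"{path.stem}_{i}", b, e, e - b, f))
    events.sort(key=lambda c: c.t_start)
    if n_rejected:
        logger.warning("%s: rejected %d invalid call rows", path, n_rejected)
    return events


def _rect_from_mapping(m: Mapping, arena: Rect, what: str) -> Rect:
    if {"xmin", "ymin", "xmax", "ymax"} <= set(m):
        r = Rect(float(m["xmin"]), float(m["ymin"]), float(m["xmax"]), float(m["ymax"]))
    elif "center" in m:
        cx, cy = (float(v) for v in m["center"])
        w = float(m.get("width", DEFAULT_CONTAINER_SIZE[0]))
        h = float(m.get("height", DEFAULT_CONTAINER_SIZE[1]))
        r = Rect(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
    else:
        raise ConfigError(f"{what}: give xmin/ymin/xmax/ymax or center/width/height")
    if not arena.contains(r):
        raise ConfigError(f"{what} {r} lies outside the arena {arena}")
    return r


def read_arena_config(path: str | Path | None) -> ArenaGeometry:
    """Read arena geometry from a YAML config; omitted fields take the
    defaults (60 x 60 cm arena, 15 x 20 cm containers, 10 cm near buffer).

    ``None`` or an empty file yields the default geometry.
    """
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: arena config must be a mapping")
    arena_raw = raw.get("arena") or {}
    size = float(arena_raw.get("size", arena_raw.get("width", DEFAULT_ARENA_SIZE)))
    corridor_w = float(raw.get("corridor_width", DEFAULT_CORRIDOR_WIDTH))
    buffer = float(raw.get("near_buffer", DEFAULT_NEAR_BUFFER))
    geo = default_geometry(arena_size=size, corridor_width=corridor_w, near_buffer=buffer)
    if "containers" in raw:
        conts = raw["containers"]
        if len(conts) != 2:
            raise ConfigError("exactly two containers are required")
        rects = tuple(_rect_from_mapping(c, geo.arena, f"container {i + 1}") for i, c in enumerate(conts))
        geo = ArenaGeometry(geo.arena, geo.chambers, geo.corridor, rects, buffer)
    return geo


# -- writers -----------------------------------------------------------------


def write_track_table(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame({"time": traj.t, "x": traj.x, "y": traj.y}).to_csv(path, index=False, lineterminator="\n")


def write_call_table(events: Iterable[CallEvent], path: str | Path) -> None:
    rows = [
        {
            "begin_time": e.t_start,
            "end_time": e.t_end,
            "duration": e.duration,
            "principal_frequency": e.principal_freq,
        }
        for e in events
    ]
    cols = ["begin_time", "end_time", "duration", "principal_frequency"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, lineterminator="\n")


def write_sucrose_table(records: Iterable[SucroseRecord], path: str | Path) -> None:
    rows = [
        {
            "rat_id": r.rat_id,
            "strain": r.strain_label,
            "phase": r.phase,
            "fluid": r.fluid,
            "volume": r.volume,
        }
        for r in records
    ]
    cols = ["rat_id", "strain", "phase", "fluid", "volume"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, lineterminator="\n")


def read_sucrose_table(path: str | Path) -> list[SucroseRecord]:
    df = pd.read_csv(path)
    need = {"rat_id", "strain", "phase", "fluid", "volume"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: sucrose table needs columns {sorted(need)}")
    return [
        SucroseRecord(str(r.rat_id), str(r.strain), str(r.phase), str(r.fluid), float(r.volume))
        for r in df.itertuples()
    ]


SUMMARY_COLUMNS = (
    ["session_id", "subject_id", "strain_label", "distance_cm", "freezing_n", "freezing_total_s"]
    + [f"occ_{r}" for r in ("chamber_1", "corridor", "chamber_2", "near", "distant")]
    + [f"{k}_{c}_{z}" for c in SUMMARY_CATEGORIES for z in SUMMARY_ZONES for k in ("n", "dur")]
    + ["n_calls_dropped"]
)

LOCALIZED_COLUMNS = (
    "session_id",
    "call_id",
    "t_start",
    "t_end",
    "duration",
    "principal_freq",
    "category",
    "status",
    "x",
    "y",
    "zone",
)


def read_summary_table(path: str | Path) -> list[SessionSummary]:
    """Inverse of the session-summary CSV written by write_summary_tables."""
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing summary columns {sorted(missing)}")
    out = []
    for r in df.itertuples():
        occupancy = {k: float(getattr(r, f"occ_{k}")) for k in ("chamber_1", "corridor", "chamber_2", "near", "distant")}
        counts = {}
        durs = {}
        for c in SUMMARY_CATEGORIES:
            for z in SUMMARY_ZONES:
                counts[(c, z)] = int(getattr(r, f"n_{c}_{z}"))
                durs[(c, z)] = float(getattr(r, f"dur_{c}_{z}"))
        out.append(
            SessionSummary(
                session_id=str(r.session_id),
                subject_id=str(r.subject_id),
                strain_label=str(r.strain_label),
                distance_cm=float(r.distance_cm),
                freezing_total_s=float(r.freezing_total_s),
                freezing_n=int(r.freezing_n),
                occupancy=occupancy,
                call_counts=counts,
                call_durations=durs,
                n_calls_dropped=int(r.n_calls_dropped),
            )
        )
    return out


def write_summary_tables(
    summaries: Sequence[SessionSummary],
    localized,
    out_dir: str | Path,
    localized_session_ids: Sequence[str] | None = None,
) -> dict[str, Path]:
    """Write per-session aggregates and per-call localized records.

    Column order is fixed and rows are sorted, so identical input yields
    byte-identical files.  ``localized`` is a flat list of LocalizedCall;
    ``localized_session_ids`` optionally tags each with its session.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sorted(summaries, key=lambda s: s.session_id):
        row = {
            "session_id": s.session_id,
            "subject_id": s.subject_id,
            "strain_label": s.strain_label,
            "distance_cm": s.distance_cm,
            "freezing_n": s.freezing_n,
            "freezing_total_s": s.freezing_total_s,
            "n_calls_dropped": s.n_calls_dropped,
        }
        for r, v in s.occupancy.items():
            row[f"occ_{r}"] = v
        for c in SUMMARY_CATEGORIES:
            for z in SUMMARY_ZONES:
                row[f"n_{c}_{z}"] = s.call_counts.get((c, z), 0)
                row[f"dur_{c}_{z}"] = s.call_durations.get((c, z), 0.0)
        rows.append(row)
    sum_path = out_dir / "session_summaries.csv"
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(sum_path, index=False, lineterminator="\n")

    if localized_session_ids is None:
        localized_session_ids = [""] * len(localized)
    lrows = []
    for sid, lc in zip(localized_session_ids, localized):
        e = lc.call.event
        lrows.append(
            {
                "session_id": sid,
                "call_id": e.call_id,
                "t_start": e.t_start,
                "t_end": e.t_end,
                "duration": e.duration,
                "principal_freq": e.principal_freq,
                "category": lc.call.category,
                "status": lc.localization_status,
                "x": lc.position[0] if lc.position else "",
                "y": lc.position[1] if lc.position else "",
                "zone": lc.zone or "",
            }
        )
    loc_path = out_dir / "localized_calls.csv"
    pd.DataFrame(lrows, columns=list(LOCALIZED_COLUMNS)).to_csv(loc_path, index=False, lineterminator="\n")
    return {"summaries": sum_path, "localized": loc_path}
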