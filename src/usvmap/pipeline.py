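"""End-to-end orchestration: read or simulate, classify, localize, summarize,
test, render.

A run is a pure function of its resolved configuration (including the seed):
re-running with the same config reproduces every CSV byte-identically.  The
resolved configuration is written alongside the outputs, and a per-stage log
records row counts so the conservation identity
``calls_in = classified = localized_ok + dropped`` is auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io_formats as io
from .calls import BandCriteria, ClassifiedCall, classify_calls
from .errors import ConfigError, UsvMapError
from .io_formats import SessionSummary, Trajectory
from .stats import (
    TestResult,
    kruskal_wallis,
    rm_anova_strain_by_measurement,
    spearman,
    sucrose_summary,
    wilcoxon_signed_rank,
)
from .synthetic import default_config, simulate_cohort, simulate_sucrose
from .trajectories import FreezingParams, detect_freezing, freezing_time, occupancy, path_length
from .viz import MapStyle, composite_track_map
from .zoning import ArenaGeometry, LocalizedCall, localize_calls, zonal_summary

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    out_dir: str = "usvmap_out"
    # either simulate a cohort ...
    simulate: bool = False
    n_per_strain: int = 12
    session_length: float = io.DEFAULT_SESSION_LENGTH
    frame_rate: float = 25.0
    # ... or analyze session files: list of dicts with track/calls paths + ids
    sessions: list[dict] = field(default_factory=list)
    sucrose_path: str | None = None
    geometry_path: str | None = None
    near_buffer: float | None = None
    aversive_freq: tuple[float, float] = (19.0, 33.0)
    aversive_dur: tuple[float, float] = (0.5, 5.0)
    prosocial_freq: tuple[float, float] = (40.0, 60.0)
    prosocial_dur: tuple[float, float] = (0.0, 1.0)
    speed_threshold: float = 2.0
    min_freeze_duration: float = 1.0
    smoothing_window: float = 0.2
    sync_offset: float = 0.0
    seed: int = 0
    make_maps: bool = True

    def band_criteria(self) -> BandCriteria:
        return BandCriteria(
            tuple(self.aversive_freq),
            tuple(self.aversive_dur),
            tuple(self.prosocial_freq),
            tuple(self.prosocial_dur),
        )

    def freezing_params(self) -> FreezingParams:
        return FreezingParams(self.speed_threshold, self.min_freeze_duration, self.smoothing_window)


def summarize_session(
    traj: Trajectory,
    classified: list[ClassifiedCall],
    geometry: ArenaGeometry,
    freezing: FreezingParams = FreezingParams(),
    sync_offset: float = 0.0,
) -> tuple[SessionSummary, list[LocalizedCall]]:
    """Locomotor metrics + zonal call statistics for one session."""
    episodes = detect_freezing(traj, freezing)
    localized = localize_calls(classified, traj, geometry, sync_offset)
    zs = zonal_summary(localized)
    summary = SessionSummary(
        session_id=traj.session_id,
        subject_id=traj.subject_id,
        strain_label=traj.strain_label,
        distance_cm=path_length(traj),
        freezing_total_s=freezing_time(episodes),
        freezing_n=len(episodes),
        occupancy=occupancy(traj, geometry),
        call_counts=dict(zs.counts),
        call_durations=dict(zs.durations),
        n_calls_dropped=zs.n_dropped,
    )
    return summary, localized


# -- the statistical battery over a cohort of summaries -----------------------

SESSION_METRICS = {
    "distance_cm": lambda s: s.distance_cm,
    "freezing_total_s": lambda s: s.freezing_total_s,
    "freezing_n": lambda s: float(s.freezing_n),
    "n_aversive": lambda s: float(s.count("aversive")),
    "dur_aversive": lambda s: s.duration("aversive"),
    "n_prosocial": lambda s: float(s.count("prosocial")),
    "dur_prosocial": lambda s: s.duration("prosocial"),
    "time_near": lambda s: s.occupancy.get("near", 0.0),
}


def cohort_statistics(summaries: list[SessionSummary]) -> pd.DataFrame:
    """Between-strain, within-strain zonal, and correlation tests, tidy."""
    strains = sorted({s.strain_label for s in summaries})
    by_strain = {g: [s for s in summaries if s.strain_label == g] for g in strains}
    rows: list[dict] = []

    def add(test: str, metric: str, scope: str, res: TestResult) -> None:
        rows.append(
            {
                "test": test,
                "metric": metric,
                "scope": scope,
                "statistic_name": res.statistic_name,
                "statistic": res.statistic_value,
                "df": "/".join(f"{d:g}" for d in res.df),
                "p_value": res.p_value,
                "n": "/".join(str(n) for n in res.n_per_group),
                "degenerate": res.degenerate,
            }
        )

    if len(strains) >= 2:
        for metric, fn in SESSION_METRICS.items():
            groups = [[fn(s) for s in by_strain[g]] for g in strains]
            if all(len(g) > 0 for g in groups):
                add("kruskal_wallis", metric, "between:" + "|".join(strains), kruskal_wallis(groups))

    for g in strains:
        subs = by_strain[g]
        if len(subs) < 2:
            continue
        for cat in ("aversive", "prosocial"):
            near_n = [float(s.count(cat, "near")) for s in subs]
            dist_n = [float(s.count(cat, "distant")) for s in subs]
            add("wilcoxon_near_vs_distant", f"n_{cat}", g, wilcoxon_signed_rank(near_n, dist_n))
            near_d = [s.duration(cat, "near") for s in subs]
            dist_d = [s.duration(cat, "distant") for s in subs]
            add("wilcoxon_near_vs_distant", f"dur_{cat}", g, wilcoxon_signed_rank(near_d, dist_d))
        if len(subs) >= 3:
            add(
                "spearman_freezing_vs_aversive_dur",
                "freezing_total_s~dur_aversive",
                g,
                spearman([s.freezing_total_s for s in subs], [s.duration("aversive") for s in subs]),
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and write outputs under ``config.out_dir``.

    Stages: read/simulate -> classify -> track metrics -> localize -> zonal
    summary -> statistics -> maps.  Any stage failure aborts with a
    stage-named error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("usvmap")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out)
    except UsvMapError:
        raise
    except Exception as exc:  # annotate unexpected failures with the stage
        raise UsvMapError(f"pipeline failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> Path:
    geometry = io.read_arena_config(config.geometry_path)
    if config.near_buffer is not None:
        geometry = dataclasses.replace(geometry, near_buffer=config.near_buffer)
    criteria = config.band_criteria()
    freezing = config.freezing_params()

    # -- stage: inputs --------------------------------------------------------
    session_inputs: list[tuple[Trajectory, list]] = []
    sucrose_records = None
    if config.simulate:
        sim_cfg = default_config(
            config.n_per_strain,
            seed=config.seed,
            session_length=config.session_length,
            frame_rate=config.frame_rate,
        )
        sessions, manifest = simulate_cohort(sim_cfg, geometry, criteria)
        in_dir = out / "inputs"
        in_dir.mkdir(exist_ok=True)
        for s in sessions:
            io.write_track_table(s.trajectory, in_dir / f"{s.trajectory.session_id}_track.csv")
            io.write_call_table(s.calls, in_dir / f"{s.trajectory.session_id}_calls.csv")
        sucrose_records = simulate_sucrose(seed=config.seed)
        io.write_sucrose_table(sucrose_records, in_dir / "sucrose.csv")
        (in_dir / "manifest.yaml").write_text(yaml.safe_dump(_yamlable(manifest), sort_keys=True))
        # read the tables back so the analyzed path is identical to file input
        for s in sessions:
            traj = io.read_track_table(
                in_dir / f"{s.trajectory.session_id}_track.csv",
                session_id=s.trajectory.session_id,
                subject_id=s.trajectory.subject_id,
                strain_label=s.strain,
            )
            traj.meta = s.trajectory.meta
            events = io.read_call_table(in_dir / f"{s.trajectory.session_id}_calls.csv")
            session_inputs.append((traj, events))
    else:
        if not config.sessions:
            raise ConfigError("no sessions given and simulate=False")
        for entry in config.sessions:
            traj = io.read_track_table(
                entry["track"],
                session_id=entry.get("session_id"),
                subject_id=entry.get("subject_id", ""),
                strain_label=entry.get("strain", ""),
            )
            events = io.read_call_table(entry["calls"]) if entry.get("calls") else []
            session_inputs.append((traj, events))
        if config.sucrose_path:
            sucrose_records = io.read_sucrose_table(config.sucrose_path)

    # -- stage: classify / metrics / localize / summarize ---------------------
    summaries: list[SessionSummary] = []
    all_localized: list = []
    localized_sids: list[str] = []
    per_session: list[tuple[Trajectory, list]] = []
    n_in = n_classified = n_ok = n_dropped = 0
    for traj, events in session_inputs:
        classified = classify_calls(events, criteria)
        summary, localized = summarize_session(traj, classified, geometry, freezing, config.sync_offset)
        summaries.append(summary)
        all_localized.extend(localized)
        localized_sids.extend([traj.session_id] * len(localized))
        per_session.append((traj, localized))
        ok = sum(1 for lc in localized if lc.localization_status == "ok")
        n_in += len(events)
        n_classified += len(classified)
        n_ok += ok
        n_dropped += len(localized) - ok
        logger.info(
            "session %s: calls_in=%d classified=%d localized_ok=%d dropped=%d",
            traj.session_id, len(events), len(classified), ok, len(localized) - ok,
        )
    if not (n_in == n_classified == n_ok + n_dropped):
        raise UsvMapError("conservation violated: calls_in != localized_ok + dropped")
    logger.info("cohort: calls_in=%d classified=%d ok=%d dropped=%d", n_in, n_classified, n_ok, n_dropped)

    # -- stage: tables ---------------------------------------------------------
    io.write_summary_tables(summaries, all_localized, out, localized_session_ids=localized_sids)

    # -- stage: statistics -----------------------------------------------------
    stats_df = cohort_statistics(summaries)
    stats_df.to_csv(out / "stats.csv", index=False, lineterminator="\n")
    if sucrose_records:
        suc = sucrose_summary(sucrose_records)
        suc.per_rat.to_csv(out / "sucrose_per_rat.csv", index=False, lineterminator="\n")
        suc.group.to_csv(out / "sucrose_group.csv", index=False, lineterminator="\n")
        anova_rows = []
        for res in rm_anova_strain_by_measurement(sucrose_records):
            anova_rows.append(
                {
                    "effect": res.name,
                    "F": res.statistic_value,
                    "df1": res.df[0],
                    "df2": res.df[1],
                    "p_value": res.p_value,
                }
            )
        pd.DataFrame(anova_rows).to_csv(out / "sucrose_anova.csv", index=False, lineterminator="\n")

    # -- stage: maps -----------------------------------------------------------
    if config.make_maps and per_session:
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        strains = sorted({t.strain_label for t, _ in per_session})
        import matplotlib.pyplot as plt

        for g in strains or [""]:
            sel = [(t, l) for t, l in per_session if t.strain_label == g]
            if sel:
                res = composite_track_map(
                    sel, geometry, MapStyle(), out_png=maps_dir / f"map_{g or 'all'}.png", title=g or None
                )
                plt.close(res.figure)

    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(_yamlable(dataclasses.asdict(config)), sort_keys=True)
    )
    return out


def _yamlable(obj):
    if isinstance(obj, dict):
        return {str(k): _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
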