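"""Synthetic sessions with the statistical structure the analysis assumes.

The generator emulates 10-min three-chamber sessions: a reflected,
correlated random walk with drift toward (sociable) or away from (avoidant)
the stimulus containers, Markov freezing bouts of zero speed, and
zone-/state-dependent call emission in the two acoustic bands via Poisson
thinning.  Two presets bundle the contrasting phenotypes the pipeline is
meant to resolve:

``wistar_like``
    sociable locomotion (positive container attraction, little freezing),
    pro-social-dominant and near-biased call emission.
``km_like``
    avoidant locomotion, frequent freezing, aversive-dominant and
    distant-biased emission whose rate and durations increase during
    freezing (inducing the freezing/aversive-duration coupling).

The movement model is the simplest one able to produce the occupancy and
zonal contrasts the analysis measures; it is not a claim about rat
locomotion.  Every generator is a pure function of its config and seed.

A two-bottle sucrose generator produces rat x phase x fluid volumes as
cell mean + subject offset + residual, truncated at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .calls import BandCriteria
from .errors import ConfigError
from .io_formats import CallEvent, SucroseRecord, Trajectory, DEFAULT_SESSION_LENGTH
from .trajectories import FreezingParams, detect_freezing
from .zoning import ArenaGeometry, default_geometry

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


# -- behavior and emission profiles -------------------------------------------


@dataclass(frozen=True)
class BehaviorProfile:
    """Locomotion parameters of one simulated phenotype.

    zone_attraction : dimensionless drift weight toward (+) or away from (-)
        the nearest container center, relative to unit direction noise.
        The bias integrates over thousands of steps, so small magnitudes
        produce strong zone preferences: ~0.03 yields roughly 3:1 occupancy
        asymmetry over a 10-min session; 0 is an unbiased walk.
    freeze_rate : freezing episodes per minute of mobile time.
    freeze_dur_mean : mean freezing-bout duration (s, exponential).
    step_speed_mean : mean instantaneous speed while mobile (cm/s).
    step_persistence : heading autocorrelation in [0, 1).
    """

    name: str = "custom"
    zone_attraction: float = 0.0
    freeze_rate: float = 0.0
    freeze_dur_mean: float = 3.0
    step_speed_mean: float = 8.0
    step_persistence: float = 0.7

    def __post_init__(self) -> None:
        if self.freeze_rate < 0 or self.freeze_dur_mean < 0 or self.step_speed_mean < 0:
            raise ConfigError("rates, durations and speeds must be >= 0")
        if not (0.0 <= self.step_persistence < 1.0):
            raise ConfigError("step_persistence must be in [0, 1)")


@dataclass(frozen=True)
class CategoryEmission:
    """Emission parameters for one call category.

    base_rate : calls/min in the distant zone while mobile.
    near_distant_ratio : rate(near zone) / rate(distant zone).
    freezing_rate_multiplier : rate factor while the animal is in a
        freezing bout (1 = no coupling).
    dur_lognorm : (mu, sigma) of the log-normal duration (s), clipped into
        the category's band duration limits so classification recovers the
        generating label by construction.
    freeze_duration_scale : multiplicative shift of the duration median
        during freezing (also clipped into band limits).
    """

    base_rate: float
    near_distant_ratio: float = 1.0
    freezing_rate_multiplier: float = 1.0
    dur_lognorm: tuple[float, float] = (math.log(1.0), 0.4)
    freeze_duration_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.base_rate, self.near_distant_ratio, self.freezing_rate_multiplier) < 0:
            raise ConfigError("emission rates and ratios must be >= 0")


@dataclass(frozen=True)
class EmissionProfile:
    aversive: CategoryEmission = CategoryEmission(base_rate=0.0)
    prosocial: CategoryEmission = CategoryEmission(base_rate=0.0)


@dataclass(frozen=True)
class StrainProfile:
    behavior: BehaviorProfile
    emission: EmissionProfile


@dataclass
class SimConfig:
    """Cohort-level generation settings; ``seed`` fixes all outputs."""

    n_per_strain: dict[str, int]
    profiles: dict[str, StrainProfile]
    session_length: float = DEFAULT_SESSION_LENGTH
    frame_rate: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.n_per_strain) != set(self.profiles):
            raise ConfigError("n_per_strain and profiles must cover the same strains")
        if self.session_length <= 0 or self.frame_rate <= 0:
            raise ConfigError("session_length and frame_rate must be > 0")


#: Sociable control phenotype: container-attracted, little freezing,
#: pro-social-dominant near-biased emission.
WISTAR_LIKE = StrainProfile(
    behavior=BehaviorProfile(
        name="sociable",
        zone_attraction=0.03,
        freeze_rate=0.2,
        freeze_dur_mean=2.0,
        step_speed_mean=8.0,
        step_persistence=0.7,
    ),
    emission=EmissionProfile(
        aversive=CategoryEmission(base_rate=0.5, dur_lognorm=(math.log(1.0), 0.4)),
        prosocial=CategoryEmission(
            base_rate=4.0, near_distant_ratio=2.0, dur_lognorm=(math.log(0.3), 0.4)
        ),
    ),
)

#: Avoidant phenotype: container-avoiding, pronounced freezing,
#: aversive-dominant distant-biased emission coupled to freezing.
KM_LIKE = StrainProfile(
    behavior=BehaviorProfile(
        name="avoidant",
        zone_attraction=-0.03,
        freeze_rate=1.5,
        freeze_dur_mean=5.0,
        step_speed_mean=5.0,
        step_persistence=0.7,
    ),
    emission=EmissionProfile(
        aversive=CategoryEmission(
            base_rate=3.0,
            near_distant_ratio=1.0 / 3.0,
            freezing_rate_multiplier=3.0,
            dur_lognorm=(math.log(1.2), 0.4),
            freeze_duration_scale=1.5,
        ),
        prosocial=CategoryEmission(base_rate=1.0, dur_lognorm=(math.log(0.3), 0.4)),
    ),
)


def default_config(n_per_strain: int = 12, seed: int = 0, **kwargs) -> SimConfig:
    """Two-strain cohort config with the shipped presets."""
    return SimConfig(
        n_per_strain={"wistar_like": n_per_strain, "km_like": n_per_strain},
        profiles={"wistar_like": WISTAR_LIKE, "km_like": KM_LIKE},
        seed=seed,
        **kwargs,
    )


# -- trajectory simulation -----------------------------------------------------


@njit(cache=False)
def _integrate(x0, y0, hx0, hy0, step_len, nx, ny, mobile, persistence, attraction,
               c1x, c1y, c2x, c2y, xmin, xmax, ymin, ymax):  # pragma: no cover - numba
    n = step_len.shape[0]
    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    xs[0] = x0
    ys[0] = y0
    hx, hy = hx0, hy0
    w = 1.0 - persistence
    for k in range(n):
        x = xs[k]
        y = ys[k]
        if not mobile[k]:
            xs[k + 1] = x
            ys[k + 1] = y
            continue
        d1 = (x - c1x) ** 2 + (y - c1y) ** 2
        d2 = (x - c2x) ** 2 + (y - c2y) ** 2
        if d1 <= d2:
            tx, ty = c1x - x, c1y - y
        else:
            tx, ty = c2x - x, c2y - y
        tn = math.sqrt(tx * tx + ty * ty)
        if tn > 1e-12:
            tx /= tn
            ty /= tn
        dx = persistence * hx + w * (attraction * tx + nx[k])
        dy = persistence * hy + w * (attraction * ty + ny[k])
        dn = math.sqrt(dx * dx + dy * dy)
        if dn < 1e-12:
            dx, dy = nx[k], ny[k]
            dn = math.sqrt(dx * dx + dy * dy) + 1e-12
        hx, hy = dx / dn, dy / dn
        x1 = x + hx * step_len[k]
        y1 = y + hy * step_len[k]
        if x1 < xmin:
            x1 = 2 * xmin - x1
            hx = -hx
        elif x1 > xmax:
            x1 = 2 * xmax - x1
            hx = -hx
        if y1 < ymin:
            y1 = 2 * ymin - y1
            hy = -hy
        elif y1 > ymax:
            y1 = 2 * ymax - y1
            hy = -hy
        # a reflected point can only re-exit for steps longer than the arena
        xs[k + 1] = min(max(x1, xmin), xmax)
        ys[k + 1] = min(max(y1, ymin), ymax)
    return xs, ys


def _draw_freeze_bouts(rng: np.random.Generator, rate_per_min: float, dur_mean: float,
                       span: float) -> list[tuple[float, float]]:
    """Alternating mobile/frozen renewal process, exponential in both states."""
    if rate_per_min <= 0 or dur_mean <= 0:
        return []
    bouts = []
    t = rng.exponential(60.0 / rate_per_min)
    while t < span:
        d = rng.exponential(dur_mean)
        bouts.append((t, min(t + d, span)))
        t += d + rng.exponential(60.0 / rate_per_min)
    return bouts


def simulate_trajectory(
    profile: BehaviorProfile,
    geometry: ArenaGeometry | None = None,
    session_length: float = DEFAULT_SESSION_LENGTH,
    frame_rate: float = 25.0,
    seed: int | np.random.SeedSequence = 0,
    session_id: str = "sim",
    subject_id: str = "sim",
    strain_label: str = "",
) -> Trajectory:
    """Simulate one session as a reflected correlated random walk.

    Heading mixes the previous heading (weight ``step_persistence``) with
    container-directed drift and isotropic noise; per-frame speeds are
    gamma-distributed around ``step_speed_mean``; freezing bouts interleave
    as a renewal process and zero the speed.  The generating bouts are
    recorded in ``meta["freeze_bouts"]``.
    """
    geometry = geometry or default_geometry()
    rng = np.random.default_rng(seed)
    n = int(round(session_length * frame_rate))
    dt = 1.0 / frame_rate
    t = np.arange(n + 1) * dt

    if profile.step_speed_mean > 0:
        speeds = rng.gamma(4.0, profile.step_speed_mean / 4.0, size=n)
    else:
        speeds = np.zeros(n)
    noise = rng.standard_normal((2, n))
    bouts = _draw_freeze_bouts(rng, profile.freeze_rate, profile.freeze_dur_mean, session_length)
    mobile = np.ones(n, dtype=np.bool_)
    mid = t[:n] + dt / 2
    for b0, b1 in bouts:
        mobile[(mid >= b0) & (mid < b1)] = False

    cx, cy = geometry.arena.center
    theta = rng.uniform(0, 2 * np.pi)
    c1 = geometry.containers[0].center
    c2 = geometry.containers[1].center
    xs, ys = _integrate(
        cx, cy, math.cos(theta), math.sin(theta),
        speeds * dt, noise[0], noise[1], mobile,
        profile.step_persistence, profile.zone_attraction,
        c1[0], c1[1], c2[0], c2[1],
        geometry.arena.xmin, geometry.arena.xmax, geometry.arena.ymin, geometry.arena.ymax,
    )
    return Trajectory(
        session_id=session_id,
        subject_id=subject_id,
        strain_label=strain_label,
        t=t,
        x=np.asarray(xs),
        y=np.asarray(ys),
        nominal_rate=frame_rate,
        meta={"freeze_bouts": bouts, "profile": profile.name},
    )


# -- call simulation -----------------------------------------------------------

_BAND_LIMITS = {
    "aversive": ("aversive_freq", "aversive_dur"),
    "prosocial": ("prosocial_freq", "prosocial_dur"),
}


def _frozen_mask(traj: Trajectory, times: np.ndarray) -> np.ndarray:
    bouts = traj.meta.get("freeze_bouts")
    if bouts is None:
        bouts = [(e.t_start, e.t_end) for e in detect_freezing(traj, FreezingParams())]
    mask = np.zeros(len(times), dtype=bool)
    for b0, b1 in bouts:
        mask |= (times >= b0) & (times < b1)
    return mask


def simulate_calls(
    traj: Trajectory,
    emission: EmissionProfile,
    criteria: BandCriteria = BandCriteria(),
    geometry: ArenaGeometry | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[CallEvent]:
    """Sample call events along a trajectory by Poisson thinning.

    The instantaneous rate per category is ``base_rate`` scaled by the
    near/distant zone factor at the animal's current position and by the
    freezing multiplier during freezing bouts (taken from the trajectory's
    recorded bouts, or detected if absent).  Acoustics are sampled inside
    the category's band, so classification recovers the generating label.
    """
    geometry = geometry or default_geometry()
    rng = np.random.default_rng(seed)
    t_frames = traj.t[:-1]
    dt = np.diff(traj.t)
    near = geometry.is_near(traj.x[:-1], traj.y[:-1])
    frozen = _frozen_mask(traj, t_frames)

    events: list[CallEvent] = []
    for cat in ("aversive", "prosocial"):
        ce: CategoryEmission = getattr(emission, cat)
        if ce.base_rate <= 0:
            continue
        lam = np.full(len(t_frames), ce.base_rate / 60.0)
        lam[near] *= ce.near_distant_ratio
        lam[frozen] *= ce.freezing_rate_multiplier
        hits = np.nonzero(rng.random(len(t_frames)) < lam * dt)[0]
        fband = getattr(criteria, _BAND_LIMITS[cat][0])
        dband = getattr(criteria, _BAND_LIMITS[cat][1])
        dlo = max(dband[0], 0.02)  # open-at-zero bands get a small positive floor
        mu, sigma = ce.dur_lognorm
        for i in hits:
            m = mu + (math.log(ce.freeze_duration_scale) if frozen[i] else 0.0)
            dur = float(np.clip(rng.lognormal(m, sigma), dlo, dband[1]))
            freq = float(rng.uniform(fband[0], fband[1]))
            t0 = float(t_frames[i])
            events.append(CallEvent(f"{traj.session_id}_{cat}_{i}", t0, t0 + dur, dur, freq))
    events.sort(key=lambda e: e.t_start)
    return events


# -- cohort and sucrose ----------------------------------------------------------


@dataclass
class SimulatedSession:
    strain: str
    trajectory: Trajectory
    calls: list[CallEvent]


def simulate_cohort(
    config: SimConfig,
    geometry: ArenaGeometry | None = None,
    criteria: BandCriteria = BandCriteria(),
) -> tuple[list[SimulatedSession], dict]:
    """Generate ``n_per_strain`` sessions per strain plus a manifest of every
    generating parameter.  Deterministic: child seeds are spawned from
    ``config.seed`` in a fixed strain/session order."""
    geometry = geometry or default_geometry()
    root = np.random.SeedSequence(config.seed)
    sessions: list[SimulatedSession] = []
    for strain in sorted(config.n_per_strain):
        prof = config.profiles[strain]
        n = config.n_per_strain[strain]
        for i in range(n):
            s_traj, s_calls = root.spawn(1)[0], root.spawn(1)[0]
            sid = f"{strain}_{i:03d}"
            traj = simulate_trajectory(
                prof.behavior,
                geometry,
                config.session_length,
                config.frame_rate,
                seed=s_traj,
                session_id=sid,
                subject_id=sid,
                strain_label=strain,
            )
            calls = simulate_calls(traj, prof.emission, criteria, geometry, seed=s_calls)
            sessions.append(SimulatedSession(strain, traj, calls))
    manifest = {
        "seed": config.seed,
        "session_length": config.session_length,
        "frame_rate": config.frame_rate,
        "n_per_strain": dict(config.n_per_strain),
        "profiles": {s: asdict(p) for s, p in config.profiles.items()},
        "band_criteria": asdict(criteria),
        "near_buffer": geometry.near_buffer,
    }
    return sessions, manifest


#: Default sucrose cell means (mL per 12 h), strain x (phase, fluid); the
#: control strain drinks ~8 mL of 1% sucrose by day, the avoidant model ~20.
SUCROSE_CELL_MEANS = {
    "wistar_like": {
        ("day", "water"): 2.1,
        ("night", "water"): 2.1,
        ("day", "sucrose"): 8.1,
        ("night", "sucrose"): 32.1,
    },
    "km_like": {
        ("day", "water"): 2.5,
        ("night", "water"): 1.4,
        ("day", "sucrose"): 20.1,
        ("night", "sucrose"): 36.4,
    },
}

#: Default noise (mL): between-rat offset and residual, matched to the
#: dispersion implied by the reference cohort's SEMs at n = 10-20.
SUCROSE_SUBJECT_SD = 3.0
SUCROSE_RESIDUAL_SD = 8.0


def simulate_sucrose(
    n_per_strain: dict[str, int] | None = None,
    cell_means: dict[str, dict[tuple[str, str], float]] | None = None,
    subject_sd: float = SUCROSE_SUBJECT_SD,
    residual_sd: float = SUCROSE_RESIDUAL_SD,
    seed: int | np.random.SeedSequence = 0,
) -> list[SucroseRecord]:
    """Two-bottle consumption records: cell mean + subject offset + residual,
    truncated at 0 mL.  Defaults: 10 control + 20 avoidant rats."""
    if subject_sd < 0 or residual_sd < 0:
        raise ConfigError("SDs must be >= 0")
    n_per_strain = n_per_strain or {"wistar_like": 10, "km_like": 20}
    cell_means = cell_means or SUCROSE_CELL_MEANS
    rng = np.random.default_rng(seed)
    records: list[SucroseRecord] = []
    for strain in sorted(n_per_strain):
        means = cell_means[strain]
        for i in range(n_per_strain[strain]):
            rid = f"{strain}_r{i:03d}"
            offset = rng.normal(0.0, subject_sd) if subject_sd > 0 else 0.0
            for phase, fluid in (("day", "water"), ("night", "water"), ("day", "sucrose"), ("night", "sucrose")):
                resid = rng.normal(0.0, residual_sd) if residual_sd > 0 else 0.0
                vol = max(0.0, means[(phase, fluid)] + offset + resid)
                records.append(SucroseRecord(rid, strain, phase, fluid, vol))
    return records
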