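"""Determinism, construction guarantees and statistical structure of the
synthetic-session generator."""

import dataclasses

import numpy as np
import pytest

from usvmap import (
    KM_LIKE,
    WISTAR_LIKE,
    BehaviorProfile,
    CategoryEmission,
    EmissionProfile,
    classify_call,
    default_config,
    default_geometry,
    detect_freezing,
    freezing_time,
    occupancy,
    simulate_calls,
    simulate_cohort,
    simulate_sucrose,
    simulate_trajectory,
    spearman,
)


class TestTrajectorySimulation:
    def test_same_seed_identical(self, geometry):
        a = simulate_trajectory(KM_LIKE.behavior, geometry, seed=5)
        b = simulate_trajectory(KM_LIKE.behavior, geometry, seed=5)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)
        assert a.meta["freeze_bouts"] == b.meta["freeze_bouts"]
        c = simulate_trajectory(KM_LIKE.behavior, geometry, seed=6)
        assert not np.array_equal(a.x, c.x)

    def test_track_stays_in_arena_and_on_grid(self, geometry):
        tr = simulate_trajectory(WISTAR_LIKE.behavior, geometry, seed=1)
        assert len(tr) == 600 * 25 + 1
        assert tr.x.min() >= 0 and tr.x.max() <= 60
        assert tr.y.min() >= 0 and tr.y.max() <= 60
        assert np.allclose(np.diff(tr.t), 0.04)

    def test_zero_speed_profile_is_one_long_freeze(self, geometry):
        prof = BehaviorProfile(step_speed_mean=0.0)
        tr = simulate_trajectory(prof, geometry, seed=2)
        eps = detect_freezing(tr)
        assert len(eps) == 1
        assert eps[0].duration == pytest.approx(tr.span)

    def test_unbiased_walk_occupancy_matches_area_fraction(self, geometry):
        """Zone occupancy of a drift-free, freeze-free walk approaches the
        near zone's geometric area fraction (grid oracle, +/-20% rel)."""
        xs = np.linspace(0.05, 59.95, 400)
        grid_x, grid_y = np.meshgrid(xs, xs)
        area_frac = float(geometry.is_near(grid_x, grid_y).mean())
        prof = BehaviorProfile(zone_attraction=0.0, freeze_rate=0.0, step_speed_mean=8.0)
        total = 0.0
        for i in range(10):
            tr = simulate_trajectory(prof, geometry, seed=100 + i)
            total += occupancy(tr, geometry)["near"]
        emp = total / (10 * 600.0)
        assert emp == pytest.approx(area_frac, rel=0.20)

    def test_freezing_bouts_have_zero_speed(self, geometry):
        tr = simulate_trajectory(KM_LIKE.behavior, geometry, seed=3)
        for b0, b1 in tr.meta["freeze_bouts"]:
            sel = (tr.t >= b0 + 0.05) & (tr.t <= b1 - 0.05)
            if sel.sum() > 1:
                assert np.all(np.diff(tr.x[sel]) == 0.0)


class TestCallSimulation:
    def test_all_rates_zero_no_calls(self, geometry):
        tr = simulate_trajectory(WISTAR_LIKE.behavior, geometry, seed=4)
        assert simulate_calls(tr, EmissionProfile(), geometry=geometry, seed=1) == []

    def test_labels_recovered_by_classifier(self, geometry):
        tr = simulate_trajectory(KM_LIKE.behavior, geometry, seed=5)
        calls = simulate_calls(tr, KM_LIKE.emission, geometry=geometry, seed=6)
        assert len(calls) > 0
        for c in calls:
            generating = "aversive" if "_aversive_" in c.call_id else "prosocial"
            assert classify_call(c) == generating

    def test_poisson_rate_recovered_on_stationary_sessions(self, geometry):
        """2 calls/min over 100 x 600 s sums to ~2000 calls (within 5%)."""
        emission = EmissionProfile(aversive=CategoryEmission(base_rate=2.0))
        prof = BehaviorProfile(step_speed_mean=0.0, freeze_rate=0.0)
        n = 0
        for i in range(100):
            tr = simulate_trajectory(prof, geometry, seed=200 + i, session_id=f"s{i}")
            n += len(simulate_calls(tr, emission, geometry=geometry, seed=3000 + i))
        assert n == pytest.approx(100 * 600 / 60 * 2.0, rel=0.05)

    def test_same_seed_identical_calls(self, geometry):
        tr = simulate_trajectory(KM_LIKE.behavior, geometry, seed=7)
        a = simulate_calls(tr, KM_LIKE.emission, geometry=geometry, seed=8)
        b = simulate_calls(tr, KM_LIKE.emission, geometry=geometry, seed=8)
        assert a == b


class TestCohort:
    def test_empty_cohort_valid_manifest(self):
        cfg = default_config(0, seed=1)
        sessions, manifest = simulate_cohort(cfg)
        assert sessions == []
        assert manifest["n_per_strain"] == {"wistar_like": 0, "km_like": 0}

    def test_default_cohort_size(self):
        cfg = default_config(2, seed=1, session_length=30.0)
        sessions, _ = simulate_cohort(cfg)
        assert len(sessions) == 4
        assert {s.strain for s in sessions} == {"wistar_like", "km_like"}

    def test_cohort_deterministic(self):
        cfg = default_config(2, seed=9, session_length=30.0)
        s1, _ = simulate_cohort(cfg)
        s2, _ = simulate_cohort(cfg)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.trajectory.x, b.trajectory.x)
            assert a.calls == b.calls

    def test_freezing_aversive_coupling_positive(self, geometry):
        """The avoidant preset's freezing multiplier induces a positive
        freezing-time vs aversive-duration correlation across sessions."""
        ss = np.random.SeedSequence(21)
        fz, dur = [], []
        for _ in range(40):
            s1, s2 = ss.spawn(2)
            tr = simulate_trajectory(KM_LIKE.behavior, geometry, seed=s1)
            calls = simulate_calls(tr, KM_LIKE.emission, geometry=geometry, seed=s2)
            fz.append(freezing_time(detect_freezing(tr)))
            dur.append(sum(c.duration for c in calls if classify_call(c) == "aversive"))
        assert spearman(fz, dur).statistic_value > 0


class TestSucrose:
    def test_zero_sd_reproduces_cell_means(self):
        recs = simulate_sucrose(subject_sd=0.0, residual_sd=0.0, seed=1)
        from usvmap.synthetic import SUCROSE_CELL_MEANS

        for r in recs:
            assert r.volume == SUCROSE_CELL_MEANS[r.strain_label][(r.phase, r.fluid)]

    def test_default_design_shape(self):
        recs = simulate_sucrose(seed=2)
        assert len(recs) == (10 + 20) * 4
        assert all(r.volume >= 0 for r in recs)

    def test_same_seed_identical(self):
        assert simulate_sucrose(seed=3) == simulate_sucrose(seed=3)

    def test_negative_sd_rejected(self):
        from usvmap import ConfigError

        with pytest.raises(ConfigError):
            simulate_sucrose(subject_sd=-1.0)
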