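"""Ratemap construction, smoothing, velocity, templates and remap exclusion."""
import numpy as np
import pytest

from thetaflicker import simulate as sim
from thetaflicker.arena import Arena
from thetaflicker.preprocess import (
    SMOOTHING_KERNEL,
    CoverageError,
    PositionTrack,
    build_ratemap,
    build_templates,
    compute_velocity,
    detect_remapped_cells,
    smooth_ratemap,
)


class TestArena:
    def test_bin_geometry(self):
        a = Arena(60.0, 3.0)
        assert a.n_bins == 20
        assert a.n_bins_total == 400
        ix, iy = a.bin_index(0.0, 59.9)
        assert (ix, iy) == (0, 19)
        # far edge folds into the last bin
        assert a.bin_index(60.0, 60.0) == (19, 19)
        assert a.flat_index(4.0, 3.0) == 1 * 20 + 1

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            Arena(60.0, 7.0)
        with pytest.raises(ValueError):
            Arena(3.0, 3.0)


class TestVelocity:
    def test_stationary_track_has_zero_speed(self):
        t = np.arange(0, 10, 0.04)
        v = compute_velocity(t, np.full(t.size, 30.0), np.full(t.size, 30.0))
        assert np.allclose(v, 0.0)

    def test_straight_line_speed_recovered(self):
        t = np.arange(0, 5, 0.04)
        v = compute_velocity(t, 10.0 * t, np.zeros(t.size))
        assert abs(v.mean() - 10.0) < 0.2  # within 2 %

    def test_speed_threshold_partitions_samples(self):
        # first half stationary, second half moving at 10 cm/s
        t = np.arange(0, 20, 0.04)
        x = np.where(t < 10, 5.0, 5.0 + 10.0 * (t - 10))
        v = compute_velocity(t, x, np.zeros(t.size), smooth_window_ms=40)
        below = v <= 2.0
        # away from the transition, the filter separates exactly
        assert below[: t.size // 2 - 10].all()
        assert (~below[t.size // 2 + 10 :]).all()

    def test_too_short_track_raises(self):
        with pytest.raises(ValueError):
            compute_velocity([0.0, 0.04], [0, 1], [0, 1])


class TestRatemap:
    def test_rate_is_spikes_over_dwell(self):
        # hold still... moving: sweep one bin for 2 s with 4 spikes in it
        arena = Arena(12.0, 3.0)
        t = np.arange(0, 2.0, 0.04)
        track = PositionTrack(t, 1.0 + 0.5 * t, np.full(t.size, 1.5), speed=np.full(t.size, 5.0))
        occ, rate = build_ratemap(track, [0.5, 0.9, 1.3, 1.7], arena, occupancy_floor=0.0)
        assert occ[0, 0] == pytest.approx(2.0, abs=0.05)
        assert rate[0, 0] == pytest.approx(4.0 / occ[0, 0])

    def test_zero_spikes_gives_zero_map_on_visited_bins(self, arena):
        track = sim.simulate_trajectory(arena, 60.0, 10.0, seed=5)
        occ, rate = build_ratemap(track, [], arena)
        visited = np.isfinite(rate)
        assert visited.any()
        assert np.all(rate[visited] == 0.0)

    def test_gaussian_field_peak_recovered(self, arena):
        cell = sim.CellSpec(0, {"A": (sim.GaussField(30.0, 30.0, 6.0, 8.0),), "B": ()})
        spec = sim.SessionSpec("S", "PRE1", "A", duration=300.0)
        sess = sim.simulate_session(spec, [cell], arena, seed=7)
        _, rate = build_ratemap(sess.track, sess.spikes[0], arena)
        sm = smooth_ratemap(rate)
        iy, ix = np.unravel_index(np.nanargmax(sm), sm.shape)
        cx, cy = (ix + 0.5) * 3.0, (iy + 0.5) * 3.0
        assert np.hypot(cx - 30.0, cy - 30.0) <= 3.0 * np.sqrt(2)  # within one bin

    def test_occupancy_conserves_filtered_duration(self, arena):
        track = sim.simulate_trajectory(arena, 120.0, 10.0, seed=9)
        occ, _ = build_ratemap(track, [], arena, occupancy_floor=0.0)
        dt = np.median(np.diff(track.t))
        expected = np.sum(track.speed > 2.0) * dt
        assert abs(occ.sum() - expected) <= dt + 1e-9

    def test_estimator_error_shrinks_with_session_length(self, arena):
        cell = sim.CellSpec(0, {"A": (sim.GaussField(30.0, 30.0, 8.0, 8.0),), "B": ()})
        truth = sim.true_ratemap(cell, "A", arena)
        errs = []
        for dur, seed in ((300.0, 21), (1200.0, 22)):
            sess = sim.simulate_session(
                sim.SessionSpec("S", "PRE1", "A", duration=dur), [cell], arena, seed=seed
            )
            _, rate = build_ratemap(sess.track, sess.spikes[0], arena)
            sm = smooth_ratemap(rate)
            m = np.isfinite(sm)
            errs.append(np.nanmean(np.abs(sm - truth)[m]))
        assert errs[1] < errs[0]


class TestSmoothing:
    def test_kernel_constants(self):
        assert SMOOTHING_KERNEL.sum() == pytest.approx(1.0, abs=1e-12)
        assert SMOOTHING_KERNEL[2, 2] == 0.16
        # 4-fold symmetry
        assert np.array_equal(SMOOTHING_KERNEL, SMOOTHING_KERNEL[::-1])
        assert np.array_equal(SMOOTHING_KERNEL, SMOOTHING_KERNEL[:, ::-1])
        assert np.array_equal(SMOOTHING_KERNEL, SMOOTHING_KERNEL.T)

    def test_uniform_map_unchanged(self):
        m = np.full((20, 20), 3.7)
        assert np.allclose(smooth_ratemap(m), 3.7, atol=1e-12)

    def test_delta_centre_weight(self):
        m = np.zeros((20, 20))
        m[10, 10] = 1.0
        out = smooth_ratemap(m)
        assert out[10, 10] == pytest.approx(0.16, abs=1e-12)
        assert out[10, 11] == pytest.approx(0.10, abs=1e-12)
        assert out[8, 8] == pytest.approx(0.0025, abs=1e-12)

    def test_mass_conserved_on_interior_support(self):
        rng = np.random.default_rng(4)
        m = np.zeros((20, 20))
        m[5:15, 5:15] = rng.uniform(0, 10, (10, 10))
        out = smooth_ratemap(m)
        assert out.sum() == pytest.approx(m.sum(), abs=1e-9)

    def test_matches_direct_kernel_summation(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(0, 5, (9, 9))
        m[rng.uniform(size=(9, 9)) < 0.15] = np.nan
        out = smooth_ratemap(m)
        # brute-force oracle: renormalised weighted sum over valid neighbours
        for iy in range(9):
            for ix in range(9):
                if not np.isfinite(m[iy, ix]):
                    assert np.isnan(out[iy, ix])
                    continue
                num = den = 0.0
                for dy in range(-2, 3):
                    for dx in range(-2, 3):
                        y, x = iy + dy, ix + dx
                        if 0 <= y < 9 and 0 <= x < 9 and np.isfinite(m[y, x]):
                            w = SMOOTHING_KERNEL[dy + 2, dx + 2]
                            num += w * m[y, x]
                            den += w
                assert out[iy, ix] == pytest.approx(num / den, abs=1e-9)

    def test_nan_only_where_input_nan(self):
        m = np.ones((20, 20))
        m[3, 3] = np.nan
        out = smooth_ratemap(m)
        assert np.isnan(out[3, 3])
        assert np.isfinite(np.delete(out.ravel(), 3 * 20 + 3)).all()


class TestTemplates:
    def test_template_window_is_first_half(self, pre_sessions, template_bundle):
        tset = template_bundle["templates"]
        t0, t1 = tset.provenance["A"]
        track = pre_sessions["PRE1"].track
        assert t0 == track.t[0]
        assert t1 == pytest.approx(track.t[0] + (track.t[-1] - track.t[0]) / 2)

    def test_orthogonal_cell_silent_in_other_environment(self, arena):
        # flicker-free sessions: a cell with fields only in A stays at
        # exactly zero in the B template
        cells = sim.make_cell_library(n_cells=6, frac_both=0.0, seed=2, arena=arena)
        s1 = sim.simulate_session(sim.SessionSpec("PRE1", "PRE1", "A"), cells, arena, seed=41)
        s2 = sim.simulate_session(sim.SessionSpec("PRE2", "PRE2", "B"), cells, arena, seed=42)
        tset, _ = build_templates(
            {"A": (s1.track, s1.spikes), "B": (s2.track, s2.spikes)}, arena
        )
        a_only = [i for i, c in enumerate(cells) if c.fields["A"] and not c.fields["B"]]
        assert a_only
        for i in a_only:
            assert np.nanmax(tset.rates["B"][i]) == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_coverage_raises(self, arena):
        # trajectory confined to one corner quadrant
        t = np.arange(0, 60, 0.04)
        x = 7.5 + 7.0 * np.sin(2 * np.pi * 0.2 * t)
        y = 7.5 + 7.0 * np.cos(2 * np.pi * 0.17 * t)
        track = PositionTrack(t, x, y)
        spikes = {0: np.array([1.0, 2.0])}
        with pytest.raises(CoverageError, match="coverage"):
            build_templates({"A": (track, spikes), "B": (track, spikes)}, arena)


class TestRemapDetection:
    def _stable_maps(self, templates):
        return {
            env: (templates.rates[env].copy(), np.full((20, 20), 1.0))
            for env in templates.envs
        }

    def test_identical_maps_retained(self, template_bundle):
        tset = template_bundle["templates"]
        assert detect_remapped_cells(tset, self._stable_maps(tset)) == {}

    def test_rate_scaling_retained(self, template_bundle):
        tset = template_bundle["templates"]
        maps = self._stable_maps(tset)
        maps = {env: (2.0 * m, occ) for env, (m, occ) in maps.items()}
        assert detect_remapped_cells(tset, maps) == {}

    def test_shifted_field_excluded(self, arena):
        cell_pre = sim.CellSpec(0, {"A": (sim.GaussField(15.0, 15.0, 6.0, 8.0),), "B": ()})
        cell_post = sim.CellSpec(0, {"A": (sim.GaussField(45.0, 45.0, 6.0, 8.0),), "B": ()})
        pre = sim.simulate_session(sim.SessionSpec("P", "PRE1", "A"), [cell_pre], arena, seed=31)
        post = sim.simulate_session(sim.SessionSpec("Q", "POST1", "A"), [cell_post], arena, seed=32)
        tset, _ = build_templates(
            {"A": (pre.track, pre.spikes), "B": (pre.track, {0: np.empty(0)})}, arena
        )
        occ, rate = build_ratemap(post.track, post.spikes[0], arena)
        excluded = detect_remapped_cells(tset, {"A": (smooth_ratemap(rate)[None], occ)})
        assert 0 in excluded

    def test_silent_cell_excluded_as_no_post_activity(self, template_bundle):
        tset = template_bundle["templates"]
        maps = self._stable_maps(tset)
        silent = {env: (np.zeros_like(m), occ) for env, (m, occ) in maps.items()}
        excluded = detect_remapped_cells(tset, silent)
        assert all(reason == "no POST activity" for reason in excluded.values())
        assert len(excluded) == tset.n_cells
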