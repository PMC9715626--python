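"""Permutation nulls, autocorrelograms, clustering tests, circular stats."""
import numpy as np
import pytest
from scipy.stats import kstest

from thetaflicker import simulate as sim
from thetaflicker.arena import Arena
from thetaflicker.preprocess import PositionTrack
from thetaflicker.stats import (
    bonferroni,
    circ_mean_deg,
    cycle_autocorrelogram,
    downsample_events,
    interevent_interval_test,
    phase_shift_summary,
    spatial_clustering_controlmatch,
    spatial_clustering_trackshift,
    velocity_by_pattern,
    watson_williams,
)


class TestCircular:
    def test_circular_mean_wraps(self):
        m = circ_mean_deg([10.0, 350.0])
        assert min(m, 360.0 - m) == pytest.approx(0.0, abs=1e-9)

    def test_bonferroni_monotone_and_capped(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)
        assert bonferroni(0.5, 4) == 1.0
        assert bonferroni(0.2, 2) >= 0.2


class TestWatsonWilliams:
    def test_identical_samples_give_f_near_zero(self):
        rng = np.random.default_rng(0)
        g = np.degrees(rng.vonmises(0.0, 4.0, 100)) % 360
        F, p = watson_williams(g, g.copy())
        assert F == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99

    def test_type_i_error_near_alpha(self):
        """Equal von Mises means: rejection rate ~ alpha over 500 draws."""
        rng = np.random.default_rng(1)
        rej = 0
        n_sim = 500
        for _ in range(n_sim):
            a = np.degrees(rng.vonmises(1.0, 3.0, 50)) % 360
            b = np.degrees(rng.vonmises(1.0, 3.0, 50)) % 360
            _, p = watson_williams(a, b)
            rej += p < 0.05
        assert 0.02 <= rej / n_sim <= 0.09

    def test_power_to_detect_90_degree_shift(self):
        rng = np.random.default_rng(2)
        rej = 0
        for _ in range(100):
            a = np.degrees(rng.vonmises(0.0, 4.0, 200)) % 360
            b = np.degrees(rng.vonmises(np.pi / 2, 4.0, 200)) % 360
            _, p = watson_williams(a, b)
            rej += p < 0.05
        assert rej >= 95

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            watson_williams([1.0] * 5, [2.0] * 50)


class TestInterEventIntervals:
    def test_equally_spaced_events_mean_gap(self):
        out = interevent_interval_test(np.arange(0, 100, 10.0), (0.0, 100.0), n_sim=200, seed=0)
        assert out["observed_mean_s"] == pytest.approx(10.0)

    def test_p_uniform_under_null(self):
        """Events drawn from the null itself yield uniform p over repeats."""
        rng = np.random.default_rng(3)
        ps = []
        for k in range(200):
            ev = np.sort(rng.uniform(0, 600, 12))
            ps.append(interevent_interval_test(ev, (0, 600), n_sim=300, seed=k)["p"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_temporally_concentrated_events_detected(self):
        # the mean consecutive gap is ~range/(n-1), so the statistic responds
        # to temporal concentration (events packed into the session start,
        # as after a restabilising experience), not to local pairing
        rng = np.random.default_rng(12)
        ev = np.sort(rng.uniform(0, 150, 12))
        out = interevent_interval_test(ev, (0, 600), n_sim=2000, seed=1)
        assert out["observed_mean_s"] < out["null_mean_s"]
        assert out["p"] < 0.05
        assert out["z"] < -2

    def test_single_event_rejected(self):
        with pytest.raises(ValueError):
            interevent_interval_test([1.0], (0, 10))


class TestAutocorrelogram:
    def test_lag_zero_equals_event_count(self):
        ev = np.zeros(500, dtype=int)
        ev[np.arange(0, 500, 36)] = 1
        out = cycle_autocorrelogram(ev, np.ones(500, bool), max_lag=5, n_shuffle=50, seed=0)
        assert out.C[0] == ev.sum()

    def test_isolated_events_have_zero_lag1(self):
        ev = np.zeros(400, dtype=int)
        ev[np.arange(0, 400, 30)] = 1
        out = cycle_autocorrelogram(ev, np.ones(400, bool), n_shuffle=50, seed=0)
        assert out.C[1] == 0

    def test_adjacent_pairs_counted_and_significant(self):
        ev = np.zeros(3000, dtype=int)
        for k in range(6):
            ev[200 * k + 7] = 1
            ev[200 * k + 8] = 1
        out = cycle_autocorrelogram(ev, np.ones(3000, bool), n_shuffle=1000, seed=1)
        assert out.C[1] == 6
        assert out.z[1] > 2
        assert out.p_lag1 == pytest.approx(1.0 / 1001.0)  # no shuffle reaches 6

    def test_p_convention_n_plus_one_over_1001(self):
        ev = np.zeros(100, dtype=int)
        ev[::8] = 1
        out = cycle_autocorrelogram(ev, np.ones(100, bool), n_shuffle=1000, seed=2)
        n = int(np.sum([1 for _ in range(0)]))  # structural: p is (n+1)/1001
        assert out.p_lag1 * 1001 == pytest.approx(round(out.p_lag1 * 1001))

    def test_sessions_below_12_events_skipped(self):
        ev = np.zeros(100, dtype=int)
        ev[:5] = 1
        out = cycle_autocorrelogram(ev, np.ones(100, bool))
        assert out.skipped is not None

    def test_empirical_p_valid_under_own_null(self):
        """P(p <= alpha) <= alpha (+ sampling slack) when events are placed
        uniformly within the eligible bins -- the discrete statistic makes
        the p-value conservative, never anticonservative."""
        rng = np.random.default_rng(4)
        elig = np.ones(800, bool)
        elig[rng.random(800) < 0.3] = False
        idx = np.nonzero(elig)[0]
        ps = []
        for k in range(200):
            ev = np.zeros(800, dtype=int)
            ev[rng.choice(idx, 15, replace=False)] = 1
            ps.append(cycle_autocorrelogram(ev, elig, n_shuffle=200, seed=k).p_lag1)
        ps = np.array(ps)
        for alpha in (0.05, 0.1, 0.25, 0.5):
            assert np.mean(ps <= alpha) <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 200)


class TestDownsampling:
    def _track(self, speed=10.0, duration=300.0):
        t = np.arange(0, duration, 0.04)
        # zig-zag path with known cumulative length: |dx/dt| = speed
        x = 30 + 25 * np.abs(((speed * t / 25) % 4) - 2) - 25
        return PositionTrack(t, np.clip(x, 0, 60), np.full(t.size, 30.0), np.full(t.size, speed))

    def test_close_in_time_dropped(self):
        track = self._track()
        kept = downsample_events([10.0, 13.0, 30.0], track)
        assert list(kept) == [10.0, 30.0]

    def test_enough_time_but_short_path_dropped(self):
        track = self._track(speed=1.5)  # 6 s apart -> only 9 cm of path
        kept = downsample_events([10.0, 16.0], track)
        assert list(kept) == [10.0]

    def test_both_gaps_satisfied_kept(self):
        track = self._track(speed=10.0)  # 10 s apart -> 100 cm of path
        kept = downsample_events([10.0, 20.0], track)
        assert list(kept) == [10.0, 20.0]


class TestTrackshiftClustering:
    def test_colocated_events_significant_on_dispersed_track(self, arena):
        track = sim.simulate_trajectory(arena, 600.0, 10.0, seed=5)
        # events whenever the animal is in one small corner region
        near = np.nonzero((track.x < 10) & (track.y < 10) & (track.speed > 2))[0]
        assert near.size >= 5
        ev_t = track.t[near[:: max(1, near.size // 8)]][:8]
        out = spatial_clustering_trackshift(
            ev_t, track, arena, np.ones((20, 20), bool), n=500, seed=0
        )
        assert out.p <= 0.05

    def test_null_size_is_configured(self, arena):
        track = sim.simulate_trajectory(arena, 300.0, 10.0, seed=6)
        ev_t = track.t[[100, 800, 2000, 4000, 6000]]
        out = spatial_clustering_trackshift(track.t[[100, 800, 2000, 4000, 6000]], track, arena, np.ones((20, 20), bool), n=1000, seed=0)
        assert out.null.size == 1000

    def test_too_few_events_skipped(self, arena):
        track = sim.simulate_trajectory(arena, 60.0, 10.0, seed=7)
        out = spatial_clustering_trackshift([1.0, 2.0], track, arena, np.ones((20, 20), bool))
        assert out.skipped is not None

    def test_p_uniform_when_events_drawn_from_null(self, arena):
        track = sim.simulate_trajectory(arena, 300.0, 10.0, seed=8)
        rng = np.random.default_rng(9)
        pool = np.nonzero(track.speed > 2)[0]
        ps = []
        for k in range(100):
            ev_t = track.t[rng.choice(pool, 8, replace=False)]
            ps.append(
                spatial_clustering_trackshift(
                    ev_t, track, arena, np.ones((20, 20), bool), n=199, seed=k
                ).p
            )
        assert kstest(ps, "uniform").pvalue > 0.01


class TestControlMatchClustering:
    def test_block_size_is_12cm(self, arena):
        assert arena.side_cm / 5 == pytest.approx(12.0)

    def test_p_uniform_under_matched_null(self, arena):
        rng = np.random.default_rng(10)
        occupancy = rng.uniform(0, 60, (4000, 2))
        control = rng.uniform(0, 60, (1500, 2))
        ps = []
        for k in range(100):
            events = control[rng.choice(1500, 8, replace=False)]
            out = spatial_clustering_controlmatch(
                events, occupancy, control, arena, n=199, seed=k
            )
            ps.append(out.p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_events_skipped(self, arena):
        out = spatial_clustering_controlmatch(
            np.ones((2, 2)), np.ones((10, 2)), np.ones((10, 2)), arena
        )
        assert out.skipped is not None


class TestPhaseSummaries:
    def test_known_shift_recovered(self):
        import pandas as pd

        rng = np.random.default_rng(11)
        rows = []
        for grp, mu in (("ICPV", 180.0), ("OCPV", 205.0)):
            ph = np.degrees(rng.vonmises(np.radians(mu), 4.0, 400)) % 360
            rows.append(pd.DataFrame({"phase_deg": ph, "group": grp}))
        out = phase_shift_summary(pd.concat(rows))
        row = out.iloc[0]
        assert row["shift_deg"] == pytest.approx(25.0, abs=5.0)
        assert row["p_bonferroni"] < 0.01
        assert row["p_bonferroni"] >= row["p"]

    def test_velocity_by_pattern_excludes_slow_cycles(self):
        import pandas as pd

        labels = pd.DataFrame(
            {
                "label": ["ICPV", "ICPV", "OCPV", "OCPV"],
                "speed": [10.0, 12.0, 5.0, 1.0],
                "included": [True, True, True, False],
                "eligible_bin": [True, True, True, True],
            }
        )
        out = velocity_by_pattern(labels)
        assert out.loc[out["label"] == "ICPV", "speed_mean"].iloc[0] == pytest.approx(11.0)
        assert out.loc[out["label"] == "OCPV", "speed_mean"].iloc[0] == pytest.approx(5.0)
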