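import numpy as np
import pandas as pd
import pytest

from killscan.protocol import (
    deduplicate,
    detect_clusters,
    detection_probability,
    label_points,
    make_windows,
    select_visits,
    clusters_to_frame,
    clusters_to_geojson,
)
from killscan.stpss import ScanConfig
from killscan.synthetic import SimConfig, simulate_trajectory

from conftest import make_traj


class TestMakeWindows:
    def test_april_study_period(self):
        wins = make_windows("2014-04-01", "2014-04-28")
        starts = [pd.Timestamp(w.start) for w in wins]
        assert starts == [
            pd.Timestamp("2014-04-01"),
            pd.Timestamp("2014-04-08"),
            pd.Timestamp("2014-04-15"),
        ]
        for w in wins:
            assert (w.end - w.start) == np.timedelta64(14 * 86400, "s")

    def test_exactly_fourteen_days(self):
        wins = make_windows("2014-06-01", "2014-06-15")
        assert len(wins) == 2
        assert pd.Timestamp(wins[1].start) == pd.Timestamp("2014-06-08")

    def test_short_span_single_window(self):
        assert len(make_windows("2014-06-01", "2014-06-05")) == 1

    def test_coverage_and_double_coverage(self):
        t0, t1 = pd.Timestamp("2014-06-01"), pd.Timestamp("2014-07-13")
        wins = make_windows(t0, t1)
        rng = np.random.default_rng(0)
        for _ in range(200):
            t = t0 + pd.Timedelta(seconds=int(rng.uniform(0, (t1 - t0).total_seconds())))
            t64 = np.datetime64(t.to_datetime64(), "s")
            n_cover = sum(w.start <= t64 < w.end for w in wins)
            assert n_cover >= 1
            if t0 + pd.Timedelta(days=7) <= t < t1 - pd.Timedelta(days=7):
                assert n_cover == 2

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            make_windows("2014-06-15", "2014-06-01")


def _bout_trajectory(bout_start_h, bout_len_h=40, total_h=500, seed=1):
    """Random walk with one planted tight bout."""
    rng = np.random.default_rng(seed)
    steps = rng.gamma(2.0, 150.0, (total_h, 2)) * rng.choice([-1, 1], (total_h, 2))
    xy = np.cumsum(steps, axis=0)
    x, y = xy[:, 0].copy(), xy[:, 1].copy()
    sl = slice(bout_start_h, bout_start_h + bout_len_h)
    n_b = bout_len_h
    r = 15 * np.sqrt(rng.uniform(size=n_b))
    th = rng.uniform(0, 2 * np.pi, n_b)
    x[sl] = x[bout_start_h] + r * np.cos(th)
    y[sl] = y[bout_start_h] + r * np.sin(th)
    return make_traj(np.arange(total_h), x, y)


class TestDetectClusters:
    def test_planted_bout_recovered(self):
        traj = _bout_trajectory(bout_start_h=100)
        found = detect_clusters(traj, ScanConfig(n_replicates=99, rng_seed=3))
        assert found, "planted 40 h bout must be detected"
        bout_ids = {f"b1-{i}" for i in range(100, 140)}
        assert any(len(cl.member_fix_ids & bout_ids) > 20 for cl in found)

    def test_bout_straddling_window_boundary_found_in_overlap(self):
        # bout across the day-14 boundary: the 7-day overlap window sees it whole
        traj = _bout_trajectory(bout_start_h=14 * 24 - 20)
        found = detect_clusters(traj, ScanConfig(n_replicates=99, rng_seed=4))
        bout_ids = {f"b1-{i}" for i in range(14 * 24 - 20, 14 * 24 + 20)}
        assert any(len(cl.member_fix_ids & bout_ids) > 20 for cl in found)

    def test_deterministic_given_seed(self):
        traj = _bout_trajectory(bout_start_h=50, seed=2)
        cfg = ScanConfig(n_replicates=49, rng_seed=9)
        a = detect_clusters(traj, cfg)
        b = detect_clusters(traj, cfg)
        assert [c.cluster_id for c in a] == [c.cluster_id for c in b]
        assert [c.cylinder.p for c in a] == [c.cylinder.p for c in b]


class TestDeduplicate:
    def _mk(self, cid, animal, window, members, log_glr, start="2014-06-01"):
        from killscan.protocol import SpaceTimeCluster
        from killscan.stpss import Cylinder

        cyl = Cylinder(
            center_idx=0, center=(0.0, 0.0), radius=10.0, t_start=0.0, t_end=1.0,
            c=len(members), n_s=len(members), n_t=len(members), mu=1.0,
            log_glr=log_glr, member_idx=tuple(range(len(members))), p=0.01,
            t_start_time=np.datetime64(start, "s"),
            t_end_time=np.datetime64(start, "s") + np.timedelta64(3600, "s"),
            member_fix_ids=frozenset(members),
        )
        return SpaceTimeCluster(cid, animal, window, cyl, alpha=0.05)

    def test_identical_cluster_two_windows_keeps_one(self):
        a = self._mk("c1", "b1", 0, {"f1", "f2", "f3"}, 5.0)
        b = self._mk("c2", "b1", 1, {"f1", "f2", "f3"}, 5.0)
        out = deduplicate([a, b])
        assert len(out) == 1 and out[0].cluster_id == "c1"  # earlier window

    def test_disjoint_clusters_both_kept(self):
        a = self._mk("c1", "b1", 0, {"f1", "f2"}, 5.0)
        b = self._mk("c2", "b1", 1, {"f3", "f4"}, 4.0)
        assert len(deduplicate([a, b])) == 2

    def test_partial_overlap_keeps_larger_glr(self):
        a = self._mk("c1", "b1", 0, {"f1", "f2", "f3"}, np.log(9.5))
        b = self._mk("c2", "b1", 1, {"f3", "f4", "f5"}, np.log(12.0))
        out = deduplicate([a, b])
        assert len(out) == 1 and out[0].cluster_id == "c2"

    def test_same_fixes_different_animals_not_duplicates(self):
        a = self._mk("c1", "b1", 0, {"f1", "f2"}, 5.0)
        b = self._mk("c2", "b2", 0, {"f1", "f2"}, 4.0)
        assert len(deduplicate([a, b])) == 2

    def test_idempotent_and_never_grows(self):
        cls = [
            self._mk("c1", "b1", 0, {"f1", "f2"}, 3.0),
            self._mk("c2", "b1", 1, {"f2", "f3"}, 2.0),
            self._mk("c3", "b1", 2, {"f9"}, 1.0),
        ]
        once = deduplicate(cls)
        assert len(once) <= len(cls)
        assert [c.cluster_id for c in deduplicate(once)] == [c.cluster_id for c in once]


class TestSelectVisits(TestDeduplicate):
    def test_top_two_by_size(self):
        cls = [
            self._mk(f"c{i}", "b1", 0, {f"f{j}" for j in range(10 * i, 10 * i + n)}, 1.0)
            for i, n in enumerate([3, 7, 5, 2, 4])
        ]
        out = select_visits(cls, extra_fraction=0.0)
        assert {c.cluster_id for c in out} == {"c1", "c2"}  # sizes 7 and 5

    def test_fewer_than_quota(self):
        cls = [self._mk("c1", "b1", 0, {"f1", "f2"}, 1.0)]
        assert len(select_visits(cls)) == 1

    def test_extra_fraction_seeded(self):
        cls = [
            self._mk(f"c{i}", "b1", 0, {f"f{j}" for j in range(5 * i, 5 * i + 2 + i % 3)}, 1.0)
            for i in range(8)
        ]
        a = select_visits(cls, extra_fraction=0.5, rng=np.random.default_rng(1))
        b = select_visits(cls, extra_fraction=0.5, rng=np.random.default_rng(1))
        assert [c.cluster_id for c in a] == [c.cluster_id for c in b]
        assert len(a) > 2


class TestLabelPoints(TestDeduplicate):
    def test_spatial_and_temporal_constraints(self):
        cl = self._mk("c1", "b1", 0, {"f1"}, 3.0)
        pts = pd.DataFrame(
            {
                "timestamp": ["2014-06-01T00:30:00"] * 2 + ["2014-06-01T02:00:00"],
                "x": [0.0, 51.0, 0.0],
                "y": [0.0, 0.0, 0.0],
            }
        )
        labels = label_points(pts, [cl], max_radius=50.0)
        assert labels == ["within", "outside", "outside"]


class TestSummaries(TestDeduplicate):
    def test_detection_probability(self):
        assert detection_probability(27, 464) == pytest.approx(0.058, abs=5e-4)
        assert detection_probability(54, 335) == pytest.approx(0.161, abs=5e-4)

    def test_cluster_frame_and_geojson(self):
        cls = [self._mk("c1", "b1", 0, {"f1", "f2"}, 3.0)]
        df = clusters_to_frame(cls)
        assert list(df["cluster_id"]) == ["c1"]
        gj = clusters_to_geojson(cls)
        assert gj["type"] == "FeatureCollection"
        assert gj["features"][0]["properties"]["cluster_id"] == "c1"
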