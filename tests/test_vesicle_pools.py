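"""Vesicle distances, pool binning, DCV dedup and docked counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _geomfix import build_stack, circle
from synaptomorph.contour_io import Contour, VesicleMark
from synaptomorph.vesicle_pools import (
    POOLS,
    VesicleRecord,
    assign_pool,
    build_pool_table,
    count_docked,
    dedup_dcv,
    min_distance_to_preaz,
)


def segment(x=0.0, y0=-500.0, y1=500.0):
    return Contour(0, "preaz", "az0", np.array([[x, y0], [x, y1]]), False)


def brute_force_distance(mark: VesicleMark, points: np.ndarray, step=0.1) -> float:
    """Membrane distance by dense sampling of the polyline at 0.1 nm steps."""
    samples = []
    for a, b in zip(points, points[1:]):
        length = np.linalg.norm(b - a)
        n = max(2, int(np.ceil(length / step)) + 1)
        t = np.linspace(0.0, 1.0, n)[:, None]
        samples.append(a + t * (b - a))
    pts = np.vstack(samples)
    d = np.linalg.norm(pts - mark.center, axis=1).min()
    return max(0.0, d - 0.5 * mark.diameter)


class TestMinDistance:
    def test_center_minus_radius(self):
        mark = VesicleMark(0, "b0", (100.0, 0.0), 40.0)
        assert min_distance_to_preaz(mark, [segment()]) == pytest.approx(80.0)

    def test_touching_is_zero(self):
        mark = VesicleMark(0, "b0", (20.0, 0.0), 40.0)
        assert min_distance_to_preaz(mark, [segment()]) == 0.0

    def test_against_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            pts = rng.uniform(0.0, 1000.0, size=(rng.integers(2, 7), 2))
            outline = Contour(0, "preaz", "az0", pts, False)
            mark = VesicleMark(
                0, "b0", rng.uniform(0, 1000, 2), rng.uniform(20, 80)
            )
            fast = min_distance_to_preaz(mark, [outline])
            slow = brute_force_distance(mark, outline.points)
            assert fast == pytest.approx(slow, abs=0.5)


class TestAssignPool:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (5.0, "rrp_p10"),
            (100.0, "rp_60_200"),
            (250.0, "resting_gt200"),
            (40.0, "interzone_20_60"),
            # boundary values belong to the lower bin
            (10.0, "rrp_p10"),
            (20.0, "rrp_p20"),
            (60.0, "interzone_20_60"),
            (200.0, "rp_60_200"),
            (0.0, "rrp_p10"),
        ],
    )
    def test_bins(self, d, expected):
        assert assign_pool(d) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_pool(-1.0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.floats(0.0, 600.0), st.floats(0.0, 600.0))
    def test_monotone_step(self, d1, d2):
        order = {p: i for i, p in enumerate(POOLS)}
        lo, hi = sorted((d1, d2))
        assert order[assign_pool(lo)] <= order[assign_pool(hi)]


class TestPoolTable:
    @staticmethod
    def enumeration_stack():
        distances = [5, 5, 15, 40, 100, 100, 150, 250, 300, 500]
        marks = [
            VesicleMark(0, "b0", (d + 20.0, float(i) * 7 - 30), 40.0)
            for i, d in enumerate(distances)
        ]
        return build_stack([(0, 50.0, [segment()], marks)])

    def test_enumerated_counts(self):
        table = build_pool_table(self.enumeration_stack(), "b0", az_ids=["az0"])
        assert table.total_svs == 10
        assert table.n_rrp_p10 == 2
        assert table.n_rrp_p20 == 3  # cumulative
        assert table.n_interzone == 1
        assert table.n_rp == 3
        assert table.n_resting == 3
        hist = table.scholl_histogram
        assert hist.sum() == table.total_svs
        assert hist[0] == 2   # 5, 5
        assert hist[1] == 1   # 15
        assert hist[3] == 1   # 40 in (30, 40]
        assert hist[9] == 2   # 100, 100
        assert hist[14] == 1  # 150
        assert hist[24] == 1  # 250
        assert hist[29] == 1  # 300
        assert hist[49] == 1  # 500 in (490, 500]

    def test_zero_vesicles(self):
        stack = build_stack([(0, 50.0, [segment()], [])])
        table = build_pool_table(stack, "b0", az_ids=["az0"])
        assert table.total_svs == 0
        assert table.scholl_histogram.sum() == 0

    def test_no_preaz_warns(self):
        marks = [VesicleMark(0, "b0", (0.0, 0.0), 40.0)]
        stack = build_stack(
            [(0, 50.0, [Contour(0, "bouton_membrane", "b0", circle(300), True)], marks)]
        )
        with pytest.warns(UserWarning, match="no associated PreAZ"):
            table = build_pool_table(stack, "b0")
        assert table.total_svs == 0
        assert table.n_undefined == 1

    def test_cross_section_distance(self):
        # vesicle on section 1, PreAZ only on section 0: Pythagorean distance
        marks = [VesicleMark(1, "b0", (30.0, 0.0), 40.0)]
        stack = build_stack(
            [(0, 50.0, [segment()], []), (1, 50.0, [], marks)]
        )
        table = build_pool_table(stack, "b0", az_ids=["az0"])
        rec = table.records[0]
        assert rec.cross_section
        assert rec.min_dist_preaz == pytest.approx(np.hypot(30.0, 50.0) - 20.0)

    def test_generated_bouton_invariants(self, default_stack):
        stack, _, _ = default_stack
        table = build_pool_table(stack, "b0", az_ids=["az0"])
        assert table.n_rrp_p20 >= table.n_rrp_p10
        assert (
            table.n_rrp_p20 + table.n_interzone + table.n_rp + table.n_resting
            == table.total_svs
        )
        assert table.scholl_histogram.sum() == table.total_svs


class TestDedupDcv:
    @staticmethod
    def mark(sec, d, x=0.0, y=0.0):
        return VesicleMark(sec, "b0", (x, y), d, "dense_core")

    def test_three_section_run_keeps_largest(self):
        marks = [self.mark(10, 60.0), self.mark(11, 80.0), self.mark(12, 70.0)]
        kept = dedup_dcv(marks)
        assert len(kept) == 1
        assert kept[0].section_index == 11 and kept[0].diameter == 80.0

    def test_non_adjacent_not_merged(self):
        marks = [self.mark(10, 70.0), self.mark(13, 70.0)]
        assert len(dedup_dcv(marks)) == 2

    def test_tie_breaks_to_lower_section(self):
        marks = [self.mark(6, 70.0), self.mark(5, 70.0)]
        kept = dedup_dcv(marks)
        assert len(kept) == 1 and kept[0].section_index == 5

    def test_lateral_separation_not_merged(self):
        marks = [self.mark(10, 60.0, x=0.0), self.mark(11, 60.0, x=100.0)]
        assert len(dedup_dcv(marks)) == 2

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(
        st.tuples(
            st.integers(0, 8),
            st.floats(50.0, 90.0),
            st.floats(-100.0, 100.0),
            st.floats(-100.0, 100.0),
        ),
        max_size=12,
    ))
    def test_idempotent_and_nonincreasing(self, raw):
        marks = [self.mark(s, d, x, y) for s, d, x, y in raw]
        once = dedup_dcv(marks)
        assert len(once) <= len(marks)
        twice = dedup_dcv(once)
        assert len(twice) == len(once)


class TestCountDocked:
    @staticmethod
    def record(dist, docked=False):
        return VesicleRecord(
            object_id="b0",
            section_index=0,
            kind="clear",
            diameter=40.0,
            min_dist_preaz=dist,
            assigned_az="az0",
            pool=assign_pool(dist),
            docked=docked,
        )

    def test_distance_rule(self):
        records = [self.record(0.0), self.record(1.0), self.record(50.0)]
        assert count_docked(records, epsilon=2.0) == 2

    def test_flag_precedence(self):
        records = [self.record(300.0, docked=True) for _ in range(5)]
        assert count_docked(records, epsilon=2.0) == 5

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            count_docked([], epsilon=-1.0)
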