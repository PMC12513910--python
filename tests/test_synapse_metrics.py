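"""Active-zone measurements against analytic patches and arithmetic oracles."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _geomfix import arc, build_stack, circle, cylinder_patch_stack
from synaptomorph.contour_io import Contour
from synaptomorph.reconstruct3d import mesh_surface_area, stitch_mesh
from synaptomorph.synapse_metrics import (
    aggregate_clefts,
    classify_az_shape,
    estimate_psd_area,
    measure_az,
    measure_cleft,
    measure_preaz,
)


class TestCleft:
    def test_symmetric_triple(self):
        m = measure_cleft(20.0, 24.0, 22.0)
        assert m.lateral_mean == 22.0
        assert m.cleft_mean == 22.0
        assert m.cleft_sd == 0.0

    def test_asymmetric_triple(self):
        m = measure_cleft(18.0, 22.0, 26.0)
        assert m.lateral_mean == 20.0
        assert m.cleft_mean == 23.0
        # sample SD of {20, 26}
        assert m.cleft_sd == pytest.approx(np.sqrt(18.0), rel=1e-12)

    @pytest.mark.parametrize("w", [15.0, 22.0, 30.0])
    def test_identical_widths(self, w):
        m = measure_cleft(w, w, w)
        assert m.cleft_mean == w and m.cleft_sd == 0.0

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            measure_cleft(0.0, 22.0, 22.0)

    def test_aggregate_single(self):
        with pytest.warns(UserWarning, match="single"):
            mean, sd, n = aggregate_clefts([measure_cleft(22, 22, 22)])
        assert (mean, sd, n) == (22.0, 0.0, 1)

    def test_aggregate_pair(self):
        ms = [measure_cleft(20, 20, 20), measure_cleft(24, 24, 24)]
        mean, sd, n = aggregate_clefts(ms)
        assert mean == 22.0
        assert sd == pytest.approx(np.sqrt(8.0), rel=1e-12)
        assert n == 2

    def test_aggregate_simulated(self):
        rng = np.random.default_rng(11)
        ms = [
            measure_cleft(*np.clip(rng.normal(22.0, 1.0, 3), 1.0, None))
            for _ in range(100)
        ]
        mean, sd, n = aggregate_clefts(ms)
        assert abs(mean - 22.0) < 0.5
        assert n == 100

    def test_aggregate_empty(self):
        with pytest.raises(ValueError):
            aggregate_clefts([])


class TestPsdEstimate:
    def test_equal_outlines(self):
        assert estimate_psd_area(0.20e6, 1000.0, 1000.0) == pytest.approx(0.20e6)

    def test_printed_formula(self):
        # 0.12 um^2 * 1.5 um / 1.0 um = 0.18 um^2
        assert estimate_psd_area(0.12e6, 1500.0, 1000.0) == pytest.approx(0.18e6)

    def test_empty_psd_outline(self):
        assert estimate_psd_area(0.30e6, 0.0, 1200.0) == 0.0

    def test_zero_preaz_length_rejected(self):
        with pytest.raises(ValueError, match="l_preaz"):
            estimate_psd_area(0.1e6, 100.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        sa=st.floats(0.0, 1e7),
        l_psd=st.floats(0.0, 1e4),
        l_pre=st.floats(1e-3, 1e4),
        lam=st.floats(1e-3, 1e3),
    )
    def test_linearity(self, sa, l_psd, l_pre, lam):
        base = estimate_psd_area(sa, l_psd, l_pre)
        assert estimate_psd_area(lam * sa, l_psd, l_pre) == pytest.approx(
            lam * base, rel=1e-12, abs=1e-9
        )
        assert estimate_psd_area(sa, lam * l_psd, l_pre) == pytest.approx(
            lam * base, rel=1e-12, abs=1e-9
        )


class TestPreAZBand:
    def test_cylindrical_patch_area(self):
        # 60 degree arc on a cylinder wall spanning 4 sections of 50 nm:
        # flanges extend the band to the full 200 nm of tissue
        stack = cylinder_patch_stack(radius=400.0, thickness=50.0, n_sections=4)
        sa, l_preaz = measure_preaz(stack, "b0", "az0")
        expected = (60.0 / 360.0) * 2 * np.pi * 400.0 * 200.0
        assert sa == pytest.approx(expected, rel=0.10)
        assert l_preaz == pytest.approx(4 * np.deg2rad(60) * 400.0, rel=0.01)

    def test_displaced_outline_zero_area(self):
        # PreAZ trace floats 100 nm outside the membrane: no coincidence
        sections = []
        for i in range(3):
            cs = [
                Contour(i, "bouton_membrane", "b0", circle(400.0, 256), True),
                Contour(i, "preaz", "az0", arc(500.0, 60.0), False),
            ]
            sections.append((i, 50.0, cs, []))
        stack = build_stack(sections)
        with pytest.warns(UserWarning, match="farther than"):
            sa, l_preaz = measure_preaz(stack, "b0", "az0")
        assert sa == 0.0
        assert l_preaz > 0.0

    def test_full_circumference(self):
        sections = []
        for i in range(4):
            ring = circle(400.0, 256)
            cs = [
                Contour(i, "bouton_membrane", "b0", ring, True),
                Contour(i, "preaz", "az0", np.vstack([ring, ring[:1]]), False),
            ]
            sections.append((i, 50.0, cs, []))
        stack = build_stack(sections)
        sa, _ = measure_preaz(stack, "b0", "az0")
        assert sa == pytest.approx(2 * np.pi * 400.0 * 200.0, rel=0.10)

    def test_monotone_in_coincidence(self, default_stack):
        stack, _, scene = default_stack
        areas = [
            measure_preaz(stack, "b0", "az0", coincidence_nm=c)[0]
            for c in (10.0, 30.0, 60.0)
        ]
        assert areas[0] <= areas[1] <= areas[2]

    def test_preaz_at_most_bouton_area(self, default_stack):
        stack, _, _ = default_stack
        sa, _ = measure_preaz(stack, "b0", "az0")
        total = mesh_surface_area(stitch_mesh(stack, "b0"))
        assert 0.0 < sa <= total

    def test_preaz_recovery_on_default_scene(self, default_stack):
        stack, truth, _ = default_stack
        sa, _ = measure_preaz(stack, "b0", "az0")
        assert sa == pytest.approx(truth.sa_preaz[0], rel=0.10)


class TestShapeClassification:
    def test_macular_straight_outlines(self):
        sections = []
        for i in range(3):
            pts = np.column_stack([np.linspace(0, 400, 30), np.zeros(30)])
            sections.append((i, 50.0, [Contour(i, "preaz", "az0", pts, False)], []))
        stack = build_stack(sections)
        assert classify_az_shape(stack, "az0") == "macular"

    def test_ring_annulus(self):
        # full-circle outline: its dilated footprint is an annulus with a
        # large central hole
        pts = circle(200.0, 128)
        loop = np.vstack([pts, pts[:1]])
        stack = build_stack([(0, 55.0, [Contour(0, "preaz", "az0", loop, False)], [])])
        assert classify_az_shape(stack, "az0") == "ring"

    def test_perforated_small_hole(self):
        pts = circle(50.0, 64)
        loop = np.vstack([pts, pts[:1]])
        stack = build_stack([(0, 55.0, [Contour(0, "preaz", "az0", loop, False)], [])])
        assert classify_az_shape(stack, "az0") == "perforated"

    def test_horseshoe_c_shape(self):
        pts = arc(200.0, 300.0, n=96)
        stack = build_stack([(0, 55.0, [Contour(0, "preaz", "az0", pts, False)], [])])
        assert classify_az_shape(stack, "az0") == "horseshoe"

    def test_fragmented_projection_is_perforated(self):
        c1 = arc(300.0, 40.0, psi0=0.0)
        c2 = arc(300.0, 40.0, psi0=np.pi)
        stack = build_stack(
            [(0, 55.0, [Contour(0, "preaz", "az0", c1, False),
                        Contour(0, "preaz", "az0", c2, False)], [])]
        )
        assert classify_az_shape(stack, "az0") == "perforated"

    def test_rigid_invariance(self, default_stack):
        stack, _, _ = default_stack
        base = classify_az_shape(stack, "az0")
        theta = np.deg2rad(70.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        import copy

        moved = copy.deepcopy(stack)
        for sec in moved.sections:
            for c in sec.contours:
                c.points = c.points @ rot.T + np.array([500.0, -250.0])
        assert classify_az_shape(moved, "az0") == base


class TestMeasureAZ:
    def test_cross_product_invariant(self):
        stack = cylinder_patch_stack(radius=400.0, n_sections=4, cleft=22.0)
        m = measure_az(stack, "b0", "az0", "psd0")
        assert m.sa_psd * m.l_preaz == pytest.approx(
            m.sa_preaz * m.l_psd, rel=1e-12
        )
        assert m.n_sections_spanned == 4
        assert m.l_psd > m.l_preaz  # PSD outline offset outward

    def test_missing_psd_warns(self):
        stack = cylinder_patch_stack(radius=400.0, n_sections=4)
        with pytest.warns(UserWarning, match="no PSD outline"):
            m = measure_az(stack, "b0", "az0", None)
        assert m.sa_psd == 0.0 and m.l_psd == 0.0
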