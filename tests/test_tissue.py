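"""Tissue extents, union volume, growth phases, midline crossing, d_rel."""

import numpy as np
import pytest

from psmflow import (
    default_config,
    generate_stage_snapshot,
    growth_phase,
    labelled_extents,
    labelled_volume,
    midline_crossing_fraction,
    relative_displacement,
)
from psmflow.errors import DegenerateGeometryError, InsufficientDataError
from psmflow.types import AxisFrame, StageSnapshot


def snap_of(cells, stage=22):
    return StageSnapshot(stage=stage, cells=cells, frame=AxisFrame.default())


class TestExtents:
    def test_single_sphere(self, cell_factory):
        cell = cell_factory(axes=(5.0, 5.0, 5.0))
        dims = labelled_extents(snap_of([cell]))
        assert dims.length_um == pytest.approx(10.0)
        assert dims.height_um == pytest.approx(10.0)
        assert dims.width_um == pytest.approx(10.0)

    def test_two_separated_cells(self, cell_factory):
        a = cell_factory(cid=1, centroid=(0, 0, 0), axes=(2.0, 2.0, 2.0))
        b = cell_factory(cid=2, centroid=(100, 0, 0), axes=(2.0, 2.0, 2.0))
        dims = labelled_extents(snap_of([a, b]))
        assert dims.length_um == pytest.approx(104.0)

    def test_no_labelled_cells_rejected(self):
        with pytest.raises(InsufficientDataError):
            labelled_extents(snap_of([]))

    def test_strand_elongation_across_stages(self, config):
        """The labelled strand roughly doubles its AP length between the
        early and late tail-bud stages (~500 -> ~1200 µm)."""
        d22 = labelled_extents(generate_stage_snapshot(config, 22, 1))
        d30 = labelled_extents(generate_stage_snapshot(config, 30, 1))
        assert d22.length_um == pytest.approx(500.0, rel=0.15)
        assert d30.length_um == pytest.approx(1200.0, rel=0.15)

    def test_stage30_height_regular_along_strand(self, config):
        """DV height stays near the configured ~140 µm along the stage-30
        strand (windowed extents away from the posterior hook)."""
        snap = generate_stage_snapshot(config, 30, 1)
        cells = [c for c in snap.cells if not c.sox2]
        xs = np.array([c.centroid[0] for c in cells])
        heights = []
        for lo in np.arange(xs.min() + 100, xs.max() - 200, 100):
            window = [c for c in cells if lo <= c.centroid[0] < lo + 100]
            if len(window) >= 10:
                z = np.array([c.centroid[2] for c in window])
                r = np.array([c.axes_um[0] for c in window])
                heights.append((z + r).max() - (z - r).min())
        heights = np.array(heights)
        assert heights.max() / heights.min() < 1.45
        assert np.median(heights) == pytest.approx(140.0, rel=0.35)


class TestVolume:
    def test_single_sphere_closed_form(self, cell_factory):
        cell = cell_factory(axes=(10.0, 10.0, 10.0))
        v = labelled_volume(snap_of([cell]), voxel_um=1.0)
        assert v == pytest.approx(4 / 3 * np.pi * 1000, rel=0.05)

    def test_union_counts_overlap_once(self, cell_factory):
        a = cell_factory(cid=1, axes=(8.0, 8.0, 8.0))
        b = cell_factory(cid=2, axes=(8.0, 8.0, 8.0))
        v1 = labelled_volume(snap_of([a]), voxel_um=1.0)
        v2 = labelled_volume(snap_of([a, b]), voxel_um=1.0)
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_disjoint_parts_add(self, cell_factory):
        a = cell_factory(cid=1, centroid=(0, 0, 0), axes=(6.0, 5.0, 4.0))
        b = cell_factory(cid=2, centroid=(100, 0, 0), axes=(7.0, 6.0, 5.0))
        va = labelled_volume(snap_of([a]), 1.0)
        vb = labelled_volume(snap_of([b]), 1.0)
        vab = labelled_volume(snap_of([a, b]), 1.0)
        assert vab == pytest.approx(va + vb, rel=0.02)

    def test_grid_refinement_converges(self, config):
        cfg = config.with_(counts={22: (200, 0)})
        snap = generate_stage_snapshot(cfg, 22, 4)
        v2 = labelled_volume(snap, voxel_um=2.0)
        v1 = labelled_volume(snap, voxel_um=1.0)
        assert abs(v1 - v2) / v1 < 0.02


class TestGrowthPhase:
    def test_constant_then_doubling(self):
        assert growth_phase([100.0, 100.0, 200.0]) == ["isovolumetric", "volumetric"]

    def test_identity(self):
        assert growth_phase([100.0, 100.0]) == ["isovolumetric"]

    def test_shrinking(self):
        assert growth_phase([100.0, 80.0]) == ["shrinking"]

    def test_bad_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            growth_phase([100.0])
        with pytest.raises(DegenerateGeometryError):
            growth_phase([100.0, -1.0])


class TestMidlineCrossing:
    def test_all_on_graft_side(self, cell_factory):
        cells = [cell_factory(cid=i, centroid=(0, -10 - i, 0)) for i in range(5)]
        assert midline_crossing_fraction(snap_of(cells)) == 0.0

    def test_cell_on_midline_not_crossed(self, cell_factory):
        cells = [cell_factory(cid=1, centroid=(0, 0.0, 0)), cell_factory(cid=2, centroid=(0, -5, 0))]
        assert midline_crossing_fraction(snap_of(cells)) == 0.0

    def test_graft_series_crossing_rules(self, config):
        from psmflow import generate_graft_series

        (median,) = generate_graft_series(config, "median", [28], 1)
        assert midline_crossing_fraction(median) > 0
        (para,) = generate_graft_series(config, "paramedian", [28], 1)
        crossed_outside_pz = [
            c for c in para.cells if c.centroid[1] > 0 and c.region != "PZ"
        ]
        assert crossed_outside_pz == []


class TestRelativeDisplacement:
    def test_straight_outline_midpoint(self):
        outline = np.array([[0, 0, 0], [9300.0, 0, 0]])
        d = relative_displacement(outline, np.array([4650.0, 10.0, 0]))
        assert d.d_rel == pytest.approx(0.5)
        assert d.b_um == pytest.approx(9300.0)

    def test_anterior_tip_is_zero(self):
        outline = np.array([[0, 0, 0], [100.0, 0, 0]])
        assert relative_displacement(outline, np.zeros(3)).d_rel == 0.0

    def test_semicircle_quarter_arc(self):
        theta = np.linspace(0, np.pi, 2000)
        r = 500.0
        outline = np.column_stack([r * np.sin(theta), np.zeros_like(theta), r * (1 - np.cos(theta))])
        quarter = np.array([r * np.sin(np.pi / 4), 0.0, r * (1 - np.cos(np.pi / 4))])
        assert relative_displacement(outline, quarter).d_rel == pytest.approx(0.25, abs=1e-3)

    def test_zero_length_outline_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            relative_displacement(np.zeros((2, 3)), np.zeros(3))

    def test_rigid_and_scale_invariance(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 1, 300)
        outline = np.column_stack([1000 * t, 80 * np.sin(3 * t), 50 * t**2])
        centroid = outline[173] + np.array([0.0, 6.0, -4.0])
        d0 = relative_displacement(outline, centroid).d_rel
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.uniform(-100, 100, 3)
        for scale in (1.0, 3.7):
            d1 = relative_displacement(scale * outline @ q.T + shift, scale * q @ centroid + shift).d_rel
            assert d1 == pytest.approx(d0, rel=1e-9)
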