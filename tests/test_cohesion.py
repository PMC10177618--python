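"""Region assignment, pairwise cohesion and nearest-neighbour density against
brute-force oracles."""

import numpy as np
import pytest

from psmflow import default_config, generate_stage_snapshot
from psmflow.cohesion import (
    assign_regions,
    compare_epidermis_conditions,
    nearest_neighbour_density,
    pairwise_cohesion,
)
from psmflow.errors import InsufficientDataError
from psmflow.io import assign_sections
from psmflow.strand import ArcSpline, RegionPartition, region_partition, strand_centerline


def brute_force_pairs(points):
    out = []
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            out.append(float(np.linalg.norm(points[i] - points[j])))
    return np.array(out)


class TestAssignRegions:
    def test_straight_spline_matches_x_binning(self, cell_factory):
        rng = np.random.default_rng(0)
        n = 300
        xs = rng.uniform(0, 300, n)
        cells = [cell_factory(cid=i, centroid=(x, rng.uniform(-5, 5), rng.uniform(-5, 5)))
                 for i, x in enumerate(xs)]
        # spline stored anterior-to-posterior: x from 0 to 300, arc-from-posterior = 300 - x
        spline = ArcSpline.straight(300.0)
        part = RegionPartition(np.array([100.0, 200.0, 300.0]), ("PZ", "posterior_PSM", "medial_PSM"))
        labelled = assign_regions(cells, part, spline)
        expected = np.where(300 - xs <= 100, "PZ", np.where(300 - xs <= 200, "posterior_PSM", "medial_PSM"))
        assert [c.region for c in labelled] == list(expected)

    def test_breakpoint_tie_goes_posterior(self, cell_factory):
        spline = ArcSpline.straight(300.0)
        part = RegionPartition(np.array([100.0, 200.0, 300.0]), ("PZ", "posterior_PSM", "medial_PSM"))
        cell = cell_factory(cid=1, centroid=(200.0, 0, 0))  # arc-from-posterior exactly 100
        (labelled,) = assign_regions([cell], part, spline)
        assert labelled.region == "PZ"

    def test_generated_snapshot_fully_assigned(self, config):
        snap = generate_stage_snapshot(config, 28, 1)
        spline = strand_centerline(config.geometry[28])
        part = region_partition(config, 28)
        meso = [c for c in snap.cells if not c.sox2]
        labelled = assign_regions(meso, part, spline)
        assert all(c.region in part.labels for c in labelled)

    def test_outside_domain_warns_and_clamps(self, cell_factory):
        spline = ArcSpline.straight(100.0)
        part = RegionPartition(np.array([50.0, 100.0]), ("PZ", "posterior_PSM"))
        far = cell_factory(cid=1, centroid=(150.0, 0, 0))
        with pytest.warns(UserWarning, match="nearest terminal"):
            (labelled,) = assign_regions([far], part, spline)
        assert labelled.region == "PZ"


class TestPairwiseCohesion:
    def test_two_cells_single_pair(self, cell_factory):
        cells = [cell_factory(cid=1, centroid=(5, 0, 0)), cell_factory(cid=2, centroid=(5, 10, 0))]
        secs = assign_sections(cells, "AP", 80.0)
        res = pairwise_cohesion(cells, secs, region="PZ")
        assert res.n_pairs == 1
        assert res.median_um == pytest.approx(10.0)
        assert res.frac_below_25um == 1.0

    def test_matches_brute_force_within_sections(self, cell_factory):
        rng = np.random.default_rng(1)
        cells = [cell_factory(cid=i, centroid=rng.uniform(0, 240, 3)) for i in range(50)]
        secs = assign_sections(cells, "AP", 80.0)
        res = pairwise_cohesion(cells, secs, region="PZ")
        expected = []
        for ids in secs.members.values():
            grp = [c.centroid for c in cells if c.id in ids]
            if len(grp) >= 2:
                expected.append(brute_force_pairs(grp))
        expected = np.sort(np.concatenate(expected))
        assert res.n_pairs == expected.size
        np.testing.assert_allclose(np.sort(res.distances_um), expected, rtol=1e-12)

    def test_no_cross_section_pairs(self, cell_factory):
        cells = [cell_factory(cid=1, centroid=(10, 0, 0)), cell_factory(cid=2, centroid=(100, 0, 0)),
                 cell_factory(cid=3, centroid=(110, 0, 0))]
        secs = assign_sections(cells, "AP", 80.0)
        res = pairwise_cohesion(cells, secs)
        assert res.n_pairs == 1  # only the two co-sectioned cells pair up

    def test_insufficient_pairs_rejected(self, cell_factory):
        cells = [cell_factory(cid=1, centroid=(10, 0, 0)), cell_factory(cid=2, centroid=(100, 0, 0))]
        secs = assign_sections(cells, "AP", 80.0)
        with pytest.raises(InsufficientDataError, match="insufficient pairs"):
            pairwise_cohesion(cells, secs)

    def test_2d_mode_projects_out_section_axis(self, cell_factory):
        cells = [cell_factory(cid=1, centroid=(0, 0, 0)), cell_factory(cid=2, centroid=(30, 40, 0))]
        secs = assign_sections(cells, "AP", 80.0)
        assert pairwise_cohesion(cells, secs, mode="3d").median_um == pytest.approx(50.0)
        assert pairwise_cohesion(cells, secs, mode="2d").median_um == pytest.approx(40.0)

    def test_rigid_motion_invariance(self, cell_factory):
        """Rotating the whole body and sectioning along the rotated AP axis
        (plus a translation orthogonal to it) leaves the cohesion statistics
        unchanged."""
        from psmflow.types import AxisFrame

        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 200, (30, 3))
        cells = [cell_factory(cid=i, centroid=p) for i, p in enumerate(pts)]
        res0 = pairwise_cohesion(cells, assign_sections(cells, "AP", 80.0))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        ap, ml, dv = q @ np.eye(3)[0], q @ np.eye(3)[1], q @ np.eye(3)[2]
        shift = 13.0 * ml - 4.0 * dv  # orthogonal to AP: slab grid unchanged
        frame = AxisFrame(np.zeros(3), ap, ml, dv)
        moved = [cell_factory(cid=i, centroid=q @ p + shift) for i, p in enumerate(pts)]
        res1 = pairwise_cohesion(moved, assign_sections(moved, "AP", 80.0, frame=frame))
        assert res1.median_um == pytest.approx(res0.median_um, rel=1e-9)
        assert res1.n_pairs == res0.n_pairs


class TestNearestNeighbour:
    def test_collinear_arithmetic(self, cell_factory):
        cells = [cell_factory(cid=i, centroid=(x, 0, 0)) for i, x in enumerate((0.0, 10.0, 25.0))]
        res = nearest_neighbour_density(cells)
        np.testing.assert_allclose(sorted(res.nn_distances_um), [10.0, 10.0, 15.0])

    def test_matches_brute_force(self, cell_factory):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 100, (200, 3))
        cells = [cell_factory(cid=i, centroid=p) for i, p in enumerate(pts)]
        res = nearest_neighbour_density(cells)
        d2 = ((pts[:, None] - pts[None]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        np.testing.assert_allclose(res.nn_distances_um, np.sqrt(d2.min(1)), rtol=1e-12)

    def test_nn_bounded_by_any_pair(self, cell_factory):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 50, (40, 3))
        cells = [cell_factory(cid=i, centroid=p) for i, p in enumerate(pts)]
        res = nearest_neighbour_density(cells)
        for i in range(len(pts)):
            dists = np.linalg.norm(pts - pts[i], axis=1)
            assert res.nn_distances_um[i] <= dists[dists > 0].min() + 1e-12

    def test_too_few_cells_rejected(self, cell_factory):
        with pytest.raises(InsufficientDataError):
            nearest_neighbour_density([cell_factory()])

    def test_density_ordering_somite_denser_than_psm(self, config):
        """Sphere-grouped density recovers the configured ordering: newly
        formed somites are packed tighter (~25 µm) than the PSM (~30 µm)."""
        from psmflow.pipeline import region_density

        nn_psm, nn_som = [], []
        for seed in (1, 2, 3):
            snap = generate_stage_snapshot(config, 30, seed)
            rng = np.random.default_rng(seed)
            dens = region_density(snap, config, rng)
            nn_som.extend(dens["somite"].nn_distances_um)
            for key in ("PZ", "posterior_PSM", "medial_PSM", "anterior_PSM"):
                nn_psm.extend(dens[key].nn_distances_um)
        assert np.median(nn_som) < np.median(nn_psm)


class TestCompareEpidermis:
    def test_identity_gives_zero_differences(self, cell_factory):
        rng = np.random.default_rng(5)
        cells = [cell_factory(cid=i, centroid=rng.uniform(0, 60, 3)) for i in range(30)]
        res = nearest_neighbour_density(cells, region="PZ")
        rows = compare_epidermis_conditions({"PZ": res}, {"PZ": res})
        assert rows[0]["median_diff_um"] == 0.0
        assert rows[0]["p_value"] == 1.0

    def test_missing_region_skipped_with_warning(self, cell_factory):
        rng = np.random.default_rng(6)
        cells = [cell_factory(cid=i, centroid=rng.uniform(0, 60, 3)) for i in range(20)]
        res = nearest_neighbour_density(cells, region="PZ")
        with pytest.warns(UserWarning, match="missing"):
            rows = compare_epidermis_conditions({"PZ": res, "somite": res}, {"PZ": res})
        assert [r["region"] for r in rows] == ["PZ"]
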