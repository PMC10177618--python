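"""Synthetic tail-bud generator: counts, determinism, schedules, grafts,
epidermis removal, timecourses."""

import numpy as np
import pytest

from psmflow import (
    apply_epidermis_removal,
    default_config,
    generate_embryo_timecourse,
    generate_graft_series,
    generate_stage_snapshot,
)
from psmflow.config import config_from_dict, config_to_dict, load_config, save_config
from psmflow.errors import ConfigurationError
from psmflow.generator import sample_aspect_ratios
from psmflow.types import is_mesodermal


class TestStageSnapshot:
    def test_exact_configured_counts(self, config):
        snap = generate_stage_snapshot(config, 22, 1)
        meso = [c for c in snap.cells if not c.sox2]
        neural = [c for c in snap.cells if c.sox2]
        assert len(meso) == 1095
        assert len(neural) == 27
        assert all(is_mesodermal(c.region) for c in meso)

    def test_region_count_conservation_across_stages(self, config):
        for stage, expected in ((19, 527), (28, 1232), (30, 1989)):
            snap = generate_stage_snapshot(config, stage, 2)
            assert sum(1 for c in snap.cells if not c.sox2) == expected

    def test_seed_determinism_bit_identical(self, config):
        a = generate_stage_snapshot(config, 30, 17)
        b = generate_stage_snapshot(config, 30, 17)
        assert len(a.cells) == len(b.cells)
        for ca, cb in zip(a.cells, b.cells):
            assert np.array_equal(ca.centroid, cb.centroid)
            assert np.array_equal(ca.axes_um, cb.axes_um)
            assert ca.filopodia_um == cb.filopodia_um
        for da, db in zip(a.divisions, b.divisions):
            assert np.array_equal(da.centriole1, db.centriole1)

    def test_different_seeds_differ(self, config):
        a = generate_stage_snapshot(config, 22, 1)
        b = generate_stage_snapshot(config, 22, 2)
        assert not np.array_equal(a.cells[0].centroid, b.cells[0].centroid)

    def test_empty_config_gives_empty_snapshot(self, config):
        cfg = config.with_(counts={22: (0, 0)})
        snap = generate_stage_snapshot(cfg, 22, 1)
        assert snap.cells == []
        assert abs(np.linalg.norm(snap.frame.ap) - 1) < 1e-12

    def test_unknown_stage_rejected(self, config):
        with pytest.raises(ConfigurationError):
            generate_stage_snapshot(config, 99, 1)

    def test_aspect_sample_matches_configured_moments(self, config):
        rng = np.random.default_rng(0)
        draws = sample_aspect_ratios(config.shapes["PZ"], 10_000, rng)
        assert draws.mean() == pytest.approx(2.33, rel=0.02)
        assert draws.min() >= 1.0

    def test_cell_volume_halving_schedule(self, config):
        # configured: late PSM/somite mean volume is half the early PZ mean
        assert config.shapes["posterior_PSM"].mean_volume_um3 == pytest.approx(
            config.shapes["PZ"].mean_volume_um3 / 2
        )
        snap22 = generate_stage_snapshot(config, 22, 5)
        snap30 = generate_stage_snapshot(config, 30, 5)
        v22 = np.mean([c.volume_um3 for c in snap22.cells if c.region == "PZ"])
        v30 = np.mean(
            [c.volume_um3 for c in snap30.cells if c.region.startswith(("posterior", "medial", "anterior", "somite"))]
        )
        assert v30 == pytest.approx(v22 / 2, rel=0.05)

    def test_tissue_volume_two_phase_schedule(self, config):
        g = config.geometry
        assert g[28].tissue_volume_um3 == pytest.approx(g[22].tissue_volume_um3)
        assert g[30].tissue_volume_um3 == pytest.approx(2 * g[28].tissue_volume_um3)


class TestConfigSerialization:
    def test_yaml_round_trip(self, tmp_path, config):
        cfg = config.with_(cohesion_group_size=28, seed=9)
        p = tmp_path / "cfg.yaml"
        save_config(cfg, p)
        back = load_config(p)
        assert config_to_dict(back) == config_to_dict(cfg)

    def test_json_round_trip(self, tmp_path, config):
        p = tmp_path / "cfg.json"
        save_config(config, p)
        assert config_to_dict(load_config(p)) == config_to_dict(config)

    def test_invalid_orientation_probs_rejected(self, config):
        d = config_to_dict(config)
        d["shapes"]["PZ"]["orientation_probs"] = [0.5, 0.5, 0.5, 0.5]
        with pytest.raises(ConfigurationError):
            config_from_dict(d)


class TestGraftSeries:
    @pytest.mark.parametrize("stage", [22, 28, 30])
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_anterior_reach_ordering(self, config, stage, seed):
        mins = {}
        for origin in ("median", "paramedian", "lateral"):
            (snap,) = generate_graft_series(config, origin, [stage], seed)
            mins[origin] = min(c.centroid[0] for c in snap.cells)
        assert mins["median"] < mins["paramedian"] < mins["lateral"]

    def test_origin_label_carried(self, config):
        (snap,) = generate_graft_series(config, "median", [28], 1)
        assert all(c.origin == "median" for c in snap.cells)

    def test_median_reaches_anterior_and_crosses(self, config):
        (snap,) = generate_graft_series(config, "median", [28], 1)
        regions = {c.region for c in snap.cells}
        assert regions <= {"medial_PSM", "anterior_PSM"}
        assert any(c.centroid[1] > 0 for c in snap.cells)

    def test_lateral_confined_posteriorly_at_28(self, config):
        (snap,) = generate_graft_series(config, "lateral", [28], 1)
        assert {c.region for c in snap.cells} <= {"PZ", "posterior_PSM"}

    @pytest.mark.parametrize("origin", ["paramedian", "lateral"])
    def test_no_contralateral_outside_pz(self, config, origin):
        for stage in (28, 30):
            (snap,) = generate_graft_series(config, origin, [stage], 4)
            crossed = [c for c in snap.cells if c.centroid[1] > 0]
            assert all(c.region == "PZ" for c in crossed)

    def test_unknown_origin_rejected(self, config):
        with pytest.raises(ConfigurationError):
            generate_graft_series(config, "dorsal", [28], 1)


class TestEpidermisRemoval:
    def test_identity_at_factor_one(self, config):
        snap = generate_stage_snapshot(config, 28, 2)
        out = apply_epidermis_removal(snap, "left", 1.0)
        assert all(np.array_equal(a.centroid, b.centroid) for a, b in zip(snap.cells, out.cells))

    def test_left_removal_spreads_left_pz_only(self, config):
        from psmflow.cohesion import nearest_neighbour_density

        snap = generate_stage_snapshot(config, 28, 2)
        out = apply_epidermis_removal(snap, "left", 1.5)
        assert len(out.cells) == len(snap.cells)

        def med(s, region, side):
            cells = [c for c in s.cells if c.region == region and np.sign(c.centroid[1]) == side]
            return nearest_neighbour_density(cells).median_um

        assert med(out, "PZ", -1) > med(snap, "PZ", -1)
        assert med(out, "PZ", 1) == pytest.approx(med(snap, "PZ", 1))
        assert med(out, "anterior_PSM", -1) == pytest.approx(med(snap, "anterior_PSM", -1))

    def test_bilateral_spreads_both_sides(self, config):
        from psmflow.cohesion import nearest_neighbour_density

        snap = generate_stage_snapshot(config, 28, 3)
        out = apply_epidermis_removal(snap, "bilateral", 1.5)
        for side in (-1, 1):
            c0 = [c for c in snap.cells if c.region == "PZ" and np.sign(c.centroid[1]) == side]
            c1 = [c for c in out.cells if c.region == "PZ" and np.sign(c.centroid[1]) == side]
            assert nearest_neighbour_density(c1).median_um > nearest_neighbour_density(c0).median_um

    def test_bad_factor_rejected(self, config):
        snap = generate_stage_snapshot(config, 28, 2)
        with pytest.raises(ConfigurationError):
            apply_epidermis_removal(snap, "left", 0.5)


class TestTimecourse:
    def test_epidermis_keeps_arc_position(self, config):
        from psmflow.tissue import relative_displacement

        series = generate_embryo_timecourse(config, "epidermis", 0.4, [22, 28, 30, 40], 0)
        a_vals = [relative_displacement(o, c).a_um for o, c in series]
        assert np.allclose(a_vals, a_vals[0], rtol=1e-6)

    def test_endoderm_stationary_until_30(self, config):
        from psmflow.tissue import relative_displacement

        series = generate_embryo_timecourse(config, "endoderm", 0.6, [22, 30, 40], 0)
        a = [relative_displacement(o, c).a_um for o, c in series]
        assert a[1] == pytest.approx(a[0], rel=1e-6)
        assert a[2] < a[1]

    def test_paraxial_anterior_most_site_stays_zero(self, config):
        series = generate_embryo_timecourse(config, "paraxial", 0.0, [22, 30, 40], 0)
        from psmflow.tissue import relative_displacement

        assert all(relative_displacement(o, c).a_um == pytest.approx(0.0, abs=1e-9) for o, c in series)

    def test_paraxial_shifts_more_than_epidermis(self, config):
        from psmflow.tissue import relative_displacement

        stages = [22, 28, 30, 35, 40]
        par = [relative_displacement(o, c).d_rel
               for o, c in generate_embryo_timecourse(config, "paraxial", 0.5, stages, 0)]
        epi = [relative_displacement(o, c).d_rel
               for o, c in generate_embryo_timecourse(config, "epidermis", 0.5, stages, 0)]
        for i in range(1, len(stages)):
            assert par[i] - par[0] < epi[i] - epi[0]

    def test_bad_site_rejected(self, config):
        with pytest.raises(ConfigurationError):
            generate_embryo_timecourse(config, "paraxial", 1.2, [22, 30], 0)
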