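"""End-to-end orchestration and group statistics.

``run_morphometry`` composes the generator and all analysis stages into the
per-stage report (cell numbers, division orientation, shape/orientation,
cohesion, density, tissue dimensions, growth phases, relative displacement)
plus per-statistic TSV tables.  ``compare_groups`` is the one-way ANOVA with
Holm-adjusted pairwise follow-ups used wherever group differences are
reported.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohesion import (
    nearest_neighbour_density,
    pairwise_cohesion,
    thin_to_density,
)
from .config import GeneratorConfig, load_config
from .errors import InsufficientDataError
from .generator import generate_embryo_timecourse, generate_stage_snapshot
from .geometry import orientation_fractions, spindle_ap_fraction
from .io import assign_sections
from .strand import cross_section_halfwidth, region_partition
from .summary import SummaryTable, write_summary_table
from .tissue import growth_phase, labelled_extents, relative_displacement
from .types import StageSnapshot, cell_ellipsoid, is_mesodermal

log = logging.getLogger("psmflow")


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    groups: tuple[str, ...]
    f_statistic: float
    p_value: float
    pairwise_adjusted_p: dict[tuple[str, str], float]
    pairwise_raw_p: dict[tuple[str, str], float]
    method: str = "one-way-anova+holm"


def compare_groups(groups: dict[str, np.ndarray], parameter: str = "") -> GroupComparison:
    """One-way ANOVA across named groups with Holm-adjusted pairwise tests."""
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(names) < 2:
        raise InsufficientDataError("need at least 2 groups")
    for k, arr in zip(names, arrays):
        if arr.size < 2:
            raise InsufficientDataError(f"group {k!r} has fewer than 2 values")
    # explicit sums of squares (keeps the degenerate all-equal case exact)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    dfb = len(arrays) - 1
    dfw = sum(a.size for a in arrays) - len(arrays)
    if ssw == 0 and ssb == 0:
        f, p = 0.0, 1.0
    elif ssw == 0:
        f, p = np.inf, 0.0
    else:
        f = (ssb / dfb) / (ssw / dfw)
        p = float(stats.f.sf(f, dfb, dfw))
    pairs = list(itertools.combinations(names, 2))
    raw = []
    for a_name, b_name in pairs:
        a, b = groups[a_name], groups[b_name]
        if np.var(a) == 0 and np.var(b) == 0:
            raw.append(1.0 if np.mean(a) == np.mean(b) else 0.0)
        else:
            raw.append(float(stats.ttest_ind(a, b).pvalue))
    if raw:
        adj = multipletests(raw, method="holm")[1]
    else:
        adj = []
    return GroupComparison(
        parameter=parameter,
        groups=tuple(names),
        f_statistic=float(f),
        p_value=float(p),
        pairwise_adjusted_p=dict(zip(pairs, (float(x) for x in adj))),
        pairwise_raw_p=dict(zip(pairs, (float(x) for x in raw))),
    )


# --- report helpers -------------------------------------------------------------

def _regions_present(snapshot: StageSnapshot) -> list[str]:
    seen: list[str] = []
    for c in snapshot.cells:
        key = "somite" if c.region.startswith("somite") else c.region
        if is_mesodermal(c.region) and key not in seen:
            seen.append(key)
    return seen


def _region_cells(snapshot: StageSnapshot, key: str):
    if key == "somite":
        return [c for c in snapshot.cells if c.region.startswith("somite")]
    return [c for c in snapshot.cells if c.region == key]


def region_cohesion(snapshot: StageSnapshot, section_um: float = 80.0):
    """Per-region cohesion: prefers the focally labelled clump (origin
    'median') when present, otherwise all labelled cells of the region."""
    out = {}
    for key in _regions_present(snapshot):
        cells = _region_cells(snapshot, key)
        clump = [c for c in cells if c.origin == "median"]
        use = clump if len(clump) >= 2 else cells
        sections = assign_sections(use, axis="AP", thickness_um=section_um, frame=snapshot.frame)
        try:
            out[key] = pairwise_cohesion(use, sections, region=key)
        except InsufficientDataError:
            continue
    return out


def region_density(snapshot: StageSnapshot, config: GeneratorConfig, rng: np.random.Generator):
    """Per-region sphere-grouped density at the configured NN scales."""
    geom = config.geometry.get(snapshot.stage)
    part = region_partition(config, snapshot.stage)
    halfwidth = cross_section_halfwidth(geom)
    out = {}
    for key in _regions_present(snapshot):
        cells = [c for c in _region_cells(snapshot, key) if c.origin != "median"]
        if len(cells) < 2:
            continue
        if key == "somite":
            spans = [part.interval(lab) for lab in part.labels if lab.startswith("somite")]
            span = sum(hi - lo for lo, hi in spans)
        else:
            lo, hi = part.interval(key)
            span = hi - lo
        vol = np.pi * halfwidth**2 * span
        grp = thin_to_density(cells, vol, config.shape_for(key).nn_um, rng)
        if len(grp) >= 2:
            out[key] = nearest_neighbour_density(grp, region=key)
    return out


def _aspect_table(snapshot: StageSnapshot) -> dict[str, tuple[float, float, int]]:
    out = {}
    for key in _regions_present(snapshot):
        ar = np.array([c.aspect_ratio for c in _region_cells(snapshot, key)])
        out[key] = (float(ar.mean()), float(ar.std(ddof=1)) if ar.size > 1 else 0.0, ar.size)
    return out


def _join(d: dict, fmt) -> str:
    return ";".join(f"{k}:{fmt(v)}" for k, v in d.items())


def run_morphometry(config_path, out_dir, seed: int | None = None):
    """Full deterministic pipeline run from a config file.

    Generates one snapshot per configured stage, computes every report
    statistic, and writes the summary TSV plus per-statistic tables under
    ``out_dir``.  All results are computed before anything is written, so a
    failing stage leaves no partial output.  Returns the SummaryTable.
    """
    config = load_config(config_path) if not isinstance(config_path, GeneratorConfig) else config_path
    seed = config.seed if seed is None else seed
    out_dir = Path(out_dir)
    table = SummaryTable()
    tsv_frames: dict[str, pd.DataFrame] = {}
    cohesion_rows, nn_rows, orient_rows, aspect_rows, dim_rows = [], [], [], [], []

    stages = config.stages()
    for stage in stages:
        log.info("run_morphometry: stage=%s seed=%s", stage, seed)
        snap = generate_stage_snapshot(config, stage, seed)
        prov = f"generate_stage_snapshot(stage={stage}, seed={seed})"
        rng = np.random.default_rng(np.random.SeedSequence((seed, stage, 7)))

        sections = assign_sections(snap.cells, axis="AP", thickness_um=80.0, frame=snap.frame)
        meso_ids = {
            c.id
            for c in snap.cells
            if is_mesodermal(c.region) and not c.sox2 and c.origin == config.graft_origin
        }
        n_meso = sum(1 for ids in sections.members.values() for i in ids if i in meso_ids)
        table.set("gfp_psm_cell_number", stage, n_meso, prov + " -> assign_sections")

        frac = spindle_ap_fraction(snap.divisions, snap.frame, config.cone_half_angle_deg)
        if frac is not None:
            table.set("ap_oriented_divisions_pct", stage, 100 * frac, prov + " -> spindle_ap_fraction")

        orient = {}
        for key in _regions_present(snap):
            cells = _region_cells(snap, key)
            fr = orientation_fractions((cell_ellipsoid(c) for c in cells), snap.frame, config.min_ar)
            orient[key] = fr
            for cls, v in fr.items():
                orient_rows.append({"stage": stage, "region": key, "class": cls, "fraction": v})
        table.set(
            "cell_orientation",
            stage,
            _join({k: max(v, key=v.get) + f" {100 * max(v.values()):.0f}%" for k, v in orient.items()}, str),
            prov + " -> orientation_fractions",
        )

        coh = region_cohesion(snap)
        for key, res in coh.items():
            for d in res.distances_um:
                cohesion_rows.append({"stage": stage, "region": key, "distance_um": d})
        if coh:
            table.set(
                "cohesion_median_um",
                stage,
                _join({k: r.median_um for k, r in coh.items()}, lambda v: f"{v:.3g}"),
                prov + " -> pairwise_cohesion",
            )

        dens = region_density(snap, config, rng)
        for key, res in dens.items():
            nn_rows.append({"stage": stage, "region": key, "median_nn_um": res.median_um, "n": res.nn_distances_um.size})
        if dens:
            table.set(
                "nn_median_um",
                stage,
                _join({k: r.median_um for k, r in dens.items()}, lambda v: f"{v:.3g}"),
                prov + " -> nearest_neighbour_density",
            )

        asp = _aspect_table(snap)
        for key, (m, sd, n) in asp.items():
            aspect_rows.append({"stage": stage, "region": key, "mean": m, "sd": sd, "n": n})
        table.set(
            "aspect_ratio_mean_sd",
            stage,
            _join({k: f"{m:.3g}±{sd:.2g}" for k, (m, sd, _) in asp.items()}, str),
            prov + " -> aspect_ratio",
        )

        filo = {}
        for key in _regions_present(snap):
            lens = [L for c in _region_cells(snap, key) for L in c.filopodia_um]
            if lens:
                filo[key] = float(np.mean(lens))
        if filo:
            table.set("filopodia_mean_um", stage, _join(filo, lambda v: f"{v:.3g}"), prov + " -> filopodia_stats")

        dims = labelled_extents(snap)
        dim_rows.append(
            {"stage": stage, "length_um": dims.length_um, "height_um": dims.height_um, "width_um": dims.width_um}
        )
        table.set("tissue_length_um", stage, dims.length_um, prov + " -> labelled_extents")
        table.set("tissue_height_um", stage, dims.height_um, prov + " -> labelled_extents")
        table.set("tissue_width_um", stage, dims.width_um, prov + " -> labelled_extents")
        geom = config.geometry.get(stage)
        if geom:
            table.set("tissue_volume_um3", stage, geom.tissue_volume_um3, "config.geometry")

    vols = [config.geometry[s].tissue_volume_um3 for s in stages if s in config.geometry]
    if len(vols) >= 2:
        phases = growth_phase(vols)
        for s, ph in zip(stages[1:], phases):
            table.set("growth_phase", s, ph, "growth_phase(config volume schedule)")

    tc_stages = [s for s in stages if s in config.body_length_um]
    if len(tc_stages) >= 2:
        for tissue_name in ("paraxial", "epidermis"):
            series = generate_embryo_timecourse(config, tissue_name, 0.5, tc_stages, seed)
            for st, (outline, centroid) in zip(tc_stages, series):
                d = relative_displacement(outline, centroid)
                table.set(f"d_rel_{tissue_name}", st, d.d_rel, "relative_displacement(timecourse)")

    tsv_frames["cohesion_distances.tsv"] = pd.DataFrame(cohesion_rows)
    tsv_frames["nn_density.tsv"] = pd.DataFrame(nn_rows)
    tsv_frames["orientation_fractions.tsv"] = pd.DataFrame(orient_rows)
    tsv_frames["aspect_ratios.tsv"] = pd.DataFrame(aspect_rows)
    tsv_frames["tissue_dimensions.tsv"] = pd.DataFrame(dim_rows)

    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in tsv_frames.items():
        df.to_csv(out_dir / name, sep="\t", index=False, float_format="%.6g")
    write_summary_table(table, out_dir / "summary.tsv")
    prov_rows = [
        {"parameter": p, "stage": s, "provenance": table.provenance(p, s)}
        for p in table.parameters
        for s in table.stages
        if table.provenance(p, s)
    ]
    pd.DataFrame(prov_rows).to_csv(out_dir / "provenance.tsv", sep="\t", index=False)
    return table
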