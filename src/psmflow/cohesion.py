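"""Group cohesion (in-section pairwise distances), cell density
(nearest-neighbour distances), and region assignment along the stream."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .errors import InsufficientDataError
from .io import SectionSet
from .strand import ArcSpline, RegionPartition, posterior_arc_to_stored
from .types import CellRecord

COHESION_PROXIMITY_UM = 25.0  # 'close proximity' threshold for the <25 µm fraction


@dataclass(frozen=True)
class CohesionResult:
    region: str
    distances_um: np.ndarray
    median_um: float
    n_pairs: int
    frac_below_25um: float


@dataclass(frozen=True)
class DensityResult:
    region: str
    nn_distances_um: np.ndarray
    median_um: float


def assign_regions(
    cells: list[CellRecord], partition: RegionPartition, spline: ArcSpline
) -> list[CellRecord]:
    """Relabel cells by nearest-point projection onto the stream centerline
    followed by arc-length lookup in the partition.  The spline is stored
    anterior-to-posterior; partition arc lengths run from the posterior tip."""
    if not cells:
        return []
    q = np.array([c.centroid for c in cells])
    s_stored, _ = spline.project(q)
    at_end = (s_stored <= 1e-9) | (s_stored >= spline.length - 1e-9)
    if at_end.any():
        warnings.warn(
            f"{int(at_end.sum())} cell(s) project beyond the spline domain; "
            "assigned to the nearest terminal region"
        )
    s_post = spline.length - s_stored
    labels = partition.label_for(s_post)
    out = []
    for c, lab in zip(cells, labels):
        from dataclasses import replace

        out.append(replace(c, region=lab))
    return out


def pairwise_cohesion(
    cells: list[CellRecord], sections: SectionSet, region: str | None = None, mode: str = "3d"
) -> CohesionResult:
    """Pooled pairwise center-to-center distances between labelled cells
    co-resident in a section.

    ``mode='3d'`` (default) uses full 3D Euclidean distances; ``mode='2d'``
    projects out the sectioning-axis coordinate first (in-plane distances).
    No cross-section pairs contribute.
    """
    if mode not in ("3d", "2d"):
        raise ValueError(f"unknown mode {mode!r}")
    region = region if region is not None else (cells[0].region if cells else "NA")
    by_section: dict[int, list[CellRecord]] = {}
    for c in cells:
        k = sections.by_cell.get(c.id)
        if k is None:
            continue
        by_section.setdefault(k, []).append(c)
    drop = {"AP": 0, "ML": 1, "DV": 2}[sections.axis]
    chunks = []
    for k in sorted(by_section):
        grp = by_section[k]
        if len(grp) < 2:
            continue
        pts = np.array([c.centroid for c in grp])
        if mode == "2d":
            pts = np.delete(pts, drop, axis=1)
        chunks.append(pdist(pts))
    if not chunks:
        raise InsufficientDataError(
            f"region {region!r}: insufficient pairs (no section holds >= 2 labelled cells)"
        )
    d = np.concatenate(chunks)
    return CohesionResult(
        region=region,
        distances_um=d,
        median_um=float(np.median(d)),
        n_pairs=int(d.size),
        frac_below_25um=float((d < COHESION_PROXIMITY_UM).mean()),
    )


def nearest_neighbour_density(cells: list[CellRecord], region: str | None = None) -> DensityResult:
    """Per-cell distance to its closest neighbour within the same group."""
    if len(cells) < 2:
        raise InsufficientDataError("density needs at least 2 cells in the group")
    region = region if region is not None else cells[0].region
    pts = np.array([c.centroid for c in cells])
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    nn = dist[:, 1]
    return DensityResult(region=region, nn_distances_um=nn, median_um=float(np.median(nn)))


def thin_to_density(
    cells: list[CellRecord],
    group_volume_um3: float,
    target_median_um: float,
    rng: np.random.Generator,
) -> list[CellRecord]:
    """Emulate sphere-grouping of labelled cells at a configured density.

    Uniform random thinning of a homogeneous group scales the expected
    median nearest-neighbour distance by q^(-1/3); the retention rate q is
    chosen so the thinned intensity matches the target median
    (median = (3 ln 2 / (4 pi lambda))^(1/3) for a Poisson process).  If the
    group is already sparser than the target it is returned whole.
    """
    n = len(cells)
    if n < 2:
        return list(cells)
    lam0 = n / group_volume_um3
    lam_t = 3.0 * np.log(2.0) / (4.0 * np.pi * target_median_um**3)
    q = min(1.0, lam_t / lam0)
    k = max(2, int(round(q * n)))
    if k >= n:
        return list(cells)
    idx = rng.choice(n, size=k, replace=False)
    return [cells[i] for i in sorted(idx)]


def compare_epidermis_conditions(
    control: dict[str, DensityResult], treated: dict[str, DensityResult]
):
    """Per-region effect of epidermis removal on cell density.

    Returns a list of dict rows: region, control/treated medians, the median
    difference (treated - control), its sign, and a one-way-ANOVA p-value
    (two groups, i.e. the two-sample F test).  Regions missing from either
    condition are skipped with a warning.
    """
    from .pipeline import compare_groups

    rows = []
    for region in control:
        if region not in treated:
            warnings.warn(f"region {region!r} missing in treated condition; skipped")
            continue
        c = control[region]
        t = treated[region]
        diff = t.median_um - c.median_um
        if np.array_equal(c.nn_distances_um, t.nn_distances_um):
            p = 1.0
        else:
            cmp = compare_groups({"control": c.nn_distances_um, "treated": t.nn_distances_um})
            p = cmp.p_value
        rows.append(
            {
                "region": region,
                "median_control_um": c.median_um,
                "median_treated_um": t.median_um,
                "median_diff_um": diff,
                "sign": int(np.sign(diff)),
                "p_value": p,
            }
        )
    for region in treated:
        if region not in control:
            warnings.warn(f"region {region!r} missing in control condition; skipped")
    return rows
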