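"""Synthetic tail-bud generator.

Produces labelled 3D cell ensembles with known ground truth: per-region cell
counts, shape (aspect-ratio) and orientation distributions, cohesion clumps
with a calibrated in-section median pairwise distance, mitotic spindles with
a configured AP-oriented fraction, filopodia count/length distributions, and
whole-embryo displacement timecourses.

Randomness: every entry point takes an integer seed; equal (config, seed)
yields bit-identical output.  Internal streams are decoupled with
``numpy.random.SeedSequence`` spawning so that adding cells to one region
does not perturb another.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import pdist

from .config import GeneratorConfig, RegionShape
from .errors import ConfigurationError
from .strand import (
    ArcSpline,
    cross_section_halfwidth,
    region_partition,
    strand_centerline,
    strand_point,
)
from .types import AxisFrame, CellRecord, DivisionEvent, StageSnapshot

SECTION_UM = 80.0  # transverse section thickness used for cohesion calibration

_AXIS_INDEX = {"AP": 0, "ML": 1, "DV": 2}


# --- elementary samplers -------------------------------------------------------

def sample_aspect_ratios(
    shape: RegionShape, n: int, rng: np.random.Generator, lower: float = 1.0
) -> np.ndarray:
    """Draw long/short aspect ratios from a log-normal matched to the
    configured mean/SD, truncated below at ``lower`` (>= 1) by resampling."""
    if n == 0:
        return np.zeros(0)
    cv2 = (shape.aspect_sd / shape.aspect_mean) ** 2
    s2 = np.log1p(cv2)
    mu = np.log(shape.aspect_mean) - s2 / 2
    out = rng.lognormal(mu, np.sqrt(s2), size=n)
    bad = out < lower
    while bad.any():
        out[bad] = rng.lognormal(mu, np.sqrt(s2), size=int(bad.sum()))
        bad = out < lower
    return out


def sample_volumes(shape: RegionShape, n: int, rng: np.random.Generator) -> np.ndarray:
    s2 = np.log1p(shape.volume_cv**2)
    mu = np.log(shape.mean_volume_um3) - s2 / 2
    return rng.lognormal(mu, np.sqrt(s2), size=n)


def uniform_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_class_directions(
    classes: Sequence[int], rng: np.random.Generator
) -> np.ndarray:
    """Directions for orientation classes 0..3 = (AP, ML, DV, unclassified).

    An axis class gets a direction uniform over the spherical patch where
    that frame axis dominates (|u_k| strictly maximal); 'unclassified' gets
    an isotropic direction.  Rejection sampling, vectorized.
    """
    classes = np.asarray(classes, dtype=int)
    n = classes.size
    out = np.zeros((n, 3))
    pending = np.arange(n)
    while pending.size:
        cand = uniform_sphere(pending.size, rng)
        got = np.argmax(np.abs(cand), axis=1)
        ok = (got == classes[pending]) | (classes[pending] == 3)
        out[pending[ok]] = cand[ok]
        pending = pending[~ok]
    return out


def semi_axes_from(ar: np.ndarray, volumes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Semi-axes (a, b, c) with a/c = ar, b uniform in [c, a], abc = 3V/(4pi)."""
    u = rng.uniform(size=ar.shape)
    brel = 1.0 + u * (ar - 1.0)  # b / c
    c = np.cbrt(3.0 * volumes / (4.0 * np.pi * ar * brel))
    return np.column_stack([ar * c, brel * c, c])


def sample_filopodia(
    shape: RegionShape, n_cells: int, rng: np.random.Generator
) -> list[list[float]]:
    """Per-cell filopodium lengths: Poisson counts, gamma(shape 2) lengths
    truncated to the observable (0, 40] µm range."""
    counts = rng.poisson(shape.filopodia_mean_count, size=n_cells)
    total = int(counts.sum())
    lengths = rng.gamma(2.0, shape.filopodia_mean_um / 2.0, size=total)
    bad = lengths > 40.0
    while bad.any():
        lengths[bad] = rng.gamma(2.0, shape.filopodia_mean_um / 2.0, size=int(bad.sum()))
        bad = lengths > 40.0
    out, k = [], 0
    for c in counts:
        out.append(list(lengths[k : k + c]))
        k += c
    return out


# --- cohesion-scale calibration ------------------------------------------------

_SIGMA_CACHE: dict[tuple[float, float], float] = {}


def _standardize_clump(z: np.ndarray) -> np.ndarray:
    """Moment-match one sub-clump's displacement draws: center and rescale so
    the empirical mean-square displacement equals that of a standard normal
    (3 per point).  Small labelled groups then realize the configured
    cohesion scale exactly instead of only in expectation."""
    z = z - z.mean(axis=0)
    ms = (z**2).sum() / z.shape[0]
    if ms <= 0:
        return z
    return z * np.sqrt(3.0 / ms)


def _substream_points(
    sigma: float, thickness: float, n_anchors: int, z: np.ndarray, off: float
) -> np.ndarray:
    """One labelled group: ``n_anchors`` sub-clumps spaced one section apart
    along AP (global offset ``off`` in units of the thickness), cells
    isotropically Gaussian about their anchor (moment-matched per
    sub-clump).  ``z`` is (n_anchors, m, 3)."""
    zs = np.concatenate([_standardize_clump(z[a]) for a in range(z.shape[0])])
    pts = sigma * zs
    pts[:, 0] += (np.repeat(np.arange(n_anchors), z.shape[1]) + off) * thickness
    return pts


def _insection_median(
    sigma: float, thickness: float, n_anchors: int, z: np.ndarray, offs: np.ndarray
) -> float:
    dists = []
    for i in range(z.shape[0]):
        pts = _substream_points(sigma, thickness, n_anchors, z[i], offs[i])
        sec = np.floor(pts[:, 0] / thickness).astype(int)
        for s in np.unique(sec):
            grp = pts[sec == s]
            if grp.shape[0] >= 2:
                dists.append(pdist(grp))
    if not dists:
        return 0.0
    return float(np.median(np.concatenate(dists)))


def calibrate_cohesion_sigma(
    target_median_um: float,
    thickness_um: float = SECTION_UM,
    n_anchors: int = 4,
    cells_per_anchor: int = 7,
) -> float:
    """Isotropic Gaussian scale for substream sub-clumps whose expected
    in-section median pairwise distance equals the target.

    The labelled group is modelled as ``n_anchors`` sub-clumps one section
    apart along AP; co-sectioned pairs mix within- and (for loose groups)
    cross-anchor distances, so the scale is solved numerically with common
    random numbers and root bracketing.  Results are cached."""
    key = (
        round(float(target_median_um), 6),
        round(float(thickness_um), 6),
        int(n_anchors),
        int(cells_per_anchor),
    )
    if key in _SIGMA_CACHE:
        return _SIGMA_CACHE[key]
    rng = np.random.default_rng(190347)
    n_groups = 400
    z = rng.normal(size=(n_groups, n_anchors, cells_per_anchor, 3))
    offs = rng.uniform(size=n_groups)
    f = lambda s: _insection_median(s, thickness_um, n_anchors, z, offs) - target_median_um
    lo = 1e-3 * target_median_um
    hi = target_median_um
    while f(hi) < 0:
        hi *= 2.0
    sigma = float(brentq(f, lo, hi, xtol=1e-3 * target_median_um))
    _SIGMA_CACHE[key] = sigma
    return sigma


# --- count allocation ----------------------------------------------------------

def allocate_counts(total: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment; conserves the total exactly."""
    names = list(fractions)
    raw = np.array([fractions[k] * total for k in names])
    base = np.floor(raw).astype(int)
    rem = total - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return dict(zip(names, (int(b) for b in base)))


# --- cell construction ---------------------------------------------------------

def _build_cells(
    config: GeneratorConfig,
    region: str,
    stage: int,
    centroids: np.ndarray,
    origin: str,
    sox2: bool,
    rng: np.random.Generator,
    start_id: int,
) -> list[CellRecord]:
    n = centroids.shape[0]
    if n == 0:
        return []
    shape = config.shape_for(region)
    # shape and direction are drawn independently: the configured orientation
    # probabilities are realized exactly when the shape distribution sits
    # above the classifier threshold (set aspect_lower_bound >= min_ar for
    # that); otherwise sub-threshold cells classify as 'unclassified'
    ar = sample_aspect_ratios(shape, n, rng, config.aspect_lower_bound)
    classes = rng.choice(4, size=n, p=np.asarray(shape.orientation_probs))
    dirs = sample_class_directions(classes, rng)
    vols = sample_volumes(shape, n, rng)
    axes = semi_axes_from(ar, vols, rng)
    filo = sample_filopodia(shape, n, rng)
    return [
        CellRecord(
            id=start_id + i,
            centroid=centroids[i],
            axes_um=axes[i],
            direction=dirs[i],
            volume_um3=float(vols[i]),
            sox2=sox2,
            origin=origin,
            region=region,
            stage=stage,
            filopodia_um=filo[i],
        )
        for i in range(n)
    ]


def _tube_positions(
    n: int,
    s_lo: float,
    s_hi: float,
    spline: ArcSpline,
    halfwidth: float,
    center_y: float,
    rng: np.random.Generator,
) -> np.ndarray:
    s = rng.uniform(s_lo, s_hi, size=n)
    base = strand_point(spline, s)
    r = halfwidth * np.sqrt(rng.uniform(size=n))
    phi = rng.uniform(0, 2 * np.pi, size=n)
    pos = base.copy()
    pos[:, 1] = center_y + r * np.cos(phi)
    pos[:, 2] = base[:, 2] + r * np.sin(phi)
    return pos


def _side_sign(side: str) -> int:
    return -1 if side == "left" else 1


# --- main entry points ---------------------------------------------------------

def generate_stage_snapshot(config: GeneratorConfig, stage: int, seed: int) -> StageSnapshot:
    """One embryo snapshot: bulk labelled cells per region (exact configured
    counts), neural (Sox2+) cells, optional cohesion clumps, and mitotic
    division events."""
    config.validate()
    if stage not in config.counts:
        raise ConfigurationError(f"stage {stage} not configured")
    frame = AxisFrame.default(graft_side="left")
    n_meso, n_neural = config.counts[stage]
    geom = config.geometry.get(stage)
    if geom is None and (n_meso or n_neural):
        raise ConfigurationError(f"no strand geometry configured for stage {stage}")

    ss = np.random.SeedSequence((config.seed, int(seed), int(stage)))
    r_place, r_cells, r_neural, r_clump, r_div = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )

    cells: list[CellRecord] = []
    next_id = 1
    if n_meso == 0 and n_neural == 0:
        return StageSnapshot(stage=stage, cells=[], frame=frame, divisions=[])

    spline = strand_centerline(geom)
    partition = region_partition(config, stage)
    halfwidth = cross_section_halfwidth(geom)
    center_y = _side_sign(frame.graft_side) * (config.midline_gap_um + halfwidth)

    fractions = config.region_fractions.get(stage, {})
    per_region = allocate_counts(n_meso, fractions)
    for region, count in per_region.items():
        if count == 0:
            continue
        if region == "somite":
            geom_s = config.geometry[stage]
            per_somite = allocate_counts(
                count, {f"somite_{k}": 1.0 / geom_s.n_somites for k in range(1, geom_s.n_somites + 1)}
            )
            sub = per_somite.items()
        else:
            sub = [(region, count)]
        for label, cnt in sub:
            lo, hi = partition.interval(label)
            pos = _tube_positions(cnt, lo, hi, spline, halfwidth, center_y, r_place)
            # a small fraction of half-plate graft derivatives cross the midline
            if config.graft_origin in ("left_half", "entire"):
                p_cross = 0.5 if config.graft_origin == "entire" else 0.03
                crossed = r_place.uniform(size=cnt) < p_cross
                pos[crossed, 1] = -pos[crossed, 1]
            cells.extend(
                _build_cells(config, label, stage, pos, config.graft_origin, False, r_cells, next_id)
            )
            next_id += cnt

    if n_neural:
        s = r_neural.uniform(0, spline.length, size=n_neural)
        base = strand_point(spline, s)
        pos = base.copy()
        pos[:, 1] = r_neural.normal(0.0, 8.0, size=n_neural)
        pos[:, 2] = base[:, 2] + halfwidth + 20.0 + r_neural.normal(0.0, 8.0, size=n_neural)
        cells.extend(_build_cells(config, "NT", stage, pos, "host", True, r_neural, next_id))
        next_id += n_neural

    if config.cohesion_group_size > 0:
        k = config.cohesion_subclumps
        m = config.cohesion_group_size // k
        for label in partition.labels:
            shape = config.shape_for(label)
            sigma = calibrate_cohesion_sigma(shape.cohesion_um, SECTION_UM, k, m)
            lo, hi = partition.interval(label)
            mid = 0.5 * (lo + hi)
            anchor_s = mid + 0.2 * (hi - lo) * r_clump.uniform(-1, 1)
            anchor = strand_point(spline, np.atleast_1d(anchor_s))[0]
            anchor[1] = center_y + r_clump.uniform(-10, 10)
            anchor[2] += r_clump.uniform(-10, 10)
            # substream: k sub-clumps one section apart along AP, displacements
            # moment-matched per sub-clump (see _standardize_clump)
            anchor_x = anchor[0] + (np.arange(k) - (k - 1) / 2.0) * SECTION_UM
            z = r_clump.normal(size=(k, m, 3))
            disp = sigma * np.concatenate([_standardize_clump(z[a]) for a in range(k)])
            pos = np.repeat(anchor[None, :], k * m, axis=0)
            pos[:, 0] = np.repeat(anchor_x, m)
            pos += disp
            cells.extend(
                _build_cells(config, label, stage, pos, "median", False, r_clump, next_id)
            )
            next_id += config.cohesion_group_size

    divisions = _sample_divisions(config, stage, spline, halfwidth, center_y, r_div)
    return StageSnapshot(stage=stage, cells=cells, frame=frame, divisions=divisions)


def _sample_divisions(
    config: GeneratorConfig,
    stage: int,
    spline: ArcSpline,
    halfwidth: float,
    center_y: float,
    rng: np.random.Generator,
) -> list[DivisionEvent]:
    n = config.n_divisions
    if n == 0 or stage not in config.spindle_ap_fraction:
        return []
    p_ap = config.spindle_ap_fraction[stage]
    pos = _tube_positions(n, 0, spline.length, spline, halfwidth, center_y, rng)
    dirs = sample_spindle_directions(n, p_ap, config.cone_half_angle_deg, rng)
    half = 4.0  # half the inter-centriole distance, µm
    return [
        DivisionEvent(cell_id=i + 1, centriole1=pos[i] - half * dirs[i], centriole2=pos[i] + half * dirs[i])
        for i in range(n)
    ]


def sample_spindle_directions(
    n: int, p_ap: float, cone_half_angle_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Spindle unit vectors: with probability ``p_ap`` uniform inside the AP
    cone (angle folded to [0°, 90°]), otherwise uniform outside it.  Sampling
    and classification share the same cone so the configured fraction is
    recovered exactly in expectation."""
    c = np.cos(np.deg2rad(cone_half_angle_deg))
    in_cone = rng.uniform(size=n) < p_ap
    u = np.where(in_cone, rng.uniform(c, 1.0, size=n), rng.uniform(0.0, c, size=n))
    u *= rng.choice([-1.0, 1.0], size=n)
    phi = rng.uniform(0, 2 * np.pi, size=n)
    rho = np.sqrt(1.0 - u**2)
    return np.column_stack([u, rho * np.cos(phi), rho * np.sin(phi)])


# --- focal graft series --------------------------------------------------------

# anterior-reach rules per origin: (arc interval builder, anterior handicap µm)
_GRAFT_HANDICAP = {"median": 0.0, "paramedian": 30.0, "lateral": 60.0, "left_half": 0.0, "entire": 0.0}


def _graft_interval(config: GeneratorConfig, origin: str, stage: int) -> tuple[float, float]:
    part = region_partition(config, stage)
    L = float(part.breakpoints[-1])
    labels = part.labels
    has_psm = "posterior_PSM" in labels

    def lo_of(label):
        return part.interval(label)[0]

    hi = L - _GRAFT_HANDICAP[origin]
    if not has_psm:  # early stages: everything still in the PZ bulge
        return 0.0, hi
    if origin == "median":
        lo = lo_of("medial_PSM") if stage < 30 else lo_of("anterior_PSM")
    elif origin == "paramedian":
        lo = lo_of("posterior_PSM")
    elif origin == "lateral":
        lo = 0.0
        if stage < 30:
            hi = part.interval("posterior_PSM")[1]  # confined to PZ + posterior PSM
    else:  # left_half / entire span the whole strand
        lo = 0.0
    return lo, hi


def generate_graft_series(
    config: GeneratorConfig, origin: str, stages: Iterable[int], seed: int
) -> list[StageSnapshot]:
    """Snapshots of a focal graft followed across stages.

    Labelled cells carry the origin label; the anterior reach is ordered
    median > paramedian > lateral at every stage by construction (the
    anterior-most cell is pinned to the interval bound, which carries an
    origin-specific handicap), and only median/entire grafts contribute
    contralateral cells outside the PZ.
    """
    config.validate()
    if origin not in ("median", "paramedian", "lateral", "left_half", "entire"):
        raise ConfigurationError(f"unknown graft origin {origin!r}")
    frame = AxisFrame.default(graft_side="left")
    origin_code = ("median", "paramedian", "lateral", "left_half", "entire").index(origin)
    out = []
    for stage in stages:
        if stage not in config.geometry:
            raise ConfigurationError(f"no strand geometry configured for stage {stage}")
        ss = np.random.SeedSequence((config.seed, int(seed), int(stage), origin_code))
        rng = np.random.default_rng(ss)
        geom = config.geometry[stage]
        spline = strand_centerline(geom)
        part = region_partition(config, stage)
        halfwidth = cross_section_halfwidth(geom)
        center_y = _side_sign(frame.graft_side) * (config.midline_gap_um + halfwidth)
        lo, hi = _graft_interval(config, origin, stage)
        n = config.graft_cell_count
        s_vals = rng.uniform(lo, hi, size=n)
        # pin the first cell to the anterior bound so the reach ordering is
        # strict for every seed
        s_vals[0] = hi
        base = strand_point(spline, s_vals)
        r = halfwidth * np.sqrt(rng.uniform(size=n))
        phi = rng.uniform(0, 2 * np.pi, size=n)
        pos = base.copy()
        pos[:, 1] = center_y + r * np.cos(phi)
        pos[:, 2] = base[:, 2] + r * np.sin(phi)
        pos[0, 1] = center_y
        # contralateral placement
        if origin in ("median", "entire"):
            p_cross = 0.10 if origin == "median" else 0.5
            crossed = rng.uniform(size=n) < p_cross
            crossed[0] = False
            pos[crossed, 1] = -pos[crossed, 1]
        elif origin in ("paramedian", "lateral") and stage >= 30 and part.labels[0] == "PZ":
            # a couple of laggards cross within the PZ only
            pz_lo, pz_hi = part.interval("PZ")
            for i in (1, 2):
                if i < n:
                    s_vals[i] = rng.uniform(pz_lo, pz_hi)
                    p = strand_point(spline, np.atleast_1d(s_vals[i]))[0]
                    p[1] = -center_y + rng.uniform(-5, 5)
                    pos[i] = p
        labels = part.label_for(s_vals)
        cells = []
        for i in range(n):
            built = _build_cells(
                config, labels[i], stage, pos[i : i + 1], origin, False,
                rng, start_id=i + 1,
            )
            cells.extend(built)
        out.append(StageSnapshot(stage=stage, cells=cells, frame=frame, divisions=[]))
    return out


# --- epidermis removal ---------------------------------------------------------

def apply_epidermis_removal(
    snapshot: StageSnapshot, side: str, spread_factor: float, seed: int = 0
) -> StageSnapshot:
    """Kinematic effect of removing the epidermal lateral barrier: the ML
    coordinates of PZ and posterior-PSM cells on the deprived side(s) spread
    away from the midline by ``spread_factor``; the anterior PSM and the
    contralateral side are untouched.  Deterministic; cell count conserved."""
    if side not in ("left", "right", "bilateral"):
        raise ConfigurationError(f"unknown side {side!r}")
    if spread_factor < 1:
        raise ConfigurationError("spread_factor must be >= 1")
    affected_regions = ("PZ", "posterior_PSM")
    new_cells = []
    for c in snapshot.cells:
        y = c.centroid[1]
        on_side = (
            (side == "bilateral")
            or (side == "left" and y < 0)
            or (side == "right" and y > 0)
        )
        if c.region in affected_regions and on_side:
            cc = c.centroid.copy()
            cc[1] = spread_factor * y
            from .types import with_centroid

            new_cells.append(with_centroid(c, cc))
        else:
            new_cells.append(c)
    return StageSnapshot(
        stage=snapshot.stage,
        cells=new_cells,
        frame=snapshot.frame,
        divisions=list(snapshot.divisions),
        outline=snapshot.outline,
    )


# --- whole-embryo displacement timecourse --------------------------------------

def _body_outline(length_um: float, n_vertices: int = 256) -> np.ndarray:
    """Ventral body contour: a shallow arc of exactly the given arc length,
    vertex 0 at the anterior tip."""
    t = np.linspace(0.0, 1.0, n_vertices)
    x = t
    z = 0.05 * np.sin(np.pi * t)
    pts = np.column_stack([x, np.zeros_like(t), z])
    arc = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
    return pts * (length_um / arc)


def _arc_position(outline: np.ndarray, a: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(outline, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    a = float(np.clip(a, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, a, side="right")) - 1
    i = min(i, len(seg) - 1)
    t = (a - cum[i]) / seg[i] if seg[i] > 0 else 0.0
    return outline[i] + t * (outline[i + 1] - outline[i])


def generate_embryo_timecourse(
    config: GeneratorConfig,
    tissue: str,
    label_site: float,
    stages: Sequence[int],
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Outline polyline + displaced label centroid per stage.

    The label starts at arc fraction ``label_site`` of the first stage's
    contour.  Epidermal labels keep their absolute arc position; paraxial
    (and, less strongly, LPM) labels shift anteriorly as the body elongates;
    endodermal labels start shifting only after the late tail-bud stage.
    """
    if not 0.0 <= label_site <= 1.0:
        raise ConfigurationError("label_site must lie in [0, 1]")
    if tissue not in ("paraxial", "epidermis", "LPM", "endoderm"):
        raise ConfigurationError(f"unknown tissue {tissue!r}")
    stages = list(stages)
    lengths = []
    for st in stages:
        if st not in config.body_length_um:
            raise ConfigurationError(f"no body length configured for stage {st}")
        lengths.append(config.body_length_um[st])
    if any(b < a for a, b in zip(lengths, lengths[1:])):
        raise ConfigurationError("body length schedule must be non-decreasing over stages")
    b0 = lengths[0]
    a0 = label_site * b0
    out = []
    for st, b in zip(stages, lengths):
        if tissue == "epidermis":
            a = a0
        elif tissue == "paraxial":
            a = a0 * (b0 / b)
        elif tissue == "LPM":
            a = a0 * np.sqrt(b0 / b)
        else:  # endoderm: stationary until stage 30
            if st <= 30:
                a = a0
            else:
                b30 = config.body_length_um.get(30, b0)
                a = a0 * (b30 / b)
        outline = _body_outline(b)
        out.append((outline, _arc_position(outline, a)))
    return out
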