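"""Whole-tissue measurements: extents, union volume, growth phases, midline
crossing, and the relative-displacement metric d_rel = a / b (arc length from
the anterior body tip to the labelled region, over total contour length)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, InsufficientDataError
from .types import AxisFrame, CellRecord, StageSnapshot, cell_ellipsoid, is_mesodermal


@dataclass(frozen=True)
class DisplacementMeasure:
    a_um: float
    b_um: float

    @property
    def d_rel(self) -> float:
        return self.a_um / self.b_um

    def __post_init__(self):
        if not (0 <= self.a_um <= self.b_um) or self.b_um <= 0:
            raise DegenerateGeometryError("need 0 <= a <= b and b > 0")


@dataclass(frozen=True)
class TissueDimensions:
    stage: int
    length_um: float  # AP extent
    height_um: float  # DV extent
    width_um: float  # ML extent
    volume_um3: float | None = None

    def __post_init__(self):
        for v in (self.length_um, self.height_um, self.width_um):
            if v < 0:
                raise DegenerateGeometryError("extents must be non-negative")
        if self.volume_um3 is not None and self.volume_um3 > (
            self.length_um * self.height_um * self.width_um + 1e-6
        ):
            raise DegenerateGeometryError("volume exceeds the bounding box")


def _ellipsoid_support(cell: CellRecord, u: np.ndarray) -> float:
    """Half-extent of the cell's ellipsoid along unit direction u."""
    e = cell_ellipsoid(cell)
    return float(np.sqrt(((cell.axes_um * (e.vectors @ u)) ** 2).sum()))


def labelled_extents(snapshot: StageSnapshot, frame: AxisFrame | None = None) -> TissueDimensions:
    """AP/DV/ML extents of the labelled mesodermal tissue, measured from the
    cells' ellipsoid surfaces (centroid +/- projected semi-axis support)."""
    frame = frame or snapshot.frame
    cells = [c for c in snapshot.cells if is_mesodermal(c.region)]
    if not cells:
        raise InsufficientDataError("no labelled mesodermal cells")
    dims = {}
    for name, u in (("AP", frame.ap), ("DV", frame.dv), ("ML", frame.ml)):
        proj = np.array([c.centroid @ u for c in cells])
        r = np.array([_ellipsoid_support(c, u) for c in cells])
        dims[name] = float((proj + r).max() - (proj - r).min())
    return TissueDimensions(
        stage=snapshot.stage, length_um=dims["AP"], height_um=dims["DV"], width_um=dims["ML"]
    )


def labelled_volume(snapshot: StageSnapshot, voxel_um: float = 2.0, labelled_only: bool = True) -> float:
    """Union volume of the labelled cells' ellipsoids by voxel counting.

    Overlaps count once (union semantics).
    """
    cells = [c for c in snapshot.cells if (is_mesodermal(c.region) or not labelled_only)]
    if not cells:
        raise InsufficientDataError("no labelled cells")
    v = float(voxel_um)
    cents = np.array([c.centroid for c in cells])
    radii = np.array([c.axes_um[0] for c in cells])
    lo = np.floor((cents - radii[:, None]).min(axis=0) / v).astype(int) - 1
    hi = np.ceil((cents + radii[:, None]).max(axis=0) / v).astype(int) + 2
    occ = np.zeros(tuple(hi - lo), dtype=bool)
    from .io import rasterize_cell_points

    for c in cells:
        pts = rasterize_cell_points(c, v)
        if pts.shape[0] == 0:
            continue
        idx = np.floor(pts / v).astype(int) - lo
        occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return float(occ.sum()) * v**3


def growth_phase(volumes, tolerance: float = 0.15) -> list[str]:
    """Classify each consecutive volume interval as isovolumetric
    (|dV|/V <= tolerance), volumetric (growth beyond tolerance) or shrinking."""
    vols = np.asarray(volumes, dtype=float)
    if vols.size < 2:
        raise InsufficientDataError("growth-phase classification needs >= 2 stages")
    if (vols <= 0).any():
        raise DegenerateGeometryError("volumes must be positive")
    labels = []
    for v0, v1 in zip(vols[:-1], vols[1:]):
        rel = (v1 - v0) / v0
        if rel > tolerance:
            labels.append("volumetric")
        elif rel < -tolerance:
            labels.append("shrinking")
        else:
            labels.append("isovolumetric")
    return labels


def midline_crossing_fraction(snapshot: StageSnapshot, frame: AxisFrame | None = None) -> float:
    """Fraction of labelled mesodermal cells strictly across the midline from
    the graft side (a cell exactly on the midline has not crossed)."""
    frame = frame or snapshot.frame
    cells = [c for c in snapshot.cells if is_mesodermal(c.region) and c.origin != "host"]
    if not cells:
        return 0.0
    ml = np.array([c.centroid @ frame.ml for c in cells])
    if frame.graft_side == "left":
        crossed = ml > 0
    else:
        crossed = ml < 0
    return float(crossed.mean())


def relative_displacement(outline: np.ndarray, centroid, anterior_index: int = 0) -> DisplacementMeasure:
    """d_rel of a labelled region: nearest-point projection of its centroid
    onto the body contour polyline; a = arc length from the anterior tip
    (vertex 0) to the projection, b = total contour length.  Projection ties
    resolve to the smallest arc length."""
    outline = np.asarray(outline, dtype=float)
    if outline.ndim != 2 or outline.shape[0] < 2:
        raise DegenerateGeometryError("outline needs at least 2 vertices")
    if outline.shape[1] == 2:
        outline = np.column_stack([outline, np.zeros(outline.shape[0])])
    if anterior_index != 0:
        raise DegenerateGeometryError("the anterior point must be outline vertex 0")
    q = np.asarray(centroid, dtype=float)
    if q.shape[0] == 2:
        q = np.append(q, 0.0)
    seg = np.diff(outline, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    b = float(seg_len.sum())
    if b <= 0:
        raise DegenerateGeometryError("zero-length outline")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_a, best_d = 0.0, np.inf
    for i in range(seg.shape[0]):
        if seg_len[i] == 0:
            continue
        t = np.clip((q - outline[i]) @ seg[i] / seg_len[i] ** 2, 0.0, 1.0)
        proj = outline[i] + t * seg[i]
        d = np.linalg.norm(q - proj)
        if d < best_d - 1e-12:  # strict improvement => ties keep smallest arc
            best_d = d
            best_a = cum[i] + t * seg_len[i]
    return DisplacementMeasure(a_um=float(best_a), b_um=b)


def read_outline(path) -> np.ndarray:
    """2- or 3-column TSV of outline vertex coordinates in µm."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    arr = df.to_numpy(dtype=float)
    if arr.shape[1] == 2:
        arr = np.column_stack([arr, np.zeros(arr.shape[0])])
    return arr


def write_outline(outline: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(outline), delimiter="\t", fmt="%.10g")
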