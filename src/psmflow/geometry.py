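"""Per-cell morphometrics.

The ellipsoid fit is the moment fit classical in 3D microscopy: the cell's
voxel (or point) cloud is summarized by its mean and second central moment
tensor; eigenvectors give the principal axes and, for a uniformly filled
solid ellipsoid, the semi-axis along eigenvector i is exactly
sqrt(5 * eigenvalue_i).
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import DegenerateGeometryError, InsufficientDataError
from .types import AxisFrame, CellRecord, DivisionEvent, FittedEllipsoid

_MOMENT_TO_SEMIAXIS = np.sqrt(5.0)  # solid uniform ellipsoid


def fit_ellipsoid(points: np.ndarray) -> FittedEllipsoid:
    """Moment-based ellipsoid fit of a 3D point cloud (µm coordinates).

    Parameters
    ----------
    points : (n, 3) array, n >= 4, not coplanar.

    Returns
    -------
    FittedEllipsoid with eigenvalues sorted descending and a deterministic
    sign convention: each axis vector is flipped so that its
    largest-magnitude component is positive.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DegenerateGeometryError("points must be an (n, 3) array")
    if pts.shape[0] < 4:
        raise DegenerateGeometryError("ellipsoid fit needs at least 4 points")
    center = pts.mean(axis=0)
    centered = pts - center
    cov = centered.T @ centered / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= max(evals[-1], 1.0) * 1e-12:
        raise DegenerateGeometryError("points are coplanar or otherwise degenerate")
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    vectors = evecs[:, order].T  # rows
    for i in range(3):
        j = np.argmax(np.abs(vectors[i]))
        if vectors[i, j] < 0:
            vectors[i] = -vectors[i]
    axes = _MOMENT_TO_SEMIAXIS * np.sqrt(evals)
    return FittedEllipsoid(center=center, axes_um=axes, vectors=vectors)


def aspect_ratio(e: FittedEllipsoid) -> float:
    """Long/short semi-axis ratio (the 'cellular coefficient'); >= 1."""
    return float(e.axes_um[0] / e.axes_um[2])


def classify_orientation(e: FittedEllipsoid, frame: AxisFrame, min_ar: float = 1.3) -> str:
    """Classify a cell's long axis as AP / ML / DV, or 'unclassified' when the
    cell is too round (aspect ratio below ``min_ar``) for its long axis to be
    meaningful."""
    if aspect_ratio(e) < min_ar:
        return "unclassified"
    long_axis = e.vectors[0]
    dots = np.abs([long_axis @ frame.ap, long_axis @ frame.ml, long_axis @ frame.dv])
    return ("AP", "ML", "DV")[int(np.argmax(dots))]


def orientation_fractions(
    ellipsoids, frame: AxisFrame, min_ar: float = 1.3
) -> dict[str, float]:
    """Class fractions over a cell population; values sum to 1."""
    ells = list(ellipsoids)
    if not ells:
        raise InsufficientDataError("no cells to classify")
    counts = {"AP": 0, "ML": 0, "DV": 0, "unclassified": 0}
    for e in ells:
        counts[classify_orientation(e, frame, min_ar)] += 1
    n = len(ells)
    return {k: v / n for k, v in counts.items()}


def spindle_ap_fraction(
    events: list[DivisionEvent], frame: AxisFrame, cone_half_angle: float = 30.0
) -> float | None:
    """Fraction of mitotic spindles within ``cone_half_angle`` degrees of the
    AP axis (angles folded to [0°, 90°]).  Returns None for an empty list.
    Events with coincident centrioles are skipped with a warning."""
    if not events:
        return None
    cos_cone = np.cos(np.deg2rad(cone_half_angle))
    n_total = 0
    n_ap = 0
    for ev in events:
        v = ev.spindle
        if v is None:
            warnings.warn(f"division event {ev.cell_id}: coincident centrioles, skipped")
            continue
        n_total += 1
        if abs(v @ frame.ap) >= cos_cone:
            n_ap += 1
    if n_total == 0:
        return None
    return n_ap / n_total


def filopodia_stats(cells: list[CellRecord], region: str):
    """Filopodia summary over the cells of one region.

    Returns (fraction of cells with >= 1 filopodium, fraction with >= 5,
    mean length µm, max length µm).  The length statistics are NaN when the
    region carries no filopodia at all.
    """
    members = [c for c in cells if c.region == region or (region == "somite" and c.region.startswith("somite"))]
    if not members:
        raise InsufficientDataError(f"region {region!r} has no cells")
    n = len(members)
    frac1 = sum(len(c.filopodia_um) >= 1 for c in members) / n
    frac5 = sum(len(c.filopodia_um) >= 5 for c in members) / n
    lengths = np.array([L for c in members for L in c.filopodia_um], dtype=float)
    if lengths.size == 0:
        return frac1, frac5, float("nan"), float("nan")
    return frac1, frac5, float(lengths.mean()), float(lengths.max())
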