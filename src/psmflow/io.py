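"""Cell-table TSV dialect, transverse sectioning, and label-stack handling.

The cell table is a flat UTF-8, tab-separated file with one row per cell and
a fixed header; filopodium lengths are a semicolon-separated list in one
column.  Label stacks are ZYX-ordered integer TIFF volumes with isotropic
voxels, 0 = background, one positive label per cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .errors import FormatError
from .geometry import fit_ellipsoid
from .types import AxisFrame, CellRecord, StageSnapshot, cell_ellipsoid

CELL_TABLE_COLUMNS = [
    "id",
    "stage",
    "region",
    "origin",
    "sox2",
    "x_um",
    "y_um",
    "z_um",
    "axis_a_um",
    "axis_b_um",
    "axis_c_um",
    "dir_x",
    "dir_y",
    "dir_z",
    "volume_um3",
    "filopodia_lengths",
]

_AXIS_COLUMN = {"AP": 0, "ML": 1, "DV": 2}


def write_cell_table(cells: list[CellRecord], path) -> None:
    rows = []
    for c in cells:
        rows.append(
            {
                "id": c.id,
                "stage": c.stage,
                "region": c.region,
                "origin": c.origin,
                "sox2": int(c.sox2),
                "x_um": c.centroid[0],
                "y_um": c.centroid[1],
                "z_um": c.centroid[2],
                "axis_a_um": c.axes_um[0],
                "axis_b_um": c.axes_um[1],
                "axis_c_um": c.axes_um[2],
                "dir_x": c.direction[0],
                "dir_y": c.direction[1],
                "dir_z": c.direction[2],
                "volume_um3": c.volume_um3,
                "filopodia_lengths": ";".join(format(L, ".6g") for L in c.filopodia_um),
            }
        )
    df = pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cell_table(path) -> list[CellRecord]:
    """Parse a cell table; raises FormatError naming the first problem."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"filopodia_lengths": str}, keep_default_na=False)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cell table {path.name}: missing column(s) {', '.join(missing)}")
    cells = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        coords = np.array([row.x_um, row.y_um, row.z_um], dtype=float)
        if not np.isfinite(coords).all():
            raise FormatError(f"cell table {path.name}: non-finite coordinate at row {row_no}")
        axes = np.array([row.axis_a_um, row.axis_b_um, row.axis_c_um], dtype=float)
        if not (axes[0] >= axes[1] >= axes[2] > 0):
            raise FormatError(
                f"cell table {path.name}: semi-axes not sorted a >= b >= c > 0 at row {row_no}"
            )
        filo_raw = str(row.filopodia_lengths).strip()
        filo = [float(t) for t in filo_raw.split(";") if t] if filo_raw else []
        direction = np.array([row.dir_x, row.dir_y, row.dir_z], dtype=float)
        n = np.linalg.norm(direction)
        if n == 0:
            raise FormatError(f"cell table {path.name}: zero direction vector at row {row_no}")
        cells.append(
            CellRecord(
                id=int(row.id),
                centroid=coords,
                axes_um=axes,
                direction=direction / n,
                volume_um3=float(row.volume_um3),
                sox2=bool(int(row.sox2)),
                origin=str(row.origin),
                region=str(row.region),
                stage=int(row.stage),
                filopodia_um=filo,
            )
        )
    return cells


def write_snapshot(snapshot: StageSnapshot, path) -> None:
    write_cell_table(snapshot.cells, path)


def read_snapshot(path, stage: int | None = None) -> StageSnapshot:
    cells = read_cell_table(path)
    if stage is None:
        stage = cells[0].stage if cells else 0
    return StageSnapshot(stage=stage, cells=cells, frame=AxisFrame.default())


# --- transverse sectioning -----------------------------------------------------

@dataclass(frozen=True)
class SectionSet:
    """Partition of cells into half-open slabs [k*t, (k+1)*t) along one axis."""

    axis: str
    thickness_um: float
    members: dict[int, list[int]]  # section index -> cell ids
    by_cell: dict[int, int]  # cell id -> section index

    def n_cells(self) -> int:
        return sum(len(v) for v in self.members.values())


def assign_sections(
    cells: list[CellRecord],
    axis: str = "AP",
    thickness_um: float = 80.0,
    frame: AxisFrame | None = None,
) -> SectionSet:
    """Assign each cell (by centroid) to exactly one section slab."""
    if thickness_um <= 0:
        raise FormatError("section thickness must be positive")
    if axis not in _AXIS_COLUMN:
        raise FormatError(f"unknown sectioning axis {axis!r}")
    frame = frame or AxisFrame.default()
    u = {"AP": frame.ap, "ML": frame.ml, "DV": frame.dv}[axis]
    members: dict[int, list[int]] = {}
    by_cell: dict[int, int] = {}
    for c in cells:
        k = int(np.floor((c.centroid @ u) / thickness_um))
        members.setdefault(k, []).append(c.id)
        by_cell[c.id] = k
    return SectionSet(axis=axis, thickness_um=thickness_um, members=members, by_cell=by_cell)


# --- label stacks ---------------------------------------------------------------

def _check_voxel(voxel_um) -> float:
    v = np.atleast_1d(np.asarray(voxel_um, dtype=float))
    if v.size not in (1, 3):
        raise FormatError("voxel size must be a scalar or a 3-vector")
    if v.size == 3 and not (v[0] == v[1] == v[2]):
        raise FormatError("anisotropic voxel sizes are not supported")
    if v.flat[0] <= 0:
        raise FormatError("voxel size must be positive")
    return float(v.flat[0])


def cells_from_label_stack(
    stack: np.ndarray, voxel_um, stage: int = 0, region: str = "PZ"
) -> list[CellRecord]:
    """One CellRecord per positive label in a ZYX stack.

    Centroid and principal axes come from the label's voxel-center
    coordinates (µm); volume is voxel count times voxel volume.  ``stage``
    and ``region`` are placeholder annotations until region assignment runs.
    """
    v = _check_voxel(voxel_um)
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise FormatError("label stack must be 3D (ZYX)")
    if stack.size and stack.min() < 0:
        raise FormatError("labels must be non-negative integers")
    labels = np.unique(stack)
    labels = labels[labels > 0]
    slices = ndimage.find_objects(stack)
    cells = []
    for lab in labels:
        sl = slices[int(lab) - 1]
        if sl is None:
            continue
        local = np.argwhere(stack[sl] == lab)  # (n, 3) in z, y, x
        zyx = local + np.array([s.start for s in sl])
        xyz = zyx[:, ::-1].astype(float)
        pts = (xyz + 0.5) * v
        ell = fit_ellipsoid(pts)
        cells.append(
            CellRecord(
                id=int(lab),
                centroid=ell.center,
                axes_um=ell.axes_um,
                direction=ell.vectors[0],
                volume_um3=float(pts.shape[0]) * v**3,
                sox2=False,
                origin="host",
                region=region,
                stage=stage,
                filopodia_um=[],
            )
        )
    return cells


def rasterize_cell_points(cell: CellRecord, voxel_um: float = 2.0) -> np.ndarray:
    """Voxelize one cell's ellipsoid on an isotropic grid; returns the µm
    coordinates of the centers of the inside voxels."""
    v = _check_voxel(voxel_um)
    ell = cell_ellipsoid(cell)
    a = float(cell.axes_um[0])
    lo = np.floor((cell.centroid - a) / v).astype(int)
    hi = np.ceil((cell.centroid + a) / v).astype(int) + 1
    xs = (np.arange(lo[0], hi[0]) + 0.5) * v
    ys = (np.arange(lo[1], hi[1]) + 0.5) * v
    zs = (np.arange(lo[2], hi[2]) + 0.5) * v
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    rel = (pts - cell.centroid) @ ell.vectors.T
    inside = ((rel / cell.axes_um) ** 2).sum(axis=1) <= 1.0
    return pts[inside]


def rasterized_ellipsoid_fit(cell: CellRecord, voxel_um: float = 2.0, min_voxels_across: int = 5):
    """Voxelize one cell and re-fit its ellipsoid from the voxel cloud.

    The voxel size is refined per cell so the shortest semi-axis spans at
    least ``min_voxels_across`` voxels; very thin cells would otherwise
    digitize to a degenerate (coplanar) set.
    """
    from .geometry import fit_ellipsoid

    v = min(float(voxel_um), 2.0 * float(cell.axes_um[2]) / min_voxels_across)
    return fit_ellipsoid(rasterize_cell_points(cell, v))


def rasterize_snapshot(
    snapshot: StageSnapshot, voxel_um: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize all cells to a ZYX label stack (uint16/uint32).

    Returns (stack, origin_um) where ``origin_um`` is the µm coordinate of
    the corner of voxel (0,0,0).  Overlapping cells: the higher id wins.
    """
    v = _check_voxel(voxel_um)
    if not snapshot.cells:
        return np.zeros((1, 1, 1), dtype=np.uint16), np.zeros(3)
    cents = snapshot.centroids()
    radii = np.array([c.axes_um[0] for c in snapshot.cells])
    lo = np.floor((cents - radii[:, None]).min(axis=0) / v).astype(int) - 1
    hi = np.ceil((cents + radii[:, None]).max(axis=0) / v).astype(int) + 2
    shape_xyz = hi - lo
    dtype = np.uint16 if len(snapshot.cells) < 65535 else np.uint32
    stack = np.zeros((shape_xyz[2], shape_xyz[1], shape_xyz[0]), dtype=dtype)  # ZYX
    origin_um = lo * v
    for c in snapshot.cells:
        pts = rasterize_cell_points(c, v)
        if pts.shape[0] == 0:
            continue
        idx = np.floor(pts / v).astype(int) - lo
        stack[idx[:, 2], idx[:, 1], idx[:, 0]] = c.id
    return stack, origin_um


def write_label_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, stack)


def read_label_stack(path) -> np.ndarray:
    return tifffile.imread(path)


# re-exported summary helpers (part of the I/O surface)
from .summary import SummaryTable, read_summary_table, write_summary_table  # noqa: E402,F401
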