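"""Core in-memory containers for labelled-cell ensembles.

Coordinate convention (used everywhere in the package): x is the
anteroposterior (AP) axis with positive values pointing posterior, y is
mediolateral (ML) with positive values to the embryo's right, z is
dorsoventral (DV) with positive values dorsal. The origin sits at the
anterior-most point of the embryo. All lengths are in micrometres, volumes
in cubic micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DegenerateGeometryError

#: Valid region labels for cells.  ``somite_k`` labels (somite_1, somite_2,
#: ...) are validated by prefix.
REGIONS = (
    "PZ",
    "posterior_PSM",
    "medial_PSM",
    "anterior_PSM",
    "NT",
    "epidermis",
    "LPM",
    "endoderm",
)

GRAFT_ORIGINS = ("median", "paramedian", "lateral", "left_half", "entire", "host")

#: Ordered mesodermal stream regions, posterior to anterior.
MESODERM_REGIONS = ("PZ", "posterior_PSM", "medial_PSM", "anterior_PSM")


def is_valid_region(label: str) -> bool:
    return label in REGIONS or label.startswith("somite_")


def is_somite(label: str) -> bool:
    return label.startswith("somite_")


def is_mesodermal(label: str) -> bool:
    """PSM-stream or somite regions (the Sox2-negative compartment)."""
    return label in MESODERM_REGIONS or is_somite(label)


@dataclass(frozen=True)
class AxisFrame:
    """Embryo coordinate frame: orthonormal right-handed AP/ML/DV axes."""

    origin: np.ndarray
    ap: np.ndarray
    ml: np.ndarray
    dv: np.ndarray
    graft_side: str = "left"

    def __post_init__(self):
        for name in ("origin", "ap", "ml", "dv"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("ap", "ml", "dv"):
            v = getattr(self, name)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} axis is not unit length")
        if (
            abs(self.ap @ self.ml) > 1e-9
            or abs(self.ap @ self.dv) > 1e-9
            or abs(self.ml @ self.dv) > 1e-9
        ):
            raise ConfigurationError("axis vectors are not mutually orthogonal")
        if np.dot(np.cross(self.ap, self.ml), self.dv) < 0:
            raise ConfigurationError("axis frame is not right-handed")
        if self.graft_side not in ("left", "right"):
            raise ConfigurationError(f"unknown graft side {self.graft_side!r}")

    @classmethod
    def default(cls, graft_side: str = "left") -> "AxisFrame":
        return cls(
            origin=np.zeros(3),
            ap=np.array([1.0, 0.0, 0.0]),
            ml=np.array([0.0, 1.0, 0.0]),
            dv=np.array([0.0, 0.0, 1.0]),
            graft_side=graft_side,
        )


@dataclass
class CellRecord:
    """One labelled cell: centroid, fitted-ellipsoid shape, annotations."""

    id: int
    centroid: np.ndarray  # (3,) µm
    axes_um: np.ndarray  # semi-axes (a, b, c), a >= b >= c > 0
    direction: np.ndarray  # unit long-axis vector
    volume_um3: float
    sox2: bool
    origin: str
    region: str
    stage: int
    filopodia_um: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.axes_um = np.asarray(self.axes_um, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        a, b, c = self.axes_um
        if not (a >= b >= c > 0):
            raise DegenerateGeometryError(
                f"cell {self.id}: semi-axes must satisfy a >= b >= c > 0, got {self.axes_um}"
            )
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-6:
            raise DegenerateGeometryError(f"cell {self.id}: long-axis vector not unit norm")
        if not np.isfinite(self.centroid).all():
            raise DegenerateGeometryError(f"cell {self.id}: non-finite centroid")
        if self.volume_um3 <= 0:
            raise DegenerateGeometryError(f"cell {self.id}: non-positive volume")
        if not is_valid_region(self.region):
            raise ConfigurationError(f"cell {self.id}: unknown region {self.region!r}")
        if self.origin not in GRAFT_ORIGINS:
            raise ConfigurationError(f"cell {self.id}: unknown origin {self.origin!r}")
        for L in self.filopodia_um:
            if not (0 < L <= 40):
                raise ConfigurationError(
                    f"cell {self.id}: filopodium length {L} outside (0, 40] µm"
                )

    @property
    def aspect_ratio(self) -> float:
        return float(self.axes_um[0] / self.axes_um[2])


@dataclass
class DivisionEvent:
    """Mitotic cell with two centriole positions defining the spindle."""

    cell_id: int
    centriole1: np.ndarray
    centriole2: np.ndarray

    def __post_init__(self):
        self.centriole1 = np.asarray(self.centriole1, dtype=float)
        self.centriole2 = np.asarray(self.centriole2, dtype=float)

    @property
    def spindle(self) -> np.ndarray | None:
        d = self.centriole2 - self.centriole1
        n = np.linalg.norm(d)
        if n == 0:
            return None
        return d / n


@dataclass
class StageSnapshot:
    """All labelled cells of one embryo at one developmental stage."""

    stage: int
    cells: list[CellRecord]
    frame: AxisFrame
    divisions: list[DivisionEvent] = field(default_factory=list)
    outline: np.ndarray | None = None  # (n, 3) ventral contour polyline, µm

    def __post_init__(self):
        for c in self.cells:
            if not np.isfinite(c.centroid).all():
                raise DegenerateGeometryError(f"cell {c.id}: non-finite coordinates")

    def select(self, *, region=None, origin=None, sox2=None, mesodermal=None):
        """Filter cells; ``region`` may be a label, a prefix tuple, or 'somite'."""
        out = self.cells
        if region is not None:
            if region == "somite":
                out = [c for c in out if is_somite(c.region)]
            else:
                out = [c for c in out if c.region == region]
        if origin is not None:
            out = [c for c in out if c.origin == origin]
        if sox2 is not None:
            out = [c for c in out if c.sox2 == sox2]
        if mesodermal:
            out = [c for c in out if is_mesodermal(c.region)]
        return out

    def centroids(self, cells=None) -> np.ndarray:
        cells = self.cells if cells is None else cells
        if not cells:
            return np.zeros((0, 3))
        return np.array([c.centroid for c in cells])


@dataclass(frozen=True)
class FittedEllipsoid:
    """Moment-fitted ellipsoid: center, sorted semi-axes, orthonormal axes."""

    center: np.ndarray
    axes_um: np.ndarray  # (a, b, c) descending
    vectors: np.ndarray  # rows e_a, e_b, e_c

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "axes_um", np.asarray(self.axes_um, dtype=float))
        object.__setattr__(self, "vectors", np.asarray(self.vectors, dtype=float))
        a, b, c = self.axes_um
        if not (a >= b >= c > 0):
            raise DegenerateGeometryError("semi-axes must satisfy a >= b >= c > 0")
        g = self.vectors @ self.vectors.T
        if not np.allclose(g, np.eye(3), atol=1e-6):
            raise DegenerateGeometryError("axis vectors are not orthonormal")


def cell_ellipsoid(cell: CellRecord) -> FittedEllipsoid:
    """Ellipsoid view of a stored cell (long axis from the cell record,
    remaining axes completed to an orthonormal set)."""
    e_a = cell.direction
    helper = np.array([0.0, 0.0, 1.0])
    if abs(e_a @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e_b = np.cross(e_a, helper)
    e_b /= np.linalg.norm(e_b)
    e_c = np.cross(e_a, e_b)
    return FittedEllipsoid(cell.centroid, cell.axes_um, np.vstack([e_a, e_b, e_c]))


def with_centroid(cell: CellRecord, centroid) -> CellRecord:
    return replace(cell, centroid=np.asarray(centroid, dtype=float))
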