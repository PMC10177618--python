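"""Strand centerline geometry and the region partition along it.

The labelled paraxial-mesoderm stream is modelled as a tube around an
arc-length-parameterized centerline that runs anteriorly from the tail-bud
tip, with a short dorsal hook at the posterior end.  Arc length ``s`` is
measured from the posterior tip (s = 0) and increases anteriorly; the
stream regions are half-open arc intervals, posterior to anterior:
PZ, posterior/medial/anterior PSM (equal thirds of the PSM span by
default), then fixed-width somite blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import GeneratorConfig, StageGeometry
from .errors import ConfigurationError, DegenerateGeometryError


class ArcSpline:
    """Arc-length-parameterized 3D polyline with projection support."""

    def __init__(self, points: np.ndarray):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
            raise DegenerateGeometryError("spline needs >= 2 3D points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if seg.sum() <= 0:
            raise DegenerateGeometryError("zero-length spline")
        self.points = pts
        self.s = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.s[-1])

    @classmethod
    def straight(cls, length: float, origin=(0.0, 0.0, 0.0), direction=(1.0, 0.0, 0.0)):
        o = np.asarray(origin, dtype=float)
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        return cls(np.vstack([o, o + length * d]))

    def point(self, s) -> np.ndarray:
        """Point(s) at arc length s (clamped to the domain).  Scalar input
        yields a (3,) point, array input an (n, 3) array."""
        scalar = np.ndim(s) == 0
        sv = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, self.length)
        out = np.column_stack([np.interp(sv, self.s, self.points[:, k]) for k in range(3)])
        return out[0] if scalar else out

    def project(self, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-point projection of query points onto the polyline.

        Returns (arc lengths, distances).  Ties resolve to the smallest arc
        length (segments scanned posterior... i.e. in stored order, strict
        improvement required).
        """
        q = np.atleast_2d(np.asarray(q, dtype=float))
        a = self.points[:-1]
        d = np.diff(self.points, axis=0)
        L2 = (d * d).sum(axis=1)
        best_s = np.empty(q.shape[0])
        best_dist = np.full(q.shape[0], np.inf)
        for i in range(a.shape[0]):
            t = np.clip((q - a[i]) @ d[i] / L2[i], 0.0, 1.0)
            proj = a[i] + t[:, None] * d[i]
            dist = np.linalg.norm(q - proj, axis=1)
            upd = dist < best_dist - 1e-12
            best_dist[upd] = dist[upd]
            best_s[upd] = self.s[i] + t[upd] * np.sqrt(L2[i])
        return best_s, best_dist


def strand_centerline(
    geometry: StageGeometry,
    hook_length_um: float = 150.0,
    hook_angle_rad: float = 0.6,
    n_samples: int = 1024,
) -> ArcSpline:
    """Unit-speed centerline of one PSM stream in the x-z (AP-DV) plane.

    Mostly straight along AP, with a dorsal hook of the given arc length and
    peak pitch at the posterior tip.  Stored anterior-to-posterior so that
    arc length *from the posterior tip* is ``length - stored s``; use
    :func:`strand_point` for posterior-based arc lengths.
    """
    L = geometry.arc_length_um
    hook = min(hook_length_um, 0.5 * L)
    s = np.linspace(0.0, L, n_samples)  # from posterior tip
    pitch = hook_angle_rad * np.clip(1.0 - s / hook, 0.0, 1.0)
    # integrate moving anteriorly from the tip: dx/ds = -cos(pitch), dz/ds = -sin(pitch)
    ds = np.diff(s)
    x = np.concatenate([[0.0], np.cumsum(-np.cos(pitch[:-1]) * ds)])
    z = np.concatenate([[0.0], np.cumsum(-np.sin(pitch[:-1]) * ds)])
    x = x - x.min() + geometry.anterior_offset_um
    z = z - z.min()
    pts = np.column_stack([x, np.zeros_like(x), z])
    # store anterior-to-posterior (ascending stored arc = descending s)
    return ArcSpline(pts[::-1])


def posterior_arc_to_stored(spline: ArcSpline, s_post) -> np.ndarray:
    return spline.length - np.asarray(s_post, dtype=float)


def strand_point(spline: ArcSpline, s_post) -> np.ndarray:
    """Centerline point at arc length measured from the posterior tip."""
    return spline.point(posterior_arc_to_stored(spline, np.atleast_1d(s_post)))


@dataclass(frozen=True)
class RegionPartition:
    """Arc-length partition of the stream: ``labels[i]`` occupies
    (breakpoints[i-1], breakpoints[i]] with breakpoints[-1] == span end;
    a cell exactly at a breakpoint belongs to the more posterior region."""

    breakpoints: np.ndarray  # ascending; one per region (upper bounds)
    labels: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "breakpoints", np.asarray(self.breakpoints, dtype=float))
        if len(self.labels) != len(self.breakpoints):
            raise ConfigurationError("one upper breakpoint per region label required")
        if not np.all(np.diff(self.breakpoints) > 0):
            raise ConfigurationError("breakpoints must be strictly increasing")

    def label_for(self, s_post) -> list[str]:
        s = np.atleast_1d(np.asarray(s_post, dtype=float))
        out_of_domain = (s < 0) | (s > self.breakpoints[-1])
        if out_of_domain.any():
            warnings.warn(
                f"{int(out_of_domain.sum())} cell(s) project outside the spline domain; "
                "assigned to the nearest terminal region"
            )
        idx = np.searchsorted(self.breakpoints[:-1], s, side="left")
        return [self.labels[i] for i in idx]

    def interval(self, label: str) -> tuple[float, float]:
        i = self.labels.index(label)
        lo = 0.0 if i == 0 else float(self.breakpoints[i - 1])
        return lo, float(self.breakpoints[i])


def region_partition(config: GeneratorConfig, stage: int) -> RegionPartition:
    """Default partition at a stage: PZ, then equal PSM thirds, then somites."""
    try:
        geom = config.geometry[stage]
    except KeyError:
        raise ConfigurationError(f"no strand geometry configured for stage {stage}") from None
    L = geom.arc_length_um
    pz = min(geom.pz_length_um, L)
    som_span = geom.n_somites * config.somite_spacing_um
    psm_hi = L - som_span
    labels: list[str] = ["PZ"]
    bps: list[float] = [pz]
    if psm_hi > pz + 1e-9:
        third = (psm_hi - pz) / 3.0
        labels += ["posterior_PSM", "medial_PSM", "anterior_PSM"]
        bps += [pz + third, pz + 2 * third, psm_hi]
    for k in range(1, geom.n_somites + 1):
        labels.append(f"somite_{k}")
        bps.append(psm_hi + k * config.somite_spacing_um)
    bps[-1] = L  # absorb rounding
    return RegionPartition(np.array(bps), tuple(labels))


def cross_section_halfwidth(geometry: StageGeometry) -> float:
    """Tube cross-section radius from the configured envelope volume."""
    return float(np.sqrt(geometry.tissue_volume_um3 / (np.pi * geometry.arc_length_um)))
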