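"""Planar point-in-polygon tests in geographic coordinates.

Polygons are treated as planar figures in longitude/latitude degrees (no
great-circle edges), which matches what users expect from polygons digitised
in a GIS. Containment uses the even-odd (ray-casting) rule; ring orientation
is ignored. Points within ``BOUNDARY_TOL`` degrees of an edge or vertex are
reported inside, so that grid-aligned fixtures behave deterministically on
shared edges.

Polygons whose edges would span more than 180 degrees of longitude are
rejected: a ring crossing the anti-meridian is ambiguous in planar
coordinates and must be split by the user into two rings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Points closer than this (degrees) to an edge or vertex count as inside.
BOUNDARY_TOL = 1e-9


class GeometryError(ValueError):
    """Invalid geometric input (degenerate ring, non-finite coordinate...)."""


def normalize_longitude(lon: float) -> float:
    """Map a longitude onto [-180, 180], congruent mod 360.

    Values congruent to 180 (including -180 and -540) map to +180.
    """
    if not math.isfinite(lon):
        raise GeometryError(f"longitude must be finite, got {lon!r}")
    r = (lon + 180.0) % 360.0 - 180.0
    if r == -180.0:
        r = 180.0
    return r


@dataclass(frozen=True)
class GeoPoint:
    """A geographic point; longitude is normalized into [-180, 180] on creation."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.lat):
            raise GeometryError(f"latitude must be finite, got {self.lat!r}")
        if not -90.0 <= self.lat <= 90.0:
            raise GeometryError(f"latitude out of range [-90, 90]: {self.lat}")
        object.__setattr__(self, "lon", normalize_longitude(self.lon))


class EdgeTestCounter:
    """Counts point-edge tests, used to check that work scales linearly."""

    def __init__(self) -> None:
        self.edge_tests = 0
        self.bbox_tests = 0

    def reset(self) -> None:
        self.edge_tests = 0
        self.bbox_tests = 0


#: Module-level counter incremented by every containment test.
perf_counter = EdgeTestCounter()


class PolygonDef:
    """A named simple polygon given by one outer ring of >= 3 distinct vertices.

    The ring is implicitly closed (the last vertex need not repeat the first).
    Orientation may be clockwise or counter-clockwise.
    """

    __slots__ = ("name", "lons", "lats", "bbox")

    def __init__(self, name: str, ring) -> None:
        if not name or not str(name).strip():
            raise GeometryError("polygon name must be non-empty")
        # vertices already in [-180, 180] are kept verbatim so that rings
        # touching the anti-meridian (lon = -180) stay valid
        pts = [
            (
                float(lon)
                if -180.0 <= float(lon) <= 180.0
                else normalize_longitude(float(lon)),
                float(lat),
            )
            for lon, lat in ring
        ]
        if pts and pts[0] == pts[-1]:
            pts = pts[:-1]
        if len(set(pts)) < 3:
            raise GeometryError(
                f"polygon {name!r}: ring must have >= 3 distinct vertices"
            )
        for _, lat in pts:
            if not math.isfinite(lat) or not -90.0 <= lat <= 90.0:
                raise GeometryError(f"polygon {name!r}: latitude out of range: {lat}")
        lons = np.array([p[0] for p in pts], dtype=float)
        lats = np.array([p[1] for p in pts], dtype=float)
        dlon = np.abs(np.diff(np.append(lons, lons[0])))
        if np.any(dlon > 180.0):
            raise GeometryError(
                f"polygon {name!r}: an edge spans more than 180 degrees of "
                "longitude; split polygons crossing the anti-meridian into "
                "two rings"
            )
        self.name = str(name)
        self.lons = lons
        self.lats = lats
        self.bbox = (lons.min(), lons.max(), lats.min(), lats.max())

    @property
    def n_vertices(self) -> int:
        return len(self.lons)

    @property
    def ring(self) -> list[GeoPoint]:
        return [GeoPoint(lo, la) for lo, la in zip(self.lons, self.lats)]

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"PolygonDef({self.name!r}, {self.n_vertices} vertices)"


def bbox_prefilter(p: GeoPoint, poly: PolygonDef) -> bool:
    """Cheap necessary condition: False guarantees the point is outside."""
    perf_counter.bbox_tests += 1
    lo0, lo1, la0, la1 = poly.bbox
    t = BOUNDARY_TOL
    return (lo0 - t <= p.lon <= lo1 + t) and (la0 - t <= p.lat <= la1 + t)


def points_in_polygon(
    lons, lats, poly: PolygonDef, counter: EdgeTestCounter | None = None
) -> np.ndarray:
    """Vectorised even-odd containment test for many points against one polygon.

    Returns a boolean array; boundary points (within ``BOUNDARY_TOL``) are True.
    """
    if counter is None:
        counter = perf_counter
    x = np.asarray(lons, dtype=float)
    y = np.asarray(lats, dtype=float)
    if x.shape != y.shape:
        raise GeometryError("lons and lats must have the same shape")
    result = np.zeros(x.shape, dtype=bool)

    lo0, lo1, la0, la1 = poly.bbox
    t = BOUNDARY_TOL
    counter.bbox_tests += x.size
    cand = (x >= lo0 - t) & (x <= lo1 + t) & (y >= la0 - t) & (y <= la1 + t)
    if not np.any(cand):
        return result
    cx = x[cand]
    cy = y[cand]

    xs = np.append(poly.lons, poly.lons[0])
    ys = np.append(poly.lats, poly.lats[0])
    n_edges = poly.n_vertices
    counter.edge_tests += int(cx.size) * n_edges

    inside = np.zeros(cx.shape, dtype=bool)
    boundary = np.zeros(cx.shape, dtype=bool)
    tol2 = BOUNDARY_TOL * BOUNDARY_TOL
    for i in range(n_edges):
        x1, y1, x2, y2 = xs[i], ys[i], xs[i + 1], ys[i + 1]
        dx = x2 - x1
        dy = y2 - y1
        seg2 = dx * dx + dy * dy
        # distance to segment (degenerate edges fall back to the vertex)
        if seg2 > 0.0:
            tpar = np.clip(((cx - x1) * dx + (cy - y1) * dy) / seg2, 0.0, 1.0)
        else:
            tpar = 0.0
        px = x1 + tpar * dx
        py = y1 + tpar * dy
        boundary |= (cx - px) ** 2 + (cy - py) ** 2 <= tol2
        # even-odd crossing with the half-open rule on edge endpoints
        crosses = (y1 > cy) != (y2 > cy)
        if np.any(crosses):
            with np.errstate(divide="ignore", invalid="ignore"):
                xint = x1 + (cy - y1) / dy * dx
            inside ^= crosses & (cx < xint)

    result[cand] = inside | boundary
    return result


def point_in_polygon(p: GeoPoint, poly: PolygonDef) -> bool:
    """Even-odd containment test for a single point; boundary counts as inside."""
    return bool(points_in_polygon([p.lon], [p.lat], poly)[0])
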