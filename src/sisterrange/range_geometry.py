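"""Species range polygons from point localities.

Ranges are estimated as minimum convex polygons (MCPs) for species with three
or more non-collinear localities.  Species known from only one or two points
get a buffer zone instead; two buffer policies are carried through every
analysis so results can be compared under a generous and a quasi-zero
assumption about microendemic ranges:

* ``RSA`` - 25 km radius buffers,
* ``RSB`` - 17 m radius buffers.

All geometry is planar, in meters, via shapely; areas are reported in km² and
centroids/distances in km.  Helper :func:`lonlat_to_planar` converts
geographic coordinates with an equirectangular approximation, adequate at the
~1500 km extent of a single large island.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiPoint, Point, Polygon
from shapely.prepared import prep

__all__ = [
    "BUFFER_RADII_M",
    "RangePolygon",
    "RangeSet",
    "build_range",
    "build_range_set",
    "overlap_pct",
    "overlap_matrix",
    "centroid_distance_matrix",
    "classify_pairs",
    "lonlat_to_planar",
]

log = logging.getLogger(__name__)

#: Buffer radius (meters) by policy for 1-2-locality species.
BUFFER_RADII_M = {"RSA": 25_000.0, "RSB": 17.0}

#: Segments per quarter circle in buffer approximations (128 per full circle,
#: keeping the polygonal area within 0.05% of the true disc).
QUAD_SEGS = 32

#: Areas below this (km²) are treated as zero when classifying overlap.
AREA_EPS_KM2 = 1e-12

M2_PER_KM2 = 1e6


@dataclass
class RangePolygon:
    """One species' range estimate under one buffer policy."""

    species: str
    polygon: Polygon
    area_km2: float
    centroid_km: tuple[float, float]
    n_localities: int
    construction: str  # "mcp" or "buffer"


@dataclass
class RangeSet:
    """All species' ranges built under a single buffer policy."""

    policy: str
    buffer_radius_m: float
    ranges: dict[str, RangePolygon]

    def __getitem__(self, species: str) -> RangePolygon:
        return self.ranges[species]

    def __contains__(self, species: str) -> bool:
        return species in self.ranges

    @property
    def species(self) -> list[str]:
        return sorted(self.ranges)


def build_range(points_m: np.ndarray, policy: str, species: str = "") -> RangePolygon:
    """Build one range polygon from locality coordinates in meters.

    One point gives a disc of the policy radius; two points (or any collinear
    set) give a capsule — the buffered segment through the points, i.e. the
    union of the end discs and the connecting corridor — so the range is a
    single connected polygon.  Three or more non-collinear points give the
    convex hull.  The centroid follows the construction: the point itself for
    one locality, the midpoint for two, the area centroid otherwise.
    """
    pts = np.asarray(points_m, float)
    if pts.ndim != 2 or pts.shape[0] == 0 or pts.shape[1] != 2:
        raise ValueError("need an (n, 2) array with n >= 1 locality")
    if policy not in BUFFER_RADII_M:
        raise ValueError(f"unknown buffer policy {policy!r}")
    radius = BUFFER_RADII_M[policy]
    pts = np.unique(pts, axis=0)
    n = pts.shape[0]

    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if isinstance(hull, Polygon):
        poly = hull
        construction = "mcp"
        centroid = (poly.centroid.x, poly.centroid.y)
    else:
        # Point (n==1) or LineString (n==2 or collinear): buffer it.
        poly = hull.buffer(radius, quad_segs=QUAD_SEGS)
        construction = "buffer"
        if n == 1:
            centroid = (float(pts[0, 0]), float(pts[0, 1]))
        elif n == 2:
            centroid = tuple((pts[0] + pts[1]) / 2.0)
        else:
            centroid = (poly.centroid.x, poly.centroid.y)
    return RangePolygon(
        species=species,
        polygon=poly,
        area_km2=poly.area / M2_PER_KM2,
        centroid_km=(centroid[0] / 1e3, centroid[1] / 1e3),
        n_localities=n,
        construction=construction,
    )


def build_range_set(localities: pd.DataFrame, policy: str) -> RangeSet:
    """Build ranges for every species in a locality table (meters)."""
    ranges = {}
    for species, grp in localities.groupby("species", sort=True):
        ranges[str(species)] = build_range(
            grp[["x", "y"]].to_numpy(float), policy, species=str(species)
        )
    return RangeSet(policy=policy, buffer_radius_m=BUFFER_RADII_M[policy], ranges=ranges)


def overlap_pct(a: RangePolygon, b: RangePolygon) -> float:
    """Range overlap as a percentage of the smaller polygon's area."""
    smaller = min(a.area_km2, b.area_km2)
    if smaller <= AREA_EPS_KM2:
        return 0.0
    inter = a.polygon.intersection(b.polygon).area / M2_PER_KM2
    if inter <= AREA_EPS_KM2:
        return 0.0
    return min(100.0, 100.0 * inter / smaller)


def overlap_area_km2(a: RangePolygon, b: RangePolygon) -> float:
    return a.polygon.intersection(b.polygon).area / M2_PER_KM2


def overlap_matrix(ranges: RangeSet) -> pd.DataFrame:
    """Symmetric species × species matrix of overlap percentages."""
    species = ranges.species
    n = len(species)
    mat = np.full((n, n), 0.0)
    prepared = {s: prep(ranges[s].polygon) for s in species}
    for i, si in enumerate(species):
        mat[i, i] = 100.0
        pi = prepared[si]
        for j in range(i + 1, n):
            sj = species[j]
            if not pi.intersects(ranges[sj].polygon):
                continue
            val = overlap_pct(ranges[si], ranges[sj])
            mat[i, j] = mat[j, i] = val
    return pd.DataFrame(mat, index=species, columns=species)


def centroid_distance_matrix(ranges: RangeSet) -> pd.DataFrame:
    """Euclidean distances between range centroids, in km."""
    species = ranges.species
    cent = np.array([ranges[s].centroid_km for s in species])
    diff = cent[:, None, :] - cent[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    return pd.DataFrame(dist, index=species, columns=species)


def classify_pairs(pairs, ranges: RangeSet) -> dict[tuple[str, str], str]:
    """Classify sister pairs as allopatric (zero overlap) or sympatric.

    Pairs with a member missing from the range set are skipped with a log
    entry.  Overlap is evaluated on the polygons of *ranges*' policy.
    """
    labels = {}
    for pair in pairs:
        key = (pair.species_a, pair.species_b)
        if pair.species_a not in ranges or pair.species_b not in ranges:
            log.warning("pair %s skipped: missing range data", key)
            continue
        pct = overlap_pct(ranges[pair.species_a], ranges[pair.species_b])
        labels[key] = "allopatric" if pct == 0.0 else "sympatric"
    return labels


EARTH_RADIUS_KM = 6371.0


def lonlat_to_planar(
    lon: np.ndarray, lat: np.ndarray, lat0: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat (degrees) to planar meters, equirectangular about lat0.

    ``x = R·cos(lat0)·lon``, ``y = R·lat`` (radians); lat0 defaults to the mean
    latitude of the data.
    """
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    if lat0 is None:
        lat0 = float(np.mean(lat))
    k = EARTH_RADIUS_KM * 1e3
    x = k * math.cos(math.radians(lat0)) * np.radians(lon)
    y = k * np.radians(lat)
    return x, y
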