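"""Area-weighted post-stratification of cell trends to arbitrary regions.

A reporting region (e.g. a Bird Conservation Region) is reduced to per-cell
weights: the overlap proportion ``w'_ck`` (fraction of the cell's area
inside the region) corrected for the latitude dependence of degree-block
size, ``w''_ck = w'_ck * A_c / Abar_k`` where ``Abar_k`` is the mean area
of the overlapped cells.  The region trend is the ``w''``-weighted average
of member-cell trends, computed per posterior draw by default so the
credible interval propagates the joint posterior uncertainty.

Overlap geometry is computed in lon/lat coordinates (shapely) and measured
with the spherical area element ``R^2 cos(phi) dphi dlambda`` via an exact
line integral along the polygon boundary — consistent with the spherical
band formula used for whole cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import GeometryCollection, MultiPolygon, Polygon, box, shape
from shapely.geometry.polygon import orient
from shapely.validation import make_valid

from .lattice import EARTH_RADIUS_KM, Cell, Lattice
from .trend import TrendEstimate, expected_abundance, summarize, trend_draws

__all__ = [
    "RegionSpec",
    "cell_region_proportion",
    "build_region_weights",
    "region_trend",
    "spherical_polygon_area",
]


def _ring_area_steradians(coords) -> float:
    """Signed integral of cos(phi) over a lon/lat ring (CCW positive).

    Green's theorem with edges straight in the equirectangular plane:
    ``integral of cos(phi) dA = - contour integral of sin(phi) dlambda``
    for positively oriented rings, each edge contributing the exact
    ``dlambda * (cos(phi1) - cos(phi2)) / (phi2 - phi1)`` mean of sin(phi).
    """
    total = 0.0
    pts = list(coords)
    for (lon1, lat1), (lon2, lat2) in zip(pts[:-1], pts[1:]):
        lam1, phi1 = math.radians(lon1), math.radians(lat1)
        lam2, phi2 = math.radians(lon2), math.radians(lat2)
        dlam = lam2 - lam1
        if dlam == 0.0:
            continue
        if phi1 == phi2:
            mean_sin = math.sin(phi1)
        else:
            mean_sin = (math.cos(phi1) - math.cos(phi2)) / (phi2 - phi1)
        total -= dlam * mean_sin
    return total


def _polygon_area_steradians(poly: Polygon) -> float:
    poly = orient(poly)  # CCW exterior, CW holes -> signed parts add up
    area = _ring_area_steradians(poly.exterior.coords)
    for hole in poly.interiors:
        area += _ring_area_steradians(hole.coords)
    return area


def spherical_polygon_area(geom, earth_radius: float = EARTH_RADIUS_KM) -> float:
    """Spherical area (km^2) of a lon/lat polygon with straight edges.

    "Straight" means straight in the equirectangular plane, which makes the
    result exact for lattice-cell rectangles and their intersections.
    """
    if geom.is_empty:
        return 0.0
    if isinstance(geom, Polygon):
        parts = [geom]
    elif isinstance(geom, (MultiPolygon, GeometryCollection)):
        parts = [g for g in geom.geoms if isinstance(g, Polygon)]
    else:
        return 0.0
    return earth_radius**2 * sum(_polygon_area_steradians(p) for p in parts)


def _clean_polygon(region):
    if isinstance(region, dict):
        region = shape(region.get("geometry", region))
    if not region.is_valid:
        region = make_valid(region)
        if not region.is_valid:
            raise ValueError("region polygon is invalid and could not be repaired")
    return region


def _split_antimeridian(region):
    """Clip to [-180, 180] and wrap any overhanging parts back in."""
    minx, _, maxx, _ = region.bounds
    if -180.0 <= minx and maxx <= 180.0:
        return region
    from shapely.affinity import translate
    from shapely.ops import unary_union

    world = box(-180.0, -90.0, 180.0, 90.0)
    pieces = [region.intersection(world)]
    for shift in (-360.0, 360.0):
        pieces.append(translate(region, xoff=shift).intersection(world))
    return unary_union([p for p in pieces if not p.is_empty])


def cell_region_proportion(cell, region, earth_radius: float = EARTH_RADIUS_KM) -> float:
    """Fraction of a cell's (spherical) area contained in a region polygon.

    ``cell`` is a Cell or a bbox ``(long1, lat1, long2, lat2)``; ``region``
    a shapely (Multi)Polygon or a GeoJSON mapping.
    """
    if isinstance(cell, Cell):
        bbox = cell.bbox
    else:
        bbox = tuple(cell)
    long1, lat1, long2, lat2 = bbox
    if long1 > long2 or lat2 > lat1:
        raise ValueError(f"inverted cell bbox {bbox!r}")
    region = _split_antimeridian(_clean_polygon(region))
    cell_geom = box(long1, lat2, long2, lat1)
    inter = cell_geom.intersection(region)
    if inter.is_empty:
        return 0.0
    from .lattice import cell_area

    frac = spherical_polygon_area(inter, earth_radius) / cell_area(bbox, earth_radius)
    return float(min(max(frac, 0.0), 1.0))


@dataclass
class RegionSpec:
    """Per-cell weights of a reporting region.

    ``w_prime``: overlap proportions in [0, 1] (cells with 0 excluded);
    ``areas``: spherical cell areas; ``w``: area-corrected weights
    ``w'_ck * A_c / Abar_k`` with ``Abar_k`` the mean area of included cells.
    """

    region_id: object
    cell_ids: list
    w_prime: np.ndarray
    areas: np.ndarray

    def __post_init__(self):
        self.w_prime = np.asarray(self.w_prime, float)
        self.areas = np.asarray(self.areas, float)
        if len(self.cell_ids) == 0:
            raise ValueError("region overlaps no lattice cell")
        if not (len(self.cell_ids) == len(self.w_prime) == len(self.areas)):
            raise ValueError("cell_ids, w_prime and areas must align")
        if ((self.w_prime <= 0) | (self.w_prime > 1)).any():
            raise ValueError("overlap proportions must lie in (0, 1]")
        if (self.areas <= 0).any():
            raise ValueError("cell areas must be positive")

    @property
    def w(self) -> np.ndarray:
        return self.w_prime * self.areas / self.areas.mean()

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "region_id": self.region_id,
                "cell_lon": [c[0] for c in self.cell_ids],
                "cell_lat": [c[1] for c in self.cell_ids],
                "w_prime": self.w_prime,
                "area_km2": self.areas,
                "w": self.w,
            }
        )


def build_region_weights(region, lattice: Lattice, region_id="region") -> RegionSpec:
    """Overlap + area-corrected weights of a region over a lattice."""
    region = _split_antimeridian(_clean_polygon(region))
    ids, wp, ar = [], [], []
    for cell, area in zip(lattice.cells, lattice.areas):
        p = cell_region_proportion(cell, region, cell.earth_radius)
        if p > 0.0:
            ids.append(cell.id)
            wp.append(p)
            ar.append(area)
    if not ids:
        raise ValueError(f"region {region_id!r} overlaps no lattice cell")
    return RegionSpec(region_id, ids, np.array(wp), np.array(ar))


def region_weights_from_frame(df, lattice: Lattice) -> list:
    """RegionSpecs from a precomputed table ``region_id,cell_lon,cell_lat,w_prime``."""
    specs = []
    for rid, grp in df.groupby("region_id"):
        ids = [tuple(x) for x in grp[["cell_lon", "cell_lat"]].itertuples(index=False)]
        ids = [lattice.cells[lattice.position(c)].id for c in ids]
        areas = np.array([lattice.areas[lattice.position(c)] for c in ids])
        specs.append(RegionSpec(rid, ids, grp["w_prime"].to_numpy(), areas))
    return specs


def region_trend(
    draws,
    spec: RegionSpec,
    year_a: int,
    year_b: int,
    level: float = 0.95,
    retransform: str = "lognormal",
    point: str = "median",
    mode: str = "per-draw",
    keep_draws: bool = False,
) -> TrendEstimate:
    """Weighted-average trend of a region's member cells.

    ``mode='per-draw'`` (default) averages the member-cell trends within
    each retained draw and summarizes afterwards; ``mode='point-estimate'``
    averages the cells' posterior point estimates (no interval).
    """
    if year_a >= year_b:
        raise ValueError("need year_a < year_b")
    w = spec.w
    wsum = w.sum()
    cell_tr = np.column_stack(
        [
            trend_draws(
                expected_abundance(draws, cid, year_a, retransform),
                expected_abundance(draws, cid, year_b, retransform),
                year_a,
                year_b,
            )
            for cid in spec.cell_ids
        ]
    )
    if mode == "point-estimate":
        stat = np.median if point == "median" else np.mean
        pts = stat(cell_tr, axis=0)
        val = float((w * pts).sum() / wsum)
        return TrendEstimate(spec.region_id, int(year_a), int(year_b), val, val, val, level)
    if mode != "per-draw":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    td = cell_tr @ (w / wsum)
    pt, lo, hi = summarize(td, level=level, point=point)
    return TrendEstimate(
        spec.region_id, int(year_a), int(year_b), pt, lo, hi, level,
        draws=td if keep_draws else None,
    )
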