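"""Degree-block lattice: cells, route assignment, adjacency, spherical areas.

Survey routes are identified by their start coordinates and binned into
half-open longitude/latitude blocks ``[lon, lon+res) x [lat, lat+res)``.
The occupied blocks form the lattice on which the intrinsic CAR spatial
effect is defined: a symmetric binary adjacency ``W`` (rook by default),
neighbor counts ``n_c`` and the conditional-variance scaling ``M_c = 1/n_c``.
Cell areas are exact spherical band areas, ``A = R^2 (lam2-lam1)(sin phi1 -
sin phi2)`` with the bbox stored in upper-left / lower-right convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "Cell",
    "Lattice",
    "SurveyDataset",
    "assign_route",
    "build_lattice",
    "cell_area",
    "EARTH_RADIUS_KM",
]


def _snap(value: float, resolution: float):
    """Lower corner of the block containing ``value``; int when integral."""
    v = math.floor(value / resolution) * resolution
    if float(resolution).is_integer():
        return int(round(v))
    return v


def assign_route(start_lon: float, start_lat: float, resolution: float = 1.0):
    """Map a route start point to its degree-block cell id.

    The id is the lower-left corner of the half-open block
    ``[lon, lon+res) x [lat, lat+res)`` containing the point.

    Parameters
    ----------
    start_lon, start_lat : float
        Route start coordinates in decimal degrees (WGS84 lon/lat).
    resolution : float
        Block side length in degrees (1.0 for BBS degree blocks).

    Returns
    -------
    tuple
        ``(lon, lat)`` lower-left corner identifying the cell.
    """
    if not (np.isfinite(start_lon) and np.isfinite(start_lat)):
        raise ValueError("route coordinates must be finite")
    if not (-180.0 <= start_lon < 180.0):
        raise ValueError(f"longitude {start_lon!r} outside [-180, 180)")
    if not (-90.0 < start_lat < 90.0):
        raise ValueError(f"latitude {start_lat!r} outside (-90, 90)")
    if not (np.isfinite(resolution) and resolution > 0):
        raise ValueError("resolution must be a positive finite number")
    return (_snap(start_lon, resolution), _snap(start_lat, resolution))


def cell_area(bbox: Sequence[float], earth_radius: float = EARTH_RADIUS_KM) -> float:
    """Spherical surface area (km^2) of a lon/lat rectangle.

    ``bbox`` is ``(long1, lat1, long2, lat2)`` with ``long1 <= long2`` and
    ``lat2 <= lat1`` (upper-left / lower-right corners).  The area of the
    spherical band slice is ``R^2 * (long2-long1 in radians) *
    (sin lat1 - sin lat2)``, exact on the sphere.
    """
    long1, lat1, long2, lat2 = bbox
    if long1 > long2 or lat2 > lat1:
        raise ValueError(f"inverted bbox {bbox!r}: need long1 <= long2, lat2 <= lat1")
    if not (-90.0 <= lat2 <= 90.0 and -90.0 <= lat1 <= 90.0):
        raise ValueError("latitudes must lie in [-90, 90]")
    dlam = math.radians(long2 - long1)
    return earth_radius**2 * dlam * (math.sin(math.radians(lat1)) - math.sin(math.radians(lat2)))


@dataclass(frozen=True)
class Cell:
    """A degree block: id = lower-left corner, bbox in UL/LR convention."""

    id: tuple
    resolution: float = 1.0
    earth_radius: float = EARTH_RADIUS_KM

    @property
    def bbox(self) -> tuple:
        """(long1, lat1, long2, lat2): upper-left and lower-right corners."""
        lon, lat = self.id
        return (lon, lat + self.resolution, lon + self.resolution, lat)

    @property
    def area(self) -> float:
        return cell_area(self.bbox, self.earth_radius)

    @property
    def centroid(self) -> tuple:
        lon, lat = self.id
        return (lon + self.resolution / 2.0, lat + self.resolution / 2.0)

    def contains(self, lon: float, lat: float) -> bool:
        x, y = self.id
        r = self.resolution
        return x <= lon < x + r and y <= lat < y + r


def _great_circle_km(p1, p2, radius=EARTH_RADIUS_KM):
    lam1, phi1, lam2, phi2 = map(math.radians, (p1[0], p1[1], p2[0], p2[1]))
    h = (
        math.sin((phi2 - phi1) / 2) ** 2
        + math.cos(phi1) * math.cos(phi2) * math.sin((lam2 - lam1) / 2) ** 2
    )
    return 2 * radius * math.asin(min(1.0, math.sqrt(h)))


class Lattice:
    """Ordered cell collection with binary adjacency and neighbor counts.

    Attributes
    ----------
    cells : list of Cell
        Ordered cells; all arrays/matrices are indexed in this order.
    W : scipy.sparse.csr_matrix
        Symmetric 0/1 adjacency with zero diagonal.
    n : ndarray
        Neighbor counts ``n_c`` (row sums of W).
    M : ndarray
        Conditional-variance scaling ``M_c = 1/n_c`` of the intrinsic CAR.
    areas : ndarray
        Spherical cell areas in km^2.
    """

    def __init__(self, cells: Sequence[Cell], W: sp.spmatrix):
        self.cells = list(cells)
        self.index = {c.id: i for i, c in enumerate(self.cells)}
        if len(self.index) != len(self.cells):
            raise ValueError("duplicate cell ids")
        W = sp.csr_matrix(W)
        if (W != W.T).nnz or W.diagonal().any():
            raise ValueError("adjacency must be symmetric with zero diagonal")
        self.W = W
        self.n = np.asarray(W.sum(axis=1)).ravel()
        if (self.n < 1).any():
            bad = [self.cells[i].id for i in np.flatnonzero(self.n < 1)]
            raise ValueError(f"isolated cells (n_c = 0): {bad}")
        self.M = 1.0 / self.n
        self.areas = np.array([c.area for c in self.cells])
        self._colors = None
        self._eig = None

    def __len__(self):
        return len(self.cells)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def position(self, cell_id) -> int:
        return self.index[tuple(cell_id)]

    @property
    def laplacian(self) -> sp.csr_matrix:
        """Graph Laplacian D - W, the (scaled) intrinsic CAR precision."""
        return sp.diags(self.n) - self.W

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self)))
        rows, cols = self.W.nonzero()
        g.add_edges_from((int(a), int(b)) for a, b in zip(rows, cols) if a < b)
        return g

    def coloring(self) -> list:
        """Color classes: index arrays with no within-class adjacency.

        Used to vectorize Metropolis updates of the spatial field — cells in
        one class have conditionally independent full conditionals.
        """
        if self._colors is None:
            col = nx.coloring.greedy_color(self.graph(), strategy="largest_first")
            k = max(col.values()) + 1 if col else 1
            self._colors = [
                np.array(sorted(i for i, c in col.items() if c == g), dtype=int)
                for g in range(k)
            ]
        return self._colors

    def icar_eigensystem(self):
        """Eigendecomposition of the Laplacian, cached (used for sampling)."""
        if self._eig is None:
            vals, vecs = np.linalg.eigh(self.laplacian.toarray())
            self._eig = (vals, vecs)
        return self._eig

    def to_frames(self) -> tuple:
        """(cells, edges) DataFrames for CSV export."""
        cells = pd.DataFrame(
            {
                "cell_lon": [c.id[0] for c in self.cells],
                "cell_lat": [c.id[1] for c in self.cells],
                "long1": [c.bbox[0] for c in self.cells],
                "lat1": [c.bbox[1] for c in self.cells],
                "long2": [c.bbox[2] for c in self.cells],
                "lat2": [c.bbox[3] for c in self.cells],
                "area_km2": self.areas,
                "n_neighbors": self.n,
            }
        )
        rows, cols = self.W.nonzero()
        edges = pd.DataFrame(
            [
                {
                    "cell_a_lon": self.cells[a].id[0],
                    "cell_a_lat": self.cells[a].id[1],
                    "cell_b_lon": self.cells[b].id[0],
                    "cell_b_lat": self.cells[b].id[1],
                }
                for a, b in zip(rows, cols)
                if a < b
            ]
        )
        return cells, edges


class SurveyDataset:
    """Route-level survey counts with observer, year and start coordinates.

    Wraps a DataFrame with columns ``route_id, observer_id, year, count,
    start_lon, start_lat`` and derives the model's index structure: the cell
    assignment c(i) of each route and the observer index K(i,t) (one effect
    per observer-route pair by default, matching BBS practice, or per
    observer with ``observer_mode='observer'``).
    """

    REQUIRED = ["route_id", "observer_id", "year", "count", "start_lon", "start_lat"]

    def __init__(self, df: pd.DataFrame, resolution: float = 1.0,
                 observer_mode: str = "observer-route"):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if observer_mode not in ("observer-route", "observer"):
            raise ValueError(f"unknown observer_mode {observer_mode!r}")
        df = df.reset_index(drop=True).copy()
        counts = df["count"].to_numpy()
        if not np.issubdtype(np.asarray(counts).dtype, np.number):
            raise ValueError("counts must be numeric")
        if (counts < 0).any():
            bad = int(np.flatnonzero(counts < 0)[0])
            raise ValueError(f"negative count at row {bad}")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        years = df["year"].to_numpy()
        if not np.allclose(years, np.round(years)):
            raise ValueError("years must be integers")
        dup = df.duplicated(subset=["route_id", "observer_id", "year"])
        if dup.any():
            raise ValueError(
                f"duplicated (route, observer, year) rows: {list(df.index[dup][:5])}"
            )
        # one cell per route: assignment uses the route's (first) start point
        route_start = df.groupby("route_id")[["start_lon", "start_lat"]].first()
        if df.groupby("route_id")[["start_lon", "start_lat"]].nunique().gt(1).any().any():
            raise ValueError("a route_id has inconsistent start coordinates")

        self.df = df
        self.resolution = float(resolution)
        self.observer_mode = observer_mode
        self.counts = np.round(counts).astype(np.int64)

        cell_by_route = {
            rid: assign_route(row.start_lon, row.start_lat, resolution)
            for rid, row in route_start.iterrows()
        }
        self.cell_ids = [cell_by_route[r] for r in df["route_id"]]
        self.route_cell = cell_by_route

        y = np.round(years).astype(int)
        self.year_min, self.year_max = int(y.min()), int(y.max())
        self.years = np.arange(self.year_min, self.year_max + 1)
        self.year_idx = y - self.year_min

        if observer_mode == "observer-route":
            keys = list(zip(df["route_id"], df["observer_id"]))
        else:
            keys = list(df["observer_id"])
        self.obs_labels, self.obs_idx = np.unique(
            pd.Series(keys).astype(str), return_inverse=True
        )

    @classmethod
    def from_csv(cls, path, resolution: float = 1.0,
                 observer_mode: str = "observer-route") -> "SurveyDataset":
        return cls(pd.read_csv(path), resolution=resolution, observer_mode=observer_mode)

    def __len__(self):
        return len(self.df)

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_observers(self) -> int:
        return len(self.obs_labels)

    @property
    def n_routes(self) -> int:
        return self.df["route_id"].nunique()

    def summary(self) -> dict:
        return {
            "records": self.n_records,
            "routes": self.n_routes,
            "cells": len(set(self.cell_ids)),
            "detections": int(self.counts.sum()),
            "years": [self.year_min, self.year_max],
            "observers": int(self.df["observer_id"].nunique()),
            "observer_effects": self.n_observers,
        }


def _neighbor_offsets(scheme: str):
    rook = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    if scheme == "rook":
        return rook
    if scheme == "queen":
        return rook + [(1, 1), (1, -1), (-1, 1), (-1, -1)]
    raise ValueError(f"unknown adjacency scheme {scheme!r}")


def _wrap_lon(lon, resolution):
    # keep ids in [-180, 180) so the grid closes at the antimeridian
    span = 360.0
    w = ((lon + 180.0) % span) - 180.0
    if float(resolution).is_integer():
        w = int(round(w))
    return w


def build_lattice(
    dataset,
    resolution: float = 1.0,
    scheme: str = "rook",
    connectivity: str = "largest-component",
    buffer: int = 0,
    earth_radius: float = EARTH_RADIUS_KM,
) -> Lattice:
    """Build the occupied-block lattice for a survey dataset.

    Parameters
    ----------
    dataset : SurveyDataset or iterable of cell ids
        Occupied blocks are those containing at least one route record;
        a raw iterable of (lon, lat) ids is also accepted.
    scheme : {'rook', 'queen'}
        Edge-sharing (default, the literal "common boundary") or
        corner-sharing adjacency.
    connectivity : {'strict', 'largest-component', 'bridge'}
        The intrinsic CAR is undefined on a disconnected graph.  ``strict``
        raises, ``largest-component`` keeps the largest component (warning),
        ``bridge`` adds an edge from every smaller component to its nearest
        cell (centroid great-circle distance) until connected.
    buffer : int
        Number of rings of unoccupied neighbor blocks to add around the
        occupied set (0 = occupied blocks only).
    """
    if isinstance(dataset, SurveyDataset):
        occupied = sorted(set(dataset.cell_ids))
    else:
        occupied = sorted(set(tuple(c) for c in dataset))
    if not occupied:
        raise ValueError("empty dataset: no occupied cells")
    if connectivity not in ("strict", "largest-component", "bridge"):
        raise ValueError(f"unknown connectivity policy {connectivity!r}")

    offsets = _neighbor_offsets(scheme)
    ids = set(occupied)
    for _ in range(buffer):
        ring = set()
        for (lon, lat) in ids:
            for dx, dy in offsets:
                nb = (_wrap_lon(lon + dx * resolution, resolution), lat + dy * resolution)
                if -90 < nb[1] < 90 and nb not in ids:
                    ring.add(nb)
        ids |= ring
    ids = sorted(ids)
    pos = {cid: i for i, cid in enumerate(ids)}

    rows, cols = [], []
    for (lon, lat) in ids:
        i = pos[(lon, lat)]
        for dx, dy in offsets:
            nb = (_wrap_lon(lon + dx * resolution, resolution), lat + dy * resolution)
            j = pos.get(nb)
            if j is not None and j != i:
                rows.append(i)
                cols.append(j)
    W = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(ids), len(ids))
    )
    W.data[:] = 1.0  # collapse duplicate entries from symmetric listing
    W = W.maximum(W.T)

    g = nx.from_scipy_sparse_array(W)
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    cells = [Cell(cid, resolution, earth_radius) for cid in ids]

    if len(comps) > 1 or (len(ids) == 1):
        if len(ids) == 1:
            raise ValueError(
                "lattice has a single cell with no neighbors; the intrinsic "
                "CAR needs n_c >= 1 for every cell"
            )
        if connectivity == "strict":
            named = [[ids[i] for i in sorted(c)] for c in comps]
            raise ValueError(f"adjacency graph is disconnected; components: {named}")
        if connectivity == "largest-component":
            keep = sorted(comps[0])
            dropped = [ids[i] for c in comps[1:] for i in c]
            warnings.warn(
                f"dropping {len(dropped)} cells outside the largest component: "
                f"{dropped}",
                stacklevel=2,
            )
            keep_ids = [ids[i] for i in keep]
            return build_lattice(keep_ids, resolution, scheme, "strict", 0, earth_radius)
        # bridge: connect each smaller component to its nearest outside cell
        W = W.tolil()
        while len(comps) > 1:
            comp = comps[-1]
            others = [i for c in comps[:-1] for i in c]
            best, bd = None, np.inf
            for a in comp:
                for b in others:
                    d = _great_circle_km(cells[a].centroid, cells[b].centroid, earth_radius)
                    if d < bd:
                        best, bd = (a, b), d
            a, b = best
            W[a, b] = 1.0
            W[b, a] = 1.0
            g.add_edge(a, b)
            comps = sorted(nx.connected_components(g), key=len, reverse=True)
        W = W.tocsr()

    return Lattice(cells, W)
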