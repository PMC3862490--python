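"""Geometric-mean population trends from posterior draws.

The abundance index is the expected count of a theoretical route in cell c
at year t, ``n_ct = exp(alpha_t + b_ct + sigma^2/2)`` (lognormal
retransformation over the observer-effect distribution; ``retransform=
'none'`` drops the sigma^2/2 term).  The trend between years a < b is the
geometric mean annual change, reported as a percentage:

    T_c = 100 * ((n_cb / n_ca)^(1/(b-a)) - 1)

computed per retained posterior draw and summarized by the median (or
mean) and a central credible interval.  Because sigma^2 is shared across
years within a draw, the retransformation constant cancels in the ratio:
both retransform settings give identical trends, and differ only in the
reported abundance level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["TrendEstimate", "expected_abundance", "cell_trend", "summarize", "trend_draws"]


@dataclass
class TrendEstimate:
    """A summarized trend: % change per year with a credible interval."""

    target: object
    year_a: int
    year_b: int
    estimate: float  # posterior point estimate, % per year
    lo: float
    hi: float
    level: float = 0.95
    draws: Optional[np.ndarray] = None

    def __post_init__(self):
        if not (self.lo <= self.estimate <= self.hi):
            raise ValueError("point estimate must lie within the interval")


def summarize(draws, level: float = 0.95, point: str = "median"):
    """(point, lower, upper) from a vector of trend draws.

    Empirical percentiles with type-7 (linear) interpolation; the central
    ``level`` interval is the (1-level)/2 and (1+level)/2 percentiles.
    """
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("empty draw vector")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    a = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(x, [a, 100.0 - a])
    pt = float(np.median(x) if point == "median" else np.mean(x))
    pt = min(max(pt, lo), hi)  # mean can fall outside the CI only by fp noise
    return pt, float(lo), float(hi)


def expected_abundance(draws, cell_id, year, retransform: str = "lognormal") -> np.ndarray:
    """Posterior draws of n_ct, the abundance of a theoretical route.

    ``exp(alpha_t + b_ct + sigma^2/2)`` per retained draw;
    ``retransform='none'`` gives ``exp(alpha_t + b_ct)``.
    """
    if retransform not in ("lognormal", "none"):
        raise ValueError(f"unknown retransform {retransform!r}")
    t = draws.year_pos(year)
    c = draws.cell_pos(cell_id)
    alpha = draws.stacked("alpha")[:, t]
    b = draws.stacked("b")[:, c, t]
    extra = draws.stacked("sig2") / 2.0 if retransform == "lognormal" else 0.0
    return np.exp(alpha + b + extra)


def trend_draws(n_a: np.ndarray, n_b: np.ndarray, year_a: int, year_b: int) -> np.ndarray:
    """Per-draw % annual trend between two abundance vectors."""
    if year_a >= year_b:
        raise ValueError("need year_a < year_b")
    n_a = np.asarray(n_a, float)
    n_b = np.asarray(n_b, float)
    if (n_a <= 0).any() or (n_b <= 0).any():
        raise ValueError("abundances must be strictly positive")
    B = (n_b / n_a) ** (1.0 / (year_b - year_a))
    return 100.0 * (B - 1.0)


def cell_trend(
    draws,
    cell_id,
    year_a: int,
    year_b: int,
    level: float = 0.95,
    retransform: str = "lognormal",
    point: str = "median",
    keep_draws: bool = False,
) -> TrendEstimate:
    """Interval-specific geometric-mean trend for one lattice cell."""
    n_a = expected_abundance(draws, cell_id, year_a, retransform)
    n_b = expected_abundance(draws, cell_id, year_b, retransform)
    td = trend_draws(n_a, n_b, year_a, year_b)
    pt, lo, hi = summarize(td, level=level, point=point)
    return TrendEstimate(
        target=tuple(cell_id),
        year_a=int(year_a),
        year_b=int(year_b),
        estimate=pt,
        lo=lo,
        hi=hi,
        level=level,
        draws=td if keep_draws else None,
    )


def trend_table(draws, intervals, level: float = 0.95, retransform: str = "lognormal",
                point: str = "median"):
    """Per-cell trends for a list of (year_a, year_b) intervals as a DataFrame."""
    import pandas as pd

    rows = []
    for (a, b) in intervals:
        for cid in draws.cell_ids:
            est = cell_trend(draws, cid, a, b, level=level,
                             retransform=retransform, point=point)
            rows.append(
                {
                    "target": f"{cid[0]},{cid[1]}",
                    "year_a": a,
                    "year_b": b,
                    "median": est.estimate,
                    "lo95": est.lo,
                    "hi95": est.hi,
                }
            )
    return pd.DataFrame(rows)


def cells_geojson(draws, year_a: int, year_b: int, level: float = 0.95) -> dict:
    """Per-cell trends as a GeoJSON FeatureCollection of cell polygons."""
    feats = []
    for cell in draws.lattice.cells:
        est = cell_trend(draws, cell.id, year_a, year_b, level=level)
        long1, lat1, long2, lat2 = cell.bbox
        ring = [
            [long1, lat2], [long2, lat2], [long2, lat1], [long1, lat1], [long1, lat2]
        ]
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "cell_lon": cell.id[0],
                    "cell_lat": cell.id[1],
                    "trend": est.estimate,
                    "lo95": est.lo,
                    "hi95": est.hi,
                    "year_a": year_a,
                    "year_b": year_b,
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}
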