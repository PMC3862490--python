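"""Run configuration, counts reading and the fit -> trend -> region pipeline."""

from __future__ import annotations

import json
import logging
import time
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .lattice import SurveyDataset, build_lattice
from .model import CARTrendModel, ModelConfig
from .poststrat import build_region_weights, region_trend, region_weights_from_frame
from .trend import trend_table

log = logging.getLogger("cartrend")

__all__ = ["RunConfig", "read_counts", "run_pipeline", "load_regions"]


def read_counts(path, resolution: float = 1.0,
                observer_mode: str = "observer-route") -> SurveyDataset:
    """Read and validate a counts CSV (``route_id,observer_id,year,count,
    start_lon,start_lat``); logs a dataset inventory."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface the parser's message
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    missing = [c for c in SurveyDataset.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    neg = df.index[pd.to_numeric(df["count"], errors="coerce") < 0]
    if len(neg):
        # +2: header line and 1-based numbering
        raise ValueError(f"{path}: negative count at line {int(neg[0]) + 2}")
    try:
        ds = SurveyDataset(df, resolution=resolution, observer_mode=observer_mode)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    s = ds.summary()
    log.info(
        "%s: %s records; %s routes, distributed among %s cells, %s detections, "
        "years %s-%s, %s observers",
        path.name, s["records"], s["routes"], s["cells"], s["detections"],
        s["years"][0], s["years"][1], s["observers"],
    )
    return ds


def load_regions(path):
    """Region geometries from a GeoJSON file: list of (id, geometry)."""
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    out = []
    for i, f in enumerate(feats):
        props = f.get("properties") or {}
        rid = props.get("id") or props.get("name") or f.get("id") or f"region{i}"
        out.append((rid, shape(f["geometry"] if "geometry" in f else f)))
    return out


@dataclass
class RunConfig:
    """Single-file (TOML) pipeline configuration; flags override fields."""

    counts: str
    out_dir: str = "cartrend_run"
    regions: Optional[str] = None  # GeoJSON path
    region_weights: Optional[str] = None  # precomputed CSV path
    intervals: list = field(default_factory=list)  # [(year_a, year_b), ...]
    resolution: float = 1.0
    scheme: str = "rook"
    connectivity: str = "largest-component"
    buffer: int = 0
    level: float = 0.95
    seed: Optional[int] = None
    model: dict = field(default_factory=dict)  # ModelConfig overrides

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.intervals = [tuple(map(int, ab)) for ab in cfg.intervals]
        return cfg

    def validate(self):
        if not Path(self.counts).exists():
            raise ValueError(f"counts file not found: {self.counts}")
        for p in (self.regions, self.region_weights):
            if p is not None and not Path(p).exists():
                raise ValueError(f"file not found: {p}")
        for a, b in self.intervals:
            if a >= b:
                raise ValueError(f"invalid interval ({a}, {b}): need a < b")


def run_pipeline(config: RunConfig) -> dict:
    """fit -> cell trends -> region trends; writes all artifacts.

    Returns a manifest dict (also written as JSON) with per-stage timings,
    acceptance rates and convergence diagnostics.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"stages": {}, "seed": config.seed}
    t0 = time.perf_counter()

    ds = read_counts(config.counts, resolution=config.resolution,
                     observer_mode=config.model.get("observer_mode", "observer-route"))
    manifest["dataset"] = ds.summary()
    yr0, yr1 = ds.year_min, ds.year_max
    for a, b in config.intervals:
        if not (yr0 <= a < b <= yr1):
            raise ValueError(
                f"interval ({a}, {b}) outside data year range {yr0}-{yr1}"
            )
    intervals = config.intervals or [(yr0, yr1)]
    manifest["stages"]["read"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    model = CARTrendModel(
        resolution=config.resolution,
        scheme=config.scheme,
        connectivity=config.connectivity,
        buffer=config.buffer,
        random_state=config.seed,
        **config.model,
    )
    model.fit(ds)
    draws = model.draws_
    manifest["stages"]["fit"] = time.perf_counter() - t1
    manifest["acceptance"] = model.acceptance_
    manifest["rhat"] = model.rhat_
    manifest["n_keep_total"] = int(draws.n_draws)
    manifest["n_keep_per_chain"] = int(draws.alpha.shape[1])
    manifest["model_config"] = {
        k: v for k, v in vars(model._config()).items() if not k.startswith("_")
    }

    cells_df, edges_df = model.lattice_.to_frames()
    cells_df.to_csv(out / "lattice_cells.csv", index=False)
    edges_df.to_csv(out / "lattice_edges.csv", index=False)
    draws.to_frame().to_csv(out / "posterior_draws.csv", index=False)

    t2 = time.perf_counter()
    ct = trend_table(draws, intervals, level=config.level)
    ct.to_csv(out / "cell_trends.csv", index=False)
    manifest["stages"]["trend"] = time.perf_counter() - t2

    t3 = time.perf_counter()
    rrows = []
    specs = []
    if config.regions:
        for rid, geom in load_regions(config.regions):
            specs.append(build_region_weights(geom, model.lattice_, region_id=rid))
    elif config.region_weights:
        specs = region_weights_from_frame(
            pd.read_csv(config.region_weights), model.lattice_
        )
    for spec in specs:
        for a, b in intervals:
            est = region_trend(draws, spec, a, b, level=config.level)
            rrows.append(
                {"target": spec.region_id, "year_a": a, "year_b": b,
                 "median": est.estimate, "lo95": est.lo, "hi95": est.hi}
            )
    pd.DataFrame(
        rrows, columns=["target", "year_a", "year_b", "median", "lo95", "hi95"]
    ).to_csv(out / "region_trends.csv", index=False)
    manifest["stages"]["regions"] = time.perf_counter() - t3
    manifest["stages"]["total"] = time.perf_counter() - t0

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("pipeline complete: %s", out)
    return manifest
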