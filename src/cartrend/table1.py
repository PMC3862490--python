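"""Published BCR trend comparison table and its summary statistics.

Ships the printed 1999-2009 BCR-level trend table for three focal species
(Carolina wren, cerulean warbler, red-bellied woodpecker) under the spatial
CAR model and the nonspatial hierarchical route-regression analysis, and
computes the comparison statistics: counts of significant trends, the
spread of credible-interval lengths, and the average precision gain of the
spatial approach.

All statistics operate on the printed (rounded) values — the only ones
available.  One deliberate convention: a printed interval bound exactly
equal to 0 is treated as excluding 0 (flag ``zero_bound_excludes``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "TrendTable",
    "load_table1",
    "count_significant",
    "ci_length_sd",
    "precision_gain",
    "compare_ci_lengths",
]

METHODS = ("car", "nonspatial")
SPECIES = ("carolina_wren", "cerulean_warbler", "red_bellied_woodpecker")


@dataclass
class TrendTable:
    """Printed trend table: one row per (BCR, species, method).

    ``df`` keeps the printed strings (for digit-exact round-tripping) in
    ``estimate``, ``lo``, ``hi`` and adds float views ``estimate_f``,
    ``lo_f``, ``hi_f`` and the CI length.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.copy()
        for col in ("estimate", "lo", "hi"):
            df[col] = df[col].astype(str)
            df[f"{col}_f"] = df[col].astype(float)
        df["ci_length"] = df["hi_f"] - df["lo_f"]
        bad = ~((df["lo_f"] <= df["estimate_f"]) & (df["estimate_f"] <= df["hi_f"]))
        if bad.any():
            raise ValueError(f"estimate outside its CI in rows {list(df.index[bad])}")
        combos = df.groupby("method").apply(
            lambda g: frozenset(zip(g["bcr"], g["species"])), include_groups=False
        )
        if len(set(combos)) > 1:
            raise ValueError("methods cover different (BCR, species) sets")
        self.df = df

    def __len__(self):
        return len(self.df)

    def rows(self, method: str, species: str = "all") -> pd.DataFrame:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
        sel = self.df[self.df["method"] == method]
        if species != "all":
            if species not in set(self.df["species"]):
                raise ValueError(f"species {species!r} not in table")
            sel = sel[sel["species"] == species]
        return sel

    def to_csv(self, path) -> None:
        """Round-trip serialization: printed strings, digit for digit."""
        self.df[["bcr", "species", "method", "estimate", "lo", "hi"]].to_csv(
            path, index=False
        )


def load_table1(path=None) -> TrendTable:
    """Load the shipped fixture (or a table in the same CSV dialect)."""
    if path is None:
        ref = resources.files("cartrend").joinpath("data/table1.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    return TrendTable(df)


def count_significant(table: TrendTable, method: str,
                      zero_bound_excludes: bool = True) -> int:
    """Rows whose 95% CI excludes 0 (printed 0 bounds exclude by default)."""
    d = table.rows(method)
    if zero_bound_excludes:
        sig = (d["lo_f"] >= 0) | (d["hi_f"] <= 0)
    else:
        sig = (d["lo_f"] > 0) | (d["hi_f"] < 0)
    return int(sig.sum())


def ci_length_sd(table: TrendTable, method: str, decimals: int = 2) -> float:
    """Sample SD (n-1) of the method's CI lengths, rounded for reporting."""
    d = table.rows(method)
    if len(d) < 2:
        raise ValueError("need at least 2 rows to compute an SD")
    return round(float(d["ci_length"].std(ddof=1)), decimals)


def precision_gain(table: TrendTable, species: str = "all") -> int:
    """Average CI shortening of the spatial model, % (nearest integer).

    ``100 * (1 - mean CAR length / mean nonspatial length)`` over the
    selected rows; positive when the spatial intervals are shorter.
    """
    car = table.rows("car", species)["ci_length"]
    ns = table.rows("nonspatial", species)["ci_length"]
    if len(car) == 0 or len(ns) == 0:
        raise ValueError(f"no rows for species {species!r}")
    return int(round(100.0 * (1.0 - car.mean() / ns.mean())))


def compare_ci_lengths(table: TrendTable, atol: float = 1e-9) -> tuple:
    """(rows where the nonspatial CI is strictly shorter, ties).

    Computed from printed bounds; ties are equal lengths at printed
    precision.
    """
    p = table.df.pivot_table(
        index=["bcr", "species"], columns="method", values="ci_length"
    )
    if p.isna().any().any():
        raise ValueError("mismatched (BCR, species) sets between methods")
    diff = p["nonspatial"] - p["car"]
    ties = int((np.abs(diff) <= atol).sum())
    smaller = int((diff < -atol).sum())
    return smaller, ties


def summary(table: TrendTable) -> dict:
    """All comparison statistics in one mapping (as printed/rounded)."""
    smaller, ties = compare_ci_lengths(table)
    return {
        "n_comparisons": len(table) // 2,
        "significant_car": count_significant(table, "car"),
        "significant_nonspatial": count_significant(table, "nonspatial"),
        "ci_length_sd_car": ci_length_sd(table, "car"),
        "ci_length_sd_nonspatial": ci_length_sd(table, "nonspatial"),
        "precision_gain_overall_pct": precision_gain(table, "all"),
        "precision_gain_carolina_wren_pct": precision_gain(table, "carolina_wren"),
        "precision_gain_cerulean_warbler_pct": precision_gain(table, "cerulean_warbler"),
        "precision_gain_red_bellied_woodpecker_pct": precision_gain(
            table, "red_bellied_woodpecker"
        ),
        "nonspatial_ci_shorter": smaller,
        "ci_length_ties": ties,
    }
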