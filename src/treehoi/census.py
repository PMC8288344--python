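"""Stem-mapped census tables: reading, validation, grouping, focal eligibility.

A census is one row per free-standing stem alive at the first census:
``id, species, x, y, dbh0, alive1, dbh1``.  Coordinates are continuous metres
from the plot corner; DBH is diameter at breast height in cm with a 1-cm
census floor; ``alive1`` is the stem's status at the second census and
``dbh1`` its DBH then (empty if dead).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("treehoi")

REQUIRED_COLUMNS = ["id", "species", "x", "y", "dbh0", "alive1", "dbh1"]
DBH_FLOOR_CM = 1.0


class CensusFormatError(ValueError):
    """The file does not have the expected tabular shape."""


class CensusValidationError(ValueError):
    """One or more rows violate census invariants; ``report`` lists them."""

    def __init__(self, message: str, report: pd.DataFrame | None = None):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class Tree:
    """One stem: identity, location (m), group label, size (cm) and fate."""

    id: str
    species: str
    x: float
    y: float
    dbh0: float
    alive1: int
    dbh1: float | None = None
    group: str | None = None


@dataclass
class CensusPlot:
    """A validated census: a tree table plus rectangular plot bounds.

    ``trees`` always carries the REQUIRED_COLUMNS; a ``group`` column is
    added by :func:`assign_groups`.
    """

    trees: pd.DataFrame
    bounds: tuple[float, float, float, float]  # (xmin, xmax, ymin, ymax)

    def __post_init__(self):
        self.trees = self.trees.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.trees)

    @property
    def groups(self) -> list[str]:
        if "group" not in self.trees.columns:
            raise ValueError("groups not assigned; call assign_groups first")
        return sorted(self.trees["group"].unique())

    def tree(self, tree_id) -> Tree:
        row = self.trees.loc[self.trees["id"] == tree_id]
        if row.empty:
            raise KeyError(f"no tree with id {tree_id!r}")
        r = row.iloc[0]
        dbh1 = r["dbh1"]
        return Tree(
            id=r["id"], species=r["species"], x=float(r["x"]), y=float(r["y"]),
            dbh0=float(r["dbh0"]), alive1=int(r["alive1"]),
            dbh1=None if pd.isna(dbh1) else float(dbh1),
            group=r.get("group"),
        )


@dataclass(frozen=True)
class GroupingScheme:
    """How neighbours are pooled: by species identity or by a DBH size cut.

    ``by_size_threshold`` labels a stem "large" iff dbh0 > threshold and
    "small" iff dbh0 <= threshold (the threshold itself is small).
    """

    mode: str = "by_species"
    threshold: float | None = None

    def __post_init__(self):
        if self.mode not in ("by_species", "by_size_threshold"):
            raise ValueError(f"unknown grouping mode {self.mode!r}")
        if self.mode == "by_size_threshold":
            if self.threshold is None or self.threshold <= 0:
                raise ValueError("by_size_threshold requires threshold > 0")


def _validate_rows(df: pd.DataFrame, bounds) -> pd.DataFrame:
    """Return a per-row violation report (empty if all rows valid)."""
    xmin, xmax, ymin, ymax = bounds
    problems: list[dict] = []

    dup = df["id"].duplicated(keep=False)
    for i in df.index[dup]:
        problems.append({"row": i, "id": df.at[i, "id"],
                         "reason": f"duplicate id {df.at[i, 'id']!r}"})
    low = df["dbh0"] < DBH_FLOOR_CM
    for i in df.index[low & df["dbh0"].notna()]:
        problems.append({"row": i, "id": df.at[i, "id"],
                         "reason": f"dbh0 = {df.at[i, 'dbh0']} below the "
                                   f"{DBH_FLOOR_CM:g}-cm census floor"})
    for col in ("x", "y", "dbh0"):
        for i in df.index[df[col].isna()]:
            problems.append({"row": i, "id": df.at[i, "id"],
                             "reason": f"missing {col}"})
    oob = (df["x"] < xmin) | (df["x"] > xmax) | (df["y"] < ymin) | (df["y"] > ymax)
    for i in df.index[oob.fillna(False)]:
        problems.append({"row": i, "id": df.at[i, "id"],
                         "reason": "coordinates outside plot bounds"})
    bad_status = ~df["alive1"].isin([0, 1])
    for i in df.index[bad_status]:
        problems.append({"row": i, "id": df.at[i, "id"],
                         "reason": f"alive1 = {df.at[i, 'alive1']!r} not in {{0, 1}}"})
    # dbh1 only meaningful for survivors
    ghost = (df["alive1"] == 0) & df["dbh1"].notna()
    for i in df.index[ghost]:
        problems.append({"row": i, "id": df.at[i, "id"],
                         "reason": "dbh1 present but alive1 = 0"})
    return pd.DataFrame(problems, columns=["row", "id", "reason"])


def read_census(path, bounds, strict: bool = True) -> CensusPlot:
    """Read and validate a delimited census table.

    Parameters
    ----------
    path
        CSV/TSV file (delimiter sniffed from the header line) with columns
        ``id, species, x, y, dbh0, alive1, dbh1``; dead stems leave ``dbh1``
        empty.
    bounds
        ``(xmin, xmax, ymin, ymax)`` in metres.
    strict
        If True (default), any invalid row raises
        :class:`CensusValidationError` whose ``report`` attribute names each
        offending row and the rule it breaks.  If False, offending rows are
        dropped; the report is attached to the returned plot as
        ``plot.validation_report``.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "species": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CensusFormatError(f"missing required column(s): {', '.join(missing)}")
    df = df[REQUIRED_COLUMNS].copy()

    report = _validate_rows(df, bounds)
    if not report.empty:
        if strict:
            lines = "; ".join(f"row {r.row} (id {r.id!r}): {r.reason}"
                              for r in report.itertuples())
            raise CensusValidationError(
                f"{len(report)} invalid row(s): {lines}", report=report)
        logger.warning("dropping %d invalid row(s)", report["row"].nunique())
        df = df.drop(index=report["row"].unique())

    plot = CensusPlot(trees=df, bounds=tuple(float(b) for b in bounds))
    plot.validation_report = report  # type: ignore[attr-defined]
    return plot


def write_census(plot: CensusPlot, path, sep: str = ",") -> None:
    """Write a census table in the dialect :func:`read_census` reads."""
    out = plot.trees[REQUIRED_COLUMNS].copy()
    out.to_csv(path, sep=sep, index=False)


def assign_groups(plot: CensusPlot, scheme: GroupingScheme) -> CensusPlot:
    """Return a copy of ``plot`` with a ``group`` label on every tree."""
    trees = plot.trees.copy()
    if scheme.mode == "by_species":
        trees["group"] = trees["species"].astype(str)
    elif scheme.mode == "by_size_threshold":
        trees["group"] = np.where(trees["dbh0"] > scheme.threshold, "large", "small")
    else:  # pragma: no cover - guarded by GroupingScheme
        raise ValueError(f"unknown grouping mode {scheme.mode!r}")
    return CensusPlot(trees=trees, bounds=plot.bounds)


def eligible_focals(plot: CensusPlot, R: float) -> set:
    """Ids of trees at least 2R inside every plot edge (focal-eligible).

    The exclusion is strict (a tree exactly at 2R from an edge is eligible):
    focals need their neighbours' neighbours, up to 2R away, fully observed.
    Ineligible trees remain available as neighbours.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    xmin, xmax, ymin, ymax = plot.bounds
    if 4 * R >= (xmax - xmin) or 4 * R >= (ymax - ymin):
        raise ValueError(
            f"no interior region: 4R = {4 * R:g} m does not fit inside the "
            f"{xmax - xmin:g} x {ymax - ymin:g} m plot")
    t = plot.trees
    ok = ((t["x"] >= xmin + 2 * R) & (t["x"] <= xmax - 2 * R)
          & (t["y"] >= ymin + 2 * R) & (t["y"] <= ymax - 2 * R))
    return set(t.loc[ok, "id"])


def load_config(path) -> dict:
    """Load a YAML config holding plot bounds and a grouping scheme."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    out: dict = {}
    if "bounds" in cfg:
        out["bounds"] = tuple(float(v) for v in cfg["bounds"])
    if "grouping" in cfg:
        g = cfg["grouping"]
        out["grouping"] = GroupingScheme(mode=g["mode"],
                                         threshold=g.get("threshold"))
    return out
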