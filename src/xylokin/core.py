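"""Domain types, CSV readers/writers and validation shared by all stages.

The time axis used throughout is the *season day*: days since January 1 of
the season's start year, running past 365 when a growing season crosses the
calendar boundary (a Mediterranean season monitored from February to the
following March spans roughly days 60-430 on this axis).  Counts are recorded
as integers per radial file; every downstream computation works on fractional
per-tree means over the radial files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellCountObservation",
    "TracheidRecord",
    "SeasonConfig",
    "SchemaError",
    "ValidationError",
    "read_counts",
    "write_counts",
    "counts_to_frame",
    "read_tracheids",
    "write_tracheids",
    "tracheids_to_frame",
    "average_radial_files",
    "PHASES",
]

#: canonical differentiation phases, in developmental order
PHASES = ("cambial", "enlarging", "thickening", "mature")

COUNT_COLUMNS = [
    "tree_id",
    "group",
    "season_day",
    "radial_file",
    "n_cambial",
    "n_enlarging",
    "n_thickening",
    "n_mature",
]

TRACHEID_COLUMNS = [
    "tree_id",
    "group",
    "radial_file",
    "cell_index",
    "lumen_diameter",
    "wall_thickness",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """An input row violates a domain invariant."""


@dataclass(frozen=True)
class CellCountObservation:
    """One microcore census record: cells per differentiation phase.

    ``n_cambial`` (#C), ``n_enlarging`` (#E), ``n_thickening`` (#L) and
    ``n_mature`` (#M) are the cells counted along one radial file on one
    sampling day.
    """

    tree_id: str
    group: str
    season_day: int
    radial_file: int
    n_cambial: float
    n_enlarging: float
    n_thickening: float
    n_mature: float

    def __post_init__(self) -> None:
        if self.season_day <= 0:
            raise ValidationError(
                f"season_day must be positive, got {self.season_day}"
            )
        for name in ("n_cambial", "n_enlarging", "n_thickening", "n_mature"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class TracheidRecord:
    """One tracheid measured in the final ring.

    ``lumen_diameter`` (LD) and ``wall_thickness`` (CWT, a single radial
    wall) are in micrometres; the radial cell diameter is LD + 2 CWT.
    """

    tree_id: str
    group: str
    radial_file: int
    cell_index: int
    lumen_diameter: float
    wall_thickness: float

    def __post_init__(self) -> None:
        if self.cell_index < 1:
            raise ValidationError(f"cell_index must be >= 1, got {self.cell_index}")
        if self.lumen_diameter <= 0:
            raise ValidationError(
                f"lumen_diameter must be > 0, got {self.lumen_diameter}"
            )
        if self.wall_thickness <= 0:
            raise ValidationError(
                f"wall_thickness must be > 0, got {self.wall_thickness}"
            )

    @property
    def radial_diameter(self) -> float:
        """Radial cell diameter in µm: lumen plus the two radial walls."""
        return self.lumen_diameter + 2.0 * self.wall_thickness


@dataclass(frozen=True)
class SeasonConfig:
    """Season-wide conventions: start year, prediction grid step, CI level."""

    start_year: int = 2017
    grid_step: float = 1.0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.grid_step <= 0:
            raise ValidationError(f"grid_step must be > 0, got {self.grid_step}")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )


def read_counts(path) -> list[CellCountObservation]:
    """Read a cell-count CSV into validated observations.

    The table must have one row per tree x sampling day x radial file with
    the columns ``tree_id, group, season_day, radial_file, n_cambial,
    n_enlarging, n_thickening, n_mature``.  Raises :class:`SchemaError` for a
    missing column, :class:`ValidationError` (with the offending row number)
    for a negative count or a duplicated (tree, day, file) key.
    """
    df = pd.read_csv(path)
    _require_columns(df, COUNT_COLUMNS, path)
    obs: list[CellCountObservation] = []
    seen: set[tuple] = set()
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        key = (str(row.tree_id), int(row.season_day), int(row.radial_file))
        if key in seen:
            raise ValidationError(
                f"{path}: duplicate (tree_id, season_day, radial_file) "
                f"{key} at row {pos}"
            )
        seen.add(key)
        try:
            obs.append(
                CellCountObservation(
                    tree_id=str(row.tree_id),
                    group=str(row.group),
                    season_day=int(row.season_day),
                    radial_file=int(row.radial_file),
                    n_cambial=float(row.n_cambial),
                    n_enlarging=float(row.n_enlarging),
                    n_thickening=float(row.n_thickening),
                    n_mature=float(row.n_mature),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {pos}: {exc}") from exc
    return obs


def counts_to_frame(obs: Iterable[CellCountObservation]) -> pd.DataFrame:
    """Tidy DataFrame view of count observations (column order fixed)."""
    rows = [
        (
            o.tree_id,
            o.group,
            o.season_day,
            o.radial_file,
            o.n_cambial,
            o.n_enlarging,
            o.n_thickening,
            o.n_mature,
        )
        for o in obs
    ]
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def write_counts(obs: Iterable[CellCountObservation], path) -> None:
    """Write observations as the canonical comma-separated UTF-8 table."""
    counts_to_frame(obs).to_csv(path, index=False)


def read_tracheids(path) -> list[TracheidRecord]:
    """Read a tracheid anatomy CSV (ordered pith-to-bark within each file).

    Enforces that ``cell_index`` is contiguous from 1 within each
    (tree, radial_file) series.
    """
    df = pd.read_csv(path)
    _require_columns(df, TRACHEID_COLUMNS, path)
    records: list[TracheidRecord] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                TracheidRecord(
                    tree_id=str(row.tree_id),
                    group=str(row.group),
                    radial_file=int(row.radial_file),
                    cell_index=int(row.cell_index),
                    lumen_diameter=float(row.lumen_diameter),
                    wall_thickness=float(row.wall_thickness),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {pos}: {exc}") from exc
    frame = tracheids_to_frame(records)
    for (tree, rfile), sub in frame.groupby(["tree_id", "radial_file"]):
        idx = np.sort(sub["cell_index"].to_numpy())
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise ValidationError(
                f"{path}: cell_index not contiguous from 1 for tree "
                f"{tree!r} radial file {rfile}"
            )
    return records


def tracheids_to_frame(records: Iterable[TracheidRecord]) -> pd.DataFrame:
    rows = [
        (
            r.tree_id,
            r.group,
            r.radial_file,
            r.cell_index,
            r.lumen_diameter,
            r.wall_thickness,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=TRACHEID_COLUMNS)


def write_tracheids(records: Iterable[TracheidRecord], path) -> None:
    tracheids_to_frame(records).to_csv(path, index=False)


def average_radial_files(obs: Iterable[CellCountObservation]) -> pd.DataFrame:
    """Collapse radial files to per-tree per-day mean counts.

    Counting runs along (up to) three radial files per microcore; analysis
    uses their arithmetic mean, so fractional cell numbers are expected.
    Returns a tidy DataFrame with columns ``tree_id, group, season_day,
    n_cambial, n_enlarging, n_thickening, n_mature``, one row per
    (tree, day).  Empty input yields an empty frame.
    """
    df = counts_to_frame(obs)
    if df.empty:
        return df.drop(columns=["radial_file"])
    out = (
        df.groupby(["tree_id", "group", "season_day"], as_index=False)[
            ["n_cambial", "n_enlarging", "n_thickening", "n_mature"]
        ]
        .mean()
        .sort_values(["group", "tree_id", "season_day"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out
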