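"""Differentiation kinetics: from phase-count curves to per-cell timings.

A census at time ``t`` sees a cell in the enlargement phase while
``t_enl <= t < t_thick``, wall thickening while ``t_thick <= t < t_mature``
and mature afterwards.  Counts therefore satisfy, at the level of (smoothed)
means::

    C_E(t) = E(t) + L(t) + M(t)    cells having entered enlargement
    C_L(t) =        L(t) + M(t)    cells having entered wall thickening
    C_M(t) =               M(t)    cells having matured

Each cumulative curve is clipped at zero and monotonized by running maximum;
the date cell ``i`` enters a phase is the first time the curve crosses level
``i`` (linear interpolation between grid points).  Residence durations are
``d_E = t_thick - t_enl`` (enlargement) and ``d_T = t_mature - t_thick``
(wall deposition); attaching a group-mean tracheidogram yields per-cell
rates ``r_enl = LD / d_E`` and ``r_wall = CWT / d_T`` in µm/day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .smoothing import FittedPhaseCurve

__all__ = [
    "CumulativeEntryCurve",
    "CellKinetics",
    "RateCurve",
    "cumulative_entry_curves",
    "entrance_date",
    "cell_kinetics",
    "production_rate_curves",
    "conservation_diagnostic",
    "invert_observed_counts",
    "kinetics_to_frame",
    "rates_to_frame",
]

ENTRY_PHASES = ("enlarging", "thickening", "mature")


@dataclass(frozen=True)
class CumulativeEntryCurve:
    """Monotone cumulative number of cells having entered a phase."""

    phase: str
    grid: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.value, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("cumulative values must be finite")
        if np.any(v < 0):
            raise ValueError("cumulative values must be >= 0")
        if np.any(np.diff(v) < -1e-12):
            raise ValueError("cumulative values must be non-decreasing")


@dataclass(frozen=True)
class CellKinetics:
    """Timings and rates for one cell, in formation order.

    Missing stages (a cell never observed to mature) carry NaN.
    """

    cell_index: int
    t_enl: float
    t_thick: float
    t_mature: float
    d_E: float
    d_T: float
    r_enl: float = float("nan")
    r_wall: float = float("nan")


@dataclass(frozen=True)
class RateCurve:
    """Cells/day entering a compartment; kind in {rC, rE, rL, rM}."""

    kind: str
    grid: np.ndarray
    rate: np.ndarray


def _clip_monotonize(values: np.ndarray) -> np.ndarray:
    return np.maximum.accumulate(np.maximum(np.asarray(values, dtype=float), 0.0))


def cumulative_entry_curves(curves: dict) -> dict:
    """Build C_E, C_L, C_M from the four fitted phase curves of one group.

    ``curves`` maps phase name -> :class:`FittedPhaseCurve`; all on one
    grid.  Returns phase -> :class:`CumulativeEntryCurve` for the three
    entry phases.
    """
    needed = ("enlarging", "thickening", "mature")
    grids = [np.asarray(curves[p].grid, dtype=float) for p in needed]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise ValueError("phase curves must share one grid")
    grid = grids[0]
    E = np.maximum(np.asarray(curves["enlarging"].mean, dtype=float), 0.0)
    L = np.maximum(np.asarray(curves["thickening"].mean, dtype=float), 0.0)
    M = np.maximum(np.asarray(curves["mature"].mean, dtype=float), 0.0)
    raw = {"enlarging": E + L + M, "thickening": L + M, "mature": M}
    return {
        phase: CumulativeEntryCurve(
            phase=phase, grid=grid, value=_clip_monotonize(raw[phase])
        )
        for phase in needed
    }


def entrance_date(c: CumulativeEntryCurve, i: float) -> float:
    """First time the cumulative curve crosses level ``i``.

    Linear interpolation between the bracketing grid points; if the curve
    already starts at or above ``i`` the first grid time is returned, and
    NaN signals a cell that never reaches the phase.
    """
    v = np.asarray(c.value, dtype=float)
    grid = np.asarray(c.grid, dtype=float)
    if i > v[-1]:
        return float("nan")
    if v[0] >= i:
        return float(grid[0])
    k = int(np.searchsorted(v, i, side="left"))  # first index with v[k] >= i
    t0, t1 = grid[k - 1], grid[k]
    v0, v1 = v[k - 1], v[k]
    if v1 == v0:
        return float(t1)
    return float(t0 + (i - v0) / (v1 - v0) * (t1 - t0))


def cell_kinetics(
    cums: dict,
    anatomy: pd.DataFrame | None = None,
) -> list[CellKinetics]:
    """Per-cell entrance dates, residence durations, and (optionally) rates.

    ``cums`` maps the three entry phases to their cumulative curves (same
    group).  ``anatomy`` is an optional group-mean tracheidogram-like frame
    with columns ``lumen_diameter`` and ``wall_thickness`` ordered from ring
    start; it is resampled to the recovered cell count so cell ``i`` is
    matched to the i-th tracheid of the group profile.
    """
    c_e = cums["enlarging"]
    c_l = cums["thickening"]
    c_m = cums["mature"]
    n_cells = int(math.floor(np.max(c_e.value) + 1e-9))
    ld = cwt = None
    if anatomy is not None and len(anatomy) > 0 and n_cells > 0:
        ld = _resample_profile(
            np.asarray(anatomy["lumen_diameter"], dtype=float), n_cells
        )
        cwt = _resample_profile(
            np.asarray(anatomy["wall_thickness"], dtype=float), n_cells
        )
    out: list[CellKinetics] = []
    for i in range(1, n_cells + 1):
        t_enl = entrance_date(c_e, i)
        t_thick = entrance_date(c_l, i)
        t_mature = entrance_date(c_m, i)
        d_e = t_thick - t_enl
        d_t = t_mature - t_thick
        r_enl = r_wall = float("nan")
        if ld is not None:
            if d_e > 0:
                r_enl = ld[i - 1] / d_e
            if d_t > 0:
                r_wall = cwt[i - 1] / d_t
        out.append(
            CellKinetics(
                cell_index=i,
                t_enl=t_enl,
                t_thick=t_thick,
                t_mature=t_mature,
                d_E=d_e,
                d_T=d_t,
                r_enl=r_enl,
                r_wall=r_wall,
            )
        )
    return out


def _resample_profile(values: np.ndarray, n: int) -> np.ndarray:
    """Resample an ordered per-cell trait series to ``n`` cells by linear
    interpolation on the cell-order quantile."""
    m = values.size
    if m == 0:
        return np.full(n, np.nan)
    if m == 1:
        return np.full(n, values[0])
    q_src = (np.arange(m) + 0.5) / m
    q_dst = (np.arange(n) + 0.5) / n
    return np.interp(q_dst, q_src, values)


def production_rate_curves(
    cums: dict,
    cambial: FittedPhaseCurve | None = None,
    *,
    rc_mode: str = "export_plus_pool",
) -> dict:
    """Entry-rate curves rE, rL, rM and the cambial production rate rC.

    Rates are centered finite differences of the monotonized cumulative
    curves, floored at zero.  ``rC`` counts cells produced by the cambium:
    cells exported to enlargement plus net growth of the cambial pool above
    its season-start size (``rc_mode='export_plus_pool'``), or simply
    ``dC_E/dt`` (``rc_mode='export_only'``).
    """
    first = next(iter(cums.values()))
    grid = np.asarray(first.grid, dtype=float)
    if grid.size < 3:
        raise ValueError("grid must have at least 3 points for derivatives")
    kinds = {"enlarging": "rE", "thickening": "rL", "mature": "rM"}
    out: dict = {}
    for phase, kind in kinds.items():
        v = np.asarray(cums[phase].value, dtype=float)
        out[kind] = RateCurve(
            kind=kind, grid=grid, rate=np.maximum(np.gradient(v, grid), 0.0)
        )
    base = np.asarray(cums["enlarging"].value, dtype=float).copy()
    if rc_mode == "export_plus_pool":
        if cambial is not None:
            nc = np.maximum(np.asarray(cambial.mean, dtype=float), 0.0)
            base = base + np.maximum(nc - nc[0], 0.0)
    elif rc_mode != "export_only":
        raise ValueError(f"unknown rc_mode {rc_mode!r}")
    out["rC"] = RateCurve(
        kind="rC", grid=grid, rate=np.maximum(np.gradient(base, grid), 0.0)
    )
    return out


def conservation_diagnostic(cums: dict, enlarging: FittedPhaseCurve) -> float:
    """Max abs discrepancy between C_E - C_L and the clipped enlarging count.

    Exactly zero wherever no clipping/monotonization fired; reported as a
    pipeline diagnostic.
    """
    diff = np.asarray(cums["enlarging"].value) - np.asarray(cums["thickening"].value)
    e_clip = np.maximum(np.asarray(enlarging.mean, dtype=float), 0.0)
    return float(np.max(np.abs(diff - e_clip)))


def invert_observed_counts(
    mean_counts: pd.DataFrame,
    *,
    censoring: str = "midpoint",
) -> dict:
    """Fit-free inversion: cumulative entry curves straight from counts.

    Builds C_E, C_L, C_M for one tree (or one group-mean series) directly
    from per-day mean counts, bypassing the smoother — the oracle path used
    to validate the inversion itself.  Census counts are interval-censored:
    a census at day ``t`` reports entries that happened since the previous
    visit, so with ``censoring='midpoint'`` the count observed at ``t`` is
    attributed to ``t - step/2`` (step = local sampling interval), centering
    the recovery error at half an interval; ``censoring='none'`` keeps the
    nominal sampling times.
    """
    df = mean_counts.sort_values("season_day")
    t = np.asarray(df["season_day"], dtype=float)
    E = np.asarray(df["n_enlarging"], dtype=float)
    L = np.asarray(df["n_thickening"], dtype=float)
    M = np.asarray(df["n_mature"], dtype=float)
    if censoring == "midpoint":
        steps = np.diff(t)
        half = np.concatenate([[steps[0] if steps.size else 0.0], steps]) / 2.0
        t = t - half
    elif censoring != "none":
        raise ValueError(f"unknown censoring {censoring!r}")
    raw = {"enlarging": E + L + M, "thickening": L + M, "mature": M}
    return {
        phase: CumulativeEntryCurve(
            phase=phase, grid=t, value=_clip_monotonize(raw[phase])
        )
        for phase in raw
    }


def kinetics_to_frame(kin: list[CellKinetics], group: str = "") -> pd.DataFrame:
    rows = [
        (group, k.cell_index, k.t_enl, k.t_thick, k.t_mature, k.d_E, k.d_T, k.r_enl, k.r_wall)
        for k in kin
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "cell_index",
            "t_enl",
            "t_thick",
            "t_mature",
            "d_E",
            "d_T",
            "r_enl",
            "r_wall",
        ],
    )


def rates_to_frame(rates: dict, group: str = "") -> pd.DataFrame:
    rows = []
    for kind in ("rC", "rE", "rL", "rM"):
        if kind not in rates:
            continue
        rc = rates[kind]
        for t, r in zip(rc.grid, rc.rate):
            rows.append((group, kind, float(t), float(r)))
    return pd.DataFrame(rows, columns=["group", "kind", "season_day", "rate"])
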