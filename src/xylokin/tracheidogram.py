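"""Tracheidograms: relative-position standardization and group comparison.

A tracheidogram is the ordered profile of tracheid dimensions across one
ring, pith to bark.  Because rings differ in cell number, traits are
standardized to *relative position*: the distance from the ring start to
each tracheid's center divided by the total ring width, which puts every
ring on a common (0, 1) axis.  Standardized profiles are compared between
treatment groups with the same penalized-spline machinery used for the
seasonal count curves (predictor = relative position, random intercept per
tree), and earlywood/latewood are separated by Mork's index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import TracheidRecord, ValidationError
from .smoothing import (
    FittedPhaseCurve,
    SignificanceWindows,
    SmoothConfig,
    compare_groups,
    fit_phase_curve,
)

__all__ = [
    "Tracheidogram",
    "StandardizedProfile",
    "relative_positions",
    "standardize_profile",
    "compare_trait_profiles",
    "earlywood_latewood_split",
    "group_mean_profile",
    "profiles_to_frame",
]


@dataclass(frozen=True)
class Tracheidogram:
    """Ordered tracheids of one radial file with in-ring positions (µm)."""

    tree_id: str
    radial_file: int
    cells: tuple
    ring_width: float
    centers: np.ndarray
    rel_pos: np.ndarray


@dataclass(frozen=True)
class StandardizedProfile:
    """Trait values resampled onto an even relative-position grid."""

    label: str
    rel_grid: np.ndarray
    LD_profile: np.ndarray
    CWT_profile: np.ndarray


def relative_positions(cells: list[TracheidRecord]) -> Tracheidogram:
    """Cumulative cell centers and relative positions for one radial file.

    Cell ``i``'s center sits at the summed diameters of all earlier cells
    plus half its own; dividing by the ring width (sum of all diameters)
    gives positions strictly inside (0, 1).
    """
    if not cells:
        raise ValidationError("tracheidogram requires at least one cell")
    diam = np.array([c.radial_diameter for c in cells], dtype=float)
    if np.any(diam <= 0):
        raise ValidationError("all radial diameters must be positive")
    centers = np.cumsum(diam) - diam / 2.0
    ring_width = float(diam.sum())
    return Tracheidogram(
        tree_id=cells[0].tree_id,
        radial_file=cells[0].radial_file,
        cells=tuple(cells),
        ring_width=ring_width,
        centers=centers,
        rel_pos=centers / ring_width,
    )


def standardize_profile(t: Tracheidogram, n_points: int) -> StandardizedProfile:
    """Interpolate LD and CWT onto ``n_points`` even relative positions.

    Linear interpolation between cell centers, constant beyond the first
    and last center.  A single-cell ring yields constant profiles.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = (np.arange(n_points) + 1.0) / n_points
    ld = np.array([c.lumen_diameter for c in t.cells], dtype=float)
    cwt = np.array([c.wall_thickness for c in t.cells], dtype=float)
    return StandardizedProfile(
        label=t.tree_id,
        rel_grid=grid,
        LD_profile=np.interp(grid, t.rel_pos, ld),
        CWT_profile=np.interp(grid, t.rel_pos, cwt),
    )


def group_mean_profile(
    tracheidograms: list[Tracheidogram], n_points: int = 100
) -> pd.DataFrame:
    """Mean standardized profile over a group's radial files.

    Returns a frame ordered from ring start with columns ``rel_pos,
    lumen_diameter, wall_thickness`` — the group-mean tracheidogram used to
    attach anatomy to kinetics.
    """
    profiles = [standardize_profile(t, n_points) for t in tracheidograms]
    grid = profiles[0].rel_grid
    ld = np.mean([p.LD_profile for p in profiles], axis=0)
    cwt = np.mean([p.CWT_profile for p in profiles], axis=0)
    return pd.DataFrame(
        {"rel_pos": grid, "lumen_diameter": ld, "wall_thickness": cwt}
    )


def compare_trait_profiles(
    records: pd.DataFrame,
    trait: str,
    config: SmoothConfig | None = None,
) -> tuple[dict, list[SignificanceWindows]]:
    """Fit per-group trait curves over relative position and compare them.

    ``records`` is a tidy frame with columns ``group, tree_id, rel_pos`` and
    the trait column (``lumen_diameter`` or ``wall_thickness``).  Each group
    gets a penalized-spline fit with a random intercept per tree; every
    group pair is compared by confidence-band overlap, windows reported in
    relative-position units.
    """
    if config is None:
        config = SmoothConfig(grid_step=0.01)
    groups = sorted(records["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    lo = float(records["rel_pos"].min())
    hi = float(records["rel_pos"].max())
    curves: dict = {}
    for g in groups:
        sub = records[records["group"] == g].rename(columns={trait: "value"})
        curves[g] = _fit_on_range(sub, config, lo, hi, group=str(g), phase=trait)
    windows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            windows.append(compare_groups(curves[ga], curves[gb]))
    return curves, windows


def _fit_on_range(sub, config, lo, hi, *, group, phase) -> FittedPhaseCurve:
    # the seasonal fitter is reused with rel_pos as the predictor; curves
    # are regridded onto the groups' common range so bands can be compared
    curve = fit_phase_curve(
        sub,
        config,
        group=group,
        phase=phase,
        time_col="rel_pos",
    )
    return _regrid(curve, lo, hi, config)


def _regrid(curve: FittedPhaseCurve, lo, hi, config) -> FittedPhaseCurve:
    grid = np.arange(lo, hi + config.grid_step * 0.5, config.grid_step)
    if grid.size == curve.grid.size and np.allclose(grid, curve.grid):
        return curve
    mean = np.interp(grid, curve.grid, curve.mean)
    lower = np.interp(grid, curve.grid, curve.lower)
    upper = np.interp(grid, curve.grid, curve.upper)
    return FittedPhaseCurve(
        group=curve.group,
        phase=curve.phase,
        grid=grid,
        mean=mean,
        lower=lower,
        upper=upper,
        edf=curve.edf,
        lam_smooth=curve.lam_smooth,
        lam_tree=curve.lam_tree,
        sigma2=curve.sigma2,
    )


def earlywood_latewood_split(t: Tracheidogram) -> tuple[int, int]:
    """Earlywood/latewood cell counts by Mork's index.

    A tracheid is latewood when twice the double wall thickness is at least
    the lumen diameter: ``4 * CWT >= LD``.
    """
    ld = np.array([c.lumen_diameter for c in t.cells])
    cwt = np.array([c.wall_thickness for c in t.cells])
    late = int(np.sum(4.0 * cwt >= ld))
    return len(t.cells) - late, late


def profiles_to_frame(curves: dict) -> pd.DataFrame:
    """Tidy export: group, rel_pos, trait mean and band per grid point."""
    rows = []
    for g, c in sorted(curves.items()):
        for x, m, lo, hi in zip(c.grid, c.mean, c.lower, c.upper):
            rows.append((g, c.phase, x, m, lo, hi))
    return pd.DataFrame(
        rows, columns=["group", "trait", "rel_pos", "mean", "lower", "upper"]
    )
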