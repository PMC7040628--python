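"""Seasonal smoothing of phase counts with pointwise confidence bands.

Each treatment group x differentiation phase is fitted independently with a
penalized cubic regression spline (B-spline basis, order-2 difference
penalty) plus a random intercept per tree, written in the standard ridge
representation of a mixed model: the tree effects are a second penalized
coefficient block whose ridge weight plays the role of the variance ratio
``sigma^2 / sigma_tree^2``.  Both penalties are chosen by generalized
cross-validation.  Confidence bands are pointwise Wald bands built from the
posterior covariance of the penalized fit, evaluated at the population level
(tree effects set to zero).

Group differences are read off the bands: two groups differ significantly
wherever their pointwise confidence intervals do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.stats import norm

__all__ = [
    "SmoothConfig",
    "FittedPhaseCurve",
    "SignificanceWindows",
    "InsufficientDataError",
    "fit_phase_curve",
    "fit_group_phase_curves",
    "compare_groups",
    "curves_to_frame",
    "windows_to_frame",
]


def _pow10(e: float) -> float:
    return 10.0 ** min(float(e), 300.0)


class InsufficientDataError(ValueError):
    """Too few distinct predictor values to support the spline basis."""


@dataclass(frozen=True)
class SmoothConfig:
    """Smoother settings.

    basis_dim
        Number of cubic B-spline basis functions (>= 4).
    penalty_order
        Order of the difference penalty on spline coefficients.
    ci_level
        Pointwise confidence level for the bands.
    grid_step
        Spacing of the prediction grid, in predictor units (days for the
        seasonal curves, relative-position units for tracheidograms).
    lam_smooth, lam_tree
        Fixed penalty weights; ``None`` selects each by GCV.
    family
        Response family; fractional mean counts are modelled as Gaussian.
    """

    basis_dim: int = 10
    penalty_order: int = 2
    ci_level: float = 0.95
    grid_step: float = 1.0
    lam_smooth: float | None = None
    lam_tree: float | None = None
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if self.basis_dim < 4:
            raise ValueError("basis_dim must be >= 4 for a cubic basis")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.family != "gaussian":
            raise NotImplementedError(
                f"family {self.family!r} not supported (only 'gaussian')"
            )


@dataclass(frozen=True)
class FittedPhaseCurve:
    """Smoothed mean curve with pointwise confidence bounds on a grid."""

    group: str
    phase: str
    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    edf: float = float("nan")
    lam_smooth: float = float("nan")
    lam_tree: float = float("nan")
    sigma2: float = float("nan")

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing 1-D")
        for name in ("mean", "lower", "upper"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != grid.shape:
                raise ValueError(f"{name} must match grid shape")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
        if np.any(self.lower > self.mean + 1e-12) or np.any(
            self.mean > self.upper + 1e-12
        ):
            raise ValueError("bands must satisfy lower <= mean <= upper")

    def clipped(self) -> "FittedPhaseCurve":
        """Copy with mean and bounds floored at zero, for reporting: a
        fitted cell count below zero has no physical reading."""
        return FittedPhaseCurve(
            group=self.group,
            phase=self.phase,
            grid=self.grid,
            mean=np.maximum(self.mean, 0.0),
            lower=np.maximum(self.lower, 0.0),
            upper=np.maximum(self.upper, 0.0),
            edf=self.edf,
            lam_smooth=self.lam_smooth,
            lam_tree=self.lam_tree,
            sigma2=self.sigma2,
        )


@dataclass(frozen=True)
class SignificanceWindows:
    """Predictor intervals on which two groups' bands are disjoint."""

    phase: str
    group_pair: tuple[str, str]
    windows: list = field(default_factory=list)


def _bspline_design(x: np.ndarray, lo: float, hi: float, basis_dim: int) -> tuple:
    """Cubic B-spline design matrix with equally spaced interior knots."""
    k = 3
    n_interior = basis_dim - (k + 1)
    interior = (
        np.linspace(lo, hi, n_interior + 2)[1:-1] if n_interior > 0 else np.array([])
    )
    knots = np.concatenate([[lo] * (k + 1), interior, [hi] * (k + 1)])
    X = BSpline.design_matrix(np.clip(x, lo, hi), knots, k).toarray()
    return X, knots


def _difference_penalty(p: int, order: int) -> np.ndarray:
    D = np.eye(p)
    for _ in range(order):
        D = np.diff(D, axis=0)
    return D.T @ D


def _penalized_fit(AtA, Aty, y, A, P):
    theta = np.linalg.solve(AtA + P, Aty)
    resid = y - A @ theta
    rss = float(resid @ resid)
    edf = float(np.trace(np.linalg.solve(AtA + P, AtA)))
    return theta, rss, edf


def fit_phase_curve(
    data: pd.DataFrame,
    config: SmoothConfig = SmoothConfig(),
    *,
    group: str = "",
    phase: str = "",
    value_col: str = "value",
    time_col: str = "season_day",
    tree_col: str = "tree_id",
) -> FittedPhaseCurve:
    """Fit one group x phase seasonal curve.

    ``data`` holds one row per tree x time with the response in
    ``value_col``.  Requires at least ``max(6, basis_dim)`` distinct
    predictor values.  An all-identical response yields an exact flat fit.
    """
    t = np.asarray(data[time_col], dtype=float)
    y = np.asarray(data[value_col], dtype=float)
    trees = np.asarray(data[tree_col])
    n = y.size
    n_distinct = np.unique(t).size
    required = max(6, config.basis_dim)
    if n_distinct < required:
        raise InsufficientDataError(
            f"need >= {required} distinct {time_col} values "
            f"(basis_dim={config.basis_dim}), got {n_distinct}"
        )

    lo, hi = float(t.min()), float(t.max())
    X, knots = _bspline_design(t, lo, hi, config.basis_dim)
    p = X.shape[1]
    tree_levels = np.unique(trees)
    use_trees = tree_levels.size >= 2
    if use_trees:
        Z = (trees[:, None] == tree_levels[None, :]).astype(float)
        A = np.hstack([X, Z])
    else:
        A = X
    Dpen = _difference_penalty(p, config.penalty_order)
    AtA = A.T @ A
    Aty = A.T @ y

    def penalty(lam_s: float, lam_t: float) -> np.ndarray:
        P = np.zeros((A.shape[1], A.shape[1]))
        P[:p, :p] = lam_s * Dpen
        if use_trees:
            idx = np.arange(p, A.shape[1])
            P[idx, idx] = lam_t
        # tiny ridge keeps the system well-posed when penalties vanish
        P[np.diag_indices_from(P)] += 1e-10
        return P

    def gcv(log_lams: np.ndarray) -> float:
        lam_s = _pow10(log_lams[0])
        lam_t = _pow10(log_lams[1]) if use_trees else 0.0
        try:
            _, rss, edf = _penalized_fit(AtA, Aty, y, A, penalty(lam_s, lam_t))
        except np.linalg.LinAlgError:
            return np.inf
        denom = n - edf
        if denom <= 1e-8:
            return np.inf
        return n * rss / denom**2

    fixed_s = config.lam_smooth
    fixed_t = config.lam_tree
    if fixed_s is None or (use_trees and fixed_t is None):
        # coarse grid then local polish; GCV surfaces here are cheap and
        # can be multimodal, so the grid guards the simplex start
        s_grid = np.arange(-4.0, 9.0, 1.0) if fixed_s is None else [np.log10(fixed_s)]
        t_grid = (
            np.arange(-2.0, 7.0, 1.0)
            if (use_trees and fixed_t is None)
            else [np.log10(fixed_t) if (use_trees and fixed_t) else 0.0]
        )
        best, best_val = None, np.inf
        for ls in s_grid:
            for lt in t_grid:
                val = gcv(np.array([ls, lt]))
                if val < best_val:
                    best, best_val = np.array([ls, lt]), val
        res = optimize.minimize(
            gcv, best, method="Nelder-Mead", options={"xatol": 0.01, "fatol": 1e-10}
        )
        sol = res.x if res.fun <= best_val else best
        lam_s = _pow10(sol[0]) if fixed_s is None else fixed_s
        lam_t = (_pow10(sol[1]) if fixed_t is None else fixed_t) if use_trees else 0.0
    else:
        lam_s = fixed_s
        lam_t = fixed_t if use_trees else 0.0

    P = penalty(lam_s, lam_t)
    theta, rss, edf = _penalized_fit(AtA, Aty, y, A, P)
    sigma2 = rss / max(n - edf, 1.0)

    grid = np.arange(lo, hi + config.grid_step * 0.5, config.grid_step)
    Xg, _ = _bspline_design(grid, lo, hi, config.basis_dim)
    beta = theta[:p]
    mean = Xg @ beta
    if use_trees:
        # population curve includes the average tree offset so that the
        # spline-vs-dummy split of the intercept does not shift the level
        mean = mean + float(np.mean(theta[p:]))
    cov = sigma2 * np.linalg.inv(AtA + P)
    if use_trees:
        T = tree_levels.size
        C = np.zeros((grid.size, A.shape[1]))
        C[:, :p] = Xg
        C[:, p:] = 1.0 / T
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, cov, C), 0.0))
    else:
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, cov[:p, :p], Xg), 0.0))
    z = norm.ppf(0.5 + config.ci_level / 2.0)
    return FittedPhaseCurve(
        group=group,
        phase=phase,
        grid=grid,
        mean=mean,
        lower=mean - z * se,
        upper=mean + z * se,
        edf=edf,
        lam_smooth=lam_s,
        lam_tree=lam_t,
        sigma2=sigma2,
    )


def fit_group_phase_curves(
    mean_counts: pd.DataFrame, config: SmoothConfig = SmoothConfig()
) -> dict:
    """Fit every (group, phase) curve from per-tree per-day mean counts.

    ``mean_counts`` is the output of
    :func:`xylokin.core.average_radial_files`.  Returns a dict keyed by
    ``(group, phase)``.
    """
    from .core import PHASES

    col = {
        "cambial": "n_cambial",
        "enlarging": "n_enlarging",
        "thickening": "n_thickening",
        "mature": "n_mature",
    }
    curves: dict = {}
    for group, sub in mean_counts.groupby("group", sort=True):
        for phase in PHASES:
            d = sub.rename(columns={col[phase]: "value"})
            curves[(group, phase)] = fit_phase_curve(
                d, config, group=str(group), phase=phase
            )
    return curves


def compare_groups(a: FittedPhaseCurve, b: FittedPhaseCurve) -> SignificanceWindows:
    """Intervals where the two pointwise confidence bands are disjoint.

    The gap function ``g(t) = max(a.lower - b.upper, b.lower - a.upper)`` is
    positive exactly where the bands are disjoint; maximal positive runs are
    returned with endpoints refined by linear interpolation of ``g`` between
    the bracketing grid points.
    """
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise ValueError("curves must share an identical grid")
    g = np.maximum(a.lower - b.upper, b.lower - a.upper)
    pos = g > 0
    windows: list[tuple[float, float]] = []
    grid = a.grid
    i = 0
    n = grid.size
    while i < n:
        if not pos[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and pos[j + 1]:
            j += 1
        start = grid[i]
        if i > 0:
            # linear root of g between grid[i-1] (<=0) and grid[i] (>0)
            frac = -g[i - 1] / (g[i] - g[i - 1]) if g[i] != g[i - 1] else 0.0
            start = grid[i - 1] + frac * (grid[i] - grid[i - 1])
        end = grid[j]
        if j + 1 < n:
            frac = g[j] / (g[j] - g[j + 1]) if g[j] != g[j + 1] else 0.0
            end = grid[j] + frac * (grid[j + 1] - grid[j])
        windows.append((float(start), float(end)))
        i = j + 1
    return SignificanceWindows(
        phase=a.phase, group_pair=(a.group, b.group), windows=windows
    )


def curves_to_frame(curves: dict) -> pd.DataFrame:
    """Tidy export of fitted curves: group, phase, season_day, mean, lower,
    upper (bounds clipped at zero cells for reporting)."""
    rows = []
    for (group, phase), c in sorted(curves.items()):
        cc = c.clipped()
        for t, m, lo, hi in zip(cc.grid, cc.mean, cc.lower, cc.upper):
            rows.append((group, phase, t, m, lo, hi))
    return pd.DataFrame(
        rows, columns=["group", "phase", "season_day", "mean", "lower", "upper"]
    )


def windows_to_frame(all_windows: list) -> pd.DataFrame:
    rows = []
    for w in all_windows:
        for start, end in w.windows:
            rows.append((w.phase, w.group_pair[0], w.group_pair[1], start, end))
    return pd.DataFrame(
        rows, columns=["phase", "group_a", "group_b", "start_day", "end_day"]
    )
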