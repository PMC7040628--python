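"""End-to-end orchestration: counts + anatomy in, tidy result tables out.

``run_pipeline`` chains the stages — radial-file averaging, penalized-spline
smoothing per group x phase, band-overlap comparison, kinetics inversion,
tracheidogram standardization and comparison, phenology extraction and the
group-level tests — and writes one tidy CSV per product plus a JSON manifest
(config echo, seed, package versions, diagnostics) and a units sidecar.
Outputs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import average_radial_files, read_counts, read_tracheids, PHASES
from .kinetics import (
    cell_kinetics,
    conservation_diagnostic,
    cumulative_entry_curves,
    kinetics_to_frame,
    production_rate_curves,
    rates_to_frame,
)
from .phenology import phenology_metrics, phenology_to_frame
from .smoothing import (
    SmoothConfig,
    compare_groups,
    curves_to_frame,
    fit_group_phase_curves,
    windows_to_frame,
)
from .stats import anova_to_frame, mixed_slope, one_way_anova
from .synthetic import (
    default_paper_scenario,
    observe_counts,
    simulate,
    tracheids_from_cohort,
    truth_to_frame,
)
from .tracheidogram import (
    compare_trait_profiles,
    earlywood_latewood_split,
    group_mean_profile,
    profiles_to_frame,
    relative_positions,
)
__all__ = ["PipelineConfig", "run_pipeline"]

UNITS = {
    "fitted_curves.csv": {
        "season_day": "days since Jan 1 of start year",
        "mean/lower/upper": "cells (fitted count, clipped at 0)",
    },
    "significance_windows.csv": {
        "start_day/end_day": "days (or relative position in (0,1] for trait rows)"
    },
    "kinetics.csv": {
        "t_enl/t_thick/t_mature": "season day",
        "d_E/d_T": "days",
        "r_enl/r_wall": "µm/day",
    },
    "rates.csv": {"rate": "cells/day", "season_day": "season day"},
    "profiles.csv": {"rel_pos": "fraction of ring width", "mean/lower/upper": "µm"},
    "phenology.csv": {"onset/cessation/duration": "season days", "peak_days": "season day list"},
    "stats.csv": {"statistic": "F or mean difference (cells)", "p": "probability"},
}


@dataclass
class PipelineConfig:
    """What to analyse and how.

    Either both input paths are given or ``simulate=True`` generates the
    default scenario inputs first (written next to the outputs).
    """

    counts_path: str | None = None
    tracheids_path: str | None = None
    simulate: bool = False
    out_dir: str = "xylokin_out"
    seed: int = 2017
    grid_step: float = 1.0
    ci_level: float = 0.95
    basis_dim: int = 10
    phase_threshold: float = 0.5  # cells; onset/cessation rule
    min_prominence: float = 0.2
    min_separation: float = 60.0

    def __post_init__(self) -> None:
        if not self.simulate and self.counts_path is None:
            raise ValueError("either counts_path or simulate=True is required")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    diagnostics: dict = {}

    if config.simulate:
        scenario = default_paper_scenario(seed=config.seed)
        sim = simulate(scenario)
        obs = observe_counts(sim)
        from .core import write_counts

        write_counts(obs, out / "simulated_counts.csv")
        tracheids_from_cohort(sim).to_csv(out / "simulated_tracheids.csv", index=False)
        truth_to_frame(sim).to_csv(out / "simulated_truth.csv", index=False)
        counts_path = out / "simulated_counts.csv"
        tracheids_path = out / "simulated_tracheids.csv"
    else:
        counts_path = Path(config.counts_path)
        if not counts_path.exists():
            raise FileNotFoundError(f"counts file not found: {counts_path}")
        tracheids_path = (
            Path(config.tracheids_path) if config.tracheids_path else None
        )
        obs = read_counts(counts_path)

    mean_counts = average_radial_files(obs)
    smooth_cfg = SmoothConfig(
        basis_dim=config.basis_dim,
        ci_level=config.ci_level,
        grid_step=config.grid_step,
    )
    curves = fit_group_phase_curves(mean_counts, smooth_cfg)
    curves_to_frame(curves).to_csv(out / "fitted_curves.csv", index=False)

    groups = sorted(mean_counts["group"].unique())
    windows = []
    for phase in PHASES:
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                windows.append(compare_groups(curves[(ga, phase)], curves[(gb, phase)]))

    tracheid_records = None
    trait_windows = []
    profile_frames = []
    group_anatomy = {}
    if tracheids_path is not None and Path(tracheids_path).exists():
        tracheid_records = read_tracheids(tracheids_path)
        tract_df = _tracheids_with_relpos(tracheid_records)
        for trait in ("lumen_diameter", "wall_thickness"):
            tcurves, twin = compare_trait_profiles(
                tract_df, trait, SmoothConfig(
                    basis_dim=config.basis_dim,
                    ci_level=config.ci_level,
                    grid_step=0.01,
                )
            )
            profile_frames.append(profiles_to_frame(tcurves))
            trait_windows.extend(twin)
        for g in groups:
            tgs = _tracheidograms_for_group(tracheid_records, g)
            if tgs:
                group_anatomy[g] = group_mean_profile(tgs)
    if profile_frames:
        pd.concat(profile_frames, ignore_index=True).to_csv(
            out / "profiles.csv", index=False
        )
    else:
        pd.DataFrame(
            columns=["group", "trait", "rel_pos", "mean", "lower", "upper"]
        ).to_csv(out / "profiles.csv", index=False)
    windows_to_frame(windows + trait_windows).to_csv(
        out / "significance_windows.csv", index=False
    )

    kin_frames, rate_frames, consv = [], [], {}
    kinetics_by_group = {}
    for g in groups:
        phase_curves = {p: curves[(g, p)] for p in PHASES}
        cums = cumulative_entry_curves(phase_curves)
        kin = cell_kinetics(cums, group_anatomy.get(g))
        kinetics_by_group[g] = kin
        kin_frames.append(kinetics_to_frame(kin, group=g))
        rates = production_rate_curves(cums, phase_curves["cambial"])
        rate_frames.append(rates_to_frame(rates, group=g))
        consv[g] = conservation_diagnostic(cums, phase_curves["enlarging"])
    pd.concat(kin_frames, ignore_index=True).to_csv(out / "kinetics.csv", index=False)
    pd.concat(rate_frames, ignore_index=True).to_csv(out / "rates.csv", index=False)
    diagnostics["conservation_max_abs"] = consv

    metrics = [
        phenology_metrics(
            curves[(g, p)],
            threshold=config.phase_threshold,
            min_prominence=config.min_prominence,
            min_separation=config.min_separation,
        )
        for g in groups
        for p in PHASES
    ]
    phenology_to_frame(metrics).to_csv(out / "phenology.csv", index=False)

    stats_frames = []
    totals = _per_tree_totals(mean_counts)
    if all(len(v) >= 2 for v in totals.values()) and len(totals) >= 2:
        res = one_way_anova(totals)
        stats_frames.append(anova_to_frame("total_cells", res))
        diagnostics["anova_total_cells"] = {"F": res.F, "p": res.p}
    if tracheid_records is not None:
        ew, lw = _per_tree_ew_lw(tracheid_records)
        for name, table in (("earlywood_cells", ew), ("latewood_cells", lw)):
            if all(len(v) >= 2 for v in table.values()) and len(table) >= 2:
                stats_frames.append(anova_to_frame(name, one_way_anova(table)))
        slope_rows = _trait_duration_slopes(
            tracheid_records, kinetics_by_group, groups
        )
        if slope_rows:
            stats_frames.append(pd.DataFrame(slope_rows))
    if stats_frames:
        pd.concat(stats_frames, ignore_index=True).to_csv(
            out / "stats.csv", index=False
        )
    else:
        pd.DataFrame(
            columns=["test", "kind", "group_a", "group_b", "statistic", "df", "p"]
        ).to_csv(out / "stats.csv", index=False)

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "xylokin_version": __version__,
        "versions": _versions(),
        "diagnostics": diagnostics,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "units.json").write_text(json.dumps(UNITS, indent=2, sort_keys=True))
    return out


def _versions() -> dict:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _tracheids_with_relpos(records) -> pd.DataFrame:
    """Tidy frame of tracheid traits with per-file relative positions."""
    rows = []
    frame = {}
    for r in records:
        frame.setdefault((r.tree_id, r.radial_file), []).append(r)
    for (tree, rfile), cells in sorted(frame.items()):
        cells = sorted(cells, key=lambda c: c.cell_index)
        tg = relative_positions(cells)
        for c, rp in zip(cells, tg.rel_pos):
            rows.append(
                (c.group, c.tree_id, rfile, float(rp), c.lumen_diameter, c.wall_thickness)
            )
    return pd.DataFrame(
        rows,
        columns=["group", "tree_id", "radial_file", "rel_pos", "lumen_diameter", "wall_thickness"],
    )


def _tracheidograms_for_group(records, group):
    by_file: dict = {}
    for r in records:
        if r.group == group:
            by_file.setdefault((r.tree_id, r.radial_file), []).append(r)
    return [
        relative_positions(sorted(cells, key=lambda c: c.cell_index))
        for cells in by_file.values()
    ]


def _per_tree_totals(mean_counts: pd.DataFrame) -> dict:
    """Per-tree total cells formed: season maximum of E + L + M."""
    df = mean_counts.copy()
    df["total"] = df["n_enlarging"] + df["n_thickening"] + df["n_mature"]
    out: dict = {}
    for (group, tree), sub in df.groupby(["group", "tree_id"]):
        out.setdefault(group, []).append(float(sub["total"].max()))
    return out


def _per_tree_ew_lw(records) -> tuple[dict, dict]:
    by_tree: dict = {}
    for r in records:
        by_tree.setdefault((r.group, r.tree_id, r.radial_file), []).append(r)
    ew: dict = {}
    lw: dict = {}
    agg: dict = {}
    for (group, tree, rfile), cells in sorted(by_tree.items()):
        tg = relative_positions(sorted(cells, key=lambda c: c.cell_index))
        e, l = earlywood_latewood_split(tg)
        agg.setdefault((group, tree), []).append((e, l))
    for (group, tree), pairs in sorted(agg.items()):
        ew.setdefault(group, []).append(float(np.mean([p[0] for p in pairs])))
        lw.setdefault(group, []).append(float(np.mean([p[1] for p in pairs])))
    return ew, lw


def _trait_duration_slopes(records, kinetics_by_group, groups) -> list[dict]:
    """Per-group mixed-model slopes: LD ~ d_E and CWT ~ d_T, random
    intercept per tree.  Each tree's tracheids are matched to the group
    kinetics by formation quantile."""
    rows: list[dict] = []
    for g in groups:
        kin = kinetics_by_group.get(g, [])
        d_e = np.array([k.d_E for k in kin], dtype=float)
        d_t = np.array([k.d_T for k in kin], dtype=float)
        if d_e.size < 3:
            continue
        per_tree: dict = {}
        for r in records:
            if r.group == g and r.radial_file == 1:
                per_tree.setdefault(r.tree_id, []).append(r)
        y_ld, x_de, y_cwt, x_dt, tree_ids = [], [], [], [], []
        for tree, cells in sorted(per_tree.items()):
            cells = sorted(cells, key=lambda c: c.cell_index)
            n = len(cells)
            q = (np.arange(n) + 0.5) / n
            qk = (np.arange(d_e.size) + 0.5) / d_e.size
            de_i = np.interp(q, qk, d_e)
            dt_i = np.interp(q, qk, d_t)
            for c, a, b in zip(cells, de_i, dt_i):
                y_ld.append(c.lumen_diameter)
                x_de.append(a)
                y_cwt.append(c.wall_thickness)
                x_dt.append(b)
                tree_ids.append(tree)
        for name, y, x in (
            (f"ld_vs_enlargement_duration", y_ld, x_de),
            (f"cwt_vs_deposition_duration", y_cwt, x_dt),
        ):
            try:
                res = mixed_slope(y, x, tree_ids)
            except (ValueError, np.linalg.LinAlgError):
                continue
            rows.append(
                {
                    "test": f"{name}[{g}]",
                    "kind": "lmm_slope",
                    "group_a": g,
                    "group_b": "",
                    "statistic": res.slope,
                    "df": "",
                    "p": float("nan"),
                }
            )
    return rows
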