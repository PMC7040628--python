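import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import xylokin as xk
from xylokin.core import PHASES
from xylokin.kinetics import (
    CumulativeEntryCurve,
    cell_kinetics,
    conservation_diagnostic,
    cumulative_entry_curves,
    entrance_date,
    invert_observed_counts,
    production_rate_curves,
)
from xylokin.smoothing import FittedPhaseCurve
from xylokin.synthetic import cambial_pool_curve


def _curve(phase, grid, mean, group="g"):
    mean = np.asarray(mean, dtype=float)
    return FittedPhaseCurve(
        group=group, phase=phase, grid=np.asarray(grid, dtype=float),
        mean=mean, lower=mean, upper=mean,
    )


def _cum(grid, value, phase="enlarging"):
    return CumulativeEntryCurve(
        phase=phase, grid=np.asarray(grid, dtype=float), value=np.asarray(value, float)
    )


class TestCumulativeCurves:
    def test_additivity(self):
        t = [60.0, 70.0, 80.0]
        cums = cumulative_entry_curves(
            {
                "enlarging": _curve("enlarging", t, [2, 1, 0]),
                "thickening": _curve("thickening", t, [0, 1, 1]),
                "mature": _curve("mature", t, [0, 0, 1]),
                "cambial": _curve("cambial", t, [5, 5, 5]),
            }
        )
        assert np.allclose(cums["enlarging"].value, [2, 2, 2])
        assert np.allclose(cums["thickening"].value, [0, 1, 2])
        assert np.allclose(cums["mature"].value, [0, 0, 1])

    def test_running_maximum_monotonization(self):
        from xylokin.kinetics import _clip_monotonize

        assert np.allclose(
            _clip_monotonize(np.array([0.0, 1.2, 1.0, 1.5])), [0.0, 1.2, 1.2, 1.5]
        )

    def test_reconstruction_identity(self):
        """C_E - C_L equals the clipped enlarging curve where nothing was
        monotonized."""
        t = np.arange(60.0, 120.0, 10.0)
        e = np.array([0.5, 2.0, 3.0, 2.0, 1.0, 0.0])
        l = np.array([0.0, 0.5, 1.5, 3.0, 4.0, 5.0])
        m = np.array([0.0, 0.0, 0.0, 0.5, 1.5, 2.0])
        cums = cumulative_entry_curves(
            {
                "enlarging": _curve("enlarging", t, e),
                "thickening": _curve("thickening", t, l),
                "mature": _curve("mature", t, m),
                "cambial": _curve("cambial", t, np.full(6, 5.0)),
            }
        )
        assert conservation_diagnostic(cums, _curve("enlarging", t, e)) < 1e-12

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            cumulative_entry_curves(
                {
                    "enlarging": _curve("enlarging", [60, 70], [1, 1]),
                    "thickening": _curve("thickening", [60, 75], [0, 1]),
                    "mature": _curve("mature", [60, 70], [0, 0]),
                    "cambial": _curve("cambial", [60, 70], [5, 5]),
                }
            )


class TestEntranceDate:
    def test_linear_interpolation(self):
        c = _cum([60.0, 70.0], [0.0, 2.0])
        assert entrance_date(c, 1) == pytest.approx(65.0)

    def test_not_formed_is_nan(self):
        c = _cum([60.0, 70.0], [0.0, 2.4])
        assert np.isnan(entrance_date(c, 3))

    def test_curve_starting_above_level(self):
        c = _cum([60.0, 70.0], [1.5, 2.0])
        assert entrance_date(c, 1) == pytest.approx(60.0)

    def test_brute_force_scan_agreement(self):
        """Crossing times match a 0.01-day scan of the interpolated curve."""
        rng = np.random.default_rng(8)
        grid = np.arange(60.0, 160.0, 10.0)
        value = np.cumsum(rng.uniform(0.0, 1.5, grid.size))
        value[0] = 0.0
        value = np.maximum.accumulate(value)
        c = _cum(grid, value)
        fine = np.arange(60.0, 150.0 + 1e-9, 0.01)
        interp = np.interp(fine, grid, value)
        for i in range(1, int(np.floor(value[-1])) + 1):
            t = entrance_date(c, i)
            oracle = fine[np.argmax(interp >= i)]
            assert t == pytest.approx(oracle, abs=0.011)

    def test_monotone_in_cell_index(self):
        rng = np.random.default_rng(9)
        grid = np.arange(60.0, 260.0, 10.0)
        value = np.maximum.accumulate(np.cumsum(rng.uniform(0, 1, grid.size)))
        c = _cum(grid, value)
        dates = [entrance_date(c, i) for i in range(1, int(value[-1]) + 1)]
        assert np.all(np.diff(dates) >= 0)


class TestCellKinetics:
    def test_duration_subtraction(self):
        t = [60.0, 70.0, 80.0, 95.0]
        cums = {
            "enlarging": _cum(t, [0.0, 1.0, 1.0, 1.0]),
            "thickening": _cum(t, [0.0, 0.0, 1.0, 1.0], "thickening"),
            "mature": _cum(t, [0.0, 0.0, 0.0, 1.0], "mature"),
        }
        (k,) = cell_kinetics(cums)
        assert k.t_enl == pytest.approx(70.0)
        assert k.d_E == pytest.approx(k.t_thick - k.t_enl)
        assert k.d_T == pytest.approx(k.t_mature - k.t_thick)

    def test_rates_forced_arithmetic(self):
        """40 µm lumen over 20 days -> 2 µm/day; 6 µm wall over 120 days ->
        0.05 µm/day."""
        t = [60.0, 80.0, 100.0, 220.0]
        cums = {
            "enlarging": _cum(t, [0.0, 1.0, 1.0, 1.0]),
            "thickening": _cum(t, [0.0, 0.0, 1.0, 1.0], "thickening"),
            "mature": _cum(t, [0.0, 0.0, 0.0, 1.0], "mature"),
        }
        anatomy = pd.DataFrame({"lumen_diameter": [40.0], "wall_thickness": [6.0]})
        (k,) = cell_kinetics(cums, anatomy)
        assert k.d_E == pytest.approx(20.0)
        assert k.r_enl == pytest.approx(2.0)
        assert k.d_T == pytest.approx(120.0)
        assert k.r_wall == pytest.approx(0.05)

    def test_never_maturing_cell_has_nan_maturity(self):
        t = [60.0, 70.0, 80.0]
        cums = {
            "enlarging": _cum(t, [0.0, 1.0, 2.0]),
            "thickening": _cum(t, [0.0, 0.5, 1.0], "thickening"),
            "mature": _cum(t, [0.0, 0.0, 0.0], "mature"),
        }
        kin = cell_kinetics(cums)
        assert len(kin) == 2
        assert np.isnan(kin[0].t_mature) and np.isnan(kin[0].d_T)


class TestRateCurves:
    def test_linear_cumulative_gives_constant_rate(self):
        t = np.arange(60.0, 160.0, 10.0)
        cums = {
            "enlarging": _cum(t, 0.3 * (t - 60.0)),
            "thickening": _cum(t, np.zeros_like(t), "thickening"),
            "mature": _cum(t, np.zeros_like(t), "mature"),
        }
        rates = production_rate_curves(cums)
        assert np.allclose(rates["rE"].rate, 0.3)

    def test_flat_curves_zero_rates(self):
        t = np.arange(60.0, 160.0, 10.0)
        flat = np.full_like(t, 2.0)
        cums = {
            "enlarging": _cum(t, flat),
            "thickening": _cum(t, flat, "thickening"),
            "mature": _cum(t, flat, "mature"),
        }
        cambial = _curve("cambial", t, np.full_like(t, 5.0))
        rates = production_rate_curves(cums, cambial)
        for kind in ("rC", "rE", "rL", "rM"):
            assert np.allclose(rates[kind].rate, 0.0)

    def test_short_grid_rejected(self):
        t = [60.0, 70.0]
        cums = {"enlarging": _cum(t, [0.0, 1.0])}
        with pytest.raises(ValueError, match="3 points"):
            production_rate_curves(cums)

    def test_rc_peak_matches_simulator_truth(self):
        """Full smoothing pipeline at daily noiseless sampling recovers the
        peak cambial production rate within 15%."""
        cfg = replace(
            xk.default_paper_scenario(seed=3),
            sampling_days=tuple(range(10, 431)),
            tree_total_sd=0.0,
        )
        group = "exclusion"
        cfg = replace(cfg, groups={group: cfg.groups[group]})
        sim = xk.synthetic.simulate(cfg)
        obs = xk.synthetic.observe_counts(sim)
        mc = xk.average_radial_files(obs)
        curves = xk.fit_group_phase_curves(
            mc, xk.SmoothConfig(basis_dim=20, grid_step=1.0)
        )
        pc = {p: curves[(group, p)] for p in PHASES}
        cums = cumulative_entry_curves(pc)
        rc = production_rate_curves(cums, pc["cambial"])["rC"]
        params = cfg.groups[group]
        grid = rc.grid
        pdf = np.zeros_like(grid)
        for pk in params.peaks:
            pdf += (
                pk.weight
                * np.exp(-0.5 * ((grid - pk.peak_day) / pk.sd_days) ** 2)
                / (pk.sd_days * np.sqrt(2 * np.pi))
            )
        pool = cambial_pool_curve(params, grid)
        truth = params.total_cells * pdf + np.maximum(
            np.gradient(np.maximum(pool - pool[0], 0.0), grid), 0.0
        )
        assert rc.rate.max() == pytest.approx(truth.max(), rel=0.15)


class TestFitFreeInversion:
    def test_conservation_exact_on_noiseless_counts(self):
        cfg = xk.default_paper_scenario(seed=4)
        sim = xk.synthetic.simulate(cfg)
        mc = xk.average_radial_files(xk.synthetic.observe_counts(sim))
        tree = mc["tree_id"].iloc[0]
        sub = mc[mc["tree_id"] == tree]
        cums = invert_observed_counts(sub, censoring="none")
        e = np.asarray(sub.sort_values("season_day")["n_enlarging"], dtype=float)
        diff = cums["enlarging"].value - cums["thickening"].value
        assert np.max(np.abs(diff - e)) < 1e-9

    def test_entrance_recovery_within_half_interval(self):
        """Noiseless fit-free inversion at daily sampling recovers every
        entrance date within half a day."""
        cfg = replace(
            xk.default_paper_scenario(seed=5), sampling_days=tuple(range(1, 431))
        )
        sim = xk.synthetic.simulate(cfg)
        mc = xk.average_radial_files(xk.synthetic.observe_counts(sim))
        for (group, tid), cohort in list(sim.trees.items())[:3]:
            sub = mc[mc["tree_id"] == tid]
            kin = cell_kinetics(invert_observed_counts(sub))
            assert len(kin) == cohort.n_cells
            for k, truth in zip(kin, cohort.t_enl):
                assert abs(k.t_enl - truth) <= 0.5 + 1e-9
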