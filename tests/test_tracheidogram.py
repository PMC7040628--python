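import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xylokin.core import TracheidRecord, ValidationError
from xylokin.tracheidogram import (
    compare_trait_profiles,
    earlywood_latewood_split,
    group_mean_profile,
    relative_positions,
    standardize_profile,
)


def _cells(lds, cwts, tree="t1"):
    return [
        TracheidRecord(tree, "g", 1, i + 1, ld, cwt)
        for i, (ld, cwt) in enumerate(zip(lds, cwts))
    ]


class TestRelativePositions:
    def test_single_cell(self):
        tg = relative_positions(_cells([6.0], [2.0]))  # diameter 10
        assert tg.ring_width == pytest.approx(10.0)
        assert tg.centers[0] == pytest.approx(5.0)
        assert tg.rel_pos[0] == pytest.approx(0.5)

    def test_two_equal_cells(self):
        tg = relative_positions(_cells([6.0, 6.0], [2.0, 2.0]))
        assert np.allclose(tg.rel_pos, [0.25, 0.75])

    @pytest.mark.parametrize("n", [3, 7, 20])
    def test_equal_cells_closed_form(self, n):
        tg = relative_positions(_cells([6.0] * n, [2.0] * n))
        assert np.allclose(tg.rel_pos, (np.arange(1, n + 1) - 0.5) / n)

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(st.floats(1.0, 60.0), min_size=1, max_size=30),
        st.floats(0.1, 10.0),
    )
    def test_scaling_invariance(self, lds, scale):
        cwts = [2.0] * len(lds)
        a = relative_positions(_cells(lds, cwts))
        b = relative_positions(
            _cells([x * scale for x in lds], [2.0 * scale] * len(lds))
        )
        assert np.allclose(a.rel_pos, b.rel_pos, atol=1e-9)

    def test_last_center_plus_half_diameter_is_ring_width(self):
        tg = relative_positions(_cells([40.0, 30.0, 10.0], [2.0, 3.0, 6.0]))
        last = tg.cells[-1]
        assert tg.centers[-1] + last.radial_diameter / 2.0 == pytest.approx(
            tg.ring_width
        )

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            relative_positions([])


class TestStandardizeProfile:
    def test_constant_trait(self):
        tg = relative_positions(_cells([40.0] * 5, [2.0] * 5))
        prof = standardize_profile(tg, 10)
        assert np.allclose(prof.LD_profile, 40.0)

    def test_linear_trait_exact_at_centers(self):
        n = 10
        lds = np.linspace(40.0, 10.0, n)
        tg = relative_positions(_cells(lds, [2.0] * n))
        prof = standardize_profile(tg, 200)
        expected = np.interp(prof.rel_grid, tg.rel_pos, lds)
        assert np.max(np.abs(prof.LD_profile - expected)) < 1e-9

    def test_profile_length_contract(self):
        tg = relative_positions(_cells([40.0] * 8, [2.0] * 8))
        prof = standardize_profile(tg, 100)
        assert prof.LD_profile.size == 100 and prof.CWT_profile.size == 100

    def test_equal_widths_roundtrip_at_cell_count(self):
        # constant radial diameter (LD + 2 CWT = 60) so centers sit at
        # (i - 0.5)/n; a trait linear in cell index is then linear in
        # rel_pos and interpolating the profile back at the centers is exact
        n = 12
        lds = 40.0 - 2.0 * np.arange(n)
        cwts = (60.0 - lds) / 2.0
        tg = relative_positions(_cells(lds, cwts))
        assert np.allclose(tg.rel_pos, (np.arange(1, n + 1) - 0.5) / n)
        prof = standardize_profile(tg, n)
        back = np.interp(tg.rel_pos, prof.rel_grid, prof.LD_profile)
        # the two boundary centers fall under constant end-extrapolation of
        # the grid; all interior centers are recovered exactly
        assert np.allclose(back[1:-1], lds[1:-1], atol=1e-9)


class TestMorkSplit:
    @pytest.mark.parametrize(
        "ld,cwt,expect_late",
        [(40.0, 2.0, False), (10.0, 6.0, True), (8.0, 2.0, True)],
    )
    def test_mork_rule(self, ld, cwt, expect_late):
        tg = relative_positions(_cells([ld], [cwt]))
        ew, lw = earlywood_latewood_split(tg)
        assert (lw == 1) is expect_late

    def test_all_earlywood(self):
        tg = relative_positions(_cells([40.0] * 6, [2.0] * 6))
        ew, lw = earlywood_latewood_split(tg)
        assert (ew, lw) == (6, 0)

    def test_counts_sum_to_total(self):
        lds = [40.0, 30.0, 20.0, 12.0, 8.0]
        tg = relative_positions(_cells(lds, [2.0, 2.5, 3.0, 4.0, 6.0]))
        ew, lw = earlywood_latewood_split(tg)
        assert ew + lw == 5


def _trait_frame(effect, rng, lo=0.68, hi=0.92, noise=0.3):
    rows = []
    for g, eff in (("a", 0.0), ("b", effect)):
        for tr in range(5):
            n = 40
            rp = (np.arange(n) + 0.5) / n
            cwt = (
                2.0
                + 6.0 * rp
                + eff * ((rp >= lo) & (rp <= hi))
                + noise * rng.standard_normal(n)
            )
            rows.extend((g, f"{g}{tr}", r, c) for r, c in zip(rp, cwt))
    return pd.DataFrame(rows, columns=["group", "tree_id", "rel_pos", "wall_thickness"])


class TestCompareProfiles:
    def test_localized_effect_detected(self):
        """A +4 µm wall-thickness offset confined to late ring positions is
        found as a window overlapping the true region."""
        df = _trait_frame(4.0, np.random.default_rng(11))
        _, wins = compare_trait_profiles(df, "wall_thickness")
        windows = wins[0].windows
        assert len(windows) >= 1
        start, end = max(windows, key=lambda w: w[1] - w[0])  # dominant window
        assert 0.6 <= start and end <= 1.0
        assert start < 0.92 and end > 0.68  # overlaps the true effect region

    def test_exchangeable_groups_no_windows(self):
        df = _trait_frame(0.0, np.random.default_rng(12))
        _, wins = compare_trait_profiles(df, "wall_thickness")
        assert wins[0].windows == []

    def test_constant_offset_full_range_window(self):
        rng = np.random.default_rng(13)
        df = _trait_frame(0.0, rng, noise=0.05)
        df.loc[df["group"] == "b", "wall_thickness"] += 5.0
        _, wins = compare_trait_profiles(df, "wall_thickness")
        windows = wins[0].windows
        assert len(windows) == 1
        start, end = windows[0]
        grid_lo = df["rel_pos"].min()
        grid_hi = df["rel_pos"].max()
        assert start == pytest.approx(grid_lo, abs=0.02)
        assert end == pytest.approx(grid_hi, abs=0.02)


class TestGroupMeanProfile:
    def test_mean_of_identical_trees(self):
        tgs = [
            relative_positions(_cells([40.0, 20.0, 10.0], [2.0, 4.0, 6.0], tree=f"t{i}"))
            for i in range(3)
        ]
        prof = group_mean_profile(tgs, n_points=30)
        assert prof.shape == (30, 3)
        assert prof["lumen_diameter"].iloc[0] == pytest.approx(40.0)
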