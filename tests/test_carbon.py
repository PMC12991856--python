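"""Carbon accounting: volume formulas, densities, plot-level stocks."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from forest_csb.carbon import (
    DensityTable,
    deadwood_density,
    living_tree_volume,
    plot_carbon_stocks,
    standing_dead_volume,
    truncated_cone_volume,
)
from forest_csb.harmonize import DeadwoodPiece, TreeRecord
from .conftest import random_piece, random_tree


class TestTruncatedCone:
    def test_equal_ends_reduce_to_cylinder(self):
        assert truncated_cone_volume(20, 20, 10) == pytest.approx(
            math.pi * 0.1**2 * 10, abs=1e-12
        )

    def test_zero_end_reduces_to_cone(self):
        assert truncated_cone_volume(20, 0, 3) == pytest.approx(
            math.pi * 0.1**2 * 3 / 3, abs=1e-12
        )

    def test_hand_evaluated_value(self):
        assert truncated_cone_volume(30, 15, 2) == pytest.approx(0.0824668, abs=1e-7)

    @given(
        d1=st.floats(0, 100), d2=st.floats(0, 100), length=st.floats(0, 30)
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_nonnegativity(self, d1, d2, length):
        v = truncated_cone_volume(d1, d2, length)
        assert v >= 0
        assert v == pytest.approx(truncated_cone_volume(d2, d1, length), rel=1e-14)

    def test_negative_input_raises(self):
        with pytest.raises(ValueError):
            truncated_cone_volume(-1, 10, 5)


class TestStandingAndLivingVolumes:
    def test_standing_dead_hand_value(self):
        assert standing_dead_volume(40, 10) == pytest.approx(0.1256637, abs=1e-7)

    @pytest.mark.parametrize("dbh,height", [(40, 0), (0, 10)])
    def test_degenerate_zero(self, dbh, height):
        assert standing_dead_volume(dbh, height) == 0.0
        assert living_tree_volume(dbh, height) == 0.0

    def test_living_hand_value_and_cylinder_limit(self):
        assert living_tree_volume(40, 20, 0.5) == pytest.approx(1.256637, abs=1e-6)
        assert living_tree_volume(40, 20, 1.0) == pytest.approx(
            math.pi / 4 * 0.4**2 * 20, abs=1e-12
        )

    def test_form_factor_domain(self):
        with pytest.raises(ValueError):
            living_tree_volume(40, 20, 0.0)
        with pytest.raises(ValueError):
            living_tree_volume(40, 20, 1.5)

    def test_strictly_increasing_in_dbh_and_height(self):
        assert living_tree_volume(41, 20) > living_tree_volume(40, 20)
        assert living_tree_volume(40, 21) > living_tree_volume(40, 20)


class TestDensityTable:
    def test_density_is_base_times_multiplier(self):
        table = DensityTable(
            species_density={"x": 0.6},
            decay_correction={(3, "log", "coniferous"): 0.75},
        )
        piece = DeadwoodPiece("P1", "log", 20, 15, 4, 3, "coniferous", species="x")
        assert deadwood_density(piece, table) == pytest.approx(0.45)

    def test_stage_one_default_keeps_base_density(self):
        table = DensityTable()
        piece = DeadwoodPiece("P1", "log", 20, 15, 4, 1, "broadleaved")
        assert deadwood_density(piece, table) == pytest.approx(
            table.group_density["broadleaved"]
        )

    def test_default_multipliers_decrease_with_decay(self):
        table = DensityTable()
        for pos in ("log", "snag", "stump"):
            for grp in ("coniferous", "broadleaved"):
                mults = [table.correction(s, pos, grp) for s in range(1, 6)]
                assert mults == sorted(mults, reverse=True)

    def test_missing_correction_raises(self):
        table = DensityTable(decay_correction={(1, "log", "coniferous"): 1.0})
        piece = DeadwoodPiece("P1", "snag", 20, None, 4, 2, "coniferous")
        with pytest.raises(KeyError):
            deadwood_density(piece, table)

    def test_invalid_multiplier_rejected(self):
        with pytest.raises(ValueError):
            DensityTable(decay_correction={(1, "log", "coniferous"): 1.2})

    def test_csv_round_trip(self, tmp_path):
        table = DensityTable()
        table.corrections_to_csv(tmp_path / "corr.csv")
        back = DensityTable.from_csv(corrections_path=tmp_path / "corr.csv")
        assert back.decay_correction == table.decay_correction


class TestPlotCarbonStocks:
    def test_living_carbon_fraction(self, meta_1ha):
        # one tree whose biomass is exactly 100 t -> c_living = 48 t/ha
        t = TreeRecord("P1", "big", dbh=100.0, height=20.0)
        vol = living_tree_volume(100.0, 20.0, 0.5)
        table = DensityTable(species_density={"big": 100.0 / vol})
        stocks = plot_carbon_stocks([t], [], meta_1ha, table)
        assert stocks.c_living == pytest.approx(48.0, rel=1e-12)
        assert stocks.c_dead == 0.0

    def test_dead_carbon_fraction(self, meta_1ha):
        # one undecayed log whose biomass is exactly 10 t -> c_dead = 4.85
        p = DeadwoodPiece("P1", "log", 40, 40, 10, 1, "coniferous", species="x")
        vol = truncated_cone_volume(40, 40, 10)
        table = DensityTable(species_density={"x": 10.0 / vol})
        stocks = plot_carbon_stocks([], [p], meta_1ha, table)
        assert stocks.c_dead == pytest.approx(4.85, rel=1e-12)

    def test_empty_plot_is_zero(self, meta_1ha):
        stocks = plot_carbon_stocks([], [], meta_1ha)
        assert (stocks.c_living, stocks.c_dead) == (0.0, 0.0)

    def test_missing_height_raises(self, meta_1ha):
        with pytest.raises(ValueError):
            plot_carbon_stocks(
                [TreeRecord("P1", "sp1", 30.0, None)], [], meta_1ha
            )

    def test_additive_over_record_subsets(self, rng, meta_1ha):
        trees = [random_tree(rng) for _ in range(20)]
        pieces = [random_piece(rng) for _ in range(20)]
        whole = plot_carbon_stocks(trees, pieces, meta_1ha)
        part1 = plot_carbon_stocks(trees[:7], pieces[:11], meta_1ha)
        part2 = plot_carbon_stocks(trees[7:], pieces[11:], meta_1ha)
        assert whole.c_living == pytest.approx(part1.c_living + part2.c_living)
        assert whole.c_dead == pytest.approx(part1.c_dead + part2.c_dead)

    def test_linear_in_density(self, rng, meta_1ha):
        trees = [random_tree(rng) for _ in range(10)]
        pieces = [random_piece(rng) for _ in range(10)]
        base = DensityTable()
        doubled = DensityTable(
            group_density={k: 2 * v for k, v in base.group_density.items()}
        )
        s1 = plot_carbon_stocks(trees, pieces, meta_1ha, base)
        s2 = plot_carbon_stocks(trees, pieces, meta_1ha, doubled)
        assert s2.c_living == pytest.approx(2 * s1.c_living)
        assert s2.c_dead == pytest.approx(2 * s1.c_dead)

    def test_standing_dead_trees_enter_dead_pool(self, meta_1ha):
        dead = TreeRecord("P1", "sp1", 40.0, 10.0, alive=False)
        stocks = plot_carbon_stocks([dead], [], meta_1ha)
        assert stocks.c_living == 0.0
        table = DensityTable()
        expected = (
            0.485
            * standing_dead_volume(40.0, 10.0)
            * table.group_density["broadleaved"]
            * table.correction(1, "snag", "broadleaved")
        )
        assert stocks.c_dead == pytest.approx(expected)

    def test_per_hectare_scaling(self, rng):
        from forest_csb.harmonize import PlotMeta

        trees = [random_tree(rng) for _ in range(10)]
        m1 = PlotMeta("P1", "S", "F", "M", 50, 1.0, 8, 800)
        m4 = PlotMeta("P1", "S", "F", "M", 50, 0.25, 8, 800)
        assert plot_carbon_stocks(trees, [], m4).c_living == pytest.approx(
            4 * plot_carbon_stocks(trees, [], m1).c_living
        )
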