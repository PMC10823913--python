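import math

import numpy as np
import pandas as pd
import pytest

from virtualforest.core import FieldPlot, StandSummary, TreeRecord, tree_basal_area
from virtualforest.downscale import (
    CELLS_PER_HA,
    alpha,
    bernoulli_round,
    cell_rng,
    cell_weight,
    continuous_weight,
    final_dbh,
    generate_cell,
    generate_landscape,
    joint_minmax_scale,
    match_plot,
    tree_target_ba,
)
from virtualforest.errors import InvalidInputError


class TestJointScaling:
    def test_joint_range(self):
        plots = [
            FieldPlot("a", [TreeRecord("Pi.ab.", 2 * math.sqrt(10), 1000.0)]),
            FieldPlot("b", [TreeRecord("Pi.ab.", 2 * math.sqrt(30), 1000.0)]),
        ]
        # those plots have BA = pi*4*s/40000*1000 -> choose cells spanning [5,35]
        cells = [StandSummary(5.0, 20.0, 0.0), StandSummary(35.0, 30.0, 1.0)]
        space = joint_minmax_scale(cells, plots)
        ba_all = np.concatenate(
            [space.cell_scaled[:, 0], space.plot_scaled[:, 0]]
        )
        assert ba_all.min() == 0.0 and ba_all.max() == 1.0
        # a mid value scales by the joint range, not by its own set's range
        lo, hi = space.lo[0], space.hi[0]
        assert (20.0 - lo) / (hi - lo) == pytest.approx(
            (20.0 - space.lo[0]) / (space.hi[0] - space.lo[0])
        )

    def test_constant_coordinate_maps_to_zero(self):
        plots = [FieldPlot("a", [TreeRecord("Pi.ab.", 25.0, 100.0)])]
        s = plots[0].summary()
        space = joint_minmax_scale([s], plots)
        assert np.all(space.cell_scaled == 0.0)
        assert np.all(space.plot_scaled == 0.0)


class TestMatching:
    def _space(self, plots, cells):
        return joint_minmax_scale(cells, plots)

    def test_identical_summary_matches_at_distance_zero(self, mixed_plot):
        other = FieldPlot("zz", [TreeRecord("Pi.ab.", 12.0, 40.0)])
        cells = [mixed_plot.summary()]
        space = self._space([mixed_plot, other], cells)
        pid, d = match_plot(space.cell_scaled[0], space)
        assert pid == "pm" and d == pytest.approx(0.0, abs=1e-12)

    def test_equidistant_tie_breaks_on_smaller_id(self):
        p1 = FieldPlot("a2", [TreeRecord("Pi.ab.", 20.0, 100.0)])
        p2 = FieldPlot("a1", [TreeRecord("Pi.ab.", 20.0, 100.0)])
        cells = [StandSummary(10.0, 25.0, 0.5)]
        space = self._space([p1, p2], cells)
        pid, _ = match_plot(space.cell_scaled[0], space)
        assert pid == "a1"

    def test_forest_type_filter_beats_global_nearest(self, rng):
        """Brute force over candidates: the constrained match is the nearest
        plot of the requested type, even when another type is closer."""
        plots = []
        for j in range(12):
            dbh = float(rng.uniform(15, 45))
            p = FieldPlot(
                f"p{j:02d}",
                [TreeRecord("Pi.ab.", dbh, float(rng.uniform(50, 300)))],
                forest_type="beech" if j % 2 else "spruce",
            )
            plots.append(p)
        cells = [StandSummary(20.0, 30.0, 0.0)]
        space = self._space(plots, cells)
        pid, dist = match_plot(space.cell_scaled[0], space, forest_type="beech")
        beech = [i for i, p in enumerate(plots) if p.forest_type == "beech"]
        dists = {
            plots[i].plot_id: float(
                np.linalg.norm(space.plot_scaled[i] - space.cell_scaled[0])
            )
            for i in beech
        }
        assert pid == min(dists, key=dists.get)
        assert dist == pytest.approx(min(dists.values()))

    def test_missing_forest_type_falls_back(self, mixed_plot):
        cells = [mixed_plot.summary()]
        space = self._space([mixed_plot], cells)
        pid, _ = match_plot(space.cell_scaled[0], space, forest_type="nonesuch")
        assert pid == "pm"


class TestAlpha:
    @pytest.mark.parametrize("dg_als,dg_f,expected", [(30, 25, 1.2), (25, 25, 1.0)])
    def test_ratio(self, dg_als, dg_f, expected):
        assert alpha(dg_als, dg_f) == pytest.approx(expected)

    def test_zero_plot_dg_rejected(self):
        with pytest.raises(InvalidInputError):
            alpha(30.0, 0.0)

    def test_scaling_reaches_cell_dg_exactly(self, two_tree_plot):
        a = alpha(30.0, two_tree_plot.summary().dg)
        scaled = [
            TreeRecord(t.species, t.dbh * a, t.weight) for t in two_tree_plot.trees
        ]
        dg_new = FieldPlot("s", scaled).summary().dg
        assert dg_new == pytest.approx(30.0, rel=1e-12)
        assert dg_new == pytest.approx(a * math.sqrt(650.0), rel=1e-12)


class TestTreeTargetBa:
    def test_single_broadleaf_gets_class_share(self):
        plot = FieldPlot("p", [TreeRecord("Fa.sy.", 30.0, 50.0, broadleaf=True)])
        targets, _ = tree_target_ba(20.0, 0.5, plot)
        # lone broadleaf takes the broadleaf half; conifer half is
        # reallocated to keep the total attainable
        assert sum(targets.values()) == pytest.approx(20.0)

    def test_two_equal_conifers_split_evenly(self):
        plot = FieldPlot(
            "p",
            [
                TreeRecord("Pi.ab.", 30.0, 50.0, broadleaf=False),
                TreeRecord("Ab.al.", 30.0, 50.0, broadleaf=False),
            ],
        )
        targets, realloc = tree_target_ba(20.0, 0.0, plot)
        assert targets[0] == pytest.approx(10.0)
        assert targets[1] == pytest.approx(10.0)
        assert realloc == 0.0

    def test_targets_sum_to_cell_ba(self, rng, make_random_plot):
        """Algebraic identity checked by brute force on random plots."""
        for _ in range(50):
            plot = make_random_plot(rng)
            ba_als = float(rng.uniform(5, 50))
            ba_b = float(rng.uniform(0, 1))
            targets, realloc = tree_target_ba(ba_als, ba_b, plot)
            assert sum(targets.values()) == pytest.approx(ba_als, rel=1e-9)
            assert realloc == 0.0  # both classes present by construction

    def test_class_mismatch_reallocates_with_warning(self, caplog):
        plot = FieldPlot("p", [TreeRecord("Pi.ab.", 30.0, 50.0, broadleaf=False)])
        targets, realloc = tree_target_ba(20.0, 0.3, plot)
        assert realloc == pytest.approx(6.0)
        assert sum(targets.values()) == pytest.approx(20.0)


class TestWeightsAndRounding:
    def test_continuous_weight_hand_value(self):
        # ba=10 m2/ha at corrected diameter 50 cm
        w = continuous_weight(10.0, 1.0, 50.0)
        assert w == pytest.approx(40000.0 * 10.0 / (math.pi * 2500.0), rel=1e-12)
        assert w == pytest.approx(50.9296, abs=1e-3)

    def test_weight_inverts_single_tree_ba(self):
        dbh = 37.3
        assert continuous_weight(tree_basal_area(dbh), 1.0, dbh) == pytest.approx(1.0)

    def test_weight_linear_in_ba(self):
        assert continuous_weight(20.0, 1.1, 40.0) == pytest.approx(
            2 * continuous_weight(10.0, 1.1, 40.0)
        )

    def test_published_worked_example(self):
        # 1 tree fully enumerated on 400 m2 -> 25 stems/ha -> 1.5625 per cell
        assert cell_weight(10000.0 / 400.0) == pytest.approx(1.5625)

    @pytest.mark.parametrize("w,expected", [(16.0, 1.0), (0.0, 0.0)])
    def test_cell_weight_ratio(self, w, expected):
        assert cell_weight(w) == expected

    def test_bernoulli_round_integer_weight_deterministic(self, rng):
        assert all(bernoulli_round(3.0, rng) == 3 for _ in range(20))

    def test_bernoulli_round_unbiased_at_published_example(self):
        """10^5 draws at weight 1.56: mean within 1.56 +/- 0.005 and only the
        values 1 and 2 occur, with ~56% twos."""
        rng = np.random.default_rng(12345)
        draws = np.array([bernoulli_round(1.56, rng) for _ in range(100_000)])
        assert set(np.unique(draws)) == {1, 2}
        assert abs(draws.mean() - 1.56) < 0.005
        assert np.mean(draws == 2) == pytest.approx(0.56, abs=0.01)


class TestFinalDbh:
    def test_hand_value(self):
        d = final_dbh(10.0, 1)
        assert d == pytest.approx(math.sqrt(40000.0 / math.pi * 10.0 / 16.0))
        assert d == pytest.approx(89.21, abs=0.01)

    def test_identity_when_rounding_changes_nothing(self, rng):
        """If omega_int equals the unrounded per-cell weight, the final dbh
        is exactly alpha * dbh_F."""
        a, dbh_f = 1.2, 30.0
        omega_int = 3
        ba = omega_int * CELLS_PER_HA * tree_basal_area(a * dbh_f)
        assert final_dbh(ba, omega_int) == pytest.approx(a * dbh_f, rel=1e-12)

    def test_doubling_stems_divides_dbh_by_sqrt2(self):
        assert final_dbh(10.0, 2) == pytest.approx(final_dbh(10.0, 1) / math.sqrt(2))

    def test_zero_stems_rejected(self):
        with pytest.raises(InvalidInputError):
            final_dbh(10.0, 0)


class TestGenerateCell:
    def test_exact_ba_per_retained_tree(self, rng, make_random_plot):
        """Every retained tree carries its target ba exactly; the cell BA
        shortfall equals exactly the ba of dropped trees."""
        for trial in range(30):
            plot = make_random_plot(rng)
            cell = StandSummary(
                float(rng.uniform(5, 50)),
                float(rng.uniform(12, 45)),
                float(rng.uniform(0, 1)),
            )
            asg = generate_cell(trial, cell, plot, cell_rng(7, trial))
            gen_ba = sum(
                CELLS_PER_HA * t.n * tree_basal_area(t.dbh) for t in asg.trees
            )
            assert gen_ba + asg.lost_ba == pytest.approx(cell.ba, rel=1e-9)

    def test_dg_ratio_preservation(self, rng):
        """Before rounding, inter-species Dg ratios equal the field plot's
        (the alpha scaling is a common factor)."""
        plot = FieldPlot(
            "p",
            [
                TreeRecord("Fa.sy.", 22.0, 90.0, broadleaf=True),
                TreeRecord("Fa.sy.", 34.0, 40.0, broadleaf=True),
                TreeRecord("Pi.ab.", 28.0, 70.0, broadleaf=False),
                TreeRecord("Pi.ab.", 45.0, 15.0, broadleaf=False),
            ],
        )
        cell = StandSummary(27.0, 33.0, 0.4)
        a = alpha(cell.dg, plot.summary().dg)
        targets, _ = tree_target_ba(cell.ba, cell.ba_b, plot)

        def dg_of(trees):
            w = np.array([t.weight for t in trees])
            d = np.array([t.dbh for t in trees])
            return math.sqrt(float(np.sum(w * d**2) / np.sum(w)))

        # transformed (pre-rounding) trees: dbh alpha-scaled, weights from Eq 8
        def dg_transformed(sp):
            ds, ws = [], []
            for i, t in enumerate(plot.trees):
                if t.species != sp:
                    continue
                ds.append(a * t.dbh)
                ws.append(continuous_weight(targets[i], a, t.dbh))
            d, w = np.array(ds), np.array(ws)
            return math.sqrt(float(np.sum(w * d**2) / np.sum(w)))

        def dg_field(sp):
            return dg_of([t for t in plot.trees if t.species == sp])

        ratio_field = dg_field("Fa.sy.") / dg_field("Pi.ab.")
        ratio_gen = dg_transformed("Fa.sy.") / dg_transformed("Pi.ab.")
        assert ratio_gen == pytest.approx(ratio_field, rel=1e-9)

    def test_empty_cell(self, mixed_plot, rng):
        asg = generate_cell(0, StandSummary(0.0, 0.0, 0.0), mixed_plot, rng)
        assert asg.trees == []

    def test_randomness_only_in_stem_counts(self, mixed_plot):
        """Two seeds may differ in n, never in the dbh a (species, target)
        pair gets for the same n."""
        cell = StandSummary(24.0, 29.0, 0.55)
        a1 = generate_cell(0, cell, mixed_plot, cell_rng(1, 0))
        a2 = generate_cell(0, cell, mixed_plot, cell_rng(2, 0))
        assert a1.alpha == a2.alpha
        d1 = {(t.species, t.n): t.dbh for t in a1.trees}
        d2 = {(t.species, t.n): t.dbh for t in a2.trees}
        for key in set(d1) & set(d2):
            assert d1[key] == pytest.approx(d2[key], rel=1e-12)


class TestGenerateLandscape:
    def _setup(self, rng, n_cells=25, n_plots=8):
        plots = []
        for j in range(n_plots):
            trees = [
                TreeRecord("Fa.sy.", float(rng.uniform(10, 50)),
                           float(rng.uniform(30, 200)), broadleaf=True),
                TreeRecord("Pi.ab.", float(rng.uniform(10, 50)),
                           float(rng.uniform(30, 200)), broadleaf=False),
            ]
            plots.append(FieldPlot(f"p{j}", trees))
        cells = pd.DataFrame(
            {
                "BA": rng.uniform(5, 45, n_cells),
                "Dg": rng.uniform(15, 40, n_cells),
                "BA_b": rng.uniform(0, 1, n_cells),
            },
            index=pd.RangeIndex(n_cells, name="cellID25"),
        )
        return cells, plots

    def test_deterministic_given_seed(self, rng):
        cells, plots = self._setup(rng)
        t1, _ = generate_landscape(cells, plots, seed=99)
        t2, _ = generate_landscape(cells, plots, seed=99)
        pd.testing.assert_frame_equal(t1, t2)

    def test_order_independent(self, rng):
        cells, plots = self._setup(rng)
        t1, _ = generate_landscape(cells, plots, seed=99)
        t2, _ = generate_landscape(cells.iloc[::-1], plots, seed=99)
        pd.testing.assert_frame_equal(
            t1, t2.sort_values(["cellID25", "sp", "dbh"],
                               kind="mergesort").reset_index(drop=True)
        )

    def test_total_ba_within_bernoulli_losses(self, rng):
        cells, plots = self._setup(rng, n_cells=60)
        table, asgs = generate_landscape(cells, plots, seed=3)
        gen_ba = float(
            np.sum(CELLS_PER_HA * table["n"] * np.pi * table["dbh"] ** 2 / 40000.0)
        )
        lost = sum(a.lost_ba for a in asgs)
        assert gen_ba + lost == pytest.approx(float(cells["BA"].sum()), rel=1e-9)

    def test_distance_zero_reproduces_plot_composition(self, rng):
        _, plots = self._setup(rng)
        target = plots[0].summary()
        cells = pd.DataFrame(
            {"BA": [target.ba], "Dg": [target.dg], "BA_b": [target.ba_b]},
            index=pd.Index([0], name="cellID25"),
        )
        table, asgs = generate_landscape(cells, plots, seed=5)
        assert asgs[0].plot_id == "p0"
        assert asgs[0].distance == pytest.approx(0.0, abs=1e-12)
        # species BA shares of the generated cell match the plot's
        sp_gen = table.assign(
            ba=CELLS_PER_HA * table["n"] * np.pi * table["dbh"] ** 2 / 40000.0
        ).groupby("sp")["ba"].sum()
        sp_obs = {}
        for t in plots[0].trees:
            sp_obs[t.species] = sp_obs.get(t.species, 0) + t.weight * t.basal_area
        tot_lost = asgs[0].lost_ba
        for sp in sp_obs:
            if sp in sp_gen.index:
                assert sp_gen[sp] == pytest.approx(sp_obs[sp], rel=0.35)
        assert sp_gen.sum() + tot_lost == pytest.approx(target.ba, rel=1e-9)
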