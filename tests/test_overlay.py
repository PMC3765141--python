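"""Maximum-risk overlay, tabulation, cross-tabulation and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palmrisk import (
    CLASS_NODATA,
    GridCongruenceError,
    RiskClass,
    UnknownZoneError,
    ZoneMap,
    combine_liebig,
    cross_tabulate,
    rank_expansion_options,
    round_half_up,
    tabulate,
)

from oracles import brute_class_counts, brute_joint_histogram, brute_liebig


def class_grid(make_grid, cells):
    return make_grid(np.asarray(cells, dtype=np.uint8), nodata=CLASS_NODATA)


class TestCombineLiebig:
    def test_highest_risk_overrules(self, make_grid):
        layers = [
            class_grid(make_grid, [[0]]),
            class_grid(make_grid, [[2]]),
            class_grid(make_grid, [[3]]),
        ]
        assert combine_liebig(layers).cells[0, 0] == RiskClass.VERY_HIGH.rank

    def test_single_layer_is_identity(self, make_grid):
        layer = class_grid(make_grid, [[0, 1], [2, 3]])
        np.testing.assert_array_equal(combine_liebig([layer]).cells, layer.cells)

    def test_all_low_stays_low(self, make_grid):
        layers = [class_grid(make_grid, np.zeros((4, 4))) for _ in range(3)]
        assert (combine_liebig(layers).cells == 0).all()

    def test_empty_layer_list_rejected(self, make_grid):
        with pytest.raises(ValueError):
            combine_liebig([])

    def test_incongruent_layers_rejected(self, make_grid):
        a = class_grid(make_grid, np.zeros((3, 3)))
        b = class_grid(make_grid, np.zeros((4, 4)))
        with pytest.raises(GridCongruenceError):
            combine_liebig([a, b])

    def test_nodata_policies(self, make_grid):
        a = class_grid(make_grid, [[1, CLASS_NODATA]])
        b = class_grid(make_grid, [[CLASS_NODATA, CLASS_NODATA]])
        ignore = combine_liebig([a, b], nodata_policy="ignore")
        assert ignore.cells.tolist() == [[1, CLASS_NODATA]]
        propagate = combine_liebig([a, b], nodata_policy="propagate")
        assert propagate.cells.tolist() == [[CLASS_NODATA, CLASS_NODATA]]

    def test_seven_random_layers_match_per_cell_oracle(self, make_grid):
        rng = np.random.default_rng(41)
        stacks = []
        for _ in range(7):
            cells = rng.integers(0, 4, size=(60, 60)).astype(np.uint8)
            cells[rng.random((60, 60)) < 0.05] = CLASS_NODATA
            stacks.append(cells)
        layers = [class_grid(make_grid, s) for s in stacks]
        for policy in ("ignore", "propagate"):
            got = combine_liebig(layers, nodata_policy=policy)
            np.testing.assert_array_equal(got.cells, brute_liebig(stacks, policy))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        data=st.lists(
            st.lists(st.integers(0, 3), min_size=6, max_size=6),
            min_size=2, max_size=5,
        ),
        perm_seed=st.integers(0, 1000),
    )
    def test_permutation_and_duplication_invariance(self, data, perm_seed):
        from palmrisk import Grid

        layers = [
            Grid(np.array(row, dtype=np.uint8).reshape(2, 3),
                 cell_size=1000.0, nodata=CLASS_NODATA)
            for row in data
        ]
        base = combine_liebig(layers).cells
        rng = np.random.default_rng(perm_seed)
        shuffled = [layers[i] for i in rng.permutation(len(layers))]
        np.testing.assert_array_equal(combine_liebig(shuffled).cells, base)
        np.testing.assert_array_equal(combine_liebig(layers + layers).cells, base)

    def test_liebig_dominance_and_monotone_shrinkage(self, make_grid):
        rng = np.random.default_rng(43)
        layers = [
            class_grid(make_grid, rng.integers(0, 4, size=(30, 30)).astype(np.uint8))
            for _ in range(5)
        ]
        combined = combine_liebig(layers)
        for lyr in layers:
            assert (combined.cells >= lyr.cells).all()
        # adding layers can only shrink the LOW area
        prev_low = (combine_liebig(layers[:1]).cells == 0).sum()
        for k in range(2, 6):
            low = (combine_liebig(layers[:k]).cells == 0).sum()
            assert low <= prev_low
            prev_low = low

    def test_combined_low_region_is_intersection_of_low_regions(self, make_grid):
        rng = np.random.default_rng(47)
        layers = [
            class_grid(make_grid, rng.integers(0, 4, size=(40, 40)).astype(np.uint8))
            for _ in range(4)
        ]
        combined_low = combine_liebig(layers).cells == 0
        intersection = np.logical_and.reduce([l.cells == 0 for l in layers])
        np.testing.assert_array_equal(combined_low, intersection)


class TestTabulate:
    def test_all_low_grid(self, make_grid):
        layer = class_grid(make_grid, np.zeros((10, 10)))
        layer.cell_size = 100.0  # 1 ha cells
        table = tabulate(layer, "uniform")
        assert table.area_ha[RiskClass.LOW] == pytest.approx(100.0)
        assert table.percent[RiskClass.LOW] == 100
        assert table.percent[RiskClass.VERY_HIGH] == 0

    def test_mixed_shares(self, make_grid):
        cells = np.array([0] * 20 + [2] * 10 + [3] * 70).reshape(10, 10)
        layer = class_grid(make_grid, cells)
        layer.cell_size = 100.0
        table = tabulate(layer)
        pct = table.percent
        assert (pct[RiskClass.LOW], pct[RiskClass.HIGH],
                pct[RiskClass.VERY_HIGH]) == (20, 10, 70)

    def test_counts_match_brute_histogram(self, make_grid):
        rng = np.random.default_rng(53)
        cells = rng.integers(0, 4, size=(45, 45)).astype(np.uint8)
        cells[rng.random((45, 45)) < 0.1] = CLASS_NODATA
        layer = class_grid(make_grid, cells)
        table = tabulate(layer)
        ref = brute_class_counts(cells)
        for cls in (RiskClass.LOW, RiskClass.MEDIUM, RiskClass.HIGH,
                    RiskClass.VERY_HIGH):
            assert table.area_ha[cls] == pytest.approx(
                ref[cls.rank] * layer.cell_area_ha
            )

    def test_area_conservation(self, make_grid):
        rng = np.random.default_rng(59)
        cells = rng.integers(0, 4, size=(33, 33)).astype(np.uint8)
        cells[rng.random((33, 33)) < 0.2] = CLASS_NODATA
        layer = class_grid(make_grid, cells)
        table = tabulate(layer)
        assert table.total_ha == pytest.approx(layer.total_mapped_area_ha())

    @pytest.mark.parametrize("x,expected", [(0.5, 1), (1.5, 2), (2.4, 2),
                                            (2.5, 3), (99.5, 100)])
    def test_rounding_is_half_up(self, x, expected):
        assert round_half_up(x) == expected


class TestCrossTabulate:
    def _zones(self, make_grid, codes, labels):
        return ZoneMap(grid=make_grid(np.asarray(codes)), zones=labels)

    def test_single_zone_reduces_to_tabulate(self, make_grid):
        rng = np.random.default_rng(61)
        cells = rng.integers(0, 4, size=(20, 20)).astype(np.uint8)
        rim = class_grid(make_grid, cells)
        zones = self._zones(make_grid, np.ones((20, 20), dtype=int), {1: "all"})
        [table] = cross_tabulate(rim, zones)
        ref = tabulate(rim)
        assert table.area_ha == ref.area_ha

    def test_zone_totals_partition_map_total(self, make_grid):
        rng = np.random.default_rng(67)
        cells = rng.integers(0, 4, size=(20, 20)).astype(np.uint8)
        rim = class_grid(make_grid, cells)
        codes = np.ones((20, 20), dtype=int)
        codes[:, 10:] = 2
        zones = self._zones(make_grid, codes, {1: "west", 2: "east"})
        tables = cross_tabulate(rim, zones)
        assert sum(t.total_ha for t in tables) == pytest.approx(
            tabulate(rim).total_ha
        )

    def test_random_inputs_match_joint_histogram_oracle(self, make_grid):
        rng = np.random.default_rng(71)
        cells = rng.integers(0, 4, size=(50, 50)).astype(np.uint8)
        cells[rng.random((50, 50)) < 0.1] = CLASS_NODATA
        rim = class_grid(make_grid, cells)
        codes = rng.integers(1, 5, size=(50, 50))
        zones = self._zones(make_grid, codes, {i: f"z{i}" for i in range(1, 5)})
        tables = {t.label: t for t in cross_tabulate(rim, zones)}
        joint = brute_joint_histogram(cells, codes)
        for (code, rank), count in joint.items():
            cls = RiskClass.from_rank(rank)
            assert tables[f"z{code}"].area_ha[cls] == pytest.approx(
                count * rim.cell_area_ha
            )

    def test_unknown_zone_code_rejected(self, make_grid):
        rim = class_grid(make_grid, np.zeros((3, 3)))
        zones = self._zones(make_grid, np.full((3, 3), 9), {1: "only"})
        with pytest.raises(UnknownZoneError, match="9"):
            cross_tabulate(rim, zones)

    def test_explicit_denominator_scales_percentages(self, make_grid):
        rim = class_grid(make_grid, np.zeros((10, 10)))
        zones = self._zones(make_grid, np.ones((10, 10), dtype=int), {1: "half"})
        [own] = cross_tabulate(rim, zones)
        [scaled] = cross_tabulate(rim, zones, denominator_ha=2 * own.total_ha)
        assert own.percent[RiskClass.LOW] == 100
        assert scaled.percent[RiskClass.LOW] == 50


class TestRankExpansionOptions:
    def _setup(self, make_grid, rim_cells, lup_codes, conc_codes):
        rim = class_grid(make_grid, rim_cells)
        lup = ZoneMap(
            grid=make_grid(np.asarray(lup_codes)),
            zones={1: "other use", 2: "conversion forest",
                   3: "production forest", 4: "protection forest"},
        )
        conc = ZoneMap(
            grid=make_grid(np.asarray(conc_codes)),
            zones={0: "none", 1: "active", 2: "inactive"},
        )
        return rim, lup, conc

    def test_all_very_high_gives_zero_everywhere(self, make_grid):
        rim, lup, conc = self._setup(
            make_grid, np.full((4, 4), 3), np.ones((4, 4), dtype=int),
            np.zeros((4, 4), dtype=int),
        )
        recs = rank_expansion_options(rim, lup, conc)
        assert all(r.low_risk_ha == 0 for r in recs.rows)

    def test_all_low_other_use_no_concessions(self, make_grid):
        rim, lup, conc = self._setup(
            make_grid, np.zeros((4, 4)), np.ones((4, 4), dtype=int),
            np.zeros((4, 4), dtype=int),
        )
        recs = rank_expansion_options(rim, lup, conc)
        by_zone = {r.zone_label: r.low_risk_ha for r in recs.rows}
        assert by_zone["other use"] == pytest.approx(rim.total_mapped_area_ha())
        assert by_zone["inactive concessions"] == 0
        assert by_zone["conversion forest"] == 0

    def test_priority_order_is_fixed(self, make_grid):
        rim, lup, conc = self._setup(
            make_grid, np.zeros((4, 4)), np.ones((4, 4), dtype=int),
            np.zeros((4, 4), dtype=int),
        )
        recs = rank_expansion_options(rim, lup, conc)
        assert [r.zone_label for r in recs.rows] == [
            "inactive concessions", "other use", "conversion forest",
            "production forest", "protection forest",
        ]
        assert [r.priority for r in recs.rows] == [1, 2, 3, 4, 5]

    def test_random_inputs_match_cross_tab_oracle(self, make_grid):
        rng = np.random.default_rng(73)
        rim_cells = rng.integers(0, 4, size=(30, 30)).astype(np.uint8)
        lup_codes = rng.integers(1, 5, size=(30, 30))
        conc_codes = rng.integers(0, 3, size=(30, 30))
        rim, lup, conc = self._setup(make_grid, rim_cells, lup_codes, conc_codes)
        recs = rank_expansion_options(rim, lup, conc)
        by_zone = {r.zone_label: r.low_risk_ha for r in recs.rows}

        low = rim_cells == 0
        inactive = conc_codes == 2
        outside = conc_codes == 0
        cell_ha = rim.cell_area_ha
        assert by_zone["inactive concessions"] == pytest.approx(
            (low & inactive).sum() * cell_ha
        )
        for code, label in lup.zones.items():
            expected = (low & outside & (lup_codes == code)).sum() * cell_ha
            assert by_zone[label] == pytest.approx(expected)

    def test_unknown_legal_label_rejected(self, make_grid):
        rim = class_grid(make_grid, np.zeros((2, 2)))
        lup = ZoneMap(grid=make_grid(np.ones((2, 2), dtype=int)),
                      zones={1: "wilderness"})
        conc = ZoneMap(grid=make_grid(np.zeros((2, 2), dtype=int)),
                       zones={0: "none"})
        with pytest.raises(UnknownZoneError, match="wilderness"):
            rank_expansion_options(rim, lup, conc)
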