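import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from luces.study import SUITABILITY_STRUCTURE, TOTAL_AREA_KM2
from luces.suitability import (
    ConsistencyError,
    SuitabilityAtlas,
    ahp_weights,
    build_atlas,
    composite_suitability,
    decode_composite,
    encode_composite,
    geometric_mean_matrix,
    score_criterion,
    suitability_area_table,
)


class TestAHP:
    def test_consistent_3x3_matrix_exact_solution(self):
        m = np.array([[1, 2, 4], [0.5, 1, 2], [0.25, 0.5, 1]])
        res = ahp_weights(m)
        assert np.allclose(res.weights, [4 / 7, 2 / 7, 1 / 7], atol=1e-9)
        assert res.lambda_max == pytest.approx(3.0, abs=1e-9)
        assert res.consistency_ratio == pytest.approx(0.0, abs=1e-9)
        assert res.consistent

    def test_all_ones_matrix_gives_equal_weights(self):
        res = ahp_weights(np.ones((5, 5)))
        assert np.allclose(res.weights, 0.2)
        assert res.consistency_ratio == pytest.approx(0.0, abs=1e-9)

    def test_any_2x2_reciprocal_matrix_is_consistent(self):
        res = ahp_weights(np.array([[1, 7], [1 / 7, 1]]))
        assert res.consistency_ratio == 0.0

    @given(st.lists(st.floats(0.1, 10.0), min_size=3, max_size=9))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_weights_of_perfectly_consistent_matrix_are_recovered(self, w):
        w = np.asarray(w) / np.sum(w)
        m = w[:, None] / w[None, :]
        res = ahp_weights(m)
        assert np.allclose(res.weights, w, atol=1e-9)
        assert res.consistency_ratio == pytest.approx(0.0, abs=1e-9)

    def test_inconsistent_matrix_is_flagged_not_fatal(self):
        # strong circular preference a > b > c > a
        m = np.array([[1, 5, 1 / 5], [1 / 5, 1, 5], [5, 1 / 5, 1]])
        res = ahp_weights(m)
        assert res.consistency_ratio >= 0.1
        assert not res.consistent

    def test_non_reciprocal_matrix_rejected(self):
        with pytest.raises(ConsistencyError, match="reciprocal"):
            ahp_weights(np.array([[1, 2], [2, 1]]))

    def test_non_positive_matrix_rejected(self):
        with pytest.raises(ConsistencyError, match="positive"):
            ahp_weights(np.array([[1, 0], [np.inf, 1]]))

    def test_geometric_mean_preserves_reciprocity(self):
        a = np.array([[1, 2], [0.5, 1]])
        b = np.array([[1, 8], [0.125, 1]])
        g = geometric_mean_matrix([a, b])
        assert np.allclose(g * g.T, 1.0)
        assert g[0, 1] == pytest.approx(4.0)  # geometric mean of 2 and 8


class TestScoreCriterion:
    def test_interval_lookup(self):
        grades = score_criterion(np.array([10.0]), (5.0, 15.0, 25.0), (4, 3, 2, 1))
        assert grades[0] == 3

    def test_value_at_breakpoint_goes_to_upper_interval(self):
        grades = score_criterion(np.array([5.0, 15.0, 25.0]), (5.0, 15.0, 25.0), (4, 3, 2, 1))
        assert list(grades) == [3, 2, 1]

    def test_constant_raster_constant_grades(self):
        grades = score_criterion(np.full((4, 4), 7.0), (5.0,), (4, 2))
        assert np.all(grades == 2)

    def test_nan_cells_stay_nan(self):
        grades = score_criterion(np.array([np.nan, 1.0]), (5.0,), (4, 2))
        assert np.isnan(grades[0]) and grades[1] == 4

    def test_non_monotone_breakpoints_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            score_criterion(np.zeros(2), (5.0, 5.0), (4, 3, 2))


class TestComposite:
    def test_all_grade_4_scores_one(self):
        score, grade = composite_suitability([np.full((3, 3), 4.0)], [1.0])
        assert np.all(score == 1.0) and np.all(grade == 4)

    def test_all_grade_1_scores_zero_and_grades_worst(self):
        score, grade = composite_suitability([np.full((3, 3), 1.0)], [1.0])
        assert np.all(score == 0.0) and np.all(grade == 1)

    def test_weighted_sum_example(self):
        score, grade = composite_suitability(
            [np.full((2, 2), 4.0), np.full((2, 2), 1.0)], [0.75, 0.25]
        )
        assert np.all(score == pytest.approx(0.75))
        assert np.all(grade == 4)

    def test_exclusion_mask_forces_worst_grade(self):
        mask = np.array([[True, False]])
        _, grade = composite_suitability([np.full((1, 2), 4.0)], [1.0], exclusion_mask=mask)
        assert list(grade[0]) == [1, 4]

    def test_weight_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            composite_suitability([np.zeros((2, 2))], [0.5, 0.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_improving_one_criterion_never_lowers_the_grade(self, seed):
        rng = np.random.default_rng(seed)
        grades = [rng.integers(1, 5, size=(8, 8)).astype(float) for _ in range(3)]
        w = rng.random(3) + 0.1
        _, before = composite_suitability(grades, w)
        for k in range(3):
            improved = [g.copy() for g in grades]
            improved[k] = np.minimum(improved[k] + 1, 4.0)
            _, after = composite_suitability(improved, w)
            assert np.all(after >= before)


class TestAreaTable:
    def _atlas(self, grade_map):
        atlas = SuitabilityAtlas(cell_size=1000.0)  # 1 km cells -> 1 km² each
        atlas.add("CL", np.zeros_like(grade_map, dtype=float), grade_map)
        return atlas

    def test_hand_counted_grades(self):
        grades = np.array([[4, 4, 3], [2, 1, 4]], dtype=float)
        table = suitability_area_table(self._atlas(grades))
        assert table.loc["appropriate", "CL"] == pytest.approx(3.0)
        assert table.loc["relatively_appropriate", "CL"] == pytest.approx(1.0)
        assert table.loc["inappropriate", "CL"] == pytest.approx(2.0)
        assert table.loc["suitable_total", "CL"] == pytest.approx(4.0)

    def test_all_grade_4_everything_appropriate(self):
        table = suitability_area_table(self._atlas(np.full((5, 5), 4.0)))
        assert table.loc["appropriate", "CL"] == pytest.approx(25.0)
        assert table.loc["inappropriate", "CL"] == 0

    def test_published_structure_suitable_total_and_conservation(self):
        """The published district table: cropland suitable area sums to
        514.36 km² and every class column conserves the 1454.88 km² total."""
        import pandas as pd

        table = pd.DataFrame(SUITABILITY_STRUCTURE)
        suitable_cl = table.loc["appropriate", "CL"] + table.loc["relatively_appropriate", "CL"]
        assert suitable_cl == pytest.approx(514.36)
        assert np.allclose(table.sum(axis=0), TOTAL_AREA_KM2)


class TestCompositeCode:
    def _atlas_with(self, grades_by_class):
        atlas = SuitabilityAtlas(cell_size=30.0)
        for label, g in grades_by_class.items():
            g = np.asarray(g, dtype=float)
            atlas.add(label, np.zeros_like(g), g)
        return atlas

    def test_digit_assembly(self):
        atlas = self._atlas_with({
            "CL": [[4.0]], "OC": [[3.0]], "FL": [[4.0]], "GL": [[4.0]], "SL": [[4.0]],
        })
        assert encode_composite(atlas)[0, 0] == 43444

    def test_all_four_cell(self):
        atlas = self._atlas_with({c: [[4.0]] for c in ("CL", "OC", "FL", "GL", "SL")})
        assert encode_composite(atlas)[0, 0] == 44444

    @given(st.tuples(*[st.integers(1, 4) for _ in range(5)]))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_decode_encode_round_trip(self, grades):
        atlas = self._atlas_with(
            dict(zip(("CL", "OC", "FL", "GL", "SL"), [[[float(g)]] for g in grades]))
        )
        decoded = decode_composite(encode_composite(atlas))
        for label, g in zip(("CL", "OC", "FL", "GL", "SL"), grades):
            assert decoded[label][0, 0] == g

    def test_missing_class_rejected(self):
        atlas = self._atlas_with({"CL": [[4.0]]})
        with pytest.raises(KeyError, match="OC"):
            encode_composite(atlas)


class TestBuildAtlas:
    def test_steep_slope_excludes_cropland(self, terrain_small):
        layers = {
            "slope": terrain_small["slope"].values,
            "elevation": terrain_small["dem"].values,
            "ph": terrain_small["ph"].values,
        }
        atlas = build_atlas(layers, cell_size=30.0)
        steep = layers["slope"] >= 25.0
        if steep.any():
            assert np.all(atlas.grades["CL"][steep] == 1)

    def test_scores_stay_in_unit_interval(self, terrain_small):
        layers = {
            "slope": terrain_small["slope"].values,
            "elevation": terrain_small["dem"].values,
            "ph": terrain_small["ph"].values,
        }
        atlas = build_atlas(layers, cell_size=30.0)
        for label, score in atlas.scores.items():
            assert np.nanmin(score) >= 0 and np.nanmax(score) <= 1
            assert set(np.unique(atlas.grades[label])) <= {1.0, 2.0, 3.0, 4.0}
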