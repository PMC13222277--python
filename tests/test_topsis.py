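"""Fuzzy TOPSIS: decision matrix, normalization, weighting, ideals, closeness."""

import numpy as np
import pytest

from panelrank import (
    INVOLVEMENT_SCALE,
    RELEVANCE_SCALE,
    TriangularFuzzyNumber as TFN,
    apply_weights,
    build_decision_matrix,
    closeness,
    ideal_solutions,
    normalize_benefit,
    normalize_weights,
    rank_criteria,
    vertex_distance,
)
from panelrank.topsis import FuzzyDecisionMatrix, weights_from_panel

from conftest import make_panel, random_panel


def matrix_from(cells, dimension="relevance"):
    """Matrix from a nested list of (l, m, u) tuples, rows = criteria."""
    values = np.asarray(cells, dtype=float)
    m, n = values.shape[:2]
    return FuzzyDecisionMatrix(
        dimension,
        tuple(f"C{i + 1}" for i in range(m)),
        tuple(f"E{j + 1}" for j in range(n)),
        values,
    )


class TestDecisionMatrix:
    def test_cells_are_scale_tfns(self):
        p = make_panel(
            {
                "C1": {"relevance": [5, 5], "applicability": [5, 5]},
                "C2": {"relevance": [4, 5], "applicability": [5, 5]},
            }
        )
        mat = build_decision_matrix(p, ["C1", "C2"], "relevance", RELEVANCE_SCALE)
        assert mat.shape == (2, 2)
        assert tuple(mat.values[0, 0]) == (7, 9, 9)
        assert tuple(mat.values[1, 0]) == (5, 7, 9)

    def test_empty_retained_set_rejected(self, two_expert_panel):
        with pytest.raises(ValueError, match="empty"):
            build_decision_matrix(two_expert_panel, [], "relevance", RELEVANCE_SCALE)

    def test_unknown_codes_rejected(self, two_expert_panel):
        with pytest.raises(ValueError, match="C99"):
            build_decision_matrix(two_expert_panel, ["C1", "C99"], "relevance", RELEVANCE_SCALE)

    def test_misordered_cells_rejected(self):
        with pytest.raises(ValueError, match="l <= m <= u"):
            matrix_from([[(3, 2, 4)]])


class TestNormalization:
    def test_column_divided_by_max_upper(self):
        mat = matrix_from([[(3, 5, 7)], [(5, 7, 9)]])
        r = normalize_benefit(mat)
        assert r.values[0, 0] == pytest.approx([3 / 9, 5 / 9, 7 / 9])
        assert r.values[1, 0] == pytest.approx([5 / 9, 7 / 9, 1.0])

    def test_single_row_column(self):
        r = normalize_benefit(matrix_from([[(7, 9, 9)]]))
        assert r.values[0, 0] == pytest.approx([7 / 9, 1.0, 1.0])

    def test_identical_column_normalizes_upper_to_one(self):
        mat = matrix_from([[(3, 5, 7)], [(3, 5, 7)]])
        r = normalize_benefit(mat)
        assert np.allclose(r.values[:, 0, 2], 1.0)
        assert np.allclose(r.values[0], r.values[1])


class TestWeights:
    def test_uniform_panel_gives_equal_weights(self):
        w = normalize_weights([TFN(5, 7, 9)] * 4)
        assert np.allclose(w.normalized, 0.25)

    def test_two_expert_hand_oracle(self):
        # component sums (8, 12, 14)
        w = normalize_weights([TFN(7, 9, 9), TFN(1, 3, 5)])
        assert w.normalized[0] == pytest.approx([7 / 8, 9 / 12, 9 / 14])
        assert w.normalized[1] == pytest.approx([1 / 8, 3 / 12, 5 / 14])

    def test_single_expert_weight_is_unity(self):
        w = normalize_weights([TFN(3, 5, 7)])
        assert w.normalized[0] == pytest.approx([1.0, 1.0, 1.0])

    def test_component_families_sum_to_one(self):
        rng = np.random.default_rng(0)
        levels = rng.integers(1, 6, 25)
        tfns = [INVOLVEMENT_SCALE[int(lv)] for lv in levels]
        w = normalize_weights(tfns)
        assert np.allclose(w.normalized.sum(axis=0), 1.0, atol=1e-12)


class TestApplyWeights:
    def test_single_expert_identity_weight_leaves_matrix_unchanged(self):
        mat = normalize_benefit(matrix_from([[(3, 5, 7)], [(5, 7, 9)]]))
        w = normalize_weights([TFN(3, 5, 7)])
        out = apply_weights(mat, w)
        assert np.allclose(out.values, mat.values)

    def test_uniform_panel_scales_by_reciprocal_count(self):
        mat = normalize_benefit(
            matrix_from([[(3, 5, 7), (3, 5, 7), (3, 5, 7)], [(5, 7, 9), (5, 7, 9), (5, 7, 9)]])
        )
        w = normalize_weights([TFN(5, 7, 9)] * 3)
        out = apply_weights(mat, w)
        assert np.allclose(out.values, mat.values / 3.0)

    def test_skewed_weights_reordered_cells_stay_valid(self):
        # a dominant specialist makes the normalized triple decreasing (l' > u')
        p = make_panel(
            {
                "C1": {"relevance": [5, 2, 2], "applicability": [3, 3, 3]},
                "C2": {"relevance": [1, 4, 3], "applicability": [3, 3, 3]},
            },
            involvement=[5, 2, 2],
        )
        mat = normalize_benefit(build_decision_matrix(p, ["C1", "C2"], "relevance", RELEVANCE_SCALE))
        w = weights_from_panel(p)
        assert w.normalized[0, 0] > w.normalized[0, 2]  # mis-ordered weight triple
        out = apply_weights(mat, w)
        assert np.all(out.values[..., 0] <= out.values[..., 1])
        assert np.all(out.values[..., 1] <= out.values[..., 2])

    def test_dimension_mismatch_rejected(self):
        mat = matrix_from([[(1, 2, 3), (1, 2, 3)]])
        with pytest.raises(ValueError, match="does not match"):
            apply_weights(mat, normalize_weights([TFN(1, 1, 1)]))


class TestIdealSolutions:
    def test_per_column_max_u_min_l(self):
        mat = matrix_from([[(0.1, 0.2, 0.3)], [(0.2, 0.4, 0.6)]])
        ideals = ideal_solutions(mat, "per_column")
        assert ideals.a_plus[0] == pytest.approx([0.6, 0.6, 0.6])
        assert ideals.a_minus[0] == pytest.approx([0.1, 0.1, 0.1])

    def test_chen_fixed_anchors(self):
        mat = matrix_from([[(0.1, 0.2, 0.3), (0.2, 0.3, 0.4)]])
        ideals = ideal_solutions(mat, "chen_fixed")
        assert np.all(ideals.a_plus == 1.0)
        assert np.all(ideals.a_minus == 0.0)

    def test_single_row_matrix(self):
        mat = matrix_from([[(0.2, 0.5, 0.8)]])
        ideals = ideal_solutions(mat, "per_column")
        assert ideals.a_plus[0] == pytest.approx([0.8, 0.8, 0.8])
        assert ideals.a_minus[0] == pytest.approx([0.2, 0.2, 0.2])

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError, match="convention"):
            ideal_solutions(matrix_from([[(0, 0, 0)]]), "nope")


class TestCloseness:
    def test_rows_at_the_ideals_hit_the_cc_bounds(self):
        mat = matrix_from([[(1, 1, 1)], [(0, 0, 0)], [(0.3, 0.5, 0.7)]])
        res = closeness(mat, ideal_solutions(mat, "chen_fixed"))
        assert res.table.loc["C1", "cc"] == pytest.approx(1.0)
        assert res.table.loc["C2", "cc"] == pytest.approx(0.0)
        assert 0 < res.table.loc["C3", "cc"] < 1

    def test_symmetric_pair_cc_sums_to_one(self):
        mat = matrix_from([[(0.25, 0.25, 0.25)], [(0.75, 0.75, 0.75)]])
        res = closeness(mat, ideal_solutions(mat, "chen_fixed"))
        assert res.table.loc["C1", "cc"] == pytest.approx(0.25)
        assert res.table.loc["C2", "cc"] == pytest.approx(0.75)

    def test_degenerate_coincident_ideals_rejected(self):
        mat = matrix_from([[(0.5, 0.5, 0.5)]])
        with pytest.raises(ValueError, match="D\\+ \\+ D-"):
            closeness(mat, ideal_solutions(mat, "per_column"))

    def test_distance_sums_match_naive_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            values = np.sort(rng.uniform(0, 1, size=(4, 3, 3)), axis=2)
            mat = matrix_from(values)
            ideals = ideal_solutions(mat, "per_column")
            res = closeness(mat, ideals)
            for i, code in enumerate(mat.criteria):
                d_plus = sum(
                    vertex_distance(TFN(*values[i, j]), TFN(*ideals.a_plus[j]))
                    for j in range(3)
                )
                d_minus = sum(
                    vertex_distance(TFN(*values[i, j]), TFN(*ideals.a_minus[j]))
                    for j in range(3)
                )
                assert res.table.loc[code, "d_plus"] == pytest.approx(d_plus, abs=1e-12)
                assert res.table.loc[code, "d_minus"] == pytest.approx(d_minus, abs=1e-12)


class TestEndToEndProperties:
    def test_duplicate_rating_rows_get_equal_cc_and_code_tiebreak(self):
        p = make_panel(
            {
                "C1": {"relevance": [4, 3, 5], "applicability": [3, 3, 3]},
                "C2": {"relevance": [4, 3, 5], "applicability": [3, 3, 3]},
                "C3": {"relevance": [2, 2, 1], "applicability": [3, 3, 3]},
            },
            involvement=[5, 3, 4],
        )
        res = rank_criteria(p, ["C1", "C2", "C3"], "relevance", RELEVANCE_SCALE)
        assert res.table.loc["C1", "cc"] == pytest.approx(res.table.loc["C2", "cc"], abs=1e-15)
        assert res.table.loc["C1", "rank"] == 1
        assert res.table.loc["C2", "rank"] == 2

    def test_expert_permutation_invariance(self):
        rng = np.random.default_rng(3)
        p = random_panel(rng, 5, 6)
        codes = p.criteria
        base = rank_criteria(p, codes, "relevance", RELEVANCE_SCALE)
        perm = list(rng.permutation(p.n_experts))
        experts = p.experts.iloc[perm].reset_index(drop=True)
        shuffled = type(p)(experts, p.ratings.copy())
        res = rank_criteria(shuffled, codes, "relevance", RELEVANCE_SCALE)
        for c in codes:
            assert res.table.loc[c, "cc"] == pytest.approx(base.table.loc[c, "cc"], abs=1e-12)

    def test_monotone_in_rating_under_fixed_ideals_single_expert(self):
        # chen_fixed anchors do not move when a rating changes, so raising a
        # rating must strictly raise that criterion's closeness coefficient
        for level in (1, 2, 3, 4):
            low = make_panel(
                {
                    "C1": {"relevance": [level, level], "applicability": [3, 3]},
                    "C2": {"relevance": [3, 3], "applicability": [3, 3]},
                },
                involvement=[3, 3],
            )
            high = make_panel(
                {
                    "C1": {"relevance": [level + 1, level + 1], "applicability": [3, 3]},
                    "C2": {"relevance": [3, 3], "applicability": [3, 3]},
                },
                involvement=[3, 3],
            )
            cc_low = rank_criteria(low, ["C1", "C2"], "relevance", RELEVANCE_SCALE,
                                   convention="chen_fixed").table.loc["C1", "cc"]
            cc_high = rank_criteria(high, ["C1", "C2"], "relevance", RELEVANCE_SCALE,
                                    convention="chen_fixed").table.loc["C1", "cc"]
            assert cc_high > cc_low

    @pytest.mark.parametrize("convention", ["per_column", "chen_fixed"])
    def test_cc_bounded_on_random_panels(self, convention):
        rng = np.random.default_rng(17)
        for _ in range(60):
            p = random_panel(rng, int(rng.integers(2, 6)), int(rng.integers(2, 7)))
            res = rank_criteria(p, p.criteria, "relevance", RELEVANCE_SCALE,
                                convention=convention)
            cc = res.table["cc"].to_numpy()
            assert np.all((cc >= 0) & (cc <= 1))
            assert sorted(res.table["rank"]) == list(range(1, len(cc) + 1))
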