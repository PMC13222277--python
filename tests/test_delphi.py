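"""Fuzzy Delphi aggregation, cut-off and quadrant screening."""

import itertools
import math

import numpy as np
import pytest

from panelrank import (
    DEFAULT_SCALES,
    RELEVANCE_SCALE,
    aggregate_panel,
    compute_cutoff,
    screen_criteria,
    screen_panel,
    tfn_from_likert,
)
from panelrank.delphi import aggregate_all

from conftest import make_panel


def panel_of(ratings_rel, involvement=None):
    """Single-criterion panel with the given relevance ratings."""
    return make_panel(
        {"C1": {"relevance": list(ratings_rel), "applicability": [3] * len(ratings_rel)}},
        involvement,
    )


class TestAggregation:
    def test_unanimous_top_rating_reproduces_scale_tfn(self):
        p = panel_of([5] * 25)
        r = aggregate_panel(p, "C1", "relevance", RELEVANCE_SCALE)
        assert r.aggregate.astuple() == (7, 9, 9)
        assert r.g == pytest.approx(25 / 3, abs=1e-9)

    def test_mixed_ratings_min_geomean_max(self):
        # levels {3,4,5} map to modes {5,7,9}: aggregate (3, 315^(1/3), 9)
        p = panel_of([3, 4, 5])
        r = aggregate_panel(p, "C1", "relevance", RELEVANCE_SCALE)
        assert r.aggregate.l == 3
        assert r.aggregate.u == 9
        assert r.aggregate.m == pytest.approx(315 ** (1 / 3), rel=1e-12)
        assert r.g == pytest.approx((3 + 315 ** (1 / 3) + 9) / 3, abs=1e-9)
        assert r.g == pytest.approx(6.2680, abs=1e-4)

    def test_unanimous_bottom_rating(self):
        r = aggregate_panel(panel_of([1, 1, 1]), "C1", "relevance", RELEVANCE_SCALE)
        assert r.aggregate.astuple() == (1, 1, 1)
        assert r.g == 1.0

    def test_single_expert_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            aggregate_panel(panel_of([4]), "C1", "relevance", RELEVANCE_SCALE)

    def test_incomplete_panel_lists_missing_cells(self):
        p = panel_of([4, 5, 3])
        p.ratings = p.ratings[
            ~((p.ratings["expert_id"] == "E02") & (p.ratings["dimension"] == "relevance"))
        ]
        with pytest.raises(ValueError, match="E02"):
            aggregate_panel(p, "C1", "relevance", RELEVANCE_SCALE)

    @pytest.mark.parametrize("ratings", list(itertools.product([1, 3, 5], repeat=3))[:12])
    def test_agrees_with_enumeration_oracle(self, ratings):
        """Independent oracle: map each rating, take min/geomean/max by hand."""
        mapped = [tfn_from_likert(r, RELEVANCE_SCALE) for r in ratings]
        lo = min(t.l for t in mapped)
        hi = max(t.u for t in mapped)
        mode = math.prod(t.m for t in mapped) ** (1 / len(mapped))
        r = aggregate_panel(panel_of(ratings), "C1", "relevance", RELEVANCE_SCALE)
        assert r.aggregate.l == lo
        assert r.aggregate.u == hi
        assert r.aggregate.m == pytest.approx(mode, rel=1e-9)
        assert r.g == pytest.approx((lo + mode + hi) / 3, rel=1e-9)

    def test_expert_permutation_invariance(self):
        rng = np.random.default_rng(42)
        ratings = list(rng.integers(1, 6, 10))
        base = aggregate_panel(panel_of(ratings), "C1", "relevance", RELEVANCE_SCALE)
        for _ in range(5):
            rng.shuffle(ratings)
            perm = aggregate_panel(panel_of(ratings), "C1", "relevance", RELEVANCE_SCALE)
            assert perm.aggregate == base.aggregate
            assert perm.g == pytest.approx(base.g, abs=1e-12)

    def test_monotone_in_any_single_rating(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            ratings = list(rng.integers(1, 5, 6))  # leave headroom to raise
            i = int(rng.integers(0, 6))
            lo = aggregate_panel(panel_of(ratings), "C1", "relevance", RELEVANCE_SCALE)
            raised = list(ratings)
            raised[i] += 1
            hi = aggregate_panel(panel_of(raised), "C1", "relevance", RELEVANCE_SCALE)
            assert hi.aggregate.m >= lo.aggregate.m - 1e-12
            assert hi.aggregate.u >= lo.aggregate.u
            assert hi.aggregate.l <= lo.aggregate.l
            assert hi.g >= lo.g - 1e-12


class TestCutoff:
    def test_two_point_mean(self):
        assert compute_cutoff([4.0, 6.0]) == pytest.approx(5.0)

    def test_constant_list(self):
        assert compute_cutoff([5.5] * 9) == pytest.approx(5.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_cutoff([])


class TestScreening:
    def test_quadrant_decisions(self):
        g_rel = {"A": 7.0, "B": 5.0, "C": 7.0, "D": 5.0}
        g_app = {"A": 6.0, "B": 6.0, "C": 4.0, "D": 4.0}
        out = screen_criteria(g_rel, g_app, 6.0, 5.0)
        assert out.table.loc["A", "quadrant"] == "Q1"
        assert out.table.loc["B", "quadrant"] == "Q2"
        assert out.table.loc["C", "quadrant"] == "Q4"
        assert out.table.loc["D", "quadrant"] == "Q3"
        assert out.retained_q1 == ["A"]
        assert set(out.retained_with_caution) == {"B", "C"}
        assert out.excluded == ["D"]
        assert set(out.retained) == {"A", "B", "C"}

    def test_exact_tie_at_both_cutoffs_is_excluded(self):
        out = screen_criteria({"X": 6.0, "Y": 7.0}, {"X": 5.0, "Y": 6.0}, 6.0, 5.0)
        assert out.table.loc["X", "quadrant"] == "Q3"
        assert out.table.loc["X", "decision"] == "exclude"

    def test_mismatched_criterion_sets_rejected(self):
        with pytest.raises(ValueError, match="different criteria"):
            screen_criteria({"A": 6.0}, {"B": 6.0}, 5.0, 5.0)

    def test_screen_panel_end_to_end_alpha_is_mean_of_g(self, two_expert_panel):
        results, out = screen_panel(two_expert_panel, ["C1", "C2"], DEFAULT_SCALES)
        gs = [r.g for r in results["relevance"]]
        assert out.alpha_relevance == pytest.approx(np.mean(gs), abs=1e-12)
        # with two criteria the higher one is above the mean, the lower below
        assert out.table.loc["C1", "g_relevance"] > out.table.loc["C2", "g_relevance"]

    def test_aggregate_all_requires_complete_panel(self, two_expert_panel):
        with pytest.raises(ValueError, match="missing rating"):
            aggregate_all(two_expert_panel, ["C1", "C2", "C3"], "relevance", RELEVANCE_SCALE)
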