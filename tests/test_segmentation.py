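"""Log-score curve construction, 3-segment fitting, and selection."""

import numpy as np
import pytest

from fealect import (
    RunConfig,
    ScoreTable,
    build_curve,
    fit_three_segment,
    select_informative,
)
from fealect.segmentation import MIN_SEGMENT, ScoreCurve, _fit_pair


def table_from_scores(scores):
    scores = np.asarray(scores, dtype=float)
    return ScoreTable(
        scores=scores,
        feature_names=tuple(f"f{j}" for j in range(len(scores))),
        per_bootstrap_sizes=(1,),
        config=RunConfig(m=1),
    )


def piecewise_curve(L, k1, k2, alpha, beta, dl, cl, dr, cr):
    """Noise-free quadratic–linear–quadratic curve, continuous at the
    half-integer knots, expressed in the same family the fitter searches."""
    x = np.arange(1, L + 1, dtype=float)
    t1, t2 = k1 + 0.5, k2 + 0.5
    left = np.where(x < t1, x - t1, 0.0)
    right = np.where(x > t2, x - t2, 0.0)
    return x, alpha + beta * x + dl * left + cl * left**2 + dr * right + cr * right**2


def brute_force_best_pair(y):
    """Independent per-pair least squares over every admissible knot pair."""
    L = len(y)
    x = np.arange(1, L + 1, dtype=float)
    best = None
    for k1 in range(MIN_SEGMENT, L - 2 * MIN_SEGMENT + 1):
        for k2 in range(k1 + MIN_SEGMENT, L - MIN_SEGMENT + 1):
            _, sse = _fit_pair(x, y, k1, k2)
            if best is None or sse < best[0] - 1e-12:
                best = (sse, k1, k2)
    return best


class TestBuildCurve:
    def test_log_of_known_scores(self):
        scores = [np.e, np.e**2, np.e**3] + [30 + i for i in range(6)]
        curve = build_curve(table_from_scores(scores))
        assert curve.log_scores[0] == pytest.approx(1.0)
        assert curve.log_scores[1] == pytest.approx(2.0)
        assert curve.log_scores[2] == pytest.approx(3.0)
        assert np.all(np.diff(curve.log_scores) >= 0)

    def test_constant_scores_give_flat_curve(self):
        curve = build_curve(table_from_scores(np.full(10, 2.0)))
        np.testing.assert_allclose(curve.log_scores, np.log(2.0))

    def test_zero_scores_excluded_and_counted(self):
        scores = np.concatenate([np.zeros(4), np.arange(1.0, 11.0)])
        curve = build_curve(table_from_scores(scores))
        assert curve.n_zero == 4
        assert len(curve) + curve.n_zero == 14

    def test_fewer_than_nine_positive_is_an_error(self):
        with pytest.raises(ValueError, match="at least 9"):
            build_curve(table_from_scores(np.concatenate([np.zeros(5), np.ones(8)])))

    def test_ties_ordered_by_feature_index(self):
        scores = np.array([2.0, 1.0, 2.0, 1.0, 3, 4, 5, 6, 7, 8])
        curve = build_curve(table_from_scores(scores))
        assert list(curve.feature_ids[:4]) == [1, 3, 0, 2]


class TestFitThreeSegment:
    @pytest.mark.parametrize(
        "L,k1,k2,params",
        [
            (40, 10, 30, (0.5, 0.05, -0.3, 0.08, 0.4, 0.25)),
            (25, 5, 18, (-1.0, 0.1, 0.2, 0.05, -0.1, 0.3)),
            (60, 20, 40, (0.0, 0.02, -0.5, 0.02, 0.1, 0.1)),
        ],
    )
    def test_recovers_constructed_knots_exactly(self, L, k1, k2, params):
        x, y = piecewise_curve(L, k1, k2, *params)
        curve = ScoreCurve(log_scores=y, feature_ids=np.arange(L), n_zero=0)
        fit = fit_three_segment(curve)
        assert fit.knots == (k1, k2)
        assert fit.sse < 1e-12
        np.testing.assert_allclose(fit.predict(x), y, atol=1e-8)

    def test_perfect_line_fit_has_no_curvature(self):
        y = 0.3 * np.arange(1, 21) - 2.0
        curve = ScoreCurve(log_scores=y.astype(float), feature_ids=np.arange(20), n_zero=0)
        fit = fit_three_segment(curve)
        assert fit.coefficients["g2"][1] == pytest.approx(0.3, abs=1e-9)
        assert abs(fit.coefficients["g1"][2]) < 1e-9
        assert abs(fit.coefficients["g3"][2]) < 1e-9
        assert fit.sse < 1e-12

    def test_knot_search_matches_brute_force(self, rng):
        for L in (9, 12, 15):
            for _ in range(5):
                y = np.sort(rng.standard_normal(L)).cumsum()
                y.sort()
                curve = ScoreCurve(log_scores=y, feature_ids=np.arange(L), n_zero=0)
                fit = fit_three_segment(curve)
                sse_b, k1_b, k2_b = brute_force_best_pair(y)
                assert fit.sse <= sse_b + 1e-9
                _, sse_at_found = _fit_pair(
                    np.arange(1, L + 1, dtype=float), y, *fit.knots
                )
                assert sse_at_found == pytest.approx(sse_b, abs=1e-9)

    def test_continuity_at_both_knots(self, rng):
        y = np.sort(rng.standard_normal(30)).cumsum()
        y.sort()
        curve = ScoreCurve(log_scores=y, feature_ids=np.arange(30), n_zero=0)
        fit = fit_three_segment(curve)
        k1, k2 = fit.knots
        for t in (k1 + 0.5, k2 + 0.5):
            below = fit.predict(np.array([t - 1e-9]))[0]
            above = fit.predict(np.array([t + 1e-9]))[0]
            assert below == pytest.approx(above, abs=1e-6)

    def test_scale_invariance_of_knots_and_selection(self):
        x, y = piecewise_curve(40, 10, 30, 0.5, 0.05, -0.3, 0.08, 0.4, 0.25)
        base = table_from_scores(np.exp(y))
        scaled = table_from_scores(17.0 * np.exp(y))
        fit_a = fit_three_segment(build_curve(base))
        fit_b = fit_three_segment(build_curve(scaled))
        assert fit_a.knots == fit_b.knots
        sel_a = select_informative(base, fit_a)
        sel_b = select_informative(scaled, fit_b)
        assert sel_a.selected_ids == sel_b.selected_ids


class TestSelectInformative:
    def _fit_and_select(self, scores):
        table = table_from_scores(scores)
        fit = fit_three_segment(build_curve(table))
        return table, fit, select_informative(table, fit)

    def test_selection_is_upper_order_ideal(self):
        x, y = piecewise_curve(40, 10, 30, 0.5, 0.05, -0.3, 0.08, 0.4, 0.25)
        table, fit, sel = self._fit_and_select(np.exp(y))
        selected = set(sel.selected_ids)
        unselected = [j for j in range(40) if j not in selected and table.scores[j] > 0]
        assert min(table.scores[list(selected)]) > max(table.scores[unselected])

    def test_upper_knot_at_last_admissible_selects_minimum_tail(self):
        # strong bend only in the last 3 points forces k2 = L - 3
        x, y = piecewise_curve(20, 10, 17, 0.0, 0.01, 0.0, 0.0, 2.0, 3.0)
        table, fit, sel = self._fit_and_select(np.exp(y))
        assert fit.knots[1] == 17
        assert sel.selected_ids == (17, 18, 19)
        assert len(sel.selected_ids) == MIN_SEGMENT

    def test_segment_counts_sum_to_curve_length(self):
        x, y = piecewise_curve(25, 5, 18, -1.0, 0.1, 0.2, 0.05, -0.1, 0.3)
        table, fit, sel = self._fit_and_select(np.exp(y))
        assert sum(sel.segment_counts) == 25
        assert sel.threshold_score == pytest.approx(np.exp(y[fit.knots[1] - 1]))

    def test_adding_a_clearly_informative_feature_keeps_selection(self):
        # extend the curve by one more point on the same generating g3:
        # identical shape, one extra high scorer (params keep the curve
        # monotone so the score sort preserves the constructed shape)
        params = (0.5, 0.05, 0.0, -0.05, 0.1, 0.05)
        _, y40 = piecewise_curve(40, 10, 30, *params)
        _, y41 = piecewise_curve(41, 10, 30, *params)
        _, fit1, sel1 = self._fit_and_select(np.exp(y40))
        _, fit2, sel2 = self._fit_and_select(np.exp(y41))
        assert fit1.knots == fit2.knots == (10, 30)
        assert set(sel1.selected_ids) <= set(sel2.selected_ids)

    def test_mismatched_fit_rejected(self):
        x, y = piecewise_curve(40, 10, 30, 0.5, 0.05, -0.3, 0.08, 0.4, 0.25)
        table = table_from_scores(np.exp(y))
        fit = fit_three_segment(build_curve(table))
        other = table_from_scores(np.exp(y[:30]))
        with pytest.raises(ValueError, match="curve"):
            select_informative(other, fit)
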