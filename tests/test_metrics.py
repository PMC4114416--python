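"""Validation metrics and survey statistics, with worked-example
arithmetic, a maximum-bipartite-matching oracle, closed-form alpha
recovery and Monte-Carlo null checks."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import linear_sum_assignment

from coughspot.errors import InputError, UndefinedMetricError
from coughspot.metrics import (
    EventLabelSet,
    MatchResult,
    SurveyResponse,
    cronbach_alpha,
    fp_per_hour,
    item_agreement,
    item_correlation,
    match_events,
    percent_agreement,
    responses_to_matrix,
    score_survey,
    sensitivity,
)
from coughspot.synthetic import synth_survey


def max_matching_size(det_mids, tru_mids, tol):
    """Oracle: maximum-cardinality one-to-one matching via assignment."""
    if not det_mids or not tru_mids:
        return 0
    cost = np.ones((len(det_mids), len(tru_mids)))
    for i, d in enumerate(det_mids):
        for j, t in enumerate(tru_mids):
            if abs(d - t) <= tol:
                cost[i, j] = 0.0
    ri, cj = linear_sum_assignment(cost)
    return int(np.sum(cost[ri, cj] == 0.0))


class TestMatchEvents:
    def test_identity_all_matched(self):
        truth = EventLabelSet([(1.0, 1.4), (5.0, 5.3), (9.0, 9.5)], 20.0)
        m = match_events(list(truth.events), truth, 0.5)
        assert (m.tp, m.fn, m.fp) == (3, 0, 0)

    def test_empty_detected_all_missed(self):
        truth = EventLabelSet([(i * 10.0, i * 10.0 + 0.4) for i in range(30)], 400.0)
        m = match_events([], truth, 0.5)
        assert (m.tp, m.fn, m.fp) == (0, 30, 0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_maximum_bipartite_oracle(self, seed):
        """Greedy earliest-within-tolerance matching attains the
        maximum one-to-one matching on random small instances."""
        rng = np.random.default_rng(seed)
        n_det, n_tru = rng.integers(0, 9), rng.integers(1, 9)
        tol = 0.5
        tru = np.sort(rng.uniform(0, 10, n_tru))
        truth = EventLabelSet(
            [(t, t + 0.05) for t in tru if True], 20.0) if _nonoverlap(tru) else None
        if truth is None:
            return
        det_mid = np.sort(rng.uniform(0, 10, n_det))
        detected = [(d - 0.025, d + 0.025) for d in det_mid]
        m = match_events(detected, truth, tol)
        oracle = max_matching_size(
            list(det_mid), [(a + b) / 2 for a, b in truth.events], tol)
        assert m.tp == oracle
        assert m.tp + m.fn == n_tru
        assert m.tp + m.fp == n_det

    def test_counting_identities(self):
        truth = EventLabelSet([(1.0, 1.2), (2.0, 2.2)], 10.0)
        m = match_events([(0.9, 1.1), (5.0, 5.2), (7.0, 7.1)], truth, 0.5)
        assert m.tp + m.fn == 2
        assert m.tp + m.fp == 3

    def test_time_shift_invariance(self):
        truth_a = EventLabelSet([(1.0, 1.4), (5.0, 5.4)], 100.0)
        truth_b = EventLabelSet([(31.0, 31.4), (35.0, 35.4)], 100.0)
        det_a = [(1.1, 1.3), (8.0, 8.2)]
        det_b = [(31.1, 31.3), (38.0, 38.2)]
        ma, mb = match_events(det_a, truth_a, 0.5), match_events(det_b, truth_b, 0.5)
        assert (ma.tp, ma.fn, ma.fp) == (mb.tp, mb.fn, mb.fp)
        assert sensitivity(ma) == sensitivity(mb)
        assert fp_per_hour(ma, 3600) == fp_per_hour(mb, 3600)


def _nonoverlap(starts):
    return np.all(np.diff(starts) > 0.06) if len(starts) > 1 else True


class TestRates:
    def test_study_sensitivity_worked_example(self):
        # 21 detected of 30 verified coughs
        assert sensitivity(MatchResult(tp=21, fn=9, fp=0)) == pytest.approx(0.70)

    @pytest.mark.parametrize("tp,fn,expected", [(5, 0, 1.0), (0, 7, 0.0)])
    def test_sensitivity_bounds(self, tp, fn, expected):
        assert sensitivity(MatchResult(tp=tp, fn=fn, fp=0)) == expected

    def test_sensitivity_undefined_without_truth(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(MatchResult(tp=0, fn=0, fp=3))

    @pytest.mark.parametrize("fp,dur,expected", [
        (4, 7200.0, 2.0), (0, 3600.0, 0.0), (3, 1800.0, 6.0),
    ])
    def test_fp_per_hour(self, fp, dur, expected):
        assert fp_per_hour(MatchResult(0, 0, fp), dur) == pytest.approx(expected)

    def test_rater_agreement_worked_example(self):
        # 116 of 120 sound classifications agreed
        assert percent_agreement(116, 120) == pytest.approx(96.666666, abs=1e-4)
        assert percent_agreement(0, 10) == 0.0
        assert percent_agreement(10, 10) == 100.0


class TestScoreSurvey:
    def test_cutoff_boundary_all_agree(self):
        r = SurveyResponse("a", [4] * 7)
        df = score_survey([r])
        assert df.loc[0, "total"] == 28
        assert bool(df.loc[0, "satisfied"])

    def test_extremes(self):
        df = score_survey([SurveyResponse("lo", [1] * 7),
                           SurveyResponse("hi", [5] * 7)])
        assert list(df["total"]) == [7, 35]
        assert list(df["satisfied"]) == [False, True]

    def test_satisfied_monotone_in_cutoff(self):
        responses = synth_survey(200, rho=0.3, seed=0, favorability=0.5)
        props = [score_survey(responses, cutoff=c).attrs["summary"]["prop_satisfied"]
                 for c in range(7, 36)]
        assert all(a >= b for a, b in zip(props, props[1:]))

    def test_malformed_response_named(self):
        with pytest.raises(InputError, match="bad_resp"):
            SurveyResponse("bad_resp", [1, 2, 3, 4, 5, 6, 7])


class TestItemAgreement:
    def test_worked_example_35_of_42(self):
        responses = [SurveyResponse(f"r{i}", [3, 3, 3, 3, 3, 5 if i < 35 else 3, 3])
                     for i in range(42)]
        df = item_agreement(responses)
        row = df[df["item"] == 6].iloc[0]
        assert row["n_agree"] == 35
        assert row["proportion"] == pytest.approx(35 / 42)
        assert round(100 * row["proportion"]) == 83

    def test_all_neutral_zero(self):
        responses = [SurveyResponse(f"r{i}", [3] * 7) for i in range(10)]
        assert (item_agreement(responses)["proportion"] == 0.0).all()

    def test_missing_values_change_denominator(self):
        responses = [SurveyResponse(f"r{i}", [4, 4, 4, 4, 4, 4,
                                              None if i < 8 else 4])
                     for i in range(42)]
        df = item_agreement(responses)
        assert df.loc[df["item"] == 7, "n_valid"].iloc[0] == 34
        assert df.loc[df["item"] == 7, "n_missing"].iloc[0] == 8
        assert df.loc[df["item"] == 1, "n_valid"].iloc[0] == 42


class TestCronbachAlpha:
    def test_identical_items_alpha_one(self):
        x = np.random.default_rng(0).normal(size=50)
        X = np.column_stack([x] * 5)
        assert cronbach_alpha(X) == pytest.approx(1.0)

    def test_hand_computed_two_item_matrix(self):
        # item variances 5/3 and 19/12; total variance 67/12
        X = np.array([[1, 2], [2, 4], [3, 5], [4, 4]], dtype=float)
        assert cronbach_alpha(X) == pytest.approx(
            2 * (1 - (np.var([1, 2, 3, 4], ddof=1) + np.var([2, 4, 5, 4], ddof=1))
                 / np.var([3, 6, 8, 8], ddof=1)), abs=1e-12)
        assert cronbach_alpha(X) == pytest.approx(56 / 67, abs=1e-12)

    def test_parallel_items_closed_form_recovery(self):
        """Simulated 7-item scale at inter-item correlation 0.33 and
        n = 5000 recovers alpha = 7 rho/(1 + 6 rho) within 0.03."""
        responses = synth_survey(5000, rho=0.33, seed=7)
        alpha = cronbach_alpha(responses_to_matrix(responses))
        assert alpha == pytest.approx(7 * 0.33 / (1 + 6 * 0.33), abs=0.03)

    def test_column_shift_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4))
        X2 = X.copy()
        X2[:, 2] += 11.0
        assert cronbach_alpha(X2) == pytest.approx(cronbach_alpha(X), abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedMetricError):
            cronbach_alpha(np.ones((10, 3)))


class TestItemCorrelation:
    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, p, n = item_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_five_pair_manual_arithmetic(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 7])
        r, _, _ = item_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        manual = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        assert r == pytest.approx(manual, abs=1e-12)

    def test_nan_pairs_dropped(self):
        x = np.array([1.0, 2, np.nan, 4, 5, 6])
        y = np.array([1.0, 2, 3, np.nan, 5, 6])
        r, p, n = item_correlation(x, y)
        assert n == 4
        assert r == pytest.approx(1.0)

    def test_null_p_values_uniform(self):
        """Two-sided p-values are uniform under independence
        (Kolmogorov-Smirnov on 1000 replicates at n = 42)."""
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(1000):
            x = rng.normal(size=42)
            y = rng.normal(size=42)
            _, p, _ = item_correlation(x, y)
            ps.append(p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01
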