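"""Quality indicators, ROC and external regression statistics.

The regression statistics are checked against an independent spreadsheet-
style oracle (explicit sums, no shared code with the implementation).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import btlqsar as bq
from btlqsar import metrics as mx
from btlqsar.data import ACTIVE, INACTIVE


class TestConfusion:
    def test_all_correct_no_false_counts(self):
        y = [ACTIVE, INACTIVE, ACTIVE]
        cc = mx.confusion(y, y)
        assert (cc.fp, cc.fn) == (0, 0) and (cc.tp, cc.tn) == (2, 1)

    def test_all_abstain_zero_counts_and_zero_pr(self):
        cc = mx.confusion([ACTIVE, INACTIVE], [None, "abstain"])
        assert cc.n_predicted == 0
        q = mx.quality_indicators(cc)
        assert q.pr == 0.0 and "MCC" in q.undefined

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_pairwise_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.choice([ACTIVE, INACTIVE], size=60)
        y_pred = rng.choice([ACTIVE, INACTIVE, None], size=60)
        cc = mx.confusion(list(y_true), list(y_pred))
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == p == ACTIVE)
        tn = sum(1 for t, p in zip(y_true, y_pred) if t == p == INACTIVE)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t == INACTIVE and p == ACTIVE)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == ACTIVE and p == INACTIVE)
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (tp, tn, fp, fn)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            mx.confusion([ACTIVE], ["maybe"])


class TestQualityIndicators:
    def test_perfect_classifier_all_ones(self):
        q = mx.quality_indicators(mx.ConfusionCounts(5, 5, 0, 0, 10))
        assert (q.se, q.sp, q.acc_standard, q.npv, q.ppv, q.mcc) == (1, 1, 1, 1, 1, 1)

    def test_mcc_matches_sklearn_on_random_counts(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(1)
        for _ in range(20):
            y_true = rng.choice([0, 1], size=80)
            y_pred = rng.choice([0, 1], size=80)
            lab = {1: ACTIVE, 0: INACTIVE}
            cc = mx.confusion([lab[v] for v in y_true], [lab[v] for v in y_pred])
            q = mx.quality_indicators(cc)
            assert q.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-10)

    def test_balanced_vs_standard_accuracy_differ_on_imbalance(self):
        cc = mx.ConfusionCounts(tp=9, tn=50, fp=20, fn=1, n_total=80)
        q = mx.quality_indicators(cc)
        assert q.acc_standard == pytest.approx(59 / 80)
        assert q.acc_balanced == pytest.approx((50 / 70 + 9 / 10) / 2)
        assert q.acc_standard != q.acc_balanced

    @given(
        tp=st.integers(0, 40), tn=st.integers(0, 40),
        fp=st.integers(0, 40), fn=st.integers(0, 40),
    )
    @settings(max_examples=200, deadline=None)
    def test_indicator_bounds(self, tp, tn, fp, fn):
        cc = mx.ConfusionCounts(tp, tn, fp, fn, tp + tn + fp + fn + 5)
        q = mx.quality_indicators(cc)
        for v in (q.se, q.sp, q.acc_standard, q.acc_balanced, q.npv, q.ppv, q.pr):
            assert 0.0 <= v <= 1.0
        assert -1.0 <= q.mcc <= 1.0

    def test_round_half_even_reporting(self):
        q = mx.quality_indicators(mx.ConfusionCounts(5, 5, 0, 0, 10))
        assert mx.QualityReport(0.625, 0, 0, 0, 0, 0, 0, 0).rounded()["SE"] == 0.62
        assert q.rounded()["SE"] == 1.0


class TestRoc:
    def test_scores_equal_labels_auc_one(self):
        y = [ACTIVE] * 5 + [INACTIVE] * 5
        scores = [1.0] * 5 + [0.0] * 5
        _, auc = mx.roc_curve(scores, y)
        assert auc == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        y = [ACTIVE if v else INACTIVE for v in rng.choice([0, 1], size=2000)]
        scores = rng.normal(size=2000)
        _, auc = mx.roc_curve(scores, y)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_reversed_scores_mirror_auc(self):
        rng = np.random.default_rng(3)
        y = [ACTIVE if v else INACTIVE for v in rng.choice([0, 1], size=100)]
        scores = rng.normal(size=100)
        _, auc = mx.roc_curve(scores, y)
        _, auc_rev = mx.roc_curve([-s for s in scores], y)
        assert auc_rev == pytest.approx(1.0 - auc, abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mx.roc_curve([0.1, 0.2], [ACTIVE, ACTIVE])


def _oracle_regression(y_obs, y_pred, y_train):
    """Independent spreadsheet-style computation with explicit sums."""
    n = len(y_obs)
    mo = sum(y_obs) / n
    mp = sum(y_pred) / n
    rmse = (sum((o - p) ** 2 for o, p in zip(y_obs, y_pred)) / n) ** 0.5
    so = sum((o - mo) ** 2 for o in y_obs) / n
    sp_ = sum((p - mp) ** 2 for p in y_pred) / n
    cov = sum((o - mo) * (p - mp) for o, p in zip(y_obs, y_pred)) / n
    r2 = cov**2 / (so * sp_)
    ccc = 2 * cov / (so + sp_ + (mo - mp) ** 2)
    mt = sum(y_train) / len(y_train)
    st_ = sum((t - mt) ** 2 for t in y_train) / len(y_train)
    q2f3 = 1 - (sum((o - p) ** 2 for o, p in zip(y_obs, y_pred)) / n) / st_
    k = sum(o * p for o, p in zip(y_obs, y_pred)) / sum(p * p for p in y_pred)
    r0_2 = 1 - sum((o - k * p) ** 2 for o, p in zip(y_obs, y_pred)) / sum(
        (o - mo) ** 2 for o in y_obs
    )
    rm2 = r2 * (1 - max(r2 - r0_2, 0.0) ** 0.5)
    return r2, rmse, q2f3, ccc, rm2


class TestRegressionMetrics:
    def test_perfect_prediction_all_ones(self):
        y = [1.5, 2.0, 3.1, 0.7, 2.2]
        rep = bq.regression_metrics(y, y, y)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.rmse == 0.0
        assert rep.q2_f3 == pytest.approx(1.0)
        assert rep.ccc == pytest.approx(1.0)
        assert rep.rm2 == pytest.approx(1.0)

    def test_constant_shift_keeps_r2_but_lowers_ccc(self):
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        shifted = [v + 0.8 for v in y]
        rep = bq.regression_metrics(y, shifted, y)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.ccc < 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_independent_oracle_on_five_point_vectors(self, seed):
        rng = np.random.default_rng(seed)
        y_obs = list(rng.normal(2.0, 1.0, 5))
        y_pred = list(np.array(y_obs) * 0.8 + rng.normal(0, 0.4, 5))
        y_train = list(rng.normal(2.0, 1.2, 8))
        rep = bq.regression_metrics(y_obs, y_pred, y_train)
        r2, rmse, q2f3, ccc, rm2 = _oracle_regression(y_obs, y_pred, y_train)
        assert rep.r2 == pytest.approx(r2, abs=1e-10)
        assert rep.rmse == pytest.approx(rmse, abs=1e-10)
        assert rep.q2_f3 == pytest.approx(q2f3, abs=1e-10)
        assert rep.ccc == pytest.approx(ccc, abs=1e-10)
        assert rep.rm2 == pytest.approx(rm2, abs=1e-10)

    def test_zero_variance_flagged(self):
        rep = bq.regression_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 2.0])
        assert "R2" in rep.undefined
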