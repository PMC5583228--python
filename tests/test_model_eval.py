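"""LOOCV SVM/SVR evaluation: metrics, oracles, leakage guards, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

import wmentropy as wm
from wmentropy.errors import (
    DegenerateFoldError,
    DegenerateTargetError,
    UndefinedAUCError,
    UnsupportedInputError,
)


def labels_from(z):
    return np.where(np.asarray(z) > 0, "high", "low")


class TestConfusionMetrics:
    def test_balanced_example(self):
        ca, se, sp = wm.confusion_metrics(9, 9, 1, 1)
        assert (ca, se, sp) == (0.9, 0.9, 0.9)

    def test_perfect(self):
        assert wm.confusion_metrics(10, 10, 0, 0) == (1.0, 1.0, 1.0)

    def test_random_tables_match_arithmetic(self, rng):
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 30, size=4)
            if tp + tn + fp + fn == 0:
                continue
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ca, se, sp = wm.confusion_metrics(tp, tn, fp, fn)
            assert ca == (tp + tn) / (tp + tn + fp + fn)
            if tp + fn:
                assert se == tp / (tp + fn)
            if tn + fp:
                assert sp == tn / (tn + fp)

    def test_negative_count_rejected(self):
        with pytest.raises(UnsupportedInputError):
            wm.confusion_metrics(-1, 2, 3, 4)


class TestRocAuc:
    def test_separated_scores_give_one(self):
        scores = [3.0, 2.5, 2.0, -1.0, -2.0]
        labels = ["high", "high", "high", "low", "low"]
        _, auc = wm.roc_auc(scores, labels)
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        _, auc = wm.roc_auc([1.0] * 6, ["high"] * 3 + ["low"] * 3)
        assert auc == 0.5

    def test_equals_normalized_mann_whitney(self, rng):
        for _ in range(500):
            n1, n0 = rng.integers(2, 12), rng.integers(2, 12)
            scores = np.concatenate(
                [rng.normal(0.5, 1, n1), rng.normal(0, 1, n0)]
            ).round(1)  # rounding forces ties
            labels = ["high"] * n1 + ["low"] * n0
            _, auc = wm.roc_auc(scores, labels)
            u = mannwhitneyu(scores[:n1], scores[n1:]).statistic
            assert auc == pytest.approx(u / (n1 * n0), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            wm.roc_auc([1.0, 2.0], ["high", "high"])


class TestLoocvClassify:
    def test_separable_feature_perfect_metrics(self, rng):
        feat = np.concatenate([5 + 0.1 * rng.normal(size=10),
                               1 + 0.1 * rng.normal(size=10)])
        y = labels_from(np.concatenate([np.ones(10), -np.ones(10)]))
        rep = wm.loocv_classify(feat, y)
        assert (rep.ca, rep.se, rep.sp, rep.auc) == (1.0, 1.0, 1.0, 1.0)

    def test_every_subject_tested_once(self, rng):
        feat = rng.normal(size=12)
        y = labels_from(rng.normal(size=12) + np.where(feat > 0, 1, -1))
        if min((y == "high").sum(), (y == "low").sum()) < 2:
            pytest.skip("degenerate draw")
        rep = wm.loocv_classify(feat, y)
        assert len(rep.predictions) == 12
        assert rep.predictions.subject.is_unique

    def test_permutation_null_centered_on_half(self, rng):
        # mean CA over random relabelings is near chance with balanced weights
        cas = []
        for _ in range(200):
            feat = rng.normal(size=20)
            y = rng.permutation(labels_from(rng.normal(size=20)))
            if min((y == "high").sum(), (y == "low").sum()) < 2:
                continue
            cas.append(wm.loocv_classify(feat, y).ca)
        mean, se = np.mean(cas), np.std(cas, ddof=1) / np.sqrt(len(cas))
        assert abs(mean - 0.5) <= 2 * se + 0.02

    def test_degenerate_class_rejected(self):
        with pytest.raises(DegenerateFoldError):
            wm.loocv_classify([1.0, 2.0, 3.0, 4.0], ["high"] * 3 + ["low"])

    def test_deterministic(self, rng):
        feat = rng.normal(size=14)
        y = labels_from(rng.normal(size=14) + feat)
        if min((y == "high").sum(), (y == "low").sum()) < 2:
            pytest.skip("degenerate draw")
        a = wm.loocv_classify(feat, y)
        b = wm.loocv_classify(feat, y)
        pd.testing.assert_frame_equal(a.predictions, b.predictions)
        assert (a.ca, a.auc) == (b.ca, b.auc)


class TestCrossSession:
    def test_separable_both_directions(self, rng):
        f1 = np.concatenate([5 + 0.1 * rng.normal(size=6), 0.1 * rng.normal(size=6)])
        f2 = np.concatenate([5 + 0.1 * rng.normal(size=6), 0.1 * rng.normal(size=6)])
        y = labels_from(np.concatenate([np.ones(6), -np.ones(6)]))
        for tr, te in ((f1, f2), (f2, f1)):
            rep = wm.cross_session_classify(tr, y, te, y)
            assert rep.ca == 1.0 and rep.auc == 1.0

    def test_one_class_test_set_gives_nan_metric(self, rng):
        f_tr = np.concatenate([5 + rng.normal(size=5), rng.normal(size=5)])
        y_tr = labels_from(np.concatenate([np.ones(5), -np.ones(5)]))
        f_te = 5 + rng.normal(size=4)
        y_te = np.array(["high"] * 4)
        with pytest.warns(UserWarning):
            rep = wm.cross_session_classify(f_tr, y_tr, f_te, y_te)
        assert np.isnan(rep.sp) and np.isnan(rep.auc)
        assert 0.0 <= rep.ca <= 1.0


class TestLoocvSvr:
    def test_noiseless_linear_target_recovered(self, rng):
        feat = np.linspace(0, 1, 20)
        target = 3.0 * feat + 1.0
        # noiseless data: tighten the epsilon tube so the fit can be exact
        rep = wm.loocv_svr(feat, target, wm.SVRConfig(C=100.0, epsilon=1e-3))
        assert rep.rmsep <= 0.05 * target.std(ddof=1)
        assert rep.r >= 0.99

    def test_zero_error_iff_exact_predictions(self):
        rep = wm.RegressionReport(
            scope="x", rmsep=0.0, r=1.0, p=0.0,
            predictions=pd.DataFrame({"actual": [1.0], "predicted": [1.0]}),
        )
        assert rep.rmsep == 0.0

    def test_zero_target_variance_rejected(self):
        with pytest.raises(DegenerateTargetError):
            wm.loocv_svr([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_fold_local_standardization_matters(self, rng):
        # mutation test: replacing fold-local scaling by global scaling must
        # change the pooled predictions, proving fold-local scaling is live
        from sklearn.svm import SVR

        feat = rng.normal(size=15)
        target = 2 * feat + rng.normal(scale=0.5, size=15)
        rep = wm.loocv_svr(feat, target)

        mu, sd = feat.mean(), feat.std(ddof=1)
        mu_t, sd_t = target.mean(), target.std(ddof=1)
        xg = (feat - mu) / sd
        tg = (target - mu_t) / sd_t
        global_preds = np.empty(15)
        for i in range(15):
            m = np.ones(15, bool)
            m[i] = False
            model = SVR(kernel="rbf", C=1.0, epsilon=0.1, gamma=1.0)
            model.fit(xg[m].reshape(-1, 1), tg[m])
            global_preds[i] = model.predict([[xg[i]]])[0] * sd_t + mu_t
        assert not np.allclose(rep.predictions.predicted.to_numpy(), global_preds)


class TestNestedSelection:
    def test_planted_channel_selected_in_every_fold(self, rng):
        import wmentropy as wm

        srt = np.concatenate([rng.normal(3, 0.3, 10), rng.normal(-3, 0.3, 10)])
        channels = ["Fz", "Cz", "FC4", "Pz"]
        rows = []
        for ci, ch in enumerate(channels):
            for subj in range(1, 21):
                sen = srt[subj - 1] * 0.1 + 1.4 if ch == "FC4" else rng.normal(1.4, 0.05)
                rows.append({"subject": subj, "session": 1, "channel": ch, "sen": sen})
        feats = pd.DataFrame(rows)
        scores = wm.zscore_group(
            pd.DataFrame({"subject": range(1, 21), "session": 1, "srt": srt})
        )
        rep = wm.loocv_classify_nested(feats, scores, session=1)
        assert (rep.predictions.channel == "FC4").all()
        assert rep.ca == 1.0 and rep.auc == 1.0
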