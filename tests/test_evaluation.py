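"""Participant-level metrics, condition contrasts, bias probe, attribution."""

import numpy as np
import pandas as pd
import pytest

from rhotic.errors import DataError, ParameterError, StateError
from rhotic.evaluation import (
    bias_probe,
    combined_best,
    condition_contrast,
    global_attribution,
    participant_confusion,
    participant_f1,
)


def _brute_f1(y_true, y_pred):
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    if tp == 0 and (fp == 0 or fn == 0) and (fp + fn) == 0:
        return 0.0
    denom = 2 * tp + fp + fn
    return 0.0 if denom == 0 else 2 * tp / denom


class TestParticipantF1:
    def test_perfect_predictions(self):
        y = np.array([1, 1, 0, 1, 0, 1])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        scores, summary = participant_f1(y, y, g)
        assert scores == {"a": 1.0, "b": 1.0}
        assert summary["mean"] == 1.0 and summary["n"] == 2

    def test_worked_example_tp2_fp1(self):
        # one speaker: TP=2, FP=1, FN=0 -> precision 2/3, recall 1, F1 0.8
        y_true = np.array([1, 1, 0, 0])
        y_pred = np.array([1, 1, 1, 0])
        scores, _ = participant_f1(y_true, y_pred, np.array(["s"] * 4))
        assert scores["s"] == pytest.approx(0.8)

    def test_all_negative_predictions_zero_division(self):
        y_true = np.array([1, 1, 0])
        y_pred = np.zeros(3, dtype=int)
        scores, _ = participant_f1(y_true, y_pred, np.array(["s"] * 3))
        assert scores["s"] == 0.0

    def test_agrees_with_brute_force_on_random_instances(self, rng):
        """F1 and confusion both agree with direct counting on 100 random
        small instances."""
        for _ in range(100):
            n = int(rng.integers(3, 30))
            y_true = rng.integers(0, 2, size=n)
            y_pred = rng.integers(0, 2, size=n)
            g = np.array(["s"] * n)
            scores, _ = participant_f1(y_true, y_pred, g)
            assert scores["s"] == pytest.approx(_brute_f1(y_true, y_pred))
            if len(np.unique(y_true)) == 2:
                cm = participant_confusion(y_true, y_pred, g)
                for t in (0, 1):
                    sel = y_true == t
                    np.testing.assert_allclose(cm[t, 1], np.mean(y_pred[sel]))
                np.testing.assert_allclose(cm.sum(axis=1), 1.0)

    def test_equal_speaker_weighting_under_duplication(self, rng):
        y = rng.integers(0, 2, size=30)
        p = rng.integers(0, 2, size=30)
        g = np.repeat(["a", "b", "c"], 10)
        _, s1 = participant_f1(y, p, g)
        # duplicate speaker a's utterances: summary must not move
        y2 = np.concatenate([y, y[:10]])
        p2 = np.concatenate([p, p[:10]])
        g2 = np.concatenate([g, ["a"] * 10])
        _, s2 = participant_f1(y2, p2, g2)
        assert s1["mean"] == pytest.approx(s2["mean"])


class TestParticipantConfusion:
    def test_identity_for_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        cm = participant_confusion(y, y, np.array(["s"] * 4))
        np.testing.assert_allclose(cm, np.eye(2))

    def test_rows_always_sum_to_one(self, rng):
        y = np.array([0, 0, 1, 1, 1, 0, 1, 0])
        p = rng.integers(0, 2, size=8)
        cm = participant_confusion(y, p, np.repeat(["a", "b"], 4))
        np.testing.assert_allclose(cm.sum(axis=1), 1.0, atol=1e-9)

    def test_equal_weight_average_of_recalls(self):
        # speaker a recall 0.6 (3/5), speaker b recall 1.0 -> pooled 0.8
        ya = np.array([1] * 5 + [0] * 2)
        pa = np.array([1, 1, 1, 0, 0, 0, 0])
        yb = np.array([1] * 4 + [0] * 2)
        pb = np.array([1, 1, 1, 1, 0, 0])
        cm = participant_confusion(
            np.concatenate([ya, yb]), np.concatenate([pa, pb]),
            np.array(["a"] * 7 + ["b"] * 6),
        )
        assert cm[1, 1] == pytest.approx(0.8)

    def test_single_class_speaker_excluded(self):
        y = np.array([1, 1, 1, 0, 1, 1])
        p = np.array([1, 0, 1, 0, 1, 1])
        cm = participant_confusion(y, p, np.array(["only1"] * 3 + ["both"] * 3))
        np.testing.assert_allclose(cm, np.eye(2))  # only "both" is usable


class TestCombinedBest:
    def test_elementwise_maximum(self):
        pers = {"a": 0.70, "b": 0.9}
        oob = {"a": 0.75, "b": 0.8}
        best, summary = combined_best(pers, oob)
        assert best == {"a": 0.75, "b": 0.9}
        assert all(best[k] >= pers[k] and best[k] >= oob[k] for k in best)

    def test_personalized_dominant_returns_personalized(self):
        pers = {"a": 0.9, "b": 0.8}
        oob = {"a": 0.5, "b": 0.6}
        best, _ = combined_best(pers, oob)
        assert best == pers

    def test_mismatched_speakers_rejected(self):
        with pytest.raises(DataError):
            combined_best({"a": 0.5}, {"b": 0.5})


def _factorial_table(effect=0.08, re_sd=0.05, noise=0.03, n_speakers=100, seed=7):
    rng = np.random.default_rng(seed)
    rows = []
    for spk in range(n_speakers):
        b = rng.normal(0, re_sd)
        for fam in ("random_forest", "sgd_linear"):
            for norm in ("utterance", "age_sex"):
                for rep in ("mfcc", "formant"):
                    for tp in ("out_of_box", "personalized"):
                        f1 = 0.7 + b + (effect if norm == "age_sex" else 0.0)
                        f1 += rng.normal(0, noise) if noise else 0.0
                        rows.append(
                            dict(speaker_id=f"s{spk}", family=fam, normalization=norm,
                                 representation=rep, timepoint=tp, f1=f1)
                        )
    return pd.DataFrame(rows)


class TestConditionContrast:
    def test_noiseless_exact_recovery(self):
        df = _factorial_table(effect=0.08, re_sd=0.0, noise=0.0, n_speakers=10)
        res = condition_contrast(df)
        est, _ = res.effect("normalization")
        assert est == pytest.approx(0.08, abs=1e-6)

    def test_recovery_within_two_se(self):
        df = _factorial_table(effect=0.08, re_sd=0.05, noise=0.03, n_speakers=100)
        res = condition_contrast(df)
        est, se = res.effect("normalization")
        assert abs(est - 0.08) <= 2 * se

    def test_permuted_conditions_give_null(self):
        df = _factorial_table(effect=0.08, re_sd=0.05, noise=0.03, n_speakers=100)
        rng = np.random.default_rng(1)
        df = df.assign(normalization=rng.permutation(df["normalization"].to_numpy()))
        res = condition_contrast(df)
        est, se = res.effect("normalization")
        assert abs(est) <= 2 * se

    def test_missing_columns_rejected(self):
        with pytest.raises(DataError):
            condition_contrast(pd.DataFrame({"f1": [0.5]}))


class TestBiasProbe:
    def test_null_metadata_not_significant(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "f1": 0.8 + rng.normal(0, 0.05, size=48),
                "age_years": rng.uniform(7, 17, size=48),
                "sex": rng.choice(["M", "F"], size=48),
            }
        )
        res = bias_probe(df)
        assert res.pvalues["age_years"] > 0.05

    def test_exact_linear_age_effect(self):
        ages = np.linspace(7, 17, 40)
        df = pd.DataFrame(
            {
                "f1": 0.5 + 0.02 * ages,
                "age_years": ages,
                "sex": ["M", "F"] * 20,
            }
        )
        res = bias_probe(df)
        assert res.params["age_years"] == pytest.approx(0.02, abs=1e-8)

    def test_single_sex_rejected(self):
        df = pd.DataFrame({"f1": [0.5, 0.6], "age_years": [8, 9], "sex": ["M", "M"]})
        with pytest.raises(ParameterError):
            bias_probe(df)


NAMES = ("F1", "F2", "F3", "F3-F2", "dF3-F2")


def _attribution_corpus(rng, sep=1.0):
    from rhotic.grnn import GRNNClassifier

    def make(n, s, two_to_one=False):
        y = (rng.random(n) < (2 / 3 if two_to_one else 0.5)).astype(int)
        X = rng.normal(size=(n, 10, 5, 8))
        X[:, :, 2, :] += np.where(y == 1, s, -s)[:, None, None]
        return X.reshape(n, 10, 40), y

    Xtr, ytr = make(500, sep)
    net = GRNNClassifier(input_dim=40, hidden_size=24, dense_size=12, seed=1)
    net.fit(Xtr, ytr)
    background, _ = make(200, 0.0)  # ambiguous: classes indistinct
    inputs, y_in = make(200, sep, two_to_one=True)  # unanimous, 2:1 rhotic
    return net, background, inputs, y_in


class TestGlobalAttribution:
    def test_informative_feature_ranks_first_with_positive_class1_sign(self, rng):
        net, background, inputs, y_in = _attribution_corpus(rng)
        _, per_utt = global_attribution(
            net, background, inputs, NAMES, seed=0, return_per_utterance=True
        )
        importance = np.abs(per_utt).mean(axis=0)
        assert int(np.argmax(importance)) == 2  # F3
        # sign convention: the feature pushing class-1 probability up for
        # class-1 inputs carries positive mean attribution
        assert per_utt[y_in == 1].mean(axis=0)[2] > 0

    def test_uninformative_features_near_zero(self, rng):
        net, background, inputs, _ = _attribution_corpus(rng)
        _, per_utt = global_attribution(
            net, background, inputs, NAMES, seed=0, return_per_utterance=True
        )
        importance = np.abs(per_utt).mean(axis=0)
        for i in (0, 1, 3, 4):
            assert importance[i] < 0.3 * importance[2]

    def test_global_value_is_mean_of_per_utterance_attributions(self, rng):
        net, background, inputs, _ = _attribution_corpus(rng)
        series, per_utt = global_attribution(
            net, background, inputs[:80], NAMES, seed=3, return_per_utterance=True
        )
        assert per_utt.shape == (80, 5)
        np.testing.assert_allclose(series.values, per_utt.mean(axis=0), atol=1e-12)

    def test_untrained_model_rejected(self, rng):
        from rhotic.grnn import GRNNClassifier

        net = GRNNClassifier(input_dim=40, seed=0)
        X = rng.normal(size=(5, 10, 40))
        with pytest.raises(StateError):
            global_attribution(net, X, X, NAMES, seed=0)
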