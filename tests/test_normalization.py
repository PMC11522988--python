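"""Normative tables and the two z-standardization conditions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rhotic.errors import ConfigurationError
from rhotic.normalization import (
    NormativeTable,
    build_normative_table,
    normalize_age_sex,
    normalize_utterance,
    scale_deltas,
)

NAMES = ("F1", "F2", "F3", "F3-F2", "dF3-F2")


class TestScaleDeltas:
    def test_worked_example(self):
        np.testing.assert_allclose(scale_deltas(np.array([-2.0, 0.0, 4.0])), [-5.0, 0.0, 10.0])

    def test_all_zero_stays_zero(self):
        np.testing.assert_array_equal(scale_deltas(np.zeros(5)), np.zeros(5))

    @given(
        st.lists(st.floats(-1e4, 1e4, allow_nan=False), min_size=2, max_size=30).filter(
            lambda v: max(abs(x) for x in v) > 1e-9
        )
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_max_magnitude_is_ten(self, series):
        out = scale_deltas(np.array(series))
        assert np.max(np.abs(out)) == pytest.approx(10.0)


def _table():
    rows = []
    for age in (8, 10):
        for sex in ("M", "F"):
            for i, feat in enumerate(NAMES):
                rows.append(
                    {"age_years": age, "sex": sex, "feature": feat,
                     "mean": 1000.0 * (i + 1) + 10 * age + (50 if sex == "F" else 0),
                     "sd": 100.0}
                )
    return NormativeTable(pd.DataFrame(rows))


class TestNormativeTable:
    def test_nearest_age_match_prefers_closer_row(self):
        t = _table()
        mean, _ = t.lookup("F3", age_years=9.4, sex="M")
        assert mean == 3000.0 + 100  # the age-10 row: |9.4-10| < |9.4-8|

    def test_tie_goes_to_younger(self):
        t = _table()
        mean, _ = t.lookup("F3", age_years=9.0, sex="M")
        assert mean == 3000.0 + 80

    def test_missing_sex_falls_back(self):
        rows = _table().rows
        t = NormativeTable(rows[rows["sex"] == "M"])
        mean, sd = t.lookup("F1", age_years=8, sex="F")
        assert np.isfinite(mean) and sd > 0

    def test_positive_sd_enforced(self):
        bad = _table().rows.copy()
        bad.loc[0, "sd"] = 0.0
        with pytest.raises(Exception):
            NormativeTable(bad)

    def test_csv_round_trip(self, tmp_path):
        t = _table()
        t.to_csv(tmp_path / "norms.csv")
        back = NormativeTable.from_csv(tmp_path / "norms.csv")
        pd.testing.assert_frame_equal(back.rows, t.rows)


def _frames_corpus(seed=0):
    """Tiny training table + frame features proportional to vt scale."""
    from rhotic.synth import vt_scale

    rng = np.random.default_rng(seed)
    speakers = pd.DataFrame(
        {
            "speaker_id": [f"s{i}" for i in range(6)],
            "age_years": [7.2, 8.5, 10.1, 12.7, 15.0, 16.8],
            "sex": ["M", "F", "M", "F", "M", "F"],
            "cohort": ["RSSD"] * 6,
        }
    )
    utts, feats = [], {}
    for _, spk in speakers.iterrows():
        s = vt_scale(spk["age_years"], spk["sex"])
        for k in range(6):
            uid = f"{spk['speaker_id']}_u{k}"
            utts.append({"utterance_id": uid, "speaker_id": spk["speaker_id"], "label": 1})
            base = np.array([500.0, 1500.0, 2000.0, 500.0, 0.0]) * s
            feats[uid] = base + rng.normal(0, 5.0, size=(40, 5))
    return pd.DataFrame(utts), feats, speakers


class TestBuildTable:
    def test_identical_on_rebuild(self):
        utts, feats, speakers = _frames_corpus()
        a = build_normative_table(utts, feats, NAMES, speakers)
        b = build_normative_table(utts, feats, NAMES, speakers)
        pd.testing.assert_frame_equal(a.rows, b.rows)

    def test_mean_f3_decreases_with_age_within_sex(self):
        utts, feats, speakers = _frames_corpus()
        t = build_normative_table(utts, feats, NAMES, speakers)
        for sex in ("M", "F"):
            f3 = t.rows[(t.rows["feature"] == "F3") & (t.rows["sex"] == sex)]
            f3 = f3.sort_values("age_years")
            assert np.all(np.diff(f3["mean"]) < 0)

    def test_degenerate_corpus_exact_means_and_floored_sd(self):
        utts, feats, speakers = _frames_corpus()
        from rhotic.synth import vt_scale

        exact = {
            uid: np.tile(
                np.array([500.0, 1500.0, 2000.0, 500.0, 0.0])
                * vt_scale(
                    speakers.set_index("speaker_id").loc[uid.split("_")[0], "age_years"],
                    speakers.set_index("speaker_id").loc[uid.split("_")[0], "sex"],
                ),
                (40, 1),
            )
            for uid in feats
        }
        t = build_normative_table(utts, exact, NAMES, speakers)
        meta = speakers.set_index("speaker_id")
        for _, row in t.rows[t.rows["feature"] == "F3"].iterrows():
            match = meta[(meta["age_years"].astype(int) == row["age_years"]) & (meta["sex"] == row["sex"])]
            s = vt_scale(float(match["age_years"].iloc[0]), row["sex"])
            assert row["mean"] == pytest.approx(2000.0 * s)
            assert row["sd"] == pytest.approx(1e-6)  # floored

    def test_leakage_guard_refuses_eval_speakers(self):
        utts, feats, speakers = _frames_corpus()
        with pytest.raises(ConfigurationError):
            build_normative_table(utts, feats, NAMES, speakers, forbidden_speakers={"s3"})


class TestNormalizeAgeSex:
    def test_matched_mean_maps_to_zero(self):
        t = _table()
        X = np.tile([1080.0, 2080.0, 3080.0, 4080.0, 0.0], (20, 1))
        out = normalize_age_sex(X, NAMES, t, age_years=8, sex="M")
        np.testing.assert_allclose(out[:, :4], 0.0, atol=1e-12)

    def test_self_standardization_recovers_unit_scale(self):
        utts, feats, speakers = _frames_corpus()
        t = build_normative_table(utts, feats, NAMES, speakers)
        meta = speakers.set_index("speaker_id")
        pooled = []
        for uid, X in feats.items():
            spk = uid.split("_")[0]
            pooled.append(
                normalize_age_sex(X, NAMES, t, float(meta.loc[spk, "age_years"]), meta.loc[spk, "sex"])
            )
        pooled = np.vstack(pooled)[:, :3]  # plain (non-delta) features
        assert np.abs(pooled.mean(axis=0)).max() < 0.2
        assert np.abs(pooled.std(axis=0) - 1).max() < 0.2

    def test_empty_table_rejected(self):
        t = NormativeTable(pd.DataFrame(columns=["age_years", "sex", "feature", "mean", "sd"]))
        with pytest.raises(ConfigurationError):
            normalize_age_sex(np.zeros((3, 5)), NAMES, t, 9.0, "M")

    def test_affine_map_preserves_frame_ordering(self, rng):
        t = _table()
        X = rng.normal(3000, 200, size=(30, 5))
        out = normalize_age_sex(X, NAMES, t, 10, "F")
        orders_in = np.argsort(X[:, 2])
        orders_out = np.argsort(out[:, 2])
        np.testing.assert_array_equal(orders_in, orders_out)


class TestNormalizeUtterance:
    def test_zero_mean_unit_sd(self, rng):
        X = rng.normal(1500, 120, size=(50, 5))
        out = normalize_utterance(X, NAMES)
        np.testing.assert_allclose(out[:, :4].mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out[:, :4].std(axis=0), 1.0, atol=1e-9)

    def test_affine_invariance(self, rng):
        X = rng.normal(0, 1, size=(40, 5))
        a = normalize_utterance(X, NAMES)
        b = normalize_utterance(3.7 * X + 55.0, NAMES)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_single_frame_collapses_to_zeros(self):
        out = normalize_utterance(np.full((1, 5), 123.0), NAMES)
        np.testing.assert_array_equal(out, np.zeros((1, 5)))

    def test_delta_feature_rescaled_to_ten(self, rng):
        X = rng.normal(0, 1, size=(30, 5))
        out = normalize_utterance(X, NAMES)
        assert np.max(np.abs(out[:, 4])) == pytest.approx(10.0)


class TestClassSeparationMechanism:
    def test_age_sex_separates_better_than_utterance(self):
        """Pooled standardized mean class difference of F3 is larger under
        age-and-sex normalization than under utterance normalization on a
        confounded corpus — the mechanism behind the normalization effect."""
        from rhotic.synth import SynthSpec, generate_corpus
        from rhotic.corpus import label_corpus, speakers_frame

        corpus = generate_corpus(
            SynthSpec(n_speakers=24, prop_typical=0.0, rssd_skill=0.5,
                      utterances_per_speaker=20, age_range=(6.0, 18.0), seed=9)
        )
        labels = label_corpus(corpus)
        speakers = speakers_frame(corpus)
        feats = {u.utterance_id: u.track.feature_matrix() for u in corpus.utterances}
        table = build_normative_table(labels, feats, NAMES, speakers)
        meta = speakers.set_index("speaker_id")

        def smd(norm_fn):
            by_class = {0: [], 1: []}
            for u in corpus.utterances:
                X = norm_fn(u)
                lab = int(labels.set_index("utterance_id").loc[u.utterance_id, "label"])
                by_class[lab].append(X[:, 2])
            a, b = (np.concatenate(by_class[c]) for c in (0, 1))
            pooled_sd = np.sqrt((a.var() + b.var()) / 2)
            return abs(a.mean() - b.mean()) / pooled_sd

        smd_age_sex = smd(
            lambda u: normalize_age_sex(
                u.track.feature_matrix(), NAMES, table,
                float(meta.loc[u.speaker_id, "age_years"]), meta.loc[u.speaker_id, "sex"],
            )
        )
        smd_utt = smd(lambda u: normalize_utterance(u.track.feature_matrix(), NAMES))
        assert smd_age_sex > smd_utt
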