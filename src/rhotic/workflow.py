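"""End-to-end orchestration of the rhoticity-classification experiments.

A :class:`RunConfig` fully determines one experimental condition: corpus
parameters, representation (formant vs. MFCC), normalization (age-and-sex
vs. utterance), classifier family, tuning budget, and the global seed. The
pipeline runs simulate → label → split → extract → normalize → tensorize →
(tune) → train → personalize → evaluate, and returns per-timepoint
:class:`~rhotic.evaluation.EvaluationReport` objects.

``replicate_swap`` reruns a completed configuration with the validation and
test roles exchanged and merges the per-speaker results of both runs (the
replication scheme that doubles the effective number of test participants);
``run_grid`` executes the 2 × 2 condition factorial per classifier family
and assembles the per-speaker F1 table consumed by
:func:`~rhotic.evaluation.condition_contrast`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import acoustics, corpus as corpus_mod, normalization as norm_mod, synth
from .classify import (
    GrnnConfig,
    SHALLOW_FAMILIES,
    personalize_grnn,
    personalize_shallow,
    predict,
    train_grnn,
    train_shallow,
    tune,
)
from .errors import ConfigurationError, DataError
from .evaluation import EvaluationReport, combined_best, participant_confusion, participant_f1

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One experimental run, serializable to/from a single JSON document."""

    synth: dict = field(default_factory=dict)  # SynthSpec overrides
    representation: str = "formant"  # {"formant", "mfcc"}
    normalization: str = "age_sex"  # {"age_sex", "utterance", "none"}
    family: str = "random_forest"
    features_from: str = "track"  # {"track", "audio"}
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    n_trials: int = 0  # 0 skips tuning and uses `hyperparams`
    hyperparams: dict = field(default_factory=dict)
    grnn: dict = field(default_factory=dict)  # GrnnConfig overrides
    personalize: bool = True
    swap_eval: bool = False  # exchange validation/test roles
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.representation not in ("formant", "mfcc"):
            raise ConfigurationError(f"unknown representation {self.representation!r}")
        if self.normalization not in ("age_sex", "utterance", "none"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")
        if self.features_from not in ("track", "audio"):
            raise ConfigurationError(f"unknown feature source {self.features_from!r}")
        if self.representation == "mfcc" and self.features_from == "track":
            self.features_from = "audio"  # MFCCs only exist via audio

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "fractions" in data:
            data["fractions"] = tuple(data["fractions"])
        return cls(**data)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------


def extract_frame_features(
    corpus: synth.Corpus,
    representation: str = "formant",
    features_from: str = "track",
    ceiling_grid=None,
) -> tuple[dict, tuple[str, ...]]:
    """Frame-level feature matrices per utterance.

    ``track`` reads the generator's formant tracks directly (exact timing,
    no estimation error); ``audio`` synthesizes each utterance and runs the
    LPC formant estimator (with per-speaker ceiling grid search) or the
    MFCC front end on the buffered rhotic interval.
    """
    feats: dict[str, np.ndarray] = {}
    times: dict[str, np.ndarray] = {}
    if representation == "formant" and features_from == "track":
        names = acoustics.FORMANT_FEATURES
        for u in corpus.utterances:
            feats[u.utterance_id] = u.track.feature_matrix()
            times[u.utterance_id] = u.track.frame_times_s
        return {"X": feats, "t": times}, names

    grid = ceiling_grid if ceiling_grid is not None else [4500.0, 5500.0, 6500.0]
    by_spk = corpus.by_speaker()
    ceilings: dict[str, float] = {}
    names = None
    for spk_id, utts in by_spk.items():
        segs = []
        for u in utts:
            audio = u.audio if u.audio is not None else synth._utterance_audio(u)
            buffered = acoustics.buffer_interval(u.interval, u.duration_s)
            i0 = int(buffered.start_s * u.sample_rate_hz)
            i1 = int(buffered.end_s * u.sample_rate_hz)
            segs.append((u, audio[i0:i1]))
        if representation == "formant":
            ceilings[spk_id] = acoustics.optimize_ceiling_train(
                [(seg, utts[0].sample_rate_hz) for _, seg in segs[:5]], grid
            )
        for u, seg in segs:
            if representation == "formant":
                track = acoustics.estimate_formants(seg, u.sample_rate_hz, ceilings[spk_id])
            else:
                track = acoustics.estimate_mfcc(seg, u.sample_rate_hz)
            feats[u.utterance_id] = track.feature_matrix()
            times[u.utterance_id] = track.frame_times_s
            names = track.feature_names
    return {"X": feats, "t": times, "ceilings": ceilings}, tuple(names)


def build_tensors(
    frame_features: dict,
    feature_names: tuple[str, ...],
    utterances: pd.DataFrame,
    speakers: pd.DataFrame,
    representation: str,
    mode: str,
    table: norm_mod.NormativeTable | None,
) -> dict[str, acoustics.FeatureTensor]:
    """Normalize each utterance's frames and reduce to feature tensors."""
    meta = speakers.set_index("speaker_id")
    out = {}
    for _, row in utterances.iterrows():
        uid = row["utterance_id"]
        X = frame_features["X"].get(uid)
        if X is None:
            continue
        Xn = norm_mod.normalize_frames(
            X,
            feature_names,
            mode,
            table=table,
            age_years=float(meta.loc[row["speaker_id"], "age_years"]),
            sex=str(meta.loc[row["speaker_id"], "sex"]),
        )
        track = _TimedFrames(frame_features["t"][uid], feature_names)
        out[uid] = acoustics.tensorize(
            track, representation=representation, normalization=mode, feature_matrix=Xn
        )
    return out


class _TimedFrames:
    """Timing + names shim so tensorize can consume normalized matrices."""

    def __init__(self, times, names):
        self.frame_times_s = np.asarray(times, dtype=float)
        self.feature_names = tuple(names)

    def feature_matrix(self):  # pragma: no cover - always overridden
        raise DataError("no raw features on a timing shim")


def _design(df: pd.DataFrame, tensors: dict, family: str):
    """(X, y, groups) for a labeled utterance table."""
    rows = [r for _, r in df.iterrows() if r["utterance_id"] in tensors]
    y = np.array([r["label"] for r in rows], dtype=int)
    groups = np.array([r["speaker_id"] for r in rows])
    if family in SHALLOW_FAMILIES:
        X = np.stack([tensors[r["utterance_id"]].flat_median() for r in rows])
    else:
        X = np.stack([tensors[r["utterance_id"]].sequence() for r in rows])
    return X, y, groups


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute one full experimental condition; returns reports keyed by
    timepoint plus the artifacts needed for replication and contrasts."""
    seed = config.seed
    spec = synth.SynthSpec(**{**config.synth, "seed": seed})
    corpus = synth.generate_corpus(spec)
    labels = corpus_mod.label_corpus(corpus)
    speakers = corpus_mod.speakers_frame(corpus)
    split = corpus_mod.split_participants(labels, speakers, config.fractions, seed=seed + 1)
    if config.swap_eval:
        split = split.swapped()

    frame_features, feature_names = extract_frame_features(
        corpus, config.representation, config.features_from
    )

    table = None
    if config.normalization == "age_sex":
        table = norm_mod.build_normative_table(
            split.train,
            frame_features["X"],
            feature_names,
            speakers,
            representation=config.representation,
            forbidden_speakers=split.val_ids | split.test_ids,
        )

    tensors = build_tensors(
        frame_features, feature_names, labels, speakers,
        config.representation, config.normalization, table,
    )

    train_df = corpus_mod.balance_train(split.train, seed=seed + 2)
    val_df = corpus_mod.balance_eval(split.val, seed=seed + 3)
    test_df = corpus_mod.balance_eval(split.test, seed=seed + 4)

    X_tr, y_tr, _ = _design(train_df, tensors, config.family)
    X_va, y_va, g_va = _design(val_df, tensors, config.family)
    X_te, y_te, g_te = _design(test_df, tensors, config.family)

    hp = dict(config.hyperparams)
    grnn_cfg = GrnnConfig(**{**config.grnn, "seed": seed})
    trial_log = None
    if config.n_trials > 0:
        hp, trial_log = tune(
            config.family, X_tr, y_tr, X_va, y_va, g_va,
            n_trials=config.n_trials, seed=seed + 5, grnn_config=grnn_cfg,
        )
    if config.family == "grnn":
        for k, v in hp.items():
            setattr(grnn_cfg, k, v)
        bundle = train_grnn(
            grnn_cfg, X_tr, y_tr, X_va, y_va, g_va, train_speakers=split.train_ids
        )
    else:
        bundle = train_shallow(
            config.family, X_tr, y_tr, hp, seed=seed + 6, train_speakers=split.train_ids
        )

    condition = {
        "representation": config.representation,
        "normalization": config.normalization,
        "family": config.family,
        "swap_eval": config.swap_eval,
    }

    _, pred_oob = predict(bundle, X_te)
    f1_oob, sum_oob = participant_f1(y_te, pred_oob, g_te)
    reports = {
        "out_of_box": EvaluationReport(
            per_participant_f1=f1_oob,
            summary=sum_oob,
            confusion=participant_confusion(y_te, pred_oob, g_te),
            condition={**condition, "timepoint": "out_of_box"},
        )
    }

    if config.personalize:
        pred_pers = pred_oob.copy()
        for spk in sorted(set(g_te)):
            m = g_te == spk
            try:
                if config.family == "grnn":
                    _, pr, _ = personalize_grnn(
                        bundle, X_te[m], y_te[m], spk,
                        fine_tune_epochs=grnn_cfg.personal_epochs,
                        learning_rate=grnn_cfg.personal_learning_rate,
                        seed=seed + 7,
                    )
                else:
                    _, pr, _ = personalize_shallow(bundle, X_te[m], y_te[m], spk, seed=seed + 7)
                pred_pers[m] = pr
            except DataError as exc:
                log.warning("personalization skipped for %s: %s", spk, exc)
        f1_pers, sum_pers = participant_f1(y_te, pred_pers, g_te)
        reports["personalized"] = EvaluationReport(
            per_participant_f1=f1_pers,
            summary=sum_pers,
            confusion=participant_confusion(y_te, pred_pers, g_te),
            condition={**condition, "timepoint": "personalized"},
        )
        best, sum_best = combined_best(f1_pers, f1_oob)
        reports["best"] = EvaluationReport(
            per_participant_f1=best,
            summary=sum_best,
            condition={**condition, "timepoint": "best"},
        )

    out = {
        "reports": reports,
        "split": split,
        "bundle": bundle,
        "tensors": tensors,
        "labels": labels,
        "speakers": speakers,
        "feature_names": feature_names,
        "trial_log": trial_log,
        "config": config,
    }
    if config.out_dir:
        _write_run(out, Path(config.out_dir))
    return out


def _write_run(out: dict, run_dir: Path) -> None:
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.json").write_text(out["config"].to_json())
    payload = {k: r.to_dict() for k, r in out["reports"].items()}
    (run_dir / "reports.json").write_text(json.dumps(payload, indent=1))
    if out["trial_log"] is not None:
        out["trial_log"].to_csv(run_dir / "trials.csv", index=False)
    split = out["split"]
    for name in ("train_ids", "val_ids", "test_ids"):
        (run_dir / f"{name}.txt").write_text("\n".join(sorted(getattr(split, name))) + "\n")


def replicate_swap(config: RunConfig) -> dict:
    """Primary run plus a full rerun with validation/test exchanged; the
    union merges the two disjoint per-speaker result sets."""
    primary = run_pipeline(config)
    swapped_cfg = dataclasses.replace(config, swap_eval=not config.swap_eval, out_dir=None)
    replication = run_pipeline(swapped_cfg)
    union = {}
    for key in primary["reports"]:
        if key not in replication["reports"]:
            continue
        merged = dict(primary["reports"][key].per_participant_f1)
        overlap = set(merged) & set(replication["reports"][key].per_participant_f1)
        if overlap:
            raise DataError(f"replication speakers overlap primary: {sorted(overlap)[:5]}")
        merged.update(replication["reports"][key].per_participant_f1)
        union[key] = EvaluationReport(
            per_participant_f1=merged,
            summary=_summary_of(merged),
            condition={**primary["reports"][key].condition, "timepoint": key, "union": True},
        )
    return {"primary": primary, "replication": replication, "union": union}


def _summary_of(scores: dict[str, float]) -> dict:
    vals = np.array(list(scores.values()), dtype=float)
    return {
        "mean": float(np.mean(vals)),
        "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
        "median": float(np.median(vals)),
        "n": int(vals.size),
    }


def run_grid(
    base: RunConfig,
    families=("random_forest", "sgd_linear"),
    representations=("formant",),
    normalizations=("age_sex", "utterance"),
    timepoints=("out_of_box", "personalized"),
) -> tuple[pd.DataFrame, dict]:
    """Condition factorial; returns the per-speaker F1 long table (for the
    mixed-model contrast) and every run's reports."""
    rows = []
    runs = {}
    for family in families:
        for rep in representations:
            for norm in normalizations:
                cfg = dataclasses.replace(
                    base, family=family, representation=rep, normalization=norm, out_dir=None
                )
                out = run_pipeline(cfg)
                runs[(family, rep, norm)] = out["reports"]
                for tp in timepoints:
                    if tp not in out["reports"]:
                        continue
                    for spk, f1 in out["reports"][tp].per_participant_f1.items():
                        rows.append(
                            {
                                "speaker_id": spk,
                                "family": family,
                                "representation": rep,
                                "normalization": norm,
                                "timepoint": tp,
                                "f1": f1,
                            }
                        )
    return pd.DataFrame(rows), runs


def render_report(reports: dict) -> str:
    """Markdown summary: per-condition mean (SD) table and confusions."""
    lines = ["# Rhoticity classification report", ""]
    lines.append("| condition | timepoint | mean F1 | SD | median | n |")
    lines.append("|---|---|---|---|---|---|")
    for key, rep in reports.items():
        c = rep.condition
        cond = f"{c.get('representation','?')}/{c.get('normalization','?')}/{c.get('family','?')}"
        s = rep.summary
        lines.append(
            f"| {cond} | {c.get('timepoint', key)} | {s['mean']:.3f} | {s['sd']:.3f} "
            f"| {s['median']:.3f} | {s['n']} |"
        )
    for key, rep in reports.items():
        if rep.confusion is None:
            continue
        lines += [
            "",
            f"## Participant-weighted confusion — {key}",
            "| truth \\ predicted | derhotic | fully rhotic |",
            "|---|---|---|",
            f"| derhotic | {rep.confusion[0,0]:.2f} | {rep.confusion[0,1]:.2f} |",
            f"| fully rhotic | {rep.confusion[1,0]:.2f} | {rep.confusion[1,1]:.2f} |",
        ]
    return "\n".join(lines) + "\n"
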