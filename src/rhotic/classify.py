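"""Classifier families, hyperparameter tuning, and per-speaker personalization.

Three families consume the feature tensors:

* ``random_forest`` and ``sgd_linear`` (the *shallow* families) read the
  flattened per-window median slice. Both support warm-start retraining,
  which is what personalization exploits: the forest grows 100 additional
  participant-specific trees, the linear model trains ten additional
  stochastic-gradient epochs on the participant's data.
* ``grnn`` reads the full 8-statistic window sequence through the GRU
  network in :mod:`rhotic.grnn`; personalization fine-tunes a copy of the
  trained weights at a reduced learning rate.

Personalization always runs stratified fivefold cross-validation within the
speaker, so every utterance receives exactly one held-out prediction. Base
model states are never mutated — personalized states are derived copies,
kept per (speaker, fold) in the bundle.

Hyperparameter search is seeded random sampling over documented spaces,
scored by mean participant-specific validation F1.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .errors import DataError, ParameterError, StateError
from .grnn import GRNNClassifier, _sigmoid

log = logging.getLogger(__name__)

SHALLOW_FAMILIES = ("random_forest", "sgd_linear")
FAMILIES = SHALLOW_FAMILIES + ("grnn",)

#: trees added per participant during forest personalization
PERSONALIZATION_TREES = 100
#: extra stochastic-gradient epochs during linear-model personalization
PERSONALIZATION_EPOCHS = 10
#: within-speaker cross-validation folds for personalization
PERSONALIZATION_FOLDS = 5


@dataclass
class GrnnConfig:
    """Architecture and optimization settings of the gated recurrent net."""

    hidden_size: int = 64
    n_layers: int = 1
    dense_size: int = 32
    activation: str = "hardswish"
    optimizer: str = "rmsprop"
    loss: str = "bce"
    max_epochs: int = 25
    early_stopping_patience: int = 5
    learning_rate: float = 3e-3
    personal_learning_rate: float | None = None  # default 0.1 × base
    personal_epochs: int = 5
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if not self.max_epochs >= self.early_stopping_patience >= 1:
            raise ParameterError("require max_epochs >= patience >= 1")

    def build(self, input_dim: int) -> GRNNClassifier:
        return GRNNClassifier(
            input_dim=input_dim,
            hidden_size=self.hidden_size,
            dense_size=self.dense_size,
            n_layers=self.n_layers,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            patience=self.early_stopping_patience,
            batch_size=self.batch_size,
            seed=self.seed,
        )


@dataclass
class ClassifierBundle:
    """A trained base model plus its per-(speaker, fold) personalized states."""

    family: str
    model: object
    hyperparams: dict = field(default_factory=dict)
    scaler: StandardScaler | None = None
    train_speakers: frozenset = frozenset()
    personalized: dict = field(default_factory=dict)  # (speaker_id, fold) -> model

    def personalized_for(self, speaker_id: str) -> list:
        return [m for (spk, _), m in sorted(self.personalized.items()) if spk == speaker_id]


# ---------------------------------------------------------------------------
# shallow training
# ---------------------------------------------------------------------------


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if not np.all(np.isfinite(X)):
        raise DataError("features must be finite")
    if len(np.unique(y)) < 2:
        raise DataError("single-class training data")
    return X, y


def _fit_sgd_epochs(model: SGDClassifier, X, y, epochs: int, seed: int):
    rng = np.random.default_rng(seed)
    classes = np.array([0, 1])
    for _ in range(epochs):
        order = rng.permutation(len(X))
        model.partial_fit(X[order], y[order], classes=classes)
    return model


def train_shallow(
    family: str,
    X,
    y,
    hyperparams: dict | None = None,
    seed: int = 0,
    train_speakers=frozenset(),
) -> ClassifierBundle:
    """Fit a base shallow model on (median-view) features.

    Random forest: ``n_estimators`` / ``max_depth`` / ``min_samples_leaf``.
    SGD linear: ``loss`` (log_loss or hinge), ``alpha``, ``epochs``; trained
    by explicit per-epoch ``partial_fit`` so personalization can continue
    the same optimization.
    """
    if family not in SHALLOW_FAMILIES:
        raise ParameterError(f"unknown shallow family {family!r}")
    X, y = _check_xy(X, y)
    hp = dict(hyperparams or {})
    if family == "random_forest":
        model = RandomForestClassifier(
            n_estimators=int(hp.get("n_estimators", 300)),
            max_depth=hp.get("max_depth", 16),
            min_samples_leaf=int(hp.get("min_samples_leaf", 1)),
            random_state=seed,
            n_jobs=1,
        )
        model.fit(X, y)
        scaler = None
    else:
        scaler = StandardScaler().fit(X)
        model = SGDClassifier(
            loss=hp.get("loss", "log_loss"),
            alpha=float(hp.get("alpha", 1e-4)),
            random_state=seed,
        )
        _fit_sgd_epochs(model, scaler.transform(X), y, int(hp.get("epochs", 30)), seed)
    return ClassifierBundle(
        family=family,
        model=model,
        hyperparams=hp,
        scaler=scaler,
        train_speakers=frozenset(train_speakers),
    )


def train_grnn(
    config: GrnnConfig,
    X_seq,
    y,
    X_val=None,
    y_val=None,
    val_groups=None,
    train_speakers=frozenset(),
) -> ClassifierBundle:
    """Train the GRU network on full-statistic window sequences with early
    stopping on validation mean participant F1."""
    X_seq = np.asarray(X_seq, dtype=float)
    _, y = _check_xy(X_seq.reshape(len(X_seq), -1), y)
    model = config.build(input_dim=X_seq.shape[2])
    model.fit(X_seq, y, X_val=X_val, y_val=y_val, val_groups=val_groups)
    return ClassifierBundle(
        family="grnn",
        model=model,
        hyperparams=asdict(config),
        train_speakers=frozenset(train_speakers),
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def _proba_one(family: str, model, scaler, X) -> np.ndarray:
    if family == "random_forest":
        return model.predict_proba(X)[:, 1]
    if family == "sgd_linear":
        Xs = scaler.transform(X) if scaler is not None else X
        if hasattr(model, "predict_proba") and model.loss == "log_loss":
            return model.predict_proba(Xs)[:, 1]
        # hinge loss has no native probability; documented sigmoid map of the margin
        return _sigmoid(model.decision_function(Xs))
    return model.predict_proba(X)


def predict(bundle: ClassifierBundle, X, speaker_id: str | None = None, fold: int | None = None):
    """(probabilities, labels) for features ``X``.

    With a ``speaker_id`` whose personalized states exist, the matching
    fold state is used (or, lacking a fold, fold probabilities are
    averaged); otherwise the base model answers.
    """
    if bundle.model is None:
        raise StateError("bundle has no trained model")
    X = np.asarray(X, dtype=float)
    if speaker_id is not None:
        if fold is not None and (speaker_id, fold) in bundle.personalized:
            models = [bundle.personalized[(speaker_id, fold)]]
        else:
            models = bundle.personalized_for(speaker_id) or [bundle.model]
    else:
        models = [bundle.model]
    probas = np.mean([_proba_one(bundle.family, m, bundle.scaler, X) for m in models], axis=0)
    return probas, (probas >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# personalization
# ---------------------------------------------------------------------------


def _personal_folds(y, n_folds, seed):
    y = np.asarray(y, dtype=int).ravel()
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise DataError(
            f"speaker needs >= {n_folds} utterances of each class "
            f"(has {counts[1]} rhotic / {counts[0]} derhotic)"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def personalize_shallow(
    bundle: ClassifierBundle,
    X_sp,
    y_sp,
    speaker_id: str,
    n_folds: int = PERSONALIZATION_FOLDS,
    seed: int = 0,
):
    """Warm-start the base model per fold on one speaker's data.

    Forest: +100 trees fitted to the fold's training part. SGD: ten extra
    epochs. Returns (held_out_proba, held_out_pred, fold_of) aligned with
    the speaker's rows; each utterance is predicted by the fold in which it
    was held out. Personalized states are stored on the bundle.
    """
    if bundle.family not in SHALLOW_FAMILIES:
        raise ParameterError("personalize_shallow expects a shallow bundle")
    X_sp = np.asarray(X_sp, dtype=float)
    y_sp = np.asarray(y_sp, dtype=int).ravel()
    folds = _personal_folds(y_sp, n_folds, seed)
    proba = np.empty(len(y_sp))
    fold_of = np.empty(len(y_sp), dtype=int)
    for fi, (tr, te) in enumerate(folds):
        pers = copy.deepcopy(bundle.model)
        if bundle.family == "random_forest":
            pers.set_params(warm_start=True, n_estimators=pers.n_estimators + PERSONALIZATION_TREES)
            pers.fit(X_sp[tr], y_sp[tr])
        else:
            Xtr = bundle.scaler.transform(X_sp[tr]) if bundle.scaler is not None else X_sp[tr]
            _fit_sgd_epochs(pers, Xtr, y_sp[tr], PERSONALIZATION_EPOCHS, seed + fi)
        bundle.personalized[(speaker_id, fi)] = pers
        proba[te] = _proba_one(bundle.family, pers, bundle.scaler, X_sp[te])
        fold_of[te] = fi
    return proba, (proba >= 0.5).astype(int), fold_of


def personalize_grnn(
    bundle: ClassifierBundle,
    X_sp,
    y_sp,
    speaker_id: str,
    n_folds: int = PERSONALIZATION_FOLDS,
    fine_tune_epochs: int = 5,
    learning_rate: float | None = None,
    seed: int = 0,
):
    """Fine-tune copies of the trained GRU per within-speaker fold."""
    if bundle.family != "grnn":
        raise ParameterError("personalize_grnn expects a grnn bundle")
    X_sp = np.asarray(X_sp, dtype=float)
    y_sp = np.asarray(y_sp, dtype=int).ravel()
    if learning_rate is None:
        lr = bundle.hyperparams.get("personal_learning_rate")
        learning_rate = lr if lr is not None else 0.1 * bundle.model.learning_rate
    folds = _personal_folds(y_sp, n_folds, seed)
    proba = np.empty(len(y_sp))
    fold_of = np.empty(len(y_sp), dtype=int)
    for fi, (tr, te) in enumerate(folds):
        pers = bundle.model.fine_tune(
            X_sp[tr], y_sp[tr], epochs=fine_tune_epochs, learning_rate=learning_rate, seed=seed + fi
        )
        bundle.personalized[(speaker_id, fi)] = pers
        proba[te] = pers.predict_proba(X_sp[te])
        fold_of[te] = fi
    return proba, (proba >= 0.5).astype(int), fold_of


# ---------------------------------------------------------------------------
# bundle persistence
# ---------------------------------------------------------------------------

BUNDLE_FORMAT_VERSION = 1


def save_bundle(bundle: ClassifierBundle, directory) -> None:
    """Serialize a bundle: human-readable config JSON + weight blobs."""
    import pickle
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "family": bundle.family,
        "hyperparams": bundle.hyperparams,
        "train_speakers": sorted(bundle.train_speakers),
        "personalized_keys": [list(k) for k in sorted(bundle.personalized)],
    }
    (d / "config.json").write_text(json.dumps(meta, indent=1))
    with open(d / "weights.pkl", "wb") as fh:
        pickle.dump(
            {"model": bundle.model, "scaler": bundle.scaler, "personalized": bundle.personalized},
            fh,
        )


def load_bundle(directory) -> ClassifierBundle:
    import pickle
    from pathlib import Path

    d = Path(directory)
    meta = json.loads((d / "config.json").read_text())
    if meta.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise StateError(f"unsupported bundle format {meta.get('format_version')}")
    with open(d / "weights.pkl", "rb") as fh:
        blobs = pickle.load(fh)
    return ClassifierBundle(
        family=meta["family"],
        model=blobs["model"],
        hyperparams=meta["hyperparams"],
        scaler=blobs["scaler"],
        train_speakers=frozenset(meta["train_speakers"]),
        personalized=blobs["personalized"],
    )


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------


def _mean_participant_f1(y_true, y_pred, groups) -> float:
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    groups = np.asarray(groups)
    return float(
        np.mean(
            [
                f1_score(y_true[groups == g], y_pred[groups == g], zero_division=0)
                for g in np.unique(groups)
            ]
        )
    )


def _sample_params(family: str, rng, space: dict | None) -> dict:
    if space is not None:  # collapsed / custom spaces (tests, configs)
        return {
            k: (v if not isinstance(v, (list, tuple)) else v[rng.integers(len(v))])
            for k, v in space.items()
        }
    if family == "random_forest":
        return {
            "n_estimators": int(rng.integers(100, 501)),
            "max_depth": int(rng.integers(4, 33)),
            "min_samples_leaf": int(rng.integers(1, 9)),
        }
    if family == "sgd_linear":
        return {
            "loss": ["log_loss", "hinge"][rng.integers(2)],
            "alpha": float(10 ** rng.uniform(-6, -2)),
            "epochs": int(rng.integers(10, 101)),
        }
    if family == "grnn":
        return {
            "hidden_size": int(rng.integers(16, 129)),
            "learning_rate": float(10 ** rng.uniform(-4, -2)),
        }
    raise ParameterError(f"unknown family {family!r}")


def tune(
    family: str,
    X_train,
    y_train,
    X_val,
    y_val,
    val_groups,
    n_trials: int = 50,
    seed: int = 0,
    search_space: dict | None = None,
    grnn_config: GrnnConfig | None = None,
):
    """Seeded random search maximizing mean participant validation F1.

    Returns (best_hyperparams, trial_log) where the log is a DataFrame of
    every sampled configuration and its score; the returned configuration
    attains the log's maximum (first such trial on ties).
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    best_score, best_hp = -np.inf, None
    for trial in range(n_trials):
        hp = _sample_params(family, rng, search_space)
        if family == "grnn":
            cfg = copy.deepcopy(grnn_config) if grnn_config is not None else GrnnConfig()
            for k, v in hp.items():
                setattr(cfg, k, v)
            cfg.seed = seed + trial
            bundle = train_grnn(cfg, X_train, y_train, X_val, y_val, val_groups)
        else:
            bundle = train_shallow(family, X_train, y_train, hp, seed=seed + trial)
        _, pred = predict(bundle, X_val)
        score = _mean_participant_f1(y_val, pred, val_groups)
        records.append({"trial": trial, "params": json.dumps(hp), "score": score})
        if score > best_score:
            best_score, best_hp = score, hp
    return best_hp, pd.DataFrame(records)
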