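"""Feature normalization: age-and-sex normative z-scores vs. utterance z-scores.

Two competing normalizations of the frame-level features are compared by the
experiments:

* **age-and-sex** — each feature is z-standardized against the nearest
  age-and-sex-matched mean and SD of *fully rhotic* productions, taken from
  a normative table built on training-set speakers only (leakage-guarded);
* **utterance** — each feature is z-standardized against the mean and SD of
  its own utterance's frame distribution, removing absolute level entirely.

In both conditions the Δ(F3−F2) delta series is afterwards rescaled linearly
and symmetrically into [−10, +10].

Normalization operates on frame-level values *before* tensorization, so all
eight window statistics summarize normalized values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acoustics import DELTA_FEATURES
from .errors import ConfigurationError, DataError

log = logging.getLogger(__name__)

#: variance floor for degenerate normative cells
SD_FLOOR = 1e-6


def scale_deltas(series: np.ndarray) -> np.ndarray:
    """Symmetric linear rescaling of a delta series into [−10, +10]:
    y = 10·x / max(|x|); an all-zero (or all-undefined) series maps to
    zeros. NaNs pass through."""
    x = np.asarray(series, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size == 0:
        return np.zeros_like(x)
    m = float(np.max(np.abs(finite)))
    if m == 0.0:
        return np.where(np.isfinite(x), 0.0, x)
    return 10.0 * x / m


@dataclass
class NormativeTable:
    """Per (age-year, sex, feature) mean and SD of fully rhotic frames."""

    rows: pd.DataFrame  # columns: age_years, sex, feature, mean, sd
    representation: str = "formant"

    def __post_init__(self):
        need = {"age_years", "sex", "feature", "mean", "sd"}
        if not need.issubset(self.rows.columns):
            raise DataError(f"normative table needs columns {sorted(need)}")
        if len(self.rows) and (self.rows["sd"] <= 0).any():
            raise DataError("normative SDs must be positive")

    def lookup(self, feature: str, age_years: float, sex: str) -> tuple[float, float]:
        """(mean, sd) of the nearest age-matched row of the same sex; ties
        resolve to the younger row; a sex absent from the table falls back
        to the other sex with a log message."""
        if self.rows.empty:
            raise ConfigurationError("empty normative table")
        key = (feature, round(float(age_years), 6), sex)
        cache = self.__dict__.setdefault("_cache", {})
        if key in cache:
            return cache[key]
        cand = self.rows[(self.rows["feature"] == feature) & (self.rows["sex"] == sex)]
        if cand.empty:
            log.warning("normative table has no %s rows for sex=%s; using other sex", feature, sex)
            cand = self.rows[self.rows["feature"] == feature]
        if cand.empty:
            raise ConfigurationError(f"normative table has no rows for feature {feature!r}")
        dist = (cand["age_years"] - age_years).abs()
        best = cand.loc[dist == dist.min()].sort_values("age_years").iloc[0]
        out = (float(best["mean"]), float(best["sd"]))
        cache[key] = out
        return out

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, representation: str = "formant") -> "NormativeTable":
        return cls(rows=pd.read_csv(path), representation=representation)


def build_normative_table(
    utterances: pd.DataFrame,
    frame_features: dict,
    feature_names: tuple[str, ...],
    speakers: pd.DataFrame,
    representation: str = "formant",
    min_support: int = 10,
    forbidden_speakers=None,
) -> NormativeTable:
    """Build the age-and-sex normative table from fully rhotic training data.

    ``utterances`` carries (utterance_id, speaker_id, label);
    ``frame_features`` maps utterance_id → (n_frames × n_features) arrays.
    Frames of label-1 utterances are pooled per (integer age year, sex) and
    reduced to a per-feature mean and SD; cells with fewer than
    ``min_support`` frames are omitted (downstream lookup falls back to the
    nearest populated cell). ``forbidden_speakers`` (the validation/test
    IDs) are refused outright, guarding against leakage.
    """
    if forbidden_speakers:
        bad = set(utterances["speaker_id"]) & set(forbidden_speakers)
        if bad:
            raise ConfigurationError(
                f"normative table must not see evaluation speakers: {sorted(bad)[:5]}"
            )
    meta = speakers.set_index("speaker_id")
    pools: dict[tuple[int, str], list[np.ndarray]] = {}
    for _, row in utterances.iterrows():
        if row["label"] != 1:
            continue
        X = frame_features.get(row["utterance_id"])
        if X is None:
            continue
        age = int(meta.loc[row["speaker_id"], "age_years"])
        sex = str(meta.loc[row["speaker_id"], "sex"])
        pools.setdefault((age, sex), []).append(np.asarray(X, dtype=float))
    if not pools:
        raise DataError("no fully rhotic utterances to build a normative table from")

    out = []
    for (age, sex), mats in sorted(pools.items()):
        X = np.vstack(mats)
        for j, feat in enumerate(feature_names):
            col = X[:, j]
            col = col[np.isfinite(col)]
            if col.size < min_support:
                continue
            out.append(
                {
                    "age_years": age,
                    "sex": sex,
                    "feature": feat,
                    "mean": float(np.mean(col)),
                    "sd": max(float(np.std(col)), SD_FLOOR),
                }
            )
    return NormativeTable(rows=pd.DataFrame(out), representation=representation)


def normalize_age_sex(
    X: np.ndarray,
    feature_names: tuple[str, ...],
    table: NormativeTable,
    age_years: float,
    sex: str,
) -> np.ndarray:
    """z-standardize frame features against the nearest age-and-sex-matched
    fully rhotic norms; delta features are then rescaled to ±10."""
    X = np.asarray(X, dtype=float)
    out = np.empty_like(X)
    for j, feat in enumerate(feature_names):
        mean, sd = table.lookup(feat, age_years, sex)
        out[:, j] = (X[:, j] - mean) / sd
    for j, feat in enumerate(feature_names):
        if feat in DELTA_FEATURES:
            out[:, j] = scale_deltas(out[:, j])
    return out


def normalize_utterance(X: np.ndarray, feature_names: tuple[str, ...]) -> np.ndarray:
    """z-standardize each feature against its own utterance's frame
    distribution; zero-SD features collapse to all zeros (logged); delta
    features are then rescaled to ±10."""
    X = np.asarray(X, dtype=float)
    out = np.empty_like(X)
    for j, feat in enumerate(feature_names):
        col = X[:, j]
        finite = col[np.isfinite(col)]
        if finite.size < 2 or float(np.std(finite)) == 0.0:
            log.info("utterance normalization: zero-SD feature %s set to zeros", feat)
            out[:, j] = np.where(np.isfinite(col), 0.0, col)
            continue
        out[:, j] = (col - float(np.mean(finite))) / float(np.std(finite))
    for j, feat in enumerate(feature_names):
        if feat in DELTA_FEATURES:
            out[:, j] = scale_deltas(out[:, j])
    return out


def normalize_frames(
    X: np.ndarray,
    feature_names: tuple[str, ...],
    mode: str,
    table: NormativeTable | None = None,
    age_years: float | None = None,
    sex: str | None = None,
) -> np.ndarray:
    """Dispatch on the normalization condition {none, utterance, age_sex}."""
    if mode == "none":
        return np.asarray(X, dtype=float)
    if mode == "utterance":
        return normalize_utterance(X, feature_names)
    if mode == "age_sex":
        if table is None or age_years is None or sex is None:
            raise ConfigurationError("age_sex normalization needs a table and speaker age/sex")
        return normalize_age_sex(X, feature_names, table, age_years, sex)
    raise ConfigurationError(f"unknown normalization mode {mode!r}")
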