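"""Label derivation and experimental dataset construction.

Binary class labels come from the mean of multi-listener rhoticity ratings,
with 0.66 as the (inclusive) floor for class 1, the fully rhotic class.
Speakers are split into participant-disjoint training / validation / test
sets holding roughly 70 / 15 / 15 % of utterances: typical speakers are
confined to training, and only *stimulable* speakers with residual speech
sound disorder (RSSD) — fully-rhotic : derhotic utterance ratio above
0.33 — are eligible for validation and test, allocated by age-and-sex
stratified random draw without replacement. Training classes are balanced
1:1; evaluation sets are balanced to the 2:1 correct : incorrect ratio
expected in clinical use, within speaker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

log = logging.getLogger(__name__)

#: inclusive minimum mean rating for the fully rhotic class
LABEL_FLOOR = 0.66

#: fully-rhotic : derhotic count ratio above which a speaker is stimulable
STIMULABILITY_RATIO = 0.33


@dataclass(frozen=True)
class LabeledUtterance:
    utterance_id: str
    speaker_id: str
    rating_mean: float
    label: int
    unanimous: bool


def derive_label(ratings) -> tuple[float, int, bool]:
    """(rating_mean, label, unanimous) from one utterance's listener votes.

    label = 1 iff the arithmetic mean rating is at or above the 0.66 floor;
    unanimous iff all votes are identical.
    """
    r = np.asarray(ratings, dtype=float)
    if r.size == 0:
        raise DataError("empty rating list")
    if np.any((r < 0) | (r > 1)):
        raise DataError("ratings must lie in [0, 1]")
    mean = float(np.mean(r))
    label = 1 if mean >= LABEL_FLOOR else 0
    unanimous = bool(np.all(r == r[0]))
    return mean, label, unanimous


def label_corpus(corpus) -> pd.DataFrame:
    """One row per utterance: ids, rating_mean, label, unanimous, plus the
    generator's true class for diagnostics."""
    rows = []
    for u in corpus.utterances:
        mean, label, unan = derive_label(u.ratings)
        rows.append(
            {
                "utterance_id": u.utterance_id,
                "speaker_id": u.speaker_id,
                "rating_mean": mean,
                "label": label,
                "unanimous": unan,
                "rhotic_true": int(u.rhotic),
            }
        )
    return pd.DataFrame(rows)


def speakers_frame(corpus) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "speaker_id": [s.speaker_id for s in corpus.speakers],
            "age_years": [s.age_years for s in corpus.speakers],
            "sex": [s.sex for s in corpus.speakers],
            "cohort": [s.cohort for s in corpus.speakers],
        }
    )


def is_stimulable(labels) -> bool:
    """Whether a speaker's fully-rhotic : derhotic utterance ratio exceeds
    0.33. A speaker with no derhotic utterance at all is treated as
    stimulable (infinite ratio) and logged."""
    lab = np.asarray(labels, dtype=int)
    if lab.size == 0:
        raise DataError("no utterances for stimulability")
    n1 = int(np.sum(lab == 1))
    n0 = int(np.sum(lab == 0))
    if n0 == 0:
        log.info("speaker with zero derhotic utterances: ratio +inf, stimulable")
        return True
    return n1 / n0 > STIMULABILITY_RATIO


@dataclass
class DatasetSplit:
    """Participant-disjoint speaker allocation plus per-set utterances."""

    train_ids: frozenset
    val_ids: frozenset
    test_ids: frozenset
    train: pd.DataFrame = field(default_factory=pd.DataFrame)
    val: pd.DataFrame = field(default_factory=pd.DataFrame)
    test: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if (
            self.train_ids & self.val_ids
            or self.train_ids & self.test_ids
            or self.val_ids & self.test_ids
        ):
            raise DataError("split sets must be speaker-disjoint")

    def swapped(self) -> "DatasetSplit":
        """Validation/test roles exchanged (replication experiment)."""
        return DatasetSplit(
            train_ids=self.train_ids,
            val_ids=self.test_ids,
            test_ids=self.val_ids,
            train=self.train,
            val=self.test,
            test=self.val,
        )


def split_participants(
    utterances: pd.DataFrame,
    speakers: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    age_bin_years: float = 2.0,
) -> DatasetSplit:
    """Allocate speakers to train/val/test.

    Typical speakers are forced into training. Stimulable RSSD speakers are
    drawn without replacement into validation and test, stratified by
    (2-year age bin × sex), until each set approaches its utterance
    fraction; all remaining speakers train. Deterministic given ``seed``.
    """
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ConfigurationError(f"fractions must sum to 1, got {fractions}")
    meta = speakers.set_index("speaker_id")
    per_spk = utterances.groupby("speaker_id")

    candidates = []  # stimulable RSSD speakers
    forced_train = []
    for spk, grp in per_spk:
        if meta.loc[spk, "cohort"] != "RSSD":
            forced_train.append(spk)
        elif is_stimulable(grp["label"].to_numpy()):
            candidates.append(spk)
        else:
            forced_train.append(spk)
    if not candidates:
        raise ConfigurationError(
            "no stimulable RSSD speakers available for validation/test "
            f"({len(forced_train)} speakers all forced to training)"
        )

    counts = per_spk.size()
    total = int(counts.sum())
    targets = {"val": fractions[1] * total, "test": fractions[2] * total}

    # age-bin × sex strata, shuffled within stratum
    rng = np.random.default_rng(seed)
    strata: dict[tuple, list[str]] = {}
    for spk in sorted(candidates):
        key = (
            int(meta.loc[spk, "age_years"] // age_bin_years),
            str(meta.loc[spk, "sex"]),
        )
        strata.setdefault(key, []).append(spk)
    for key in sorted(strata):
        rng.shuffle(strata[key])

    alloc = {"val": [], "test": []}
    filled = {"val": 0, "test": 0}
    stratum_keys = sorted(strata)
    progress = True
    while progress:
        progress = False
        for key in stratum_keys:
            if not strata[key]:
                continue
            # the set currently furthest below its target receives next
            deficits = {s: targets[s] - filled[s] for s in ("val", "test")}
            dest = max(deficits, key=lambda s: deficits[s])
            if deficits[dest] <= 0:
                continue
            spk = strata[key].pop()
            alloc[dest].append(spk)
            filled[dest] += int(counts[spk])
            progress = True

    leftover = [s for lst in strata.values() for s in lst]
    train_ids = frozenset(forced_train) | frozenset(leftover)
    val_ids = frozenset(alloc["val"])
    test_ids = frozenset(alloc["test"])
    if not val_ids or not test_ids:
        raise ConfigurationError(
            f"too few stimulable RSSD speakers to fill both evaluation sets "
            f"(got {len(candidates)} candidates)"
        )

    def _sel(ids):
        return utterances[utterances["speaker_id"].isin(ids)].reset_index(drop=True)

    return DatasetSplit(
        train_ids=train_ids,
        val_ids=val_ids,
        test_ids=test_ids,
        train=_sel(train_ids),
        val=_sel(val_ids),
        test=_sel(test_ids),
    )


def balance_train(utterances: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Downsample the majority class to a 1:1 ratio, without replacement."""
    df = utterances.sort_values("utterance_id").reset_index(drop=True)
    n1 = int((df["label"] == 1).sum())
    n0 = int((df["label"] == 0).sum())
    if n1 == 0 or n0 == 0:
        raise DataError(f"both classes required for balancing (have {n1} / {n0})")
    k = min(n1, n0)
    rng = np.random.default_rng(seed)
    keep = []
    for lab in (0, 1):
        idx = df.index[df["label"] == lab].to_numpy()
        keep.append(rng.choice(idx, size=k, replace=False))
    out = df.loc[np.sort(np.concatenate(keep))].reset_index(drop=True)
    return out


def balance_eval(
    utterances: pd.DataFrame,
    seed: int = 0,
    per_speaker: bool = True,
) -> pd.DataFrame:
    """Downsample to the 2:1 fully-rhotic : derhotic clinical ratio.

    Applied within speaker (each evaluated speaker's retained set is 2:1,
    at the largest achievable integer pair); speakers lacking a class, or
    without at least one derhotic and two fully rhotic utterances, are
    excluded with a warning.
    """
    df = utterances.sort_values("utterance_id").reset_index(drop=True)
    rng = np.random.default_rng(seed)
    groups = df.groupby("speaker_id") if per_speaker else [(None, df)]
    parts = []
    for spk, grp in groups:
        n1 = int((grp["label"] == 1).sum())
        n0 = int((grp["label"] == 0).sum())
        k0 = min(n0, n1 // 2)
        k1 = 2 * k0
        if k0 == 0:
            log.warning("balance_eval: speaker %s lacks a 2:1-balanceable class mix "
                        "(%d rhotic / %d derhotic), excluded", spk, n1, n0)
            continue
        sel = []
        for lab, k in ((1, k1), (0, k0)):
            idx = grp.index[grp["label"] == lab].to_numpy()
            sel.append(rng.choice(idx, size=k, replace=False))
        parts.append(df.loc[np.sort(np.concatenate(sel))])
    if not parts:
        raise DataError("no speaker survived 2:1 balancing")
    return pd.concat(parts).reset_index(drop=True)
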