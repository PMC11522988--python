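"""Participant-level evaluation, condition contrasts, and explainability.

The study outcome is the F1 of the fully rhotic class computed *within*
each evaluated speaker, then summarized across speakers with equal speaker
weight (clinical utility is speaker-level). The same equal weighting builds
the participant-weighted, ground-truth-normalized confusion matrix.

Condition effects (normalization × representation × timepoint) are
estimated on the per-speaker F1 table with a linear mixed model — treatment
coding with utterance-normalized / MFCC / out-of-box reference levels,
crossed random intercepts for participant and classifier family, fitted by
restricted maximum likelihood. The demographic bias probe is an ordinary
linear model of per-speaker F1 on age, sex and their interaction.

Global feature attribution of the gated recurrent network follows the
expected-gradients (GradientShap-style) scheme: gradients of the class-1
probability taken at random interpolates between each input and baselines
sampled from a background set of perceptually ambiguous utterances,
multiplied by input-minus-baseline, then averaged over utterances, the 10
time windows, and the 8 summary statistics to one signed value per feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from sklearn.metrics import f1_score

from .errors import DataError, ParameterError, StateError

log = logging.getLogger(__name__)


def _f1_summary(scores: dict[str, float]) -> dict:
    vals = np.array(list(scores.values()), dtype=float)
    return {
        "mean": float(np.mean(vals)),
        "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
        "median": float(np.median(vals)),
        "n": int(vals.size),
    }


def participant_f1(y_true, y_pred, groups) -> tuple[dict[str, float], dict]:
    """Per-speaker F1 of the fully rhotic class, plus the across-speaker
    summary (mean, SD, median, n). Zero-division (no predicted and no true
    positives) yields F1 = 0 with a warning."""
    y_true = np.asarray(y_true).ravel().astype(int)
    y_pred = np.asarray(y_pred).ravel().astype(int)
    groups = np.asarray(groups)
    if not (len(y_true) == len(y_pred) == len(groups)):
        raise DataError("predictions, labels and groups must align")
    scores: dict[str, float] = {}
    for g in np.unique(groups):
        m = groups == g
        if not m.any():
            continue
        yt, yp = y_true[m], y_pred[m]
        if yt.sum() == 0 and yp.sum() == 0:
            log.warning("speaker %s: no true or predicted positives, F1 set to 0", g)
            scores[str(g)] = 0.0
        else:
            scores[str(g)] = float(f1_score(yt, yp, pos_label=1, zero_division=0))
    if not scores:
        raise DataError("no non-empty speaker groups")
    return scores, _f1_summary(scores)


def participant_confusion(y_true, y_pred, groups) -> np.ndarray:
    """Participant-weighted 2×2 confusion, rows normalized by ground-truth
    class (row 0 = derhotic truth, row 1 = fully rhotic truth; columns are
    the predicted classes). Speakers missing a ground-truth class are
    excluded with a warning."""
    y_true = np.asarray(y_true).ravel().astype(int)
    y_pred = np.asarray(y_pred).ravel().astype(int)
    groups = np.asarray(groups)
    mats = []
    for g in np.unique(groups):
        m = groups == g
        yt, yp = y_true[m], y_pred[m]
        if len(np.unique(yt)) < 2:
            log.warning("speaker %s lacks a ground-truth class, excluded from confusion", g)
            continue
        cm = np.zeros((2, 2))
        for t in (0, 1):
            sel = yt == t
            cm[t, 0] = np.mean(yp[sel] == 0)
            cm[t, 1] = np.mean(yp[sel] == 1)
        mats.append(cm)
    if not mats:
        raise DataError("no speaker with both ground-truth classes")
    return np.mean(mats, axis=0)


def combined_best(
    personalized: dict[str, float], out_of_box: dict[str, float]
) -> tuple[dict[str, float], dict]:
    """Per-speaker maximum of personalized and speaker-independent F1 —
    a speaker keeps the out-of-box score when personalization hurt."""
    if set(personalized) != set(out_of_box):
        raise DataError(
            f"speaker sets differ: {sorted(set(personalized) ^ set(out_of_box))[:5]}"
        )
    best = {k: max(personalized[k], out_of_box[k]) for k in personalized}
    return best, _f1_summary(best)


@dataclass
class EvaluationReport:
    """Per-participant F1 with summary, confusion, and condition labels."""

    per_participant_f1: dict[str, float]
    summary: dict
    confusion: np.ndarray | None = None
    condition: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "per_participant_f1": self.per_participant_f1,
            "summary": self.summary,
            "confusion": None if self.confusion is None else self.confusion.tolist(),
        }


# ---------------------------------------------------------------------------
# condition contrasts (linear mixed model)
# ---------------------------------------------------------------------------


@dataclass
class ContrastResult:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    random_variances: dict
    converged: bool
    result: object  # the underlying statsmodels results

    def summary(self) -> str:
        return str(self.result.summary())

    def effect(self, name_fragment: str) -> tuple[float, float]:
        """(estimate, SE) of the first fixed effect whose name contains the
        fragment; raises if none matches."""
        for name in self.params.index:
            if name_fragment in name:
                return float(self.params[name]), float(self.bse[name])
        raise KeyError(f"no fixed effect matching {name_fragment!r}")


_CONTRAST_FORMULA = (
    "f1 ~ C(normalization, Treatment('utterance'))"
    " * C(representation, Treatment('mfcc'))"
    " * C(timepoint, Treatment('out_of_box'))"
)


def condition_contrast(results: pd.DataFrame) -> ContrastResult:
    """REML linear mixed model of per-speaker F1 on the full factorial of
    normalization × representation × timepoint, with crossed random
    intercepts for participant and classifier family.

    ``results`` needs one row per speaker × condition with columns
    speaker_id, normalization, representation, timepoint, family, f1.
    """
    need = {"speaker_id", "normalization", "representation", "timepoint", "family", "f1"}
    if not need.issubset(results.columns):
        raise DataError(f"results table needs columns {sorted(need)}")
    df = results.copy()
    vc = {"participant": "0 + C(speaker_id)"}
    if df["family"].nunique() > 1:
        vc["family"] = "0 + C(family)"
    df["_one"] = 1
    model = smf.mixedlm(_CONTRAST_FORMULA, df, groups="_one", vc_formula=vc, re_formula="0")
    with np.errstate(all="ignore"):
        res = model.fit(reml=True)
    if not res.converged:
        log.warning("mixed model did not fully converge; estimates reported with diagnostics")
    fe = res.fe_params.index
    return ContrastResult(
        params=res.params[fe],
        bse=res.bse[fe],
        tvalues=res.tvalues[fe],
        pvalues=res.pvalues[fe],
        random_variances={k: float(v) for k, v in res.vcomp_to_dict().items()}
        if hasattr(res, "vcomp_to_dict")
        else dict(zip(vc.keys(), np.atleast_1d(res.vcomp).tolist())),
        converged=bool(res.converged),
        result=res,
    )


def bias_probe(per_speaker: pd.DataFrame) -> ContrastResult:
    """Linear model of per-speaker F1 on age, sex, and their interaction.

    ``per_speaker`` needs columns f1, age_years, sex.
    """
    need = {"f1", "age_years", "sex"}
    if not need.issubset(per_speaker.columns):
        raise DataError(f"bias probe needs columns {sorted(need)}")
    if per_speaker["sex"].nunique() < 2:
        raise ParameterError("bias probe requires both sexes present")
    if per_speaker["age_years"].nunique() < 2:
        raise ParameterError("bias probe requires age variation")
    if per_speaker["f1"].nunique() < 2:
        log.warning("constant F1: degenerate bias-probe fit")
    res = smf.ols("f1 ~ age_years * C(sex)", per_speaker).fit()
    return ContrastResult(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        random_variances={},
        converged=True,
        result=res,
    )


# ---------------------------------------------------------------------------
# global attribution (expected gradients)
# ---------------------------------------------------------------------------


def global_attribution(
    model,
    background: np.ndarray,
    inputs: np.ndarray,
    feature_names,
    seed: int = 0,
    n_baselines: int = 20,
    return_per_utterance: bool = False,
):
    """Signed mean attribution per feature for the class-1 output.

    For every input sequence, ``n_baselines`` baselines are drawn from the
    ambiguous-utterance background set; the gradient of the class-1
    probability is evaluated at a uniform random interpolate between input
    and baseline and multiplied by (input − baseline). Attributions are
    averaged over baselines, utterances, time windows, and statistics,
    leaving one signed value per feature.
    """
    if hasattr(model, "model"):  # accept a ClassifierBundle
        model = model.model
    if not getattr(model, "fitted_", False):
        raise StateError("global_attribution requires a trained network")
    background = np.asarray(background, dtype=float)
    inputs = np.asarray(inputs, dtype=float)
    if background.size == 0 or inputs.size == 0:
        raise DataError("background and input sets must be nonempty")
    n_feat = len(feature_names)
    N, T, D = inputs.shape
    if D != n_feat * 8:
        raise DataError(f"input dim {D} inconsistent with {n_feat} features × 8 statistics")
    rng = np.random.default_rng(seed)
    total = np.zeros_like(inputs)
    for _ in range(n_baselines):
        base = background[rng.integers(0, len(background), size=N)]
        alpha = rng.random((N, 1, 1))
        points = base + alpha * (inputs - base)
        grads = model.input_gradients(points)
        total += (inputs - base) * grads
    attr = total / n_baselines  # (N, T, F*8)
    per_utt = attr.reshape(N, T, n_feat, 8).mean(axis=(1, 3))  # (N, F)
    series = pd.Series(per_utt.mean(axis=0), index=list(feature_names), name="mean_attribution")
    if return_per_utterance:
        return series, per_utt
    return series
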