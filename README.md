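# rhotic

Binary classification of children's /ɹ/ productions as **fully rhotic**
(clinically correct) vs. **derhotic** (incorrect), from acoustic features,
against multi-listener perceptual ground truth.

The package is aimed at clinical speech-technology researchers who want a
fully testable, end-to-end reimplementation of this kind of pipeline without
access to a clinical speech corpus: every stage — corpus structure, feature
extraction, normalization, classifiers, personalization, evaluation,
explainability — runs on a synthetic corpus generator that reproduces the
statistical structure of the clinical problem, including its central
confound: the fully rhotic productions of a young child (small vocal tract,
high formants) can occupy the same raw acoustic region as the derhotic
productions of an older adolescent.

## The method

American English rhoticity is carried acoustically by the third formant:
a fully rhotic /ɹ/ lowers F3 toward F2 (small F3−F2 distance), a derhotic
/ɹ/ leaves F3 near neutral-tract values. The pipeline:

1. **Labels.** Each utterance's binary label is derived from the mean of
   multi-listener ratings, with label 1 (fully rhotic) iff the mean ≥ 0.66.
   Ambiguous (non-unanimous) utterances are retained.
2. **Datasets.** Participant-disjoint train/validation/test sets holding
   ≈70/15/15 % of utterances; typical speakers train-only; validation and
   test contain only *stimulable* speakers with residual speech sound
   disorder (fully-rhotic : derhotic utterance ratio > 0.33). Training is
   balanced 1:1; evaluation sets are balanced 2:1 (correct : incorrect), the
   ratio expected in clinical use.
3. **Features.** From each rhotic interval (10 ms buffer on both sides):
   five formants by robust Burg-method LPC on 5 ms Gaussian frames with a
   5 ms step and pre-emphasis above 50 Hz, with the per-speaker formant
   ceiling tuned by grid search; plus the transforms F3−F2 and Δ(F3−F2) —
   or 13 MFCCs on identical frames. Frame series are reduced to a fixed
   tensor of n_features × 10 time windows × 8 summary statistics (median,
   mean, SD, min, max, variance, skewness, kurtosis).
4. **Normalization.** Either z-standardization against the nearest
   age-and-sex-matched norms of fully rhotic productions (built from
   training speakers only), or against the utterance's own frame
   distribution. Δ(F3−F2) is rescaled linearly into [−10, +10].
5. **Classifiers.** Random forest and SGD linear models on the per-window
   medians; a gated recurrent network (GRU → Hardswish dense → sigmoid,
   binary cross-entropy, RMSprop, ≤25 epochs with early-stopping patience 5)
   on the full window-statistic sequence. Hyperparameters are tuned by
   seeded random search maximizing mean participant-specific validation F1.
6. **Personalization.** Per test speaker, stratified fivefold
   cross-validation with warm-start updates: +100 participant-specific
   trees (forest), +10 epochs (SGD), or low-learning-rate fine-tuning of a
   copied network (GRU). Every utterance is scored by the fold that held it
   out.
7. **Evaluation.** The outcome is F1 of the fully rhotic class computed per
   participant and summarized with equal speaker weight, plus a
   participant-weighted confusion matrix normalized by ground-truth class.
   Condition effects (normalization × representation × timepoint) are
   estimated with a REML linear mixed model with crossed random intercepts
   for participant and classifier family; a linear probe checks for age/sex
   performance bias; GradientShap-style expected-gradient attribution
   reports each feature's global influence on the network's decisions.

## Worked example

```python
from rhotic import RunConfig, run_pipeline
from rhotic.workflow import render_report

cfg = RunConfig(
    synth=dict(n_speakers=12, utterances_per_speaker=40, prop_typical=0.25,
               rssd_skill=0.5, ambiguity_rate=0.2, age_range=(7.0, 17.0)),
    representation="formant", normalization="age_sex",
    family="random_forest", hyperparams={"n_estimators": 200}, seed=1,
)
out = run_pipeline(cfg)
print(render_report(out["reports"]))
```

prints

```
| condition | timepoint | mean F1 | SD | median | n |
|---|---|---|---|---|---|
| formant/age_sex/random_forest | out_of_box | 0.930 | 0.067 | 0.930 | 2 |
| formant/age_sex/random_forest | personalized | 0.907 | 0.070 | 0.907 | 2 |
| formant/age_sex/random_forest | best | 0.930 | 0.067 | 0.930 | 2 |

## Participant-weighted confusion — out_of_box
| truth \ predicted | derhotic | fully rhotic |
|---|---|---|
| derhotic | 0.90 | 0.10 |
| fully rhotic | 0.08 | 0.92 |
```

Mean F1 is the average of per-speaker F1 scores over the two stimulable
RSSD test speakers of this small corpus; the confusion rows say how each
ground-truth class was predicted, averaged with equal speaker weight.
`best` keeps, per speaker, the better of the personalized and
speaker-independent scores. With 40+ speakers (see the test suite's
experiment configurations) the age-and-sex-normalized conditions reliably
outperform utterance-normalized ones — the pipeline's central comparison.

A command-line interface mirrors the library
(`rhotic simulate | split | extract | normalize | train | personalize |
evaluate | report | grid`, each accepting `--config` and `--seed`).

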