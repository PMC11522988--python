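# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic experiments do and do not show.

## The classification problem

The target is a listener-judgment construct: whether an /ɹ/ production by a
child is perceived as fully rhotic. Ground truth is the mean of independent
binary listener votes, thresholded at 0.66 (inclusive). Because expert
listeners genuinely disagree about marginal productions, ambiguous
(non-unanimous) utterances are kept in training and evaluation; any
pipeline evaluated only on clean utterances would overstate clinical
performance.

Evaluation is participant-centred throughout: the clinical question is
whether a classifier works for *a* child, so F1 of the fully rhotic class
is computed within each test speaker and summarized across speakers with
equal weight, and evaluation sets are rebalanced per speaker to the 2:1
correct : incorrect ratio observed in therapy practice.

## Synthetic corpus model

The generator emulates the statistical structure the analysis assumes; it
is not a speech synthesizer of phonetic fidelity.

**Vocal-tract scaling.** All formant targets are the neutral adult-male
values (500, 1500, 2500, 3500, 4500 Hz) multiplied by
s(age, sex) = 1 + c·max(0, 18 − age)/12 with c = 0.35 (male) and 0.45
(female). s is monotone decreasing in age and larger for females at matched
age, which makes a 7-year-old's formant space ≈30–45 % higher than an
adult's — enough that young fully rhotic and old derhotic raw feature
distributions overlap (the generator's documented confound property checks
exactly this on F3−F2 quartiles).

**Gradient rhoticity.** Articulation is gradient, which is why listeners
disagree: each attempt draws a dip depth d — the fraction of the distance
from neutral F3 to the fully rhotic target F3 = F2 + 500 Hz (base units)
actually reached — from clipped normals, N(0.70, 0.15) on [0.5, 1] for
fully rhotic attempts and N(0.25, 0.15) on [0, 0.45] for derhotic ones.
The disjoint depth ranges keep the noise-free class ordering deterministic
while placing a substantial fraction of productions near the class
boundary. The dip is a Gaussian bump in time whose centre (N(0.5, 0.12),
clipped to [0.25, 0.75]) and width (U(0.18, 0.30), in interval fractions)
vary per attempt, reflecting forced-alignment intervals that are not
hand-corrected and therefore do not neatly centre the gesture.

**Nuisance variability.** Per-formant linear onglide/offglide drift
(slope SD = 0.8 × the frame-noise SD) stands in for coarticulation with
the flanking segments, and i.i.d. Gaussian frame noise (default SD 150 Hz,
the magnitude of LPC tracking error typical for child speech) corrupts
every formant. All nuisance randomness is tied to the `noise_sd_hz` knob:
at zero the track is the exact deterministic target, which the contract
tests exploit.

These choices make the class cue primarily a *level* cue — how far F3 sits
below neutral, relative to the speaker's own formant space. Utterance-level
z-scoring destroys that level (and rescales away the dip amplitude),
leaving only trajectory shape, which the variable dip geometry and drift
degrade; age-and-sex normalization preserves it. This is the mechanism by
which the synthetic experiments reproduce the direction of the
normalization effect. What passing these experiments does **not** show:
that the effect size on real child speech is matched; that the generator's
spectra are phonetically realistic (no consonantal context, no prosody,
impulse-train source); or that MFCC and formant representations are
equivalent in general.

**Ratings.** Each listener votes the true class except for an independent
flip whose probability is calibrated (by root finding on the closed-form
binomial expression) so the expected non-unanimous fraction equals the
requested ambiguity rate. Votes are binary; the label threshold then
operates on their mean. Note that rating flips are independent of the
acoustics, so label noise and acoustic marginality are uncorrelated in the
generator — a simplification.

**Audio.** Optional source–filter synthesis drives an impulse train at f0
(default 120 Hz) through cascaded two-pole resonators at the frame-wise
track frequencies with bandwidth 80 + 0.04·f Hz, carrying filter state
across frames; output is peak-normalized. Its purpose is to give the
formant estimator a ground-truth oracle, and it does: the estimator
recovers constant F1–F3 within 5 % (the F1 bias, ≈4.5 %, comes from the
harmonic structure of the source interacting with 5 ms windows).

## Formant estimation

Per 5 ms step, a Gaussian window of twice the nominal 5 ms length is
analyzed after resampling to 2 × the formant ceiling and pre-emphasis above
50 Hz. LPC coefficients of order 2 × n_formants come from the Burg lattice
recursion; the robust refinement then iterates (at most 5 times, stopping
when the relative residual-variance change is < 1e−5) a weighted
covariance-method re-fit in which samples with residuals beyond 1.5
standard deviations get Huber weights k/|e|. Formants are the positive-
frequency pole angles between 50 Hz and ceiling − 50 Hz, sorted ascending;
silent frames (RMS < 1e−8 of full scale) are left undefined.

The per-speaker ceiling is chosen by grid search (default 3500–6500 Hz in
50 Hz steps; the orchestration layer uses a coarse 3-point grid for desk-
scale runs): for each candidate, a quadratic-in-time polynomial is fitted
per formant per segment and the ceiling minimizing the summed squared
residuals of F1–F3 wins, ties toward the lowest ceiling. A smooth
trajectory fits well exactly when pole picking is stable across frames,
which is the practical signature of a well-chosen ceiling. The same
optimization is applied to evaluation speakers (a clinician-set ceiling
would replace it in a clinical deployment).

MFCCs use the same frames: periodogram → 26 triangular Mel filters spanning
0 Hz–Nyquist → log → orthonormal DCT-II, keeping c0–c12. c0 carries overall
gain; the higher coefficients are gain-invariant.

## Tensorization and normalization

The buffered interval is cut into 10 equal-duration windows; per window and
feature the 8 statistics are computed over defined frames (population SD;
skewness g1 and excess kurtosis g2 defined as 0 for windows with fewer than
3 frames or near-zero variance). Windows with no defined frame are imputed
by linear interpolation across the window axis (nearest-copy at edges), so
the tensor shape is invariant. Δ series start at 0 so their length matches
the frame count.

Normalization operates on frame-level values *before* tensorization, so all
8 statistics summarize normalized values. The normative table pools frames
of fully rhotic training utterances per (integer age year, sex, feature)
with a minimum support of 10 frames and an SD floor of 1e−6; lookup matches
the same sex and nearest age (ties to the younger row) and falls back to
the other sex only when a sex is entirely absent. The table builder refuses
validation/test speaker IDs outright (leakage guard). Delta scaling is the
symmetric map y = 10·x/max|x| (not min–max), preserving the sign of the
deltas; it is applied after z-standardization.

## Classifiers

Shallow models consume the flattened 10-window median slice; the recurrent
network consumes all 8 statistics per window as a 10-step sequence.

The GRU is implemented directly on numpy with hand-written
backpropagation-through-time (verified against finite differences in the
test suite), a Hardswish dense head, sigmoid output, binary cross-entropy,
and RMSprop (α 0.99, ε 1e−8). Default architecture: 1 recurrent layer of
64 units and a 32-unit head (configurable); training runs ≤25 epochs with
early stopping (patience 5) on mean participant validation F1 and restores
the best-epoch weights. Owning the network also yields exact input
gradients, which the attribution analysis needs.

Personalization never mutates the base model: per within-speaker stratified
fold (5 folds; speakers lacking 5 utterances of a class are skipped with a
warning), the forest grows +100 trees fitted to the fold's training part
(warm start), the SGD model trains 10 further epochs via `partial_fit`, and
the network fine-tunes a deep copy for 5 epochs at 0.1 × the base learning
rate. Hinge-loss linear models expose probabilities through a logistic map
of the decision margin so the prediction contract is uniform.

Hyperparameter search is seeded random sampling (50 trials by default) over
forest {trees 100–500, depth 4–32, min-leaf 1–8}, SGD {log/hinge loss,
α 1e−6–1e−2 log-uniform, epochs 10–100} and GRU {hidden 16–128, learning
rate 1e−4–1e−2 log-uniform}, scored by mean participant validation F1.

## Statistical analyses

The condition contrast is a linear mixed model of per-speaker F1 on the
full normalization × representation × timepoint factorial (treatment coding
with utterance / MFCC / out-of-box reference levels), REML-estimated, with
crossed random intercepts for participant and classifier family (variance
components on a single grouping). Singular or boundary fits are reported
with statsmodels' diagnostics rather than suppressed. The bias probe is an
ordinary linear model of per-speaker F1 on age × sex.

Global attribution follows the expected-gradients scheme: per input, 20
baselines are sampled from the ambiguous-utterance background set, the
gradient of the class-1 probability is evaluated at a uniform-random
interpolate and multiplied by (input − baseline), and attributions are
averaged over baselines, utterances, windows and statistics to one signed
value per feature. Global *importance* ranks features by the mean absolute
per-utterance attribution (signed means over a mixed-class input set can
cancel); the sign convention is read off the fully rhotic inputs, where the
feature pushing the class-1 probability upward carries a positive mean.

## Problem sizes

The experiment configurations used by the test suite run at desk scale:
the confounded-corpus comparison uses 40 speakers × 60 utterances over ages
7–17 (RSSD skill 0.5, ambiguity 0.2) across 5 seeds with the two shallow
families; personalization, attribution and contrast checks use a few
hundred utterances or a simulated 100-speaker factorial. These sizes were
chosen so the full suite runs comfortably on a single CPU; the pipeline
itself has no scale-dependent logic.

## Known limitations

* The generator's independence of label noise and acoustic marginality
  understates the difficulty of real ambiguous utterances.
* Formant estimation is tested against its own synthesis oracle, not
  against a reference implementation of the robust LPC variant; the robust
  reweighting kernel (Huber) follows the cited method class, whose exact
  kernel is not printed anywhere accessible.
* The MFCC front end uses a generic Mel filter bank; absolute coefficient
  values differ from other toolkits (only relative structure matters here).
* Replication by swapping validation and test roles re-tunes and re-trains
  but reuses the same synthetic corpus draw, so the two runs are not
  independent samples of anything beyond speaker allocation.
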