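"""Synthetic /ɹ/ corpus generation.

Emulates the statistical structure the classification experiments assume,
so the whole pipeline is testable without any speech recording:

* speakers with age- and sex-dependent vocal-tract scaling (younger and
  female speakers have shorter tracts, hence higher formants);
* fully rhotic productions whose F3 dips toward F2 mid-interval (small
  F3−F2) vs. derhotic productions whose F3 stays near neutral;
* a typical-speaker cohort (high rhotic skill) and an RSSD cohort
  (residual speech sound disorder; configurable, lower skill);
* per-utterance multi-listener binary ratings with a controllable fraction
  of ambiguous (non-unanimous) rating sets;
* optional source–filter audio synthesis so the formant estimator can be
  exercised against known resonances.

The vocal-tract scale s(age, sex) = 1 + c·max(0, 18 − age)/12 with
c = 0.35 (male) and 0.45 (female) makes raw formant distributions of young
fully rhotic speakers overlap those of older derhotic speakers — the
confound that age-and-sex normalization is meant to remove.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile
from scipy.optimize import brentq

from .acoustics import FormantTrack, RhoticInterval
from .errors import DataError, ParameterError
from .textgrids import Interval, IntervalTier, TextGrid, write_textgrid

#: neutral vocal-tract formant targets for the adult-male reference (Hz)
NEUTRAL_FORMANTS_HZ = (500.0, 1500.0, 2500.0, 3500.0, 4500.0)

#: base-unit F3 target at the centre of a maximally rhotic interval: F2 + 500 Hz
RHOTIC_F3_CENTER_HZ = NEUTRAL_FORMANTS_HZ[1] + 500.0

#: attempt-level rhoticity-degree distributions (mean, sd, clip lo, clip hi):
#: articulation is gradient — fully rhotic attempts draw a deep F3 dip,
#: derhotic attempts a shallow one, with marginal productions near the
#: class boundary (the acoustically ambiguous tokens of clinical practice)
RHOTIC_DEPTH = (0.70, 0.15, 0.50, 1.00)
DERHOTIC_DEPTH = (0.25, 0.15, 0.00, 0.45)

#: vocal-tract scaling slope per sex (relative formant increase at age 6)
VT_SLOPE = {"M": 0.35, "F": 0.45}


def vt_scale(age_years: float, sex: str) -> float:
    """Vocal-tract formant multiplier relative to the adult-male reference.

    Monotone decreasing in age until 18 (then 1.0), female above male at
    matched age: s = 1 + c·max(0, 18 − age)/12, c = 0.35 (M) / 0.45 (F).
    """
    if sex not in VT_SLOPE:
        raise ParameterError(f"sex must be 'M' or 'F', got {sex!r}")
    return 1.0 + VT_SLOPE[sex] * max(0.0, 18.0 - float(age_years)) / 12.0


@dataclass(frozen=True)
class SpeakerProfile:
    speaker_id: str
    age_years: float
    sex: str  # {"M", "F"}
    cohort: str  # {"typical", "RSSD"}
    vt_scale: float
    rhotic_skill: float  # P(an attempt is fully rhotic)
    formant_ceiling_hz: float | None = None


@dataclass
class SynthSpec:
    """Parameters of one synthetic corpus."""

    n_speakers: int = 40
    age_range: tuple[float, float] = (6.0, 18.0)
    sex_ratio: float = 0.5  # fraction male
    prop_typical: float = 0.25
    utterances_per_speaker: int = 40
    ambiguity_rate: float = 0.2
    n_listeners: int = 3
    noise_sd_hz: float = 150.0
    typical_skill: float = 0.95
    rssd_skill: float = 0.5
    duration_range_s: tuple[float, float] = (0.20, 0.35)
    frame_step_s: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.n_speakers < 2:
            raise ParameterError("n_speakers must be >= 2")
        for name in ("sex_ratio", "prop_typical", "ambiguity_rate",
                     "typical_skill", "rssd_skill"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.n_listeners < 3:
            raise ParameterError("n_listeners must be >= 3")
        if self.noise_sd_hz < 0:
            raise ParameterError("noise_sd_hz must be >= 0")
        if not self.age_range[1] >= self.age_range[0]:
            raise ParameterError("age_range must be (min, max) with max >= min")
        if self.utterances_per_speaker < 1:
            raise ParameterError("utterances_per_speaker must be >= 1")


def generate_speakers(spec: SynthSpec) -> list[SpeakerProfile]:
    """Draw the speaker panel: ages uniform over the range, sexes by
    ``sex_ratio``, cohorts by ``prop_typical``; deterministic given seed."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    speakers = []
    for i in range(spec.n_speakers):
        age = float(rng.uniform(lo, hi))
        sex = "M" if rng.random() < spec.sex_ratio else "F"
        typical = rng.random() < spec.prop_typical
        cohort = "typical" if typical else "RSSD"
        skill = spec.typical_skill if typical else spec.rssd_skill
        speakers.append(
            SpeakerProfile(
                speaker_id=f"spk{i:03d}",
                age_years=age,
                sex=sex,
                cohort=cohort,
                vt_scale=vt_scale(age, sex),
                rhotic_skill=skill,
            )
        )
    return speakers


def generate_formant_track(
    speaker: SpeakerProfile,
    rhotic: bool,
    duration_s: float = 0.30,
    frame_step_s: float = 0.005,
    noise_sd_hz: float = 150.0,
    seed: int = 0,
    depth: float | None = None,
) -> FormantTrack:
    """Frame-level 5-formant track for one /ɹ/ attempt.

    Targets are the neutral adult-male values scaled by the speaker's
    ``vt_scale``. F3 dips toward F2 along a Gaussian bump in time; the dip
    ``depth`` (fraction of the neutral-to-fully-rhotic distance) is drawn
    per attempt — deep for fully rhotic attempts, shallow (near-neutral)
    for derhotic ones, so marginal productions of either class approach the
    class boundary. With nonzero ``noise_sd_hz`` the bump's centre and
    width vary (uncorrected alignment), every formant carries a linear
    coarticulatory drift, and i.i.d. Gaussian frame noise is added.
    """
    if duration_s <= 0:
        raise ParameterError(f"duration_s must be > 0, got {duration_s}")
    if noise_sd_hz < 0:
        raise ParameterError("noise_sd_hz must be >= 0")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_s + 1e-9, frame_step_s)
    n = times.size
    base = np.tile(np.asarray(NEUTRAL_FORMANTS_HZ), (n, 1))
    if depth is None:
        mu, sd, lo, hi = RHOTIC_DEPTH if rhotic else DERHOTIC_DEPTH
        depth = float(np.clip(rng.normal(mu, sd), lo, hi))
    u = times / duration_s
    # F3 dip: Gaussian bump whose centre and width vary with the
    # acoustic-variability knob — forced-alignment intervals are not
    # hand-corrected, so the articulatory gesture is not always centred in,
    # or fully spanned by, the interval; noise-free tracks use the
    # canonical centred geometry
    if noise_sd_hz > 0:
        u0 = float(np.clip(rng.normal(0.5, 0.12), 0.25, 0.75))
        width = float(rng.uniform(0.18, 0.30))
    else:
        u0, width = 0.5, 0.25
    w = np.exp(-((u - u0) ** 2) / (2.0 * width**2))
    base[:, 2] -= depth * (NEUTRAL_FORMANTS_HZ[2] - RHOTIC_F3_CENTER_HZ) * w
    if noise_sd_hz > 0:
        # coarticulatory onglide/offglide: linear per-formant transition
        # left by the segments flanking /ɹ/, unrelated to rhoticity
        slope = rng.normal(0.0, 0.8 * noise_sd_hz, size=base.shape[1])
        base = base + np.outer(u - 0.5, slope)
    track = base * speaker.vt_scale
    if noise_sd_hz > 0:
        track = track + rng.normal(0.0, noise_sd_hz, size=track.shape)
    return FormantTrack(frame_times_s=times, formants=track)


def synthesize_audio(
    track: FormantTrack,
    f0_hz: float = 120.0,
    sample_rate_hz: int = 16000,
) -> np.ndarray:
    """Source–filter synthesis of a formant track.

    An impulse-train glottal source at ``f0_hz`` is passed through cascaded
    second-order resonators at the track's frame-wise formant frequencies
    (bandwidth 80 + 0.04·f Hz, Klatt-style default); filter state is carried
    across frames so trajectories are continuous. Output is peak-normalized
    to [−1, 1].
    """
    if sample_rate_hz < 16000:
        raise ParameterError("sample_rate_hz must be >= 16000")
    if track.n_frames == 0:
        raise DataError("empty (zero-duration) formant track")
    fs = float(sample_rate_hz)
    finite = track.formants[np.isfinite(track.formants)]
    if finite.size and float(np.max(finite)) >= fs / 2.0:
        raise ParameterError("formant at or above Nyquist frequency")

    if track.n_frames > 1:
        frame_len_s = float(np.median(np.diff(track.frame_times_s)))
    else:
        frame_len_s = 0.010
    spf = max(1, int(round(frame_len_s * fs)))
    n_total = spf * track.n_frames

    # impulse-train source
    source = np.zeros(n_total)
    period = max(1, int(round(fs / f0_hz)))
    source[::period] = 1.0

    n_res = track.formants.shape[1]
    zis = [np.zeros(2) for _ in range(n_res)]
    out = np.empty(n_total)
    for i in range(track.n_frames):
        seg = source[i * spf : (i + 1) * spf]
        for j in range(n_res):
            f = track.formants[i, j]
            if not np.isfinite(f):
                continue
            bw = 80.0 + 0.04 * f
            r = math.exp(-math.pi * bw / fs)
            theta = 2.0 * math.pi * f / fs
            b = [1.0 - r]  # unit-ish gain scaling
            a = [1.0, -2.0 * r * math.cos(theta), r * r]
            seg, zis[j] = signal.lfilter(b, a, seg, zi=zis[j])
        out[i * spf : (i + 1) * spf] = seg
    peak = float(np.max(np.abs(out)))
    if peak > 0:
        out = out / peak
    return out


# ---------------------------------------------------------------------------
# listener ratings
# ---------------------------------------------------------------------------


def flip_rate_for_ambiguity(ambiguity: float, n_listeners: int) -> float:
    """Per-listener flip probability giving the requested expected
    non-unanimous fraction: solves 1 − (1−f)^L − f^L = ambiguity on
    f ∈ [0, 0.5]. Ambiguity above the f = 0.5 maximum is clamped."""
    if not 0.0 <= ambiguity <= 1.0:
        raise ParameterError(f"ambiguity={ambiguity} outside [0, 1]")
    L = int(n_listeners)
    if ambiguity == 0.0:
        return 0.0
    max_amb = 1.0 - 2.0 ** (1 - L)
    if ambiguity >= max_amb:
        return 0.5

    def g(f):
        return 1.0 - (1.0 - f) ** L - f**L - ambiguity

    return float(brentq(g, 0.0, 0.5))


def simulate_ratings(
    rhotic: bool,
    ambiguity: float,
    n_listeners: int,
    seed: int = 0,
) -> np.ndarray:
    """Binary votes of ``n_listeners`` raters for one utterance.

    Each listener votes the true class independently except for a flip with
    probability calibrated so the expected non-unanimous fraction equals
    ``ambiguity``.
    """
    if n_listeners < 1:
        raise ParameterError("n_listeners must be >= 1")
    flip = flip_rate_for_ambiguity(ambiguity, n_listeners)
    rng = np.random.default_rng(seed)
    truth = 1 if rhotic else 0
    flips = rng.random(n_listeners) < flip
    return np.where(flips, 1 - truth, truth).astype(int)


# ---------------------------------------------------------------------------
# corpus assembly
# ---------------------------------------------------------------------------


@dataclass
class Utterance:
    utterance_id: str
    speaker_id: str
    rhotic: bool  # generating (true) class
    interval: RhoticInterval  # rhotic interval in file coordinates
    duration_s: float  # utterance (file) duration
    track: FormantTrack  # interval-local track (t=0 at interval start)
    ratings: np.ndarray
    audio: np.ndarray | None = None
    sample_rate_hz: int = 16000

    @property
    def rating_mean(self) -> float:
        return float(np.mean(self.ratings))


@dataclass
class Corpus:
    spec: SynthSpec
    speakers: list[SpeakerProfile]
    utterances: list[Utterance]

    def speaker(self, speaker_id: str) -> SpeakerProfile:
        for s in self.speakers:
            if s.speaker_id == speaker_id:
                return s
        raise DataError(f"unknown speaker {speaker_id!r}")

    def by_speaker(self) -> dict[str, list[Utterance]]:
        out: dict[str, list[Utterance]] = {s.speaker_id: [] for s in self.speakers}
        for u in self.utterances:
            out[u.speaker_id].append(u)
        return out


#: silence padding on each side of the rhotic interval in synthesized files
_PAD_S = 0.05


def generate_corpus(spec: SynthSpec, with_audio: bool = False) -> Corpus:
    """Full synthetic corpus: speakers, per-speaker attempts drawn from
    ``rhotic_skill``, tracks, listener ratings, optional audio."""
    speakers = generate_speakers(spec)
    rng = np.random.default_rng(spec.seed + 1)
    utterances = []
    for spk in speakers:
        for k in range(spec.utterances_per_speaker):
            rhotic = bool(rng.random() < spk.rhotic_skill)
            dur = float(rng.uniform(*spec.duration_range_s))
            tr_seed = int(rng.integers(0, 2**31 - 1))
            rt_seed = int(rng.integers(0, 2**31 - 1))
            track = generate_formant_track(
                spk,
                rhotic,
                duration_s=dur,
                frame_step_s=spec.frame_step_s,
                noise_sd_hz=spec.noise_sd_hz,
                seed=tr_seed,
            )
            ratings = simulate_ratings(rhotic, spec.ambiguity_rate, spec.n_listeners, seed=rt_seed)
            interval = RhoticInterval(start_s=_PAD_S, end_s=_PAD_S + dur, source="phones")
            utt = Utterance(
                utterance_id=f"{spk.speaker_id}_u{k:03d}",
                speaker_id=spk.speaker_id,
                rhotic=rhotic,
                interval=interval,
                duration_s=dur + 2 * _PAD_S,
                track=track,
                ratings=ratings,
            )
            if with_audio:
                utt.audio = _utterance_audio(utt)
            utterances.append(utt)
    return Corpus(spec=spec, speakers=speakers, utterances=utterances)


def _utterance_audio(utt: Utterance) -> np.ndarray:
    """File-length audio: neutral-scaled edges around the interval track."""
    step = float(np.median(np.diff(utt.track.frame_times_s))) if utt.track.n_frames > 1 else 0.005
    n_pad = max(1, int(round(_PAD_S / step)))
    edge_first = utt.track.formants[:1]
    edge_last = utt.track.formants[-1:]
    full = np.vstack(
        [np.repeat(edge_first, n_pad, axis=0), utt.track.formants, np.repeat(edge_last, n_pad, axis=0)]
    )
    times = np.arange(full.shape[0]) * step
    return synthesize_audio(
        FormantTrack(frame_times_s=times, formants=full),
        sample_rate_hz=utt.sample_rate_hz,
    )


# ---------------------------------------------------------------------------
# on-disk corpus (WAV + TextGrid + CSV + manifest)
# ---------------------------------------------------------------------------


def write_corpus(corpus: Corpus, outdir: str | Path, with_audio: bool = True) -> Path:
    """Write the corpus as WAV (16-bit PCM mono) + TextGrid per utterance,
    speakers.csv, ratings.csv and a manifest.json tying them together."""
    out = Path(outdir)
    try:
        (out / "audio").mkdir(parents=True, exist_ok=True)
        (out / "alignment").mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise DataError(f"cannot create corpus directory {out}: {exc}") from exc

    with open(out / "speakers.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["speaker_id", "age_years", "sex", "cohort"])
        for s in corpus.speakers:
            w.writerow([s.speaker_id, f"{s.age_years:.3f}", s.sex, s.cohort])

    with open(out / "ratings.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["utterance_id", "listener_id", "rating"])
        for u in corpus.utterances:
            for li, r in enumerate(u.ratings):
                w.writerow([u.utterance_id, f"L{li:02d}", int(r)])

    manifest = {"tier": "phones", "utterances": []}
    for u in corpus.utterances:
        wav_rel = f"audio/{u.utterance_id}.wav"
        tg_rel = f"alignment/{u.utterance_id}.TextGrid"
        if with_audio:
            audio = u.audio if u.audio is not None else _utterance_audio(u)
            pcm = np.clip(audio, -1.0, 1.0)
            wavfile.write(out / wav_rel, u.sample_rate_hz, (pcm * 32767).astype(np.int16))
        tier = IntervalTier(name="phones", xmin=0.0, xmax=u.duration_s)
        if u.interval.start_s > 0:
            tier.intervals.append(Interval(0.0, u.interval.start_s, ""))
        tier.intervals.append(Interval(u.interval.start_s, u.interval.end_s, "r"))
        if u.interval.end_s < u.duration_s:
            tier.intervals.append(Interval(u.interval.end_s, u.duration_s, ""))
        write_textgrid(TextGrid(xmin=0.0, xmax=u.duration_s, tiers=[tier]), out / tg_rel)
        manifest["utterances"].append(
            {
                "utterance_id": u.utterance_id,
                "speaker_id": u.speaker_id,
                "wav": wav_rel if with_audio else None,
                "textgrid": tg_rel,
                "duration_s": round(u.duration_s, 6),
            }
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
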