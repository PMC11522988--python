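"""Frame-level acoustic representations of rhotic intervals.

Two representations are produced from a rhotic-associated interval of audio:

* formants — five formant frequencies estimated per 5 ms frame by Burg-method
  linear predictive coding with an iteratively reweighted ("robust")
  refinement, plus the two rhoticity transforms F3−F2 and Δ(F3−F2);
* MFCCs — thirteen Mel frequency cepstral coefficients on identical frames.

Either track is then reduced to a fixed-shape feature tensor
(n_features × 10 time windows × 8 summary statistics), the input consumed by
every classifier downstream. Shallow classifiers read only the per-window
median slice (:func:`median_view`).

The formant ceiling — the upper frequency bound of the LPC search — is the
one speaker-specific knob; :func:`optimize_ceiling_train` tunes it per
speaker by grid search, minimising the residuals of a smooth (quadratic in
time) trajectory model fitted to the candidate F1–F3 estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import DataError, ParameterError

log = logging.getLogger(__name__)

#: order of the statistic axis of every feature tensor
STAT_ORDER = ("median", "mean", "sd", "min", "max", "variance", "skewness", "kurtosis")

#: the five modelled formant-representation features
FORMANT_FEATURES = ("F1", "F2", "F3", "F3-F2", "dF3-F2")

#: names of features that are delta (frame-difference) series and therefore
#: get the symmetric ±10 rescaling during normalization
DELTA_FEATURES = ("dF3-F2",)

N_WINDOWS = 10


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RhoticInterval:
    """A forced-alignment interval (seconds) containing the /ɹ/ segment."""

    start_s: float
    end_s: float
    source: str = "phones"

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise DataError(
                f"degenerate interval: end {self.end_s} <= start {self.start_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def buffer_interval(
    interval: RhoticInterval,
    utterance_duration_s: float,
    buffer_s: float = 0.010,
) -> RhoticInterval:
    """Expand an interval by ``buffer_s`` on each side, clipped to the file.

    The buffer counteracts edge loss of analysis frames at interval
    boundaries; 10 ms is the default on both sides.
    """
    if interval.end_s <= interval.start_s:
        raise DataError("degenerate interval")
    start = max(0.0, interval.start_s - buffer_s)
    end = min(float(utterance_duration_s), interval.end_s + buffer_s)
    return RhoticInterval(start_s=start, end_s=end, source=interval.source)


@dataclass
class FormantTrack:
    """Per-frame formant frequencies (Hz) and the rhoticity transforms.

    ``formants`` has shape (n_frames, n_formants); undefined estimates are
    NaN. The transforms are derived lazily from F2 and F3.
    """

    frame_times_s: np.ndarray
    formants: np.ndarray  # (n_frames, >=3), NaN where undefined

    def __post_init__(self):
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        self.formants = np.asarray(self.formants, dtype=float)
        if self.formants.ndim != 2 or self.formants.shape[0] != self.frame_times_s.size:
            raise DataError("formant array must be (n_frames, n_formants)")

    @property
    def n_frames(self) -> int:
        return self.frame_times_s.size

    @property
    def f3_minus_f2(self) -> np.ndarray:
        return self.formants[:, 2] - self.formants[:, 1]

    @property
    def delta_f3_minus_f2(self) -> np.ndarray:
        """First difference of F3−F2; the first frame's delta is 0."""
        d = np.diff(self.f3_minus_f2, prepend=self.f3_minus_f2[:1])
        if d.size:
            d[0] = 0.0
        return d

    @property
    def feature_names(self) -> tuple[str, ...]:
        return FORMANT_FEATURES

    def feature_matrix(self) -> np.ndarray:
        """(n_frames × 5) matrix: F1, F2, F3, F3−F2, Δ(F3−F2)."""
        return np.column_stack(
            [
                self.formants[:, 0],
                self.formants[:, 1],
                self.formants[:, 2],
                self.f3_minus_f2,
                self.delta_f3_minus_f2,
            ]
        )


@dataclass
class MfccTrack:
    """Per-frame Mel frequency cepstral coefficients (13 per frame)."""

    frame_times_s: np.ndarray
    coefficients: np.ndarray  # (n_frames, 13)

    def __post_init__(self):
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 2:
            raise DataError("coefficient array must be 2-D")

    @property
    def n_frames(self) -> int:
        return self.frame_times_s.size

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f"mfcc{i:02d}" for i in range(self.coefficients.shape[1]))

    def feature_matrix(self) -> np.ndarray:
        return self.coefficients


@dataclass
class FeatureTensor:
    """(n_features × 10 windows × 8 statistics) summary of one interval."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    representation: str  # {"formant", "mfcc"}
    normalization: str = "none"  # {"none", "utterance", "age_sex"}
    stat_order: tuple[str, ...] = STAT_ORDER

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expect = (len(self.feature_names), N_WINDOWS, len(self.stat_order))
        if self.values.shape != expect:
            raise DataError(f"tensor shape {self.values.shape} != {expect}")

    def median_matrix(self) -> np.ndarray:
        return self.values[:, :, 0]

    def flat_median(self) -> np.ndarray:
        """Flattened median slice (n_features·10,) — shallow-model input."""
        return self.median_matrix().ravel()

    def sequence(self) -> np.ndarray:
        """(10 × n_features·8) window-step sequence — recurrent-model input."""
        return self.values.transpose(1, 0, 2).reshape(N_WINDOWS, -1)


def median_view(tensor: FeatureTensor) -> np.ndarray:
    """The (n_features × 10) per-window median slice of a feature tensor."""
    return tensor.median_matrix()


# ---------------------------------------------------------------------------
# framing shared by formant and MFCC estimation
# ---------------------------------------------------------------------------


def _frames(audio: np.ndarray, fs: float, window_s: float, step_s: float):
    """Gaussian-windowed frames with 2× physical duration, centred on a
    ``step_s`` grid (Praat-style Gaussian analysis windows span twice the
    nominal window length)."""
    audio = np.asarray(audio, dtype=float)
    half = int(round(window_s * fs))  # half-width = nominal window length
    wlen = 2 * half + 1
    if audio.size < wlen:
        raise DataError(
            f"segment of {audio.size} samples shorter than one "
            f"{wlen}-sample analysis window"
        )
    win = signal.windows.gaussian(wlen, std=wlen / 6.0)
    step = max(1, int(round(step_s * fs)))
    centers = np.arange(half, audio.size - half, step)
    times = centers / fs
    out = np.empty((centers.size, wlen))
    for i, c in enumerate(centers):
        out[i] = audio[c - half : c + half + 1] * win
    return times, out


def _preemphasize(audio: np.ndarray, fs: float, from_hz: float) -> np.ndarray:
    if from_hz <= 0:
        return audio
    a = math.exp(-2.0 * math.pi * from_hz / fs)
    return signal.lfilter([1.0, -a], [1.0], audio)


def _resample_to(audio: np.ndarray, fs: float, target_fs: float) -> tuple[np.ndarray, float]:
    if abs(target_fs - fs) < 1e-9:
        return audio, fs
    frac = Fraction(int(round(target_fs)), int(round(fs))).limit_denominator(1000)
    out = signal.resample_poly(audio, frac.numerator, frac.denominator)
    return out, fs * frac.numerator / frac.denominator


# ---------------------------------------------------------------------------
# Burg LPC and robust refinement
# ---------------------------------------------------------------------------


def burg_coefficients(x: np.ndarray, order: int) -> np.ndarray:
    """AR coefficients a = (1, a1..ap) of the Burg (maximum-entropy) method.

    Minimises the sum of forward and backward prediction errors with the
    Levinson recursion constraint; numerically the standard lattice
    formulation.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if order >= n:
        raise ParameterError(f"Burg order {order} >= frame length {n}")
    a = np.zeros(order + 1)
    a[0] = 1.0
    f = x[1:].copy()  # forward error at n = 1..N-1
    b = x[:-1].copy()  # backward error at n-1 = 0..N-2
    for m in range(order):
        den = np.dot(f, f) + np.dot(b, b)
        if den <= 0:
            break
        k = -2.0 * np.dot(f, b) / den
        a_prev = a.copy()
        for i in range(1, m + 2):
            a[i] = a_prev[i] + k * a_prev[m + 1 - i]
        f, b = (f + k * b)[1:], (b + k * f)[:-1]
    return a


def _weighted_ar(x: np.ndarray, order: int, w: np.ndarray) -> np.ndarray:
    """Weighted covariance-method AR fit; returns (1, a1..ap)."""
    n = x.size
    rows = n - order
    X = np.empty((rows, order))
    for j in range(order):
        X[:, j] = x[order - 1 - j : n - 1 - j]
    y = x[order:]
    sw = np.sqrt(w[order:])
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return np.concatenate([[1.0], -coef])


def _robust_refine(
    x: np.ndarray,
    a: np.ndarray,
    order: int,
    n_std: float = 1.5,
    max_iter: int = 5,
    tol: float = 1e-5,
) -> np.ndarray:
    """Iteratively reweighted AR refinement.

    Samples whose prediction residual exceeds ``n_std`` standard deviations
    are down-weighted (Huber-style, weight k/|e|); iteration stops after
    ``max_iter`` rounds or when the relative change in residual variance
    falls below ``tol``.
    """
    n = x.size
    var_prev = None
    for _ in range(max_iter):
        e = signal.lfilter(a, [1.0], x)[order:]
        var = float(np.mean(e**2))
        if var <= 0:
            break
        if var_prev is not None and abs(var_prev - var) / var_prev < tol:
            break
        var_prev = var
        k = n_std * math.sqrt(var)
        abse = np.abs(e)
        w_tail = np.where(abse <= k, 1.0, k / np.maximum(abse, 1e-30))
        w = np.ones(n)
        w[order:] = w_tail
        try:
            a = _weighted_ar(x, order, w)
        except np.linalg.LinAlgError:  # pragma: no cover - singular frame
            break
    return a


def _formants_from_ar(a: np.ndarray, fs: float, ceiling_hz: float, n_formants: int) -> np.ndarray:
    """Pole frequencies of an AR polynomial, low-to-high, NaN-padded."""
    roots = np.roots(a)
    roots = roots[np.imag(roots) > 1e-9]
    freqs = np.angle(roots) * fs / (2.0 * math.pi)
    bw = -np.log(np.maximum(np.abs(roots), 1e-12)) * fs / math.pi
    keep = (freqs > 50.0) & (freqs < ceiling_hz - 50.0) & (bw < ceiling_hz)
    freqs = np.sort(freqs[keep])
    out = np.full(n_formants, np.nan)
    out[: min(n_formants, freqs.size)] = freqs[:n_formants]
    return out


def estimate_formants(
    audio: np.ndarray,
    fs: float,
    ceiling_hz: float,
    window_s: float = 0.005,
    step_s: float = 0.005,
    preemphasis_from_hz: float = 50.0,
    n_formants: int = 5,
    robust: bool = True,
) -> FormantTrack:
    """Estimate up to ``n_formants`` formants per frame below ``ceiling_hz``.

    The audio is resampled to 2 × ceiling, pre-emphasised above
    ``preemphasis_from_hz``, cut into Gaussian-windowed frames, and each
    frame is fitted with a Burg-method LPC polynomial of order
    2·``n_formants`` whose complex-pole angles give the formant candidates.
    With ``robust`` the per-frame fit is refined by iterative reweighting of
    high-residual samples (start ±1.5 SD, at most five iterations, stop when
    the relative variance change is below 1e−5).
    """
    audio = np.asarray(audio, dtype=float)
    target_fs = 2.0 * ceiling_hz
    if target_fs > fs:
        raise ParameterError(
            f"ceiling {ceiling_hz} Hz needs sample rate >= {target_fs} Hz (have {fs})"
        )
    x, fs2 = _resample_to(audio, fs, target_fs)
    x = _preemphasize(x, fs2, preemphasis_from_hz)
    times, frames = _frames(x, fs2, window_s, step_s)
    order = 2 * n_formants
    peak = float(np.max(np.abs(x))) if x.size else 0.0
    out = np.full((times.size, n_formants), np.nan)
    n_silent = 0
    for i, frame in enumerate(frames):
        rms = math.sqrt(float(np.mean(frame**2)))
        if peak <= 0 or rms < 1e-8:
            n_silent += 1
            continue
        a = burg_coefficients(frame, order)
        if robust:
            a = _robust_refine(frame, a, order)
        out[i] = _formants_from_ar(a, fs2, ceiling_hz, n_formants)
    if n_silent:
        log.info("formant estimation: %d/%d silent frames left undefined", n_silent, times.size)
    return FormantTrack(frame_times_s=times, formants=out)


def optimize_ceiling_train(
    segments: list[tuple[np.ndarray, float]],
    ceiling_grid: np.ndarray | list[float],
    poly_order: int = 2,
    **formant_kwargs,
) -> float:
    """Grid-search the formant ceiling for one training speaker.

    For each candidate ceiling, formants are estimated on every segment and
    a quadratic-in-time polynomial is fitted per formant (F1–F3) per
    segment; the ceiling with the smallest summed squared residual wins
    (ties broken toward the lowest ceiling). A smooth low-order trajectory
    fits well exactly when the pole picking is stable, which is the
    practical signature of a well-chosen ceiling.
    """
    grid = sorted(float(c) for c in np.atleast_1d(np.asarray(ceiling_grid, dtype=float)))
    if not grid:
        raise ParameterError("empty ceiling grid")
    if not segments:
        raise DataError("no segments supplied for ceiling optimization")
    best_c, best_ssr = None, math.inf
    for ceiling in grid:
        ssr = 0.0
        n_pts = 0
        for audio, fs in segments:
            try:
                track = estimate_formants(audio, fs, ceiling, **formant_kwargs)
            except (DataError, ParameterError):
                ssr = math.inf
                break
            for j in range(3):  # F1..F3
                y = track.formants[:, j]
                t = track.frame_times_s
                ok = np.isfinite(y)
                if ok.sum() <= poly_order + 1:
                    ssr += 1e12  # unusable ceiling for this segment
                    continue
                coef = np.polynomial.polynomial.polyfit(t[ok], y[ok], poly_order)
                resid = y[ok] - np.polynomial.polynomial.polyval(t[ok], coef)
                ssr += float(np.sum(resid**2))
                n_pts += int(ok.sum())
        if n_pts == 0:
            ssr = math.inf
        if ssr < best_ssr:  # strict: ties keep the lower ceiling
            best_ssr, best_c = ssr, ceiling
    if best_c is None:
        best_c = grid[0]
    return best_c


def default_ceiling_grid() -> np.ndarray:
    """Child-appropriate ceiling grid, 3500–6500 Hz in 50 Hz steps."""
    return np.arange(3500.0, 6500.0 + 1e-9, 50.0)


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, n_fft: int, fs: float) -> np.ndarray:
    edges = _mel_to_hz(np.linspace(_hz_to_mel(0.0), _hz_to_mel(fs / 2.0), n_filters + 2))
    bins = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    fb = np.zeros((n_filters, bins.size))
    for i in range(n_filters):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (bins - lo) / max(mid - lo, 1e-9)
        down = (hi - bins) / max(hi - mid, 1e-9)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def estimate_mfcc(
    audio: np.ndarray,
    fs: float,
    window_s: float = 0.005,
    step_s: float = 0.005,
    n_coefficients: int = 13,
    n_filters: int = 26,
) -> MfccTrack:
    """Thirteen MFCCs per frame on the same Gaussian frames as the formants.

    Default filter bank (26 triangular filters, 0 Hz to Nyquist on the Mel
    scale); no speaker-specific settings. c0 (overall log energy) is
    included as the first coefficient, so a pure gain change moves only c0.
    """
    from scipy.fft import dct

    audio = np.asarray(audio, dtype=float)
    times, frames = _frames(audio, fs, window_s, step_s)
    n_fft = 1 << max(9, int(math.ceil(math.log2(frames.shape[1]))))
    spec = np.abs(np.fft.rfft(frames, n=n_fft, axis=1)) ** 2
    fb = _mel_filterbank(n_filters, n_fft, fs)
    mel = spec @ fb.T
    logmel = np.log(np.maximum(mel, 1e-30))
    cep = dct(logmel, type=2, norm="ortho", axis=1)[:, :n_coefficients]
    return MfccTrack(frame_times_s=times, coefficients=cep)


# ---------------------------------------------------------------------------
# tensorization
# ---------------------------------------------------------------------------


def _window_stats(X: np.ndarray) -> np.ndarray:
    """The 8 summary statistics of one window, per feature.

    ``X`` is (n_frames_in_window, n_features) with NaN marking undefined
    frames; returns (n_features, 8). Skewness (Fisher g1) and excess
    kurtosis (g2) of constant or near-singleton windows are defined as 0.
    A feature with no defined frame in the window yields all-NaN stats
    (imputed later from neighbouring windows).
    """
    import warnings

    n_feat = X.shape[1] if X.ndim == 2 else 1
    out = np.full((n_feat, 8), np.nan)
    if X.size == 0:
        return out
    finite = np.isfinite(X)
    n = finite.sum(axis=0).astype(float)
    any_ok = n > 0
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0)
        d = np.where(finite, X - mu, 0.0)
        m2 = np.where(any_ok, (d**2).sum(axis=0) / np.maximum(n, 1), np.nan)
        m3 = np.where(any_ok, (d**3).sum(axis=0) / np.maximum(n, 1), np.nan)
        m4 = np.where(any_ok, (d**4).sum(axis=0) / np.maximum(n, 1), np.nan)
        out[:, 0] = np.nanmedian(X, axis=0)
        out[:, 1] = mu
        out[:, 2] = sd
        out[:, 3] = np.nanmin(X, axis=0)
        out[:, 4] = np.nanmax(X, axis=0)
        out[:, 5] = sd * sd
        shaped = any_ok & (n >= 3) & (m2 > 1e-24)
        out[:, 6] = np.where(shaped, m3 / np.maximum(m2, 1e-300) ** 1.5, np.where(any_ok, 0.0, np.nan))
        out[:, 7] = np.where(shaped, m4 / np.maximum(m2, 1e-300) ** 2 - 3.0, np.where(any_ok, 0.0, np.nan))
    return out


def _fill_empty_windows(mat: np.ndarray) -> np.ndarray:
    """Linear interpolation across the window axis for all-NaN windows;
    edge gaps copy the nearest populated window."""
    out = mat.copy()
    n_win = mat.shape[0]
    ok = np.isfinite(mat).all(axis=1)
    if not ok.any():
        raise DataError("all windows empty")
    idx = np.arange(n_win)
    for col in range(mat.shape[1]):
        good = ok  # emptiness is per-window (all stats NaN together)
        out[~good, col] = np.interp(idx[~good], idx[good], mat[good, col])
    return out


def tensorize(
    track: FormantTrack | MfccTrack,
    representation: str | None = None,
    normalization: str = "none",
    feature_matrix: np.ndarray | None = None,
) -> FeatureTensor:
    """Reduce a track to the (n_features × 10 × 8) feature tensor.

    The interval spanned by the frame times is cut into 10 equal-duration
    contiguous windows; per window and feature, the 8 summary statistics are
    computed over the defined frames. Windows without any defined frame are
    imputed by linear interpolation from their populated neighbours.

    ``feature_matrix`` overrides the track's own features (used to tensorize
    normalized frame values while keeping the track's timing).
    """
    if representation is None:
        representation = "formant" if isinstance(track, FormantTrack) else "mfcc"
    X = track.feature_matrix() if feature_matrix is None else np.asarray(feature_matrix, float)
    t = track.frame_times_s
    if t.size == 0 or not np.isfinite(X).any():
        raise DataError("no defined frames to tensorize")
    t0, t1 = float(t[0]), float(t[-1])
    span = max(t1 - t0, 1e-9)
    wix = np.minimum(((t - t0) / span * N_WINDOWS).astype(int), N_WINDOWS - 1)
    n_feat = X.shape[1]
    values = np.empty((n_feat, N_WINDOWS, 8))
    for w in range(N_WINDOWS):
        values[:, w, :] = _window_stats(X[wix == w, :])
    for f in range(n_feat):
        values[f] = _fill_empty_windows(values[f])
    return FeatureTensor(
        values=values,
        feature_names=tuple(track.feature_names),
        representation=representation,
        normalization=normalization,
    )
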