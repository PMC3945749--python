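"""Spectral feature representations: MFCC, LSF, and RASTA-PLP cepstra.

Three classic speech-analysis front ends, implemented from scratch on the
25 ms / 720-sample-hop Hamming frame grid:

``MFCC39``
    Per frame: one-sided power spectrum -> 32 triangular mel filters ->
    log -> orthonormal DCT-II -> first 13 cepstral coefficients (c0
    included by default), with 5-point-regression velocity and
    acceleration appended: 39 dimensions.

``LSF``
    Per frame: biased autocorrelation -> order-p linear prediction via
    Levinson-Durbin -> line spectral frequencies, the interleaved
    unit-circle root angles of the palindromic/anti-palindromic
    decomposition P(z), Q(z) of the prediction polynomial A(z).

``RASTA_PLPCC12``
    Per frame: power spectrum -> critical-band (Bark) integration ->
    log -> RASTA band-pass filtering of each band trajectory (sharp
    spectral zero at DC, suppressing slowly varying convolutional channel
    effects) -> exponentiation -> equal-loudness weighting and cube-root
    intensity-loudness compression -> order-12 all-pole model -> cepstral
    recursion: 12 dimensions (c1..c12).

Scales: mel(f) = 2595 log10(1 + f/700); Bark(f) = 6 asinh(f/600).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct
from scipy.signal import lfilter

from .dsp import FEAT_GRID, FrameGrid, power_frames
from .synth import AudioClip

#: energies are clamped here before any log (silent frames must stay finite)
LOG_FLOOR = 1e-10

N_MEL_FILTERS = 32
N_MFCC = 13
LP_ORDER = 12

#: cepstral lifter exponent: c_n is weighted by n^LIFTER_EXP, the standard
#: re-weighting that balances broad spectral tilt against fine envelope
#: detail before vector distances are taken
LIFTER_EXP = 0.6

#: canonical RASTA transfer function
#: H(z) = 0.1 z^4 (2 + z^-1 - z^-3 - 2 z^-4) / (1 - 0.98 z^-1)
RASTA_NUM = 0.1 * np.array([2.0, 1.0, 0.0, -1.0, -2.0])
RASTA_DEN = np.array([1.0, -0.98])

FEATURE_KINDS = ("MFCC39", "LSF", "RASTA_PLPCC12")


@dataclass
class FrameFeatures:
    """Per-frame feature matrix (n_frames x dim) of one representation."""

    values: np.ndarray
    kind: str
    grid: FrameGrid = FEAT_GRID
    n_excluded: int = 0  # frames dropped (e.g. unstable LP fits)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# mel filterbank & MFCC


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(
    n_filters: int = N_MEL_FILTERS, n_fft: int = FEAT_GRID.window_length, rate: int = 48000
) -> np.ndarray:
    """Triangular unit-peak mel filters over the one-sided DFT bins."""
    nyq = rate / 2.0
    edges_hz = mel_to_hz(np.linspace(hz_to_mel(0.0), hz_to_mel(nyq), n_filters + 2))
    bin_freqs = np.arange(n_fft // 2 + 1) * rate / n_fft
    fb = np.zeros((n_filters, len(bin_freqs)))
    for i in range(n_filters):
        lo, mid, hi = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        up = (bin_freqs - lo) / (mid - lo)
        down = (hi - bin_freqs) / (hi - mid)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mel_filter_centers(n_filters: int = N_MEL_FILTERS, rate: int = 48000) -> np.ndarray:
    nyq = rate / 2.0
    edges = mel_to_hz(np.linspace(hz_to_mel(0.0), hz_to_mel(nyq), n_filters + 2))
    return edges[1:-1]


def delta_features(values: np.ndarray, half_width: int = 2) -> np.ndarray:
    """5-point linear-regression slope along time, edges replicated."""
    n = values.shape[0]
    idx = np.clip(np.arange(-half_width, n + half_width), 0, n - 1)
    padded = values[idx]
    ks = np.arange(1, half_width + 1)
    denom = 2.0 * np.sum(ks**2)
    out = np.zeros_like(values)
    for k in ks:
        out += k * (padded[half_width + k : half_width + k + n] - padded[half_width - k : half_width - k + n])
    return out / denom


def log_mel_energies(clip: AudioClip, n_filters: int = N_MEL_FILTERS) -> np.ndarray:
    fb = mel_filterbank(n_filters, FEAT_GRID.window_length, clip.rate)
    energies = power_frames(clip, FEAT_GRID) @ fb.T
    return np.log(np.maximum(energies, LOG_FLOOR))


def compute_mfcc(clip: AudioClip, n_coeffs: int = N_MFCC, include_c0: bool = True) -> FrameFeatures:
    """39-dim MFCC: 13 static + 13 velocity + 13 acceleration per frame."""
    cepstra = dct(log_mel_energies(clip), type=2, norm="ortho", axis=1)
    static = cepstra[:, :n_coeffs] if include_c0 else cepstra[:, 1 : n_coeffs + 1]
    vel = delta_features(static)
    acc = delta_features(vel)
    return FrameFeatures(np.hstack([static, vel, acc]), kind="MFCC39")


# ---------------------------------------------------------------------------
# linear prediction


@dataclass
class LPModel:
    """All-pole model: x(n) is predicted as sum_k a_k x(n-k).

    ``coefficients`` are the predictor weights a_1..a_p (so the inverse
    filter is A(z) = 1 - sum a_k z^-k); ``gain`` is the residual energy.
    """

    order: int
    coefficients: np.ndarray
    gain: float

    def polynomial(self) -> np.ndarray:
        """A(z) coefficients [1, -a_1, ..., -a_p]."""
        return np.concatenate([[1.0], -self.coefficients])

    def is_stable(self, tol: float = 1e-9) -> bool:
        poly = self.polynomial()
        if self.order == 0:
            return True
        return bool(np.all(np.abs(np.roots(poly)) < 1.0 - tol * 0))


def levinson_durbin(autocorr: np.ndarray, order: int) -> LPModel:
    """Solve the Yule-Walker equations by Levinson-Durbin recursion."""
    r = np.asarray(autocorr, dtype=np.float64)
    if len(r) < order + 1:
        raise ValueError(f"need {order + 1} autocorrelation lags, got {len(r)}")
    if r[0] <= 0:
        raise ValueError("zero-lag autocorrelation must be positive")
    a = np.zeros(order)
    err = float(r[0])
    for i in range(1, order + 1):
        acc = r[i] - np.dot(a[: i - 1], r[1:i][::-1])
        if err <= 0:
            raise np.linalg.LinAlgError(
                f"singular Yule-Walker system at stage {i} (prediction error {err:.3e})"
            )
        k = acc / err
        a_new = a.copy()
        a_new[i - 1] = k
        a_new[: i - 1] = a[: i - 1] - k * a[: i - 1][::-1]
        a = a_new
        err *= 1.0 - k * k
    return LPModel(order=order, coefficients=a, gain=max(err, 0.0))


def _levinson_batch(r: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Levinson-Durbin over many frames at once: r is (n, order+1)."""
    n = r.shape[0]
    a = np.zeros((n, order))
    err = r[:, 0].copy()
    if np.any(err <= 0):
        raise ValueError("non-positive frame energy in batched Levinson-Durbin")
    for i in range(1, order + 1):
        acc = r[:, i] - np.einsum("nj,nj->n", a[:, : i - 1], r[:, 1:i][:, ::-1])
        k = acc / err
        prev = a[:, : i - 1].copy()
        a[:, : i - 1] = prev - k[:, None] * prev[:, ::-1]
        a[:, i - 1] = k
        err *= 1.0 - k * k
    return a, np.maximum(err, 0.0)


# ---------------------------------------------------------------------------
# line spectral frequencies

#: tolerance for discarding the trivial P/Q roots at angles 0 and pi
_TRIVIAL_ANGLE_TOL = 1e-6


@dataclass
class LSFVector:
    """Sorted line spectral frequencies in (0, pi).

    ``p_frequencies`` / ``q_frequencies`` are the subsets contributed by
    the palindromic P(z) and anti-palindromic Q(z); in the sorted union
    the two subsets strictly alternate.
    """

    frequencies: np.ndarray
    p_frequencies: np.ndarray
    q_frequencies: np.ndarray


def _pq_polynomials(a_poly: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P(z) = A(z) + z^-(p+1) A(z^-1);  Q(z) = A(z) - z^-(p+1) A(z^-1)."""
    ext = np.concatenate([a_poly, [0.0]])
    rev = ext[::-1]
    return ext + rev, ext - rev


def _upper_half_angles(poly: np.ndarray) -> np.ndarray:
    roots = np.roots(poly)
    if np.any(np.abs(np.abs(roots) - 1.0) > 1e-6):
        raise ValueError("P/Q roots left the unit circle (unstable LP model?)")
    ang = np.angle(roots)
    keep = (ang > _TRIVIAL_ANGLE_TOL) & (ang < np.pi - _TRIVIAL_ANGLE_TOL)
    return np.sort(ang[keep])


def lp_to_lsf(model: LPModel) -> LSFVector:
    """Line spectral frequencies of a stable LP model."""
    if not model.is_stable():
        raise ValueError("LSF decomposition requires a stable LP model")
    p_poly, q_poly = _pq_polynomials(model.polynomial())
    wp = _upper_half_angles(p_poly)
    wq = _upper_half_angles(q_poly)
    freqs = np.sort(np.concatenate([wp, wq]))
    if len(freqs) != model.order:
        raise ValueError(f"expected {model.order} LSFs, found {len(freqs)}")
    return LSFVector(frequencies=freqs, p_frequencies=wp, q_frequencies=wq)


def lsf_to_lp(lsf: LSFVector) -> np.ndarray:
    """Rebuild A(z) = (P(z) + Q(z)) / 2 from the root angles (inverse map)."""
    p = len(lsf.frequencies)

    def expand(angles: np.ndarray, extra: np.ndarray) -> np.ndarray:
        poly = extra
        for w in angles:
            poly = np.convolve(poly, [1.0, -2.0 * np.cos(w), 1.0])
        return poly

    # trivial roots: Q always has z=1; the root at z=-1 sits in P for even
    # p and in Q for odd p (degree bookkeeping of the decomposition)
    p_extra = np.array([1.0, 1.0]) if p % 2 == 0 else np.array([1.0])
    q_extra = (
        np.array([1.0, -1.0]) if p % 2 == 0 else np.convolve([1.0, -1.0], [1.0, 1.0])
    )
    p_poly = expand(lsf.p_frequencies, p_extra)
    q_poly = expand(lsf.q_frequencies, q_extra)
    return ((p_poly + q_poly) / 2.0)[: p + 1]


def autocorrelate(frame: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased autocorrelation r_0..r_max_lag via the Wiener-Khinchin route."""
    n = len(frame)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.abs(np.fft.rfft(frame, nfft)) ** 2
    r = np.fft.irfft(spec)[: max_lag + 1]
    return r / n


def compute_lsf_features(clip: AudioClip, order: int = LP_ORDER) -> FrameFeatures:
    """Per-frame LSFs; frames with degenerate or unstable LP fits are dropped."""
    from .dsp import frame_signal

    frames = frame_signal(clip, FEAT_GRID)
    rows, n_excluded = [], 0
    for frame in frames:
        try:
            r = autocorrelate(frame, order)
            model = levinson_durbin(r, order)
            rows.append(lp_to_lsf(model).frequencies)
        except (ValueError, np.linalg.LinAlgError):
            n_excluded += 1
    if not rows:
        raise ValueError("no frame produced a stable LP model")
    return FrameFeatures(np.array(rows), kind="LSF", n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# PLP auditory spectrum and RASTA filtering


def hz_to_bark(f):
    return 6.0 * np.arcsinh(np.asarray(f, dtype=float) / 600.0)


def bark_to_hz(z):
    return 600.0 * np.sinh(np.asarray(z, dtype=float) / 6.0)


def n_bark_bands(rate: int = 48000) -> int:
    """Grid points at 1-Bark spacing from 0 up to Bark(Nyquist), inclusive."""
    return int(np.floor(hz_to_bark(rate / 2.0))) + 1


def bark_filterbank(n_fft: int = FEAT_GRID.window_length, rate: int = 48000) -> np.ndarray:
    """Critical-band masking filters centred on integer Bark values.

    Each band is flat over +-0.5 Bark with a 10 dB/Bark lower skirt and a
    25 dB/Bark upper skirt (the classic critical-band masking shape).
    """
    bin_barks = hz_to_bark(np.arange(n_fft // 2 + 1) * rate / n_fft)
    centers = np.arange(n_bark_bands(rate), dtype=float)
    lof = bin_barks[None, :] - centers[:, None] - 0.5
    hif = bin_barks[None, :] - centers[:, None] + 0.5
    return 10.0 ** np.minimum(0.0, np.minimum(hif, -2.5 * lof))


def equal_loudness_weights(rate: int = 48000) -> np.ndarray:
    """40-phon equal-loudness pre-emphasis at the Bark band centers."""
    f = bark_to_hz(np.arange(n_bark_bands(rate), dtype=float))
    w2 = (2.0 * np.pi * f) ** 2
    return ((w2 + 56.8e6) * w2**2) / ((w2 + 6.3e6) ** 2 * (w2 + 0.38e9))


def plp_auditory_spectrum(power_frame: np.ndarray, rate: int = 48000) -> np.ndarray:
    """Bark integration, equal-loudness weighting, cube-root compression."""
    power_frame = np.asarray(power_frame, dtype=np.float64)
    if np.any(power_frame < 0):
        raise ValueError("power spectrum must be non-negative")
    bands = bark_filterbank(2 * (len(power_frame) - 1), rate) @ power_frame
    out = (equal_loudness_weights(rate) * bands) ** 0.33
    return np.maximum(out, LOG_FLOOR)


def rasta_filter(trajectories: np.ndarray, init: str = "steady") -> np.ndarray:
    """Band-pass each log band trajectory with the RASTA filter (DC gain 0).

    ``init="steady"`` uses the canonical warm-up: the FIR numerator state
    is built on the first four frames (whose outputs are zeroed) before
    the pole is engaged, so a constant input maps to exactly zero from
    frame four on. ``init="zero"`` is plain zero-state filtering, whose
    output for an impulse is the filter's impulse response.
    """
    x = np.atleast_2d(np.asarray(trajectories, dtype=np.float64))
    squeeze = np.asarray(trajectories).ndim == 1
    if squeeze:
        x = x.T
    n_warm = len(RASTA_NUM) - 1
    if x.shape[0] < n_warm + 1:
        raise ValueError(f"RASTA filtering needs more than {n_warm} frames, got {x.shape[0]}")
    if init == "zero":
        y = lfilter(RASTA_NUM, RASTA_DEN, x, axis=0)
    elif init == "steady":
        zi = np.zeros((n_warm, x.shape[1]))
        _, state = lfilter(RASTA_NUM, [1.0], x[:n_warm], axis=0, zi=zi)
        tail, _ = lfilter(RASTA_NUM, RASTA_DEN, x[n_warm:], axis=0, zi=state)
        y = np.vstack([np.zeros((n_warm, x.shape[1])), tail])
    else:
        raise ValueError(f"unknown init mode {init!r}")
    return y[:, 0] if squeeze else y


def _lpc_to_cepstrum(a: np.ndarray, gain: np.ndarray, n_ceps: int) -> np.ndarray:
    """Cepstral recursion for 1/A(z) models; rows are frames.

    With A(z) = 1 + sum ahat_k z^-k (ahat = -a for predictor weights a):
    c_n = -ahat_n - (1/n) sum_{k=1}^{n-1} k c_k ahat_{n-k}; c_0 = ln(gain).
    """
    ahat = -a
    n, p = ahat.shape
    c = np.zeros((n, n_ceps + 1))
    c[:, 0] = np.log(np.maximum(gain, LOG_FLOOR))
    for m in range(1, n_ceps + 1):
        acc = np.zeros(n)
        for k in range(1, m):
            if m - k <= p:
                acc += k * c[:, k] * ahat[:, m - k - 1]
        c[:, m] = (-ahat[:, m - 1] if m <= p else 0.0) - acc / m
    return c


def compute_rasta_plpcc(
    clip: AudioClip, order: int = LP_ORDER, include_c0: bool = False, lifter: float = LIFTER_EXP
) -> FrameFeatures:
    """RASTA-filtered perceptual linear prediction cepstra (12-dim)."""
    power = power_frames(clip, FEAT_GRID)
    fb = bark_filterbank(FEAT_GRID.window_length, clip.rate)
    bands = np.maximum(power @ fb.T, LOG_FLOOR)
    log_bands = rasta_filter(np.log(bands), init="steady")
    aud = (equal_loudness_weights(clip.rate) * np.exp(log_bands)) ** 0.33
    # duplicate edge bands before the all-pole fit (stabilizes the ends
    # of the auditory spectrum, standard PLP practice)
    aud[:, 0] = aud[:, 1]
    aud[:, -1] = aud[:, -2]
    # the auditory spectrum is a sampled one-sided power spectrum: its
    # inverse DFT gives the autocorrelation sequence for the all-pole fit
    r = np.fft.irfft(aud, axis=1)[:, : order + 1]
    a, gain = _levinson_batch(r, order)
    ceps = _lpc_to_cepstrum(a, gain, order)
    if lifter:
        ceps = ceps * np.concatenate([[1.0], np.arange(1, order + 1) ** lifter])
    values = ceps if include_c0 else ceps[:, 1:]
    return FrameFeatures(values, kind="RASTA_PLPCC12")


def extract_features(clip: AudioClip, kind: str) -> FrameFeatures:
    """Dispatch by feature kind name."""
    if kind == "MFCC39":
        return compute_mfcc(clip)
    if kind == "LSF":
        return compute_lsf_features(clip)
    if kind == "RASTA_PLPCC12":
        return compute_rasta_plpcc(clip)
    raise ValueError(f"unknown feature kind {kind!r}")
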