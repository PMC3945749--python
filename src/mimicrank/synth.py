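"""Seeded synthesis of bird-call libraries.

Real mimicry studies start from field recordings of a mimic (here, a
drongo-like generalist), its putative heterospecific model calls, calls of
other sympatric species, and the mimic's own species-specific repertoire.
This module synthesizes libraries with that role structure so the whole
matching pipeline can be exercised end to end without any recordings.

Calls fall into five coarse spectral-signature classes commonly used to
describe bird vocalizations by spectrogram shape:

- ``FM``       frequency-modulated sweep (monotone linear contour)
- ``Trill``    repeated short FM elements separated by silent gaps
- ``NB-Trill`` narrowband rapid sinusoidal modulation around a carrier
- ``HR``       harmonic stack (fundamental plus integer harmonics)
- ``BB``       band-limited noise bursts

All generated energy lies in the 500 Hz - 8 kHz band typical of bird calls.
Mimic calls are perturbed copies of their model (additive noise at a target
SNR, multiplicative frequency jitter, duration scaling, slow amplitude
modulation) standing in for natural mimic imperfection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CALL_CLASSES = ("FM", "BB", "HR", "Trill", "NB-Trill")
ROLES = ("mimic", "model", "other", "conspecific")

FREQ_MIN = 500.0
FREQ_MAX = 8000.0
DEFAULT_RATE = 48000

#: linear peak all clips are normalized to (removes gain as a confound)
PEAK_NORM = 0.9
#: raised-cosine edge fade, seconds (click / spectral-leakage control)
EDGE_FADE_S = 0.005
#: silent gap between trill elements, seconds
TRILL_GAP_S = 0.010
#: maximum frequency deviation of the NB-Trill sinusoidal FM, Hz
NB_TRILL_MAX_DEV = 200.0
#: ambient (recording) noise added to every clip, dB below the call; field
#: recordings are never noise-free and a common floor keeps the feature
#: space realistic for clean and perturbed calls alike; 25 dB is mid-range
#: for directional-microphone recordings of nearby birds
AMBIENT_SNR_DB = 25.0
#: depth of the slow random amplitude envelope every call carries
ENVELOPE_DEPTH = 0.3


@dataclass(frozen=True)
class CallSpec:
    """Parameters of one synthetic call.

    Fields are interpreted per class: FM/Trill use ``f_start``/``f_end``
    sweep endpoints; HR uses ``f0`` and ``n_harmonics``; NB-Trill uses
    ``f0`` (carrier), ``bandwidth`` (peak-to-peak deviation, capped at
    2 x 200 Hz) and ``trill_rate``; BB uses ``f0`` (band center) and
    ``bandwidth``.
    """

    call_class: str
    duration: float = 0.5
    f_start: float = 1000.0
    f_end: float = 4000.0
    f0: float = 1000.0
    n_harmonics: int = 1
    trill_rate: float = 10.0
    element_duration: float = 0.05
    bandwidth: float = 1000.0
    amplitude: float = PEAK_NORM

    def __post_init__(self) -> None:
        if self.call_class not in CALL_CLASSES:
            raise ValueError(f"unknown call class {self.call_class!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must be in (0, 1]")
        lo, hi = self.band()
        if lo < FREQ_MIN - 1e-9 or hi > FREQ_MAX + 1e-9:
            raise ValueError(
                f"{self.call_class} spec occupies [{lo:.0f}, {hi:.0f}] Hz, "
                f"outside the allowed [{FREQ_MIN:.0f}, {FREQ_MAX:.0f}] Hz band"
            )

    def band(self) -> tuple[float, float]:
        """Nominal (lowest, highest) frequency the call occupies, Hz."""
        if self.call_class in ("FM", "Trill"):
            return (min(self.f_start, self.f_end), max(self.f_start, self.f_end))
        if self.call_class == "HR":
            return (self.f0, self.f0 * self.n_harmonics)
        if self.call_class == "NB-Trill":
            dev = min(self.bandwidth / 2.0, NB_TRILL_MAX_DEV)
            return (self.f0 - dev, self.f0 + dev)
        # BB: noise band centred on f0
        return (self.f0 - self.bandwidth / 2.0, self.f0 + self.bandwidth / 2.0)


@dataclass(frozen=True)
class PerturbationSpec:
    """How a mimic call deviates from its model.

    ``snr_db`` is the signal-to-noise ratio of additive white noise
    (``inf`` = no noise); ``freq_jitter_pct`` a multiplicative frequency
    offset in per cent; ``time_stretch`` a duration scale factor;
    ``amp_mod_depth`` the depth in [0, 1] of a slow (3 Hz) amplitude
    modulation.
    """

    snr_db: float = 20.0
    freq_jitter_pct: float = 2.0
    time_stretch: float = 1.0
    amp_mod_depth: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.snr_db) or self.snr_db == math.inf):
            raise ValueError("snr_db must be finite or +inf")
        if self.time_stretch <= 0:
            raise ValueError("time_stretch must be positive")
        if not 0 <= self.amp_mod_depth <= 1:
            raise ValueError("amp_mod_depth must be in [0, 1]")

    @property
    def is_identity(self) -> bool:
        return (
            self.snr_db == math.inf
            and self.freq_jitter_pct == 0
            and self.time_stretch == 1
            and self.amp_mod_depth == 0
        )


IDENTITY_PERTURBATION = PerturbationSpec(
    snr_db=math.inf, freq_jitter_pct=0.0, time_stretch=1.0, amp_mod_depth=0.0
)


@dataclass
class AudioClip:
    """A labeled mono waveform."""

    samples: np.ndarray
    rate: int = DEFAULT_RATE
    id: str = ""
    species: str = ""
    role: str = "other"
    call_class: str = "FM"
    model_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip samples must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioClip samples must be finite")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass(frozen=True)
class LibrarySpec:
    """Composition of a synthetic call library.

    The study-scale compositions are 21/21/20/20 (the 82-file subset used
    for trial experiments) and 63 mimics with 84 heterospecific and 210
    conspecific files (the full 357-file library; models counted among the
    heterospecifics).
    """

    n_mimic: int = 21
    n_model: int = 21
    n_other: int = 20
    n_conspecific: int = 20
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    seed: int = 0
    #: if True, mimics are independent random calls (chance-level control)
    unrelated_mimics: bool = False

    def __post_init__(self) -> None:
        for n in (self.n_mimic, self.n_model, self.n_other, self.n_conspecific):
            if n < 0:
                raise ValueError("library counts must be non-negative")
        if self.n_mimic > 0 and self.n_model == 0:
            raise ValueError("library with mimics requires at least one model call")


class CallLibrary:
    """A collection of AudioClips with role bookkeeping."""

    def __init__(self, clips: list[AudioClip]):
        self.clips = list(clips)
        self.by_id = {c.id: c for c in self.clips}
        if len(self.by_id) != len(self.clips):
            raise ValueError("duplicate clip ids in library")
        for c in self.clips:
            if c.role == "mimic":
                if c.model_id is None or c.model_id not in self.by_id:
                    raise ValueError(f"mimic {c.id} has no model in the library")

    def __len__(self) -> int:
        return len(self.clips)

    def role_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in ROLES}
        for c in self.clips:
            counts[c.role] += 1
        return counts

    def ids_with_role(self, role: str) -> list[str]:
        return [c.id for c in self.clips if c.role == role]

    @property
    def mimics(self) -> list[AudioClip]:
        return [c for c in self.clips if c.role == "mimic"]

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "id": c.id,
                "path": f"{c.id}.wav",
                "species": c.species,
                "role": c.role,
                "call_class": c.call_class,
                "model_id": c.model_id if c.model_id is not None else "",
            }
            for c in self.clips
        ]
        return pd.DataFrame(rows, columns=["id", "path", "species", "role", "call_class", "model_id"])


# ---------------------------------------------------------------------------
# waveform synthesis


def _edge_fade(x: np.ndarray, rate: int) -> np.ndarray:
    n_fade = min(int(EDGE_FADE_S * rate), len(x) // 2)
    if n_fade > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_fade) / n_fade))
        x[:n_fade] *= ramp
        x[-n_fade:] *= ramp[::-1]
    return x


def _normalize(x: np.ndarray, peak: float) -> np.ndarray:
    m = np.max(np.abs(x))
    if m > 0:
        x = x * (peak / m)
    return x


def _fm_sweep(f_start: float, f_end: float, n: int, rate: int) -> np.ndarray:
    t = np.arange(n) / rate
    # phase = 2*pi * integral of the linear instantaneous frequency
    phase = 2 * np.pi * (f_start * t + 0.5 * (f_end - f_start) * t**2 / (n / rate))
    return np.sin(phase)


def _band_noise(lo: float, hi: float, n: int, rate: int, rng: np.random.Generator) -> np.ndarray:
    """White noise confined to [lo, hi] Hz by spectral masking."""
    spec = rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    return np.fft.irfft(spec, n=n)


def synthesize_call(spec: CallSpec, rate: int = DEFAULT_RATE, seed: int = 0) -> AudioClip:
    """Render a CallSpec to a waveform; deterministic for a fixed seed.

    At least 90 % of the spectral power lands inside the spec's nominal
    band (plus a 100 Hz guard on either side). Every call carries a slow
    random amplitude envelope and a low-level ambient noise floor
    (AMBIENT_SNR_DB below the call), emulating the temporal structure and
    background of field recordings.
    """
    top = spec.band()[1]
    if top >= rate / 2:
        raise ValueError(f"spec reaches {top:.0f} Hz, at or above Nyquist ({rate / 2:.0f} Hz)")
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration * rate))
    t = np.arange(n) / rate

    cls = spec.call_class
    if cls == "FM":
        x = _fm_sweep(spec.f_start, spec.f_end, n, rate)
    elif cls == "HR":
        # harmonic stack with seeded per-harmonic amplitudes and a 5 %
        # vibrato: harmonic bird calls (parakeet- or babbler-like) carry
        # pronounced frequency modulation, never a flat tone
        vib_rate = rng.uniform(4.0, 8.0)
        vib_dev = 0.05 * spec.f0
        vib = -(vib_dev / (2 * np.pi * vib_rate)) * np.cos(2 * np.pi * vib_rate * t)
        x = np.zeros(n)
        for k in range(1, spec.n_harmonics + 1):
            amp = rng.uniform(0.5, 1.0) / k
            x += amp * np.sin(2 * np.pi * k * (spec.f0 * t + vib) + rng.uniform(0, 2 * np.pi))
    elif cls == "NB-Trill":
        dev = min(spec.bandwidth / 2.0, NB_TRILL_MAX_DEV)
        phase = 2 * np.pi * spec.f0 * t - (dev / spec.trill_rate) * np.cos(
            2 * np.pi * spec.trill_rate * t
        )
        x = np.sin(phase)
    elif cls == "BB":
        lo, hi = spec.band()
        x = _band_noise(lo, hi, n, rate, rng)
        # smooth raised-cosine bursts at the trill rate; a smooth envelope
        # keeps the spectral spread well inside the 100 Hz guard band
        env = 0.5 * (1 - np.cos(2 * np.pi * spec.trill_rate * t))
        x = x * (0.2 + 0.8 * env)
    elif cls == "Trill":
        n_elem = max(1, int(round(spec.element_duration * rate)))
        n_gap = int(round(TRILL_GAP_S * rate))
        elem = _fm_sweep(spec.f_start, spec.f_end, n_elem, rate)
        elem = _edge_fade(elem.copy(), rate)
        period = np.concatenate([elem, np.zeros(n_gap)])
        reps = int(np.ceil(n / len(period)))
        x = np.tile(period, reps)[:n]
    else:  # pragma: no cover - guarded by CallSpec validation
        raise ValueError(cls)

    # slow random amplitude envelope (each call has its own contour)
    env_rate = rng.uniform(2.0, 6.0)
    env_phase = rng.uniform(0, 2 * np.pi)
    d = ENVELOPE_DEPTH
    x = x * (1 - d / 2 + (d / 2) * np.sin(2 * np.pi * env_rate * t + env_phase))

    x = _edge_fade(x, rate)
    x = _normalize(x, spec.amplitude)
    # ambient recording noise, well below the call
    noise = rng.standard_normal(n)
    noise *= np.sqrt(np.mean(x**2) / 10 ** (AMBIENT_SNR_DB / 10.0) / np.mean(noise**2))
    x = _normalize(x + noise, spec.amplitude)
    return AudioClip(samples=x, rate=rate, call_class=cls)


def _linear_resample(x: np.ndarray, n_out: int) -> np.ndarray:
    pos = np.linspace(0.0, len(x) - 1, n_out)
    return np.interp(pos, np.arange(len(x)), x)


def _pv_stretch(x: np.ndarray, factor: float, win: int = 1024, hop: int = 256) -> np.ndarray:
    """Pitch-preserving time stretch by a standard phase vocoder.

    Instantaneous frequency per bin is estimated from the analysis phase
    increment and re-integrated over the scaled synthesis hop, so local
    frequencies are preserved while duration scales by ``factor``.
    """
    n_out = int(round(len(x) * factor))
    if len(x) < 2 * win:
        return _linear_resample(x, n_out)
    # reflect-pad so the output region of interest has full window overlap
    # (otherwise the under-normalized edge frames dominate the waveform)
    pad = win
    xp = np.pad(x, pad, mode="reflect")
    w = np.hanning(win)
    n_frames = (len(xp) - win) // hop + 1
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    spec = np.fft.rfft(xp[idx] * w, axis=1)
    mag, phase = np.abs(spec), np.angle(spec)

    omega = 2 * np.pi * np.arange(win // 2 + 1) / win * hop  # expected advance/hop
    dphi = np.diff(phase, axis=0) - omega
    dphi = np.mod(dphi + np.pi, 2 * np.pi) - np.pi
    inst = (omega + dphi) / hop  # rad/sample per bin

    hop_s = hop * factor
    out_phase = np.empty_like(phase)
    out_phase[0] = phase[0]
    np.cumsum(inst * hop_s, axis=0, out=out_phase[1:])
    out_phase[1:] += phase[0]

    frames = np.fft.irfft(mag * np.exp(1j * out_phase), n=win, axis=1) * w
    out = np.zeros(int(round((n_frames - 1) * hop_s)) + win)
    norm = np.zeros_like(out)
    w2 = w * w
    for m in range(n_frames):
        s = int(round(m * hop_s))
        out[s : s + win] += frames[m]
        norm[s : s + win] += w2
    out /= np.maximum(norm, 1e-8)
    start = int(round(pad * factor))
    out = out[start : start + n_out]
    if len(out) < n_out:
        out = np.pad(out, (0, n_out - len(out)))
    return out


def make_mimic(model: AudioClip, pert: PerturbationSpec, seed: int = 0) -> AudioClip:
    """Derive a mimic call from its model by controlled degradation.

    Frequency jitter is applied by polyphase resampling, which scales all
    frequencies by 1 + jitter/100 and, like a transposed re-recording,
    carries the reciprocal duration change; an explicit ``time_stretch``
    additionally scales duration pitch-free via a phase vocoder. White
    noise is then added at exactly ``pert.snr_db`` relative to the signal
    power. The identity perturbation returns a bit-identical copy.
    """
    if len(model.samples) == 0:
        raise ValueError("model clip is empty")
    rng = np.random.default_rng(seed)
    x = model.samples.copy()

    if not pert.is_identity:
        j = pert.freq_jitter_pct / 100.0
        if j != 0:
            # polyphase resample: flat passband, so the clip's noise floor
            # keeps its character (linear interpolation would low-pass it)
            from fractions import Fraction
            from scipy.signal import resample_poly

            frac = Fraction(1.0 / (1.0 + j)).limit_denominator(2000)
            x = resample_poly(x, frac.numerator, frac.denominator)
        if pert.time_stretch != 1.0:
            target_n = int(round(len(x) * pert.time_stretch))
            x = _pv_stretch(x, target_n / len(x))
            if len(x) != target_n:
                x = _linear_resample(x, target_n)
        if pert.amp_mod_depth > 0:
            t = np.arange(len(x)) / model.rate
            d = pert.amp_mod_depth
            x = x * (1 - d / 2 + (d / 2) * np.sin(2 * np.pi * 3.0 * t))
        if math.isfinite(pert.snr_db):
            p_sig = float(np.mean(x**2))
            noise = rng.standard_normal(len(x))
            p_noise_target = p_sig / 10 ** (pert.snr_db / 10.0)
            noise *= np.sqrt(p_noise_target / np.mean(noise**2))
            x = x + noise
        x = _normalize(x, PEAK_NORM)

    return AudioClip(
        samples=x,
        rate=model.rate,
        species="mimic-sp",
        role="mimic",
        call_class=model.call_class,
        model_id=model.id,
    )


# ---------------------------------------------------------------------------
# library construction


def random_call_spec(
    rng: np.random.Generator, call_class: str | None = None, position: float | None = None
) -> CallSpec:
    """Draw a plausible CallSpec for a class.

    ``position`` in [0, 1] places the call's characteristic frequency
    within the class's usable range; when drawing a community of distinct
    species, stratified positions model the separated acoustic niches
    real species occupy (i.i.d. draws produce unrealistically many
    near-duplicate "species"). ``None`` draws the position uniformly.
    """
    if call_class is None:
        call_class = CALL_CLASSES[rng.integers(len(CALL_CLASSES))]
    u = float(rng.random()) if position is None else float(position)
    dur = float(rng.uniform(0.5, 1.2))
    if call_class == "FM":
        center = 1200 + u * 5300
        span = float(rng.uniform(800, 2400))
        f1 = max(FREQ_MIN, center - span / 2)
        f2 = min(FREQ_MAX, center + span / 2)
        if rng.random() < 0.5:
            f1, f2 = f2, f1
        return CallSpec("FM", duration=dur, f_start=f1, f_end=f2)
    if call_class == "Trill":
        center = 1200 + u * 5300
        span = float(rng.uniform(300, 1500))
        return CallSpec(
            "Trill",
            duration=dur,
            f_start=max(FREQ_MIN, center - span / 2),
            f_end=min(FREQ_MAX, center + span / 2),
            trill_rate=float(rng.uniform(8, 16)),
            element_duration=float(rng.uniform(0.03, 0.07)),
        )
    if call_class == "NB-Trill":
        return CallSpec(
            "NB-Trill",
            duration=dur,
            f0=1000 + u * 6000,
            bandwidth=float(rng.uniform(100, 400)),
            trill_rate=float(rng.uniform(20, 50)),
        )
    if call_class == "HR":
        f0 = FREQ_MIN + u * 1100  # fundamentals 500-1600 Hz
        n_h = int(rng.integers(2, max(3, int(FREQ_MAX // f0)) + 1))
        n_h = min(n_h, int(FREQ_MAX // f0))
        return CallSpec("HR", duration=dur, f0=f0, n_harmonics=max(1, n_h))
    # BB
    bw = float(rng.uniform(500, 2000))
    lo, hi = FREQ_MIN + bw / 2, FREQ_MAX - bw / 2
    return CallSpec(
        "BB", duration=dur, f0=lo + u * (hi - lo), bandwidth=bw, trill_rate=float(rng.uniform(4, 10))
    )


def build_library(spec: LibrarySpec) -> CallLibrary:
    """Build a seeded library with the requested role composition.

    Models, other-species and conspecific calls are independent random
    specs covering all five classes; each mimic is a perturbed copy of one
    model (models are reused cyclically when there are more mimics than
    models). With ``unrelated_mimics`` mimics are instead independent
    random calls — the chance-level control in which every candidate in a
    trial is statistically exchangeable.
    """
    rng = np.random.default_rng(spec.seed)
    clips: list[AudioClip] = []

    def draw(prefix: str, i: int, n_total: int, role: str, species: str) -> AudioClip:
        # classes cycle so all five are covered; within a class, distinct
        # "species" are stratified over the frequency range (niche
        # separation), with jitter inside each stratum
        cls = CALL_CLASSES[i % len(CALL_CLASSES)]
        if spec.unrelated_mimics:
            # chance-level control: every clip i.i.d. so all candidates in
            # a trial are exchangeable and rank-1 sits at 1/10 by symmetry
            position = None
        else:
            stratum = i // len(CALL_CLASSES)
            n_strata = max(1, -(-n_total // len(CALL_CLASSES)))
            position = (stratum + rng.uniform(0.15, 0.85)) / n_strata
        cs = random_call_spec(rng, cls, position=position)
        clip = synthesize_call(cs, seed=int(rng.integers(2**31)))
        clip.id = f"{prefix}{i:03d}"
        clip.role = role
        clip.species = species
        return clip

    models = [draw("mdl", i, spec.n_model, "model", f"model-sp-{i:02d}") for i in range(spec.n_model)]
    clips.extend(models)
    clips.extend(
        draw("oth", i, spec.n_other, "other", f"other-sp-{i:02d}") for i in range(spec.n_other)
    )
    clips.extend(
        draw("con", i, spec.n_conspecific, "conspecific", "mimic-sp")
        for i in range(spec.n_conspecific)
    )

    for i in range(spec.n_mimic):
        if spec.unrelated_mimics:
            # chance-level control: the mimic is an independent random call
            # and its "model" a uniformly random pick, so the model carries
            # no systematic similarity advantage over the other candidates
            m = draw("mim", i, spec.n_mimic, "mimic", "mimic-sp")
            m.model_id = models[int(rng.integers(len(models)))].id
        else:
            m = make_mimic(models[i % len(models)], spec.perturbation, seed=int(rng.integers(2**31)))
            m.id = f"mim{i:03d}"
        clips.append(m)

    return CallLibrary(clips)
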