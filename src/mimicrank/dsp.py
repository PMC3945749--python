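"""Audio I/O, framing and short-time spectral analysis.

Spectrogram parameters follow common bioacoustic practice for 48 kHz field
recordings: Hann window of 256 samples with 50 % overlap (187.5 Hz bins),
while feature extraction uses 25 ms (1200-sample) Hamming frames with a
720-sample hop (480-sample overlap). The DFT length equals the window
length (no zero padding) and trailing partial frames are dropped, so a
signal of length N yields floor((N - window)/hop) + 1 frames.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile

from .synth import AudioClip

#: spectrogram defaults (display/inspection grid)
SPEC_WINDOW = 256
SPEC_HOP = 128

#: feature-analysis defaults: 25 ms / 10 ms overlap at 48 kHz
FEAT_WINDOW = 1200
FEAT_HOP = 720


@dataclass(frozen=True)
class FrameGrid:
    window_length: int
    hop: int
    window_kind: str = "hamming"

    def __post_init__(self) -> None:
        if not 0 < self.hop <= self.window_length:
            raise ValueError("require 0 < hop <= window_length")
        if self.window_kind not in ("hann", "hamming"):
            raise ValueError(f"unknown window kind {self.window_kind!r}")

    def n_frames(self, n_samples: int) -> int:
        if n_samples < self.window_length:
            raise ValueError(
                f"signal of {n_samples} samples is shorter than one "
                f"{self.window_length}-sample window"
            )
        return (n_samples - self.window_length) // self.hop + 1

    def window(self) -> np.ndarray:
        if self.window_kind == "hann":
            return np.hanning(self.window_length)
        return np.hamming(self.window_length)


SPEC_GRID = FrameGrid(SPEC_WINDOW, SPEC_HOP, "hann")
FEAT_GRID = FrameGrid(FEAT_WINDOW, FEAT_HOP, "hamming")


@dataclass
class Spectrogram:
    power: np.ndarray  # (n_frames, n_bins), squared STFT magnitude
    bin_hz: float
    frame_s: float
    grid: FrameGrid


def load_audio(path: str | os.PathLike, **meta) -> AudioClip:
    """Read a mono PCM WAV file into an AudioClip scaled to [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.shape[1]} channels")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV encoding {data.dtype}")
    return AudioClip(samples=samples, rate=int(rate), **meta)


def save_audio(clip: AudioClip, path: str | os.PathLike) -> None:
    """Write a clip as 16-bit PCM mono WAV."""
    x = np.clip(np.round(clip.samples * 32768.0), -32768, 32767)
    wavfile.write(path, clip.rate, x.astype(np.int16))


def frame_signal(clip: AudioClip, grid: FrameGrid = FEAT_GRID) -> np.ndarray:
    """Slice a clip into overlapping windowed frames (n_frames x window)."""
    n = grid.n_frames(len(clip.samples))  # raises on too-short input
    frames = sliding_window_view(clip.samples, grid.window_length)[:: grid.hop][:n]
    return frames * grid.window()


def power_frames(clip: AudioClip, grid: FrameGrid = FEAT_GRID) -> np.ndarray:
    """One-sided short-time power spectrum, (n_frames x (window/2 + 1))."""
    spec = np.fft.rfft(frame_signal(clip, grid), axis=1)
    return np.abs(spec) ** 2


def spectrogram(clip: AudioClip, grid: FrameGrid = SPEC_GRID) -> Spectrogram:
    """Short-time power spectrogram on the display grid (Hann, 256/50 %)."""
    return Spectrogram(
        power=power_frames(clip, grid),
        bin_hz=clip.rate / grid.window_length,
        frame_s=grid.hop / clip.rate,
        grid=grid,
    )


def export_spectrogram_csv(spec: Spectrogram, path: str | os.PathLike) -> None:
    np.savetxt(path, spec.power, delimiter=",")


def write_library(library, directory: str | os.PathLike) -> None:
    """Write every clip as 16-bit PCM WAV plus a manifest.csv."""
    os.makedirs(directory, exist_ok=True)
    manifest = library.manifest()
    for clip in library.clips:
        save_audio(clip, os.path.join(directory, f"{clip.id}.wav"))
    manifest.to_csv(os.path.join(directory, "manifest.csv"), index=False)


def read_library(directory: str | os.PathLike):
    """Load a library written by :func:`write_library` (or a hand-made one)."""
    import pandas as pd

    from .synth import CallLibrary

    manifest = pd.read_csv(os.path.join(directory, "manifest.csv"), keep_default_na=False)
    clips = []
    for row in manifest.itertuples(index=False):
        clip = load_audio(
            os.path.join(directory, row.path),
            id=row.id,
            species=row.species,
            role=row.role,
            call_class=row.call_class,
            model_id=row.model_id or None,
        )
        clips.append(clip)
    return CallLibrary(clips)
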