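"""Mono waveform container and WAV file I/O.

Audio is carried as float64 samples on a linear amplitude scale, paired
with a sampling rate in Hz.  The default rate of 22 050 Hz matches the
16-bit digitisation used for the vowel-consonant-vowel recordings this
toolkit emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

DEFAULT_RATE = 22050.0

__all__ = ["Waveform", "read_wav", "write_wav", "DEFAULT_RATE"]


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal: sample array plus sampling rate in Hz."""

    samples: np.ndarray
    rate: float = DEFAULT_RATE

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional (mono)")
        if samples.size < 1:
            raise ValueError("Waveform must contain at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Waveform samples must be finite")
        if not self.rate > 0:
            raise ValueError(f"Sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.rate

    @property
    def nyquist(self) -> float:
        return self.rate / 2.0

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.rate


def read_wav(path, downmix: bool = False) -> Waveform:
    """Read a RIFF WAV file (PCM 16/32-bit or float) into a :class:`Waveform`.

    Integer PCM is rescaled to [-1, 1) by the type's full scale so that a
    16-bit round trip is exact to within one least-significant bit.

    Parameters
    ----------
    path:
        WAV file path.
    downmix:
        If True, average the channels of a multi-channel file; otherwise a
        multi-channel file raises ``ValueError``.
    """
    rate, data = wavfile.read(path)
    if data.ndim == 2:
        if not downmix:
            raise ValueError(
                f"{path}: file has {data.shape[1]} channels; "
                "pass downmix=True to average them"
            )
        data = data.astype(np.float64).mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(-np.iinfo(data.dtype).min)
        data = data.astype(np.float64) / scale
    else:
        data = np.asarray(data, dtype=np.float64)
    return Waveform(data, float(rate))


def write_wav(path, x: Waveform, bit_depth: int = 16) -> None:
    """Write a :class:`Waveform` as mono RIFF WAV.

    ``bit_depth`` 16 writes PCM16 (samples clipped to [-1, 1]); 32 writes
    IEEE float32.
    """
    if bit_depth == 16:
        clipped = np.clip(x.samples, -1.0, 32767 / 32768)
        data = np.round(clipped * 32768.0).astype(np.int16)
    elif bit_depth == 32:
        data = x.samples.astype(np.float32)
    else:
        raise ValueError(f"Unsupported bit depth: {bit_depth} (use 16 or 32)")
    wavfile.write(path, int(round(x.rate)), data)
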