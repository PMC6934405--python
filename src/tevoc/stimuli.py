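"""Psychophysical stimulus synthesis.

Ramped pure tones, sinusoidally amplitude-modulated (AM) tones with
modulation-power compensation, and the 800-Hz frequency-discrimination
tone pairs.

An AM tone is the product of a carrier with a DC-shifted modulator,

    s(t) = A * [1 + m * sin(2*pi*fm*t + phi)] * sin(2*pi*fc*t),

where ``m`` is the modulation depth.  Modulation raises the signal power
by the factor ``1 + m**2/2``; dividing the amplitude by
``sqrt(1 + m**2/2)`` equates the long-term RMS of modulated and
unmodulated intervals so that listeners (or simulated observers) cannot
use overall intensity as a cue.  Levels are expressed relative to digital
full scale (dBFS); the nominal presentation level of 70 dB SPL is a
playback-calibration constant with no digital meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .waveform import Waveform, DEFAULT_RATE

__all__ = [
    "ToneSpec",
    "AMToneSpec",
    "make_tone",
    "make_am_tone",
    "compensation_factor",
    "fd_pair",
]


@dataclass(frozen=True)
class ToneSpec:
    """A ramped pure tone; durations in ms, level in dBFS (0 = full-scale peak)."""

    freq: float
    duration: float = 100.0
    ramp: float = 10.0
    level: float = -20.0

    def __post_init__(self) -> None:
        if self.freq <= 0:
            raise ValueError("freq must be positive")
        if self.duration <= 0 or self.ramp < 0:
            raise ValueError("duration must be positive and ramp non-negative")
        if 2 * self.ramp > self.duration:
            raise ValueError("ramps cannot exceed half the duration each")


@dataclass(frozen=True)
class AMToneSpec:
    """A sinusoidally amplitude-modulated tone.

    ``start_phase`` is the modulator phase in radians; draw it per interval
    from a seeded RNG to randomise modulation phase interval by interval.
    ``compensate`` divides the amplitude by ``sqrt(1 + m**2/2)`` to cancel
    the modulation power increase.
    """

    carrier: float = 1000.0
    fm: float = 8.0
    m: float = 1.0
    duration: float = 500.0
    ramp: float = 10.0
    level: float = -20.0
    start_phase: float = 0.0
    compensate: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"modulation depth must be in [0, 1], got {self.m}")
        if self.fm >= self.carrier:
            raise ValueError("modulation rate must be below the carrier frequency")
        if self.duration <= 0 or self.ramp < 0 or 2 * self.ramp > self.duration:
            raise ValueError("invalid duration/ramp combination")


def _ramp_window(n: int, n_ramp: int) -> np.ndarray:
    """Raised-cosine onset/offset window of total length n."""
    win = np.ones(n)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        win[:n_ramp] = ramp
        win[-n_ramp:] = ramp[::-1]
    return win


def make_tone(spec: ToneSpec, rate: float = DEFAULT_RATE) -> Waveform:
    """Synthesise a ramped pure tone.

    Length is ``round(duration * rate)`` samples; raised-cosine on/off
    ramps of the stated length are applied; the steady-state peak
    amplitude is ``10**(level/20)``.
    """
    if spec.freq >= rate / 2:
        raise ValueError(f"tone frequency {spec.freq} Hz >= Nyquist {rate / 2} Hz")
    n = int(round(spec.duration / 1000.0 * rate))
    t = np.arange(n) / rate
    amp = 10.0 ** (spec.level / 20.0)
    x = amp * np.sin(2.0 * np.pi * spec.freq * t)
    n_ramp = int(round(spec.ramp / 1000.0 * rate))
    return Waveform(x * _ramp_window(n, n_ramp), rate)


def compensation_factor(m: float) -> float:
    """Amplitude divisor ``sqrt(1 + m**2/2)`` equating AM and carrier power."""
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"modulation depth must be in [0, 1], got {m}")
    return float(np.sqrt(1.0 + m**2 / 2.0))


def make_am_tone(spec: AMToneSpec, rate: float = DEFAULT_RATE) -> Waveform:
    """Synthesise a sinusoidally AM tone, optionally power-compensated.

    With compensation on, the steady-state RMS over whole modulation
    cycles equals that of the unmodulated carrier at the same level.
    Ramps are applied after compensation, so the equated RMS refers to the
    steady state.
    """
    if spec.carrier >= rate / 2:
        raise ValueError(f"carrier {spec.carrier} Hz >= Nyquist {rate / 2} Hz")
    n = int(round(spec.duration / 1000.0 * rate))
    t = np.arange(n) / rate
    amp = 10.0 ** (spec.level / 20.0)
    modulator = 1.0 + spec.m * np.sin(2.0 * np.pi * spec.fm * t + spec.start_phase)
    x = amp * modulator * np.sin(2.0 * np.pi * spec.carrier * t)
    if spec.compensate:
        x = x / compensation_factor(spec.m)
    n_ramp = int(round(spec.ramp / 1000.0 * rate))
    return Waveform(x * _ramp_window(n, n_ramp), rate)


def fd_pair(base: float = 800.0, delta_pct: float = 0.0,
            duration: float = 100.0, ramp: float = 10.0,
            level: float = -20.0) -> tuple[ToneSpec, ToneSpec]:
    """Standard/target tone pair for frequency discrimination.

    The standard is *base* Hz; the target is ``base * (1 + delta_pct/100)``
    Hz.  ``delta_pct = 0`` yields identical tones (an "impossible" trial).
    """
    if delta_pct < 0:
        raise ValueError("delta_pct must be non-negative")
    std = ToneSpec(freq=base, duration=duration, ramp=ramp, level=level)
    tgt = ToneSpec(freq=base * (1.0 + delta_pct / 100.0), duration=duration,
                   ramp=ramp, level=level)
    return std, tgt
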