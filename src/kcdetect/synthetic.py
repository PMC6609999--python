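"""Seeded generator of EEG-like recordings with annotated k-complexes.

The background emulates stage-2 sleep EEG: 1/f-type noise (spectral
exponent 1.5, between pink and brown, matching the steep low-frequency
slope of sleep EEG) plus occasional amplitude-modulated bursts in the
sleep-spindle band (12-14 Hz). K-complex transients — a single negative
sharp wave followed by a positive sharp wave, peak-to-peak at least the
configured amplitude (> 75 µV by definition; around 100 µV typical),
duration 0.5-1.5 s — are injected at non-overlapping random onsets, and the
returned annotations are exactly the injected events. Everything is driven
by one integer seed, so a recording is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .io import EventAnnotation, Signal

__all__ = ["GeneratorConfig", "kcomplex_template", "pink_noise", "generate_recording"]

_SPECTRAL_EXPONENT = 1.5  # power ~ 1/f^beta; sleep EEG is steeper than pink


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic recording.

    Defaults give the standard benchmark: 120 s at 200 Hz with 20
    k-complexes of 100 µV peak-to-peak over a 10 µV background with 3
    spindle bursts per minute.
    """

    duration: float = 120.0  # s
    fs: float = 200.0  # Hz
    n_events: int = 20
    amplitude: float = 100.0  # µV peak-to-peak, must exceed 75
    event_duration_range: tuple[float, float] = (0.5, 1.5)  # s
    background_sd: float = 10.0  # µV
    spindle_rate: float = 3.0  # bursts per minute
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.amplitude <= 75:
            raise ValueError("k-complex amplitude must exceed 75 µV")
        lo, hi = self.event_duration_range
        if not (0.5 <= lo <= hi <= 1.5):
            raise ValueError("event durations must lie within [0.5, 1.5] s")
        if self.n_events * hi >= self.duration:
            raise ValueError("events cannot fit in the recording without overlap")


def kcomplex_template(fs: float, duration: float, amplitude: float) -> np.ndarray:
    """Biphasic k-complex waveform: negative lobe then positive lobe.

    Built as the sum of two opposed raised-cosine (Hann) lobes, each
    spanning 55% of the event and overlapping in the middle; the global
    minimum precedes the global maximum, the peak-to-peak span is at least
    `amplitude`, and both ends taper exactly to zero.
    """
    if not 0.5 <= duration <= 1.5:
        raise ValueError(f"k-complex duration must be in [0.5, 1.5] s, got {duration}")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    n = int(round(duration * fs))
    wave = np.zeros(n)
    lobe_len = int(round(0.55 * n))
    # negative lobe over the first 55%, positive over the last 55%
    wave[:lobe_len] -= 0.60 * amplitude * hann(lobe_len)
    wave[n - lobe_len :] += 0.55 * amplitude * hann(lobe_len)
    wave[0] = wave[-1] = 0.0
    ptp = wave.max() - wave.min()
    if ptp < amplitude:  # overlap cancellation at short durations
        wave *= amplitude / ptp
    return wave


def pink_noise(n: int, rng: np.random.Generator, exponent: float = _SPECTRAL_EXPONENT) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via seeded spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)  # amplitude shaping; power ~ f^-exponent
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()


def _spindle_bursts(
    n: int, fs: float, rate_per_min: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Amplitude-modulated 12-14 Hz bursts, ~1 s long, at the given rate."""
    out = np.zeros(n)
    n_bursts = int(round(rate_per_min * (n / fs) / 60.0))
    for _ in range(n_bursts):
        b_dur = rng.uniform(0.7, 1.3)
        b_len = int(round(b_dur * fs))
        if b_len >= n:
            continue
        start = rng.integers(0, n - b_len)
        freq = rng.uniform(12.0, 14.0)
        t = np.arange(b_len) / fs
        phase = rng.uniform(0, 2 * np.pi)
        out[start : start + b_len] += (
            0.8 * sd * hann(b_len) * np.sin(2 * np.pi * freq * t + phase)
        )
    return out


def generate_recording(cfg: GeneratorConfig) -> tuple[Signal, list[EventAnnotation]]:
    """Synthesize one annotated recording.

    Returns the signal (µV) and the injected events, sorted and pairwise
    disjoint. Raises if the requested number of events cannot be placed
    without overlap after bounded retries.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    background = cfg.background_sd * pink_noise(n, rng)
    background += _spindle_bursts(n, cfg.fs, cfg.spindle_rate, cfg.background_sd, rng)

    events: list[EventAnnotation] = []
    placed: list[tuple[float, float]] = []
    tries = 0
    while len(events) < cfg.n_events:
        tries += 1
        if tries > 1000 * max(cfg.n_events, 1):
            raise RuntimeError(
                f"could not place {cfg.n_events} non-overlapping events in "
                f"{cfg.duration} s"
            )
        dur = rng.uniform(*cfg.event_duration_range)
        onset = rng.uniform(0.0, cfg.duration - dur)
        if any(onset < e + 0.2 and o < onset + dur + 0.2 for o, e in placed):
            continue  # keep 0.2 s clearance between events
        placed.append((onset, onset + dur))
        events.append(EventAnnotation(onset=onset, duration=dur))
        start = int(round(onset * cfg.fs))
        template = kcomplex_template(cfg.fs, dur, cfg.amplitude)
        background[start : start + len(template)] += template[: n - start]

    signal = Signal(samples=background, fs=cfg.fs, channel="synthetic")
    return signal, sorted(events)
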