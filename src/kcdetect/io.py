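"""Reading and writing EEG signals and event annotations.

Supports European Data Format (EDF) recordings (via :mod:`mne`), a trivial
plain-text one-sample-per-line signal format for fixtures, two-column
whitespace-separated annotation files (onset and duration in seconds, the
dialect used by the public DREAMS k-complex scorings), and JSON event output.

All times are seconds (float); sample indices are 0-based; annotation
intervals are half-open ``[onset, onset + duration)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Signal",
    "EventAnnotation",
    "read_signal",
    "write_signal",
    "read_annotations",
    "write_annotations",
    "events_to_json",
    "events_from_json",
]


@dataclass(frozen=True)
class Signal:
    """A single-channel EEG trace.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz. Must be positive.
    channel : str
        Channel label, e.g. ``"CZ-A1"``.
    start_time : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    channel: str = "EEG"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Signal length in seconds."""
        return len(self.samples) / self.fs

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True, order=True)
class EventAnnotation:
    """A scored event: half-open interval [onset, onset + duration) in seconds."""

    onset: float
    duration: float
    label: str = field(default="kcomplex", compare=False)

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")

    @property
    def end(self) -> float:
        return self.onset + self.duration

    def contains(self, t: float) -> bool:
        return self.onset <= t < self.end


def read_signal(
    path: str | Path,
    format: str | None = None,
    channel: str | None = None,
    fs_hint: float | None = None,
) -> Signal:
    """Read a single-channel EEG signal from an EDF or plain-text file.

    Parameters
    ----------
    path : path
        Input file. Format inferred from the extension (``.edf`` vs other)
        unless `format` is given.
    format : {"edf", "text"}, optional
        Force a reader.
    channel : str, optional
        Channel label to extract. Required for multi-channel EDF files;
        ignored for text files.
    fs_hint : float, optional
        Sampling rate in Hz. Required for text files without an ``fs=`` header.

    Returns
    -------
    Signal
        Amplitudes in microvolts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "text"
    if format == "edf":
        return _read_edf(path, channel)
    if format == "text":
        return _read_text(path, fs_hint, channel)
    raise ValueError(f"unknown signal format: {format!r}")


def _read_edf(path: Path, channel: str | None) -> Signal:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = raw.ch_names
    if channel is None:
        if len(names) != 1:
            raise ValueError(
                f"EDF file has {len(names)} channels {names}; specify one"
            )
        channel = names[0]
    if channel not in names:
        raise KeyError(f"channel {channel!r} not found; available: {names}")
    data = raw.get_data(picks=[channel])[0]
    # mne returns volts for EEG channels; the pipeline works in microvolts
    return Signal(samples=data * 1e6, fs=float(raw.info["sfreq"]), channel=channel)


def _read_text(path: Path, fs_hint: float | None, channel: str | None) -> Signal:
    fs = fs_hint
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("fs="):
                fs = float(line[3:])
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric sample {line!r}"
                ) from exc
    if fs is None:
        raise ValueError("text signal requires fs_hint or an 'fs=<Hz>' header")
    return Signal(
        samples=np.array(values, dtype=float),
        fs=float(fs),
        channel=channel or "EEG",
    )


def write_signal(path: str | Path, signal: Signal) -> None:
    """Write a signal as text: an ``fs=`` header then one sample per line."""
    with open(path, "w") as fh:
        fh.write(f"fs={signal.fs:g}\n")
        for v in signal.samples:
            fh.write(f"{v:.6f}\n")


def read_annotations(path: str | Path) -> list[EventAnnotation]:
    """Read two-column (onset, duration; seconds) event annotations.

    Returns events sorted by onset. Blank lines and ``#`` comments skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    events: list[EventAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'onset duration'")
            try:
                onset, duration = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
            label = parts[2] if len(parts) > 2 else "kcomplex"
            events.append(EventAnnotation(onset=onset, duration=duration, label=label))
    return sorted(events)


def write_annotations(path: str | Path, events: list[EventAnnotation]) -> None:
    """Write events as two-column text (onset, duration in seconds)."""
    with open(path, "w") as fh:
        for ev in sorted(events):
            fh.write(f"{ev.onset:.3f} {ev.duration:.3f}\n")


def events_to_json(events: list[EventAnnotation]) -> str:
    """Serialize events to a JSON array of {onset, duration, label} objects."""
    return json.dumps(
        [
            {"onset": round(ev.onset, 6), "duration": round(ev.duration, 6), "label": ev.label}
            for ev in sorted(events)
        ],
        indent=2,
    )


def events_from_json(text: str) -> list[EventAnnotation]:
    return sorted(
        EventAnnotation(onset=o["onset"], duration=o["duration"], label=o.get("label", "kcomplex"))
        for o in json.loads(text)
    )
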