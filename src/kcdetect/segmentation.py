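"""Sliding-window segmentation of EEG signals and binary event labelling.

The detector slices the trace into fixed-length windows of 0.5 s with an
overlap of 0.4 s (step 0.1 s), so a single k-complex spans several windows.
A window is labelled positive when its centre time falls inside an annotated
event interval (half-open convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EventAnnotation, Signal

__all__ = ["Segment", "sliding_windows", "label_segments"]


@dataclass(frozen=True)
class Segment:
    """One analysis window of a signal."""

    samples: np.ndarray  # µV
    start: float  # seconds
    index: int  # ordinal position in the sweep

    def __len__(self) -> int:
        return len(self.samples)


def sliding_windows(
    signal: Signal, window_s: float = 0.5, overlap_s: float = 0.4
) -> list[Segment]:
    """Slice a signal into overlapping fixed-length windows.

    Windows start at 0, step, 2·step, ... (step = window − overlap) and only
    full windows are kept; a trailing partial window is dropped.

    Parameters
    ----------
    signal : Signal
    window_s : float
        Window length in seconds (default 0.5).
    overlap_s : float
        Overlap between consecutive windows in seconds (default 0.4).

    Returns
    -------
    list of Segment
        ``floor((duration − window) / step) + 1`` segments, or none when the
        signal is shorter than one window.
    """
    if not window_s > 0:
        raise ValueError(f"window_s must be positive, got {window_s}")
    if not 0 <= overlap_s < window_s:
        raise ValueError(
            f"overlap_s must satisfy 0 <= overlap < window, got {overlap_s}"
        )
    win = int(round(window_s * signal.fs))
    if win < 2:
        raise ValueError("window must span at least 2 samples")
    step = int(round((window_s - overlap_s) * signal.fs))
    if step < 1:
        raise ValueError("window/overlap resolve to a zero-sample step")

    segments: list[Segment] = []
    n = len(signal.samples)
    index = 0
    start = 0
    while start + win <= n:
        segments.append(
            Segment(
                samples=signal.samples[start : start + win],
                start=start / signal.fs,
                index=index,
            )
        )
        index += 1
        start += step
    return segments


def label_segments(
    segments: list[Segment],
    events: list[EventAnnotation],
    window_s: float = 0.5,
) -> np.ndarray:
    """Assign a 0/1 label per segment: 1 iff its centre lies in some event.

    The centre rule is parameter-free and symmetric; event intervals are
    half-open, so a centre exactly at an event's end is negative.
    """
    labels = np.zeros(len(segments), dtype=int)
    if not events:
        return labels
    onsets = np.array([ev.onset for ev in events])
    ends = np.array([ev.end for ev in events])
    for i, seg in enumerate(segments):
        center = seg.start + window_s / 2.0
        if np.any((onsets <= center) & (center < ends)):
            labels[i] = 1
    return labels
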