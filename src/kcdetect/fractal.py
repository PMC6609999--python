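"""Box-counting fractal dimension of binary time-frequency images.

The box-counting dimension of a set is estimated from how the number N(r) of
occupied r×r grid boxes scales with the box size r:

    Dim = lim_{r -> 0}  log N(r) / log(1/r)

For an L×L image (L = 2^m) the boxes are grid-aligned at the image origin and
r runs over the powers of two 1, 2, ..., L. Two readings of the limit are
used as features:

* the **per-scale** dimension log10 N(r) / log10 (L/r) at each of the 10
  scales r = 1 ... L/2 (r = L is excluded: its denominator is zero), giving a
  10-element feature vector per image, each element in [0, 2];
* the **slope** dimension: the negated least-squares slope of log10 N(r)
  against log10 r over all scales with a positive count.

Base-10 logarithms are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tf_image import BinaryImage

__all__ = [
    "BoxCountSeries",
    "FDVector",
    "box_count",
    "box_count_series",
    "loglog_points",
    "fd_vector",
    "fd_slope",
]


@dataclass(frozen=True)
class BoxCountSeries:
    """Occupied-box counts N(r) over a ladder of box sizes r (powers of two)."""

    scales: np.ndarray  # box sizes r, pixels
    counts: np.ndarray  # N(r)

    def __post_init__(self) -> None:
        scales = np.asarray(self.scales, dtype=int)
        counts = np.asarray(self.counts, dtype=int)
        if scales.shape != counts.shape:
            raise ValueError("scales and counts must align")
        if np.any(np.diff(counts) > 0):
            raise ValueError("N(r) must be non-increasing in r")
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class FDVector:
    """Per-scale fractal dimensions plus the least-squares slope dimension."""

    per_scale: np.ndarray  # 10 values in [0, 2]
    slope_fd: float
    scales_used: np.ndarray


def box_count(image: BinaryImage | np.ndarray, r: int) -> int:
    """Count r×r grid boxes containing at least one foreground pixel.

    Boxes are anchored at the image origin; `r` must divide the side length.
    """
    pixels = image.pixels if isinstance(image, BinaryImage) else np.asarray(image, dtype=bool)
    L = pixels.shape[0]
    if pixels.shape != (L, L):
        raise ValueError("image must be square")
    if r < 1 or L % r != 0:
        raise ValueError(f"box size {r} does not divide image side {L}")
    blocks = pixels.reshape(L // r, r, L // r, r)
    return int(blocks.any(axis=(1, 3)).sum())


def box_count_series(image: BinaryImage | np.ndarray) -> BoxCountSeries:
    """N(r) for every power-of-two box size r = 1, 2, ..., L."""
    pixels = image.pixels if isinstance(image, BinaryImage) else np.asarray(image, dtype=bool)
    L = pixels.shape[0]
    scales = 2 ** np.arange(int(np.log2(L)) + 1)
    counts = [box_count(pixels, int(r)) for r in scales]
    return BoxCountSeries(scales=scales, counts=np.array(counts))


def loglog_points(series: BoxCountSeries) -> tuple[np.ndarray, np.ndarray]:
    """(log10 r, log10 N(r)) regression points at scales with N(r) > 0."""
    mask = series.counts > 0
    return np.log10(series.scales[mask]), np.log10(series.counts[mask])


def fd_vector(series: BoxCountSeries, L: int) -> FDVector:
    """Per-scale fractal dimensions for the 10 non-degenerate scales.

    per_scale[i] = log10 N(r_i) / log10 (L / r_i) for r_i < L, clipped to
    [0, 2] (the grid bound N(r) <= (L/r)^2 already forces the upper limit).
    An empty image yields the all-zero vector.
    """
    mask = series.scales < L
    scales = series.scales[mask]
    counts = series.counts[mask]
    if len(scales) == 0:
        raise ValueError("no usable scales below the image side")
    per_scale = np.zeros(len(scales))
    nonzero = counts > 0
    per_scale[nonzero] = np.log10(counts[nonzero]) / np.log10(L / scales[nonzero])
    per_scale = np.clip(per_scale, 0.0, 2.0)
    slope = fd_slope(series) if int(np.count_nonzero(series.counts > 0)) >= 2 else 0.0
    return FDVector(per_scale=per_scale, slope_fd=slope, scales_used=scales)


def fd_slope(series: BoxCountSeries) -> float:
    """Negated least-squares slope of log10 N(r) vs log10 r.

    Equals the slope against log10(1/r); 2.0 for an exact plane-filling
    power law N(r) = (L/r)^2.
    """
    logr, logn = loglog_points(series)
    if len(logr) < 2:
        raise ValueError("need at least 2 scales with positive counts")
    slope, _ = np.polyfit(logr, logn, 1)
    return float(-slope)
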