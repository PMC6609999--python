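"""Time-frequency images: STFT spectrograms rendered as binary images.

Each EEG segment is transformed with a short-time Fourier transform; the
squared magnitude of the STFT coefficients is the spectrogram power

    SP(n, k) = |S(n, k)|^2

which is then displayed on a peak-relative decibel scale with a fixed noise
floor, min-max normalised, bilinearly resampled to a square L×L grid (L a
power of two so grid-aligned box counting divides evenly) and binarised
with Otsu's threshold. The amplitude gain of the input cancels in the
peak-relative scaling, so the binary image depends only on the segment's
time-frequency *shape*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .segmentation import Segment

__all__ = ["STFTParams", "TFImage", "BinaryImage", "spectrogram", "render_binary_image"]


@dataclass(frozen=True)
class STFTParams:
    """STFT taper/hop/FFT configuration.

    Defaults suit 0.5 s segments at 200 Hz (100 samples): a 64-sample
    (0.32 s) Hann taper sliding one sample at a time, zero-padded to 256 FFT
    bins. The taper length sets the spectral mainlobe width (~3 Hz here),
    which must be narrow enough to resolve structure within the delta band
    where the k-complex lives.
    """

    win_len: int = 64
    hop: int = 1
    nfft: int = 256
    window_fn: str = "hann"

    def __post_init__(self) -> None:
        if not 0 < self.hop <= self.win_len <= self.nfft:
            raise ValueError(
                f"need 0 < hop <= win_len <= nfft, got "
                f"hop={self.hop}, win_len={self.win_len}, nfft={self.nfft}"
            )


@dataclass(frozen=True)
class TFImage:
    """Spectrogram power matrix (frequency × time) with its axes."""

    power: np.ndarray  # nonnegative, shape (n_freqs, n_times)
    freqs: np.ndarray  # Hz
    times: np.ndarray  # s

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.freqs), len(self.times)):
            raise ValueError("power shape must match frequency/time axes")
        if np.any(self.power < 0):
            raise ValueError("spectrogram power must be nonnegative")


@dataclass(frozen=True)
class BinaryImage:
    """Square black/white image; side length is a power of two."""

    pixels: np.ndarray  # bool, shape (side, side)

    def __post_init__(self) -> None:
        side = self.pixels.shape[0]
        if self.pixels.ndim != 2 or self.pixels.shape[1] != side:
            raise ValueError("binary image must be square")
        if side & (side - 1) != 0 or side == 0:
            raise ValueError(f"side must be a power of two, got {side}")
        object.__setattr__(self, "pixels", self.pixels.astype(bool))

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def spectrogram(
    segment: Segment | np.ndarray, fs: float, params: STFTParams = STFTParams()
) -> TFImage:
    """Compute the squared-magnitude STFT spectrogram of one segment.

    Parameters
    ----------
    segment : Segment or ndarray
        Samples in µV; must be at least ``params.win_len`` long.
    fs : float
        Sampling rate in Hz.
    params : STFTParams

    Returns
    -------
    TFImage
        Power on a one-sided frequency axis spanning [0, fs/2].
    """
    x = np.asarray(segment.samples if isinstance(segment, Segment) else segment, dtype=float)
    if len(x) < params.win_len:
        raise ValueError(
            f"segment length {len(x)} shorter than STFT window {params.win_len}"
        )
    freqs, times, mag = sps.spectrogram(
        x,
        fs=fs,
        window=sps.get_window(params.window_fn, params.win_len),
        nperseg=params.win_len,
        noverlap=params.win_len - params.hop,
        nfft=params.nfft,
        detrend=False,
        mode="magnitude",
        scaling="spectrum",
    )
    return TFImage(power=mag**2, freqs=freqs, times=times)


def render_binary_image(
    tfi: TFImage,
    side: int = 1024,
    floor_db: float = -40.0,
    freq_max: float | None = None,
) -> BinaryImage:
    """Render a spectrogram as a binary L×L image for box counting.

    Pipeline: optionally restrict the display band to ``[0, freq_max]`` Hz,
    convert to decibels relative to the frame's peak power with a noise
    floor at `floor_db` (the conventional spectrogram display scale; being
    peak-relative it is exactly invariant to the segment's amplitude gain),
    min-max normalise to [0, 1], bilinearly resample to ``side × side``, and
    binarise with Otsu's threshold. Constant images (e.g. all-zero power)
    map to all-background.
    """
    power = tfi.power
    if freq_max is not None:
        keep = tfi.freqs <= freq_max
        if not keep.any():
            raise ValueError(f"no frequency bins at or below {freq_max} Hz")
        power = power[keep]
    pmax = power.max()
    if pmax == 0:
        return BinaryImage(pixels=np.zeros((side, side), dtype=bool))
    db = 10.0 * np.log10(np.maximum(power / pmax, 10.0 ** (floor_db / 10.0)))
    lo, hi = db.min(), db.max()
    if hi == lo:
        return BinaryImage(pixels=np.zeros((side, side), dtype=bool))
    norm = (db - lo) / (hi - lo)
    img = resize(norm, (side, side), order=1, anti_aliasing=False, mode="edge")
    if img.max() == img.min():
        return BinaryImage(pixels=np.zeros((side, side), dtype=bool))
    thr = threshold_otsu(img)
    return BinaryImage(pixels=img > thr)
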