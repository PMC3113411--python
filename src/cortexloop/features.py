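"""Autoregressive band-power features and pseudo-Z normalization.

Each frame, the trailing window (0.5 s by default) of every channel is fit
with an AR model (Burg's method, order 15 by default); the model's spectral
density is evaluated on a fine grid and integrated over contiguous bins
(10 Hz wide up to 200 Hz by default), giving one channels x bands power
matrix per frame.

Powers are standardized to pseudo-Z-scores against mean and standard
deviation accumulated during a no-task baseline period:

    f_norm[i, j] = (f[i, j] - mean[i, j]) / sd[i, j]

The Burg recursion here is vectorised over channels (one pass fits all
channels of a window simultaneously), which is what keeps per-frame feature
extraction cheap enough to run every frame at the 33.3 ms frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FeatureMatrix, SignalBlock

__all__ = [
    "ArSpec",
    "burg_batch",
    "ar_spectrum",
    "ar_band_power",
    "FeatureExtractor",
    "BaselineStats",
    "normalize",
    "denormalize",
    "DegenerateFeatureError",
]


@dataclass(frozen=True)
class ArSpec:
    """AR spectral-estimation settings.

    order: AR model order; window_s: analysis window length in seconds;
    bin_width / f_max: the band grid in Hz ([0, bin) ... [f_max-bin, f_max)).
    f_max defaults to 200 Hz — everything the decoders use lies at or below
    120 Hz, so evaluating further up the spectrum would only cost time.
    """

    order: int = 15
    bin_width: float = 10.0
    window_s: float = 0.5
    f_max: float = 200.0
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("AR order must be >= 1")
        n_bands = self.f_max / self.bin_width
        if abs(n_bands - round(n_bands)) > 1e-9:
            raise ValueError("bin_width must divide f_max")
        if self.grid_step <= 0 or self.bin_width / self.grid_step < 2:
            raise ValueError("grid_step must resolve each bin with >= 2 points")

    @property
    def n_bands(self) -> int:
        return int(round(self.f_max / self.bin_width))

    @property
    def band_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.f_max, self.n_bands + 1)

    def window_samples(self, sample_rate: float) -> int:
        n = int(round(self.window_s * sample_rate))
        if n < 2 * self.order:
            raise ValueError("window too short for AR order (need >= 2*order samples)")
        return n


def burg_batch(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Burg AR fit of every row of ``x`` at once.

    Returns ``(a, sigma2)`` where ``a`` is (n_series, order+1) with a[:, 0] = 1
    in the prediction-error-filter convention A(z)x = e, and ``sigma2`` the
    driving-noise variance per series.  Constant rows (zero signal energy)
    are degenerate and rejected.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    n_series, n = x.shape
    if n < 2 * order:
        raise ValueError(f"window of {n} samples too short for AR order {order}")
    f = x.copy()
    b = x.copy()
    a = np.zeros((n_series, order + 1))
    a[:, 0] = 1.0
    energy = np.sum(x * x, axis=1) / n
    if np.any(energy <= 0):
        raise DegenerateFeatureError("constant (zero-energy) window; AR fit undefined")
    for m in range(1, order + 1):
        fm = f[:, 1:]  # forward error, one lag trimmed per stage
        bm = b[:, :-1]  # backward error
        den = np.sum(fm * fm, axis=1) + np.sum(bm * bm, axis=1)
        if np.any(den <= 0):
            raise DegenerateFeatureError("degenerate window during Burg recursion")
        k = -2.0 * np.sum(fm * bm, axis=1) / den
        a[:, 1 : m + 1] += k[:, None] * a[:, m - 1 :: -1].copy()
        f = fm + k[:, None] * bm
        b = bm + k[:, None] * fm
        energy = energy * (1.0 - k * k)
    return a, energy


def ar_spectrum(
    a: np.ndarray, sigma2: np.ndarray, sample_rate: float, freqs: np.ndarray
) -> np.ndarray:
    """One-sided AR power spectral density at ``freqs`` for each fitted series."""
    order = a.shape[1] - 1
    phase = np.exp(
        -2j * np.pi * np.outer(np.arange(order + 1), freqs) / sample_rate
    )  # (order+1, n_freqs)
    denom = np.abs(a @ phase) ** 2
    return 2.0 * sigma2[:, None] / sample_rate / denom


def ar_band_power(
    window: np.ndarray, sample_rate: float, spec: ArSpec = ArSpec()
) -> np.ndarray:
    """Band-integrated AR power of each channel of a window.

    ``window`` is (n_samples,) or (n_channels, n_samples) covering exactly the
    analysis window; returns (n_channels, n_bands) non-negative powers
    (trapezoid-integrated density over each bin).
    """
    window = np.atleast_2d(np.asarray(window, dtype=np.float64))
    expected = spec.window_samples(sample_rate)
    if window.shape[1] != expected:
        raise ValueError(f"window must hold {expected} samples, got {window.shape[1]}")
    a, sigma2 = burg_batch(window, spec.order)
    pts_per_bin = int(round(spec.bin_width / spec.grid_step))
    grid = np.linspace(0.0, spec.f_max, spec.n_bands * pts_per_bin + 1)
    psd = ar_spectrum(a, sigma2, sample_rate, grid)  # (C, G)
    power = np.empty((window.shape[0], spec.n_bands))
    for j in range(spec.n_bands):
        sl = slice(j * pts_per_bin, j * pts_per_bin + pts_per_bin + 1)
        power[:, j] = np.trapezoid(psd[:, sl], grid[sl], axis=1)
    return power


class FeatureExtractor:
    """Per-frame sliding-window feature extraction with a trailing sample buffer.

    The window advances one frame per frame (default 33.3 ms hop over a 500 ms
    window, ~93% overlap).  Until the buffer holds a full window the extractor
    is warming up and returns ``None`` — a flagged outcome, not an error.
    """

    def __init__(self, spec: ArSpec, sample_rate: float, n_channels: int):
        self.spec = spec
        self.sample_rate = float(sample_rate)
        self.n_channels = int(n_channels)
        self._win = spec.window_samples(sample_rate)
        self._buf = np.zeros((n_channels, 0))

    @property
    def warmed_up(self) -> bool:
        return self._buf.shape[1] >= self._win

    def push(self, block: SignalBlock) -> FeatureMatrix | None:
        if block.n_channels != self.n_channels:
            raise ValueError("channel count changed mid-stream")
        joined = np.concatenate([self._buf, block.data], axis=1)
        self._buf = joined[:, -self._win :]
        if joined.shape[1] < self._win:
            return None  # warm-up
        power = ar_band_power(self._buf, self.sample_rate, self.spec)
        return FeatureMatrix(power, self.spec.band_edges, self.spec.window_s, block.index)

    def state_checksum(self) -> float:
        """Cheap fingerprint of buffered samples (used by swap/suspend tests)."""
        return float(np.sum(self._buf))


class DegenerateFeatureError(ValueError):
    """A feature's variability is zero (or a window is constant), so the
    requested operation is undefined for it."""


class BaselineStats:
    """Streaming per-feature mean and standard deviation (Welford update).

    Accumulated over the baseline condition (no high-gamma modulation);
    sample standard deviation (n-1 denominator).
    """

    def __init__(self, n_channels: int, n_bands: int):
        self.n_frames = 0
        self._mean = np.zeros((n_channels, n_bands))
        self._m2 = np.zeros((n_channels, n_bands))

    @property
    def shape(self) -> tuple[int, int]:
        return self._mean.shape

    @property
    def mean(self) -> np.ndarray:
        return self._mean.copy()

    @property
    def sd(self) -> np.ndarray:
        if self.n_frames < 2:
            return np.zeros_like(self._mean)
        return np.sqrt(self._m2 / (self.n_frames - 1))

    def update(self, fm: FeatureMatrix) -> None:
        if fm.power.shape != self._mean.shape:
            raise ValueError(
                f"feature shape {fm.power.shape} does not match baseline {self._mean.shape}"
            )
        self.n_frames += 1
        delta = fm.power - self._mean
        self._mean += delta / self.n_frames
        self._m2 += delta * (fm.power - self._mean)


def normalize(fm: FeatureMatrix, stats: BaselineStats) -> FeatureMatrix:
    """Pseudo-Z-score a feature matrix against baseline statistics."""
    if stats.n_frames < 2:
        raise ValueError("baseline needs at least 2 frames before normalization")
    sd = stats.sd
    bad = np.argwhere(sd == 0)
    if bad.size:
        i, j = bad[0]
        raise DegenerateFeatureError(
            f"baseline sd is zero for feature (channel={i}, band={j})"
        )
    z = (fm.power - stats.mean) / sd
    return FeatureMatrix(z, fm.band_edges, fm.window_s, fm.index)


def denormalize(fm: FeatureMatrix, stats: BaselineStats) -> FeatureMatrix:
    """Inverse of :func:`normalize` given the same statistics."""
    raw = fm.power * stats.sd + stats.mean
    return FeatureMatrix(raw, fm.band_edges, fm.window_s, fm.index)
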