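"""Sensor-level preprocessing: marker excision, epoching, resampling, filtering.

Interval arithmetic is half-open and 0-based in samples throughout.  The
cleaning path mirrors a standard resting-state workflow: excise data
within a guard window around marked events, tile the remaining clean
segments into fixed-length epochs, randomly select a fixed number of
non-overlapping epochs, resample and band-pass filter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .geometry import SensorArray

__all__ = [
    "EpochedRecording",
    "MarkerList",
    "exclude_marked_intervals",
    "segment_epochs",
    "downsample",
    "bandpass",
    "reject_epochs_by_amplitude",
]


@dataclass
class EpochedRecording:
    """Fixed-length sensor epochs with channel geometry.

    ``data`` has shape (n_epochs, n_channels, n_samples), units tesla.
    """

    data: np.ndarray
    fs: float
    sensors: SensorArray
    epoch_length_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_samples)")
        if self.data.shape[1] != self.sensors.count:
            raise ValueError("channel axis does not match sensor array")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(self.data).any():
            raise ValueError("NaN in epoch data")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class MarkerList:
    """Event markers as seconds from recording start, sorted ascending."""

    times: np.ndarray
    label: str = "event"

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        object.__setattr__(self, "times", np.sort(t))


def exclude_marked_intervals(
    continuous: np.ndarray,
    fs: float,
    markers: MarkerList,
    pad_s: float = 10.0,
) -> list[tuple[int, int]]:
    """Clean segments after removing +/- ``pad_s`` around every marker.

    Returns half-open sample intervals ``[start, end)`` covering all data
    farther than ``pad_s`` seconds from any marker.  Overlapping exclusion
    windows merge naturally through the sample-wise mask.
    """
    if pad_s < 0:
        raise ValueError("pad_s must be non-negative")
    continuous = np.asarray(continuous)
    n = continuous.shape[-1]
    duration = n / fs
    if np.any((markers.times < 0) | (markers.times > duration)):
        raise ValueError("marker outside recording duration")
    times = np.arange(n) / fs
    clean = np.ones(n, dtype=bool)
    for t in markers.times:
        # half-open exclusion window [t - pad_s, t + pad_s)
        clean &= (times < t - pad_s) | (times >= t + pad_s)
    edges = np.diff(clean.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if clean[0]:
        starts.insert(0, 0)
    if clean[-1]:
        ends.append(n)
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def segment_epochs(
    continuous: np.ndarray,
    segments: list[tuple[int, int]],
    fs: float,
    sensors: SensorArray,
    epoch_length_s: float = 10.0,
    n_epochs: int = 30,
    seed: int | None = None,
) -> EpochedRecording:
    """Randomly select non-overlapping epochs from clean segments.

    Each clean segment is tiled into consecutive non-overlapping windows of
    ``epoch_length_s``; ``n_epochs`` windows are drawn uniformly without
    replacement from the pooled tiling and returned in randomized order.

    Raises
    ------
    ValueError
        If the tiling yields fewer than ``n_epochs`` windows; the message
        states the deficit in seconds.
    """
    continuous = np.asarray(continuous, dtype=float)
    epoch_n = int(round(epoch_length_s * fs))
    candidates: list[int] = []
    for start, end in segments:
        n_fit = (end - start) // epoch_n
        candidates.extend(start + k * epoch_n for k in range(n_fit))
    if len(candidates) < n_epochs:
        deficit_s = (n_epochs - len(candidates)) * epoch_length_s
        raise ValueError(
            f"insufficient clean data: need {n_epochs} epochs of "
            f"{epoch_length_s} s, found {len(candidates)} "
            f"(short by {deficit_s:g} s)"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_epochs, replace=False)
    data = np.stack([continuous[:, candidates[i] : candidates[i] + epoch_n] for i in chosen])
    return EpochedRecording(data=data, fs=fs, sensors=sensors, epoch_length_s=epoch_length_s)


def downsample(rec: EpochedRecording, target_fs: float = 409.6) -> EpochedRecording:
    """Polyphase anti-aliased resampling to ``target_fs``.

    The rate ratio is represented as an exact (or < 1e-6 relative error)
    rational, so non-integer ratios such as 3906.2 -> 409.6 are supported.
    """
    if target_fs >= rec.fs:
        raise ValueError(f"target_fs {target_fs} must be below current fs {rec.fs}")
    ratio = Fraction(repr(target_fs)) / Fraction(repr(rec.fs))
    ratio = ratio.limit_denominator(100_000)
    if abs(float(ratio) - target_fs / rec.fs) > 1e-6 * (target_fs / rec.fs):
        raise ValueError("cannot approximate rate ratio to 1e-6 relative error")
    up, down = ratio.numerator, ratio.denominator
    out = signal.resample_poly(rec.data, up, down, axis=2)
    expected = int(round(rec.epoch_length_s * target_fs))
    out = out[:, :, :expected]
    return replace(rec, data=out, fs=target_fs)


def bandpass(
    rec: EpochedRecording,
    low: float = 0.5,
    high: float = 70.0,
    order: int = 4,
) -> EpochedRecording:
    """Zero-phase Butterworth band-pass (forward-backward application)."""
    if not 0 < low < high < rec.fs / 2:
        raise ValueError(
            f"invalid band edges ({low}, {high}) Hz for fs {rec.fs} Hz"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=2)
    return replace(rec, data=out)


def reject_epochs_by_amplitude(rec: EpochedRecording, k: float = 8.0) -> EpochedRecording:
    """Drop epochs containing samples beyond ``k`` MADs of the per-channel median.

    A coarse automated stand-in for visual artifact review.
    """
    med = np.median(rec.data, axis=(0, 2), keepdims=True)
    mad = np.median(np.abs(rec.data - med), axis=(0, 2), keepdims=True)
    mad = np.where(mad == 0, np.inf, mad)
    bad = np.any(np.abs(rec.data - med) > k * mad, axis=(1, 2))
    if bad.all():
        raise ValueError("amplitude rejection removed every epoch")
    return replace(rec, data=rec.data[~bad])
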