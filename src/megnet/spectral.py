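"""Multitaper spectral analysis and cross-spectral density estimation.

Each frequency band is represented by a centre frequency and a spectral
half-bandwidth; DPSS (Slepian) tapers matched to that half-bandwidth give
the multitaper estimate of the complex Fourier coefficient at the band
centre with +/- halfwidth smoothing.  The per-taper coefficients are kept
because the beamformer projects them to source space; the sensor-level
cross-spectral density (CSD) is their averaged outer product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

__all__ = [
    "FrequencyBand",
    "CANONICAL_BANDS",
    "SpectralData",
    "CrossSpectralDensity",
    "dpss_tapers",
    "multitaper_csd",
]


@dataclass(frozen=True)
class FrequencyBand:
    """Band of interest as centre +/- halfwidth (Hz)."""

    name: str
    center: float
    halfwidth: float

    def __post_init__(self) -> None:
        if self.center - self.halfwidth < 0:
            raise ValueError(f"band {self.name}: centre - halfwidth must be >= 0")
        if self.halfwidth <= 0:
            raise ValueError(f"band {self.name}: halfwidth must be positive")

    @property
    def low(self) -> float:
        return self.center - self.halfwidth

    @property
    def high(self) -> float:
        return self.center + self.halfwidth


#: Canonical six-band set used throughout resting-state analysis.
CANONICAL_BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("delta", 2.0, 2.0),
    FrequencyBand("theta", 6.0, 2.0),
    FrequencyBand("alpha", 10.0, 2.0),
    FrequencyBand("beta1", 16.0, 4.0),
    FrequencyBand("beta2", 25.0, 4.0),
    FrequencyBand("gamma", 40.0, 5.0),
)


def get_band(name: str) -> FrequencyBand:
    for b in CANONICAL_BANDS:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in CANONICAL_BANDS]}")


@dataclass
class SpectralData:
    """Per-epoch, per-taper complex Fourier coefficients.

    ``fourier`` has shape (n_epochs, n_tapers, n_channels).
    """

    fourier: np.ndarray
    band: FrequencyBand
    fs: float

    @property
    def n_tapers(self) -> int:
        return self.fourier.shape[1]

    @property
    def n_observations(self) -> int:
        return self.fourier.shape[0] * self.fourier.shape[1]


@dataclass
class CrossSpectralDensity:
    """Hermitian channel x channel cross-spectral matrix for one band."""

    matrix: np.ndarray
    band: FrequencyBand
    n_observations: int

    def __post_init__(self) -> None:
        S = np.asarray(self.matrix)
        herm_err = np.linalg.norm(S - S.conj().T)
        if herm_err > 1e-10 * max(np.linalg.norm(S), 1e-300):
            raise ValueError("CSD matrix is not Hermitian")
        # enforce exactly real diagonal (imag part is rounding noise)
        self.matrix = (S + S.conj().T) / 2


def dpss_tapers(n_samples: int, fs: float, halfwidth: float) -> np.ndarray:
    """Unit-norm Slepian tapers for a given spectral half-bandwidth.

    The taper count follows the usual convention K = floor(2 T W) - 1 with
    T the epoch length (s) and W the halfwidth (Hz).

    Returns
    -------
    (K, n_samples) array; rows orthonormal.
    """
    T = n_samples / fs
    nw = T * halfwidth
    K = int(np.floor(2 * nw)) - 1
    if K < 1:
        raise ValueError(
            f"halfwidth {halfwidth} Hz over {T:.3g} s supports no taper "
            f"(need 2*T*W - 1 >= 1)"
        )
    tapers = windows.dpss(n_samples, nw, Kmax=K, norm=2)
    return np.atleast_2d(tapers)


def multitaper_csd(
    data: np.ndarray,
    fs: float,
    band: FrequencyBand,
    mode: str = "center",
    n_grid: int = 5,
) -> tuple[SpectralData, CrossSpectralDensity]:
    """Multitaper Fourier coefficients and CSD for one band.

    Parameters
    ----------
    data : (n_epochs, n_channels, n_samples)
        Epoched sensor time series.
    fs : float
        Sampling rate in Hz.
    band : FrequencyBand
        Centre frequency and spectral smoothing halfwidth.
    mode : {"center", "band_average"}
        "center" evaluates the tapered Fourier transform at the band centre
        only (DPSS smoothing covers +/- halfwidth).  "band_average"
        additionally averages the CSD over ``n_grid`` frequencies spanning
        the band; the returned coefficients are then stacked over
        frequencies along the taper axis.

    Returns
    -------
    (SpectralData, CrossSpectralDensity)
        CSD is normalized by 1/fs per the unit-norm-taper density
        convention; downstream coherence is scale-free regardless.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be (n_epochs, n_channels, n_samples)")
    n_epochs, n_channels, n_samples = data.shape
    if band.center + band.halfwidth >= fs / 2:
        raise ValueError(
            f"band {band.name} (up to {band.high} Hz) exceeds Nyquist {fs / 2} Hz"
        )
    tapers = dpss_tapers(n_samples, fs, band.halfwidth)

    if mode == "center":
        freqs = np.array([band.center])
    elif mode == "band_average":
        freqs = np.linspace(band.low, band.high, n_grid)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    t = np.arange(n_samples) / fs
    # (n_freqs, n_samples) complex exponentials
    carriers = np.exp(-2j * np.pi * freqs[:, None] * t[None, :])
    # tapered carriers: (n_freqs, K, n_samples)
    kernels = carriers[:, None, :] * tapers[None, :, :]
    # coefficients: (n_epochs, n_channels, n_freqs, K) -> reorder
    coefs = np.tensordot(data, kernels, axes=([2], [2]))
    coefs = np.transpose(coefs, (0, 2, 3, 1))  # (epochs, freqs, K, channels)
    # stack frequencies into the taper axis
    coefs = coefs.reshape(n_epochs, len(freqs) * tapers.shape[0], n_channels)

    spec = SpectralData(fourier=coefs, band=band, fs=fs)
    obs = coefs.reshape(-1, n_channels)
    S = np.einsum("oc,od->cd", obs, obs.conj()) / (obs.shape[0] * fs)
    csd = CrossSpectralDensity(matrix=S, band=band, n_observations=obs.shape[0])
    return spec, csd
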