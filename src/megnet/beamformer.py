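"""DICS spatial filtering: frequency-domain adaptive source projection.

For each source node a spatial filter is built from the band's sensor
cross-spectral density (real part, regularized) and the node's lead
field.  The scalar filter uses the orientation of maximal output power,
found inside the numerically non-degenerate lead-field subspace (a
spherical conductor makes the radial orientation exactly silent, so the
raw 3x3 inner matrix is rank-deficient by construction).  Filters are
unit-gain: ``w @ leadfield(orientation) == 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import LeadField
from .spectral import CrossSpectralDensity, FrequencyBand, SpectralData

__all__ = [
    "SpatialFilterSet",
    "SourceSpectra",
    "SourcePowerMap",
    "regularize_csd",
    "dics_filter",
    "compute_filters",
    "project_sources",
    "source_power",
]


@dataclass
class SpatialFilterSet:
    """Per-node DICS weights for one band.

    ``weights`` is (n_nodes, n_channels); ``orientations`` the chosen
    dipole orientation per node; ``kept`` the boolean mask of nodes with a
    valid (non-degenerate) filter.
    """

    weights: np.ndarray
    orientations: np.ndarray
    kept: np.ndarray
    band: FrequencyBand
    lam: float

    @property
    def kept_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.kept)


@dataclass
class SourceSpectra:
    """Complex source-level Fourier coefficients (epoch, taper, node)."""

    coefficients: np.ndarray
    band: FrequencyBand
    node_ids: np.ndarray

    @property
    def n_observations(self) -> int:
        return self.coefficients.shape[0] * self.coefficients.shape[1]

    def as_observations(self) -> np.ndarray:
        """Flatten to (n_observations, n_nodes)."""
        return self.coefficients.reshape(-1, self.coefficients.shape[2])


@dataclass
class SourcePowerMap:
    """Mean squared source amplitude per node for one band."""

    power: np.ndarray
    band: FrequencyBand
    node_ids: np.ndarray


def regularize_csd(csd: CrossSpectralDensity | np.ndarray, lam: float = 0.05) -> np.ndarray:
    """Diagonal loading: S + lam * (tr(S)/n) * I.

    ``lam`` is the loading fraction (5% default).
    """
    if lam < 0:
        raise ValueError(f"regularization fraction must be >= 0, got {lam}")
    S = csd.matrix if isinstance(csd, CrossSpectralDensity) else np.asarray(csd)
    n = S.shape[0]
    return S + lam * (np.trace(S).real / n) * np.eye(n)


def dics_filter(
    lf_node: np.ndarray,
    S_reg: np.ndarray,
    rank_tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Scalar DICS filter for one node.

    Parameters
    ----------
    lf_node : (n_channels, 3)
        Lead-field block of the node.
    S_reg : (n_channels, n_channels)
        Regularized CSD; its real part is used for the filter algebra.
    rank_tol : float
        Relative singular-value cutoff below which a lead-field direction
        is treated as silent (radial direction in a sphere).

    Returns
    -------
    (weights, orientation) with ``weights @ (lf_node @ orientation) == 1``,
    or ``None`` for a degenerate node (no non-silent direction).
    """
    Sr = np.real(S_reg)
    U, svals, Vt = np.linalg.svd(lf_node, full_matrices=False)
    keep = svals > rank_tol * svals[0] if svals[0] > 0 else np.zeros(3, bool)
    if not keep.any():
        return None
    V = Vt[keep].T                      # (3, k) orientation basis
    L = lf_node @ V                     # (n_channels, k)
    SinvL = np.linalg.solve(Sr, L)
    G = L.T @ SinvL                     # (k, k), SPD on the kept subspace
    # max power orientation: P(u) = 1/(u^T G u) -> smallest eigenvector of G
    evals, evecs = np.linalg.eigh(G)
    u_red = evecs[:, 0]
    orientation = V @ u_red
    l_opt = lf_node @ orientation
    Sinv_l = np.linalg.solve(Sr, l_opt)
    denom = l_opt @ Sinv_l
    if denom <= 0 or not np.isfinite(denom):
        return None
    w = Sinv_l / denom
    return w, orientation


def compute_filters(
    lf: LeadField,
    csd: CrossSpectralDensity,
    lam: float = 0.05,
) -> SpatialFilterSet:
    """DICS filters for every grid node at one band.

    Degenerate nodes (silent lead field, e.g. at the sphere centre) are
    flagged in ``kept`` and excluded from downstream networks.
    """
    S_reg = regularize_csd(csd, lam)
    n_nodes = lf.n_nodes
    n_chan = S_reg.shape[0]
    if lf.matrix.shape[0] != n_chan:
        raise ValueError("lead field and CSD disagree on channel count")
    W = np.zeros((n_nodes, n_chan))
    oris = np.zeros((n_nodes, 3))
    kept = np.zeros(n_nodes, dtype=bool)
    for node in range(n_nodes):
        if node in lf.degenerate_nodes:
            continue
        out = dics_filter(lf.node_gain(node), S_reg)
        if out is None:
            continue
        W[node], oris[node] = out
        kept[node] = True
    return SpatialFilterSet(weights=W, orientations=oris, kept=kept,
                            band=csd.band, lam=lam)


def project_sources(filters: SpatialFilterSet, spec: SpectralData) -> SourceSpectra:
    """Project sensor Fourier coefficients through the spatial filters.

    Only nodes with a valid filter appear in the output; ``node_ids``
    records their grid indices.
    """
    n_chan = spec.fourier.shape[2]
    if filters.weights.shape[1] != n_chan:
        raise ValueError(
            f"filter channel count {filters.weights.shape[1]} does not match "
            f"spectral data ({n_chan})"
        )
    kept = filters.kept_nodes
    W = filters.weights[kept]                       # (n_kept, n_chan)
    coefs = np.tensordot(spec.fourier, W.T, axes=([2], [0]))
    return SourceSpectra(coefficients=coefs, band=spec.band, node_ids=kept)


def source_power(src: SourceSpectra, weights_norm: np.ndarray | None = None) -> SourcePowerMap:
    """Mean |coefficient|^2 per node over epochs and tapers.

    If ``weights_norm`` (per-node ||w||^2) is given, power is divided by
    it — the neural-activity-index style depth normalization that flattens
    the white-noise floor of a unit-gain beamformer.
    """
    obs = src.as_observations()
    if obs.shape[0] < 1:
        raise ValueError("need at least one observation")
    power = np.mean(np.abs(obs) ** 2, axis=0)
    if weights_norm is not None:
        power = power / weights_norm
    return SourcePowerMap(power=power, band=src.band, node_ids=src.node_ids)
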