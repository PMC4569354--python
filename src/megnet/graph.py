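"""Weighted graph measures and surrogate-based normalization.

Measures follow the weighted conventions of the Brain Connectivity
Toolbox: nodal strength is the row sum of the adjacency; clustering is
the Onnela geometric-mean triangle intensity on max-normalized weights;
path length maps each weight w to a length 1/w and averages all-pairs
shortest paths.  Normalized clustering / path length divide the observed
global value by its mean over surrogate networks obtained by shuffling
the edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra
from scipy.sparse import csr_matrix

from .connectivity import ConnectivityNetwork

__all__ = [
    "GraphMeasures",
    "nodal_strength",
    "onnela_clustering",
    "char_path_length",
    "shuffle_weights",
    "surrogate_normalize",
    "compute_graph_measures",
]


@dataclass
class GraphMeasures:
    """Per-network summary of strength, clustering and path length."""

    nodal_strength: np.ndarray
    global_strength: float
    clustering: np.ndarray
    global_clustering: float
    char_path_length: float
    normalized_clustering: float | None = None
    normalized_path_length: float | None = None
    n_surrogates: int = 0


def _as_matrix(net: ConnectivityNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, ConnectivityNetwork):
        return net.adjacency
    A = np.asarray(net, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    return A


def nodal_strength(net: ConnectivityNetwork | np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node sum of edge weights and its mean over nodes."""
    A = _as_matrix(net)
    s = A.sum(axis=1)
    return s, float(s.mean())


def onnela_clustering(net: ConnectivityNetwork | np.ndarray) -> tuple[np.ndarray, float]:
    """Weighted clustering coefficient (geometric triangle intensity).

    C_i = sum_{j,h} (w'_ij w'_jh w'_ih)^(1/3) / (k_i (k_i - 1)) with
    w' = w / max(w) and k_i the binary degree; C_i = 0 when k_i < 2.
    """
    A = _as_matrix(net)
    wmax = A.max()
    if wmax == 0:
        z = np.zeros(A.shape[0])
        return z, 0.0
    W = (A / wmax) ** (1.0 / 3.0)
    k = (A > 0).sum(axis=1).astype(float)
    # diagonal of W^3 counts ordered triangle paths i->j->h->i
    tri = np.diag(W @ W @ W)
    denom = k * (k - 1)
    C = np.where(denom > 0, tri / np.where(denom > 0, denom, 1.0), 0.0)
    return C, float(C.mean())


def char_path_length(net: ConnectivityNetwork | np.ndarray) -> float:
    """Mean shortest-path length over ordered node pairs, edge length = 1/w.

    Raises for disconnected networks: coherence networks are dense, so a
    disconnection signals an upstream defect rather than a valid topology.
    """
    A = _as_matrix(net)
    n = A.shape[0]
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    with np.errstate(divide="ignore"):
        lengths = np.where(A > 0, 1.0 / np.where(A > 0, A, 1.0), 0.0)
    D = dijkstra(csr_matrix(lengths), directed=False)
    off = ~np.eye(n, dtype=bool)
    if np.isinf(D[off]).any():
        raise ValueError("network is disconnected; characteristic path length undefined")
    return float(D[off].mean())


def shuffle_weights(
    A: np.ndarray, rng: np.random.Generator, preserve_degree: bool = False
) -> np.ndarray:
    """Surrogate network: permute the upper-triangle weights, symmetrize.

    Preserves the weight distribution.  With ``preserve_degree`` the
    weights are permuted only across the existing edge set (zeros stay
    zeros), so the binary degree sequence is preserved as well; on the
    dense coherence networks this pipeline produces the two schemes
    coincide.
    """
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    w = A[iu].copy()
    if preserve_degree:
        nz = w > 0
        vals = w[nz]
        rng.shuffle(vals)
        w[nz] = vals
    else:
        rng.shuffle(w)
    S = np.zeros_like(A)
    S[iu] = w
    return S + S.T


def surrogate_normalize(
    net: ConnectivityNetwork | np.ndarray,
    n_surrogates: int = 100,
    seed: int | None = None,
    max_retries: int = 10,
    preserve_degree: bool = False,
) -> tuple[float, float]:
    """Normalized global clustering and path length.

    Each of ``n_surrogates`` surrogates shuffles the off-diagonal weights;
    a surrogate that comes out disconnected is redrawn (up to
    ``max_retries`` times) since its path length is undefined.

    Returns
    -------
    (normalized_clustering, normalized_path_length)
        observed / mean(surrogate) for each measure.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    A = _as_matrix(net)
    _, c_obs = onnela_clustering(A)
    l_obs = char_path_length(A)
    rng = np.random.default_rng(seed)
    cs = np.empty(n_surrogates)
    ls = np.empty(n_surrogates)
    for i in range(n_surrogates):
        for attempt in range(max_retries + 1):
            S = shuffle_weights(A, rng, preserve_degree=preserve_degree)
            try:
                ls[i] = char_path_length(S)
            except ValueError:
                if attempt == max_retries:
                    raise ValueError(
                        "surrogates repeatedly disconnected; network too sparse "
                        "for weight-shuffle normalization"
                    )
                continue
            _, cs[i] = onnela_clustering(S)
            break
    return c_obs / cs.mean(), l_obs / ls.mean()


def compute_graph_measures(
    net: ConnectivityNetwork | np.ndarray,
    n_surrogates: int = 100,
    seed: int | None = None,
) -> GraphMeasures:
    """All measures for one network, including surrogate normalization."""
    A = _as_matrix(net)
    s, s_glob = nodal_strength(A)
    C, c_glob = onnela_clustering(A)
    L = char_path_length(A)
    norm_c, norm_l = surrogate_normalize(A, n_surrogates=n_surrogates, seed=seed)
    return GraphMeasures(
        nodal_strength=s,
        global_strength=s_glob,
        clustering=C,
        global_clustering=c_glob,
        char_path_length=L,
        normalized_clustering=norm_c,
        normalized_path_length=norm_l,
        n_surrogates=n_surrogates,
    )
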