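"""Imaginary-coherence connectivity networks at grid and region resolution.

Coherency between two sources is the normalized cross-spectrum; its real
part is dominated by zero-lag mixing (field spread / volume conduction),
so only the absolute imaginary part enters the network — coupling at a
non-zero time lag survives, instantaneous mixing is cancelled exactly.
The absolute value is taken immediately, making every network weighted,
undirected and unthresholded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .beamformer import SourceSpectra
from .geometry import SourceGrid
from .spectral import FrequencyBand

__all__ = [
    "ConnectivityNetwork",
    "AtlasMapping",
    "imaginary_coherence",
    "build_high_res_network",
    "aggregate_to_regions",
    "octant_atlas",
]


@dataclass
class ConnectivityNetwork:
    """Weighted undirected adjacency matrix over nodes or regions.

    invariants: symmetric, zero diagonal, weights in [0, 1], no NaN.
    """

    adjacency: np.ndarray
    resolution: str  # "high" | "low"
    node_labels: tuple[str, ...]
    band: FrequencyBand | None = None
    subject_id: str | None = None
    node_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if np.isnan(A).any():
            raise ValueError("NaN in adjacency")
        if not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if A.min() < -1e-12 or A.max() > 1 + 1e-9:
            raise ValueError("weights must lie in [0, 1]")
        self.adjacency = np.clip(A, 0.0, 1.0)
        if len(self.node_labels) != A.shape[0]:
            raise ValueError("one label per node required")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass(frozen=True)
class AtlasMapping:
    """Node -> region lookup for aggregating grid networks to regions."""

    node_to_region: Mapping[int, str]
    regions: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.regions) < 2:
            raise ValueError("atlas needs at least 2 regions")
        bad = set(self.node_to_region.values()) - set(self.regions)
        if bad:
            raise ValueError(f"mapped regions not in region list: {sorted(bad)}")


def _coherency_matrix(obs: np.ndarray) -> np.ndarray:
    """Complex coherency from (n_observations, n_nodes) coefficients."""
    n_obs = obs.shape[0]
    if n_obs < 2:
        raise ValueError("need at least 2 observations for coherence")
    S = (obs.T @ obs.conj()) / n_obs
    p = np.real(np.diag(S))
    if np.any(p <= 0):
        bad = np.flatnonzero(p <= 0)
        raise ValueError(f"zero spectral power at node(s) {bad.tolist()}")
    denom = np.sqrt(np.outer(p, p))
    return S / denom


def imaginary_coherence(src: SourceSpectra, i: int, j: int) -> float:
    """|Im coherency| between two source nodes (indices into node_ids order)."""
    obs = src.as_observations()[:, [i, j]]
    C = _coherency_matrix(obs)
    return float(np.abs(np.imag(C[0, 1])))


def build_high_res_network(
    src: SourceSpectra,
    grid: SourceGrid | None = None,
    subject_id: str | None = None,
) -> ConnectivityNetwork:
    """All-pairs |Im coherency| network over the retained source nodes."""
    obs = src.as_observations()
    if obs.shape[1] < 2:
        raise ValueError("need at least 2 retained nodes")
    C = _coherency_matrix(obs)
    W = np.abs(np.imag(C))
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2
    labels = tuple(f"node{int(n)}" for n in src.node_ids)
    positions = grid.positions[src.node_ids] if grid is not None else None
    return ConnectivityNetwork(
        adjacency=W,
        resolution="high",
        node_labels=labels,
        band=src.band,
        subject_id=subject_id,
        node_positions=positions,
    )


def aggregate_to_regions(
    net: ConnectivityNetwork,
    atlas: AtlasMapping,
    node_ids: np.ndarray | None = None,
) -> ConnectivityNetwork:
    """Average cross-region connections into a region-level network.

    The low-resolution weight between regions R1 and R2 is the mean of all
    high-resolution weights between nodes of R1 and nodes of R2;
    within-region pairs never contribute.  Unmapped nodes are dropped;
    regions with no surviving node are dropped.
    """
    ids = np.arange(net.n_nodes) if node_ids is None else np.asarray(node_ids)
    region_nodes: dict[str, list[int]] = {r: [] for r in atlas.regions}
    for pos, nid in enumerate(ids):
        reg = atlas.node_to_region.get(int(nid))
        if reg is not None:
            region_nodes[reg].append(pos)
    surviving = [r for r in atlas.regions if region_nodes[r]]
    if len(surviving) < 2:
        raise ValueError("fewer than 2 regions have mapped nodes")
    n_reg = len(surviving)
    W = np.zeros((n_reg, n_reg))
    A = net.adjacency
    for a in range(n_reg):
        ia = region_nodes[surviving[a]]
        for b in range(a + 1, n_reg):
            ib = region_nodes[surviving[b]]
            W[a, b] = W[b, a] = float(np.mean(A[np.ix_(ia, ib)]))
    return ConnectivityNetwork(
        adjacency=W,
        resolution="low",
        node_labels=tuple(surviving),
        band=net.band,
        subject_id=net.subject_id,
    )


def octant_atlas(grid: SourceGrid, node_ids: np.ndarray | None = None) -> AtlasMapping:
    """Deterministic toy parcellation: octants of the grid around its centroid.

    Stands in for an anatomical atlas in tests and demos; a real lookup
    can be supplied as a two-column TSV (node id, region label) instead.
    """
    ids = np.arange(grid.n_nodes) if node_ids is None else np.asarray(node_ids)
    center = grid.positions.mean(axis=0)
    mapping: dict[int, str] = {}
    for nid in ids:
        rel = grid.positions[int(nid)] - center
        octant = "".join("p" if v >= 0 else "n" for v in rel)
        mapping[int(nid)] = f"oct_{octant}"
    regions = tuple(sorted(set(mapping.values())))
    return AtlasMapping(node_to_region=mapping, regions=regions)


def load_atlas_tsv(path) -> AtlasMapping:
    """Read a node->region lookup from a two-column TSV (node_id, region)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, names=["node", "region"],
                     comment="#")
    mapping = {int(r.node): str(r.region) for r in df.itertuples()}
    return AtlasMapping(node_to_region=mapping,
                        regions=tuple(sorted(set(mapping.values()))))
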