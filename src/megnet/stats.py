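"""Group-level inference: permutation cluster tests, NBS, FDR, rank tests.

The node-cluster and power-cluster tests share one engine: mass-univariate
two-sample t maps, thresholding, clustering by spatial adjacency, and a
max-cluster-statistic permutation null built per direction.  The
network-based statistic (NBS) applies the same principle to edges, with
clusters defined as connected components of supra-threshold edges and the
component extent (edge count) as the cluster statistic.

Permutation nulls include the identity relabelling, guaranteeing
p >= 1/n_permutations; when the number of distinct group assignments is
at most the requested permutation count the null is enumerated exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "ClusterResult",
    "PermutationScheme",
    "mann_whitney",
    "node_cluster_permutation",
    "power_cluster_test",
    "nbs",
    "fdr_regional",
    "spearman_corr",
    "demographics",
    "positions_to_adjacency",
]


@dataclass
class StatResult:
    """Generic test outcome."""

    statistic: float
    p_value: float
    direction: int = 0  # sign of the group-A minus group-B effect
    method: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass
class ClusterResult:
    """A supra-threshold cluster of nodes or edges with its permutation p."""

    members: tuple
    statistic: float
    p_value: float
    sign: int

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("cluster must have members")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass(frozen=True)
class PermutationScheme:
    """Permutation-test configuration (threshold on |t|, per-direction nulls)."""

    n_permutations: int = 5000
    threshold: float = 2.0
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


# ---------------------------------------------------------------------------
# rank / contingency tests


def mann_whitney(group_a, group_b) -> StatResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution for min(n, m) <= 8 without ties; normal
    approximation with mid-ranks and tie-corrected variance otherwise.
    Degenerate case (every value identical) returns p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return StatResult(statistic=len(a) * len(b) / 2, p_value=1.0,
                          method="mann-whitney")
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = sp_stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    direction = int(np.sign(np.median(a) - np.median(b)))
    return StatResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      direction=direction, method=f"mann-whitney ({method})")


def spearman_corr(x, y) -> StatResult:
    """Two-sided Spearman rank correlation.

    Exact permutation p for n <= 9 (all n! rank orders); t approximation
    otherwise.  Ties get average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: correlation undefined")
    rx = sp_stats.rankdata(x)
    ry = sp_stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        rxc = rx - rx.mean()
        perms = np.array(list(itertools.permutations(ry)))
        pc = perms - ry.mean()
        rhos = (pc @ rxc) / np.sqrt((pc**2).sum(axis=1) * (rxc**2).sum())
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        method = "spearman (exact permutation)"
    else:
        res = sp_stats.spearmanr(x, y)
        rho, p = float(res.statistic), float(res.pvalue)
        method = "spearman (t approximation)"
    return StatResult(statistic=rho, p_value=p, direction=int(np.sign(rho)),
                      method=method)


def demographics(
    sex_table,
    ages_a=None,
    ages_b=None,
    age_summary: tuple[tuple[float, float, int], tuple[float, float, int]] | None = None,
    welch: bool = False,
) -> dict[str, StatResult]:
    """Cohort comparability checks: chi-square on sex, t-test on age.

    ``sex_table`` is a 2x2 count table (rows = groups, columns = sexes);
    the Pearson chi-square is computed WITHOUT continuity correction.  Age
    enters either as raw per-subject values or as (mean, sd, n) summaries.
    """
    table = np.asarray(sex_table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("sex table must be 2x2")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in sex table")
    chi2, p_sex, _, _ = sp_stats.chi2_contingency(table, correction=False)
    out = {"sex": StatResult(statistic=float(chi2), p_value=float(p_sex),
                             method="pearson chi-square (no continuity correction)")}
    if ages_a is not None and ages_b is not None:
        res = sp_stats.ttest_ind(ages_a, ages_b, equal_var=not welch)
        out["age"] = StatResult(statistic=float(res.statistic),
                                p_value=float(res.pvalue),
                                direction=int(np.sign(res.statistic)),
                                method="two-sample t (raw ages)")
    elif age_summary is not None:
        (m1, s1, n1), (m2, s2, n2) = age_summary
        res = sp_stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                            equal_var=not welch)
        out["age"] = StatResult(statistic=float(res.statistic),
                                p_value=float(res.pvalue),
                                direction=int(np.sign(res.statistic)),
                                method="two-sample t (summary stats)")
    return out


def fdr_regional(values_a: np.ndarray, values_b: np.ndarray, q: float = 0.05,
                 region_labels=None) -> list[StatResult]:
    """Per-region Mann-Whitney tests with Benjamini-Hochberg correction.

    ``values_a``/``values_b`` are (n_subjects, n_regions) matrices of a
    regional measure (typically nodal strength).
    """
    A = np.atleast_2d(np.asarray(values_a, dtype=float))
    B = np.atleast_2d(np.asarray(values_b, dtype=float))
    n_regions = A.shape[1]
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if B.shape[1] != n_regions:
        raise ValueError("region count mismatch between groups")
    raw = [mann_whitney(A[:, r], B[:, r]) for r in range(n_regions)]
    reject, p_adj, _, _ = multipletests([r.p_value for r in raw], alpha=q,
                                        method="fdr_bh")
    labels = region_labels if region_labels is not None else list(range(n_regions))
    out = []
    for r, res in enumerate(raw):
        out.append(StatResult(
            statistic=res.statistic,
            p_value=res.p_value,
            direction=res.direction,
            method="mann-whitney + BH-FDR",
            extra={"region": labels[r], "p_adjusted": float(p_adj[r]),
                   "significant": bool(reject[r])},
        ))
    return out


# ---------------------------------------------------------------------------
# permutation machinery


def _label_matrix(n_a: int, n_b: int, n_perm: int, seed) -> np.ndarray:
    """(P, n_a+n_b) boolean matrix of group-A assignments.

    Row 0 is always the identity labelling.  If the number of distinct
    assignments C(n_a+n_b, n_a) is <= n_perm the null is enumerated
    exactly; otherwise Monte-Carlo resampling (with the identity included)
    is used.
    """
    n = n_a + n_b
    n_distinct = math.comb(n, n_a)
    if n_distinct <= n_perm:
        G = np.zeros((n_distinct, n), dtype=bool)
        rows = []
        identity = tuple(range(n_a))
        combos = [identity] + [c for c in itertools.combinations(range(n), n_a)
                               if c != identity]
        for i, combo in enumerate(combos):
            G[i, list(combo)] = True
        return G
    rng = np.random.default_rng(seed)
    G = np.zeros((n_perm, n), dtype=bool)
    G[0, :n_a] = True
    for i in range(1, n_perm):
        G[i, rng.choice(n, size=n_a, replace=False)] = True
    return G


def _pooled_t(X: np.ndarray, G: np.ndarray, n_a: int, n_b: int) -> np.ndarray:
    """Pooled-variance two-sample t for every labelling in G.

    X is (n_subjects, n_features); returns (P, n_features).
    """
    Gf = G.astype(float)
    Xsq = X**2
    sum_a = Gf @ X
    sum_b = X.sum(axis=0)[None, :] - sum_a
    ssq_a = Gf @ Xsq
    ssq_b = Xsq.sum(axis=0)[None, :] - ssq_a
    mean_a, mean_b = sum_a / n_a, sum_b / n_b
    var_a = (ssq_a - n_a * mean_a**2) / (n_a - 1)
    var_b = (ssq_b - n_b * mean_b**2) / (n_b - 1)
    sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    denom = np.sqrt(sp2 * (1 / n_a + 1 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (mean_a - mean_b) / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def positions_to_adjacency(positions: np.ndarray, spacing: float,
                           radius_factor: float = 1.1) -> np.ndarray:
    """Spatial neighbour matrix: distance < radius_factor * spacing."""
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
    adj = d < radius_factor * spacing
    np.fill_diagonal(adj, False)
    return adj


def _clusters_from_mask(mask: np.ndarray, adjacency: np.ndarray) -> list[np.ndarray]:
    """Connected components of the adjacency restricted to masked nodes."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = adjacency[np.ix_(idx, idx)]
    n_comp, labels = connected_components(csr_matrix(sub), directed=False)
    return [idx[labels == c] for c in range(n_comp)]


def _cluster_stats_one(t_row: np.ndarray, adjacency: np.ndarray,
                       threshold: float, sign: int) -> list[tuple[np.ndarray, float]]:
    mask = t_row > threshold if sign > 0 else t_row < -threshold
    clusters = _clusters_from_mask(mask, adjacency)
    return [(c, float(abs(t_row[c].sum()))) for c in clusters]


def _map_cluster_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    adjacency: np.ndarray,
    scheme: PermutationScheme,
) -> list[ClusterResult]:
    """Shared engine for node-strength and source-power cluster tests."""
    A = np.atleast_2d(np.asarray(values_a, dtype=float))
    B = np.atleast_2d(np.asarray(values_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the node set")
    n_a, n_b = A.shape[0], B.shape[0]
    X = np.vstack([A, B])
    G = _label_matrix(n_a, n_b, scheme.n_permutations, scheme.seed)
    T = _pooled_t(X, G, n_a, n_b)

    null_pos = np.zeros(T.shape[0])
    null_neg = np.zeros(T.shape[0])
    supra_any = (np.abs(T) > scheme.threshold).any(axis=1)
    for p in np.flatnonzero(supra_any):
        for sign, null in ((1, null_pos), (-1, null_neg)):
            cl = _cluster_stats_one(T[p], adjacency, scheme.threshold, sign)
            if cl:
                null[p] = max(s for _, s in cl)

    results: list[ClusterResult] = []
    t_obs = T[0]
    for sign, null in ((1, null_pos), (-1, null_neg)):
        for members, stat in _cluster_stats_one(t_obs, adjacency,
                                                scheme.threshold, sign):
            p_val = float(np.mean(null >= stat - 1e-12))
            results.append(ClusterResult(members=tuple(int(m) for m in members),
                                         statistic=stat, p_value=p_val, sign=sign))
    results.sort(key=lambda c: c.p_value)
    return results


def node_cluster_permutation(
    strengths_a: np.ndarray,
    strengths_b: np.ndarray,
    node_positions: np.ndarray,
    spacing: float,
    scheme: PermutationScheme | None = None,
) -> list[ClusterResult]:
    """Cluster-based permutation test on per-node strength maps.

    Defaults: t threshold 2.0, 5000 permutations, cluster alpha 0.01.
    Supra-threshold nodes are clustered by spatial adjacency (neighbours
    within 1.1 x grid spacing); the cluster statistic is the summed t.
    """
    scheme = scheme or PermutationScheme(threshold=2.0, alpha=0.01)
    adjacency = positions_to_adjacency(np.asarray(node_positions), spacing)
    return _map_cluster_test(strengths_a, strengths_b, adjacency, scheme)


def power_cluster_test(
    power_a: np.ndarray,
    power_b: np.ndarray,
    node_positions: np.ndarray,
    spacing: float,
    scheme: PermutationScheme | None = None,
) -> list[ClusterResult]:
    """Cluster permutation test on source power maps (t threshold 1.9)."""
    scheme = scheme or PermutationScheme(threshold=1.9, alpha=0.05)
    adjacency = positions_to_adjacency(np.asarray(node_positions), spacing)
    return _map_cluster_test(power_a, power_b, adjacency, scheme)


# ---------------------------------------------------------------------------
# network-based statistic


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _edge_components(edge_idx: np.ndarray, edges: np.ndarray,
                     n_nodes: int) -> list[np.ndarray]:
    """Group supra-threshold edges into connected components.

    ``edges`` is the (E, 2) endpoint table of the full edge ordering;
    returns lists of indices into ``edge_idx``'s edge space.
    """
    uf = _UnionFind(n_nodes)
    for e in edge_idx:
        uf.union(int(edges[e, 0]), int(edges[e, 1]))
    comp: dict[int, list[int]] = {}
    for e in edge_idx:
        root = uf.find(int(edges[e, 0]))
        comp.setdefault(root, []).append(int(e))
    return [np.array(v) for v in comp.values()]


def nbs(
    networks_a: np.ndarray,
    networks_b: np.ndarray,
    scheme: PermutationScheme | None = None,
    statistic: str = "extent",
) -> list[ClusterResult]:
    """Network-based statistic on stacks of region-level adjacency matrices.

    Parameters
    ----------
    networks_a, networks_b : (n_subjects, n_regions, n_regions)
        Symmetric weighted adjacency matrices per subject.
    scheme : PermutationScheme
        Defaults: t threshold 3.5, 5000 permutations, alpha 0.05.
    statistic : {"extent", "sum"}
        Component size in edges (default) or summed |t| over the component.

    Returns
    -------
    Clusters whose ``members`` are (region_i, region_j) edge tuples.
    """
    scheme = scheme or PermutationScheme(threshold=3.5, alpha=0.05)
    A = np.asarray(networks_a, dtype=float)
    B = np.asarray(networks_b, dtype=float)
    if A.ndim != 3 or B.ndim != 3 or A.shape[1:] != B.shape[1:]:
        raise ValueError("expect (n_subjects, n_regions, n_regions) stacks")
    n_reg = A.shape[1]
    if n_reg < 3:
        raise ValueError("NBS needs at least 3 regions")
    iu = np.triu_indices(n_reg, k=1)
    edges = np.column_stack(iu)
    Xa = A[:, iu[0], iu[1]]
    Xb = B[:, iu[0], iu[1]]
    n_a, n_b = Xa.shape[0], Xb.shape[0]
    X = np.vstack([Xa, Xb])
    G = _label_matrix(n_a, n_b, scheme.n_permutations, scheme.seed)
    T = _pooled_t(X, G, n_a, n_b)

    def comp_stats(t_row: np.ndarray, sign: int) -> list[tuple[np.ndarray, float]]:
        mask = t_row > scheme.threshold if sign > 0 else t_row < -scheme.threshold
        idx = np.flatnonzero(mask)
        comps = _edge_components(idx, edges, n_reg)
        out = []
        for c in comps:
            stat = float(len(c)) if statistic == "extent" else float(np.abs(t_row[c]).sum())
            out.append((c, stat))
        return out

    null_pos = np.zeros(T.shape[0])
    null_neg = np.zeros(T.shape[0])
    supra_any = (np.abs(T) > scheme.threshold).any(axis=1)
    for p in np.flatnonzero(supra_any):
        for sign, null in ((1, null_pos), (-1, null_neg)):
            cl = comp_stats(T[p], sign)
            if cl:
                null[p] = max(s for _, s in cl)

    results: list[ClusterResult] = []
    for sign, null in ((1, null_pos), (-1, null_neg)):
        for members, stat in comp_stats(T[0], sign):
            p_val = float(np.mean(null >= stat - 1e-12))
            edge_tuples = tuple((int(edges[e, 0]), int(edges[e, 1])) for e in members)
            results.append(ClusterResult(members=edge_tuples, statistic=stat,
                                         p_value=p_val, sign=sign))
    results.sort(key=lambda c: c.p_value)
    return results
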