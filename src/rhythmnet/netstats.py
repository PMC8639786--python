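"""Network-level statistics on band-specific FC matrices.

Distinctiveness quantifies how independent two connectivity matrices are:
D = 1 - R^2, with R^2 the squared Pearson correlation across site pairs
(optionally a partial correlation controlling for inter-site distance, since
FC in all bands jointly decays with distance). Power-product matrices serve
as controls: a matrix built purely from the spatial distribution of power
(log10 of the power product per pair, or the sending site's power for
directed metrics) that FC networks can be tested against.

Node strength collapses an FC matrix onto its sites (mean FC with all other
sites outside an exclusion radius guarding against residual volume
conduction), with significance from a permutation null that preserves the
empirical weight distribution exactly (random graph with the same weights),
corrected across sites by Benjamini-Hochberg FDR.

Consensus modularity finds one community structure shared by the four band
networks: degenerate Louvain partitions are collected across a grid of
resolution parameters and across bands, their co-assignment fractions form
an agreement matrix, which is thresholded and iteratively re-clustered until
the partition is stable. The modularity index q is reported at resolution 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import networkx as nx
import numpy as np
from networkx.algorithms.community import louvain_communities, modularity
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DistinctivenessResult",
    "StrengthMap",
    "ModularityResult",
    "distinctiveness",
    "power_product_matrix",
    "node_strength",
    "strength_significance",
    "consensus_modularity",
]


@dataclass
class DistinctivenessResult:
    d: float
    r2: float
    partialized: bool
    n_pairs: int
    log_transformed: bool = True


@dataclass
class StrengthMap:
    strength: np.ndarray  # per site
    direction: str  # undirected | outflow | inflow
    excluded_radius_mm: float
    significance: Optional[np.ndarray] = None  # bool per site
    p_values: Optional[np.ndarray] = None


@dataclass
class ModularityResult:
    partition: np.ndarray  # module id per site
    q: float  # modularity of the consensus partition at gamma=1, mean over bands
    q_per_band: Dict[str, float]
    resolution_grid: np.ndarray
    consensus_threshold: float
    agreement: np.ndarray  # (n, n) in [0, 1]
    n_iterations: int = 1


def _pair_values(m: np.ndarray, directed: bool) -> np.ndarray:
    """Flatten a pair matrix excluding the diagonal (both directions if directed)."""
    n = m.shape[0]
    if directed:
        idx = ~np.eye(n, dtype=bool)
    else:
        idx = np.triu(np.ones((n, n), dtype=bool), k=1)
    return m[idx]


def distinctiveness(
    m1: np.ndarray,
    m2: np.ndarray,
    distance: Optional[np.ndarray] = None,
    log_transform: bool = True,
    directed: bool = False,
) -> DistinctivenessResult:
    """Distinctiveness D = 1 - R^2 between two connectivity matrices.

    R^2 is the squared Pearson correlation across site pairs (self-pairs and
    non-finite entries excluded). When ``distance`` is supplied, the
    correlation is partialized for distance: both matrices are residualized
    on inter-site distance before correlating, so shared distance decay no
    longer counts as similarity. With ``log_transform``, values are
    log10-transformed first (non-positive entries excluded). D is symmetric
    in its arguments and invariant to positive affine transforms of either
    matrix.
    """
    m1 = np.asarray(m1, float)
    m2 = np.asarray(m2, float)
    if m1.shape != m2.shape:
        raise ValueError("matrices must share shape / pair index")
    x = _pair_values(m1, directed)
    y = _pair_values(m2, directed)
    keep = np.isfinite(x) & np.isfinite(y)
    d = None
    if distance is not None:
        d = _pair_values(np.asarray(distance, float), directed)
        keep &= np.isfinite(d)
    if log_transform:
        keep &= (x > 0) & (y > 0)
    x, y = x[keep], y[keep]
    if d is not None:
        d = d[keep]
    if x.size < 3:
        raise ValueError(f"only {x.size} common pairs; need >= 3")
    if log_transform:
        x, y = np.log10(x), np.log10(y)
    if np.std(x) == 0 or np.std(y) == 0:
        return DistinctivenessResult(d=np.nan, r2=np.nan, partialized=d is not None,
                                     n_pairs=int(x.size), log_transformed=log_transform)
    if d is not None:
        X = np.column_stack([np.ones_like(d), d])
        x = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        if np.std(x) == 0 or np.std(y) == 0:
            return DistinctivenessResult(d=np.nan, r2=np.nan, partialized=True,
                                         n_pairs=int(x.size),
                                         log_transformed=log_transform)
    r = float(np.corrcoef(x, y)[0, 1])
    r2 = r * r
    return DistinctivenessResult(
        d=1.0 - r2, r2=r2, partialized=d is not None, n_pairs=int(x.size),
        log_transformed=log_transform,
    )


def power_product_matrix(
    power_per_site: np.ndarray, directed: bool = False
) -> np.ndarray:
    """Pair matrix of log10 power products (or sender power, directed variant).

    Undirected: entry (i, j) = log10(p_i * p_j). Directed: entry (i, j) =
    log10(p_i), the power at the sending site, constant along each row.
    """
    p = np.asarray(power_per_site, float)
    if np.any(p <= 0):
        raise ValueError("power values must be positive")
    lp = np.log10(p)
    n = p.size
    if directed:
        out = np.tile(lp[:, None], (1, n))
    else:
        out = lp[:, None] + lp[None, :]
    np.fill_diagonal(out, np.nan)
    return out


def node_strength(
    fc_band_matrix: np.ndarray,
    site_distances: Optional[np.ndarray] = None,
    min_radius_mm: float = 2.0,
    direction: str = "undirected",
) -> StrengthMap:
    """Mean FC of every site with all other sites beyond the exclusion radius.

    ``direction='outflow'`` averages the row of a directed matrix (influence
    sent), ``'inflow'`` the column (influence received); ``'undirected'``
    treats the matrix as symmetric. Sites with no admissible partner get NaN.
    """
    W = np.asarray(fc_band_matrix, float)
    n = W.shape[0]
    admissible = ~np.eye(n, dtype=bool)
    if site_distances is not None:
        admissible &= np.asarray(site_distances, float) >= min_radius_mm
    if direction == "inflow":
        M = W.T
    elif direction in ("outflow", "undirected"):
        M = W
    else:
        raise ValueError("direction must be undirected, outflow, or inflow")
    strength = np.full(n, np.nan)
    for i in range(n):
        part = admissible[i] & np.isfinite(M[i])
        if part.any():
            strength[i] = M[i, part].mean()
    return StrengthMap(strength=strength, direction=direction,
                       excluded_radius_mm=min_radius_mm if site_distances is not None else 0.0)


def strength_significance(
    fc_band_matrix: np.ndarray,
    n_perm: int = 1000,
    fdr_q: float = 0.2,
    alpha: float = 0.05,
    seed: int = 0,
    site_distances: Optional[np.ndarray] = None,
    min_radius_mm: float = 0.0,
    direction: str = "undirected",
) -> StrengthMap:
    """Permutation significance of node strengths against an equal-weight random graph.

    The null permutes the multiset of edge weights across edges (exactly
    preserving the empirical weight distribution), recomputes strengths, and
    assigns each site a permutation p-value for its observed strength; sites
    are then selected by Benjamini-Hochberg FDR at ``fdr_q``. Degenerate
    (all-equal) weights yield no significant site. ``alpha`` is recorded as
    the nominal per-test level of the underlying exceedance test.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    W = np.asarray(fc_band_matrix, float)
    n = W.shape[0]
    rng = np.random.default_rng(seed)
    obs = node_strength(W, site_distances, min_radius_mm, direction).strength
    directed = direction in ("outflow", "inflow")
    if directed:
        idx = np.where(~np.eye(n, dtype=bool))
    else:
        idx = np.triu_indices(n, k=1)
    weights = W[idx]
    if np.all(weights == weights[0]):
        return StrengthMap(strength=obs, direction=direction,
                           excluded_radius_mm=min_radius_mm,
                           significance=np.zeros(n, dtype=bool),
                           p_values=np.ones(n))
    exceed = np.zeros(n)
    for _ in range(n_perm):
        Wp = np.full_like(W, np.nan)
        perm = rng.permutation(weights)
        Wp[idx] = perm
        if not directed:
            Wp[(idx[1], idx[0])] = perm
        sp = node_strength(Wp, site_distances, min_radius_mm, direction).strength
        exceed += sp >= obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    reject, _, _, _ = multipletests(p, alpha=fdr_q, method="fdr_bh")[:4]
    return StrengthMap(strength=obs, direction=direction,
                       excluded_radius_mm=min_radius_mm,
                       significance=reject, p_values=p)


def _graph_from_matrix(W: np.ndarray) -> nx.Graph:
    Wsym = (W + W.T) / 2.0
    np.fill_diagonal(Wsym, 0.0)
    Wsym = np.where(np.isfinite(Wsym), Wsym, 0.0)
    Wsym = np.clip(Wsym, 0.0, None)
    G = nx.Graph()
    n = W.shape[0]
    G.add_nodes_from(range(n))
    ii, jj = np.triu_indices(n, k=1)
    for i, j in zip(ii, jj):
        if Wsym[i, j] > 0:
            G.add_edge(int(i), int(j), weight=float(Wsym[i, j]))
    return G


def _louvain_labels(G: nx.Graph, resolution: float, seed: int) -> np.ndarray:
    comms = louvain_communities(G, weight="weight", resolution=resolution, seed=seed)
    labels = np.empty(G.number_of_nodes(), dtype=int)
    for k, c in enumerate(comms):
        for v in c:
            labels[v] = k
    return labels


def _agreement(partitions: np.ndarray) -> np.ndarray:
    """Fraction of partitions assigning each node pair to the same module."""
    P = np.asarray(partitions)  # (n_partitions, n_nodes)
    n = P.shape[1]
    agree = np.zeros((n, n))
    for labels in P:
        agree += labels[:, None] == labels[None, :]
    agree /= P.shape[0]
    np.fill_diagonal(agree, 0.0)
    return agree


def consensus_modularity(
    band_matrices: Dict[str, np.ndarray],
    gamma_range: Optional[np.ndarray] = None,
    n_reps: int = 10,
    consensus_tau: float = 0.25,
    seed: int = 0,
    n_consensus_reps: int = 100,
    max_consensus_iter: int = 50,
) -> ModularityResult:
    """Consensus community structure across band-specific FC networks.

    Degenerate partitions are produced with seeded Louvain over a
    logarithmic resolution grid (default 25 values in [0.1, 10], ``n_reps``
    restarts each) for every band matrix (directed matrices are symmetrized
    as (W + W^T)/2 for clustering). Their co-assignment fractions form the
    agreement matrix; values below ``consensus_tau`` are zeroed and the
    thresholded matrix is re-clustered at resolution 1 (``n_consensus_reps``
    restarts), iterating until all restarts agree. Reported q values are
    Newman modularity of the consensus partition at resolution 1, per band.
    """
    if gamma_range is None:
        gamma_range = np.logspace(np.log10(0.1), np.log10(10.0), 25)
    gamma_range = np.asarray(gamma_range, float)
    mats = {b: np.asarray(W, float) for b, W in band_matrices.items()}
    n = next(iter(mats.values())).shape[0]
    for W in mats.values():
        if W.shape != (n, n):
            raise ValueError("all band matrices must share the same node set")
    rng_seed = int(seed)
    partitions = []
    counter = 0
    for b, W in mats.items():
        G = _graph_from_matrix(W)
        for g in gamma_range:
            for _ in range(n_reps):
                partitions.append(_louvain_labels(G, g, rng_seed + counter))
                counter += 1
    agreement = _agreement(np.asarray(partitions))

    consensus = None
    agree = agreement.copy()
    for iteration in range(1, max_consensus_iter + 1):
        thr = np.where(agree >= consensus_tau, agree, 0.0)
        np.fill_diagonal(thr, 0.0)
        if not thr.any():
            consensus = np.arange(n)  # fully disconnected -> singletons
            break
        Gc = _graph_from_matrix(thr)
        reps = [
            _louvain_labels(Gc, 1.0, rng_seed + 100_000 + iteration * 1000 + k)
            for k in range(n_consensus_reps)
        ]
        reps_arr = np.asarray(reps)
        canon = [_canonical_labels(r) for r in reps_arr]
        if all(np.array_equal(canon[0], c) for c in canon[1:]):
            consensus = canon[0]
            break
        agree = _agreement(reps_arr)
    else:
        raise RuntimeError(
            f"consensus re-clustering did not stabilize in {max_consensus_iter} "
            "iterations"
        )

    comms = [set(np.flatnonzero(consensus == k)) for k in np.unique(consensus)]
    q_per_band = {}
    for b, W in mats.items():
        G = _graph_from_matrix(W)
        q_per_band[b] = (
            float(modularity(G, comms, weight="weight", resolution=1.0))
            if G.number_of_edges() > 0 else 0.0
        )
    return ModularityResult(
        partition=consensus,
        q=float(np.mean(list(q_per_band.values()))),
        q_per_band=q_per_band,
        resolution_grid=gamma_range,
        consensus_threshold=consensus_tau,
        agreement=agreement,
        n_iterations=iteration,
    )


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules in order of first appearance (partition-equality helper)."""
    out = np.empty_like(labels)
    mapping = {}
    for i, l in enumerate(labels):
        if l not in mapping:
            mapping[l] = len(mapping)
        out[i] = mapping[l]
    return out
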