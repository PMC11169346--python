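"""Consensus clustering of saliency maps into morphometry subtypes.

Pipeline: (1) repeatedly subsample a fraction of voxels (features) and
cluster all subjects on the restriction with eta-squared-distance k-means
(k-means++ seeding, many replicates); (2) accumulate a per-k consensus matrix
of co-clustering proportions (every pair appears in every iteration because
subsampling is over voxels, not subjects); (3) screen solutions with a dip
test on the consensus distribution (solutions whose consensus values fail to
reject unimodality show no real co-clustering structure) and rank the rest by
the proportion of ambiguously clustered pairs (PAC; entries strictly inside
(u1, u2)); (4) select the most complex solution with high reliability and
extract clusters plus exemplars by affinity propagation on the consensus
matrix.

The eta-squared coefficient compares two maps point by point, accounting for
scaling and offset; 1 means identical maps and values can be negative for
anti-related maps.  Its complement 1 - eta2 is the clustering distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AffinityPropagation

from .dip import dip_pvalue


# ---------------------------------------------------------------------------
# eta-squared similarity


def eta2(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Point-by-point similarity between two equal-length maps.

    eta2 = 1 - sum_i[(a_i - m_i)^2 + (b_i - m_i)^2]
             / sum_i[(a_i - M)^2 + (b_i - M)^2],
    with m_i = (a_i + b_i)/2 and M the mean of all m_i.  The numerator equals
    ||a - b||^2 / 2.  Symmetric; 1 for identical maps; may be negative.  A
    constant identical pair (zero denominator) is defined as 1.
    """
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    m = 0.5 * (a + b)
    big_m = m.mean()
    num = float(np.sum((a - m) ** 2 + (b - m) ** 2))
    den = float(np.sum((a - big_m) ** 2 + (b - big_m) ** 2))
    if den == 0.0:
        return 1.0
    return 1.0 - num / den


def eta2_rows_to_centroids(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """(n, k) matrix of eta2 between every row of x and every row of c."""
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    d = x.shape[1]
    xs, cs = x.sum(axis=1), c.sum(axis=1)
    xsq, csq = (x**2).sum(axis=1), (c**2).sum(axis=1)
    cross = x @ c.T
    num = 0.5 * (xsq[:, None] - 2.0 * cross + csq[None, :])
    big_m = (xs[:, None] + cs[None, :]) / (2.0 * d)
    den = (
        xsq[:, None]
        - 2.0 * big_m * xs[:, None]
        + csq[None, :]
        - 2.0 * big_m * cs[None, :]
        + 2.0 * d * big_m**2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 1.0 - num / den
    out[den == 0.0] = 1.0
    return out


# ---------------------------------------------------------------------------
# eta2-distance k-means


def _kmeanspp_seed(
    x: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k-means++ seeding under the 1 - eta2 distance."""
    n = x.shape[0]
    centers = [int(rng.integers(n))]
    d2 = np.maximum(1.0 - eta2_rows_to_centroids(x, x[centers[-1]][None, :])[:, 0], 0.0)
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers.append(int(rng.integers(n)))
        else:
            centers.append(int(rng.choice(n, p=d2 / total)))
        nd = np.maximum(
            1.0 - eta2_rows_to_centroids(x, x[centers[-1]][None, :])[:, 0], 0.0
        )
        d2 = np.minimum(d2, nd)
    return np.asarray(centers)


def _lloyd(
    x: np.ndarray, centroids: np.ndarray, max_iter: int = 100
) -> tuple[np.ndarray, float]:
    """Lloyd iterations with mean centroids and 1 - eta2 assignment.

    Mean centroids are a principled surrogate because the eta2 numerator is
    half the squared Euclidean distance; descent is not guaranteed, so the
    best labels seen are tracked.  Empty clusters are reseeded from the point
    farthest from its centroid.
    """
    k = centroids.shape[0]
    best_labels, best_cost = None, np.inf
    labels_prev = None
    for _ in range(max_iter):
        sim = eta2_rows_to_centroids(x, centroids)
        dist = 1.0 - sim
        labels = np.argmin(dist, axis=1)
        cost = float(dist[np.arange(len(labels)), labels].sum())
        if cost < best_cost:
            best_cost, best_labels = cost, labels.copy()
        if labels_prev is not None and np.array_equal(labels, labels_prev):
            break
        labels_prev = labels
        for c in range(k):
            members = labels == c
            if members.any():
                centroids[c] = x[members].mean(axis=0)
            else:
                far = int(np.argmax(dist[np.arange(len(labels)), labels]))
                centroids[c] = x[far]
    return best_labels, best_cost


def kmeans_eta2(
    maps: np.ndarray,
    k: int,
    replicates: int = 250,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Best-of-``replicates`` eta2-distance k-means labels."""
    x = np.asarray(maps, dtype=float)
    if x.shape[0] < k:
        raise ValueError("fewer maps than clusters")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    best_labels, best_cost = None, np.inf
    for _ in range(replicates):
        seeds = _kmeanspp_seed(x, k, rng)
        labels, cost = _lloyd(x, x[seeds].copy())
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    return best_labels


# ---------------------------------------------------------------------------
# consensus


def consensus_matrix(
    maps: np.ndarray,
    k: int,
    n_subsamples: int = 1000,
    voxel_fraction: float = 0.6,
    km_replicates: int = 250,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Co-clustering proportions over voxel-subsampled k-means runs.

    Each iteration draws a random ``voxel_fraction`` of the features and
    clusters *all* subjects on that restriction, so every pair contributes to
    every iteration and the consensus denominator is ``n_subsamples``.
    """
    x = np.asarray(maps, dtype=float)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n, d = x.shape
    n_vox = max(2, int(round(voxel_fraction * d)))
    counts = np.zeros((n, n))
    for _ in range(n_subsamples):
        cols = rng.choice(d, size=n_vox, replace=False)
        labels = kmeans_eta2(x[:, cols], k, replicates=km_replicates, rng=rng)
        same = labels[:, None] == labels[None, :]
        counts += same
    consensus = counts / n_subsamples
    np.fill_diagonal(consensus, 1.0)
    return consensus


def _upper_triangle(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def dip_test_consensus(
    consensus: np.ndarray, n_boot: int = 200, seed: int = 0,
    max_values: int = 1000,
) -> tuple[float, float]:
    """Dip test on the off-diagonal consensus values.

    Large samples are thinned deterministically to ``max_values`` entries to
    bound the bootstrap cost.
    """
    vals = _upper_triangle(consensus)
    if len(vals) < 4:
        raise ValueError("need at least 4 off-diagonal values")
    if len(vals) > max_values:
        rng = np.random.default_rng(seed)
        vals = rng.choice(vals, size=max_values, replace=False)
    return dip_pvalue(vals, n_boot=n_boot, seed=seed)


def pac(consensus: np.ndarray, u1: float = 0.1, u2: float = 0.9) -> float:
    """Proportion of ambiguously clustered pairs: entries strictly in (u1, u2)."""
    if not (0.0 <= u1 < u2 <= 1.0):
        raise ValueError("need 0 <= u1 < u2 <= 1")
    vals = _upper_triangle(consensus)
    return float(np.mean((vals > u1) & (vals < u2)))


def select_solution(
    per_k_stats: dict[int, dict[str, float]],
    pac_threshold: float = 0.1,
    alpha: float = 0.05,
) -> tuple[int, bool]:
    """Largest k whose dip test rejects unimodality and whose PAC is low.

    Solutions failing to reject unimodality of the consensus distribution
    show no consistent co-clustering and are excluded.  If nothing qualifies
    the k with minimal PAC is returned with a warning flag.
    """
    if not per_k_stats:
        raise ValueError("empty stats")
    qualified = [
        k
        for k, s in per_k_stats.items()
        if s["dip_p"] < alpha and s["pac"] <= pac_threshold
    ]
    if qualified:
        return max(qualified), True
    warnings.warn("no solution met the dip/PAC criteria; returning min-PAC k")
    return min(per_k_stats, key=lambda k: per_k_stats[k]["pac"]), False


def extract_clusters_ap(
    consensus: np.ndarray,
    target_k: int,
    damping: float = 0.7,
    max_bisect: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Affinity propagation on the consensus matrix, preference bisected so
    the number of clusters matches ``target_k`` (nearest achievable if not).

    Returns (labels, exemplar indices); exemplars are actual subjects.
    """
    s = np.asarray(consensus, dtype=float)
    lo, hi = -3.0, 1.5  # preference bounds around the [0, 1] similarity scale
    best = None
    for _ in range(max_bisect):
        pref = 0.5 * (lo + hi)
        labels, exemplars = _run_ap(s, pref, damping)
        if labels is None:
            lo = pref  # failed to converge at very low preference
            continue
        k = len(exemplars)
        if best is None or abs(k - target_k) < abs(len(best[1]) - target_k):
            best = (labels, exemplars)
        if k == target_k:
            return labels, exemplars
        if k < target_k:
            lo = pref  # higher preference -> more clusters
        else:
            hi = pref
    warnings.warn(
        f"affinity propagation reached {len(best[1])} clusters, target {target_k}"
    )
    return best


def _run_ap(s, preference, damping):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ap = AffinityPropagation(
            affinity="precomputed",
            damping=damping,
            preference=preference,
            max_iter=500,
            random_state=0,
        ).fit(s)
    if len(ap.cluster_centers_indices_) == 0 or (ap.labels_ < 0).any():
        return None, None
    return ap.labels_, ap.cluster_centers_indices_


# ---------------------------------------------------------------------------
# full run


@dataclass
class ConsensusConfig:
    k_range: tuple[int, int] = (3, 30)  # inclusive
    n_subsamples: int = 1000
    voxel_fraction: float = 0.6
    km_replicates: int = 250
    pac_bounds: tuple[float, float] = (0.1, 0.9)
    pac_threshold: float = 0.1
    dip_alpha: float = 0.05
    dip_boot: int = 200
    seed: int = 0


@dataclass
class ConsensusRun:
    config: ConsensusConfig
    consensus: dict[int, np.ndarray]
    dip_p: dict[int, float]
    pac: dict[int, float]
    selected_k: int
    criteria_met: bool
    labels: np.ndarray
    exemplar_ids: np.ndarray


def run_consensus(maps: np.ndarray, config: ConsensusConfig | None = None) -> ConsensusRun:
    """Full model-order scan, screening, selection, and cluster extraction."""
    config = config or ConsensusConfig()
    x = np.asarray(maps, dtype=float)
    rng = np.random.default_rng(config.seed)
    k_lo, k_hi = config.k_range
    k_hi = min(k_hi, x.shape[0] - 1)
    matrices: dict[int, np.ndarray] = {}
    stats: dict[int, dict[str, float]] = {}
    for k in range(k_lo, k_hi + 1):
        m = consensus_matrix(
            x, k, config.n_subsamples, config.voxel_fraction,
            config.km_replicates, rng,
        )
        d, p = dip_test_consensus(m, n_boot=config.dip_boot, seed=config.seed + k)
        u1, u2 = config.pac_bounds
        matrices[k] = m
        stats[k] = {"dip": d, "dip_p": p, "pac": pac(m, u1, u2)}
    selected_k, ok = select_solution(
        stats, pac_threshold=config.pac_threshold, alpha=config.dip_alpha
    )
    labels, exemplars = extract_clusters_ap(matrices[selected_k], selected_k)
    return ConsensusRun(
        config=config,
        consensus=matrices,
        dip_p={k: s["dip_p"] for k, s in stats.items()},
        pac={k: s["pac"] for k, s in stats.items()},
        selected_k=selected_k,
        criteria_met=ok,
        labels=labels,
        exemplar_ids=exemplars,
    )
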