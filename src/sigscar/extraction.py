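"""De novo signature extraction: bootstrap, NMF, consensus clustering.

A cohort catalogue matrix (96 channels x samples) is repeatedly perturbed by
multinomial bootstrap, factorized by non-negative matrix factorization under
the Frobenius objective, and the pooled per-bootstrap signatures are reduced
to consensus signatures by agglomerative clustering under cosine distance.
The number of signatures is chosen as the largest factorization rank whose
consensus clusters remain reproducible across bootstraps (mean silhouette
above a stability floor), which operationalizes "the minimal set of
signatures that optimally explains the catalogues".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .signature import Signature

_EPS = 1e-12


def bootstrap_resample(matrix: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Multinomial bootstrap of each sample's catalogue.

    Each column is redrawn as a multinomial of its own total from its own
    empirical channel distribution, so per-sample mutation totals are
    preserved exactly.
    """
    matrix = np.asarray(matrix)
    out = np.zeros_like(matrix, dtype=np.int64)
    for j in range(matrix.shape[1]):
        total = int(matrix[:, j].sum())
        if total == 0:
            continue
        probs = matrix[:, j] / matrix[:, j].sum()
        out[:, j] = rng.multinomial(total, probs)
    return out


def nmf_factorize(
    matrix: np.ndarray,
    k: int,
    seed: int | np.random.Generator = 0,
    max_iter: int = 2000,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Multiplicative-update NMF for the Frobenius objective.

    Factors ``matrix ~ W @ H`` with W (channels x k) and H (k x samples)
    non-negative. Initialization is random uniform scaled to the data, so the
    run is deterministic given the seed. Signature columns of W are
    normalized to sum to 1 with the removed mass absorbed into H.

    Returns (W, H, objective_trace); the trace of 0.5*||M - WH||_F^2 is
    non-increasing, a property of the multiplicative updates.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_channels, n_samples = matrix.shape
    if not (1 <= k <= min(n_channels, n_samples)):
        raise ValueError(f"k={k} out of range for a {matrix.shape} matrix")
    if (matrix < 0).any():
        raise ValueError("matrix must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = np.sqrt(matrix.mean() / k) if matrix.mean() > 0 else 1.0
    W = rng.uniform(_EPS, 1.0, size=(n_channels, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, n_samples)) * scale

    trace: list[float] = []
    previous = np.inf
    for _ in range(max_iter):
        W *= (matrix @ H.T) / (W @ (H @ H.T) + _EPS)
        H *= (W.T @ matrix) / ((W.T @ W) @ H + _EPS)
        objective = 0.5 * float(np.linalg.norm(matrix - W @ H) ** 2)
        trace.append(objective)
        if previous - objective <= tol * max(objective, 1.0):
            break
        previous = objective
    col_sums = W.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    W = W / col_sums
    H = H * col_sums[:, None]
    return W, H, trace


@dataclass
class ConsensusCluster:
    centroid: np.ndarray
    members: np.ndarray
    mean_within_similarity: float
    stable: bool


def cluster_consensus(
    signature_draws: np.ndarray,
    k: int,
    similarity_threshold: float = 0.8,
) -> list[ConsensusCluster]:
    """Reduce pooled signature draws to k consensus signatures.

    Draws (rows, each a 96-vector) are clustered by average-linkage
    agglomerative clustering under cosine distance and cut at k clusters.
    Each consensus signature is the renormalized centroid; a cluster whose
    mean within-cluster cosine similarity falls below the threshold is
    flagged unstable.
    """
    draws = np.asarray(signature_draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("signature_draws must be 2-D (draws x channels)")
    if len(draws) < k:
        raise ValueError(f"need at least k={k} draws, got {len(draws)}")
    if len(draws) == 1:
        labels = np.array([1])
    else:
        distances = pdist(draws, metric="cosine")
        labels = fcluster(linkage(distances, method="average"), t=k, criterion="maxclust")
    clusters: list[ConsensusCluster] = []
    similarity = 1.0 - squareform(pdist(draws, metric="cosine")) if len(draws) > 1 else np.ones((1, 1))
    for label in sorted(set(labels)):
        members = np.flatnonzero(labels == label)
        centroid = draws[members].mean(axis=0)
        centroid = centroid / centroid.sum()
        if len(members) > 1:
            block = similarity[np.ix_(members, members)]
            mean_sim = float(block[np.triu_indices(len(members), k=1)].mean())
        else:
            mean_sim = 1.0
        clusters.append(
            ConsensusCluster(
                centroid=centroid,
                members=members,
                mean_within_similarity=mean_sim,
                stable=mean_sim >= similarity_threshold,
            )
        )
    return clusters


def silhouette_cosine(draws: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient under cosine distance; 1.0 for one cluster."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        return 1.0
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(draws, labels, metric="cosine"))


@dataclass
class ExtractionResult:
    """Outcome of rank selection over a cohort catalogue matrix."""

    consensus_signatures: list[Signature]
    per_k_stability: dict[int, float]
    per_k_error: dict[int, float]
    chosen_k: int
    unstable_flags: list[bool] = field(default_factory=list)


def extract_signatures(
    matrix: np.ndarray,
    k_range: range | list[int],
    n_bootstraps: int = 20,
    seed: int = 0,
    stability_floor: float = 0.8,
    max_centroid_similarity: float = 0.85,
    similarity_threshold: float = 0.8,
    max_iter: int = 2000,
    tol: float = 1e-9,
    min_cluster_fraction: float = 0.5,
) -> ExtractionResult:
    """Bootstrap-NMF-consensus extraction with silhouette-based rank selection.

    For each candidate rank k, ``n_bootstraps`` multinomial resamples of the
    cohort are factorized and the pooled k * n_bootstraps signature draws are
    clustered to k consensus signatures. Rank stability is the mean
    silhouette of the clustering under cosine distance; reconstruction error
    is the mean relative Frobenius error across bootstraps. The chosen k is
    the largest rank that is stable (silhouette >= ``stability_floor``),
    whose consensus signatures are mutually distinct (pairwise cosine
    similarity <= ``max_centroid_similarity``, guarding against split
    clusters), and whose every cluster recurs across bootstraps (at least
    ``min_cluster_fraction`` * n_bootstraps member draws: a signature that
    appears in only a few resamples is noise, not a reproducible process).
    """
    matrix = np.asarray(matrix, dtype=float)
    if n_bootstraps < 2:
        raise ValueError("need at least 2 bootstraps")
    ks = sorted(set(int(k) for k in k_range))
    rng = np.random.default_rng(seed)
    matrix_norm = np.linalg.norm(matrix)

    per_k_stability: dict[int, float] = {}
    per_k_error: dict[int, float] = {}
    per_k_clusters: dict[int, list[ConsensusCluster]] = {}
    per_k_distinct: dict[int, bool] = {}

    for k in ks:
        draws = []
        errors = []
        for _ in range(n_bootstraps):
            resampled = bootstrap_resample(matrix, rng)
            W, H, _ = nmf_factorize(resampled, k, seed=rng, max_iter=max_iter, tol=tol)
            draws.append(W.T)
            errors.append(float(np.linalg.norm(matrix - W @ H)) / max(matrix_norm, _EPS))
        pooled = np.vstack(draws)
        clusters = cluster_consensus(pooled, k, similarity_threshold)
        labels = np.empty(len(pooled), dtype=int)
        for idx, cluster in enumerate(clusters):
            labels[cluster.members] = idx
        per_k_stability[k] = silhouette_cosine(pooled, labels)
        per_k_error[k] = float(np.mean(errors))
        per_k_clusters[k] = clusters
        centroids = np.array([c.centroid for c in clusters])
        if len(centroids) > 1:
            sims = 1.0 - squareform(pdist(centroids, metric="cosine"))
            off_diag = sims[np.triu_indices(len(centroids), k=1)]
            distinct = bool((off_diag <= max_centroid_similarity).all())
        else:
            distinct = True
        recurrent = all(
            len(c.members) >= min_cluster_fraction * n_bootstraps for c in clusters
        )
        per_k_distinct[k] = distinct and recurrent

    eligible = [k for k in ks if per_k_stability[k] >= stability_floor and per_k_distinct[k]]
    chosen_k = max(eligible) if eligible else min(ks)
    clusters = per_k_clusters[chosen_k]
    consensus = [
        Signature(name=f"consensus_{i + 1}", values=c.centroid)
        for i, c in enumerate(clusters)
    ]
    return ExtractionResult(
        consensus_signatures=consensus,
        per_k_stability=per_k_stability,
        per_k_error=per_k_error,
        chosen_k=chosen_k,
        unstable_flags=[not c.stable for c in clusters],
    )
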