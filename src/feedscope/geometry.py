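"""Population-geometry analyses of behavior-labeled neural activity.

PC embedding of behavior-labeled samples, mean silhouette with a
label-permutation chance distribution, and cross-assay cluster conservation
over co-registered cells (Mahalanobis distances and center distances,
compared by rank-sum).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .datatypes import ClusterEmbedding, CoRegistrationMap, StatResult, TraceMatrix

DEFAULT_KEEP = ("approach", "eat", "rear")


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def embed_pca(
    traces: TraceMatrix,
    labels: np.ndarray,
    keep_labels: tuple[str, ...] = DEFAULT_KEEP,
    n_components: int = 3,
    zscore: bool = True,
    assay: np.ndarray | None = None,
) -> ClusterEmbedding:
    """Project behavior-labeled samples onto the session's top PCs.

    The PCA is fit on *all* session samples (cells as variables); only the
    samples of ``keep_labels`` are retained in the embedding.  Components
    follow the sign convention that the largest-magnitude loading is
    positive.  Traces are z-scored per cell by default.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != traces.n_samples:
        raise ValueError("labels must have one entry per trace sample")
    if traces.n_cells < n_components:
        raise ValueError(
            f"need >= {n_components} cells for {n_components} components, "
            f"got {traces.n_cells}"
        )
    present = set(np.unique(labels))
    missing = [lab for lab in keep_labels if lab not in present]
    if missing:
        raise ValueError(f"no samples for labels {missing}")

    X = _zscore_rows(traces.values) if zscore else traces.values
    X = X.T  # samples x cells
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    # sign convention: largest-magnitude loading of each component positive
    for k in range(n_components):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, k] *= -1.0
    mask = np.isin(labels, keep_labels)
    return ClusterEmbedding(
        coords=scores[mask],
        labels=labels[mask],
        assay=None if assay is None else np.asarray(assay)[mask],
        explained_variance=pca.explained_variance_ratio_,
    )


def concatenate_coregistered(
    traces_a: TraceMatrix,
    traces_b: TraceMatrix,
    coreg: CoRegistrationMap,
) -> tuple[TraceMatrix, np.ndarray]:
    """Concatenate two sessions over their co-registered cells.

    Rows are restricted to mapped cells (in map order, ids taken from
    session A); columns are session A samples followed by session B samples.
    Returns the joint matrix and a per-sample assay tag ("A"/"B").
    """
    if len(coreg) == 0:
        raise ValueError("co-registration map is empty")
    if traces_a.rate != traces_b.rate:
        raise ValueError("sessions must share a sampling rate")
    ids_a = [a for a, _ in coreg.pairs]
    ids_b = [b for _, b in coreg.pairs]
    sub_a = traces_a.subset(ids_a)
    sub_b = traces_b.subset(ids_b)
    joint = np.hstack([sub_a.values, sub_b.values])
    tags = np.array(["A"] * sub_a.n_samples + ["B"] * sub_b.n_samples)
    return TraceMatrix(ids_a, traces_a.rate, joint), tags


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix."""
    sq = (coords**2).sum(1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * coords @ coords.T, 0.0)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2)


def silhouette(embedding: ClusterEmbedding) -> float:
    """Mean silhouette score of the behavior clusters (Euclidean).

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a = mean intra-cluster
    distance and b = the smallest mean distance to another cluster.
    Singleton clusters contribute s = 0 by convention.
    """
    return float(np.mean(silhouette_samples(embedding)))


def silhouette_samples(embedding: ClusterEmbedding) -> np.ndarray:
    return silhouette_samples_from_distances(
        pairwise_distances(embedding.coords), embedding.labels
    )


def silhouette_samples_from_distances(
    d: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Per-sample silhouettes from a precomputed distance matrix."""
    labels = np.asarray(labels)
    uniq, inverse = np.unique(labels, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise ValueError("need >= 2 clusters for a silhouette")
    onehot = np.zeros((labels.size, k))
    onehot[np.arange(labels.size), inverse] = 1.0
    sizes = onehot.sum(axis=0)
    if np.any(sizes < 2):
        warnings.warn("cluster of size 1: its samples score 0 by convention")
    sums = d @ onehot  # (n, k) summed distance to each cluster
    own_size = sizes[inverse]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sums[np.arange(labels.size), inverse] / np.maximum(own_size - 1, 1)
        means = sums / sizes[None, :]
        means[np.arange(labels.size), inverse] = np.inf  # mask own cluster
        b = means.min(axis=1)
        denom = np.maximum(a, b)
        s = np.where(denom > 0, (b - a) / denom, 0.0)
    s[own_size == 1] = 0.0  # singleton-cluster convention
    return s


def chance_silhouette(
    embedding: ClusterEmbedding,
    n_shuffles: int = 1000,
    seed: int = 0,
    method: str = "permute",
) -> dict:
    """Label-shuffle null for the silhouette score.

    ``method='permute'`` permutes the label vector; ``'shift'`` applies a
    random circular shift instead (preserves label run-lengths).  Returns the
    null distribution, the observed score, and its percentile within the
    null.
    """
    rng = np.random.default_rng(seed)
    d = pairwise_distances(embedding.coords)
    observed = float(
        np.mean(silhouette_samples_from_distances(d, embedding.labels))
    )
    null = np.empty(n_shuffles)
    labels = embedding.labels
    for s in range(n_shuffles):
        if method == "permute":
            shuffled = rng.permutation(labels)
        elif method == "shift":
            shuffled = np.roll(labels, int(rng.integers(1, labels.size)))
        else:
            raise ValueError(f"unknown shuffle method {method!r}")
        null[s] = float(np.mean(silhouette_samples_from_distances(d, shuffled)))
    percentile = float(np.mean(null < observed) * 100.0)
    return {"observed": observed, "null": null, "percentile": percentile}


def mahalanobis_cross_assay(
    samples_ref: np.ndarray,
    samples_query: np.ndarray,
    ridge: float = 1e-6,
) -> np.ndarray:
    """Mahalanobis distance of each query point to the reference cluster.

    d_M(y) = sqrt((y - mu)^T Sigma^{-1} (y - mu)) with mu, Sigma the
    reference cluster's mean and sample covariance.  A singular covariance
    is ridge-regularized (Sigma + lambda*I, lambda = ridge * mean diagonal)
    with a warning.
    """
    ref = np.asarray(samples_ref, dtype=float)
    query = np.atleast_2d(np.asarray(samples_query, dtype=float))
    n, p = ref.shape
    if n <= p:
        raise ValueError(
            f"reference cluster needs more samples ({n}) than dimensions ({p})"
        )
    mu = ref.mean(axis=0)
    cov = np.cov(ref, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular reference covariance; applying ridge")
        cov = cov + ridge * np.mean(np.diag(cov)) * np.eye(p)
    delta = query - mu
    sol = np.linalg.solve(cov, delta.T)
    return np.sqrt(np.einsum("ij,ji->i", delta, sol))


def cross_assay_distances(
    X: np.ndarray,
    tags: np.ndarray,
    labels: np.ndarray,
    behavior: str,
    pooled: bool = True,
) -> np.ndarray:
    """Cross-assay Mahalanobis distances for one behavior.

    ``X`` holds one point per sample (samples x dimensions; dimensions are
    co-registered cells or PCs).  Points of ``behavior`` in one assay are
    measured against the other assay's cluster of the same behavior (both
    directions, pooled).
    """
    X = np.asarray(X, dtype=float)
    tags = np.asarray(tags)
    labels = np.asarray(labels)
    mask = labels == behavior
    pts_a = X[mask & (tags == "A")]
    pts_b = X[mask & (tags == "B")]
    d_ab = mahalanobis_cross_assay(pts_a, pts_b)  # B queried against A
    if not pooled:
        return d_ab
    d_ba = mahalanobis_cross_assay(pts_b, pts_a)
    return np.concatenate([d_ab, d_ba])


def center_distance(samples: np.ndarray) -> np.ndarray:
    """Euclidean distance of each sample to the pooled cluster mean."""
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    return np.linalg.norm(samples - samples.mean(axis=0), axis=1)


def conservation_test(
    distances_eat: np.ndarray,
    distances_approach: np.ndarray,
) -> StatResult:
    """Rank-sum comparison of eat vs approach cross-assay distances.

    Smaller distances mean a more conserved representation; the direction
    flag reports which behavior's cluster is tighter across assays.
    """
    de = np.asarray(distances_eat, dtype=float)
    da = np.asarray(distances_approach, dtype=float)
    if de.size == 0 or da.size == 0:
        raise ValueError("both distance sets must be non-empty")
    z, p = stats.ranksums(de, da)
    direction = (
        "eat more conserved"
        if np.median(de) < np.median(da)
        else "approach more conserved"
    )
    return StatResult(
        name="conservation_eat_vs_approach",
        test="wilcoxon_rank_sum",
        statistic=float(z),
        z_value=float(z),
        p_value=float(p),
        n=(de.size, da.size),
        direction=direction,
    )
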