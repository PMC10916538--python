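"""Single-cell embedding pipeline for secretome matrices.

Mirrors the standard scRNA-seq workflow on the 32-plex MFI matrix: outlier
cell filtering, per-cell log normalization, (optional) variable-feature
ranking, PCA, patient batch correction, kNN graph, Leiden community
detection, and a UMAP strictly for visualization — no downstream statistic
consumes UMAP coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import SecretomeMatrix

__all__ = [
    "PipelineConfig",
    "EmbeddingState",
    "filter_outlier_cells",
    "normalize_log",
    "select_variable_features",
    "run_pca",
    "correct_batch",
    "build_knn_graph",
    "cluster_graph",
    "run_umap",
    "knn_mixing_entropy",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the embedding stage.

    outlier_threshold : MFI above which a cell is an outlier (default 3000,
        strict inequality); ``outlier_mode`` decides whether the rule applies
        to any single channel or to the per-cell total.
    scale_factor : global-scaling constant of the log normalization.
    n_variable_features : defaults to the full 32-plex (feature subsetting
        gains little with so few channels; the ranking exists for fidelity
        to the standard workflow).
    n_pcs, knn_k, cluster_resolution, seed : embedding parameters.
    """

    outlier_threshold: float = 3000.0
    outlier_mode: str = "any_channel"  # or "total"
    scale_factor: float = 10_000.0
    n_variable_features: int = 32
    n_pcs: int = 10
    knn_k: int = 20
    cluster_resolution: float = 0.8
    umap_min_dist: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outlier_threshold <= 0:
            raise ValueError("outlier_threshold must be positive")
        if self.outlier_mode not in ("any_channel", "total"):
            raise ValueError("outlier_mode must be 'any_channel' or 'total'")
        if self.knn_k < 2:
            raise ValueError("knn_k must be >= 2")


@dataclass
class EmbeddingState:
    """All per-cell arrays of the embedding stage, on a shared cell index."""

    cell_index: pd.Index
    normalized: pd.DataFrame
    pcs: np.ndarray
    corrected_pcs: np.ndarray
    knn: "object"  # scipy.sparse adjacency
    clusters: pd.Series
    umap: np.ndarray | None
    config: PipelineConfig

    def __post_init__(self) -> None:
        n = len(self.cell_index)
        for name, arr in (("normalized", self.normalized), ("pcs", self.pcs), ("corrected_pcs", self.corrected_pcs)):
            if len(arr) != n:
                raise ValueError(f"{name} does not share the cell index")


def filter_outlier_cells(
    matrix: SecretomeMatrix, config: PipelineConfig | None = None
) -> tuple[SecretomeMatrix, pd.DataFrame]:
    """Remove outlier cells with extreme MFI; returns (filtered, report).

    Under ``any_channel`` (default) a cell is removed iff any single
    cytokine strictly exceeds the threshold; under ``total`` iff the summed
    MFI does. The report lists removed/retained counts per sample.
    Idempotent: filtering a filtered matrix changes nothing.
    """
    config = config or PipelineConfig()
    vals = matrix.values.to_numpy()
    if config.outlier_mode == "any_channel":
        removed = (vals > config.outlier_threshold).any(axis=1)
    else:
        removed = vals.sum(axis=1) > config.outlier_threshold
    report = (
        pd.DataFrame(
            {"sample_id": matrix.cell_meta["sample_id"].to_numpy(), "removed": removed}
        )
        .groupby("sample_id")["removed"]
        .agg(n_removed="sum", n_cells="count")
        .assign(n_retained=lambda d: d["n_cells"] - d["n_removed"])
    )
    filtered = matrix.subset_cells(~removed)
    return filtered, report


def normalize_log(
    matrix: SecretomeMatrix, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Global-scaling log normalization: per cell,
    ``x -> ln(1 + x / cell_total * scale_factor)``.

    Cells with zero total MFI map to all-zero rows (their row is flagged in
    the returned frame's ``attrs["zero_total_cells"]``). Monotone within a
    cell by construction.
    """
    config = config or PipelineConfig()
    vals = matrix.values.to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    zero = totals == 0
    safe = np.where(zero, 1.0, totals)
    out = np.log1p(vals / safe[:, None] * config.scale_factor)
    out[zero] = 0.0
    res = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    res.attrs["zero_total_cells"] = list(matrix.values.index[zero])
    return res


def select_variable_features(normalized: pd.DataFrame, n: int | None = None) -> list[str]:
    """Rank cytokines by standardized variance after a mean-variance trend
    fit and return the top ``n`` (all, when ``n`` is None or the panel size).

    The trend is a quadratic fit of log variance on log mean across the 32
    features; the standardized variance is the observed variance over the
    trend prediction, clipped at 0 for constant features.
    """
    X = normalized.to_numpy()
    means = X.mean(axis=0)
    variances = X.var(axis=0, ddof=1) if len(X) > 1 else np.zeros(X.shape[1])
    eps = 1e-12
    with np.errstate(invalid="ignore"):
        logm = np.log(np.abs(means) + eps)
        logv = np.log(variances + eps)
    usable = (variances > 0) & np.isfinite(logm) & np.isfinite(logv)
    if usable.sum() >= 3 and np.ptp(logm[usable]) > 1e-8:
        coef = np.polyfit(logm[usable], logv[usable], deg=2)
        expected = np.exp(np.clip(np.polyval(coef, logm), -50.0, 50.0))
    else:
        expected = np.ones_like(variances)
    std_var = np.where(variances > 0, variances / np.maximum(expected, eps), 0.0)
    order = np.argsort(-std_var, kind="stable")
    n = normalized.shape[1] if n is None else n
    if n > normalized.shape[1]:
        raise ValueError("cannot select more features than the panel has")
    return [normalized.columns[i] for i in order[:n]]


def run_pca(normalized: pd.DataFrame, n_pcs: int = 10, seed: int = 0) -> np.ndarray:
    """Feature-centered PCA scores with a fixed sign convention (the
    largest-|loading| entry of each component is positive). Requests beyond
    the matrix rank are truncated."""
    X = normalized.to_numpy(dtype=float)
    max_rank = min(X.shape[0], X.shape[1])
    k = min(n_pcs, max_rank)
    pca = PCA(n_components=k, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(X)
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return scores


def correct_batch(
    pcs: np.ndarray,
    batch: pd.Series | np.ndarray,
    seed: int = 0,
    n_clusters: int | None = None,
    theta: float = 1.0,
    sigma: float = 0.1,
    ridge: float = 10.0,
    max_iter: int = 50,
    tol: float = 1e-3,
) -> np.ndarray:
    """Iterative soft-clustering batch correction in PC space.

    Alternates (a) diversity-penalized soft k-means over cells — soft
    assignments are down-weighted for clusters where a cell's batch is
    over-represented relative to the cluster's expected batch mix — with
    (b) per-cluster linear removal of batch-specific centroid offsets.
    Stops when the maximum centroid shift falls below ``tol`` (units of the
    embedding) or after ``max_iter`` rounds.

    With a single batch this is the identity up to numerical tolerance; its
    contract on pure batch-shift data is that kNN batch-mixing entropy
    (:func:`knn_mixing_entropy`) does not decrease.
    """
    Z = np.asarray(pcs, dtype=float).copy()
    batches = pd.Categorical(np.asarray(batch))
    B = len(batches.categories)
    if B < 2:
        return Z
    codes = batches.codes
    n, d = Z.shape
    rng = np.random.default_rng(seed)
    # few, large clusters: offsets are estimated per cluster x batch, and a
    # cluster must hold enough cells of every batch for its offsets to beat
    # the significance gate
    K = n_clusters or max(2, min(10, n // 200))
    K = min(K, n)
    # scale for soft assignment: distances measured relative to data spread
    scale = np.mean(Z.var(axis=0)) + 1e-12
    batch_freq = np.bincount(codes, minlength=B) / n

    centroids = Z[rng.choice(n, size=K, replace=False)]
    onehot = np.zeros((n, B))
    onehot[np.arange(n), codes] = 1.0

    for _ in range(max_iter):
        # cluster in batch-centered coordinates: a residual global shift
        # must not let k-means slice the data along the shift axis, which
        # would absorb the very offset we are trying to estimate
        grand = Z.mean(axis=0)
        batch_means = np.vstack([Z[codes == b].mean(axis=0) for b in range(B)])
        Zc = Z - batch_means[codes] + grand
        d2 = ((Zc[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        logR = -d2 / (2.0 * sigma * scale)
        R_dist = np.exp(logR - logsumexp(logR, axis=1, keepdims=True))
        # diversity penalty: observed vs expected batch mass per cluster;
        # shapes the centroids (clusters are pushed to span batches) but is
        # kept out of the offset estimates — penalty-weighted offsets drag
        # batches apart when their population mix genuinely differs
        O = R_dist.T @ onehot  # K x B
        E = R_dist.sum(axis=0)[:, None] * batch_freq[None, :]
        penalty = ((E + 1.0) / (O + 1.0)) ** theta  # K x B
        R_pen = R_dist * penalty[:, codes].T
        R_pen = R_pen / R_pen.sum(axis=1, keepdims=True)

        centroids = (R_pen.T @ Zc) / (R_pen.sum(axis=0)[:, None] + 1e-12)
        # cluster means in the uncentered space anchor the offsets
        means_z = (R_pen.T @ Z) / (R_pen.sum(axis=0)[:, None] + 1e-12)

        # per-cluster, per-batch offset removal with distance-only weights
        correction = np.zeros_like(Z)
        max_offset = 0.0
        for k in range(K):
            w = R_dist[:, k]
            for b in range(B):
                mask = codes == b
                wb = w[mask]
                tot = wb.sum()
                if tot < 1e-8:
                    continue
                resid = Z[mask] - means_z[k]
                offset = (resid * wb[:, None]).sum(axis=0) / tot
                # significance gate: offsets indistinguishable from
                # within-cluster sampling noise are not corrected — repeated
                # application of noise offsets would random-walk the batches
                # apart instead of aligning them
                var_dim = (wb[:, None] * (resid - offset) ** 2).sum(axis=0) / tot
                se2 = var_dim * (wb**2).sum() / tot**2
                chi2 = float((offset**2 / (se2 + 1e-12)).sum())
                if chi2 < d + 2.0 * np.sqrt(2.0 * d):
                    continue
                # ridge shrinkage: a batch barely represented in a cluster
                # carries no reliable offset and must not be yanked around
                offset = offset * (tot / (tot + ridge))
                correction[mask] += w[mask, None] * offset[None, :]
                max_offset = max(max_offset, float(np.linalg.norm(offset)))
        Z = Z - correction
        if max_offset < tol * np.sqrt(scale):
            break
    return Z


def knn_mixing_entropy(embedding: np.ndarray, batch: pd.Series | np.ndarray, k: int = 20) -> float:
    """Average over cells of the entropy of batch labels among the k nearest
    neighbors; higher means better mixed. Batches with fewer cells than
    ``k`` are excluded from the average (their neighborhoods cannot mix)."""
    batches = pd.Categorical(np.asarray(batch))
    codes = batches.codes
    counts = np.bincount(codes)
    n = len(codes)
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neigh = codes[idx[:, 1:]]
    ok = counts[codes] >= k
    ents = []
    for row in neigh[ok]:
        p = np.bincount(row, minlength=len(counts)) / k
        p = p[p > 0]
        ents.append(float(-(p * np.log(p)).sum()))
    return float(np.mean(ents)) if ents else 0.0


def build_knn_graph(corrected_pcs: np.ndarray, k: int = 20):
    """Undirected kNN adjacency (scipy.sparse, boolean-symmetrized): an edge
    joins i and j iff either lists the other among its k Euclidean nearest
    neighbors. Ties are broken by cell index (stable), self-edges excluded."""
    from scipy import sparse

    X = np.asarray(corrected_pcs, dtype=float)
    n = len(X)
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto").fit(X)
    dist, idx = nn.kneighbors(X)
    rows, cols = [], []
    for i in range(n):
        js = [j for j in idx[i] if j != i][:k]
        rows.extend([i] * len(js))
        cols.extend(js)
    A = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    A = ((A + A.T) > 0).astype(np.int8)
    A.setdiag(0)
    A.eliminate_zeros()
    return A


def cluster_graph(knn, resolution: float = 0.8, seed: int = 0) -> np.ndarray:
    """Leiden community detection on the kNN graph at the given resolution.

    Labels are relabeled by decreasing cluster size (0 = largest) and are
    deterministic given the seed.
    """
    sources, targets = knn.nonzero()
    mask = sources < targets
    g = ig.Graph(
        n=knn.shape[0], edges=list(zip(sources[mask].tolist(), targets[mask].tolist()))
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(part.membership)
    order = np.argsort(-np.bincount(labels), kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    return remap[labels]


def sweep_resolution(
    knn,
    resolutions=(0.05, 0.1, 0.25, 0.5, 0.8, 1.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster at several resolutions and score each partition by standard
    (gamma = 1) Newman modularity on the kNN graph.

    Useful when the number of communities is unknown: coarse, well-separated
    structure maximizes plain modularity, while higher resolutions trade
    modularity for granularity. Returns one row per resolution with the
    label array, cluster count and modularity.
    """
    sources, targets = knn.nonzero()
    mask = sources < targets
    g = ig.Graph(
        n=knn.shape[0], edges=list(zip(sources[mask].tolist(), targets[mask].tolist()))
    )
    records = []
    for r in resolutions:
        labels = cluster_graph(knn, resolution=r, seed=seed)
        records.append(
            {
                "resolution": r,
                "n_clusters": int(labels.max()) + 1,
                "modularity": float(g.modularity(labels.tolist())),
                "labels": labels,
            }
        )
    return pd.DataFrame.from_records(records)


def run_umap(corrected_pcs: np.ndarray, seed: int = 0, min_dist: float = 0.3) -> np.ndarray:
    """2-D UMAP for visualization only; deterministic given the seed."""
    import warnings

    from umap import UMAP

    X = np.asarray(corrected_pcs, dtype=float)
    if len(X) < 10:
        raise ValueError("UMAP needs at least 10 cells")
    n_neighbors = int(min(15, len(X) - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            emb = UMAP(
                n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
            ).fit_transform(X)
        except Exception:
            # degenerate geometry (e.g. identical cells): fall back to random init
            emb = UMAP(
                n_components=2,
                n_neighbors=n_neighbors,
                min_dist=min_dist,
                random_state=seed,
                init="random",
            ).fit_transform(X)
    return np.asarray(emb, dtype=float)


def run_pipeline(
    matrix: SecretomeMatrix,
    config: PipelineConfig | None = None,
    batch_key: str = "patient_id",
    compute_umap: bool = True,
) -> tuple[EmbeddingState, SecretomeMatrix, pd.DataFrame]:
    """Full embedding stage: filter -> normalize -> PCA -> batch correction
    -> kNN -> Leiden (-> UMAP). Returns (state, filtered matrix, filter
    report). Clustering always runs on corrected PCs, never on UMAP."""
    config = config or PipelineConfig()
    filtered, report = filter_outlier_cells(matrix, config)
    normalized = normalize_log(filtered, config)
    feats = select_variable_features(normalized, config.n_variable_features)
    pcs = run_pca(normalized[feats], n_pcs=config.n_pcs, seed=config.seed)
    batch = filtered.cell_meta[batch_key]
    if batch.nunique() > 1:
        corrected = correct_batch(pcs, batch, seed=config.seed)
    else:
        corrected = pcs.copy()
    knn = build_knn_graph(corrected, k=config.knn_k)
    clusters = pd.Series(
        cluster_graph(knn, resolution=config.cluster_resolution, seed=config.seed),
        index=normalized.index,
        name="cluster",
    )
    umap_xy = run_umap(corrected, seed=config.seed, min_dist=config.umap_min_dist) if compute_umap else None
    state = EmbeddingState(
        cell_index=normalized.index,
        normalized=normalized,
        pcs=pcs,
        corrected_pcs=corrected,
        knn=knn,
        clusters=clusters,
        umap=umap_xy,
        config=config,
    )
    return state, filtered, report
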