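"""kNN-neighborhood differential abundance between timepoints.

Implements the Milo-style framework: sample index cells on the kNN graph,
form partially overlapping neighborhoods (index cell plus its k nearest
neighbors), count member cells per sample, test each neighborhood's counts
with a negative-binomial log-linear model (timepoint as the variable of
interest, log total cells per sample as offset), and control FDR with a
distance-weighted Benjamini-Hochberg procedure (spatial FDR). Neighborhoods
are also classified by timepoint exclusivity — composed only of baseline
cells, only of post-treatment cells, or mixed — a label that depends only
on membership, never on the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "NeighborhoodSet",
    "sample_neighborhoods",
    "count_cells",
    "test_da",
    "spatial_fdr",
    "classify_exclusivity",
    "format_pct",
    "exclusivity_summary",
    "beeswarm_export",
    "run_da",
]


@dataclass
class NeighborhoodSet:
    """Partially overlapping kNN neighborhoods.

    membership : sparse bool, neighborhoods x cells (index cell included)
    index_cells : positional indices of the index cell per neighborhood
    distances : kth-NN distance of each index cell (spatial FDR weights)
    cell_index : the cell ids the positional indices refer to
    """

    membership: sparse.csr_matrix
    index_cells: np.ndarray
    distances: np.ndarray
    cell_index: pd.Index

    @property
    def n_neighborhoods(self) -> int:
        return self.membership.shape[0]

    def sizes(self) -> np.ndarray:
        return np.asarray(self.membership.sum(axis=1)).ravel()


def sample_neighborhoods(
    knn: sparse.spmatrix,
    corrected_pcs: np.ndarray,
    cell_index: pd.Index,
    proportion: float = 0.1,
    k: int | None = None,
    seed: int = 0,
) -> NeighborhoodSet:
    """Sample index cells and build their neighborhoods.

    A fraction ``proportion`` of cells is sampled uniformly; each sampled
    cell is refined to the member of its kNN closest to the mean PC position
    of that neighborhood (a density-seeking step that stabilizes the index
    set); refined indices are deduplicated. The neighborhood is the refined
    index cell plus its k nearest neighbors by Euclidean distance in the
    corrected PC space.
    """
    if not (0 < proportion <= 1):
        raise ValueError("proportion must be in (0, 1]")
    X = np.asarray(corrected_pcs, dtype=float)
    n = len(X)
    n_sample = int(np.ceil(proportion * n))
    if n_sample == 0:
        raise ValueError("proportion too small: zero neighborhoods sampled")
    rng = np.random.default_rng(seed)
    sampled = np.sort(rng.choice(n, size=n_sample, replace=False))

    if k is None:
        # infer k from the graph's construction degree
        k = int(np.median(np.asarray(knn.sum(axis=1)).ravel()))
        k = max(k, 2)
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(X)
    dist, idx = nn.kneighbors(X)

    refined = []
    for i in sampled:
        members = idx[i]  # i itself plus its kNN
        centroid = X[members].mean(axis=0)
        d2 = ((X[members] - centroid) ** 2).sum(axis=1)
        refined.append(int(members[int(np.argmin(d2))]))
    index_cells = np.unique(np.asarray(refined))

    rows, cols = [], []
    for h, i in enumerate(index_cells):
        members = idx[i]
        rows.extend([h] * len(members))
        cols.extend(members.tolist())
    membership = sparse.csr_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)),
        shape=(len(index_cells), n),
        dtype=bool,
    )
    distances = dist[index_cells, -1]
    return NeighborhoodSet(
        membership=membership,
        index_cells=index_cells,
        distances=distances,
        cell_index=cell_index,
    )


def count_cells(nhoods: NeighborhoodSet, cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Counts matrix: neighborhoods x samples member-cell tallies."""
    samples = pd.Categorical(cell_meta.loc[nhoods.cell_index, "sample_id"])
    onehot = sparse.csr_matrix(
        (
            np.ones(len(samples), dtype=np.int64),
            (np.arange(len(samples)), samples.codes),
        ),
        shape=(len(samples), len(samples.categories)),
    )
    counts = nhoods.membership.astype(np.int64) @ onehot
    return pd.DataFrame(
        counts.toarray(), columns=list(samples.categories)
    ).rename_axis(index="neighborhood")


def test_da(
    counts: pd.DataFrame,
    design: pd.Series,
    totals: pd.Series | None = None,
    shrinkage: float = 0.5,
) -> pd.DataFrame:
    """Per-neighborhood overdispersed count test of the timepoint effect.

    Model: ``count[n, s]`` follows a negative-binomial log-linear model
    ``log mu = b0 + b1 * [s is post] + log N_s`` where ``N_s`` is the total
    cells of sample ``s``. The timepoint coefficient is the closed-form
    two-group log rate ratio (the exact GLM MLE for a saturated binary
    design with offsets), reported on the natural-log scale as
    ``log_fold_change`` (post vs baseline). The per-neighborhood dispersion
    is estimated by the method of moments — the Pearson scale
    ``phi = X^2 / (S - 2)``, i.e. the NB variance inflation ``1 + alpha*mu``
    evaluated at the fitted means — and shrunk toward the cross-neighborhood
    median with weight ``shrinkage``. The Wald statistic divides the log
    rate ratio by its delta-method standard error ``sqrt(phi * (1/T_base +
    1/T_post))`` and is referred to the standard normal.

    ``design`` maps sample_id -> timepoint ("baseline"/"post_IO").
    All-zero neighborhoods are flagged untestable (missing p); a
    neighborhood empty in one arm gets a 0.5 continuity correction on both
    group totals (flag ``zero_group``).
    """
    samples = counts.columns
    design = design.loc[samples]
    is_post = (design == "post_IO").to_numpy()
    if is_post.sum() < 2 or (~is_post).sum() < 2:
        raise ValueError("need at least 2 samples per timepoint")
    Y = counts.to_numpy(dtype=float)
    if totals is None:
        totals = counts.sum(axis=0)
    N = totals.loc[samples].to_numpy(dtype=float)
    S = len(samples)

    T_base = Y[:, ~is_post].sum(axis=1)
    T_post = Y[:, is_post].sum(axis=1)
    M_base = N[~is_post].sum()
    M_post = N[is_post].sum()

    all_zero = (T_base + T_post) == 0
    zero_group = ((T_base == 0) | (T_post == 0)) & ~all_zero
    cb = np.where(zero_group, 0.5, 0.0)
    rate_base = (T_base + cb) / M_base
    rate_post = (T_post + cb) / M_post
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log(rate_post) - np.log(rate_base)

    # fitted means and moment dispersion (Pearson scale)
    mu = np.where(is_post[None, :], rate_post[:, None], rate_base[:, None]) * N[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        x2 = (((Y - mu) ** 2) / np.maximum(mu, 1e-12)).sum(axis=1)
    phi_raw = x2 / max(S - 2, 1)
    testable = ~all_zero
    phi_med = float(np.median(phi_raw[testable])) if testable.any() else 1.0
    phi = (phi_raw + shrinkage * phi_med) / (1.0 + shrinkage)
    phi = np.maximum(phi, 1e-6)

    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = phi * (
            1.0 / np.maximum(T_base + cb, 1e-12) + 1.0 / np.maximum(T_post + cb, 1e-12)
        )
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    out = pd.DataFrame(
        {
            "log_fold_change": lfc,
            "se": se,
            "statistic": z,
            "p_value": p,
            "dispersion": phi,
            "n_cells": (T_base + T_post).astype(int),
            "flag": np.where(all_zero, "untestable", np.where(zero_group, "zero_group", "")),
        },
        index=counts.index,
    )
    out.loc[all_zero, ["log_fold_change", "se", "statistic", "p_value"]] = np.nan
    return out


def spatial_fdr(p_values: np.ndarray | pd.Series, distances: np.ndarray | pd.Series) -> np.ndarray:
    """Distance-weighted Benjamini-Hochberg adjustment over neighborhoods.

    Weights are the reciprocal kth-NN distance of each neighborhood's index
    cell (dense regions, which spawn many overlapping neighborhoods, are
    down-weighted less individually but share the multiplicity burden).
    With equal distances this reduces exactly to plain BH. Zero distances
    get their weight capped at the largest finite weight (or 1 when all
    distances are zero). Missing p-values propagate as missing.
    """
    p = np.asarray(p_values, dtype=float)
    d = np.asarray(distances, dtype=float)
    if p.shape != d.shape:
        raise ValueError("p_values and distances must align")
    adjusted = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if not ok.any():
        return adjusted
    p_ok, d_ok = p[ok], d[ok]
    with np.errstate(divide="ignore"):
        w = 1.0 / d_ok
    finite = np.isfinite(w)
    cap = w[finite].max() if finite.any() else 1.0
    w = np.where(np.isfinite(w), w, cap)

    order = np.argsort(p_ok, kind="stable")
    w_sorted = w[order]
    p_sorted = p_ok[order]
    cum_w = np.cumsum(w_sorted)
    q = p_sorted * w.sum() / cum_w
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty_like(q)
    out[order] = q
    adjusted[ok] = out
    return adjusted


def classify_exclusivity(nhoods: NeighborhoodSet, cell_meta: pd.DataFrame) -> pd.Series:
    """Label each neighborhood baseline_only / post_only / mixed by the
    timepoints of its member cells. Depends only on membership."""
    tp = cell_meta.loc[nhoods.cell_index, "timepoint"].to_numpy()
    is_post = (tp == "post_IO").astype(np.int64)
    n_post = nhoods.membership.astype(np.int64) @ is_post
    sizes = nhoods.sizes()
    labels = np.where(n_post == 0, "baseline_only", np.where(n_post == sizes, "post_only", "mixed"))
    return pd.Series(labels, index=pd.RangeIndex(nhoods.n_neighborhoods, name="neighborhood"))


def format_pct(x: float) -> str:
    """Percentages to one decimal, or two decimals below 1%."""
    return f"{x:.2f}" if x < 1 else f"{x:.1f}"


def exclusivity_summary(
    exclusivity: pd.Series, fdr: np.ndarray | pd.Series | None = None, fdr_threshold: float = 0.1
) -> dict:
    """Counts and percentages of each exclusivity class over *all*
    neighborhoods, plus (when FDR values are given) the same counts
    restricted to neighborhoods significant at ``fdr_threshold``."""
    total = int(len(exclusivity))
    counts = exclusivity.value_counts().to_dict()
    summary = {"total": total}
    for cls in ("baseline_only", "post_only", "mixed"):
        c = int(counts.get(cls, 0))
        pct = 100.0 * c / total if total else float("nan")
        summary[cls] = {"count": c, "pct": pct, "pct_str": format_pct(pct) if total else ""}
    if fdr is not None:
        sig = np.asarray(fdr, dtype=float) < fdr_threshold
        sub = exclusivity[sig]
        summary["fdr_restricted"] = {
            "threshold": fdr_threshold,
            "total": int(sig.sum()),
            **{cls: int((sub == cls).sum()) for cls in ("baseline_only", "post_only", "mixed")},
        }
    return summary


def beeswarm_export(
    da_result: pd.DataFrame,
    nhoods: NeighborhoodSet,
    clusters: pd.Series,
    exclusivity: pd.Series,
) -> pd.DataFrame:
    """Long-format neighborhood table for beeswarm plotting: cluster of the
    index cell, log fold-change, spatial FDR, exclusivity. Pure joins."""
    idx_cells = nhoods.cell_index[nhoods.index_cells]
    out = pd.DataFrame(
        {
            "neighborhood": np.arange(nhoods.n_neighborhoods),
            "index_cell": idx_cells,
            "cluster": clusters.loc[idx_cells].to_numpy(),
            "log_fold_change": da_result["log_fold_change"].to_numpy(),
            "spatial_fdr": da_result["spatial_fdr"].to_numpy()
            if "spatial_fdr" in da_result
            else np.nan,
            "exclusivity": exclusivity.to_numpy(),
        }
    )
    return out


def run_da(
    state,
    cell_meta: pd.DataFrame,
    proportion: float = 0.1,
    k: int | None = None,
    seed: int = 0,
    fdr_threshold: float = 0.1,
) -> tuple[pd.DataFrame, NeighborhoodSet, dict]:
    """Convenience wrapper: neighborhoods -> counts -> NB tests -> spatial
    FDR -> exclusivity, given an EmbeddingState and cell metadata."""
    nhoods = sample_neighborhoods(
        state.knn, state.corrected_pcs, state.cell_index, proportion=proportion, k=k, seed=seed
    )
    counts = count_cells(nhoods, cell_meta)
    design = (
        cell_meta.drop_duplicates("sample_id").set_index("sample_id")["timepoint"]
    )
    result = test_da(counts, design)
    result["spatial_fdr"] = spatial_fdr(result["p_value"], nhoods.distances)
    exclusivity = classify_exclusivity(nhoods, cell_meta)
    result["exclusivity"] = exclusivity.to_numpy()
    summary = exclusivity_summary(exclusivity, result["spatial_fdr"], fdr_threshold)
    return result, nhoods, summary
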