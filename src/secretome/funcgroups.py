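"""De novo polyfunctional groups from cluster-level cytokine signatures.

Embedding clusters are summarized by their mean normalized MFI per cytokine,
the cluster x cytokine signature matrix is hierarchically clustered (Ward
linkage on Euclidean distance) and the cluster dendrogram is cut into
k_groups branches — the de novo polyfunctional groups (e.g. CD4-G1..G5).
Each group's signature cytokines are the cytokines whose group-mean
standardized score exceeds a threshold. Per-sample group proportions are
then contrasted between response arms (CR vs NR) per tissue at baseline
with rank-sum tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .psi import _bh

__all__ = [
    "ClusterSignature",
    "GroupAssignment",
    "cluster_centroids",
    "derive_groups",
    "group_proportions",
    "compare_response",
]


@dataclass
class ClusterSignature:
    """Cluster x cytokine mean normalized MFI, plus standardized scores and
    the two Ward dendrograms."""

    matrix: pd.DataFrame  # clusters x cytokines, raw means
    zscores: pd.DataFrame  # same shape, standardized per cytokine
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    sizes: pd.Series | None = None  # cells per cluster
    within_sd: pd.Series | None = None  # pooled within-cluster SD per cytokine
    small_clusters: tuple[int, ...] = ()


@dataclass
class GroupAssignment:
    """Mapping from embedding clusters to derived polyfunctional groups."""

    group_of_cluster: pd.Series  # cluster -> group label "G1".."Gk"
    signatures: dict[str, tuple[str, ...]]  # group -> signature cytokines
    zscores: pd.DataFrame  # group x cytokine mean standardized score

    @property
    def groups(self) -> list[str]:
        return sorted(self.signatures, key=lambda g: int(g[1:]))


def cluster_centroids(
    clusters: pd.Series,
    normalized: pd.DataFrame,
    sd_floor_frac: float = 0.2,
) -> ClusterSignature:
    """Per-cluster mean normalized MFI with per-cytokine standardization.

    Standardized scores are ``(centroid - mean) / max(between-cluster SD,
    sd_floor_frac * pooled within-cluster SD)``: with few clusters the plain
    between-cluster SD is a standard error and would amplify noise for
    cytokines that do not differ between clusters, so the denominator is
    floored at a fraction of the within-cluster spread. A single cluster
    yields all-zero scores by convention. Clusters with < 2 cells are
    flagged but still summarized.
    """
    clusters = clusters.loc[normalized.index]
    centroids = normalized.groupby(clusters).mean()
    centroids.index.name = "cluster"
    sizes = clusters.value_counts().reindex(centroids.index)
    small = tuple(int(c) for c in sizes[sizes < 2].index)

    within_var = normalized.sub(centroids.loc[clusters].to_numpy()) ** 2
    pooled_within = np.sqrt(within_var.mean(axis=0))
    if len(centroids) == 1:
        z = centroids * 0.0
    else:
        between_sd = centroids.std(axis=0, ddof=1)
        denom = np.maximum(between_sd, sd_floor_frac * pooled_within)
        denom = denom.replace(0.0, 1.0)
        z = centroids.sub(centroids.mean(axis=0), axis=1).div(denom, axis=1)

    row_link = linkage(z.to_numpy(), method="ward") if len(centroids) > 1 else np.empty((0, 4))
    col_link = linkage(z.to_numpy().T, method="ward") if z.shape[1] > 1 else np.empty((0, 4))
    return ClusterSignature(
        matrix=centroids, zscores=z, row_linkage=row_link, col_linkage=col_link,
        sizes=sizes, within_sd=pooled_within, small_clusters=small,
    )


def derive_groups(
    signature: ClusterSignature,
    k_groups: int,
    z_threshold: float = 0.5,
) -> GroupAssignment:
    """Cut the cluster dendrogram into ``k_groups`` branches.

    Groups are labeled G1..Gk in order of their smallest member cluster id
    (deterministic, invariant to dendrogram internals). A group's signature
    cytokines are those whose group-mean standardized score exceeds
    ``z_threshold`` and whose group-mean excess over the cross-cluster mean
    exceeds 4 standard errors of that group mean — the second condition
    keeps sampling noise out of the signature when clusters are small.
    """
    n_clusters = len(signature.matrix)
    if k_groups > n_clusters:
        raise ValueError(f"k_groups={k_groups} exceeds the {n_clusters} clusters")
    if k_groups == n_clusters or n_clusters == 1:
        branch = np.arange(n_clusters) + 1
    else:
        branch = fcluster(signature.row_linkage, t=k_groups, criterion="maxclust")

    clusters = signature.matrix.index.to_numpy()
    # deterministic relabeling: groups ordered by smallest member cluster
    first_cluster = {}
    for c, b in zip(clusters, branch):
        first_cluster.setdefault(b, c)
    ordered = sorted(first_cluster, key=lambda b: first_cluster[b])
    label_of_branch = {b: f"G{i + 1}" for i, b in enumerate(ordered)}
    labels = pd.Series(
        [label_of_branch[b] for b in branch], index=signature.matrix.index, name="group"
    )

    group_z = signature.zscores.groupby(labels).mean()
    group_diff = (
        signature.matrix.sub(signature.matrix.mean(axis=0), axis=1).groupby(labels).mean()
    )
    if signature.sizes is not None and signature.within_sd is not None:
        group_n = signature.sizes.groupby(labels).sum()
        se = pd.DataFrame(
            np.outer(1.0 / np.sqrt(group_n.to_numpy()), signature.within_sd.to_numpy()),
            index=group_n.index,
            columns=signature.within_sd.index,
        )
        noise_ok = group_diff > 4.0 * se
    else:
        noise_ok = group_diff.notna()
    keep = (group_z > z_threshold) & noise_ok
    signatures = {
        g: tuple(c for c in group_z.columns if keep.loc[g, c]) for g in group_z.index
    }
    return GroupAssignment(group_of_cluster=labels, signatures=signatures, zscores=group_z)


def group_proportions(
    assignment: GroupAssignment,
    clusters: pd.Series,
    cell_meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample fractions of cells in each derived group (rows sum to 1).

    Samples without cells are omitted (there is nothing to normalize)."""
    groups = clusters.map(assignment.group_of_cluster)
    df = pd.DataFrame(
        {"sample_id": cell_meta.loc[clusters.index, "sample_id"].to_numpy(), "group": groups.to_numpy()}
    )
    counts = pd.crosstab(df["sample_id"], df["group"])
    for g in assignment.groups:
        if g not in counts.columns:
            counts[g] = 0
    counts = counts[assignment.groups]
    return counts.div(counts.sum(axis=1), axis=0)


def compare_response(
    proportions: pd.DataFrame,
    sample_table: pd.DataFrame,
    tissue: str,
    timepoint: str = "baseline",
    test: str = "ranksum",
) -> pd.DataFrame:
    """CR-vs-NR comparison of derived-group proportions in one tissue.

    Two-sided rank-sum (Mann-Whitney) test per group on per-sample
    proportions at the given timepoint; ``test="signed_rank"`` switches to
    the paired signed-rank variant (pairing CR/NR is rarely meaningful, but
    the option exists for matched designs). Raw p and BH q are both
    reported; strata with fewer than 2 samples per arm are flagged.
    """
    meta = sample_table.loc[proportions.index]
    keep = (meta["tissue"] == tissue) & (meta["timepoint"] == timepoint)
    sub = proportions[keep]
    resp = meta.loc[keep, "response"]
    records = []
    for g in proportions.columns:
        a = sub.loc[resp == "CR", g].dropna()
        b = sub.loc[resp == "NR", g].dropna()
        rec = {
            "group": g,
            "tissue": tissue,
            "timepoint": timepoint,
            "n_CR": len(a),
            "n_NR": len(b),
            "median_CR": float(a.median()) if len(a) else np.nan,
            "median_NR": float(b.median()) if len(b) else np.nan,
            "p_value": np.nan,
            "flag": "",
        }
        if len(a) < 2 or len(b) < 2:
            rec["flag"] = "untestable"
        elif test == "signed_rank":
            n = min(len(a), len(b))
            diff = a.iloc[:n].to_numpy() - b.iloc[:n].to_numpy()
            if np.allclose(diff, 0):
                rec["p_value"], rec["flag"] = 1.0, "degenerate"
            else:
                rec["p_value"] = float(stats.wilcoxon(diff).pvalue)
        else:
            if a.nunique() <= 1 and b.nunique() <= 1 and len(a) and len(b) and a.iloc[0] == b.iloc[0]:
                rec["p_value"], rec["flag"] = 1.0, "degenerate"
            else:
                rec["p_value"] = float(
                    stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
                )
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    out["q_value"] = _bh(out["p_value"])
    out["direction"] = np.where(out["median_CR"] > out["median_NR"], "CR>NR", "NR>CR")
    return out
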