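"""Planted-truth benchmark suite.

Each benchmark builds a synthetic cohort with known ground truth, runs the
relevant pipeline stage, and measures how well the truth is recovered:

* ``psi_bruteforce_check`` — PSI vectorized implementation vs an
  independent nested-loop reference on random small instances.
* ``outlier_filter_check`` — the >3,000-MFI cell filter vs planted outliers.
* ``clustering_recovery`` — Leiden on three separable populations vs truth.
* ``da_recovery`` — neighborhood differential abundance vs a planted
  4-fold post-treatment abundance shift.
* ``da_null_calibration`` — type-I error of the neighborhood test under
  permuted timepoint labels.
* ``signature_recovery`` / ``response_power`` — de novo functional-group
  discovery of a planted IFNγ/TNFα/MIP-1β/IL8 cosecreting population and
  the CR-vs-NR proportion test with a BM-restricted planted enrichment.

Recovery benchmarks that target planted coarse structure run the clustering
at a coarse resolution (0.1) and without patient batch noise, so the planted
partition is the dominant signal; the calibration benchmark keeps the
generator's default patient effects. Problem sizes are chosen to finish in
minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .diffabund import (
    classify_exclusivity,
    count_cells,
    sample_neighborhoods,
    spatial_fdr,
    test_da,
)
from .funcgroups import cluster_centroids, compare_response, derive_groups, group_proportions
from .io import SecretomeMatrix
from .panel import default_panel
from .psi import call_secretion, compute_psi
from .scpipeline import PipelineConfig, filter_outlier_cells, run_pipeline
from .synthetic import (
    CohortDesign,
    Population,
    SecretionModel,
    plant_da_shift,
    plant_response_effect,
    simulate_cohort,
)

QUAD_SIGNATURE = ("IFNγ", "TNFα", "MIP-1β", "IL8")

__all__ = [
    "QUAD_SIGNATURE",
    "psi_reference",
    "psi_bruteforce_check",
    "outlier_filter_check",
    "clustering_recovery",
    "da_recovery",
    "da_null_calibration",
    "signature_recovery",
    "response_power",
    "three_population_model",
]


# -- model builders ----------------------------------------------------


def three_population_model(
    quad_weight: float = 0.10,
    background_prob: float = 0.2,
    signature_prob: float = 0.9,
    batch_effect_sd: float = 0.0,
    outlier_fraction: float = 0.0,
) -> SecretionModel:
    """Three subpopulations with disjoint cosecretion signatures: the
    response-associated quad (IFNγ/TNFα/MIP-1β/IL8), a cytotoxic population
    and a regulatory-leaning population. The background secretion keeps the
    per-cell geometry high-dimensional so patients interleave."""
    rest = (1.0 - quad_weight) / 2.0
    pops = [
        Population("quad", quad_weight, {c: signature_prob for c in QUAD_SIGNATURE}, default_prob=background_prob),
        Population(
            "cytotoxic", rest,
            {"Granzyme B": signature_prob, "Perforin": signature_prob, "sCD137": signature_prob},
            default_prob=background_prob,
        ),
        Population(
            "regulatory_like", rest,
            {"IL4": signature_prob, "IL10": signature_prob, "IL13": signature_prob},
            default_prob=background_prob,
        ),
    ]
    return SecretionModel(
        pops, batch_effect_sd=batch_effect_sd, outlier_fraction=outlier_fraction
    )


# -- PSI brute force ---------------------------------------------------


def psi_reference(matrix: SecretomeMatrix, thresholds: float = 0.0) -> pd.DataFrame:
    """Independent nested-loop PSI computation (the oracle): plain Python
    loops over cells and cytokines, following the definition literally."""
    panel = matrix.panel
    groups = {g: set(members) for g, members in panel.groups.items()}
    groups["overall"] = set(matrix.cytokines)
    rows = []
    cell_table = matrix.cell_meta
    for (sample_id, subset), idx in cell_table.groupby(["sample_id", "subset"]).groups.items():
        cells = matrix.values.loc[idx]
        poly_cells = []
        for cid, row in cells.iterrows():
            n_pos = sum(1 for c in matrix.cytokines if row[c] > thresholds)
            if n_pos >= 2:
                poly_cells.append(cid)
        n_cells = len(cells)
        for gname, members in groups.items():
            total = 0.0
            for cid in poly_cells:
                for c in matrix.cytokines:
                    if c in members and matrix.values.at[cid, c] > thresholds:
                        total += matrix.values.at[cid, c]
            pct = 100.0 * len(poly_cells) / n_cells
            rows.append(
                {
                    "sample_id": sample_id,
                    "subset": subset,
                    "group": gname,
                    "polyfunctional_pct": pct,
                    "mfi_sum": total,
                    "psi": pct * total,
                }
            )
    return pd.DataFrame(rows)


def psi_bruteforce_check(seed: int, n_instances: int = 1000) -> dict:
    """Largest relative PSI difference between the vectorized implementation
    and the nested-loop reference over random small instances (<= 20 cells,
    a 5-cytokine slice of the panel with random sparse MFI)."""
    rng = np.random.default_rng(seed)
    panel = default_panel()
    max_diff = 0.0
    for _ in range(n_instances):
        n_cells = int(rng.integers(1, 21))
        values = np.where(
            rng.random((n_cells, 32)) < 0.25, rng.gamma(2.0, 50.0, (n_cells, 32)), 0.0
        )
        # confine signal to 5 random cytokines so instances stay tiny
        keep = rng.choice(32, size=5, replace=False)
        mask = np.zeros(32, dtype=bool)
        mask[keep] = True
        values[:, ~mask] = 0.0
        index = pd.Index([f"c{i}" for i in range(n_cells)], name="cell_id")
        cell_meta = pd.DataFrame(
            {
                "sample_id": "s1",
                "patient_id": "P01",
                "tissue": "PB",
                "timepoint": "baseline",
                "subset": "CD4",
            },
            index=index,
        )
        sample_meta = pd.DataFrame(
            {"patient_id": ["P01"], "response": ["CR"], "age": [60.0],
             "prior_HSCT": [False], "secondary_AML": [False]},
            index=pd.Index(["s1"], name="sample_id"),
        )
        m = SecretomeMatrix(
            values=pd.DataFrame(values, index=index, columns=list(panel.cytokines)),
            cell_meta=cell_meta,
            sample_meta=sample_meta,
            panel=panel,
        )
        fast = compute_psi(m, call_secretion(m, 0.0))
        slow = psi_reference(m, 0.0)
        merged = fast.merge(slow, on=["sample_id", "subset", "group"], suffixes=("", "_ref"))
        scale = np.maximum(merged["psi_ref"].abs(), 1.0)
        diff = float(((merged["psi"] - merged["psi_ref"]).abs() / scale).max())
        max_diff = max(max_diff, diff)
    # relative to the reference; nonzero only through float summation order
    return {"max_rel_diff": max_diff, "n": n_instances}


# -- outlier filter ----------------------------------------------------


def outlier_filter_check(seed: int, n_cells: int = 10_000) -> dict:
    """Simulate a cohort with ~1% planted single-channel outliers above the
    3,000-MFI gate and compare the filter's removals with the planted truth."""
    model = three_population_model(batch_effect_sd=0.25, outlier_fraction=0.01)
    per_sample = max(1, n_cells // 10)
    design = CohortDesign(
        n_patients=5, n_CR=2, cells_per_sample=per_sample, subsets=("CD4", "CD8"),
        availability={("PB", "baseline"): 5},
    )
    matrix, truth = simulate_cohort(design, model, seed=seed)
    filtered, report = filter_outlier_cells(matrix, PipelineConfig())
    removed = set(matrix.values.index) - set(filtered.values.index)
    planted = set(truth.index[truth["is_outlier"]])
    return {
        "n_cells": matrix.n_cells,
        "n_removed": len(removed),
        "n_planted": len(planted),
        "n_mismatch": len(removed ^ planted),
    }


# -- clustering recovery ----------------------------------------------


def clustering_recovery(seed: int, cells_per_sample: int = 500) -> dict:
    """ARI of Leiden clustering (coarse resolution) against three planted
    well-separated populations."""
    pops = [
        Population("quad", 0.34, {c: 1.0 for c in QUAD_SIGNATURE}, default_prob=0.0),
        Population("cytotoxic", 0.33, {"Granzyme B": 1.0, "Perforin": 1.0, "sCD137": 1.0}, default_prob=0.0),
        Population("regulatory_like", 0.33, {"IL4": 1.0, "IL10": 1.0, "IL13": 1.0}, default_prob=0.0),
    ]
    model = SecretionModel(pops, batch_effect_sd=0.0, outlier_fraction=0.0)
    design = CohortDesign(
        n_patients=4, n_CR=2, cells_per_sample=cells_per_sample, subsets=("CD4",),
        availability={("BM", "baseline"): 4},
    )
    matrix, truth = simulate_cohort(design, model, seed=seed)
    config = PipelineConfig(seed=seed % (2**31), knn_k=15, cluster_resolution=0.1)
    state, _, _ = run_pipeline(matrix, config, compute_umap=False)
    ari = adjusted_rand_score(truth.loc[state.cell_index, "population"], state.clusters)
    return {"ari": float(ari), "n_clusters": int(state.clusters.nunique()), "n": len(state.cell_index)}


# -- differential abundance -------------------------------------------


def _da_cohort(seed: int, fold_change: float | None, cells_per_sample: int = 1000):
    model = three_population_model(batch_effect_sd=0.0 if fold_change else 0.25)
    if fold_change:
        model = plant_da_shift(model, "quad", fold_change)
    design = CohortDesign(
        n_patients=6, n_CR=3, cells_per_sample=cells_per_sample, subsets=("CD4",),
        availability={("BM", "baseline"): 6, ("BM", "post_IO"): 6},
    )
    matrix, truth = simulate_cohort(design, model, seed=seed)
    config = PipelineConfig(seed=seed % (2**31), knn_k=75)
    state, filtered, _ = run_pipeline(matrix, config, compute_umap=False)
    nhoods = sample_neighborhoods(
        state.knn, state.corrected_pcs, state.cell_index, proportion=0.1, k=75,
        seed=seed % (2**31),
    )
    counts = count_cells(nhoods, filtered.cell_meta)
    design_s = filtered.cell_meta.drop_duplicates("sample_id").set_index("sample_id")["timepoint"]
    return model, truth, state, filtered, nhoods, counts, design_s


def da_recovery(seed: int, fold_change: float = 4.0, cells_per_sample: int = 1000) -> dict:
    """Plant a post-treatment abundance shift in the quad population
    (6 samples per timepoint, ~1,000 cells each) and measure the median
    estimated neighborhood log fold-change over in-population neighborhoods
    plus the fraction significant at spatial FDR < 0.1."""
    model, truth, state, filtered, nhoods, counts, design_s = _da_cohort(
        seed, fold_change, cells_per_sample
    )
    result = test_da(counts, design_s)
    result["spatial_fdr"] = spatial_fdr(result["p_value"], nhoods.distances)
    in_quad = (truth.loc[state.cell_index, "population"] == "quad").to_numpy().astype(float)
    member_frac = (nhoods.membership.astype(float) @ in_quad) / nhoods.sizes()
    inpop = member_frac > 0.5
    return {
        "median_lfc": float(np.nanmedian(result["log_fold_change"][inpop])),
        "planted_lfc": float(model.planted["da_shift"]["log_fold_change"]),
        "target_lfc": float(np.log(fold_change)),
        "frac_significant": float((result["spatial_fdr"][inpop] < 0.1).mean()),
        "n_neighborhoods": int(nhoods.n_neighborhoods),
        "n_inpop": int(inpop.sum()),
    }


def da_null_calibration(seed: int, n_reps: int = 100, cells_per_sample: int = 1000) -> dict:
    """Type-I error of the neighborhood test at alpha = 0.05 under random
    permutations of the sample timepoint labels (no planted shift; the
    generator's default patient batch effects stay on)."""
    _, _, state, filtered, nhoods, counts, design_s = _da_cohort(seed, None, cells_per_sample)
    rng = np.random.default_rng(seed)
    rates = []
    for _ in range(n_reps):
        perm = pd.Series(rng.permutation(design_s.to_numpy()), index=design_s.index)
        res = test_da(counts, perm)
        rates.append(float((res["p_value"] < 0.05).mean()))
    return {
        "type_i_error": float(np.mean(rates)),
        "n_reps": n_reps,
        "n_neighborhoods": int(nhoods.n_neighborhoods),
    }


# -- functional groups -------------------------------------------------


def signature_recovery(seed: int, cells_per_sample: int = 600) -> dict:
    """Whether the derived functional group covering the planted quad
    population has exactly the four planted signature cytokines."""
    model = three_population_model()
    design = CohortDesign(
        n_patients=8, n_CR=4, cells_per_sample=cells_per_sample, subsets=("CD4",),
        availability={("BM", "baseline"): 8},
    )
    matrix, truth = simulate_cohort(design, model, seed=seed)
    config = PipelineConfig(seed=seed % (2**31), knn_k=15, cluster_resolution=0.4)
    state, filtered, _ = run_pipeline(matrix, config, compute_umap=False)
    signature = cluster_centroids(state.clusters, state.normalized)
    assignment = derive_groups(signature, min(3, len(signature.matrix)))
    exact = any(set(sig) == set(QUAD_SIGNATURE) for sig in assignment.signatures.values())
    return {
        "exact_match": bool(exact),
        "signatures": {g: list(sig) for g, sig in assignment.signatures.items()},
        "n_clusters": int(state.clusters.nunique()),
    }


def _response_seed(seed: int) -> tuple[float, float]:
    """One seed of the response-effect benchmark: returns (BM p, PB p) for
    the derived group matching the planted quad signature."""
    model = plant_response_effect(three_population_model(), "quad", 0.20, "CR", "BM")
    design = CohortDesign(
        n_patients=16, n_CR=8, cells_per_sample=150, subsets=("CD4",),
        availability={("PB", "baseline"): 16, ("BM", "baseline"): 16},
    )
    matrix, _ = simulate_cohort(design, model, seed=seed)
    config = PipelineConfig(seed=seed % (2**31), knn_k=15)
    state, filtered, _ = run_pipeline(matrix, config, compute_umap=False)
    signature = cluster_centroids(state.clusters, state.normalized)
    assignment = derive_groups(signature, min(3, len(signature.matrix)))
    overlap = {
        g: len(set(sig) & set(QUAD_SIGNATURE)) for g, sig in assignment.signatures.items()
    }
    quad_group = max(overlap, key=overlap.get)
    props = group_proportions(assignment, state.clusters, filtered.cell_meta)
    sample_table = filtered.sample_table()
    p_bm = compare_response(props, sample_table, tissue="BM")
    p_pb = compare_response(props, sample_table, tissue="PB")
    return (
        float(p_bm.loc[p_bm["group"] == quad_group, "p_value"].iloc[0]),
        float(p_pb.loc[p_pb["group"] == quad_group, "p_value"].iloc[0]),
    )


def response_power(seed: int, n_seeds: int = 100) -> dict:
    """Monte-Carlo power of the CR-vs-NR rank-sum test on derived-group
    proportions under a BM-restricted planted enrichment (CR BM weight 0.30
    vs NR BM 0.10, 8 vs 8 samples): fraction of seeds with a significant BM
    comparison, a null PB comparison, and both at once."""
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    bm_sig, pb_null, joint = [], [], []
    for sd in sub_seeds:
        p_bm, p_pb = _response_seed(int(sd))
        bm_sig.append(p_bm < 0.05)
        pb_null.append(p_pb >= 0.05)
        joint.append(p_bm < 0.05 and p_pb >= 0.05)
    return {
        "bm_significant_frac": float(np.mean(bm_sig)),
        "pb_null_frac": float(np.mean(pb_null)),
        "joint_frac": float(np.mean(joint)),
        "n_seeds": n_seeds,
    }
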