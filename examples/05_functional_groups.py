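"""De novo polyfunctional groups and response association.

Clusters cells, summarizes each cluster by its mean normalized cytokine
profile, cuts the Ward dendrogram of cluster signatures into k groups,
then asks whether any derived group's per-sample abundance differs between
complete responders (CR) and nonresponders (NR) — with the enrichment
planted only in bone marrow (BM), so peripheral blood (PB) stays null.
"""

from secretome import (
    PipelineConfig,
    cluster_centroids,
    compare_response,
    derive_groups,
    group_proportions,
    run_pipeline,
)
from secretome.benchmarks import three_population_model
from secretome.synthetic import CohortDesign, plant_response_effect, simulate_cohort

model = plant_response_effect(three_population_model(), "quad", 0.20, "CR", "BM")
design = CohortDesign(
    n_patients=16, n_CR=8, cells_per_sample=150, subsets=("CD4",),
    availability={("PB", "baseline"): 16, ("BM", "baseline"): 16},
)
matrix, _ = simulate_cohort(design, model, seed=7)
state, filtered, _ = run_pipeline(matrix, PipelineConfig(seed=0, knn_k=15), compute_umap=False)

signature = cluster_centroids(state.clusters, state.normalized)
assignment = derive_groups(signature, min(3, len(signature.matrix)))
print("derived groups and their signature cytokines:")
for g in assignment.groups:
    print(f"  {g}: {', '.join(assignment.signatures[g]) or '(none)'}")

proportions = group_proportions(assignment, state.clusters, filtered.cell_meta)
sample_table = filtered.sample_table()
for tissue in ("BM", "PB"):
    res = compare_response(proportions, sample_table, tissue=tissue)
    print(f"\nCR vs NR rank-sum test on group proportions, {tissue} baseline:")
    print(res[["group", "median_CR", "median_NR", "p_value", "direction"]]
          .round(4).to_string(index=False))
# The group carrying the planted IFNγ/TNFα/MIP-1β/IL8 signature should be
# significantly CR-enriched in BM and null in PB.
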