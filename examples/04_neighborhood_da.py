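"""kNN-neighborhood differential abundance between timepoints.

Plants a 4-fold post-treatment enrichment of the IFNγ/TNFα/MIP-1β/IL8
population, builds partially overlapping kNN neighborhoods, tests each
neighborhood's per-sample counts with the negative-binomial model, applies
the distance-weighted (spatial) FDR, and classifies neighborhoods by
timepoint exclusivity.
"""

import numpy as np

from secretome import PipelineConfig, run_pipeline
from secretome.benchmarks import three_population_model
from secretome.diffabund import run_da
from secretome.synthetic import CohortDesign, plant_da_shift, simulate_cohort

model = plant_da_shift(three_population_model(batch_effect_sd=0.0), "quad", 4.0)
design = CohortDesign(
    n_patients=6, n_CR=3, cells_per_sample=500, subsets=("CD4",),
    availability={("BM", "baseline"): 6, ("BM", "post_IO"): 6},
)
matrix, truth = simulate_cohort(design, model, seed=3)
state, filtered, _ = run_pipeline(matrix, PipelineConfig(seed=0, knn_k=50), compute_umap=False)

result, nhoods, summary = run_da(state, filtered.cell_meta, proportion=0.1, k=50, seed=0)

print(f"neighborhoods: {summary['total']}")
for cls in ("baseline_only", "post_only", "mixed"):
    print(f"  {cls}: {summary[cls]['count']} ({summary[cls]['pct_str']}%)")

in_quad = (truth.loc[state.cell_index, "population"] == "quad").to_numpy().astype(float)
frac = (nhoods.membership.astype(float) @ in_quad) / nhoods.sizes()
inpop = frac > 0.5
print(f"\nplanted log fold-change (post renormalization): "
      f"{model.planted['da_shift']['log_fold_change']:.3f}")
print(f"median estimated LFC in quad neighborhoods:        "
      f"{np.nanmedian(result['log_fold_change'][inpop]):.3f}")
print(f"quad neighborhoods significant at spatial FDR<0.1: "
      f"{(result['spatial_fdr'][inpop] < 0.1).mean():.0%}")
# The estimated per-neighborhood LFC tracks the planted enrichment; outside
# the shifted population the LFC is mildly negative because renormalizing
# the mixture makes the other populations relatively rarer post-treatment.
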