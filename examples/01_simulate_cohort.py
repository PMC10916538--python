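"""Simulate a synthetic single-cell secretome cohort.

Builds the default cohort design (21 patients, baseline PB/BM from 20/16
patients, post-treatment PB/BM from 10/6, CD4 and CD8 subsets) with a
reduced 100 cells per sample, draws per-cell MFI from the four-population
secretion model, and prints what was generated.
"""

from secretome import CohortDesign, default_design, default_model, simulate_cohort

design = default_design()
design.cells_per_sample = 100  # keep the demo quick; the study scale is ~1,000

matrix, truth = simulate_cohort(design, default_model(), seed=0)

print(f"cells: {matrix.n_cells}, samples: {len(matrix.sample_meta)}")
print("\ncells per (tissue, timepoint):")
print(matrix.cell_meta.groupby(["tissue", "timepoint"]).size().to_string())
print("\nplanted subpopulation sizes:")
print(truth["population"].value_counts().to_string())
print(f"\nplanted outlier cells (>3,000 MFI in one channel): {truth['is_outlier'].sum()}")

# Each row of the matrix is one cell's MFI over the 32-plex panel; the truth
# table records which latent subpopulation generated each cell, which the
# downstream recovery benchmarks compare against.
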