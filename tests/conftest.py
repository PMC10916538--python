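import numpy as np
import pandas as pd
import pytest

from secretome import (
    CohortDesign,
    Population,
    SecretionModel,
    SecretomeMatrix,
    default_panel,
    simulate_cohort,
)


def make_matrix(values: np.ndarray, n_samples: int = 1, subset: str = "CD4") -> SecretomeMatrix:
    """Wrap a raw cells x 32 array into a SecretomeMatrix, cells split
    evenly over ``n_samples`` single-subset samples."""
    panel = default_panel()
    n = len(values)
    index = pd.Index([f"c{i}" for i in range(n)], name="cell_id")
    sample_ids = [f"s{i % n_samples + 1}" for i in range(n)]
    cell_meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "patient_id": [f"P{i % n_samples + 1:02d}" for i in range(n)],
            "tissue": "PB",
            "timepoint": "baseline",
            "subset": subset,
        },
        index=index,
    )
    uniq = sorted(set(sample_ids), key=lambda s: int(s[1:]))
    sample_meta = pd.DataFrame(
        {
            "patient_id": [f"P{int(s[1:]):02d}" for s in uniq],
            "response": ["CR" if int(s[1:]) % 2 else "NR" for s in uniq],
            "age": [60.0 + int(s[1:]) for s in uniq],
            "prior_HSCT": False,
            "secondary_AML": False,
        },
        index=pd.Index(uniq, name="sample_id"),
    )
    return SecretomeMatrix(
        values=pd.DataFrame(values, index=index, columns=list(panel.cytokines)),
        cell_meta=cell_meta,
        sample_meta=sample_meta,
        panel=panel,
    )


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort with two subsets, two tissues, two timepoints."""
    model = SecretionModel(
        populations=[
            Population("hi", 0.5, {"IFNγ": 0.8, "TNFα": 0.8}, default_prob=0.1),
            Population("lo", 0.5, {"IL4": 0.8, "IL10": 0.8}, default_prob=0.1),
        ],
        batch_effect_sd=0.1,
        outlier_fraction=0.0,
    )
    design = CohortDesign(
        n_patients=4,
        n_CR=2,
        cells_per_sample=60,
        availability={
            ("PB", "baseline"): 4,
            ("BM", "baseline"): 4,
            ("PB", "post_IO"): 4,
            ("BM", "post_IO"): 4,
        },
    )
    matrix, truth = simulate_cohort(design, model, seed=123)
    return matrix, truth
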