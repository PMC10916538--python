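"""Synthetic single-cell secretome cohorts.

Generates per-cell MFI matrices with the statistical structure the analysis
assumes: zero-inflated log-normal secretion per cytokine, latent cell
subpopulations with characteristic cosecretion signatures, patient-level
batch effects (additive on the log-MFI scale, shared across a patient's
samples), tissue-/timepoint-/response-dependent subpopulation abundances,
an optional age covariate acting on one cytokine's log-mean, and a small
planted fraction of outlier cells with one extreme channel.

Nonsecretion is an exact zero MFI by default, so secretion calling with a
zero threshold is unambiguous in tests; a half-normal background is opt-in
via ``background_sd``.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import RESPONSES, SUBSETS, TIMEPOINTS, TISSUES, SecretomeMatrix
from .panel import CytokinePanel, default_panel

__all__ = [
    "Population",
    "SecretionModel",
    "CohortDesign",
    "simulate_cohort",
    "plant_da_shift",
    "plant_response_effect",
    "default_model",
    "default_design",
]

# Baseline log-normal scale for a secreting cell: median MFI ~60 a.u. with
# log-SD 0.5 keeps essentially all honest secretion below the 3,000-MFI
# outlier gate, so planted outliers are the only cells above it.
DEFAULT_LOG_MU = math.log(60.0)
DEFAULT_LOG_SIGMA = 0.5


@dataclass
class Population:
    """One latent cell subpopulation with a cosecretion signature.

    ``weight`` is the base mixing proportion; ``weight_overrides`` is a list
    of ``(condition, value)`` pairs where ``condition`` is a dict over
    {tissue, timepoint, response} — the first override whose keys all match
    the sample's condition wins. Per-condition weights are renormalized over
    populations at sampling time.
    """

    name: str
    weight: float
    secretion_prob: dict[str, float]  # cytokine -> probability, default applies otherwise
    default_prob: float = 0.0
    log_mu: dict[str, float] = field(default_factory=dict)
    default_log_mu: float = DEFAULT_LOG_MU
    log_sigma: float = DEFAULT_LOG_SIGMA
    subsets: tuple[str, ...] = SUBSETS
    weight_overrides: list[tuple[dict, float]] = field(default_factory=list)

    def weight_for(self, condition: Mapping[str, str]) -> float:
        for cond, value in self.weight_overrides:
            if all(condition.get(k) == v for k, v in cond.items()):
                return value
        return self.weight

    def prob_vector(self, cytokines: Sequence[str]) -> np.ndarray:
        return np.array([self.secretion_prob.get(c, self.default_prob) for c in cytokines])

    def log_mu_vector(self, cytokines: Sequence[str]) -> np.ndarray:
        return np.array([self.log_mu.get(c, self.default_log_mu) for c in cytokines])


@dataclass
class SecretionModel:
    populations: list[Population]
    batch_effect_sd: float = 0.25
    background_sd: float = 0.0
    outlier_fraction: float = 0.01
    outlier_range: tuple[float, float] = (3000.0, 8000.0)
    # (cytokine, slope per year on log_mu, reference age)
    age_effect: tuple[str, float, float] | None = None
    panel: CytokinePanel = field(default_factory=default_panel)
    planted: dict = field(default_factory=dict)  # record of planted effects

    def __post_init__(self) -> None:
        for p in self.populations:
            if p.weight < 0 or any(v < 0 for _, v in p.weight_overrides):
                raise ValueError(f"population {p.name!r} has a negative weight")
            if not (p.log_sigma > 0):
                raise ValueError(f"population {p.name!r} needs log_sigma > 0")
            probs = list(p.secretion_prob.values()) + [p.default_prob]
            if any(q < 0 or q > 1 for q in probs):
                raise ValueError(f"population {p.name!r} has secretion_prob outside [0,1]")

    def population(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    def condition_weights(self, condition: Mapping[str, str], subset: str) -> np.ndarray:
        w = np.array(
            [p.weight_for(condition) if subset in p.subsets else 0.0 for p in self.populations]
        )
        total = w.sum()
        if total <= 0:
            raise ValueError(f"no population has positive weight under condition {condition}")
        return w / total


@dataclass
class CohortDesign:
    """Which samples exist and how many cells each contributes.

    ``availability`` maps (tissue, timepoint) to the number of patients with
    such a sample (assigned to the lowest-numbered patients); ``None`` means
    every patient contributes every tissue x timepoint.
    """

    n_patients: int = 21
    n_CR: int = 10
    availability: dict[tuple[str, str], int] | None = None
    cells_per_sample: int = 1000
    subsets: tuple[str, ...] = SUBSETS
    age_mean: float = 68.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (47.0, 90.0)

    def __post_init__(self) -> None:
        if self.cells_per_sample < 1:
            raise ValueError("cells_per_sample must be >= 1")
        if self.n_CR > self.n_patients:
            raise ValueError("n_CR cannot exceed n_patients")

    def sample_plan(self) -> list[dict]:
        """Expand the design into one record per (patient, tissue, timepoint, subset)."""
        avail = self.availability
        if avail is None:
            avail = {
                (t, tp): self.n_patients for t in TISSUES for tp in TIMEPOINTS
            }
        plan = []
        for (tissue, timepoint), n in avail.items():
            if n > self.n_patients:
                raise ValueError(
                    f"availability for {(tissue, timepoint)} exceeds n_patients"
                )
            for i in range(n):
                for subset in self.subsets:
                    plan.append(
                        {
                            "patient_id": f"P{i + 1:02d}",
                            "tissue": tissue,
                            "timepoint": timepoint,
                            "subset": subset,
                            "n_cells": self.cells_per_sample,
                        }
                    )
        return plan


def default_design() -> CohortDesign:
    """A cohort mirroring the study arm sizes: 21 patients (10 CR / 11 NR),
    baseline PB/BM from 20/16 patients, post-treatment PB/BM from 10/6,
    ~1,000 cells per sample and subset, ages ~N(68, 10) clipped to 47-90."""
    return CohortDesign(
        n_patients=21,
        n_CR=10,
        availability={
            ("PB", "baseline"): 20,
            ("BM", "baseline"): 16,
            ("PB", "post_IO"): 10,
            ("BM", "post_IO"): 6,
        },
        cells_per_sample=1000,
    )


def default_model(panel: CytokinePanel | None = None) -> SecretionModel:
    """Demo secretion model with four subpopulations.

    Includes a population cosecreting IFNγ, TNFα, MIP-1β and IL8 (the
    response-associated effector signature), a cytotoxic population, a
    regulatory-leaning population, a quiescent background population, and a
    negative age effect on IL2 secretion intensity.
    """
    panel = panel or default_panel()
    background = 0.04
    hi = 0.85
    pops = [
        Population(
            name="effector_quad",
            weight=0.20,
            secretion_prob={"IFNγ": hi, "TNFα": hi, "MIP-1β": hi, "IL8": hi},
            default_prob=background,
            log_mu={"IFNγ": math.log(250), "TNFα": math.log(250), "MIP-1β": math.log(200), "IL8": math.log(200)},
        ),
        Population(
            name="cytotoxic",
            weight=0.25,
            secretion_prob={"Granzyme B": hi, "Perforin": hi, "sCD137": 0.5},
            default_prob=background,
            log_mu={"Granzyme B": math.log(300), "Perforin": math.log(250)},
        ),
        Population(
            name="regulatory_like",
            weight=0.20,
            secretion_prob={"IL4": 0.7, "IL10": 0.7, "IL13": 0.5, "IL2": 0.5},
            default_prob=background,
            log_mu={"IL4": math.log(150), "IL10": math.log(150)},
        ),
        Population(
            name="quiescent",
            weight=0.35,
            secretion_prob={},
            default_prob=background,
        ),
    ]
    return SecretionModel(
        populations=pops,
        age_effect=("IL2", -0.02, 68.0),
        panel=panel,
    )


# -- planted effects ---------------------------------------------------


def plant_da_shift(
    model: SecretionModel,
    population: str,
    fold_change: float,
    axis: str = "timepoint",
) -> SecretionModel:
    """Return a model whose named population is ``fold_change`` times more
    (or less) abundant in the post-treatment condition.

    Weights are renormalized per condition at sampling time, so the realized
    abundance ratio is ``fold / renorm`` rather than ``fold`` exactly; the
    planted log fold-change recorded in ``model.planted`` accounts for this.
    """
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    if axis != "timepoint":
        raise ValueError("only the timepoint axis is supported")
    new = copy.deepcopy(model)
    pop = new.population(population)  # raises KeyError if absent
    base = pop.weight_for({"timepoint": "post_IO"})
    pop.weight_overrides.insert(0, ({"timepoint": "post_IO"}, base * fold_change))
    # realized log fold-change of the population's relative abundance,
    # assuming all-population base weights sum to 1
    total = sum(p.weight for p in new.populations)
    renorm = (total - pop.weight + pop.weight * fold_change) / total
    new.planted = dict(model.planted)
    new.planted["da_shift"] = {
        "population": population,
        "fold_change": fold_change,
        "log_fold_change": math.log(fold_change / renorm),
    }
    return new


def plant_response_effect(
    model: SecretionModel,
    population: str,
    delta_weight: float,
    arm: str,
    tissue: str,
) -> SecretionModel:
    """Return a model where the named population's weight is shifted by
    ``delta_weight`` for samples of the given response arm and tissue."""
    if arm not in RESPONSES:
        raise ValueError(f"arm must be one of {RESPONSES}")
    if tissue not in TISSUES:
        raise ValueError(f"tissue must be one of {TISSUES}")
    new = copy.deepcopy(model)
    pop = new.population(population)
    cond = {"response": arm, "tissue": tissue}
    value = pop.weight_for(cond) + delta_weight
    if value < 0:
        raise ValueError("delta_weight would make the weight negative")
    pop.weight_overrides.insert(0, (cond, value))
    new.planted = dict(model.planted)
    new.planted["response_effect"] = {
        "population": population,
        "delta_weight": delta_weight,
        "arm": arm,
        "tissue": tissue,
    }
    return new


# -- simulation --------------------------------------------------------


def simulate_cohort(
    design: CohortDesign,
    model: SecretionModel,
    seed: int,
) -> tuple[SecretomeMatrix, pd.DataFrame]:
    """Draw a cohort: returns the SecretomeMatrix plus per-cell truth labels.

    Each cell's subpopulation is drawn from the condition-specific weights;
    each cytokine secretes with its population probability and, when
    secreting, draws ``exp(N(log_mu + patient_offset + age_term, log_sigma))``
    MFI, else background (exact zero by default). A fraction of cells gets
    one channel replaced by a uniform draw above the outlier gate; truth
    records each cell's population and outlier flag. Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    panel = model.panel
    cytokines = list(panel.cytokines)
    n_cyt = len(cytokines)

    patients = [f"P{i + 1:02d}" for i in range(design.n_patients)]
    responses = {p: ("CR" if i < design.n_CR else "NR") for i, p in enumerate(patients)}
    ages = {
        p: float(np.clip(rng.normal(design.age_mean, design.age_sd), *design.age_range))
        for p in patients
    }
    batch_offsets = {
        p: rng.normal(0.0, model.batch_effect_sd, size=n_cyt) for p in patients
    }

    pop_probs = [p.prob_vector(cytokines) for p in model.populations]
    pop_logmu = [p.log_mu_vector(cytokines) for p in model.populations]

    if model.age_effect is not None:
        age_cyt, age_slope, age_ref = model.age_effect
        age_col = cytokines.index(panel.resolve(age_cyt))
    else:
        age_col = None

    rows, metas, truth_rows, cell_ids = [], [], [], []
    for spec in design.sample_plan():
        patient = spec["patient_id"]
        tissue, timepoint, subset = spec["tissue"], spec["timepoint"], spec["subset"]
        n = spec["n_cells"]
        sample_id = f"{patient}_{tissue}_{timepoint}_{subset}"
        condition = {"tissue": tissue, "timepoint": timepoint, "response": responses[patient]}
        weights = model.condition_weights(condition, subset)
        pop_idx = rng.choice(len(model.populations), size=n, p=weights)

        logmu_shift = batch_offsets[patient].copy()
        if age_col is not None:
            logmu_shift[age_col] += age_slope * (ages[patient] - age_ref)

        mfi = np.zeros((n, n_cyt))
        if model.background_sd > 0:
            mfi = np.abs(rng.normal(0.0, model.background_sd, size=(n, n_cyt)))
        for k, pop in enumerate(model.populations):
            cells = np.flatnonzero(pop_idx == k)
            if not len(cells):
                continue
            secrete = rng.random((len(cells), n_cyt)) < pop_probs[k][None, :]
            draws = np.exp(
                rng.normal(
                    pop_logmu[k][None, :] + logmu_shift[None, :],
                    pop.log_sigma,
                    size=(len(cells), n_cyt),
                )
            )
            block = mfi[cells]
            block[secrete] = draws[secrete]
            mfi[cells] = block

        is_outlier = rng.random(n) < model.outlier_fraction
        out_cells = np.flatnonzero(is_outlier)
        if len(out_cells):
            channels = rng.integers(0, n_cyt, size=len(out_cells))
            lo, hi_ = model.outlier_range
            mfi[out_cells, channels] = rng.uniform(lo, hi_, size=len(out_cells))
            # the planted channel strictly exceeds the gate
            mfi[out_cells, channels] = np.maximum(mfi[out_cells, channels], np.nextafter(lo, np.inf))

        ids = [f"{sample_id}:{i}" for i in range(n)]
        cell_ids.extend(ids)
        rows.append(mfi)
        metas.extend(
            {
                "sample_id": sample_id,
                "patient_id": patient,
                "tissue": tissue,
                "timepoint": timepoint,
                "subset": subset,
            }
            for _ in range(n)
        )
        truth_rows.extend(
            {
                "population": model.populations[k].name,
                "is_outlier": bool(o),
            }
            for k, o in zip(pop_idx, is_outlier)
        )

    index = pd.Index(cell_ids, name="cell_id")
    values = pd.DataFrame(np.vstack(rows), index=index, columns=cytokines)
    cell_meta = pd.DataFrame(metas, index=index)
    sample_meta = (
        cell_meta.drop_duplicates("sample_id")
        .set_index("sample_id")[["patient_id"]]
        .assign(
            response=lambda d: d["patient_id"].map(responses),
            age=lambda d: d["patient_id"].map(ages),
            prior_HSCT=False,
            secondary_AML=False,
        )
    )
    truth = pd.DataFrame(truth_rows, index=index)
    matrix = SecretomeMatrix(
        values=values, cell_meta=cell_meta, sample_meta=sample_meta, panel=panel
    )
    return matrix, truth
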