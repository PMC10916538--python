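"""Polyfunctional strength index (PSI) and pseudobulk statistics.

A cell is *polyfunctional* when it secretes (is called positive for) two or
more cytokines of the full 32-plex panel. For each sample x T-cell subset
and each functional group g (plus "overall"), the PSI is

    PSI(g) = polyfunctional% x sum over polyfunctional cells of the MFI of
             their positive cytokines restricted to g

with the percentage on a 0-100 scale. Polyfunctionality is decided on the
full panel; only the MFI sum is group-restricted, so the five group PSI
values decompose the overall mfi_sum additively.

Pseudobulk contrasts compare per-sample PSI between compartments (PB vs
BM), timepoints (baseline vs post-treatment) or response arms (CR vs NR)
with paired t tests / rank-sum tests and Benjamini-Hochberg adjustment
within each contrast family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SecretomeMatrix
from .panel import CytokinePanel

__all__ = [
    "SecretionCalls",
    "call_secretion",
    "polyfunctional_mask",
    "compute_psi",
    "pseudobulk_contrast",
    "correlate_covariate",
]

OVERALL = "overall"


@dataclass
class SecretionCalls:
    """Boolean positivity calls: ``calls[i, c]`` iff MFI > threshold[c]."""

    calls: pd.DataFrame  # cells x cytokines, bool
    thresholds: pd.Series  # per-cytokine cutoff actually applied


def call_secretion(
    matrix: SecretomeMatrix,
    thresholds: float | Sequence[float] | Mapping[str, float] = 0.0,
) -> SecretionCalls:
    """Call a cytokine secreted when its MFI strictly exceeds the threshold.

    ``thresholds`` may be a scalar (broadcast over the panel), a vector in
    panel order, or a mapping cytokine -> cutoff (unmentioned cytokines get
    0). The default 0 counts any nonzero signal as secretion, which matches
    an exact-zero background model; instrument-specific gates are supplied
    per cytokine.
    """
    cytokines = matrix.cytokines
    if np.isscalar(thresholds):
        thr = pd.Series(float(thresholds), index=cytokines)
    elif isinstance(thresholds, Mapping):
        thr = pd.Series(0.0, index=cytokines)
        for name, v in thresholds.items():
            thr[matrix.panel.resolve(name)] = float(v)
    else:
        arr = np.asarray(thresholds, dtype=float)
        if arr.shape != (len(cytokines),):
            raise ValueError(
                f"threshold vector has length {arr.size}, panel has {len(cytokines)}"
            )
        thr = pd.Series(arr, index=cytokines)
    if (thr < 0).any():
        raise ValueError("thresholds must be nonnegative")
    calls = matrix.values.gt(thr, axis=1)
    return SecretionCalls(calls=calls, thresholds=thr)


def polyfunctional_mask(calls: SecretionCalls) -> pd.Series:
    """True for cells positive for >= 2 cytokines across the full panel."""
    return calls.calls.sum(axis=1) >= 2


def compute_psi(
    matrix: SecretomeMatrix,
    calls: SecretionCalls,
    panel: CytokinePanel | None = None,
    per_cytokine: bool = False,
    group_restricted_polyfunctionality: bool = False,
    mfi_statistic: str = "sum",
) -> pd.DataFrame:
    """PSI table per (sample_id, subset) x functional group.

    Returns one row per (sample_id, subset, group) with columns ``n_cells``,
    ``n_polyfunctional``, ``polyfunctional_pct`` (0-100), ``mfi_sum`` and
    ``psi = polyfunctional_pct * mfi_sum``. ``group`` ranges over the five
    functional groups plus ``"overall"`` (and each single cytokine when
    ``per_cytokine``). Samples without cells for a subset are emitted with
    ``n_cells = 0`` and missing PSI.

    ``group_restricted_polyfunctionality`` switches to calling a cell
    polyfunctional per group (>= 2 positives within the group) instead of
    panel-wide; ``mfi_statistic="mean"`` averages the positive MFI over
    polyfunctional cells instead of summing.
    """
    panel = panel or matrix.panel
    if calls.calls.shape != matrix.values.shape:
        raise ValueError("calls shape does not match the matrix")
    if mfi_statistic not in ("sum", "mean"):
        raise ValueError("mfi_statistic must be 'sum' or 'mean'")

    groups: dict[str, list[str]] = {
        g: [c for c in matrix.cytokines if c in members]
        for g, members in panel.groups.items()
    }
    groups[OVERALL] = list(matrix.cytokines)
    if per_cytokine:
        for c in matrix.cytokines:
            groups[c] = [c]

    values = matrix.values.to_numpy()
    call_arr = calls.calls.to_numpy()
    positive_mfi = values * call_arr
    poly_panel = call_arr.sum(axis=1) >= 2

    keys = matrix.cell_meta[["sample_id", "subset"]]
    # universe of rows: every sample x its own subset (samples are
    # subset-specific), plus observed combos
    universe = (
        matrix.cell_meta.drop_duplicates("sample_id")[["sample_id", "subset"]]
        .set_index("sample_id")["subset"]
        .to_dict()
    )

    records = []
    grouped = keys.groupby(["sample_id", "subset"], sort=True).indices
    for (sample_id, subset), idx in grouped.items():
        n_cells = len(idx)
        for gname, members in groups.items():
            cols = [matrix.cytokines.index(c) for c in members]
            if group_restricted_polyfunctionality:
                poly = call_arr[np.ix_(idx, cols)].sum(axis=1) >= 2
            else:
                poly = poly_panel[idx]
            n_poly = int(poly.sum())
            pct = 100.0 * n_poly / n_cells
            cell_sums = positive_mfi[np.ix_(idx, cols)].sum(axis=1)
            mfi_sum = float(cell_sums[poly].sum())
            if mfi_statistic == "mean" and n_poly > 0:
                mfi_sum /= n_poly
            records.append(
                {
                    "sample_id": sample_id,
                    "subset": subset,
                    "group": gname,
                    "n_cells": n_cells,
                    "n_polyfunctional": n_poly,
                    "polyfunctional_pct": pct,
                    "mfi_sum": mfi_sum,
                    "psi": pct * mfi_sum,
                }
            )
    # empty samples (declared in sample_meta but contributing no cells)
    seen = {s for (s, _) in grouped}
    for sample_id in matrix.sample_meta.index:
        if sample_id in seen:
            continue
        subset = universe.get(sample_id, "")
        for gname in groups:
            records.append(
                {
                    "sample_id": sample_id,
                    "subset": subset,
                    "group": gname,
                    "n_cells": 0,
                    "n_polyfunctional": 0,
                    "polyfunctional_pct": np.nan,
                    "mfi_sum": np.nan,
                    "psi": np.nan,
                }
            )
    return pd.DataFrame.from_records(records)


def _bh(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg over the non-missing entries of ``p``."""
    q = pd.Series(np.nan, index=p.index)
    ok = p.notna()
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


_CONTRASTS = {
    "PB_vs_BM": dict(column="tissue", levels=("PB", "BM"), paired_on=("patient_id", "timepoint")),
    "pre_vs_post": dict(column="timepoint", levels=("post_IO", "baseline"), paired_on=("patient_id", "tissue")),
    "CR_vs_NR": dict(column="response", levels=("CR", "NR"), paired_on=None),
}


def pseudobulk_contrast(
    psi_table: pd.DataFrame,
    sample_meta: pd.DataFrame,
    contrast: str,
    value: str = "psi",
    test: str = "t",
    tissue: str | None = None,
    timepoint: str | None = "baseline",
) -> pd.DataFrame:
    """Sample-level contrast of PSI between two conditions.

    ``contrast`` is one of ``PB_vs_BM``, ``pre_vs_post`` (both paired within
    patient) or ``CR_vs_NR`` (unpaired). Paired contrasts use a two-sided
    paired t test by default (``test="wilcoxon"`` switches to the
    signed-rank test); CR_vs_NR uses the two-sided rank-sum
    (Mann-Whitney) test. BH adjustment is applied within each subset's
    family of groups. Rows with too few pairs/samples or zero paired
    differences are flagged rather than dropped.

    ``tissue``/``timepoint`` restrict the samples entering the contrast
    (ignored for the axis being contrasted).
    """
    if contrast not in _CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; pick from {sorted(_CONTRASTS)}")
    spec = _CONTRASTS[contrast]
    a_level, b_level = spec["levels"]

    tbl = psi_table.copy()
    sm = sample_meta.copy()
    if "tissue" not in sm.columns or "timepoint" not in sm.columns:
        # derive tissue/timepoint from the cells' sample ids if absent
        raise ValueError("sample_meta must carry tissue and timepoint columns")
    tbl = tbl.merge(
        sm[["patient_id", "tissue", "timepoint", "response"]],
        left_on="sample_id",
        right_index=True,
        how="left",
    )
    if spec["column"] != "timepoint" and timepoint is not None:
        tbl = tbl[tbl["timepoint"] == timepoint]
    if spec["column"] != "tissue" and tissue is not None:
        tbl = tbl[tbl["tissue"] == tissue]
    tbl = tbl[tbl["n_cells"] > 0]

    records = []
    for (subset, group), sub in tbl.groupby(["subset", "group"], sort=True):
        rec = {
            "subset": subset,
            "group": group,
            "contrast": contrast,
            "statistic": np.nan,
            "p_value": np.nan,
            "n": 0,
            "direction": "",
            "flag": "",
        }
        if spec["paired_on"]:
            wide = sub.pivot_table(
                index=list(spec["paired_on"]), columns=spec["column"], values=value
            )
            if a_level not in wide.columns or b_level not in wide.columns:
                rec["flag"] = "untestable"
                records.append(rec)
                continue
            wide = wide[[a_level, b_level]].dropna()
            n = len(wide)
            rec["n"] = n
            if n < 3:
                rec["flag"] = "untestable"
                records.append(rec)
                continue
            diff = wide[a_level] - wide[b_level]
            rec["direction"] = f"{a_level}>{b_level}" if diff.mean() > 0 else f"{b_level}>{a_level}"
            if np.allclose(diff, 0):
                rec["statistic"], rec["p_value"], rec["flag"] = 0.0, 1.0, "degenerate"
            elif test == "wilcoxon":
                res = stats.wilcoxon(wide[a_level], wide[b_level])
                rec["statistic"], rec["p_value"] = float(res.statistic), float(res.pvalue)
            else:
                res = stats.ttest_rel(wide[a_level], wide[b_level])
                rec["statistic"], rec["p_value"] = float(res.statistic), float(res.pvalue)
        else:
            a = sub.loc[sub[spec["column"]] == a_level, value].dropna()
            b = sub.loc[sub[spec["column"]] == b_level, value].dropna()
            rec["n"] = min(len(a), len(b))
            if len(a) < 2 or len(b) < 2:
                rec["flag"] = "untestable"
                records.append(rec)
                continue
            rec["direction"] = f"{a_level}>{b_level}" if a.median() > b.median() else f"{b_level}>{a_level}"
            if a.var(ddof=0) == 0 and b.var(ddof=0) == 0 and a.iloc[0] == b.iloc[0]:
                rec["statistic"], rec["p_value"], rec["flag"] = np.nan, 1.0, "degenerate"
            else:
                res = stats.mannwhitneyu(a, b, alternative="two-sided")
                rec["statistic"], rec["p_value"] = float(res.statistic), float(res.pvalue)
        records.append(rec)

    out = pd.DataFrame.from_records(records)
    out["q_value"] = np.nan
    for subset, idx in out.groupby("subset").groups.items():
        out.loc[idx, "q_value"] = _bh(out.loc[idx, "p_value"])
    out["significant_raw"] = out["p_value"] < 0.05
    out["significant_fdr"] = out["q_value"] < 0.05
    return out


def correlate_covariate(
    psi_table: pd.DataFrame,
    sample_meta: pd.DataFrame,
    covariate: str = "age",
    value: str = "psi",
    min_samples: int = 5,
) -> pd.DataFrame:
    """Spearman correlation of per-sample PSI with a sample covariate,
    within each tissue x subset stratum, per group/cytokine; BH-adjusted
    within each stratum. Constant covariates are flagged untestable."""
    tbl = psi_table.merge(
        sample_meta[["tissue", "timepoint", covariate]],
        left_on="sample_id",
        right_index=True,
        how="left",
    )
    tbl = tbl[(tbl["timepoint"] == "baseline") & (tbl["n_cells"] > 0)]
    records = []
    for (tissue, subset, group), sub in tbl.groupby(["tissue", "subset", "group"], sort=True):
        sub = sub.dropna(subset=[value, covariate])
        rec = {
            "tissue": tissue,
            "subset": subset,
            "group": group,
            "n": len(sub),
            "rho": np.nan,
            "p_value": np.nan,
            "flag": "",
        }
        if len(sub) < min_samples:
            rec["flag"] = "untestable"
        elif sub[covariate].nunique() == 1:
            rec["flag"] = "constant_covariate"
        else:
            rho, p = stats.spearmanr(sub[covariate], sub[value])
            rec["rho"], rec["p_value"] = float(rho), float(p)
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    out["q_value"] = np.nan
    for (_, _), idx in out.groupby(["tissue", "subset"]).groups.items():
        out.loc[idx, "q_value"] = _bh(out.loc[idx, "p_value"])
    return out
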