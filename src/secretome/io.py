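"""Reading and writing per-cell MFI tables.

The on-disk currency is one wide CSV/TSV per cohort: one row per cell,
32 cytokine MFI columns plus cell- and sample-level metadata columns.
Sample-level fields (response, age, flags) are replicated per row on disk
and de-duplicated into a sample table on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import CytokinePanel, default_panel, validate_panel

__all__ = ["SecretomeMatrix", "read_mfi_table", "write_mfi_table", "concat_matrices"]

CELL_META_COLUMNS = ("cell_id", "sample_id", "patient_id", "tissue", "timepoint", "subset")
SAMPLE_META_COLUMNS = ("sample_id", "patient_id", "response", "age", "prior_HSCT", "secondary_AML")

TISSUES = ("PB", "BM")
TIMEPOINTS = ("baseline", "post_IO")
SUBSETS = ("CD4", "CD8")
RESPONSES = ("CR", "NR")


@dataclass
class SecretomeMatrix:
    """Per-cell nonnegative MFI values over a cytokine panel, with metadata.

    Attributes
    ----------
    values : DataFrame, cells x cytokines
        Nonnegative mean fluorescence intensities; columns are canonical
        panel cytokine names, index is ``cell_id``.
    cell_meta : DataFrame indexed by cell_id
        Columns ``sample_id, patient_id, tissue, timepoint, subset``.
    sample_meta : DataFrame indexed by sample_id
        Columns ``patient_id, response, age, prior_HSCT, secondary_AML``.
    panel : CytokinePanel
    """

    values: pd.DataFrame
    cell_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    panel: CytokinePanel = field(default_factory=default_panel)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------

    def validate(self) -> None:
        vals = self.values.to_numpy(dtype=float, copy=False)
        if not np.isfinite(vals).all():
            raise ValueError("MFI values must be finite")
        if (vals < 0).any():
            bad = int(np.argwhere(vals < 0)[0][0])
            raise ValueError(f"negative MFI value at row {bad}")
        report = validate_panel(self.panel, self.values.columns)
        if report.missing or report.extra:
            raise ValueError(
                f"value columns do not match the panel: missing={list(report.missing)}, "
                f"extra={list(report.extra)}"
            )
        if not self.values.index.equals(self.cell_meta.index):
            raise ValueError("values and cell_meta must share the same cell index")
        unknown = set(self.cell_meta["sample_id"]) - set(self.sample_meta.index)
        if unknown:
            raise ValueError(f"cells reference unknown sample_ids: {sorted(unknown)[:5]}")
        # tissue/timepoint/subset must be constant within a sample
        per_sample = self.cell_meta.groupby("sample_id")[["tissue", "timepoint", "subset"]].nunique()
        mixed = per_sample[(per_sample > 1).any(axis=1)]
        if len(mixed):
            raise ValueError(
                f"tissue/timepoint/subset vary within sample(s) {list(mixed.index)[:5]}"
            )

    # -- conveniences ---------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.values)

    @property
    def cytokines(self) -> list[str]:
        return list(self.values.columns)

    def sample_table(self) -> pd.DataFrame:
        """Sample metadata augmented with the (per-sample constant) tissue,
        timepoint and subset derived from the cells."""
        derived = (
            self.cell_meta.drop_duplicates("sample_id")
            .set_index("sample_id")[["tissue", "timepoint", "subset"]]
        )
        return self.sample_meta.join(derived)

    def cell_table(self) -> pd.DataFrame:
        """Cell metadata joined with the sample metadata, one row per cell."""
        return self.cell_meta.join(
            self.sample_meta.drop(columns=["patient_id"]), on="sample_id"
        )

    def subset_cells(self, mask) -> "SecretomeMatrix":
        """A new matrix restricted to the cells selected by ``mask``
        (boolean array or cell_id index)."""
        values = self.values.loc[mask]
        cell_meta = self.cell_meta.loc[values.index]
        keep = cell_meta["sample_id"].unique()
        return SecretomeMatrix(
            values=values.copy(),
            cell_meta=cell_meta.copy(),
            sample_meta=self.sample_meta.loc[self.sample_meta.index.isin(keep)].copy(),
            panel=self.panel,
        )


def _detect_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_mfi_table(
    path: str | Path,
    panel: CytokinePanel | None = None,
    sep: str | None = None,
) -> SecretomeMatrix:
    """Read a wide per-cell MFI table (CSV/TSV, delimiter auto-detected).

    Cytokine columns are matched against the panel under name normalization,
    so e.g. a ``TNFa`` header maps to ``TNFα``. Sample-level columns are
    de-duplicated into the sample table. Row order is preserved.
    """
    path = Path(path)
    panel = panel or default_panel()
    df = pd.read_csv(path, sep=_detect_sep(path, sep), float_precision="round_trip")

    report = validate_panel(panel, df.columns)
    if report.missing:
        raise ValueError(f"input is missing panel cytokines: {list(report.missing)}")
    mandatory = [c for c in CELL_META_COLUMNS if c != "cell_id"]
    for col in mandatory:
        if col not in df.columns:
            raise ValueError(f"missing mandatory metadata column: {col!r}")

    values = df[list(report.matched)].rename(columns=report.matched)
    values = values[list(panel.cytokines)]
    arr = values.apply(pd.to_numeric, errors="coerce")
    bad = arr.isna().any(axis=1) | (arr < 0).any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"negative or non-numeric MFI in row {row}")
    values = arr.astype(float)

    if "cell_id" in df.columns:
        cell_ids = df["cell_id"].astype(str)
    else:  # synthesize stable ids from sample and row order
        order = df.groupby("sample_id").cumcount()
        cell_ids = df["sample_id"].astype(str) + ":" + order.astype(str)
    values.index = pd.Index(cell_ids, name="cell_id")

    cell_meta = df[mandatory].copy()
    cell_meta.index = values.index

    present = [c for c in SAMPLE_META_COLUMNS if c in df.columns]
    sm = df[present].drop_duplicates(subset="sample_id").set_index("sample_id")
    for col in SAMPLE_META_COLUMNS:
        if col not in ("sample_id",) and col not in sm.columns:
            sm[col] = np.nan
    sm = sm[[c for c in SAMPLE_META_COLUMNS if c != "sample_id"]]
    return SecretomeMatrix(values=values, cell_meta=cell_meta, sample_meta=sm, panel=panel)


def write_mfi_table(
    matrix: SecretomeMatrix,
    path: str | Path,
    sep: str = ",",
    ascii_header: bool = False,
) -> Path:
    """Write the matrix as one wide table; inverse of :func:`read_mfi_table`.

    Floats are written with shortest round-trip repr, so a write/read cycle
    reproduces values exactly.
    """
    path = Path(path)
    wide = matrix.cell_meta.copy()
    wide.insert(0, "cell_id", wide.index)
    sm = matrix.sample_meta.drop(columns=["patient_id"])
    wide = wide.join(sm, on="sample_id")
    vals = matrix.values
    if ascii_header:
        from .panel import normalize_name

        vals = vals.rename(columns={c: normalize_name(c).upper() for c in vals.columns})
    out = pd.concat([wide.reset_index(drop=True), vals.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep=sep, index=False)
    return path


def concat_matrices(matrices: Sequence[SecretomeMatrix] | Iterable[SecretomeMatrix]) -> SecretomeMatrix:
    """Concatenate per-sample (or per-batch) matrices sharing one panel."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("nothing to concatenate")
    panel = matrices[0].panel
    values = pd.concat([m.values for m in matrices], axis=0)
    cell_meta = pd.concat([m.cell_meta for m in matrices], axis=0)
    sample_meta = pd.concat([m.sample_meta for m in matrices], axis=0)
    sample_meta = sample_meta[~sample_meta.index.duplicated(keep="first")]
    return SecretomeMatrix(values=values, cell_meta=cell_meta, sample_meta=sample_meta, panel=panel)
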