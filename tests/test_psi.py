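import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secretome import (
    call_secretion,
    compute_psi,
    correlate_covariate,
    polyfunctional_mask,
    pseudobulk_contrast,
)
from secretome.benchmarks import psi_reference

from conftest import make_matrix


class TestCallSecretion:
    def test_zero_matrix_zero_threshold_no_calls(self):
        m = make_matrix(np.zeros((4, 32)))
        calls = call_secretion(m, 0.0)
        assert not calls.calls.to_numpy().any()

    def test_strict_inequality_at_threshold(self):
        vals = np.zeros((1, 32))
        vals[0, 0] = 50.0
        m = make_matrix(vals)
        assert not call_secretion(m, 50.0).calls.iloc[0, 0]
        assert call_secretion(m, 49.999).calls.iloc[0, 0]

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.gamma(2, 40, (50, 32))
        thr = rng.uniform(0, 100, 32)
        m = make_matrix(vals)
        calls = call_secretion(m, thr)
        expected = np.array(
            [[vals[i, j] > thr[j] for j in range(32)] for i in range(50)]
        )
        assert (calls.calls.to_numpy() == expected).all()

    def test_mapping_thresholds_resolve_aliases(self):
        vals = np.zeros((1, 32))
        m = make_matrix(vals)
        calls = call_secretion(m, {"TNFa": 100.0})
        assert calls.thresholds["TNFα"] == 100.0

    def test_wrong_length_vector_rejected(self):
        m = make_matrix(np.zeros((2, 32)))
        with pytest.raises(ValueError, match="length"):
            call_secretion(m, np.ones(5))


class TestPolyfunctionalMask:
    @pytest.mark.parametrize("n_positive, expected", [(0, False), (1, False), (2, True), (5, True)])
    def test_two_or_more_rule(self, n_positive, expected):
        vals = np.zeros((1, 32))
        vals[0, :n_positive] = 100.0
        m = make_matrix(vals)
        assert polyfunctional_mask(call_secretion(m)).iloc[0] == expected

    def test_matches_row_sum_oracle(self):
        rng = np.random.default_rng(9)
        vals = np.where(rng.random((40, 32)) < 0.06, 100.0, 0.0)
        m = make_matrix(vals)
        mask = polyfunctional_mask(call_secretion(m))
        assert (mask.to_numpy() == ((vals > 0).sum(axis=1) >= 2)).all()


class TestComputePsi:
    def test_worked_example_20pct_400_8000(self, panel):
        """10 cells, 2 polyfunctional with two positive cytokines at MFI 100
        in one group: pct 20, mfi_sum 400, PSI 8,000."""
        vals = np.zeros((10, 32))
        cols = [list(panel.cytokines).index(c) for c in ("IFNγ", "TNFα")]  # both effector
        vals[0, cols] = 100.0
        vals[1, cols] = 100.0
        m = make_matrix(vals)
        table = compute_psi(m, call_secretion(m))
        row = table[(table["group"] == "effector")].iloc[0]
        assert row["polyfunctional_pct"] == pytest.approx(20.0)
        assert row["mfi_sum"] == pytest.approx(400.0)
        assert row["psi"] == pytest.approx(8000.0)
        overall = table[table["group"] == "overall"].iloc[0]
        assert overall["psi"] == pytest.approx(8000.0)
        # groups without positive calls have PSI 0 despite polyfunctional cells
        chemo = table[table["group"] == "chemoattractive"].iloc[0]
        assert chemo["psi"] == 0.0

    def test_no_polyfunctional_cells_gives_zero_psi(self):
        vals = np.zeros((10, 32))
        vals[:, 0] = 100.0  # every cell secretes exactly one cytokine
        m = make_matrix(vals)
        table = compute_psi(m, call_secretion(m))
        assert (table["psi"] == 0).all()
        assert (table["n_polyfunctional"] == 0).all()

    def test_psi_scales_linearly_with_mfi(self):
        rng = np.random.default_rng(3)
        vals = np.where(rng.random((30, 32)) < 0.2, rng.gamma(2, 50, (30, 32)), 0.0)
        m = make_matrix(vals)
        base = compute_psi(m, call_secretion(m))
        c = 3.7
        m2 = make_matrix(vals * c)
        scaled = compute_psi(m2, call_secretion(m2))
        assert np.allclose(scaled["psi"], base["psi"] * c)

    def test_group_additivity(self):
        rng = np.random.default_rng(8)
        vals = np.where(rng.random((50, 32)) < 0.3, rng.gamma(2, 50, (50, 32)), 0.0)
        m = make_matrix(vals, n_samples=2)
        table = compute_psi(m, call_secretion(m))
        five = table[~table["group"].isin(["overall"])]
        sums = five.groupby(["sample_id", "subset"])["mfi_sum"].sum()
        overall = table[table["group"] == "overall"].set_index(["sample_id", "subset"])["mfi_sum"]
        assert np.allclose(sums.sort_index(), overall.sort_index())

    def test_matches_bruteforce_reference(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(1, 21))
            vals = np.where(rng.random((n, 32)) < 0.3, rng.gamma(2, 50, (n, 32)), 0.0)
            m = make_matrix(vals)
            fast = compute_psi(m, call_secretion(m))
            slow = psi_reference(m)
            merged = fast.merge(slow, on=["sample_id", "subset", "group"], suffixes=("", "_ref"))
            assert np.allclose(merged["psi"], merged["psi_ref"])

    def test_empty_sample_emitted_as_missing(self, small_cohort):
        matrix, _ = small_cohort
        sub = matrix.subset_cells(matrix.cell_meta["sample_id"] != matrix.sample_meta.index[0])
        # re-attach the now-cellless sample to sample_meta
        sub.sample_meta = matrix.sample_meta
        table = compute_psi(sub, call_secretion(sub))
        empty = table[table["sample_id"] == matrix.sample_meta.index[0]]
        assert (empty["n_cells"] == 0).all()
        assert empty["psi"].isna().all()

    def test_mean_statistic_divides_by_cells(self):
        vals = np.zeros((10, 32))
        vals[0, :2] = 100.0
        vals[1, :2] = 300.0
        m = make_matrix(vals)
        calls = call_secretion(m)
        total = compute_psi(m, calls)
        mean = compute_psi(m, calls, mfi_statistic="mean")
        row_t = total[total["group"] == "overall"].iloc[0]
        row_m = mean[mean["group"] == "overall"].iloc[0]
        assert row_t["mfi_sum"] == pytest.approx(800.0)
        assert row_m["mfi_sum"] == pytest.approx(400.0)


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**32 - 1))
def test_psi_zero_iff_no_positive_group_mfi(seed):
    """PSI = 0 exactly when no polyfunctional cell has positive MFI in the group."""
    rng = np.random.default_rng(seed)
    vals = np.where(rng.random((12, 32)) < 0.1, rng.gamma(2, 50, (12, 32)), 0.0)
    m = make_matrix(vals)
    calls = call_secretion(m)
    table = compute_psi(m, calls)
    poly = polyfunctional_mask(calls)
    for g in ("chemoattractive", "effector", "overall"):
        cols = (
            list(m.panel.group(g)) if g != "overall" else list(m.cytokines)
        )
        has_signal = bool((m.values.loc[poly, cols].to_numpy() > 0).any())
        psi = float(table[table["group"] == g]["psi"].iloc[0])
        assert (psi > 0) == has_signal


class TestContrasts:
    @staticmethod
    def _psi_table(matrix):
        return compute_psi(matrix, call_secretion(matrix))

    def test_identical_paired_vectors_flagged_degenerate(self, small_cohort):
        matrix, _ = small_cohort
        table = self._psi_table(matrix)
        # force PB == BM within each patient/timepoint pair
        wide = table.copy()
        bm_map = {
            s: s.replace("_PB_", "_BM_") for s in wide["sample_id"].unique() if "_PB_" in s
        }
        pb = wide[wide["sample_id"].isin(bm_map)]
        for pb_s, bm_s in bm_map.items():
            sel_bm = wide["sample_id"] == bm_s
            for grp in wide.loc[sel_bm, "group"].unique():
                src = pb[(pb["sample_id"] == pb_s) & (pb["group"] == grp)]
                if len(src):
                    wide.loc[sel_bm & (wide["group"] == grp), "psi"] = src["psi"].iloc[0]
        res = pseudobulk_contrast(wide, matrix.sample_table(), "PB_vs_BM")
        tested = res[res["flag"] != "untestable"]
        assert (tested["flag"] == "degenerate").all()
        assert (tested["p_value"] == 1.0).all()

    def test_bh_q_monotone_and_geq_p(self, small_cohort):
        matrix, _ = small_cohort
        res = pseudobulk_contrast(self._psi_table(matrix), matrix.sample_table(), "PB_vs_BM")
        ok = res.dropna(subset=["p_value", "q_value"])
        assert (ok["q_value"] >= ok["p_value"] - 1e-12).all()
        for _, sub in ok.groupby("subset"):
            s = sub.sort_values("p_value")
            assert (np.diff(s["q_value"]) >= -1e-12).all()

    def test_planted_shift_detected(self):
        """A strong PB>BM shift in effector PSI reaches significance in most
        random cohorts (Monte-Carlo power check, reduced replication)."""
        rng = np.random.default_rng(0)
        hits = 0
        n_rep = 25
        for _ in range(n_rep):
            rows = []
            for i in range(10):
                base = rng.normal(1000, 150)
                rows.append(("PB", f"P{i:02d}", base + 450))
                rows.append(("BM", f"P{i:02d}", base))
            table = pd.DataFrame(
                {
                    "sample_id": [f"{t}{p}" for t, p, _ in rows],
                    "subset": "CD8",
                    "group": "effector",
                    "n_cells": 100,
                    "n_polyfunctional": 50,
                    "polyfunctional_pct": 50.0,
                    "mfi_sum": [v for _, _, v in rows],
                    "psi": [v for _, _, v in rows],
                }
            )
            sm = pd.DataFrame(
                {
                    "patient_id": [p for _, p, _ in rows],
                    "tissue": [t for t, _, _ in rows],
                    "timepoint": "baseline",
                    "response": "CR",
                    "age": 60.0,
                },
                index=pd.Index(table["sample_id"], name="sample_id"),
            )
            res = pseudobulk_contrast(table, sm, "PB_vs_BM")
            hits += int(res["p_value"].iloc[0] < 0.05)
        assert hits / n_rep >= 0.8

    def test_permutation_type_i_error_calibrated(self):
        """Unpaired CR-vs-NR rank-sum: empirical type-I over label permutations."""
        rng = np.random.default_rng(1)
        psi = rng.normal(1000, 200, 16)
        sample_ids = [f"s{i}" for i in range(16)]
        table = pd.DataFrame(
            {
                "sample_id": sample_ids, "subset": "CD4", "group": "overall",
                "n_cells": 100, "n_polyfunctional": 50,
                "polyfunctional_pct": 50.0, "mfi_sum": psi, "psi": psi,
            }
        )
        hits = 0
        n_perm = 1000
        for _ in range(n_perm):
            resp = rng.permutation(["CR"] * 8 + ["NR"] * 8)
            sm = pd.DataFrame(
                {
                    "patient_id": sample_ids, "tissue": "BM",
                    "timepoint": "baseline", "response": resp, "age": 60.0,
                },
                index=pd.Index(sample_ids, name="sample_id"),
            )
            res = pseudobulk_contrast(table, sm, "CR_vs_NR", tissue="BM")
            hits += int(res["p_value"].iloc[0] < 0.05)
        assert 0.03 <= hits / n_perm <= 0.07


class TestCorrelateCovariate:
    @staticmethod
    def _table(values, ages):
        n = len(values)
        sample_ids = [f"s{i}" for i in range(n)]
        table = pd.DataFrame(
            {
                "sample_id": sample_ids, "subset": "CD4", "group": "IL2",
                "n_cells": 100, "n_polyfunctional": 50,
                "polyfunctional_pct": 50.0, "mfi_sum": values, "psi": values,
            }
        )
        sm = pd.DataFrame(
            {
                "patient_id": sample_ids, "tissue": "PB", "timepoint": "baseline",
                "response": "CR", "age": ages,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        return table, sm

    def test_perfect_monotone_gives_rho_1(self):
        ages = np.arange(50.0, 62.0)
        table, sm = self._table(ages * 10, ages)
        res = correlate_covariate(table, sm)
        assert res["rho"].iloc[0] == pytest.approx(1.0)

    def test_planted_negative_age_effect_recovered(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(47, 90, 20)
        values = 3000 - 25 * ages + rng.normal(0, 100, 20)
        table, sm = self._table(values, ages)
        res = correlate_covariate(table, sm)
        assert res["rho"].iloc[0] < -0.5
        assert res["p_value"].iloc[0] < 0.05

    def test_constant_covariate_flagged(self):
        table, sm = self._table(np.arange(10.0), np.full(10, 68.0))
        res = correlate_covariate(table, sm)
        assert (res["flag"] == "constant_covariate").all()

    def test_null_covariate_false_positive_rate(self):
        """Independent covariate: |rho| crosses the 0.05 critical value ~5% of the time."""
        rng = np.random.default_rng(4)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            table, sm = self._table(rng.normal(0, 1, 12), rng.uniform(47, 90, 12))
            res = correlate_covariate(table, sm)
            hits += int(res["p_value"].iloc[0] < 0.05)
        assert 0.02 <= hits / n_rep <= 0.08
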