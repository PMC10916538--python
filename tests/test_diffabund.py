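import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from secretome import (
    beeswarm_export,
    build_knn_graph,
    classify_exclusivity,
    count_cells,
    exclusivity_summary,
    sample_neighborhoods,
    spatial_fdr,
)
from secretome.diffabund import format_pct
from secretome.diffabund import test_da as nb_test  # alias: pytest must not collect it


def make_nhoods(X, cell_ids, k=3, proportion=1.0, seed=0):
    knn = build_knn_graph(X, k=k)
    return sample_neighborhoods(knn, X, pd.Index(cell_ids, name="cell_id"),
                                proportion=proportion, k=k, seed=seed)


def meta_frame(cell_ids, sample_ids, timepoints):
    return pd.DataFrame(
        {"sample_id": sample_ids, "timepoint": timepoints},
        index=pd.Index(cell_ids, name="cell_id"),
    )


class TestSampleNeighborhoods:
    def test_full_proportion_covers_most_cells(self):
        # refinement dedups index cells, so coverage is near- but not
        # necessarily complete at proportion 1
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        nh = make_nhoods(X, [f"c{i}" for i in range(40)], k=4, proportion=1.0)
        covered = np.asarray(nh.membership.sum(axis=0)).ravel()
        assert (covered > 0).mean() >= 0.8
        assert nh.n_neighborhoods <= 40
        assert len(set(nh.index_cells)) == nh.n_neighborhoods

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 3))
        ids = [f"c{i}" for i in range(60)]
        nh1 = make_nhoods(X, ids, k=5, proportion=0.3, seed=9)
        nh2 = make_nhoods(X, ids, k=5, proportion=0.3, seed=9)
        assert (nh1.index_cells == nh2.index_cells).all()
        assert (nh1.membership != nh2.membership).nnz == 0

    def test_disconnected_populations_never_span(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.2, (30, 3)), rng.normal(50, 0.2, (30, 3))])
        nh = make_nhoods(X, [f"c{i}" for i in range(60)], k=5, proportion=1.0)
        M = nh.membership.toarray()
        for row in M:
            members = np.flatnonzero(row)
            assert members.max() < 30 or members.min() >= 30

    def test_neighborhood_size_is_k_plus_1(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 3))
        nh = make_nhoods(X, [f"c{i}" for i in range(50)], k=6, proportion=0.5)
        assert (nh.sizes() == 7).all()

    def test_zero_proportion_rejected(self):
        X = np.zeros((10, 2))
        knn = build_knn_graph(X + np.arange(10)[:, None], k=2)
        with pytest.raises(ValueError):
            sample_neighborhoods(knn, X, pd.Index([f"c{i}" for i in range(10)]), proportion=0.0)


class TestCountCells:
    def test_single_sample_single_neighborhood(self):
        X = np.arange(5, dtype=float)[:, None]
        ids = [f"c{i}" for i in range(5)]
        nh = make_nhoods(X, ids, k=4, proportion=0.2, seed=0)
        meta = meta_frame(ids, ["s1"] * 5, ["baseline"] * 5)
        counts = count_cells(nh, meta)
        assert counts.shape[1] == 1
        assert (counts.sum(axis=1) == nh.sizes()).all()

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 3))
        ids = [f"c{i}" for i in range(80)]
        samples = rng.choice(["s1", "s2", "s3"], 80)
        nh = make_nhoods(X, ids, k=7, proportion=0.4, seed=1)
        meta = meta_frame(ids, samples, ["baseline"] * 80)
        counts = count_cells(nh, meta)
        M = nh.membership.toarray()
        for h in range(nh.n_neighborhoods):
            for s in counts.columns:
                expected = int(((samples == s) & M[h]).sum())
                assert counts.iloc[h][s] == expected

    def test_even_split_gives_equal_columns(self):
        X = np.arange(10, dtype=float)[:, None]
        ids = [f"c{i}" for i in range(10)]
        samples = ["s1", "s2"] * 5
        nh = make_nhoods(X, ids, k=9, proportion=0.1, seed=0)
        meta = meta_frame(ids, samples, ["baseline"] * 10)
        counts = count_cells(nh, meta)
        assert counts.iloc[0]["s1"] == counts.iloc[0]["s2"]


class TestTestDa:
    @staticmethod
    def _design(n_base=3, n_post=3):
        names = [f"b{i}" for i in range(n_base)] + [f"p{i}" for i in range(n_post)]
        tps = ["baseline"] * n_base + ["post_IO"] * n_post
        return pd.Series(tps, index=pd.Index(names, name="sample_id"))

    def test_equal_proportions_give_null_result(self):
        design = self._design()
        counts = pd.DataFrame(
            np.full((20, 6), 10.0), columns=design.index
        )
        totals = pd.Series(100.0, index=design.index)
        res = nb_test(counts, design, totals)
        assert np.allclose(res["log_fold_change"], 0.0)
        assert (res["p_value"] > 0.9).all()

    def test_lfc_matches_rate_ratio(self):
        design = self._design()
        counts = pd.DataFrame([[5, 5, 5, 20, 20, 20.0]], columns=design.index)
        totals = pd.Series(100.0, index=design.index)
        res = nb_test(counts, design, totals)
        assert res["log_fold_change"].iloc[0] == pytest.approx(np.log(4.0))

    def test_offsets_absorb_depth_differences(self):
        design = self._design()
        counts = pd.DataFrame([[5, 5, 5, 10, 10, 10.0]], columns=design.index)
        totals = pd.Series([100, 100, 100, 200, 200, 200.0], index=design.index)
        res = nb_test(counts, design, totals)
        assert res["log_fold_change"].iloc[0] == pytest.approx(0.0)

    def test_zero_group_flagged_with_continuity(self):
        design = self._design()
        counts = pd.DataFrame([[4, 4, 4, 0, 0, 0.0]], columns=design.index)
        totals = pd.Series(100.0, index=design.index)
        res = nb_test(counts, design, totals)
        assert res["flag"].iloc[0] == "zero_group"
        assert np.isfinite(res["log_fold_change"].iloc[0])
        assert res["log_fold_change"].iloc[0] < 0

    def test_all_zero_untestable(self):
        design = self._design()
        counts = pd.DataFrame([[0, 0, 0, 0, 0, 0.0], [3, 3, 3, 3, 3, 3.0]], columns=design.index)
        totals = pd.Series(100.0, index=design.index)
        res = nb_test(counts, design, totals)
        assert res["flag"].iloc[0] == "untestable"
        assert np.isnan(res["p_value"].iloc[0])
        assert np.isfinite(res["p_value"].iloc[1])

    def test_needs_two_samples_per_arm(self):
        design = pd.Series(
            ["baseline", "post_IO", "post_IO"],
            index=pd.Index(["a", "b", "c"], name="sample_id"),
        )
        counts = pd.DataFrame([[1, 1, 1.0]], columns=design.index)
        with pytest.raises(ValueError):
            nb_test(counts, design, pd.Series(10.0, index=design.index))

    def test_null_type_i_error_on_iid_counts(self):
        """Permutation calibration on synthetic overdispersed counts."""
        rng = np.random.default_rng(5)
        design = self._design(6, 6)
        mu, alpha = 6.0, 0.25
        Y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu), size=(400, 12)).astype(float)
        totals = pd.Series(1000.0, index=design.index)
        rates = []
        for _ in range(60):
            perm = pd.Series(rng.permutation(design.to_numpy()), index=design.index)
            res = nb_test(pd.DataFrame(Y, columns=design.index), perm, totals)
            rates.append((res["p_value"] < 0.05).mean())
        assert 0.02 <= np.mean(rates) <= 0.08


class TestSpatialFdr:
    def test_equal_distances_reduce_to_bh(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(5, 60))
            ours = spatial_fdr(p, np.full(len(p), 2.5))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, ref)

    def test_all_p_one_stay_one(self):
        p = np.ones(10)
        assert np.allclose(spatial_fdr(p, np.arange(1, 11.0)), 1.0)

    def test_single_neighborhood_unchanged(self):
        assert spatial_fdr(np.array([0.04]), np.array([1.0]))[0] == pytest.approx(0.04)

    def test_zero_distance_weight_capped(self):
        p = np.array([0.01, 0.5, 0.9])
        d = np.array([0.0, 1.0, 1.0])
        q = spatial_fdr(p, d)
        assert np.isfinite(q).all() and (q <= 1).all()

    def test_missing_p_propagates(self):
        p = np.array([0.02, np.nan, 0.5])
        q = spatial_fdr(p, np.ones(3))
        assert np.isnan(q[1]) and np.isfinite(q[0])


class TestExclusivity:
    def _nhoods_with_labels(self, groups):
        """Build neighborhoods as disjoint index blocks over concatenated cells."""
        from scipy import sparse

        cells = []
        rows, cols = [], []
        tps = []
        for h, tp_list in enumerate(groups):
            for tp in tp_list:
                cols.append(len(cells))
                rows.append(h)
                cells.append(f"c{len(cells)}")
                tps.append(tp)
        membership = sparse.csr_matrix(
            (np.ones(len(cols), bool), (rows, cols)), shape=(len(groups), len(cells))
        )
        from secretome.diffabund import NeighborhoodSet

        nh = NeighborhoodSet(
            membership=membership,
            index_cells=np.array([0] * len(groups)),
            distances=np.ones(len(groups)),
            cell_index=pd.Index(cells, name="cell_id"),
        )
        meta = pd.DataFrame(
            {"sample_id": "s1", "timepoint": tps},
            index=pd.Index(cells, name="cell_id"),
        )
        return nh, meta

    def test_classes_assigned_from_member_timepoints(self):
        nh, meta = self._nhoods_with_labels(
            [["baseline", "baseline"], ["post_IO"], ["baseline", "post_IO"]]
        )
        labels = classify_exclusivity(nh, meta)
        assert list(labels) == ["baseline_only", "post_only", "mixed"]

    def test_classification_is_test_free(self):
        # identical labels regardless of any p-values computed elsewhere
        nh, meta = self._nhoods_with_labels([["baseline"], ["post_IO", "baseline"]])
        l1 = classify_exclusivity(nh, meta)
        l2 = classify_exclusivity(nh, meta)
        assert (l1 == l2).all()

    def test_exclusive_fraction_shrinks_with_size(self):
        """Random balanced labels: P(exclusive) = 2^-(size-1) halves per member."""
        rng = np.random.default_rng(7)
        for size, bound in [(3, 0.25 * 2), (8, 2 ** -7 * 4)]:
            hits = 0
            n_rep = 2000
            for _ in range(n_rep):
                tps = rng.choice(["baseline", "post_IO"], size)
                hits += int(len(set(tps)) == 1)
            assert hits / n_rep <= bound + 3 * np.sqrt(bound * (1 - bound) / n_rep)


class TestSummaryFormatting:
    def test_percent_formatting_one_decimal_or_two_below_1(self):
        assert format_pct(45.51) == "45.5"
        assert format_pct(1.34) == "1.3"
        assert format_pct(0.851) == "0.85"

    def test_summary_reproduces_tally_arithmetic(self):
        labels = pd.Series(
            ["baseline_only"] * 982 + ["post_only"] * 29 + ["mixed"] * (2158 - 982 - 29)
        )
        s = exclusivity_summary(labels)
        assert s["total"] == 2158
        assert s["baseline_only"]["pct_str"] == "45.5"
        assert s["post_only"]["pct_str"] == "1.3"

    def test_fdr_restricted_counts_separate(self):
        labels = pd.Series(["baseline_only", "mixed", "post_only", "mixed"])
        fdr = np.array([0.01, 0.5, 0.05, 0.2])
        s = exclusivity_summary(labels, fdr, 0.1)
        assert s["fdr_restricted"]["total"] == 2
        assert s["fdr_restricted"]["baseline_only"] == 1
        assert s["fdr_restricted"]["post_only"] == 1
        # all-neighborhood percentages unaffected by the FDR restriction
        assert s["baseline_only"]["count"] == 1
        assert s["mixed"]["count"] == 2


def test_beeswarm_export_joins(tmp_path):
    rng = np.random.default_rng(8)
    X = rng.normal(size=(30, 3))
    ids = [f"c{i}" for i in range(30)]
    knn = build_knn_graph(X, k=4)
    nh = sample_neighborhoods(knn, X, pd.Index(ids, name="cell_id"), proportion=0.3, k=4, seed=0)
    meta = meta_frame(ids, ["s1", "s2"] * 15, ["baseline", "post_IO"] * 15)
    labels = classify_exclusivity(nh, meta)
    da = pd.DataFrame(
        {
            "log_fold_change": rng.normal(size=nh.n_neighborhoods),
            "spatial_fdr": rng.uniform(size=nh.n_neighborhoods),
        },
        index=pd.RangeIndex(nh.n_neighborhoods),
    )
    clusters = pd.Series(rng.integers(0, 3, 30), index=pd.Index(ids, name="cell_id"))
    table = beeswarm_export(da, nh, clusters, labels)
    assert len(table) == nh.n_neighborhoods
    h = 0
    idx_cell = nh.cell_index[nh.index_cells[h]]
    assert table.loc[h, "cluster"] == clusters.loc[idx_cell]
    # round trip through CSV preserves the table
    path = tmp_path / "bs.csv"
    table.to_csv(path, index=False)
    back = pd.read_csv(path, float_precision="round_trip")
    pd.testing.assert_frame_equal(back, table)
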