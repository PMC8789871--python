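"""QC, normalization, scaling, profiling, DE, markers and composition."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from alveonet.data import QCThresholds
from alveonet.preprocess import (
    cluster_profiles,
    compare_proportions,
    differential_expression,
    marker_dor,
    normalize_cp10k,
    qc_filter,
    scale_genes,
)

from conftest import make_dataset, make_meta, random_dataset


def exact_rank_sum_p(x, y):
    """Independent oracle: full enumeration of rank-sum assignments."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, n = len(x), len(pooled)
    mu = n1 * (n + 1) / 2.0
    w_obs = ranks[:n1].sum()
    hits = total = 0
    for combo in itertools.combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestQCFilter:
    def test_strict_boundaries_human_preset(self):
        # 999 transcripts -> removed; mito exactly 0.20 -> retained
        counts = np.array([[999], [1000], [1000], [1000]])
        ds = make_dataset(
            counts,
            mito=[0.05, 0.20, 0.21, 0.05],
            unspliced=[0.30, 0.30, 0.30, 0.119],
        )
        out, report = qc_filter(ds, QCThresholds.human(), return_report=True)
        assert out.cell_meta["cell_id"].tolist() == ["c001"]
        assert report["removed_low_transcripts"] == 1
        assert report["removed_high_mito"] == 1
        assert report["removed_low_unspliced"] == 1

    def test_all_pass_identity(self):
        ds = make_dataset(np.full((5, 2), 600))
        out = qc_filter(ds, QCThresholds.human())
        assert out.cell_meta["cell_id"].tolist() == ds.cell_meta["cell_id"].tolist()

    def test_all_removed_raises_with_advice(self):
        ds = make_dataset([[1], [2]])
        with pytest.raises(ValueError, match="review thresholds"):
            qc_filter(ds, QCThresholds.human())

    def test_missing_qc_column_named(self, tiny_dataset):
        ds = tiny_dataset
        ds.cell_meta = ds.cell_meta.drop(columns=["unspliced_fraction"])
        with pytest.raises(ValueError, match="unspliced_fraction"):
            qc_filter(ds, QCThresholds(0, 1.0, 0.0))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        ds = make_dataset(
            rng.poisson(60, size=(n, 4)) * rng.integers(10, 40, size=(n, 1)),
            mito=rng.uniform(0, 0.4, n).tolist(),
            unspliced=rng.uniform(0, 0.4, n).tolist(),
        )
        thr = QCThresholds.human()
        once = qc_filter(ds, thr)
        twice = qc_filter(once, thr)
        assert twice.cell_meta["cell_id"].tolist() == once.cell_meta["cell_id"].tolist()
        np.testing.assert_array_equal(twice.counts_dense(), once.counts_dense())


class TestNormalizeCP10K:
    def test_direct_formula(self):
        ds = make_dataset([[10, 0], [5, 5]])
        out = normalize_cp10k(ds)
        assert out.normalized[0, 0] == pytest.approx(np.log(10001.0), rel=1e-12)
        assert out.normalized[0, 1] == 0.0
        assert out.normalized[1, 0] == pytest.approx(np.log(5001.0), rel=1e-12)
        assert out.normalized[1, 1] == pytest.approx(np.log(5001.0), rel=1e-12)

    def test_conservation_to_10k(self):
        ds = random_dataset(5, n_cells=30, n_genes=10)
        keep = ds.total_transcripts > 0
        out = normalize_cp10k(ds.subset_cells(keep))
        sums = np.expm1(out.normalized).sum(axis=1)
        np.testing.assert_allclose(sums, 1e4, rtol=1e-6)

    def test_zero_total_cell_named(self):
        ds = make_dataset([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="c000"):
            normalize_cp10k(ds)


class TestScaleGenes:
    def test_two_cell_z_scores(self):
        ds = make_dataset([[1, 1], [1, 1]]).with_layer(normalized=np.array([[0.0, 1.0], [2.0, 1.0]]))
        out = scale_genes(ds, covariate=None)
        np.testing.assert_allclose(out.scaled[:, 0], [-1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12)
        np.testing.assert_allclose(out.scaled[:, 1], [0.0, 0.0])  # constant gene

    def test_clip_bound(self):
        values = np.zeros((20, 1))
        values[0, 0] = 100.0
        ds = make_dataset(np.ones((20, 1), dtype=int)).with_layer(normalized=values)
        out = scale_genes(ds, covariate=None, clip=2.0)
        assert out.scaled.max() == pytest.approx(2.0)

    def test_covariate_regression_removes_linear_trend(self):
        n = 10
        mito = np.linspace(0.0, 0.2, n)
        rng = np.random.default_rng(4)
        normalized = np.column_stack([3.0 * mito + 1.0, rng.normal(1.0, 0.5, n)])
        ds = make_dataset(np.ones((n, 2), dtype=int), mito=mito.tolist()).with_layer(
            normalized=normalized
        )
        out = scale_genes(ds, covariate="mito_fraction")
        # gene 0 is a pure function of the covariate -> residuals ~ 0 -> zero column
        np.testing.assert_allclose(out.scaled[:, 0], 0.0, atol=1e-8)
        assert np.std(out.scaled[:, 1]) > 0


class TestClusterProfiles:
    def test_mean_and_pct(self):
        counts = np.array([[0], [0], [3], [7]])
        ds = make_dataset(counts)
        ds = ds.with_layer(normalized=np.array([[1.0], [2.0], [3.0], [2.0]]))
        prof = cluster_profiles(ds)
        row = prof.table.iloc[0]
        assert row["mean_norm"] == pytest.approx(2.0)
        assert row["pct_expressing"] == pytest.approx(0.5)
        assert row["n_cells"] == 4

    def test_matches_bruteforce_groupby(self):
        ds = random_dataset(11, n_cells=50, n_genes=6)
        ds = normalize_cp10k(ds.subset_cells(ds.total_transcripts > 0))
        ds = scale_genes(ds, covariate=None)
        prof = cluster_profiles(ds)
        meta = ds.cell_meta
        normalized = ds.normalized
        for row in prof.table.sample(20, random_state=0).itertuples():
            idx = np.flatnonzero(
                (meta["condition"] == row.condition) & (meta["cell_type"] == row.cell_type)
            )
            g = ds.gene_ids.index(row.gene)
            assert row.mean_norm == pytest.approx(normalized[idx, g].mean(), abs=1e-12)
            assert row.pct_expressing == pytest.approx((ds.counts_dense()[idx, g] > 0).mean())
            assert row.n_cells == len(idx)

    def test_missing_group_key_raises(self, tiny_dataset):
        ds = normalize_cp10k(tiny_dataset)
        with pytest.raises(ValueError, match="batch"):
            cluster_profiles(ds, group_by=("condition", "batch"))


def _de_dataset(values_a, values_b, n_genes=1):
    """One cell type, two conditions, normalized layer set directly."""
    n_a, n_b = len(values_a), len(values_b)
    counts = np.ones((n_a + n_b, n_genes), dtype=int)
    ds = make_dataset(counts, conditions=["control"] * n_a + ["disease"] * n_b)
    normalized = np.tile(np.concatenate([values_a, values_b])[:, None], (1, n_genes))
    return ds.with_layer(normalized=normalized.astype(float))


class TestDifferentialExpression:
    def test_identical_groups_null(self):
        ds = _de_dataset([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = differential_expression(ds, "A", "control", "disease")
        assert res.table["fold_change"][0] == pytest.approx(1.0)
        assert res.table["p_value"][0] == pytest.approx(1.0)

    def test_all_zero_gene_fc_one(self):
        ds = _de_dataset([0.0, 0.0, 0.0], [0.0, 0.0, 0.0])
        res = differential_expression(ds, "A", "control", "disease")
        assert res.table["fold_change"][0] == pytest.approx(1.0)

    def test_exact_p_matches_enumeration_4v4(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 4), rng.normal(1, 1, 4)
        ds = _de_dataset(a, b)
        res = differential_expression(ds, "A", "control", "disease")
        assert res.table["p_value"][0] == pytest.approx(exact_rank_sum_p(a, b), abs=1e-12)

    def test_unknown_labels_and_small_groups_raise(self):
        ds = _de_dataset([1.0, 2.0, 3.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="unknown cell_type"):
            differential_expression(ds, "B", "control", "disease")
        with pytest.raises(ValueError, match=">= 3 cells"):
            differential_expression(ds, "A", "control", "disease")

    def test_bonferroni_over_tested_genes_only(self):
        rng = np.random.default_rng(0)
        n = 8
        counts = np.zeros((2 * n, 3), dtype=int)
        counts[:, 0] = 1  # expressed everywhere
        counts[:n, 1] = 1  # expressed in one group only
        ds = make_dataset(counts, conditions=["control"] * n + ["disease"] * n)
        normalized = counts.astype(float) + rng.normal(0, 0.01, size=counts.shape)
        ds = ds.with_layer(normalized=np.abs(normalized))
        res = differential_expression(ds, "A", "control", "disease", min_pct=0.4)
        tested = res.table["tested"]
        assert tested.tolist() == [True, True, False]
        np.testing.assert_allclose(
            res.table.loc[tested, "p_adjusted"],
            np.minimum(1.0, res.table.loc[tested, "p_value"] * 2),
        )


class TestMarkerDOR:
    def test_continuity_corrected_arithmetic(self):
        # in-type: 8/10 detected, out-type: 2/10 detected
        counts = np.zeros((20, 1), dtype=int)
        counts[:8, 0] = 1
        counts[10:12, 0] = 1
        ds = make_dataset(counts, cell_types=["A"] * 10 + ["B"] * 10)
        table = marker_dor(ds)
        row = table[(table["cell_type"] == "A")].iloc[0]
        assert (row.TP, row.FP, row.FN, row.TN) == (8, 2, 2, 8)
        assert row.DOR == pytest.approx((8.5 * 8.5) / (2.5 * 2.5))

    def test_perfect_marker(self):
        counts = np.zeros((20, 1), dtype=int)
        counts[:10, 0] = 1
        ds = make_dataset(counts, cell_types=["A"] * 10 + ["B"] * 10)
        row = marker_dor(ds).query("cell_type == 'A'").iloc[0]
        assert row.DOR == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))  # 441

    def test_undetected_gene_symmetric_correction(self):
        counts = np.zeros((20, 1), dtype=int)
        ds = make_dataset(counts, cell_types=["A"] * 10 + ["B"] * 10)
        assert marker_dor(ds)["DOR"].tolist() == [1.0, 1.0]

    def test_in_out_swap_reciprocal(self):
        ds = random_dataset(17, n_cells=40, n_genes=5, n_types=2)
        table = marker_dor(ds)
        a = table[table["cell_type"] == "T0"].set_index("gene")["DOR"]
        b = table[table["cell_type"] == "T1"].set_index("gene")["DOR"]
        np.testing.assert_allclose(a, 1.0 / b[a.index], rtol=1e-12)

    def test_single_type_rejected(self):
        ds = make_dataset([[1], [1]])
        with pytest.raises(ValueError, match="2 cell types"):
            marker_dor(ds)


class TestCompareProportions:
    @staticmethod
    def _composition_dataset(rng, probs_by_condition, n_subjects=8, cells_per_subject=300):
        rows, conditions, subjects, types = [], [], [], []
        for cond, probs in probs_by_condition.items():
            for s in range(n_subjects):
                sid = f"{cond}_s{s}"
                counts = rng.multinomial(cells_per_subject, probs)
                for t, c in enumerate(counts):
                    for _ in range(c):
                        conditions.append(cond)
                        subjects.append(sid)
                        types.append(f"T{t}")
        n = len(types)
        return make_dataset(
            np.zeros((n, 1), dtype=int),
            conditions=conditions,
            subjects=subjects,
            cell_types=types,
        )

    def test_identical_composition_null(self):
        # every subject has exactly 20 T0, 30 T1, 50 T2 cells
        conditions, subjects, types = [], [], []
        for cond in ("control", "disease"):
            for s in range(4):
                sid = f"{cond}_s{s}"
                for t, c in zip(("T0", "T1", "T2"), (20, 30, 50)):
                    conditions += [cond] * c
                    subjects += [sid] * c
                    types += [t] * c
        ds = make_dataset(
            np.zeros((len(types), 1), dtype=int),
            conditions=conditions, subjects=subjects, cell_types=types,
        )
        res = compare_proportions(ds, "epithelial")
        np.testing.assert_allclose(res.table["fold_change"], 1.0)
        np.testing.assert_allclose(res.table["p_value"], 1.0)

    def test_absent_in_control_flagged_inf(self):
        conditions = ["control"] * 4 + ["disease"] * 4
        subjects = [f"{c}_s{i % 2}" for i, c in enumerate(conditions)]
        types = ["A", "A", "A", "A", "B", "A", "B", "A"]
        ds = make_dataset(
            np.zeros((8, 1), dtype=int),
            conditions=conditions, subjects=subjects, cell_types=types,
        )
        res = compare_proportions(ds, "epithelial")
        assert np.isinf(res.table.set_index("cell_type").loc["B", "fold_change"])

    def test_planted_doubling_recovered(self):
        """Doubling one cell type's proportion is estimated and detected."""
        base = np.array([0.2, 0.3, 0.5])
        shifted = np.array([0.4, 0.3, 0.5])
        shifted = shifted / shifted.sum() * np.array([1.0, 1.0, 1.0])
        shifted = np.array([0.4, 0.3 * 0.75, 0.5 * 0.75])
        fcs, detected = [], 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            ds = self._composition_dataset(
                rng, {"control": base, "disease": shifted}
            )
            res = compare_proportions(ds, "epithelial")
            row = res.table.set_index("cell_type").loc["T0"]
            fcs.append(row["fold_change"])
            detected += row["p_adjusted"] < 0.05
        assert 1.6 <= np.mean(fcs) <= 2.4
        assert detected / n_rep >= 0.90
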