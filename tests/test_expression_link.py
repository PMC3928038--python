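"""Normalization, regulated-gene calls and peak-gene association."""

import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from trescan import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    Peak,
    associate_peaks_to_genes,
    classify_gene_sets,
    differential_calls,
    normalize_expression,
    regulation_binding_heatmap_table,
)
from trescan.expression_link import peak_tss_gap


def _expr(values, groups, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    df = pd.DataFrame(values, index=genes, columns=list(groups))
    return ExpressionMatrix(df, groups)


def _gene(gene_id, chrom, start, end, strand="+"):
    return GeneModel(
        gene_id=gene_id,
        interval=GenomicInterval(chrom, start, end, strand),
        cds_start=start,
        cds_end=end,
        exons=(GenomicInterval(chrom, start, end, strand),),
    )


class TestNormalizeExpression:
    def test_permuted_columns_are_fixed_point(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(10, 1000, size=50)
        cols = {f"s{j}": rng.permutation(base) for j in range(4)}
        raw = pd.DataFrame(cols)
        groups = {c: "a" for c in raw.columns}
        out = normalize_expression(raw, groups).values
        for c in out.columns:
            np.testing.assert_allclose(
                np.sort(out[c]), np.sort(np.log2(base + 50)), rtol=1e-12
            )

    def test_single_sample_is_log_transform_only(self):
        raw = pd.DataFrame({"s1": [0.0, 50.0, 206.0]})
        out = normalize_expression(raw, {"s1": "a"}).values
        np.testing.assert_allclose(
            out["s1"], np.log2(np.array([0, 50, 206.0]) + 50)
        )

    def test_matches_rank_mean_oracle(self):
        rng = np.random.default_rng(2)
        raw = pd.DataFrame(
            rng.uniform(1, 5000, size=(100, 6)),
            columns=[f"s{j}" for j in range(6)],
        )
        groups = {c: "a" for c in raw.columns}
        got = normalize_expression(raw, groups).values.to_numpy()
        # independent oracle on the logged matrix
        logged = np.log2(raw.to_numpy() + 50)
        mu = np.sort(logged, axis=0).mean(axis=1)
        expected = np.empty_like(logged)
        for j in range(6):
            ranks = logged[:, j].argsort().argsort()
            expected[:, j] = mu[ranks]
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_ties_share_rank_mean(self):
        raw = pd.DataFrame({"s1": [10.0, 10.0, 100.0], "s2": [10.0, 20.0, 100.0]})
        out = normalize_expression(raw, {"s1": "a", "s2": "a"}).values
        assert out["s1"][0] == pytest.approx(out["s1"][1])

    def test_negative_intensity_raises(self):
        raw = pd.DataFrame({"s1": [1.0, -2.0]}, index=["g0", "g1"])
        with pytest.raises(ValueError, match="g1"):
            normalize_expression(raw, {"s1": "a"})

    def test_non_numeric_cell_named(self):
        raw = pd.DataFrame({"s1": [1.0, "oops"]}, index=["g0", "g1"])
        with pytest.raises(ValueError, match="g1"):
            normalize_expression(raw, {"s1": "a"})


class TestDifferentialCalls:
    GROUPS = {f"a{i}": "ctrl" for i in range(3)} | {f"b{i}": "t3" for i in range(3)}

    def test_noise_free_shift_called_induced_with_exact_fold(self):
        # two genes whose values make every column a permutation of the
        # others: quantile normalization is then the identity and the
        # planted 1.0 log2 shift is recovered as exactly fold 2
        raw = 2.0 ** np.array(
            [
                [10.0, 10.0, 10.0, 11.0, 11.0, 11.0],
                [11.0, 11.0, 11.0, 10.0, 10.0, 10.0],
            ]
        ) - 50.0
        jitter = np.array([0.0, 1e-4, 2e-4] * 2)  # break zero variance
        expr = normalize_expression(
            pd.DataFrame(raw + jitter, index=["up", "down"], columns=list(self.GROUPS)),
            self.GROUPS,
        )
        calls = differential_calls(expr, "ctrl", "t3").set_index("gene_id")
        assert calls.loc["up", "log2_fold_change"] == pytest.approx(1.0, abs=1e-3)
        assert calls.loc["up", "call"] == "induced"
        assert calls.loc["down", "call"] == "repressed"

    def test_bh_equals_step_up_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            _, adj, _, _ = multipletests(p, method="fdr_bh")
            # brute-force step-up
            m = len(p)
            order = np.argsort(p)
            stepped = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(stepped, 1.0)
            np.testing.assert_allclose(adj, expected, rtol=1e-12)

    def test_bh_analytic_example(self):
        _, adj, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_invariant_under_sample_relabeling_within_group(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(8, 1, size=(40, 6))
        expr1 = _expr(vals, self.GROUPS)
        shuffled = vals[:, [2, 0, 1, 4, 5, 3]]  # permute within each group
        expr2 = _expr(shuffled, self.GROUPS)
        c1 = differential_calls(expr1, "ctrl", "t3")
        c2 = differential_calls(expr2, "ctrl", "t3")
        np.testing.assert_allclose(c1["p_value"], c2["p_value"])
        np.testing.assert_allclose(c1["log2_fold_change"], c2["log2_fold_change"])

    def test_adj_p_never_below_p(self):
        rng = np.random.default_rng(5)
        expr = _expr(rng.normal(8, 1, size=(60, 6)), self.GROUPS)
        calls = differential_calls(expr, "ctrl", "t3")
        assert (calls["adj_p"] >= calls["p_value"] - 1e-12).all()

    def test_single_replicate_group_rejected(self):
        groups = {"a0": "ctrl", "b0": "t3", "b1": "t3"}
        expr = _expr(np.ones((5, 3)), groups)
        with pytest.raises(ValueError):
            differential_calls(expr, "ctrl", "t3")

    def test_null_false_call_rate_within_band(self):
        rng = np.random.default_rng(6)
        n = 500
        expr = _expr(rng.normal(8, 0.25, size=(n, 6)), self.GROUPS)
        calls = differential_calls(expr, "ctrl", "t3")
        n_called = int((calls["call"] != "unchanged").sum())
        # BH at alpha=0.05 on pure nulls: expected discoveries ~ 0
        assert n_called <= 0.05 * n + 3 * math.sqrt(0.05 * n)


class TestAssociation:
    def _setup(self):
        genes = [
            _gene("near", "c1", 100_000, 105_000),
            _gene("mid", "c1", 200_000, 205_000),
            _gene("far", "c1", 400_000, 405_000),
        ]
        peaks = [
            Peak(GenomicInterval("c1", 99_200, 99_300)),  # gap 700 from near TSS
            Peak(GenomicInterval("c1", 198_000, 198_800)),  # gap 1200 from mid TSS
        ]
        return genes, peaks

    def test_gap_definition(self):
        tss = 10_000
        assert peak_tss_gap(Peak(GenomicInterval("c", tss - 800, tss - 700)), tss) == 700
        assert peak_tss_gap(Peak(GenomicInterval("c", tss - 50, tss + 50)), tss) == 0

    def test_distance_thresholds_and_monotonicity(self):
        genes, peaks = self._setup()
        classes = {"induced": ["near", "mid"], "unchanged": ["far"]}
        table = associate_peaks_to_genes(classes, genes, peaks)
        ind = table[table["gene_class"] == "induced"].set_index("distance_bp")
        assert ind.loc[1000, "n_with_peak"] == 1  # gap 700 counted, 1200 not
        assert ind.loc[5000, "n_with_peak"] == 2
        assert ind.loc[25000, "n_with_peak"] == 2
        for cls in table["gene_class"].unique():
            pct = table[table["gene_class"] == cls].sort_values("distance_bp")["pct"]
            assert pct.is_monotonic_increasing
        unch = table[table["gene_class"] == "unchanged"]
        assert (unch["n_with_peak"] == 0).all()

    def test_missing_gene_model_excluded_and_counted(self):
        genes, peaks = self._setup()
        classes = {"induced": ["near", "ghost"]}
        table = associate_peaks_to_genes(classes, genes, peaks)
        assert table.attrs["n_missing_models"] == 1
        assert (table["n_genes"] == 1).all()


class TestHeatmapTable:
    GROUPS = {f"a{i}": "ctrl" for i in range(3)} | {f"b{i}": "t3" for i in range(3)}

    def _calls_and_expr(self, log2fc):
        rng = np.random.default_rng(7)
        n = len(log2fc)
        vals = np.tile(rng.normal(8, 0.1, size=(n, 1)), (1, 6))
        vals[:, 3:] += np.asarray(log2fc)[:, None]
        vals += rng.normal(0, 0.05, size=vals.shape)
        expr = _expr(vals, self.GROUPS, genes=[f"g{i}" for i in range(n)])
        calls = differential_calls(expr, "ctrl", "t3")
        return calls, expr

    def test_flags_nested_and_restricted_to_strong_folds(self):
        calls, expr = self._calls_and_expr([2.0] + [0.0] * 20)
        genes = [_gene(f"g{i}", "c1", 50_000 * (i + 1), 50_000 * (i + 1) + 2000) for i in range(21)]
        peaks = [Peak(GenomicInterval("c1", 49_600, 49_700))]  # 400 bp gap to g0 TSS
        table = regulation_binding_heatmap_table(calls, expr, genes, peaks, fold_floor=2.5)
        assert list(table["gene_id"]) == ["g0"]
        row = table.iloc[0]
        assert row["has_peak_1kb"] and row["has_peak_5kb"] and row["has_peak_25kb"]

    def test_no_gene_passes_floor_gives_empty_table(self):
        calls, expr = self._calls_and_expr([0.0] * 10)
        genes = [_gene(f"g{i}", "c1", 50_000 * (i + 1), 50_000 * (i + 1) + 2000) for i in range(10)]
        table = regulation_binding_heatmap_table(calls, expr, genes, [], fold_floor=2.5)
        assert table.empty
        assert "gene_id" in table.columns

    def test_flags_equal_association_recomputation(self, default_bundle):
        from trescan import normalize_expression as norm

        expr = norm(default_bundle.expression, default_bundle.groups)
        calls = differential_calls(expr, "control", "treated")
        peaks = [p for ps in default_bundle.peak_sets.values() for p in ps]
        table = regulation_binding_heatmap_table(
            calls, expr, default_bundle.genes, peaks
        )
        models = {g.gene_id: g for g in default_bundle.genes}
        for _, row in table.head(20).iterrows():
            g = models[row["gene_id"]]
            gap = min(
                (peak_tss_gap(p, g.tss) for p in peaks if p.interval.chrom == g.interval.chrom),
                default=math.inf,
            )
            assert row["has_peak_1kb"] == (gap <= 1000)
            assert row["has_peak_25kb"] == (gap <= 25000)


class TestGeneClassSets:
    def test_null_class_is_strict(self):
        calls = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "d"],
                "log2_fold_change": [2.0, 0.01, 0.5, -0.02],
                "p_value": [1e-6, 0.9, 0.2, 0.8],
                "adj_p": [1e-4, 0.95, 0.4, 0.9],
                "call": ["induced", "unchanged", "unchanged", "unchanged"],
            }
        )
        classes = classify_gene_sets(calls)
        assert classes["induced"] == ["a"]
        # c: adj_p < 0.5 -> not clean null; d qualifies, b qualifies
        assert set(classes["unchanged"]) == {"b", "d"}
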