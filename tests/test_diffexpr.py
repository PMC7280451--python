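"""Preprocessing, moderated statistics, BH, selection and rollup."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glycotrait.diffexpr import (
    TwoGroupFit,
    background_floor,
    bh_adjust,
    export_heatmap_table,
    fit_two_group,
    medianpolish_summarize,
    quantile_normalize,
    select_differential,
    summarize_categories,
)


def frame(values, columns=None):
    values = np.asarray(values, dtype=float)
    columns = columns or [f"a{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, columns=columns,
                        index=[f"p{i}" for i in range(values.shape[0])])


class TestBackgroundFloor:
    def test_constant_array_collapses_to_floor(self):
        m = frame(np.full((10, 2), 7.0))
        out = background_floor(m, q=0.02, floor=1.0)
        assert (out.to_numpy() == 1.0).all()

    def test_q_zero_is_identity(self):
        m = frame(np.random.default_rng(0).lognormal(5, 1, (20, 3)))
        pd.testing.assert_frame_equal(background_floor(m, q=0.0), m)

    def test_rank_order_preserved_within_arrays(self):
        rng = np.random.default_rng(1)
        m = frame(rng.lognormal(5, 1, (50, 4)))
        out = background_floor(m, q=0.1)
        for col in m.columns:
            order = np.argsort(m[col].to_numpy())
            reordered = out[col].to_numpy()[order]
            # clipping can create ties at the floor but never inversions
            assert (np.diff(reordered) >= 0).all()

    def test_bad_quantile_raises(self):
        with pytest.raises(ValueError):
            background_floor(frame([[1.0]]), q=0.6)


class TestQuantileNormalize:
    def test_reference_example(self):
        m = frame(np.array([[2.0, 4.0], [1.0, 5.0], [3.0, 6.0]]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.iloc[:, 0], [3.5, 2.5, 4.5])
        np.testing.assert_allclose(out.iloc[:, 1], [2.5, 3.5, 4.5])

    def test_identical_columns_fixed_point(self):
        col = np.random.default_rng(2).lognormal(4, 1, 30)
        m = frame(np.column_stack([col, col, col]))
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_sorted_columns_identical_afterwards(self):
        rng = np.random.default_rng(3)
        m = frame(rng.lognormal(4, 1, (200, 5)))
        out = quantile_normalize(m).to_numpy()
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, out.shape[1]):
            np.testing.assert_array_equal(sorted_cols[:, j], sorted_cols[:, 0])

    def test_ties_get_mean_rank_value(self):
        m = frame(np.array([[1.0, 10.0], [1.0, 20.0], [2.0, 30.0]]))
        out = quantile_normalize(m)
        # the tied pair shares the mean of the two lowest rank-values
        assert out.iloc[0, 0] == out.iloc[1, 0]


class TestMedianPolish:
    def test_single_probe_gene_passthrough(self):
        m = frame([[4.0, 8.0]], columns=["x", "y"])
        expr = medianpolish_summarize(m, {"p0": "G"})
        np.testing.assert_allclose(expr.loc["G"], np.log2([4.0, 8.0]))

    def test_two_by_two_hand_iteration(self):
        # probe-set log2 values [[1,2],[3,4]]: overall 2.5, column effects
        # (-0.5, +0.5), expression (2.0, 3.0), residuals all zero
        m = frame(np.exp2([[1.0, 2.0], [3.0, 4.0]]), columns=["x", "y"])
        expr = medianpolish_summarize(m, {"p0": "G", "p1": "G"})
        np.testing.assert_allclose(expr.loc["G"], [2.0, 3.0], atol=1e-12)

    def test_residual_medians_vanish(self):
        from glycotrait.diffexpr import _median_polish

        rng = np.random.default_rng(4)
        block = rng.normal(8, 2, (5, 6))
        overall, row_eff, col_eff, resid = _median_polish(block)
        assert np.abs(np.median(resid, axis=0)).max() < 1e-6
        assert np.abs(np.median(resid, axis=1)).max() < 1e-6
        # decomposition reconstructs the input
        recon = overall + row_eff[:, None] + col_eff[None, :] + resid
        np.testing.assert_allclose(recon, block, atol=1e-12)


class TestFitTwoGroup:
    def design(self, n=3):
        cols = [f"a{i}" for i in range(2 * n)]
        return cols, {c: ("g1" if i < n else "g2") for i, c in enumerate(cols)}

    def test_prior_none_equals_classical_pooled_t(self):
        rng = np.random.default_rng(5)
        cols, design = self.design(4)
        expr = pd.DataFrame(rng.normal(8, 1, (30, 8)), columns=cols,
                            index=[f"g{i}" for i in range(30)])
        fit = fit_two_group(expr, design, prior="none")
        t_ref, p_ref = stats.ttest_ind(
            expr[cols[4:]], expr[cols[:4]], axis=1, equal_var=True
        )
        np.testing.assert_allclose(fit.moderated_t, t_ref, atol=1e-10)
        np.testing.assert_allclose(fit.p, p_ref, atol=1e-10)

    def test_fold_change_sign_and_magnitude(self):
        cols, design = self.design(3)
        base = np.full((1, 6), 8.0)
        base[0, 3:] += 1.0  # group2 doubled
        expr = pd.DataFrame(base + np.arange(6) * 1e-12, columns=cols, index=["g"])
        fit = fit_two_group(expr, design, prior="moments")
        assert fit.log2_fc[0] == pytest.approx(1.0)

    def test_moderation_shrinks_extreme_variances(self):
        rng = np.random.default_rng(6)
        cols, design = self.design(3)
        expr = pd.DataFrame(rng.normal(0, 1, (500, 6)), columns=cols,
                            index=[f"g{i}" for i in range(500)])
        fit = fit_two_group(expr, design, prior="moments")
        assert np.isfinite(fit.d0) and fit.d0 > 0 or np.isinf(fit.d0)
        fit_plain = fit_two_group(expr, design, prior="none")
        # moderated statistics are less dispersed than ordinary t
        assert np.std(fit.moderated_t) < np.std(fit_plain.moderated_t)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        cols, design = self.design(3)
        expr = pd.DataFrame(rng.normal(8, 0.3, (2000, 6)), columns=cols,
                            index=[f"g{i}" for i in range(2000)])
        fit = fit_two_group(expr, design, prior="moments")
        frac = float(np.mean(fit.p < 0.05))
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_one_group_needs_two_arrays_without_prior(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["a", "b", "c"], index=["g"])
        design = {"a": "g1", "b": "g2", "c": "g2"}
        with pytest.raises(ValueError):
            fit_two_group(expr, design, prior="none")
        fit = fit_two_group(expr, design, prior="moments")
        assert np.isfinite(fit.log2_fc).all()

    def test_agrees_with_limma_oracle(self, tmp_path):
        """Cross-check the moderated fit against Bioconductor limma."""
        rng = np.random.default_rng(8)
        cols, design = self.design(3)
        values = rng.normal(8, 1, (60, 6))
        values[:6, 3:] += 1.5
        expr = pd.DataFrame(values, columns=cols,
                            index=[f"g{i}" for i in range(60)])
        expr_path = tmp_path / "expr.tsv"
        expr.to_csv(expr_path, sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly = TRUE)
            x <- as.matrix(read.delim(args[1], row.names = 1))
            design <- cbind(Intercept = 1, g2 = c(0, 0, 0, 1, 1, 1))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t = fit$t[, "g2"], p = fit$p.value[, "g2"],
                              fc = fit$coefficients[, "g2"], d0 = fit$df.prior,
                              s0 = fit$s2.prior)
            write.table(out, args[2], sep = "\t", quote = FALSE)
            """
        )
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "oracle.R"), str(expr_path),
             str(tmp_path / "out.tsv")],
            check=True, capture_output=True,
        )
        oracle = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        fit = fit_two_group(expr, design, prior="moments")
        np.testing.assert_allclose(fit.log2_fc, oracle["fc"], atol=1e-8)
        np.testing.assert_allclose(fit.d0, oracle["d0"].iloc[0], rtol=1e-3)
        np.testing.assert_allclose(fit.moderated_t, oracle["t"], rtol=1e-4)
        np.testing.assert_allclose(fit.p, oracle["p"], rtol=1e-3)


class TestBH:
    def test_hand_applied_step_up(self):
        adjusted = bh_adjust([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(adjusted, [0.02, 0.04, 0.04, 0.02])

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.031]), [0.031])

    def test_monotone_and_never_below_raw(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])


class TestSelection:
    def fit_frame(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2_fc", "moderated_t", "p"])

    def test_pass_and_fail_rules(self):
        frame_ = self.fit_frame(
            [("up", np.log2(2.0), 5.0, 1e-4),
             ("small_fc", np.log2(1.4), 4.0, 1e-4),
             ("not_sig", np.log2(3.0), 1.0, 0.9)]
        )
        out = select_differential(frame_, fc_threshold=1.5, alpha=0.1)
        passes = out.set_index("gene")["passes"]
        assert passes["up"]
        assert not passes["small_fc"]
        assert not passes["not_sig"]
        assert (out["adjusted_p"] >= out["p"] - 1e-15).all()

    def test_bad_threshold_raises(self):
        with pytest.raises(ValueError):
            select_differential(self.fit_frame([("g", 1.0, 1.0, 0.5)]), fc_threshold=0.5)


class TestCategories:
    def test_gt_share_of_passing_genes(self):
        # 73 glycosyltransferase genes among 281 passing genes -> 26%
        rows = [(f"gt{i}", 1.0, 5.0, 1e-5) for i in range(73)]
        rows += [(f"other{i}", 1.0, 5.0, 1e-5) for i in range(281 - 73)]
        frame_ = pd.DataFrame(rows, columns=["gene", "log2_fc", "moderated_t", "p"])
        cats = {f"gt{i}": "GT" for i in range(73)}
        out = select_differential(frame_, category_map=cats)
        summary = summarize_categories(out).set_index("category")
        assert summary.loc["GT", "count"] == 73
        assert summary.loc["GT", "percent"] == 26
        assert summary.loc["miscellaneous", "count"] == 208
        assert summary["count"].sum() == 281

    def test_empty_passing_set(self):
        frame_ = pd.DataFrame(
            [("g", 0.0, 0.0, 1.0)], columns=["gene", "log2_fc", "moderated_t", "p"]
        )
        out = select_differential(frame_)
        assert summarize_categories(out)["count"].sum() == 0


class TestHeatmapExport:
    def expr(self):
        rng = np.random.default_rng(10)
        values = rng.normal(8, 1, (6, 6))
        values[3] = values[0]  # an identical pair
        return pd.DataFrame(values, columns=[f"a{i}" for i in range(6)],
                            index=["gA", "gB", "gC", "gD", "gE", "gF"])

    def test_identical_rows_adjacent(self):
        out = export_heatmap_table(self.expr(), ["gA", "gB", "gC", "gD", "gE", "gF"])
        order = list(out.index)
        assert abs(order.index("gA") - order.index("gD")) == 1

    def test_row_set_equals_passing_set_and_deterministic(self, tmp_path):
        expr = self.expr()
        out1 = export_heatmap_table(expr, ["gC", "gA", "gF"], tmp_path / "h1.tsv")
        out2 = export_heatmap_table(expr, ["gF", "gC", "gA"], tmp_path / "h2.tsv")
        assert set(out1.index) == {"gA", "gC", "gF"}
        assert list(out1.index) == list(out2.index)
        assert (tmp_path / "h1.tsv").read_bytes() == (tmp_path / "h2.tsv").read_bytes()

    def test_fewer_than_two_genes_raises(self):
        with pytest.raises(ValueError):
            export_heatmap_table(self.expr(), ["gA"])
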