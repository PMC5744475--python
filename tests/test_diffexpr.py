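"""Differential abundance: normalization, moderated t, FDR, skewness."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import dryseed as ds
from conftest import two_group_matrix


def _matrix_from_values(values, groups):
    cols = [f"s{i}" for i in range(values.shape[1])]
    vals = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])], columns=cols)
    meta = pd.DataFrame({"group": groups}, index=cols)
    return ds.ExpressionMatrix(vals, meta)


class TestRemoveControls:
    def test_drops_prefixed_rows_preserving_order(self):
        vals = np.arange(20, dtype=float).reshape(10, 2)
        ids = [f"At9g{i:05d}" for i in range(8)] + ["AFFX-a", "AFFX-b"]
        mat = _matrix_from_values(vals, ["A", "B"])
        mat = ds.ExpressionMatrix(pd.DataFrame(vals, index=ids, columns=mat.values.columns), mat.samples)
        out = ds.remove_controls(mat, "AFFX")
        assert list(out.gene_ids) == ids[:8]

    def test_identity_when_no_controls(self):
        mat = _matrix_from_values(np.ones((4, 2)), ["A", "B"])
        out = ds.remove_controls(mat, "AFFX")
        assert list(out.gene_ids) == list(mat.gene_ids)

    def test_prefix_match_is_case_sensitive(self):
        vals = np.ones((3, 2))
        ids = ["affx-low", "AFFX-up", "g1"]
        meta = pd.DataFrame({"group": ["A", "B"]}, index=["s0", "s1"])
        mat = ds.ExpressionMatrix(pd.DataFrame(vals, index=ids, columns=["s0", "s1"]), meta)
        out = ds.remove_controls(mat, "AFFX")
        assert "affx-low" in out.gene_ids and "AFFX-up" not in out.gene_ids

    def test_error_when_everything_removed(self):
        meta = pd.DataFrame({"group": ["A", "B"]}, index=["s0", "s1"])
        mat = ds.ExpressionMatrix(
            pd.DataFrame(np.ones((2, 2)), index=["AFFX-1", "AFFX-2"], columns=["s0", "s1"]), meta
        )
        with pytest.raises(ValueError):
            ds.remove_controls(mat, "AFFX")


class TestQuantileNormalize:
    def test_two_by_two_hand_example(self):
        # columns [1,5] and [3,7]; sorted row means are [2,6]
        mat = _matrix_from_values(np.array([[1.0, 3.0], [5.0, 7.0]]), ["A", "B"])
        out = ds.quantile_normalize(mat)
        np.testing.assert_allclose(np.sort(out.values.to_numpy(), axis=0),
                                   np.array([[2.0, 2.0], [6.0, 6.0]]))

    def test_sorted_columns_identical_after_normalization(self):
        rng = np.random.default_rng(1)
        mat = _matrix_from_values(rng.normal(8, 2, size=(50, 4)), ["A", "A", "B", "B"])
        out = ds.quantile_normalize(mat).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_identical_distributions_unchanged(self):
        col = np.array([1.0, 4.0, 9.0])
        mat = _matrix_from_values(np.column_stack([col, col[::-1]]), ["A", "B"])
        out = ds.quantile_normalize(mat).values.to_numpy()
        np.testing.assert_allclose(np.sort(out, axis=0), np.column_stack([col, col]))

    def test_rank_order_preserved_within_sample(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        mat = _matrix_from_values(X, ["A", "A", "B"])
        out = ds.quantile_normalize(mat).values.to_numpy()
        for j in range(3):
            assert (np.argsort(X[:, j]) == np.argsort(out[:, j])).all()

    def test_nan_input_rejected(self):
        X = np.ones((3, 2))
        X[0, 0] = np.nan
        meta = pd.DataFrame({"group": ["A", "B"]}, index=["s0", "s1"])
        vals = pd.DataFrame(X, index=list("abc"), columns=["s0", "s1"])
        with pytest.raises(ValueError):
            ds.ExpressionMatrix(vals, meta)


class TestModeratedT:
    def test_prior_df_zero_equals_pooled_t(self):
        rng = np.random.default_rng(3)
        A = rng.normal(8, 1, size=(40, 3))
        B = rng.normal(8, 1, size=(40, 4))
        mat = two_group_matrix(A, B)
        res = ds.moderated_t_contrast(mat, ds.ContrastSpec("AvsB", "A", "B"), prior_df=0)
        t_ref, p_ref = stats.ttest_ind(A, B, axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["t"].to_numpy(), t_ref, rtol=1e-11)
        np.testing.assert_allclose(res.table["p"].to_numpy(), p_ref, rtol=1e-11)

    def test_prior_df_inf_gives_shared_variance(self):
        rng = np.random.default_rng(4)
        A, B = rng.normal(size=(30, 3)), rng.normal(size=(30, 3))
        mat = two_group_matrix(A, B)
        res = ds.moderated_t_contrast(mat, ds.ContrastSpec("AvsB", "A", "B"), prior_df=np.inf)
        lfc = res.table["logFC"].to_numpy()
        t = res.table["t"].to_numpy()
        se = lfc / t
        np.testing.assert_allclose(se, se[0], rtol=1e-10)

    def test_matches_limma_ebayes(self, tmp_path):
        """Independent oracle: R limma's lmFit + eBayes on the same matrix."""
        rng = np.random.default_rng(42)
        n, na, nb = 150, 3, 3
        X = rng.normal(8, 1, size=(n, 1)) + rng.normal(
            0, rng.uniform(0.1, 0.5, size=(n, 1)), size=(n, na + nb)
        )
        X[:10, :na] += 2.0
        mat = two_group_matrix(X[:, :na], X[:, na:])
        res = ds.moderated_t_contrast(mat, ds.ContrastSpec("AvsB", "A", "B"))

        mat.values.to_csv(tmp_path / "x.tsv", sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{tmp_path}/x.tsv", row.names=1))
            design <- cbind(A=rep(c(1,0),c({na},{nb})), B=rep(c(0,1),c({na},{nb})))
            fit <- eBayes(contrasts.fit(lmFit(x, design), makeContrasts(A-B, levels=design)))
            write.csv(data.frame(t=fit$t[,1], p=fit$p.value[,1], d0=fit$df.prior, s0=fit$s2.prior),
                      "{tmp_path}/limma.csv")
        """)
        (tmp_path / "s.R").write_text(script)
        proc = subprocess.run(["Rscript", str(tmp_path / "s.R")], capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"Rscript/limma unavailable: {proc.stderr[-200:]}")
        lim = pd.read_csv(tmp_path / "limma.csv", index_col=0)
        assert res.prior_df == pytest.approx(lim["d0"].iloc[0], rel=1e-5)
        assert res.prior_var == pytest.approx(lim["s0"].iloc[0], rel=1e-5)
        np.testing.assert_allclose(res.table["t"].to_numpy(), lim["t"].to_numpy(), rtol=1e-6)

    def test_sensitivity_on_planted_simulation(self):
        # 1000 genes, 50 planted at |logFC| = 2, sigma = 0.2, n = 3/group
        rng = np.random.default_rng(7)
        n, n_de = 1000, 50
        A = rng.normal(8, 0.2, size=(n, 3))
        B = rng.normal(8, 0.2, size=(n, 3))
        signs = np.where(rng.random(n_de) < 0.5, -2.0, 2.0)
        A[:n_de] += signs[:, None]
        mat = two_group_matrix(A, B)
        res = ds.moderated_t_contrast(mat, ds.ContrastSpec("AvsB", "A", "B"))
        sets = ds.classify_de(res)
        found = len((sets.up | sets.down) & {f"g{i}" for i in range(n_de)})
        assert found / n_de >= 0.9

    def test_single_replicate_group_rejected(self):
        mat = two_group_matrix(np.ones((5, 1)), np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(ValueError):
            ds.moderated_t_contrast(mat, ds.ContrastSpec("AvsB", "A", "B"))


class TestAdjustBH:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(ds.adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_and_singleton(self):
        np.testing.assert_allclose(ds.adjust_bh([1.0, 1.0, 1.0]), 1.0)
        np.testing.assert_allclose(ds.adjust_bh([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ds.adjust_bh([0.5, 1.5])

    def test_fdr_controlled_under_global_null(self):
        # 100 seeded null datasets of 1000 genes: mean false-discovery
        # proportion at BH alpha=0.05 stays within Monte-Carlo slack
        rng = np.random.default_rng(123)
        fdps = []
        for _ in range(100):
            p = rng.uniform(size=1000)
            rejected = ds.adjust_bh(p) < 0.05
            # under the global null every discovery is false
            fdps.append(1.0 if rejected.any() else 0.0)
        fdps = np.array(fdps)
        mc_err = max(fdps.std(ddof=1) / np.sqrt(len(fdps)), np.sqrt(0.05 * 0.95 / len(fdps)))
        assert fdps.mean() <= 0.05 + 3 * mc_err


class TestClassifyDE:
    def test_worked_example_dry_column(self):
        parsed = ds.parse_logfc_table(ds.worked_example_table())
        dry = parsed["timepoints"]["dry"]
        assert (len(dry.up), len(dry.down)) == (5, 2)

    def test_empty_when_nothing_significant(self):
        table = pd.DataFrame(
            {"logFC": [1.0, -1.0], "t": [1, -1], "p": [0.5, 0.6], "p_adj": [0.9, 0.9],
             "significant": [False, False]},
            index=["g1", "g2"],
        )
        res = ds.DEResult(table=table, contrast=ds.ContrastSpec("c", "A", "B"),
                          alpha=0.05, prior_df=0, prior_var=1)
        sets = ds.classify_de(res)
        assert sets.up == set() and sets.down == set()

    def test_all_positive_leaves_down_empty(self):
        table = pd.DataFrame(
            {"logFC": [1.0, 2.0], "t": [5, 6], "p": [1e-4, 1e-5], "p_adj": [1e-3, 1e-4],
             "significant": [True, True]},
            index=["g1", "g2"],
        )
        res = ds.DEResult(table=table, contrast=ds.ContrastSpec("c", "A", "B"),
                          alpha=0.05, prior_df=0, prior_var=1)
        sets = ds.classify_de(res)
        assert sets.up == {"g1", "g2"} and sets.down == set()

    def test_sets_disjoint_and_significant(self, small_config, small_dataset):
        _, _, mat = small_dataset
        cleaned = ds.quantile_normalize(ds.remove_controls(mat))
        res = ds.moderated_t_contrast(cleaned, ds.ContrastSpec("DvsWT", "D", "WT"))
        sets = ds.classify_de(res)
        assert not sets.up & sets.down
        for g in sets.all:
            assert res.table.loc[g, "p_adj"] < res.alpha


class TestSkewnessG1:
    def test_symmetric_input_is_zero(self):
        assert ds.skewness_g1([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-14)

    def test_matches_independent_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        # brute-force evaluation of the adjusted moment coefficient
        n, xb, s = len(x), x.mean(), x.std(ddof=1)
        expected = n / ((n - 1) * (n - 2)) * np.sum(((x - xb) / s) ** 3)
        assert ds.skewness_g1(x) == pytest.approx(expected, rel=1e-14)
        # scipy's bias-corrected skew is the same statistic
        assert ds.skewness_g1(x) == pytest.approx(stats.skew(x, bias=False), rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=40))
    def test_antisymmetric_under_negation(self, xs):
        x = np.asarray(xs)
        if x.std(ddof=1) == 0:
            return
        assert ds.skewness_g1(-x) == pytest.approx(-ds.skewness_g1(x), abs=1e-8)

    @pytest.mark.parametrize("bad", [[1.0, 2.0], [3.0, 3.0, 3.0]])
    def test_short_or_constant_input_rejected(self, bad):
        with pytest.raises(ValueError):
            ds.skewness_g1(bad)

    def test_down_skew_of_planted_imbalanced_contrasts(self):
        # pi_down = 0.65 planted contrasts at n = 800: G1 of the full logFC
        # distribution is negative in >= 99/100 seeded replicates.  The sign
        # of the third moment is the planted imbalance signal against
        # third-moment sampling noise: per planted gene the expected cube is
        # (0.35 - 0.65) E[m^3] ~ -1.5 with sd ~ sqrt(E[m^6]) ~ 7.1 for
        # |m| ~ |N(1.5, 0.6)|, so >= 99% sign agreement needs
        # k >~ (2.33 * 7.1 / 1.5)^2 ~ 130 planted effects; 200 gives z ~ 3.
        k = 200
        negative = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            lfc = np.zeros(800)
            de = rng.choice(800, size=k, replace=False)
            mags = np.abs(rng.normal(1.5, 0.6, size=k))
            signs = np.where(rng.random(k) < 0.65, -1, 1)
            lfc[de] = signs * mags
            lfc += rng.normal(0, 0.05, size=800)  # measurement noise
            negative += ds.skewness_g1(lfc) < 0
        assert negative >= 99
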