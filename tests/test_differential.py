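import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from scfocal.differential import (
    aggregate_subject_logfc,
    compare_logfc_sets,
    fit_moderated,
    transform,
    trigamma_inverse,
)
from scfocal.perturbation import RESISTANT, SENSITIVE, split_cells


def _split_for(cells, n_resistant):
    rho = pd.Series(
        [0.5] * n_resistant + [-0.5] * (len(cells) - n_resistant), index=cells
    )
    return split_cells(rho, mode="fixed", tau=0.0)


def _random_problem(rng, n_sig=50, n_res=12, n_sen=10, effect=0.0):
    cells = [f"c{i}" for i in range(n_res + n_sen)]
    vals = rng.normal(size=(n_sig, len(cells))) * rng.uniform(0.5, 2.0, size=(n_sig, 1))
    vals[:, :n_res] += effect
    conn = pd.DataFrame(np.tanh(vals * 0.3), index=[f"s{i}" for i in range(n_sig)], columns=cells)
    return conn, _split_for(cells, n_res)


class TestTransform:
    def test_fisher_z_values(self):
        conn = pd.DataFrame([[0.0, 0.5, 1.0, -1.0]], index=["s"], columns=list("abcd"))
        tc = transform(conn, "fisher_z")
        assert tc.values.loc["s", "a"] == 0.0
        assert tc.values.loc["s", "b"] == pytest.approx(math.atanh(0.5))
        assert np.isfinite(tc.values.loc["s", "c"])
        assert np.isfinite(tc.values.loc["s", "d"])

    def test_fisher_z_is_odd(self, rng):
        conn = pd.DataFrame(rng.uniform(-0.99, 0.99, size=(3, 10)))
        a = transform(conn, "fisher_z").values.to_numpy()
        b = transform(-conn, "fisher_z").values.to_numpy()
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_pseudocount_log_defined_at_minus_one(self):
        conn = pd.DataFrame([[-1.0, 0.0]], columns=["a", "b"])
        tc = transform(conn, "pseudocount_log")
        assert np.isfinite(tc.values.iloc[0, 0])
        assert tc.values.iloc[0, 1] == pytest.approx(math.log2(1 + 1e-6))

    def test_none_is_identity_and_unknown_errors(self, rng):
        conn = pd.DataFrame(rng.uniform(-1, 1, size=(2, 4)))
        pd.testing.assert_frame_equal(transform(conn, "none").values, conn)
        with pytest.raises(ValueError):
            transform(conn, "bogus")


class TestTrigammaInverse:
    @pytest.mark.parametrize("y", [0.01, 0.1, 1.0, 5.0, 50.0])
    def test_inverts_trigamma(self, y):
        from scipy.special import polygamma

        x = float(polygamma(1, y))
        assert trigamma_inverse(x) == pytest.approx(y, rel=1e-6)


class TestFitModerated:
    def test_equal_group_means_null(self):
        cells = [f"c{i}" for i in range(10)]
        vals = np.tile(np.array([0.2, -0.1, 0.3, 0.0, 0.1] * 2), (4, 1))
        conn = pd.DataFrame(vals, index=[f"s{i}" for i in range(4)], columns=cells)
        tc = transform(conn, "none")
        table, _ = fit_moderated(tc, _split_for(cells, 5))
        np.testing.assert_allclose(table["log2FC"].to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(table["p"].to_numpy(), 1.0, atol=1e-9)

    def test_d0_zero_matches_ols_oracle(self, rng):
        import statsmodels.api as sm

        conn, split = _random_problem(rng, n_sig=50, effect=0.3)
        tc = transform(conn, "fisher_z")
        table, params = fit_moderated(tc, split, prior_df=0.0)
        assert params.d0 == 0.0
        X = sm.add_constant((split.labels == RESISTANT).astype(float).to_numpy())
        for sig in conn.index:
            fit = sm.OLS(tc.values.loc[sig].to_numpy(), X).fit()
            assert table.loc[sig, "t"] == pytest.approx(fit.tvalues[1], abs=1e-8)
            assert table.loc[sig, "p"] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_huge_prior_df_converges_to_prior_variance(self, rng):
        conn, split = _random_problem(rng)
        tc = transform(conn, "fisher_z")
        table, params = fit_moderated(tc, split, prior_df=1e9)
        np.testing.assert_allclose(table["s2_post"].to_numpy(), params.s0_sq, atol=1e-6)

    def test_covariate_absorbs_subject_shift(self, rng):
        conn, split = _random_problem(rng, n_sig=10)
        cells = list(conn.columns)
        meta = pd.DataFrame(
            {"cell_id": cells, "subject": ["p1" if i % 2 else "p2" for i in range(len(cells))]}
        )
        tc = transform(conn, "none")
        base, _ = fit_moderated(tc, split, meta, ["subject"])
        shifted = conn.copy()
        p1_cells = [c for c, s in zip(cells, meta["subject"]) if s == "p1"]
        shifted.loc[:, p1_cells] += 5.0
        tc2 = transform(shifted, "none")
        moved, _ = fit_moderated(tc2, split, meta, ["subject"])
        np.testing.assert_allclose(
            base["log2FC"].to_numpy(), moved["log2FC"].to_numpy(), atol=1e-9
        )

    def test_moderation_stabilizes_t_statistics(self, rng):
        conn, split = _random_problem(rng, n_sig=200, effect=0.0)
        tc = transform(conn, "fisher_z")
        mod, _ = fit_moderated(tc, split)
        ols, _ = fit_moderated(tc, split, prior_df=0.0)
        assert mod["t"].var() <= ols["t"].var()

    def test_bh_adjustment_monotone_and_bounded(self, rng):
        conn, split = _random_problem(rng, n_sig=80, effect=0.2)
        table, _ = fit_moderated(transform(conn, "fisher_z"), split)
        ordered = table.sort_values("p")
        assert (ordered["adj_p"].to_numpy() >= ordered["p"].to_numpy() - 1e-15).all()
        assert (np.diff(ordered["adj_p"].to_numpy()) >= -1e-15).all()

    def test_rank_deficient_design_names_columns(self, rng):
        conn, split = _random_problem(rng, n_sig=5)
        cells = list(conn.columns)
        # covariate identical to the population indicator -> collinear
        meta = pd.DataFrame(
            {"cell_id": cells, "copy": split.labels.loc[cells].to_numpy()}
        )
        with pytest.raises(ValueError, match="collinear"):
            fit_moderated(transform(conn, "none"), split, meta, ["copy"])

    def test_matches_limma_reference(self, rng, tmp_path):
        """Cross-check moderated t and prior estimates against limma via Rscript."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        conn, split = _random_problem(rng, n_sig=40, n_res=11, n_sen=9, effect=0.25)
        tc = transform(conn, "fisher_z")
        table, params = fit_moderated(tc, split)
        y_path, out_path = tmp_path / "y.tsv", tmp_path / "limma.tsv"
        tc.values.to_csv(y_path, sep="\t")
        groups = (split.labels.loc[tc.values.columns] == RESISTANT).astype(int)
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(limma))
                y <- as.matrix(read.delim("{y_path}", row.names = 1, check.names = FALSE))
                design <- cbind(1, c({", ".join(str(g) for g in groups)}))
                fit <- eBayes(lmFit(y, design))
                out <- data.frame(t = fit$t[, 2], p = fit$p.value[, 2])
                out$d0 <- fit$df.prior
                out$s0 <- fit$s2.prior
                write.table(out, "{out_path}", sep = "\\t", quote = FALSE)
                """
            )
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(out_path, sep="\t", index_col=0)
        np.testing.assert_allclose(table["t"].to_numpy(), ref["t"].to_numpy(), atol=1e-6)
        np.testing.assert_allclose(table["p"].to_numpy(), ref["p"].to_numpy(), atol=1e-6)
        assert params.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert params.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-4)


class TestAggregateSubjectLogfc:
    def test_identical_tables_pass_through(self):
        tbl = pd.DataFrame({"log2FC": [1.0, -2.0]}, index=["s1", "s2"])
        out = aggregate_subject_logfc({"p1": tbl, "p2": tbl})
        np.testing.assert_allclose(out["log2FC"].to_numpy(), [1.0, -2.0])
        assert (out["n_subjects"] == 2).all()

    def test_opposite_values_average_to_zero(self):
        a = pd.DataFrame({"log2FC": [-1.0]}, index=["s"])
        b = pd.DataFrame({"log2FC": [1.0]}, index=["s"])
        out = aggregate_subject_logfc({"p1": a, "p2": b})
        assert out.loc["s", "log2FC"] == 0.0

    def test_three_subject_hand_means(self):
        tables = {
            "p1": pd.DataFrame({"log2FC": [0.3, 0.9]}, index=["s1", "s2"]),
            "p2": pd.DataFrame({"log2FC": [0.6, np.nan]}, index=["s1", "s2"]),
            "p3": pd.DataFrame({"log2FC": [0.0, 0.3]}, index=["s1", "s2"]),
        }
        out = aggregate_subject_logfc(tables)
        assert out.loc["s1", "log2FC"] == pytest.approx(0.3)
        assert out.loc["s2", "log2FC"] == pytest.approx(0.6)
        assert out.loc["s2", "n_subjects"] == 2


class TestCompareLogfcSets:
    def test_perfect_and_inverted_agreement(self):
        pred = pd.Series([0.1, 0.4, -0.2, 0.9], index=list("abcd"))
        same = compare_logfc_sets(pred, pred)
        assert same.loc["all", "rho"] == pytest.approx(1.0)
        assert same.loc["all", "p"] == 0.0
        inv = compare_logfc_sets(pred, -pred)
        assert inv.loc["all", "rho"] == pytest.approx(-1.0)

    def test_six_point_toy_matches_scipy(self, rng):
        from scipy.stats import spearmanr

        pred = pd.Series(rng.normal(size=6), index=list("abcdef"))
        obs = pd.Series(rng.normal(size=6), index=list("abcdef"))
        out = compare_logfc_sets(pred, obs)
        rho, p = spearmanr(pred.to_numpy(), obs.to_numpy())
        assert out.loc["all", "rho"] == pytest.approx(rho, abs=1e-12)
        assert out.loc["all", "p"] == pytest.approx(p, abs=1e-10)

    def test_small_classes_skipped(self):
        pred = pd.Series(np.arange(6.0), index=list("abcdef"))
        obs = pred + 0.1
        classes = {"a": "big", "b": "big", "c": "big", "d": "small", "e": "small"}
        out = compare_logfc_sets(pred, obs, classes)
        assert "big" in out.index and "small" not in out.index
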