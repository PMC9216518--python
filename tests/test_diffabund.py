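"""Mann-Whitney tests, BH correction, fold changes, the ±1/0 indicator,
and the empirical-Bayes moderated t."""
import itertools
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import oncomet as om
from oncomet.diffabund import fit_variance_prior, select_heatmap_features


def matrix_from(values, scale_tag="pqn"):
    arr = np.asarray(values, dtype=float)
    return om.AbundanceMatrix(
        pd.DataFrame(arr,
                     index=[f"F{i}" for i in range(arr.shape[0])],
                     columns=[f"S{j}" for j in range(arr.shape[1])]),
        scale_tag=scale_tag,
    )


class TestMannWhitney:
    def test_extreme_separation_exact(self):
        # brute force: of C(6,3)=20 labelings only the 2 extreme ones reach
        # |U - 4.5| as large as observed, giving p = 2/20 = 0.1
        u, p = om.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)
        pooled = [1, 2, 3, 4, 5, 6]
        count = 0
        for combo in itertools.combinations(range(6), 3):
            a = [pooled[i] for i in combo]
            b = [pooled[i] for i in range(6) if i not in combo]
            ua = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
                1 for x in a for y in b if x == y)
            if abs(ua - 4.5) >= abs(0.0 - 4.5):
                count += 1
        assert p == pytest.approx(count / 20)

    def test_identical_groups_p_near_one(self):
        _, p = om.mann_whitney([1.0, 2.0, 5.0], [5.0, 1.0, 2.0])
        assert p >= 0.99

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.lognormal(size=18), rng.lognormal(size=15)
        _, p_raw = om.mann_whitney(a, b)
        _, p_log = om.mann_whitney(np.log2(a), np.log2(b))
        assert p_raw == pytest.approx(p_log)

    def test_empty_group_raises(self):
        with pytest.raises(om.DataError):
            om.mann_whitney([], [1.0])

    def test_type_i_error_calibrated(self):
        # 2000 null simulations at n=20/20: rejection rate at nominal 0.05
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            a, b = rng.normal(size=20), rng.normal(size=20)
            _, p = om.mann_whitney(a, b)
            rejections += p < 0.05
        assert abs(rejections / n_sim - 0.05) <= 0.012


class TestBHAdjust:
    def test_hand_computed_vectors(self):
        np.testing.assert_allclose(om.bh_adjust([0.03]), [0.03])
        # step-up by hand: q_(i) = min_{j>=i} p_(j)*m/j
        np.testing.assert_allclose(
            om.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(
            om.bh_adjust([0.01, 0.04, 0.9]), [0.03, 0.06, 0.9])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(om.bh_adjust([0.2] * 7), [0.2] * 7)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_monotone_capped_and_order_preserving(self, p):
        q = om.bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        # order preserved
        order_p = np.argsort(p, kind="stable")
        assert np.all(np.diff(np.asarray(q)[order_p]) >= -1e-15)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_step_up_formula(self, p):
        m = len(p)
        order = np.argsort(p, kind="stable")
        expected = np.empty(m)
        for rank_pos, i in enumerate(order):
            expected[i] = min(
                min(p[j] * m / (np.searchsorted(np.sort(p), p[j], side="right"))
                    for j in order[rank_pos:]),
                1.0,
            )
        np.testing.assert_allclose(om.bh_adjust(p), expected, rtol=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(om.DataError):
            om.bh_adjust([0.5, 1.5])


class TestFoldChange:
    def test_equal_means_zero(self):
        assert om.log2_fold_change([2, 4], [1, 5]) == pytest.approx(0.0)

    def test_four_fold(self):
        assert om.log2_fold_change([8, 8], [2, 2]) == pytest.approx(2.0)

    def test_median_ratio_option(self):
        assert om.log2_fold_change([1, 2, 100], [1, 2, 4],
                                   fc_definition="median_ratio") == pytest.approx(0.0)


class TestDifferentialAbundance:
    def make_contrast(self, n_a=16, n_b=16, **kw):
        return om.ContrastSpec(
            group_a=[f"S{j}" for j in range(n_a)],
            group_b=[f"S{j}" for j in range(n_a, n_a + n_b)],
            **kw,
        )

    def test_null_yields_no_discoveries(self):
        rng = np.random.default_rng(9)
        m = matrix_from(rng.lognormal(size=(300, 32)))
        da = om.differential_abundance(m, self.make_contrast())
        assert int((da.table["q"] < 0.05).sum()) == 0

    def test_planted_effects_all_flagged_up(self):
        cfg = om.SimulationConfig(
            n_tumor=16, n_normal=16, n_metabolites=200, n_blocks=1,
            censor_quantile=0.0, dilution_range=(1.0, 1.0), n_freeze_assoc=0,
            n_latent_clusters=0,
            effect_table=[(f"M{i + 1:04d}", 3.0) for i in range(20)], seed=31,
        )
        m, ann, truth = om.simulate_metabolomics(cfg)
        contrast = om.ContrastSpec(ann.samples_in_group("tumor"),
                                   ann.samples_in_group("normal"))
        da = om.differential_abundance(om.pqn_normalize(om.impute_min(m))[0], contrast)
        assert (da.table.loc[list(truth.true_effects), "x"] == 1).all()

    def test_indicator_partition(self):
        rng = np.random.default_rng(17)
        m = matrix_from(rng.lognormal(size=(100, 20)))
        da = om.differential_abundance(m, self.make_contrast(10, 10))
        t = da.table
        assert set(t["x"]).issubset({-1, 0, 1})
        assert ((t["x"] != 0) == (t["q"] < da.alpha)).all()
        assert ((t["x"] == 1) == ((t["q"] < da.alpha) & (t["log2fc"] >= 0))).all()

    def test_small_group_raises(self):
        m = matrix_from(np.ones((3, 4)) * 2.0)
        with pytest.raises(om.DataError):
            om.differential_abundance(
                m, om.ContrastSpec(["S0"], ["S1", "S2", "S3"]))


class TestModeratedT:
    def make(self, n_genes=150, n=6, seed=3):
        rng = np.random.default_rng(seed)
        m = matrix_from(rng.normal(5, 1, size=(n_genes, 2 * n)), scale_tag="log2")
        contrast = om.ContrastSpec(
            [f"S{j}" for j in range(n)], [f"S{j}" for j in range(n, 2 * n)])
        return m, contrast

    def test_d0_zero_equals_ordinary_t(self):
        m, contrast = self.make()
        res = om.moderated_t(m, contrast, prior_df=0)
        a = m.data.iloc[:, :6].to_numpy()
        b = m.data.iloc[:, 6:].to_numpy()
        t_ref, p_ref = stats.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["statistic"], t_ref, rtol=1e-10)
        np.testing.assert_allclose(res.table["p"], p_ref, rtol=1e-10)

    def test_d0_infinite_pools_variances(self):
        m, contrast = self.make()
        res = om.moderated_t(m, contrast, prior_df=np.inf)
        # all genes share one residual SE: statistic proportional to the mean
        # difference with a common constant
        delta = res.table["log2fc"].to_numpy()
        ratio = res.table["statistic"].to_numpy() / delta
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-10)

    def test_hyperparameter_recovery(self):
        # variances from a scaled inverse chi-square with known (d0=4, s0²=0.05)
        rng = np.random.default_rng(77)
        d0_true, s02_true, df = 4.0, 0.05, 10
        sigma2 = s02_true * d0_true / rng.chisquare(d0_true, size=5000)
        s2 = sigma2 * rng.chisquare(df, size=5000) / df
        d0_hat, s02_hat = fit_variance_prior(s2, df)
        assert abs(d0_hat - d0_true) / d0_true < 0.15
        assert abs(s02_hat - s02_true) / s02_true < 0.15

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_limma_on_small_matrix(self, tmp_path):
        # independent oracle: limma's eBayes on the same 80×6 matrix with
        # heterogeneous per-gene variances (finite prior df branch)
        rng = np.random.default_rng(8)
        values = rng.normal(5, 1, size=(80, 6)) * rng.uniform(0.3, 3.0, size=(80, 1))
        m = matrix_from(values, scale_tag="log2")
        contrast = om.ContrastSpec([f"S{j}" for j in range(3)],
                                   [f"S{j}" for j in range(3, 6)])
        res = om.moderated_t(m, contrast)
        mat_path = tmp_path / "expr.tsv"
        m.data.to_csv(mat_path, sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{mat_path}", row.names=1))
            design <- cbind(Intercept=1, A=c(1,1,1,0,0,0))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,"A"], p=fit$p.value[,"A"],
                              d0=fit$df.prior, s02=fit$s2.prior)
            write.table(out, "{tmp_path}/limma.tsv", sep="\t", quote=FALSE)
        """)
        (tmp_path / "run.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        np.testing.assert_allclose(res.metadata["d0"], ref["d0"].iloc[0], rtol=1e-4)
        np.testing.assert_allclose(res.metadata["s0_squared"], ref["s02"].iloc[0],
                                   rtol=1e-4)
        np.testing.assert_allclose(res.table["statistic"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(res.table["p"], ref["p"], rtol=1e-6)


class TestSelectHeatmapFeatures:
    def make_da(self, table):
        return om.DAResult(table=table, metadata={"alpha": 0.05})

    def test_empty_result(self):
        table = pd.DataFrame(columns=["log2fc", "statistic", "p", "q", "x"])
        assert select_heatmap_features(self.make_da(table), 0.05, 1.0) == []

    def test_single_passing_feature(self):
        table = pd.DataFrame({"log2fc": [2.0], "statistic": [1.0],
                              "p": [0.001], "q": [0.01], "x": [1]}, index=["F1"])
        assert select_heatmap_features(self.make_da(table), 0.05, 1.0) == ["F1"]

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(55)
        table = pd.DataFrame(
            {"log2fc": rng.normal(0, 2, 100), "statistic": rng.normal(size=100),
             "p": rng.random(100), "q": rng.random(100),
             "x": rng.integers(-1, 2, 100)},
            index=[f"F{i}" for i in range(100)],
        )
        got = select_heatmap_features(self.make_da(table), 0.3, 1.5)
        expected = [fid for fid, row in table.iterrows()
                    if row["q"] < 0.3 and abs(row["log2fc"]) > 1.5]
        expected.sort(key=lambda fid: -abs(table.loc[fid, "log2fc"]))
        assert got == expected
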