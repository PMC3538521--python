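"""Distribution profiles, library comparison, correlation and PCA."""

import numpy as np
import pandas as pd
import pytest

from molprofiler.profiling import (
    compare_libraries, correlate, plot_scores, profile_library, run_pca,
)


def table(**cols):
    return pd.DataFrame(cols)


class TestProfileLibrary:
    def test_constant_column(self):
        p = profile_library(table(x=[3.0, 3.0, 3.0]), histogram_descriptors=["x"])
        assert p.means["x"] == 3.0 and p.sds["x"] == 0.0
        edges, freqs = p.histograms["x"]
        assert len(freqs) == 1 and freqs[0] == 1.0

    def test_sample_sd(self):
        p = profile_library(table(x=[0.0, 2.0]))
        assert p.means["x"] == 1.0
        assert p.sds["x"] == pytest.approx(np.sqrt(2))

    def test_row_order_invariant(self):
        t = table(x=[1.0, 5.0, 2.0], y=[0.1, 0.2, 0.3])
        p1 = profile_library(t)
        p2 = profile_library(t.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_series_equal(p1.means, p2.means)

    def test_histogram_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        p = profile_library(table(MW=rng.uniform(100, 600, 500)),
                            histogram_descriptors=["MW"])
        edges, freqs = p.histograms["MW"]
        assert freqs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(edges) == pytest.approx(50.0))

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            profile_library(pd.DataFrame())


class TestCompareLibraries:
    def test_identical_libraries(self):
        t = table(x=[1.0, 2.0, 3.0])
        out = compare_libraries({"a": t, "b": t.copy()})
        assert (out.mean_diff == 0).all() and (out.ks == 0).all()

    def test_shift_gives_full_ks(self):
        a = table(x=[1.0, 2.0, 3.0])
        b = table(x=[101.0, 102.0, 103.0])
        out = compare_libraries({"a": a, "b": b})
        row = out.iloc[0]
        assert row.mean_diff == pytest.approx(-100.0)
        assert row.ks == pytest.approx(1.0)

    def test_column_mismatch_raises(self):
        with pytest.raises(ValueError):
            compare_libraries({"a": table(x=[1.0]), "b": table(y=[1.0])})

    def test_natural_vs_drug_sign_pattern(self, benchmark_tables):
        out = compare_libraries({
            "naturallike": benchmark_tables["naturallike"],
            "druglike": benchmark_tables["druglike"],
        })
        diff = out.set_index("descriptor").mean_diff  # natural - drug
        assert diff["N_O"] > 0 and diff["N_N"] < 0
        assert diff["N_rot"] < 0 and diff["N_Bridge"] > 0


class TestCorrelate:
    def test_exact_line(self):
        x = np.arange(10.0)
        out = correlate(x, 2 * x + 1)
        assert out["slope"] == pytest.approx(2.0)
        assert out["intercept"] == pytest.approx(1.0)
        assert out["r"] == pytest.approx(1.0)

    def test_independent_variables_have_small_r(self):
        rng = np.random.default_rng(2)
        out = correlate(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(out["r"]) < 0.05

    def test_r_symmetric_under_swap(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert correlate(x, y)["r"] == pytest.approx(correlate(y, x)["r"])

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            correlate(np.ones(5), np.arange(5.0))


class TestPCA:
    def test_single_variance_direction_dominates(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=500)
        df = table(a=t, b=2 * t + rng.normal(0, 1e-3, 500),
                   c=rng.normal(0, 1e-3, 500))
        res = run_pca(df, 2)
        assert res.explained[0] > 0.6

    def test_isotropic_gaussian_equal_fractions(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(10_000, 5)),
                          columns=list("abcde"))
        res = run_pca(df, 5)
        assert np.allclose(res.explained, 0.2, atol=0.02)

    def test_loadings_orthonormal(self, benchmark_tables):
        res = run_pca(benchmark_tables["druglike"], 4)
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(4), atol=1e-8)

    def test_duplicated_column_loads_identically_on_pc1(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=400)
        df = table(a=x, b=x.copy(), c=rng.normal(size=400))
        res = run_pca(df, 2)
        assert res.loadings.loc["a", "PC1"] == pytest.approx(
            res.loadings.loc["b", "PC1"], abs=1e-9)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        res1 = run_pca(df, 2)
        df2 = df.copy()
        df2["a"] = df2["a"] * 37.0 - 5.0
        res2 = run_pca(df2, 2)
        assert np.allclose(res1.explained, res2.explained, atol=1e-10)
        assert np.allclose(res1.scores, res2.scores, atol=1e-8)

    def test_too_few_nonconstant_columns_raises(self):
        with pytest.raises(ValueError):
            run_pca(table(a=[1.0, 1.0, 1.0], b=[1.0, 2.0, 3.0]), 2)

    def test_projection_consistency(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        res = run_pca(df, 2)
        assert np.allclose(res.project(df), res.scores, atol=1e-10)


class TestPlots:
    def test_three_panels_shared_axes(self, tmp_path):
        rng = np.random.default_rng(5)
        pooled_df = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("wxyz"))
        res = run_pca(pooled_df, 2)
        tables = {f"lib{k}": pooled_df.iloc[k * 100:(k + 1) * 100] for k in range(3)}
        path = plot_scores(res, tables, tmp_path)
        assert path.exists() and path.stat().st_size > 0

    def test_empty_library_panel_does_not_crash(self, tmp_path):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        res = run_pca(df, 2)
        path = plot_scores(res, {"full": df, "empty": df.iloc[0:0]}, tmp_path)
        assert path.exists()
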