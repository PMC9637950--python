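import shutil
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from glycoindex import diffexpr
from glycoindex.diffexpr import (
    build_design,
    fit_linear_models,
    moderate_ebayes,
    natural_spline_basis,
    overlap_genes,
    select_degs,
)
from glycoindex.stats import bh_adjust

from conftest import make_dataset
from _oracles import bh_reference


class TestSplineBasis:
    def test_df_one_is_a_single_column(self):
        b = natural_spline_basis(np.linspace(0, 1, 20), df=1)
        assert b.shape == (20, 1)

    def test_df_three_full_rank(self):
        rng = np.random.default_rng(0)
        b = natural_spline_basis(rng.uniform(size=100), df=3)
        assert b.shape == (100, 3)
        assert np.linalg.matrix_rank(np.column_stack([np.ones(100), b])) == 4

    def test_affine_rescaling_spans_same_fit(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(60, 95, size=80)
        y = np.sin(x / 10) + rng.normal(0, 0.1, size=80)
        for df in (1, 3):
            b1 = np.column_stack([np.ones(80), natural_spline_basis(x, df)])
            b2 = np.column_stack([np.ones(80), natural_spline_basis(2 * x + 5, df)])
            f1 = b1 @ np.linalg.lstsq(b1, y, rcond=None)[0]
            f2 = b2 @ np.linalg.lstsq(b2, y, rcond=None)[0]
            np.testing.assert_allclose(f1, f2, atol=1e-8)

    def test_constant_input_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            natural_spline_basis(np.ones(10), df=1)


class TestBuildDesign:
    def _meta(self, n_per_region=6, regions=("EC", "FC", "HP", "TC")):
        rows = []
        for r in regions:
            for i in range(n_per_region):
                rows.append((f"{r}{i}", "case" if i % 2 else "control", r,
                             60.0 + i * 3 + len(r), "M" if i % 3 == 0 else "F"))
        df = pd.DataFrame(rows, columns=["sample_id", "group", "region", "age", "sex"])
        return df.set_index("sample_id")

    def test_four_regions_both_sexes_gives_seven_columns(self):
        d = build_design(self._meta())
        assert len(d.columns) == 7  # intercept + contrast + 3 regions + sex + age

    def test_single_region_drops_region_dummies(self):
        d = build_design(self._meta(regions=("FC",)))
        assert len(d.columns) == 4
        assert not any(c.startswith("region_") for c in d.columns)

    def test_contrast_flip_only_changes_coefficient_sign(self):
        meta = self._meta()
        rng = np.random.default_rng(2)
        ds = make_dataset(rng.normal(size=(30, len(meta))),
                          samples=list(meta.index),
                          groups=list(meta["group"]), regions=list(meta["region"]),
                          ages=meta["age"].values, sexes=list(meta["sex"]))
        d1 = build_design(meta)
        flipped = meta.copy()
        flipped["group"] = np.where(meta["group"] == "case", "control", "case")
        ds2 = make_dataset(ds.values.values, samples=list(meta.index),
                           groups=list(flipped["group"]),
                           regions=list(meta["region"]),
                           ages=meta["age"].values, sexes=list(meta["sex"]))
        d2 = build_design(flipped)
        f1 = fit_linear_models(ds, d1)
        f2 = fit_linear_models(ds2, d2)
        np.testing.assert_allclose(f1.coefficients["contrast"].values,
                                   -f2.coefficients["contrast"].values, atol=1e-10)

    def test_region_confounded_with_contrast_is_an_error(self):
        meta = self._meta(regions=("FC", "HP"))
        meta["group"] = np.where(meta["region"] == "FC", "case", "control")
        with pytest.raises(ValueError, match="rank-deficient|collinear"):
            build_design(meta)

    def test_high_vs_low_requires_split_labels(self):
        with pytest.raises(ValueError, match="split labels"):
            build_design(self._meta(), contrast="high_vs_low_index")


class TestFitLinearModels:
    def test_exact_fit_gives_zero_sigma(self):
        meta = TestBuildDesign()._meta(n_per_region=8, regions=("FC",))
        d = build_design(meta)
        beta = np.array([1.0, 2.0, 0.5, 0.01])
        y = d.matrix @ beta
        ds = make_dataset(y[None, :], samples=list(meta.index),
                          groups=list(meta["group"]), regions=list(meta["region"]),
                          ages=meta["age"].values, sexes=list(meta["sex"]))
        fits = fit_linear_models(ds, d)
        assert fits.sigma2[0] == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(fits.coefficients.values[0], beta, atol=1e-10)

    def test_matches_normal_equation_solution(self):
        rng = np.random.default_rng(3)
        meta = TestBuildDesign()._meta()
        d = build_design(meta)
        Y = rng.normal(size=(5, len(meta)))
        ds = make_dataset(Y, samples=list(meta.index), groups=list(meta["group"]),
                          regions=list(meta["region"]), ages=meta["age"].values,
                          sexes=list(meta["sex"]))
        fits = fit_linear_models(ds, d)
        X = d.matrix
        expected = np.linalg.solve(X.T @ X, X.T @ Y.T).T
        np.testing.assert_allclose(fits.coefficients.values, expected, atol=1e-10)

    def test_planted_log2fc_recovered(self):
        from glycoindex.simulate import SimulationConfig, generate_expression_dataset

        cfg = SimulationConfig(n_genes=400,
                               planted_set=tuple(f"GLY{i:03d}" for i in range(1, 31)),
                               n_per_group=40, effect_size=1.0, noise_sd=0.3,
                               pathway_factor_sd=0.0, coexpr_pairs=(), seed=21)
        ds = generate_expression_dataset(cfg, "FC")
        d = build_design(ds.metadata)
        fits = fit_linear_models(ds, d)
        est = fits.coefficients.loc[list(cfg.planted_set), "contrast"].mean()
        assert est == pytest.approx(1.0, abs=0.1)


class TestModerateEbayes:
    def test_identical_variances_hit_the_pooling_cap(self):
        meta = TestBuildDesign()._meta(n_per_region=8, regions=("FC",))
        d = build_design(meta)
        rng = np.random.default_rng(4)
        base = rng.normal(size=len(meta))
        # every gene = same residual pattern + different fitted part
        Y = np.array([base + k for k in range(20)])
        ds = make_dataset(Y, samples=list(meta.index), groups=list(meta["group"]),
                          regions=list(meta["region"]), ages=meta["age"].values,
                          sexes=list(meta["sex"]))
        fits = fit_linear_models(ds, d)
        table = moderate_ebayes(fits)
        assert table.attrs["d0"] == diffexpr.D0_CAP
        s2_post = (table["sigma"] ** 2 * 0 + table.attrs["s02"])
        t_manual = table["log2fc"] / np.sqrt(s2_post * fits.v_contrast)
        np.testing.assert_allclose(table["t_mod"].values, t_manual.values, rtol=1e-6)

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(5)
        n_genes, n = 2000, 30
        vals = rng.normal(7, 1, size=(n_genes, n)) * (0.5 + rng.random(n_genes))[:, None]
        ds = make_dataset(vals, groups=["control"] * 15 + ["case"] * 15)
        table = moderate_ebayes(fit_linear_models(ds, build_design(ds.metadata)))
        ks = sps.kstest(table["p_value"].values, "uniform")
        assert ks.pvalue > 0.01

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_limma_reference(self, tmp_path):
        """Independent oracle: Bioconductor limma's lmFit + eBayes."""
        rng = np.random.default_rng(7)
        n_genes, n = 60, 16
        vals = rng.normal(7, 1, size=(n_genes, n)) * (0.5 + rng.random(n_genes))[:, None]
        ds = make_dataset(vals, groups=["control"] * 8 + ["case"] * 8)
        design = build_design(ds.metadata)
        table = moderate_ebayes(fit_linear_models(ds, design))
        ds.values.to_csv(tmp_path / "y.tsv", sep="\t")
        design.values.to_csv(tmp_path / "x.tsv", sep="\t")
        script = f"""
        suppressMessages(library(limma))
        y <- as.matrix(read.delim("{tmp_path}/y.tsv", row.names=1))
        x <- as.matrix(read.delim("{tmp_path}/x.tsv", row.names=1))
        fit <- eBayes(lmFit(y, x))
        out <- data.frame(lfc=fit$coefficients[,"contrast"],
                          t=fit$t[,"contrast"], p=fit$p.value[,"contrast"],
                          d0=fit$df.prior, s02=fit$s2.prior)
        write.table(out, "{tmp_path}/out.tsv", sep="\\t", quote=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        assert table.attrs["d0"] == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        np.testing.assert_allclose(table["log2fc"].values, ref["lfc"].values, atol=1e-9)
        np.testing.assert_allclose(table["t_mod"].values, ref["t"].values, atol=1e-8)
        np.testing.assert_allclose(table["p_value"].values, ref["p"].values, atol=1e-9)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_four_value_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=50))
    def test_matches_reference_and_is_order_invariant(self, p):
        p = np.asarray(p)
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, bh_reference(p), atol=1e-12)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestDegSelection:
    def test_toy_table_strict_thresholds(self):
        table = pd.DataFrame(
            {"fdr": [0.04, 0.05, 0.04, 0.04, 0.2],
             "log2fc": [0.6, 0.6, 0.5, -0.7, 2.0]},
            index=["g1", "g2", "g3", "g4", "g5"],
        )
        assert select_degs(table, 0.05, 0.5) == ["g1", "g4"]

    def test_all_insignificant_gives_empty(self):
        table = pd.DataFrame({"fdr": [1.0, 1.0], "log2fc": [3.0, -3.0]},
                             index=["a", "b"])
        assert select_degs(table, 0.05, 0.5) == []

    def test_raising_lfc_threshold_never_adds_genes(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame({"fdr": rng.uniform(size=100),
                              "log2fc": rng.normal(size=100)},
                             index=[f"g{i}" for i in range(100)])
        prev = None
        for lfc in (0.1, 0.5, 1.0, 2.0):
            cur = set(select_degs(table, 0.5, lfc))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_overlap_identity_disjoint_and_counts(self):
        assert overlap_genes(["b", "a"], ["a", "b"]) == ["a", "b"]
        assert overlap_genes(["a"], ["b"]) == []
        rng = np.random.default_rng(8)
        pool = [f"g{i}" for i in range(300)]
        a = list(rng.choice(pool, 100, replace=False))
        b = list(rng.choice(pool, 100, replace=False))
        assert len(overlap_genes(a, b)) == len(set(a) & set(b))


class TestCovariateAdjustment:
    def test_region_confounding_is_absorbed_by_the_design(self):
        """A region-linked shift inflates DEGs only when region is omitted."""
        rng = np.random.default_rng(9)
        n_genes = 600
        n_per = 30
        # two regions with unbalanced case fractions + a region-B shift on
        # 10% of genes; genes have NO true group effect
        rows, vals = [], []
        groups, regions = [], []
        for region, n_case in (("FC", 8), ("HP", 22)):
            for i in range(n_per):
                groups.append("case" if i < n_case else "control")
                regions.append(region)
        vals = rng.normal(0, 0.5, size=(n_genes, 2 * n_per))
        shift_idx = rng.choice(n_genes, size=60, replace=False)
        region_b = np.array(regions) == "HP"
        vals[np.ix_(shift_idx, np.nonzero(region_b)[0])] += 1.0
        ds = make_dataset(vals, groups=groups, regions=regions,
                          ages=rng.uniform(60, 95, 2 * n_per))
        meta = ds.metadata
        with_region = moderate_ebayes(fit_linear_models(ds, build_design(meta)))
        n_with = len(select_degs(with_region, 0.05, 0.5))
        meta_no = meta.copy()
        meta_no["region"] = "ONE"
        ds_no = make_dataset(vals, genes=ds.genes, samples=ds.samples,
                             groups=groups, regions=["ONE"] * (2 * n_per),
                             ages=meta["age"].values, sexes=list(meta["sex"]))
        without = moderate_ebayes(fit_linear_models(ds_no, build_design(ds_no.metadata)))
        n_without = len(select_degs(without, 0.05, 0.5))
        assert n_with <= max(3, 0.01 * n_genes)
        assert n_without > 5 * max(n_with, 1)
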