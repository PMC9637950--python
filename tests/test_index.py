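import numpy as np
import pandas as pd
import pytest

from glycoindex.gsea import GseaResult
from glycoindex.index import (
    glycolysis_index,
    median_split_by_region,
    pool_core_genes,
    ssgsea_score,
)

from conftest import make_dataset
from _oracles import naive_ssgsea


def _result(dataset_id, set_name="S", es=-0.5, fdr=0.01, leading_edge=()):
    return GseaResult(dataset_id=dataset_id, set_name=set_name, es=es, nes=es * 2,
                      p_value=fdr, fdr=fdr, leading_edge=list(leading_edge),
                      n_perm=100, seed=0)


class TestPoolCoreGenes:
    def test_gene_leading_in_two_of_four_datasets_is_included(self):
        results = [
            _result("d1", leading_edge=["A"]),
            _result("d2", leading_edge=["A", "B"]),
            _result("d3", leading_edge=["C"]),
            _result("d4", leading_edge=[]),
        ]
        core = pool_core_genes(results, min_datasets=2)
        assert core.genes == ["A"]
        assert core.support["A"] == ["d1", "d2"]

    def test_single_dataset_support_is_excluded(self):
        results = [_result(f"d{i}", leading_edge=["X"] if i == 1 else ["Y"])
                   for i in range(1, 5)]
        core = pool_core_genes(results, min_datasets=2)
        assert "X" not in core.genes and "Y" in core.genes

    def test_toy_table_matches_enumeration(self):
        # 6 genes x 4 datasets with known membership; expected set by hand
        membership = {
            "A": {"d1", "d2", "d3"},
            "B": {"d1"},
            "C": {"d2", "d4"},
            "D": set(),
            "E": {"d1", "d2", "d3", "d4"},
            "F": {"d3"},
        }
        results = []
        for d in ("d1", "d2", "d3", "d4"):
            le = [g for g, ds in membership.items() if d in ds]
            results.append(_result(d, leading_edge=le))
        core = pool_core_genes(results, min_datasets=2)
        expected = sorted(g for g, ds in membership.items() if len(ds) >= 2)
        assert core.genes == expected

    def test_direction_filter_discards_upregulated_sets(self):
        results = [
            _result("d1", es=+0.5, leading_edge=["A"]),
            _result("d2", es=+0.5, leading_edge=["A"]),
            _result("d1", set_name="S2", es=-0.5, leading_edge=["B"]),
            _result("d2", set_name="S2", es=-0.5, leading_edge=["B"]),
        ]
        core = pool_core_genes(results, min_datasets=2, require_direction="down")
        assert core.genes == ["B"]

    def test_fdr_filter(self):
        results = [
            _result("d1", fdr=0.2, leading_edge=["A"]),
            _result("d2", fdr=0.2, leading_edge=["A"]),
        ]
        assert pool_core_genes(results, 2, fdr_max=0.05).genes == []
        assert pool_core_genes(results, 2, fdr_max=None).genes == ["A"]

    def test_min_datasets_below_one_is_an_error(self):
        with pytest.raises(ValueError):
            pool_core_genes([_result("d1")], min_datasets=0)

    def test_monotone_in_min_datasets(self):
        rng = np.random.default_rng(4)
        results = []
        genes = [f"G{i}" for i in range(12)]
        for d in ("d1", "d2", "d3", "d4"):
            le = list(rng.choice(genes, size=6, replace=False))
            results.append(_result(d, leading_edge=le))
        prev = None
        for m in (4, 3, 2, 1):
            core = set(pool_core_genes(results, min_datasets=m).genes)
            if prev is not None:
                assert prev <= core
            prev = core


class TestSsgsea:
    def test_hand_example_matches_naive_oracle(self):
        genes = ["A", "B", "C", "D", "E"]
        values = [5.0, 4.0, 3.0, 2.0, 1.0]
        gene_set = ["A", "C"]  # positions 1 and 3 of the descending order
        oracle = naive_ssgsea(values, genes, gene_set, alpha=0.25)
        ds = make_dataset(np.array(values)[:, None], genes=genes, samples=["s1"],
                          groups=["control"])
        sv = ssgsea_score(ds, gene_set, alpha=0.25)
        assert sv.scores[0] == pytest.approx(oracle, abs=1e-12)
        assert oracle == pytest.approx(1.730433, abs=1e-5)  # hand-computed

    def test_identical_rankings_give_identical_scores(self):
        base = np.array([5.0, 1.0, 3.0, 2.0, 4.0])
        ds = make_dataset(np.column_stack([base, base * 10 + 3]),
                          groups=["control", "case"])
        sv = ssgsea_score(ds, ds.genes[:2], alpha=0.25)
        assert sv.scores[0] == pytest.approx(sv.scores[1])

    def test_monotone_transform_of_one_sample_leaves_score_unchanged(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(30, 3))
        ds = make_dataset(vals, groups=["control"] * 3)
        doubled = vals.copy()
        doubled[:, 1] = doubled[:, 1] * 2.0
        ds2 = make_dataset(doubled, groups=["control"] * 3)
        s1 = ssgsea_score(ds, ds.genes[:7], 0.25).scores
        s2 = ssgsea_score(ds2, ds.genes[:7], 0.25).scores
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_oracle_equivalence_on_random_samples(self):
        rng = np.random.default_rng(9)
        n_genes = 120
        genes = [f"G{i:03d}" for i in range(n_genes)]
        gene_set = list(rng.choice(genes, size=12, replace=False))
        vals = rng.normal(size=(n_genes, 10))
        ds = make_dataset(vals, genes=genes, groups=["control"] * 10)
        sv = ssgsea_score(ds, gene_set, alpha=0.25)
        for j in range(10):
            oracle = naive_ssgsea(list(vals[:, j]), genes, gene_set, 0.25)
            assert sv.scores[j] == pytest.approx(oracle, abs=1e-10)

    def test_scores_independent_of_other_samples(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(20, 6))
        ds = make_dataset(vals, groups=["control"] * 6)
        single = make_dataset(vals[:, [2]], samples=[ds.samples[2]],
                              groups=["control"])
        s_joint = ssgsea_score(ds, ds.genes[:5], 0.25).scores[2]
        s_single = ssgsea_score(single, ds.genes[:5], 0.25).scores[0]
        assert s_joint == pytest.approx(s_single, abs=1e-12)

    def test_sample_permutation_permutes_scores(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(15, 5))
        ds = make_dataset(vals, groups=["control"] * 5)
        perm = [4, 2, 0, 1, 3]
        ds_p = make_dataset(vals[:, perm], samples=[ds.samples[i] for i in perm],
                            groups=["control"] * 5)
        s = ssgsea_score(ds, ds.genes[:4], 0.25).scores
        s_p = ssgsea_score(ds_p, ds.genes[:4], 0.25).scores
        np.testing.assert_allclose(s_p, s[perm], atol=1e-12)

    def test_no_set_gene_is_an_error(self, small_dataset):
        with pytest.raises(ValueError, match="no gene"):
            ssgsea_score(small_dataset, ["ABSENT"], 0.25)

    def test_normalize_single_sample_is_an_error(self):
        ds = make_dataset(np.arange(5, dtype=float)[:, None], samples=["s1"],
                          groups=["control"])
        with pytest.raises(ValueError, match="single sample"):
            ssgsea_score(ds, ds.genes[:2], 0.25, normalize=True)

    def test_normalized_scores_divided_by_range(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(25, 8))
        ds = make_dataset(vals, groups=["control"] * 8)
        raw = ssgsea_score(ds, ds.genes[:6], 0.25).scores
        norm = ssgsea_score(ds, ds.genes[:6], 0.25, normalize=True).scores
        np.testing.assert_allclose(norm, raw / (raw.max() - raw.min()), atol=1e-12)


class TestGlycolysisIndex:
    def test_single_gene_core_tracks_that_genes_rank(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(40, 12))
        ds = make_dataset(vals, groups=["control"] * 12)
        target = ds.genes[0]
        sv = glycolysis_index(ds, [target], alpha=0.25)
        # within-sample rank of the target gene (1 = lowest)
        ranks = (vals < vals[0]).sum(axis=0) + 1
        for i in range(len(ranks)):
            for j in range(len(ranks)):
                if ranks[i] < ranks[j]:
                    assert sv.scores[i] < sv.scores[j]
                elif ranks[i] == ranks[j]:
                    assert sv.scores[i] == pytest.approx(sv.scores[j], abs=1e-12)

    def test_cases_score_lower_with_planted_downregulation(self, small_config):
        from glycoindex.simulate import generate_expression_dataset

        ds = generate_expression_dataset(small_config, "HP")
        sv = glycolysis_index(ds, list(small_config.planted_set))
        s = sv.to_series()
        groups = ds.metadata["group"]
        assert s[groups == "case"].median() < s[groups == "control"].median()


class TestMedianSplit:
    def _scores(self, values, samples):
        from glycoindex.index import SampleScoreVector

        return SampleScoreVector(sample_ids=samples, scores=np.asarray(values, float),
                                 score_name="idx", alpha=0.25, normalized=False)

    def _meta(self, samples, regions):
        return pd.DataFrame(
            {"group": "case", "region": regions, "age": 70.0, "sex": "F"},
            index=pd.Index(samples, name="sample_id"),
        )

    def test_even_split(self):
        samples = ["a", "b", "c", "d"]
        labels = median_split_by_region(self._scores([1, 2, 3, 4], samples),
                                        self._meta(samples, ["FC"] * 4))
        assert list(labels) == ["low", "low", "high", "high"]

    def test_odd_split_ties_go_low(self):
        samples = ["a", "b", "c"]
        labels = median_split_by_region(self._scores([1, 2, 3], samples),
                                        self._meta(samples, ["FC"] * 3))
        assert list(labels) == ["low", "low", "high"]

    def test_regions_split_independently(self):
        samples = [f"s{i}" for i in range(6)]
        # FC scores (1,2,3); HP scores (10,20,30): per-region medians differ
        scores = self._scores([1, 2, 3, 10, 20, 30], samples)
        meta = self._meta(samples, ["FC"] * 3 + ["HP"] * 3)
        labels = median_split_by_region(scores, meta)
        assert list(labels) == ["low", "low", "high", "low", "low", "high"]

    def test_single_sample_region_labeled_low(self):
        samples = ["only"]
        labels = median_split_by_region(self._scores([5.0], samples),
                                        self._meta(samples, ["EC"]))
        assert list(labels) == ["low"]
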