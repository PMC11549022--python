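"""Feature engineering: encodings, GO vectorization, composites, scaling."""

import math

import numpy as np
import pandas as pd
import pytest

from painrank.features import (
    DatasetMeta,
    FeatureMatrix,
    GoFeaturizer,
    SymmetricMinMaxScaler,
    assemble_features,
    composite_lfc,
    correlation_filter,
    encode_categoricals,
    read_feature_matrix,
    split_stratified,
    write_feature_matrix,
)


class TestCategoricalEncoding:
    def test_codes_follow_sorted_label_order(self):
        df = pd.DataFrame({"cellular_compartment": ["membrane", "nucleus", "cytosol"]})
        codes, decode = encode_categoricals(df)
        assert codes["cellular_compartment"].tolist() == [1, 2, 0]
        assert decode["cellular_compartment"] == {0: "cytosol", 1: "membrane", 2: "nucleus"}

    def test_single_category_column_is_constant(self):
        df = pd.DataFrame({"tissue": ["DRG"] * 5})
        codes, _ = encode_categoricals(df)
        assert (codes["tissue"] == 0).all()

    def test_round_trips_through_decode_map(self):
        rng = np.random.default_rng(0)
        labs = [["a", "b", "c"], ["x", "y"], ["p", "q", "r", "s"]]
        df = pd.DataFrame({
            f"c{i}": rng.choice(l, size=50) for i, l in enumerate(labs)
        })
        codes, decode = encode_categoricals(df, columns=df.columns)
        for col in df.columns:
            restored = codes[col].map(decode[col])
            assert (restored == df[col]).all()

    def test_missing_values_get_reserved_code(self):
        df = pd.DataFrame({"chromosome_name": ["chr1", None, "chr2"]})
        codes, _ = encode_categoricals(df)
        assert codes["chromosome_name"].tolist() == [0, 2, 1]


class TestGoFeaturizer:
    def make_annotations(self):
        return {
            "g1": [("T1", "alpha"), ("T2", "beta")],
            "g2": [("T1", "alpha")],
            "g3": [("T3", "gamma"), ("T2", "beta")],
            "g4": [("T4", "common term")],
            "g5": [("T4", "common term")],
        }

    def test_ubiquitous_term_excluded_by_prevalence(self):
        ann = {g: [("T0", "everywhere")] for g in "abcdefgh"}
        ann["a"].append(("T1", "rare"))
        go = GoFeaturizer(max_prevalence=0.2).fit(ann, list("abcdefgh"))
        assert "T0" not in go.vocabulary_
        assert "T1" in go.vocabulary_

    def test_pain_named_term_always_excluded(self):
        ann = self.make_annotations()
        ann["g1"].append(("T9", "response to PAIN stimulus"))
        go = GoFeaturizer(max_prevalence=0.9).fit(ann, list(ann))
        assert "T9" not in go.vocabulary_
        assert all("pain" not in n.lower() for n in go.term_names_.values())

    def test_tfidf_matches_hand_computation(self):
        # 5 genes, term T1 in 2 of them: smoothed idf = ln(6/3)+1
        ann = self.make_annotations()
        go = GoFeaturizer(max_prevalence=0.9, n_components=2).fit(ann, list(ann))
        counts = go._count_matrix(ann, list(ann))
        weighted = go.tfidf_.transform(counts).toarray()
        n = 5
        vocab = sorted(go.vocabulary_, key=go.vocabulary_.get)
        df_counts = counts.sum(axis=0)
        idf = np.log((1 + n) / (1 + df_counts)) + 1
        raw = counts * idf
        norms = np.sqrt((raw ** 2).sum(axis=1, keepdims=True))
        norms[norms == 0] = 1.0
        np.testing.assert_allclose(weighted, raw / norms, atol=1e-12)

    def test_no_surviving_terms_warns_and_zeroes(self):
        ann = {g: [("T0", "everywhere")] for g in "abcde"}
        go = GoFeaturizer(max_prevalence=0.2).fit(ann, list("abcde"))
        with pytest.warns(UserWarning):
            out = go.transform(ann, list("abcde"))
        assert (out.to_numpy() == 0).all()

    def test_transform_params_independent_of_new_genes(self):
        ann = self.make_annotations()
        go = GoFeaturizer(max_prevalence=0.9).fit(ann, ["g1", "g2", "g3"])
        before = go.pca_.components_.copy()
        go.transform({**ann, "g9": [("T1", "alpha")]}, ["g9", "g4"])
        np.testing.assert_array_equal(go.pca_.components_, before)


class TestCompositeLfc:
    def meta(self):
        return {
            "lfc_a": DatasetMeta("DRG", "mouse", "transcriptome", "LFC", "fdr_a"),
            "lfc_b": DatasetMeta("DRG", "mouse", "transcriptome", "LFC", "fdr_b"),
            "fdr_a": DatasetMeta("DRG", "mouse", "transcriptome", "FDR"),
            "fdr_b": DatasetMeta("DRG", "mouse", "transcriptome", "FDR"),
        }

    def test_all_nonsignificant_gives_zero(self):
        t = pd.DataFrame({"lfc_a": [2.0], "lfc_b": [4.0],
                          "fdr_a": [0.5], "fdr_b": [0.9]}, index=["g"])
        out = composite_lfc(t, self.meta())
        assert out.iloc[0, 0] == 0.0

    def test_mean_of_significant_entries(self):
        t = pd.DataFrame({"lfc_a": [2.0], "lfc_b": [4.0],
                          "fdr_a": [0.01], "fdr_b": [0.02]}, index=["g"])
        assert composite_lfc(t, self.meta()).iloc[0, 0] == pytest.approx(3.0)

    def test_nonsignificant_entry_zeroed_before_mean(self):
        t = pd.DataFrame({"lfc_a": [2.0], "lfc_b": [9.0],
                          "fdr_a": [0.01], "fdr_b": [0.5]}, index=["g"])
        assert composite_lfc(t, self.meta()).iloc[0, 0] == pytest.approx(1.0)

    def test_invariant_to_column_order_within_group(self):
        rng = np.random.default_rng(4)
        t = pd.DataFrame({
            "lfc_a": rng.normal(size=20), "lfc_b": rng.normal(size=20),
            "fdr_a": rng.uniform(size=20), "fdr_b": rng.uniform(size=20),
        }, index=[f"g{i}" for i in range(20)])
        a = composite_lfc(t, self.meta())
        b = composite_lfc(t[["lfc_b", "fdr_b", "lfc_a", "fdr_a"]], self.meta())
        pd.testing.assert_frame_equal(a, b)

    def test_missing_fdr_partner_rejected(self):
        meta = {"lfc_a": DatasetMeta("DRG", "mouse", "transcriptome", "LFC")}
        t = pd.DataFrame({"lfc_a": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="lfc_a"):
            composite_lfc(t, meta)

    def test_missing_values_treated_as_nonsignificant(self):
        t = pd.DataFrame({"lfc_a": [np.nan], "lfc_b": [4.0],
                          "fdr_a": [np.nan], "fdr_b": [0.01]}, index=["g"])
        assert composite_lfc(t, self.meta()).iloc[0, 0] == pytest.approx(2.0)


class TestCorrelationFilter:
    def test_duplicated_column_drops_one_copy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        kept, dropped = correlation_filter(X)
        assert dropped == ["b"]  # tie on variance: later column goes
        assert list(kept.columns) == ["a", "c"]

    def test_independent_columns_survive(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
        kept, dropped = correlation_filter(X)
        assert dropped == []

    def test_planted_pair_drops_lower_variance_member(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=300)
        X = pd.DataFrame({
            "big": 3.0 * base + rng.normal(scale=0.3, size=300),
            "small": base + rng.normal(scale=0.1, size=300),
            "n1": rng.normal(size=300),
            "n2": rng.normal(size=300),
            "n3": rng.normal(size=300),
        })
        assert abs(X["big"].corr(X["small"])) > 0.9
        kept, dropped = correlation_filter(X)
        assert dropped == ["small"]

    def test_postcondition_no_pair_above_threshold(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=150)
        X = pd.DataFrame({f"f{i}": base + rng.normal(scale=0.2, size=150)
                          for i in range(4)})
        kept, _ = correlation_filter(X, threshold=0.75)
        if kept.shape[1] >= 2:
            corr = kept.corr().abs().to_numpy()
            np.fill_diagonal(corr, 0)
            assert corr.max() < 0.75


class TestScaler:
    def test_fit_maps_range_to_symmetric_unit(self):
        X = pd.DataFrame({"a": [0.0, 5.0, 10.0]})
        out = SymmetricMinMaxScaler().fit_transform(X)
        assert out["a"].tolist() == [-1.0, 0.0, 1.0]

    def test_constant_column_maps_to_zero(self):
        X = pd.DataFrame({"a": [3.0, 3.0, 3.0]})
        assert (SymmetricMinMaxScaler().fit_transform(X)["a"] == 0).all()

    def test_validation_rows_may_leave_unit_interval(self):
        train = pd.DataFrame({"a": [0.0, 10.0]})
        val = pd.DataFrame({"a": [15.0]})
        sc = SymmetricMinMaxScaler().fit(train)
        assert sc.transform(val)["a"].iloc[0] == pytest.approx(2.0)

    def test_idempotent_on_already_scaled_data(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        sc = SymmetricMinMaxScaler().fit(X)
        once = sc.transform(X)
        sc2 = SymmetricMinMaxScaler().fit(once)
        twice = sc2.transform(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)


class TestStratifiedSplit:
    def test_positive_proportion_preserved(self):
        y = pd.Series([1] * 100 + [0] * 4000,
                      index=[f"g{i}" for i in range(4100)])
        train, val = split_stratified(y, 0.7, seed=1)
        assert abs(int(y.loc[train].sum()) - 70) <= 1
        assert len(train) + len(val) == 4100
        assert set(train).isdisjoint(val)

    def test_boundary_fraction_rejected(self):
        y = pd.Series([1, 1, 0, 0])
        with pytest.raises(ValueError):
            split_stratified(y, 1.0, seed=0)

    def test_deterministic_under_seed(self):
        y = pd.Series([1] * 10 + [0] * 90, index=[f"g{i}" for i in range(100)])
        a = split_stratified(y, 0.7, seed=5)
        b = split_stratified(y, 0.7, seed=5)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_single_member_class_rejected(self):
        y = pd.Series([1] + [0] * 20)
        with pytest.raises(ValueError):
            split_stratified(y, 0.7, seed=0)


class TestAssembly:
    def toy_inputs(self):
        genes = ["g1", "g2", "g3"]
        table = pd.DataFrame({
            "cellular_compartment": ["m", "n", "m"],
            "tissue": ["DRG", "DRG", "skin"],
            "chromosome_name": ["c1", "c2", "c1"],
            "gc_content": [40.0, 45.0, 50.0],
            "conservation_score": [0.5, 0.6, 0.7],
            "lfc_a": [1.0, 0.0, 2.0], "fdr_a": [0.01, 0.9, 0.04],
            "lfc_b": [1.0, 1.0, 1.0], "fdr_b": [0.01, 0.01, 0.2],
            "tpm_x": [5.0, 1.0, 2.0],
        }, index=pd.Index(genes, name="gene_id"))
        meta = {
            "lfc_a": DatasetMeta("DRG", "mouse", "transcriptome", "LFC", "fdr_a"),
            "fdr_a": DatasetMeta("DRG", "mouse", "transcriptome", "FDR"),
            "lfc_b": DatasetMeta("skin", "human", "transcriptome", "LFC", "fdr_b"),
            "fdr_b": DatasetMeta("skin", "human", "transcriptome", "FDR"),
            "tpm_x": DatasetMeta("DRG", "mouse", "transcriptome", "TPM"),
        }
        topo = pd.DataFrame(1.0, index=["g1", "g2"],
                            columns=[f"t{i}" for i in range(11)])
        labels = pd.Series([1, 0, 0], index=genes)
        return table, meta, topo, labels

    def test_column_count_matches_schema(self):
        table, meta, topo, labels = self.toy_inputs()
        fm = assemble_features(table, meta, topo, labels)
        # 3 categoricals + gc + conservation + 2 composite groups +
        # 1 tpm + 11 topology + missing flag
        assert fm.X.shape == (3, 3 + 2 + 2 + 1 + 11 + 1)
        assert not fm.X.isna().any().any()

    def test_gene_missing_from_graph_flagged(self):
        table, meta, topo, labels = self.toy_inputs()
        fm = assemble_features(table, meta, topo, labels)
        assert fm.X.at["g3", "topology_missing"] == 1.0
        assert (fm.X.loc["g3", [f"t{i}" for i in range(11)]] == 0).all()
        assert fm.X.at["g1", "topology_missing"] == 0.0

    def test_all_negative_labels_still_builds(self):
        table, meta, topo, labels = self.toy_inputs()
        fm = assemble_features(table, meta, topo, labels * 0)
        assert int(fm.y.sum()) == 0

    def test_empty_gene_intersection_rejected(self):
        table, meta, topo, labels = self.toy_inputs()
        bad = pd.Series([1, 0], index=["zz1", "zz2"])
        with pytest.raises(ValueError):
            assemble_features(table, meta, topo, bad)

    def test_matrix_round_trips_through_tsv(self, tmp_path):
        table, meta, topo, labels = self.toy_inputs()
        fm = assemble_features(table, meta, topo, labels)
        write_feature_matrix(fm, tmp_path / "fm.tsv")
        back = read_feature_matrix(tmp_path / "fm.tsv")
        pd.testing.assert_frame_equal(back.X, fm.X, check_exact=False, atol=1e-9)
        assert back.y.tolist() == fm.y.tolist()

    def test_duplicate_feature_names_rejected(self):
        X = pd.DataFrame([[1.0, 2.0]], columns=["a", "a"], index=["g"])
        with pytest.raises(ValueError):
            FeatureMatrix(X, pd.Series([1], index=["g"]))
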