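import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import activebreast as ab
from activebreast.io_formats import ExpressionMatrix, SignatureDefinition, ValidationError
from conftest import recovery_accuracy


def make_matrix(values: dict, batch: str = "F") -> ExpressionMatrix:
    df = pd.DataFrame(values)
    return ExpressionMatrix(df, pd.Series({s: batch for s in df.columns}), scale="tpm")


class TestNormalize:
    def test_closed_form_example(self):
        # TPM (1,3,7) -> log2(T+1) = (1,2,3) -> centred (-1,0,1)
        m = make_matrix({"s1": [1.0], "s2": [3.0], "s3": [7.0]})
        m.values.index = ["g"]
        out = ab.normalize_log2_median_center(m)
        np.testing.assert_allclose(out.values.loc["g"], [-1.0, 0.0, 1.0])
        assert out.scale == "log2_median_centered"

    def test_all_zero_gene_stays_zero(self):
        m = make_matrix({"s1": [0.0, 1.0], "s2": [0.0, 3.0], "s3": [0.0, 7.0]})
        out = ab.normalize_log2_median_center(m)
        np.testing.assert_array_equal(out.values.iloc[0], 0.0)

    def test_every_row_median_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.gamma(2, 10, size=(20, 10)),
                          index=[f"g{i}" for i in range(20)],
                          columns=[f"s{j}" for j in range(10)])
        m = ExpressionMatrix(df, pd.Series({f"s{j}": "F" for j in range(10)}))
        out = ab.normalize_log2_median_center(m)
        np.testing.assert_allclose(out.values.median(axis=1), 0.0, atol=1e-12)

    def test_per_batch_centering(self, tiny_matrix):
        out = ab.normalize_log2_median_center(tiny_matrix, per_batch=True)
        for b in ("F", "P"):
            cols = [s for s in out.samples if out.batch[s] == b]
            np.testing.assert_allclose(out.values[cols].median(axis=1), 0.0, atol=1e-12)

    def test_empty_matrix_rejected(self):
        m = ExpressionMatrix(pd.DataFrame(), pd.Series(dtype=object))
        with pytest.raises(ValidationError):
            ab.normalize_log2_median_center(m)


class TestSelectVariableGenes:
    def _normed(self, rows):
        df = pd.DataFrame(rows).T  # genes as rows
        df.columns = [f"s{j}" for j in range(df.shape[1])]
        return ExpressionMatrix(
            df, pd.Series({c: "F" for c in df.columns}), scale="log2_median_centered"
        )

    def test_constant_gene_excluded(self):
        m = self._normed({"gA": [0.0, 0.0, 0.0, 0.0], "gB": [-2.0, -1.0, 1.0, 2.0]})
        assert ab.select_variable_genes(m, {"gA", "gB"}) == ["gB"]

    def test_iqr_oracle_at_n4(self):
        # brute-force linear-interpolation percentile oracle on (-1, 0, 1, 2):
        # h25 = 0.75 -> q25 = -1 + 0.75*(0-(-1)) = -0.25
        # h75 = 2.25 -> q75 = 1 + 0.25*(2-1) = 1.25; IQR = 1.5 > 0.8
        m = self._normed({"g": [-1.0, 0.0, 1.0, 2.0]})
        assert ab.select_variable_genes(m, {"g"}, iqr_threshold=0.8) == ["g"]
        assert ab.select_variable_genes(m, {"g"}, iqr_threshold=1.5) == []  # strict >

    def test_default_threshold_is_0_8(self):
        import inspect

        sig = inspect.signature(ab.select_variable_genes)
        assert sig.parameters["iqr_threshold"].default == 0.8

    def test_empty_intersection_names_mismatch_count(self):
        m = self._normed({"gA": [0.0, 1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError, match="2 requested"):
            ab.select_variable_genes(m, {"x1", "x2"})

    def test_order_follows_matrix(self):
        m = self._normed({"gB": [-2.0, -1.0, 1.0, 2.0], "gA": [-3.0, -1.0, 1.0, 3.0]})
        assert ab.select_variable_genes(m, {"gA", "gB"}) == ["gB", "gA"]


class TestClusterPhenotypes:
    def _planted(self, n=60, seed=0, delta=2.0):
        spec = ab.CohortSpec(
            n_per_batch=(("F", n),), active_fraction=(("F", 0.5),),
            delta=delta, seed=seed,
        )
        return spec, ab.generate_cohort(spec)

    def test_planted_two_groups_recovered(self):
        spec, (expr, _, _, truth) = self._planted()
        norm = ab.normalize_log2_median_center(expr)
        sig = ab.classifier_signature(spec)
        genes = ab.select_variable_genes(norm, sig.up | sig.down)
        c1, c2 = ab.cluster_phenotypes(norm, genes)
        labels = {s: "A" for s in c1} | {s: "B" for s in c2}
        merged = truth.assign(cl=truth["sample_id"].map(labels))
        agree = (merged["cl"] == merged["phenotype"].map({"Active": "A", "Inactive": "B"})).mean()
        assert max(agree, 1 - agree) >= 0.95

    def test_sample_order_invariance(self):
        spec, (expr, _, _, _) = self._planted(n=20, seed=1)
        norm = ab.normalize_log2_median_center(expr)
        genes = norm.genes[:30]
        c = ab.cluster_phenotypes(norm, genes)
        shuffled = norm.subset_samples(list(reversed(norm.samples)))
        c_rev = ab.cluster_phenotypes(shuffled, genes)
        assert {frozenset(c[0]), frozenset(c[1])} == {frozenset(c_rev[0]), frozenset(c_rev[1])}

    def test_duplicating_samples_keeps_bipartition(self):
        spec, (expr, _, _, _) = self._planted(n=12, seed=2)
        norm = ab.normalize_log2_median_center(expr)
        sig = ab.classifier_signature(spec)
        genes = ab.select_variable_genes(norm, sig.up | sig.down)
        c = ab.cluster_phenotypes(norm, genes)
        dup_values = pd.concat(
            [norm.values, norm.values.rename(columns=lambda s: s + "_dup")], axis=1
        )
        batch = pd.Series({s: "F" for s in dup_values.columns})
        dup = ExpressionMatrix(dup_values, batch, scale="log2_median_centered")
        cd = ab.cluster_phenotypes(dup, genes)
        orig = {frozenset(s for s in side if not s.endswith("_dup")) for side in cd}
        assert orig == {frozenset(c[0]), frozenset(c[1])}

    def test_two_distinct_profiles_split_at_minimum_size(self):
        df = pd.DataFrame(
            {"a1": [0.0, 5.0], "a2": [0.1, 5.1], "b1": [5.0, 0.0], "b2": [5.1, 0.1]},
            index=["g1", "g2"],
        )
        m = ExpressionMatrix(df, pd.Series({c: "F" for c in df.columns}), scale="log2_median_centered")
        c1, c2 = ab.cluster_phenotypes(m, ["g1", "g2"])
        assert {frozenset(c1), frozenset(c2)} == {frozenset({"a1", "a2"}), frozenset({"b1", "b2"})}

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 1.0]}, index=["g1", "g2"])
        m = ExpressionMatrix(df, pd.Series({"s1": "F", "s2": "F"}), scale="log2_median_centered")
        with pytest.raises(ValidationError, match="at least 4 samples"):
            ab.cluster_phenotypes(m, ["g1", "g2"])

    def test_identical_samples_degenerate(self):
        df = pd.DataFrame(np.ones((3, 5)), index=list("abc"), columns=[f"s{i}" for i in range(5)])
        m = ExpressionMatrix(df, pd.Series({f"s{i}": "F" for i in range(5)}), scale="log2_median_centered")
        with pytest.raises(ValidationError, match="degenerate"):
            ab.cluster_phenotypes(m, list("abc"))


class TestSignatureScore:
    def test_closed_form_examples(self):
        sig = SignatureDefinition("s", {"A"}, {"B"})
        assert ab.signature_score({"A": 3.0, "B": 1.0}, sig) == pytest.approx(0.5, abs=1e-12)
        assert ab.signature_score({"A": 0.0, "B": 0.0}, sig) == pytest.approx(0.0, abs=1e-12)
        sig2 = SignatureDefinition("s2", {"A", "B"}, {"C"})
        assert ab.signature_score({"A": 7.0, "B": 0.0, "C": 3.0}, sig2) == pytest.approx(1 / 3, abs=1e-12)

    def test_missing_genes_dropped_from_denominator(self):
        sig = SignatureDefinition("s", {"A", "X"}, {"B"})
        # X absent: score over {A up, B down} only -> (2-1)/2
        assert ab.signature_score({"A": 3.0, "B": 1.0}, sig) == pytest.approx(0.5, abs=1e-12)

    def test_no_gene_present_rejected(self):
        sig = SignatureDefinition("s", {"X"}, {"Y"})
        with pytest.raises(ValidationError, match="no signature gene"):
            ab.signature_score({"A": 1.0}, sig)

    def test_mean_log2_up_method(self):
        sig = SignatureDefinition("s", {"A", "B"}, frozenset(), method="mean_log2_up")
        assert ab.signature_score({"A": 3.0, "B": 1.0}, sig) == pytest.approx(1.5, abs=1e-12)

    @given(st.permutations(["A", "B", "C", "D"]))
    def test_gene_order_invariance(self, order):
        sig = SignatureDefinition("s", {"A", "C"}, {"B", "D"})
        tpm = {"A": 3.0, "B": 1.0, "C": 7.0, "D": 0.5}
        reordered = {g: tpm[g] for g in order}
        assert ab.signature_score(reordered, sig) == pytest.approx(
            ab.signature_score(tpm, sig), abs=1e-12
        )

    @given(
        st.lists(st.floats(0.0, 1e4), min_size=4, max_size=4),
        st.integers(1, 3),
    )
    def test_doubling_shift_property(self, tpms, n_up):
        # doubling every TPM+1 value shifts Ss by (|U|-|D|)/(|U|+|D|)
        genes = ["A", "B", "C", "D"]
        sig = SignatureDefinition("s", set(genes[:n_up]), set(genes[n_up:]))
        tpm = dict(zip(genes, tpms))
        doubled = {g: 2 * (v + 1.0) - 1.0 for g, v in tpm.items()}
        expected_shift = (n_up - (4 - n_up)) / 4
        assert ab.signature_score(doubled, sig) - ab.signature_score(tpm, sig) == pytest.approx(
            expected_shift, abs=1e-9
        )

    def test_score_samples_matches_scalar(self, tiny_matrix):
        sig = SignatureDefinition("s", {"gA"}, {"gB"})
        vec = ab.score_samples(tiny_matrix, sig)
        for s in tiny_matrix.samples:
            assert vec[s] == pytest.approx(ab.signature_score(tiny_matrix.values[s], sig))


class TestAssignLabels:
    def test_higher_mean_cluster_is_active(self, tiny_matrix):
        sig = SignatureDefinition("s", {"gA"}, {"gB"})
        out = ab.assign_labels((["s3", "s4"], ["s1", "s2"]), tiny_matrix, sig)
        labels = {a.sample_id: a.label for a in out}
        scores = ab.score_samples(tiny_matrix, sig)
        hi = max((("s3", "s4"), ("s1", "s2")), key=lambda c: scores[list(c)].mean())
        for s in hi:
            assert labels[s] == "Active"

    def test_swap_cluster_order_leaves_labels(self, tiny_matrix):
        sig = SignatureDefinition("s", {"gA"}, {"gB"})
        a = ab.assign_labels((["s1", "s2"], ["s3", "s4"]), tiny_matrix, sig)
        b = ab.assign_labels((["s3", "s4"], ["s1", "s2"]), tiny_matrix, sig)
        assert {x.sample_id: x.label for x in a} == {x.sample_id: x.label for x in b}

    def test_tied_means_rejected(self):
        df = pd.DataFrame({"s1": [1.0, 1.0], "s2": [1.0, 1.0]}, index=["gA", "gB"])
        m = ExpressionMatrix(df, pd.Series({"s1": "F", "s2": "F"}))
        sig = SignatureDefinition("s", {"gA"}, {"gB"})
        with pytest.raises(ValidationError, match="tied"):
            ab.assign_labels((["s1"], ["s2"]), m, sig)

    def test_active_mean_score_always_exceeds_inactive(self, cohort, classifier):
        expr, _, _, _ = cohort
        frame = ab.phenotyping.assignments_to_frame(ab.phenotype_cohort(expr, classifier))
        by = frame.groupby("label")["score"].mean()
        assert by["Active"] > by["Inactive"]


class TestDiffGenes:
    def test_identical_expression_yields_empty(self):
        df = pd.DataFrame(np.ones((5, 8)), index=[f"g{i}" for i in range(5)],
                          columns=[f"s{i}" for i in range(8)])
        m = ExpressionMatrix(df, pd.Series({f"s{i}": "F" for i in range(8)}))
        labels = {f"s{i}": "Active" if i < 4 else "Inactive" for i in range(8)}
        assert ab.diff_genes(m, labels) == []

    def test_group_too_small_rejected(self, tiny_matrix):
        labels = {"s1": "Active", "s2": "Inactive", "s3": "Inactive", "s4": "Inactive"}
        with pytest.raises(ValidationError, match=">= 3 samples"):
            ab.diff_genes(tiny_matrix, labels)

    def test_planted_signature_genes_recovered(self, cohort, classifier):
        expr, _, _, truth = cohort
        labels = dict(zip(truth["sample_id"], truth["phenotype"]))
        found = set(ab.diff_genes(expr, labels))
        planted = classifier.up | classifier.down
        assert len(found & planted) / len(planted) >= 0.99

    def test_null_false_positive_rate(self):
        spec = ab.CohortSpec(delta=0.0, seed=17)
        expr, _, _, truth = ab.generate_cohort(spec)
        labels = dict(zip(truth["sample_id"], truth["phenotype"]))
        hits = ab.diff_genes(expr, labels)
        assert len(hits) <= 0.10 * expr.n_genes


class TestPhenotypeRecovery:
    def test_recovery_at_default_delta(self, cohort, classifier, default_spec):
        expr, _, _, truth = cohort
        frame = ab.phenotyping.assignments_to_frame(ab.phenotype_cohort(expr, classifier))
        assert recovery_accuracy(frame, truth) >= 0.95

    def test_both_labels_occur_per_batch(self, cohort, classifier):
        expr, _, _, _ = cohort
        frame = ab.phenotyping.assignments_to_frame(ab.phenotype_cohort(expr, classifier))
        for b, grp in frame.groupby("batch"):
            assert set(grp["label"]) == {"Active", "Inactive"}
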