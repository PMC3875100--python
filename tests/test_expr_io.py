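"""Reading, writing and round-tripping datasets and pipeline artifacts."""

import json

import numpy as np
import pytest

import sffstree as st
from sffstree import errors
from sffstree.crossval import loocv
from sffstree.expr_io import (
    read_artifact,
    read_expression_tsv,
    read_series_matrix,
    write_artifact,
    write_expression_tsv,
)
from sffstree.sffs import SelectionStep, SelectionTrace
from sffstree.tree import extract_rules, fit_tree, predict


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


TINY = "probe_id\ts1\ts2\ng1\t1.5\t2.5\ng2\t-0.25\t3.75\n"
TINY_LABELS = {"s1": "tumor", "s2": "normal"}


class TestExpressionTSV:
    def test_round_trip_identity(self, tmp_path):
        p = _write(tmp_path, "tiny.tsv", TINY)
        ds = read_expression_tsv(p, TINY_LABELS)
        assert ds.values.shape == (2, 2)
        out = tmp_path / "out.tsv"
        write_expression_tsv(ds, out)
        ds2 = read_expression_tsv(out, TINY_LABELS)
        assert ds2.probe_ids == ds.probe_ids
        assert ds2.sample_ids == ds.sample_ids
        assert ds2.labels == ds.labels
        np.testing.assert_array_equal(ds2.values, ds.values)

    def test_blank_cell_names_the_cell(self, tmp_path):
        text = "probe_id\ts1\ts2\n" + "".join(
            f"g{i}\t1.0\t2.0\n" for i in range(4)
        ) + "g4\t\t2.0\n"
        p = _write(tmp_path, "blank.tsv", text)
        with pytest.raises(errors.ParseError, match=r"'g4'.*'s1'"):
            read_expression_tsv(p, {"s1": "tumor", "s2": "normal"})

    def test_non_numeric_cell_names_the_cell(self, tmp_path):
        p = _write(tmp_path, "bad.tsv", "probe_id\ts1\ts2\ng1\t1.0\toops\n")
        with pytest.raises(errors.ParseError, match=r"'oops'.*'g1'.*'s2'"):
            read_expression_tsv(p, TINY_LABELS)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = _write(tmp_path, "dupp.tsv", "probe_id\ts1\ts2\ng1\t1\t2\ng1\t3\t4\n")
        with pytest.raises(errors.FormatError):
            read_expression_tsv(p, TINY_LABELS)
        p = _write(tmp_path, "dups.tsv", "probe_id\ts1\ts1\ng1\t1\t2\n")
        with pytest.raises(errors.FormatError):
            read_expression_tsv(p, {"s1": "tumor"})

    def test_missing_label_rejected(self, tmp_path):
        p = _write(tmp_path, "tiny.tsv", TINY)
        with pytest.raises(errors.LabelError, match="s2"):
            read_expression_tsv(p, {"s1": "tumor"})

    def test_generated_matrix_round_trips_exactly(self, tmp_path):
        ds, _ = st.generate(st.SyntheticSpec(n_tumor=10, n_normal=10, n_probes=100, seed=3))
        out = tmp_path / "gen.tsv"
        write_expression_tsv(ds, out)
        ds2 = read_expression_tsv(out, dict(zip(ds.sample_ids, ds.labels)))
        np.testing.assert_allclose(
            ds2.values.mean(axis=0), ds.values.mean(axis=0), rtol=0, atol=1e-12
        )
        np.testing.assert_array_equal(ds2.values, ds.values)

    def test_read_does_not_mutate_the_file(self, tmp_path):
        p = _write(tmp_path, "tiny.tsv", TINY)
        before = p.read_bytes()
        read_expression_tsv(p, TINY_LABELS)
        assert p.read_bytes() == before

    def test_impute_missing_uses_per_class_mean(self, tmp_path):
        text = (
            "probe_id\ts1\ts2\ts3\ts4\n"
            "g1\t1.0\t3.0\t\t6.0\n"
        )
        p = _write(tmp_path, "m.tsv", text)
        labels = {"s1": "tumor", "s2": "tumor", "s3": "tumor", "s4": "normal"}
        ds = read_expression_tsv(p, labels, impute_missing=True)
        assert ds.values[0, 2] == pytest.approx((1.0 + 3.0) / 2)

    def test_log2_flag(self, tmp_path):
        p = _write(tmp_path, "raw.tsv", "probe_id\ts1\ts2\ng1\t4\t8\n")
        ds = read_expression_tsv(p, TINY_LABELS, log2=True)
        np.testing.assert_allclose(ds.values, [[2.0, 3.0]])


SERIES = """!Series_title\t"synthetic fixture"
!Series_platform_id\t"GPL000"
!series_matrix_table_begin
"ID_REF"\t"GSM1"\t"GSM2"\t"GSM3"\t"GSM4"
"p1"\t1.0\t2.0\t3.0\t4.0
"p2"\t5.0\t6.0\t7.0\t8.0
"p3"\t9.0\t10.0\t11.0\t12.0
!series_matrix_table_end
"""
SERIES_LABELS = {"GSM1": "tumor", "GSM2": "tumor", "GSM3": "normal", "GSM4": "normal"}


class TestSeriesMatrix:
    def test_minimal_fixture(self, tmp_path):
        p = _write(tmp_path, "series.txt", SERIES)
        ds = read_series_matrix(p, SERIES_LABELS)
        assert ds.values.shape == (3, 4)
        assert ds.probe_ids == ["p1", "p2", "p3"]
        assert ds.values[2, 3] == 12.0
        assert any("Series_title" in l for l in ds.meta["series_matrix_header"])

    def test_missing_end_marker(self, tmp_path):
        p = _write(tmp_path, "series.txt", SERIES.replace("!series_matrix_table_end\n", ""))
        with pytest.raises(errors.FormatError, match="table_end"):
            read_series_matrix(p, SERIES_LABELS)

    def test_missing_begin_marker(self, tmp_path):
        p = _write(tmp_path, "series.txt", SERIES.replace("!series_matrix_table_begin\n", ""))
        with pytest.raises(errors.FormatError, match="table_begin"):
            read_series_matrix(p, SERIES_LABELS)

    def test_ragged_table(self, tmp_path):
        bad = SERIES.replace('"p2"\t5.0\t6.0\t7.0\t8.0', '"p2"\t5.0\t6.0')
        p = _write(tmp_path, "series.txt", bad)
        with pytest.raises(errors.ParseError, match="ragged"):
            read_series_matrix(p, SERIES_LABELS)

    def test_equivalent_to_tsv_read(self, tmp_path):
        p = _write(tmp_path, "series.txt", SERIES)
        tsv = "probe_id\tGSM1\tGSM2\tGSM3\tGSM4\n" + "\n".join(
            "\t".join([f"p{i + 1}"] + [f"{1.0 + 4 * i + j}" for j in range(4)])
            for i in range(3)
        )
        q = _write(tmp_path, "same.tsv", tsv + "\n")
        a = read_series_matrix(p, SERIES_LABELS)
        b = read_expression_tsv(q, SERIES_LABELS)
        assert a.probe_ids == b.probe_ids and a.sample_ids == b.sample_ids
        np.testing.assert_array_equal(a.values, b.values)


class TestArtifacts:
    def test_selection_trace_round_trip(self, tmp_path):
        trace = SelectionTrace(
            steps=[
                SelectionStep(1, 10, "gA", 0.8, True),
                SelectionStep(2, 9, "gB", 0.9, True),
            ],
            selected=["gA", "gB"],
            params={"confidence": 0.25, "patience": 2},
        )
        p = tmp_path / "trace.json"
        write_artifact(trace, p)
        back = read_artifact(p)
        assert back.to_dict() == trace.to_dict()

    def test_rules_tsv_schema_and_round_trip(self, toy_dataset, tmp_path):
        t = fit_tree(toy_dataset, ["gA"], st.TreeParams(min_leaf=1, prune=False))
        rules = extract_rules(t)
        p = tmp_path / "rules.tsv"
        write_artifact(rules, p, format="tsv")
        header = p.read_text().splitlines()[0].split("\t")
        assert header == ["conditions", "predicted_class", "n_covered", "n_misclassified"]
        back = read_artifact(p, kind="rules")
        assert back == rules

    def test_tree_json_prediction_equivalence(self, tmp_path):
        rng = np.random.default_rng(11)
        x = rng.normal(8, 1, size=(40, 3))
        x[:20, 0] += 2.0
        labels = ["tumor"] * 20 + ["normal"] * 20
        from .conftest import dataset_from_matrix

        ds = dataset_from_matrix(x, labels)
        t = fit_tree(ds, ds.probe_ids, st.TreeParams(min_leaf=1))
        p = tmp_path / "tree.json"
        write_artifact(t, p)
        back = read_artifact(p)
        for _ in range(100):
            sample = {g: float(v) for g, v in zip(ds.probe_ids, rng.normal(8, 2, 3))}
            assert predict(back, sample) == predict(t, sample)

    def test_cv_result_round_trip(self, toy_dataset, tmp_path):
        result = loocv(toy_dataset, ["gA"], st.TreeParams(min_leaf=1))
        p = tmp_path / "cv.json"
        write_artifact(result, p)
        back = read_artifact(p)
        assert back.to_dict() == result.to_dict()

    def test_unsupported_type_is_usage_error(self, tmp_path):
        with pytest.raises(errors.UsageError):
            write_artifact(object(), tmp_path / "x.json")


class TestDatasetInvariants:
    def test_shape_and_uniqueness_enforced(self):
        with pytest.raises(errors.ValidationError):
            st.ExpressionDataset(["g1", "g1"], ["s1"], ["tumor"], [[1.0]])
        with pytest.raises(errors.ValidationError):
            st.ExpressionDataset(["g1"], ["s1"], ["tumor"], [[1.0, 2.0]])
        with pytest.raises(errors.ValidationError):
            st.ExpressionDataset(["g1"], ["s1"], ["tumor"], [[np.nan]])

    def test_labels_restricted_to_two_classes(self):
        with pytest.raises(errors.LabelError):
            st.ExpressionDataset(["g1"], ["s1"], ["healthy"], [[1.0]])
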