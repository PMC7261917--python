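"""Reading, pre-processing and labeling contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panprog import (
    FormatError,
    aggregate_isoforms,
    align_with_clinical,
    collapse_duplicate_ids,
    filter_missing,
    label_by_median_os,
    merge_omics,
    read_expression_tsv,
    write_expression_tsv,
)
from panprog.datatypes import HIGH_OS, LOW_OS

from conftest import make_clinical, make_matrix


def _write(tmp_path, text, name="expr.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadExpressionTsv:
    def test_linear_values_are_log2_transformed(self, tmp_path):
        p = _write(tmp_path, "feature\ts1\ts2\nf1\t0\t1\nf2\t3\t3\nf3\t1\t0\n")
        m = read_expression_tsv(p, scale="linear")
        np.testing.assert_allclose(m.data.to_numpy(), [[0, 1], [2, 2], [1, 0]])

    def test_orientation_transpose_symmetry(self, tmp_path):
        a = _write(tmp_path, "feature\ts1\ts2\nf1\t1\t2\nf2\t3\t4\n", "a.tsv")
        b = _write(tmp_path, "sample\tf1\tf2\ns1\t1\t3\ns2\t2\t4\n", "b.tsv")
        ma = read_expression_tsv(a)
        mb = read_expression_tsv(b, orientation="samples-in-rows")
        pd.testing.assert_frame_equal(ma.data, mb.data)

    def test_na_token_becomes_missing(self, tmp_path):
        p = _write(tmp_path, "feature\ts1\ts2\nf1\t1\tNA\nf2\t3\t4\n")
        m = read_expression_tsv(p)
        assert m.data.isna().sum().sum() == 1
        assert np.isnan(m.data.loc["f1", "s2"])

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        p = _write(tmp_path, "feature\ts1\ts1\nf1\t1\t2\n")
        with pytest.raises(FormatError, match="duplicate sample"):
            read_expression_tsv(p)

    def test_non_numeric_cell_rejected(self, tmp_path):
        p = _write(tmp_path, "feature\ts1\ts2\nf1\t1\thello\n")
        with pytest.raises(FormatError, match="non-numeric"):
            read_expression_tsv(p)

    def test_round_trip_preserves_values(self, tmp_path, rng):
        m = make_matrix(rng.normal(5, 2, size=(7, 5)))
        write_expression_tsv(m, tmp_path / "rt.tsv")
        back = read_expression_tsv(tmp_path / "rt.tsv")
        np.testing.assert_allclose(back.data.to_numpy(), m.data.to_numpy(), atol=1e-9)
        assert back.feature_ids == m.feature_ids and back.sample_ids == m.sample_ids


class TestFilterMissing:
    def test_feature_dropped_first_sample_survives(self):
        vals = np.ones((4, 4))
        vals[1, 2] = np.nan
        out = filter_missing(make_matrix(vals))
        assert out.data.shape == (3, 4)
        assert "f1" not in out.feature_ids

    def test_identity_without_missing(self):
        m = make_matrix(np.ones((3, 3)))
        pd.testing.assert_frame_equal(filter_missing(m).data, m.data)

    def test_fully_missing_sample_drops_everything(self):
        # one all-NA column: every feature has a missing value, so the
        # feature pass empties the matrix before the sample pass runs
        vals = np.ones((3, 3))
        vals[:, 0] = np.nan
        out = filter_missing(make_matrix(vals))
        assert out.data.shape[0] == 0

    def test_idempotent(self, rng):
        vals = rng.normal(size=(6, 5))
        vals[0, 1] = np.nan
        vals[3, 4] = np.nan
        once = filter_missing(make_matrix(vals))
        twice = filter_missing(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert not once.has_missing()


class TestAggregateIsoforms:
    def test_isoform_sum_then_log(self):
        m = make_matrix([[3.0], [5.0]], features=["i1", "i2"], scale="linear")
        out = aggregate_isoforms(m, {"i1": "mat1", "i2": "mat1"})
        np.testing.assert_allclose(out.data.loc["mat1"], np.log2(9.0))

    def test_zero_stays_zero(self):
        m = make_matrix([[0.0]], features=["i1"], scale="linear")
        out = aggregate_isoforms(m, {"i1": "mat1"})
        assert out.data.loc["mat1"].iloc[0] == 0.0

    def test_three_isoforms_of_one(self):
        m = make_matrix([[1.0], [1.0], [1.0]], features=["a", "b", "c"], scale="linear")
        out = aggregate_isoforms(m, dict.fromkeys("abc", "mat1"))
        np.testing.assert_allclose(out.data.loc["mat1"], 2.0)

    def test_unmapped_isoform_dropped(self):
        m = make_matrix([[1.0], [2.0]], features=["a", "b"], scale="linear")
        out = aggregate_isoforms(m, {"a": "mat1"})
        assert out.feature_ids == ["mat1"]


class TestCollapseDuplicateIds:
    def test_mean_of_collapsed_rows(self):
        m = make_matrix([[2.0], [4.0]], features=["acc1", "acc2"])
        out = collapse_duplicate_ids(m, {"acc1": "id1", "acc2": "id1"})
        assert out.data.loc["id1"].iloc[0] == 3.0

    def test_injective_map_keeps_rows(self):
        m = make_matrix([[1.0], [2.0]], features=["a", "b"])
        out = collapse_duplicate_ids(m, {"a": "x", "b": "y"})
        assert out.n_features == 2

    def test_three_way_collapse(self):
        m = make_matrix([[1.0], [2.0], [6.0]], features=["a", "b", "c"])
        out = collapse_duplicate_ids(m, dict.fromkeys("abc", "id1"))
        assert out.data.loc["id1"].iloc[0] == 3.0


class TestAlignWithClinical:
    def test_intersection(self):
        m = make_matrix(np.ones((2, 5)), samples=[f"s{i}" for i in range(5)])
        clin = make_clinical([10, 20, 30], samples=["s0", "s2", "s4"])
        out_m, out_c = align_with_clinical(m, clin)
        assert out_m.sample_ids == ["s0", "s2", "s4"]
        assert list(out_c["sample"]) == out_m.sample_ids

    def test_normal_tissue_code_removed(self):
        m = make_matrix(np.ones((1, 2)), samples=["s0", "s1"])
        clin = make_clinical([10, 20], samples=["s0", "s1"], sample_type_code=["01", "11"])
        out_m, _ = align_with_clinical(m, clin)
        assert out_m.sample_ids == ["s0"]

    def test_missing_os_removed_before_intersection(self):
        m = make_matrix(np.ones((1, 2)), samples=["s0", "s1"])
        clin = make_clinical([10, np.nan], samples=["s0", "s1"])
        out_m, out_c = align_with_clinical(m, clin)
        assert out_m.sample_ids == ["s0"]
        assert out_c["os_days"].notna().all()

    def test_empty_intersection_is_error(self):
        m = make_matrix(np.ones((1, 1)), samples=["sX"])
        with pytest.raises(ValueError, match="no samples"):
            align_with_clinical(m, make_clinical([10], samples=["s0"]))


class TestLabelByMedianOs:
    def test_odd_n_strict_inequality(self):
        labels = label_by_median_os(make_clinical([10, 20, 30]))
        assert labels.median_os == 20
        assert labels.high_samples == ["s2"]
        assert set(labels.low_samples) == {"s0", "s1"}

    def test_even_n_midpoint_median(self):
        labels = label_by_median_os(make_clinical([10, 20, 30, 40]))
        assert labels.median_os == 25
        assert set(labels.high_samples) == {"s2", "s3"}

    def test_all_equal_means_all_low(self):
        labels = label_by_median_os(make_clinical([7, 7, 7]))
        assert labels.high_samples == []

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1, max_value=1e4), min_size=2, max_size=60))
    def test_high_group_never_exceeds_half(self, os_days):
        labels = label_by_median_os(make_clinical(os_days))
        assert len(labels.high_samples) <= len(os_days) // 2


class TestMergeOmics:
    def test_row_concat_over_intersection(self):
        a = make_matrix(np.ones((10, 9)), features=[f"m{i}" for i in range(10)],
                        samples=[f"s{i}" for i in range(9)], omic="miRNA")
        b = make_matrix(np.ones((20, 8)), features=[f"l{i}" for i in range(20)],
                        samples=[f"s{i}" for i in range(1, 9)], omic="lncRNA")
        merged = merge_omics(a, b)
        assert merged.data.shape == (30, 8)
        assert merged.omic == "merged"

    def test_identical_sample_sets_preserved(self):
        a = make_matrix(np.ones((2, 3)), features=["m1", "m2"])
        b = make_matrix(np.ones((2, 3)), features=["l1", "l2"], omic="lncRNA")
        assert merge_omics(a, b).n_samples == 3

    def test_feature_collision_is_error(self):
        a = make_matrix(np.ones((1, 2)), features=["x"])
        b = make_matrix(np.ones((1, 2)), features=["x"], omic="lncRNA")
        with pytest.raises(ValueError, match="collide"):
            merge_omics(a, b)
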