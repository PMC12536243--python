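"""Agreement metrics: RD, categories, IoU, Pearson, grouped summaries."""

import numpy as np
import pytest

from gutseg.evaluation import (
    SUMMARY_METRIC_COLUMNS,
    EvalRecord,
    agreement_category,
    interpret_iou,
    interpret_pcc,
    iou,
    pearson,
    relative_deviation,
    summarize,
)


class TestRelativeDeviation:
    @pytest.mark.parametrize(
        "a_model,a_manual,expected",
        [(100.0, 100.0, 0.0), (110.0, 100.0, 10.0), (95.0, 100.0, -5.0)],
    )
    def test_examples(self, a_model, a_manual, expected):
        assert relative_deviation(a_model, a_manual) == pytest.approx(expected)

    def test_zero_manual_area_is_undefined(self):
        with pytest.raises(ValueError):
            relative_deviation(10.0, 0.0)


@pytest.mark.parametrize(
    "rd,expected",
    [
        (3.0, "very_good"),
        (-3.0, "very_good"),
        (7.0, "good"),
        (25.0, "poor"),
        (5.0, "good"),  # boundaries assigned upward
        (10.0, "fair"),
        (20.0, "poor"),
        (-12.0, "fair"),
    ],
)
def test_agreement_category(rd, expected):
    assert agreement_category(rd) == expected


class TestIoU:
    def test_identical_masks(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2:8, 2:8] = True
        assert iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[0:3, 0:3] = True
        b[6:9, 6:9] = True
        assert iou(a, b) == 0.0

    def test_half_overlapping_equal_squares(self):
        """Equal n-pixel squares overlapping in n/2 pixels give IoU 1/3."""
        a = np.zeros((10, 20), dtype=bool)
        b = np.zeros((10, 20), dtype=bool)
        a[0:4, 0:4] = True  # 16 px
        b[0:4, 2:6] = True  # 16 px, overlap 8
        assert iou(a, b) == pytest.approx(1.0 / 3.0)

    def test_symmetry_and_bounds(self, rng):
        a = rng.random((15, 15)) < 0.4
        b = rng.random((15, 15)) < 0.4
        assert iou(a, b) == iou(b, a)
        assert 0.0 <= iou(a, b) <= 1.0

    def test_empty_union_is_error(self):
        z = np.zeros((5, 5), dtype=bool)
        with pytest.raises(ValueError, match="undefined"):
            iou(z, z)


@pytest.mark.parametrize(
    "value,expected",
    [
        (0.92, "near_perfect"),
        (0.60, "acceptable"),
        (0.50, "below_acceptable"),  # strict inequality at the boundary
        (0.80, "good"),
        (0.90, "good"),
    ],
)
def test_interpret_iou(value, expected):
    assert interpret_iou(value) == expected


class TestPearson:
    def test_perfect_positive(self):
        r, label = pearson([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        assert label == "very_strong"

    def test_perfect_negative(self):
        r, _ = pearson([1, 2, 3], [-1, -2, -3])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, _ = pearson([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(0.981981, abs=1e-4)

    def test_errors(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2])
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])

    @pytest.mark.parametrize(
        "r,label",
        [(0.95, "very_strong"), (0.8, "strong"), (0.6, "moderate"), (0.4, "weak"),
         (0.1, "very_weak")],
    )
    def test_interpretation_bands(self, r, label):
        assert interpret_pcc(r) == label


def _record(sample_id, age, step, a_model, a_manual, iou_val=0.9, design="ad_hoc"):
    return EvalRecord(
        sample_id=sample_id,
        age_group=age,
        step=step,
        model_design=design,
        a_model_um2=a_model,
        a_manual_um2=a_manual,
        iou=iou_val,
    )


class TestSummarize:
    def test_single_identical_group(self):
        records = [_record(f"s{i}", 4, 1, 100.0, 100.0) for i in range(4)]
        table = summarize(records)
        all_row = table.metrics[table.metrics.age_group == "All"].iloc[0]
        assert all_row.rd_mean == 0.0 and all_row.rd_sd == 0.0
        counts = table.category_counts[table.category_counts.age_group == "All"].iloc[0]
        assert counts.very_good == 4 and counts.poor == 0

    def test_all_row_pools_records(self):
        """The "All" RD mean is the pooled mean, not the mean of group means."""
        records = [_record("a", 4, 1, 110.0, 100.0)] + [
            _record(f"b{i}", 67, 1, 100.0, 100.0) for i in range(3)
        ]
        table = summarize(records)
        all_row = table.metrics[table.metrics.age_group == "All"].iloc[0]
        assert all_row.rd_mean == pytest.approx(10.0 / 4.0)

    def test_category_counts_partition_group_n(self):
        rng = np.random.default_rng(0)
        records = [
            _record(f"s{i}", age, 1, 100.0 * (1 + rng.normal(0, 0.15)), 100.0)
            for i, age in enumerate([4] * 5 + [67] * 5)
        ]
        table = summarize(records)
        for _, row in table.category_counts.iterrows():
            assert row.very_good + row.good + row.fair + row.poor == row.n

    def test_table_schema(self):
        records = [_record(f"s{i}", 4, 1, 100.0, 100.0) for i in range(3)]
        table = summarize(records)
        assert tuple(table.metrics.columns) == (
            "step", "model_design", "age_group", "n", *SUMMARY_METRIC_COLUMNS,
        )
        assert set(table.bland_altman.columns) == {
            "sample_id", "age_group", "step", "model_design", "rd",
        }

    def test_small_group_pcc_not_computable(self):
        records = [_record("a", 4, 1, 105.0, 100.0), _record("b", 4, 1, 95.0, 100.0)]
        table = summarize(records)
        row = table.metrics[table.metrics.age_group == 4].iloc[0]
        assert row.pcc_interpretation == "not_computable"
        assert np.isnan(row.pcc)
        assert row.rd_mean == pytest.approx(0.0)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            summarize([])
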