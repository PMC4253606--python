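"""Contingency tables, Youden index, mutual information, and the grid search."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cutpointsim import (
    ContingencyTable,
    DiagnosticDataset,
    Method,
    build_table,
    mutual_information,
    optimize_cutoff,
    read_dataset,
    se_sp,
    youden_index,
)

from conftest import random_small_dataset

# independently hand-evaluated cell-sum formula, frozen before the build
MI_3113_BITS = 0.18872187554086717

counts = st.integers(min_value=0, max_value=50)


def _entropy_bits(p):
    return -sum(q * math.log2(q) for q in p if q > 0)


class TestDataset:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            DiagnosticDataset([1.0, 2.0], [0])

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            DiagnosticDataset([1.0, 2.0], [0, 2])

    def test_empirical_prevalence_default(self):
        data = DiagnosticDataset([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 1])
        assert data.p_d == 0.25


class TestBuildTable:
    def test_separating_cutoff(self, toy_dataset):
        table = build_table(toy_dataset, 3.0)
        assert (table.tp, table.fp, table.fn, table.tn) == (2, 0, 0, 2)

    def test_cutoff_below_all_values(self, toy_dataset):
        table = build_table(toy_dataset, 0.0)
        assert (table.tp, table.fp, table.fn, table.tn) == (2, 2, 0, 0)

    def test_cutoff_above_all_values(self, toy_dataset):
        table = build_table(toy_dataset, 5.0)
        assert (table.tp, table.fp, table.fn, table.tn) == (0, 0, 2, 2)

    def test_value_at_cutoff_is_positive(self, toy_dataset):
        # x >= c rule: an observation exactly at the cut-off tests positive
        assert build_table(toy_dataset, 4.0).tp == 1

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_table(DiagnosticDataset([], []), 1.0)


class TestSeSpYouden:
    def test_arithmetic(self):
        assert se_sp(ContingencyTable(45, 10, 5, 40)) == (0.9, 0.8)
        assert youden_index(ContingencyTable(45, 10, 5, 40)) == pytest.approx(0.7)

    def test_perfect_table(self):
        assert se_sp(ContingencyTable(3, 0, 0, 7)) == (1.0, 1.0)
        assert youden_index(ContingencyTable(3, 0, 0, 7)) == pytest.approx(1.0)

    def test_all_negative(self):
        assert se_sp(ContingencyTable(0, 0, 5, 5)) == (0.0, 1.0)

    def test_uninformative_table(self):
        assert youden_index(ContingencyTable(1, 1, 1, 1)) == pytest.approx(0.0)

    def test_empty_class_undefined(self):
        with pytest.raises(ValueError, match="empty"):
            se_sp(ContingencyTable(0, 3, 0, 7))

    @given(tp=counts, fp=counts, fn=counts, tn=counts)
    def test_youden_invariant_under_class_swap(self, tp, fp, fn, tn):
        if tp + fn == 0 or fp + tn == 0:
            return
        j = youden_index(ContingencyTable(tp, fp, fn, tn))
        j_swapped = youden_index(ContingencyTable(tn, fn, fp, tp))
        assert j == pytest.approx(j_swapped)


class TestMutualInformation:
    def test_perfect_test_at_even_prevalence(self):
        assert mutual_information(ContingencyTable(5, 0, 0, 5)) == pytest.approx(1.0)

    def test_independent_table(self):
        assert mutual_information(ContingencyTable(2, 2, 2, 2)) == 0.0

    def test_hand_evaluated_table(self):
        assert mutual_information(ContingencyTable(3, 1, 1, 3)) == pytest.approx(
            MI_3113_BITS, abs=1e-12
        )

    @given(tp=counts, fp=counts, fn=counts, tn=counts)
    def test_bounds(self, tp, fp, fn, tn):
        n = tp + fp + fn + tn
        if n == 0:
            return
        mi = mutual_information(ContingencyTable(tp, fp, fn, tn))
        assert mi >= 0.0
        h_row = _entropy_bits(((tp + fn) / n, (fp + tn) / n))
        h_col = _entropy_bits(((tp + fp) / n, (fn + tn) / n))
        assert mi <= min(h_row, h_col) + 1e-12


def _oracle_optimize(data, criterion):
    """Exhaustive candidate evaluation with independent scalar formulas."""
    lo, hi = data.values.min(), data.values.max()
    candidates = []
    c = lo
    while True:
        candidates.append(c)
        if c > hi:
            break
        c += 1.0
    best_c, best_score = None, -np.inf
    for c in candidates:
        tp = int(np.sum((data.values >= c) & (data.labels == 1)))
        fp = int(np.sum((data.values >= c) & (data.labels == 0)))
        fn = data.n_diseased - tp
        tn = data.n_healthy - fp
        if criterion == "youden":
            score = tp / data.n_diseased + tn / data.n_healthy - 1.0
        else:
            n = tp + fp + fn + tn
            score = 0.0
            for cell, row, col in (
                (tp, tp + fn, tp + fp),
                (fn, tp + fn, fn + tn),
                (fp, fp + tn, tp + fp),
                (tn, fp + tn, fn + tn),
            ):
                if cell:
                    score += cell / n * math.log2(cell * n / (row * col))
        if score > best_score + 1e-12:
            best_c, best_score = c, score
    return best_c, best_score


class TestOptimizeCutoff:
    def test_toy_youden(self, toy_dataset):
        est = optimize_cutoff(toy_dataset, Method.YOUDEN)
        assert est.cutoff == 3.0
        assert est.criterion_value == pytest.approx(1.0)
        assert est.sensitivity == est.specificity == 1.0

    def test_tie_broken_toward_smallest_cutoff(self):
        # candidates 1..5 all attain J = 1 on this gap; smallest wins
        data = DiagnosticDataset([0.5, 10.0, 11.0], [0, 1, 1])
        est = optimize_cutoff(data, Method.YOUDEN)
        assert est.cutoff == pytest.approx(1.5)  # min + 1 grid step

    @pytest.mark.parametrize("criterion", ["youden", "mutual_information"])
    def test_matches_exhaustive_oracle(self, criterion, rng):
        for _ in range(300):
            data = random_small_dataset(rng)
            est = optimize_cutoff(data, criterion)
            oracle_cut, oracle_score = _oracle_optimize(data, criterion)
            assert est.cutoff == pytest.approx(oracle_cut)
            assert est.criterion_value == pytest.approx(oracle_score, abs=1e-10)

    def test_mi_argmax_invariant_to_log_base(self, rng):
        for _ in range(100):
            data = random_small_dataset(rng)
            bits = optimize_cutoff(data, Method.MUTUAL_INFORMATION)
            nats = optimize_cutoff(data, Method.MUTUAL_INFORMATION, log_base=math.e)
            assert bits.cutoff == nats.cutoff
            assert nats.criterion_value == pytest.approx(
                bits.criterion_value * math.log(2.0)
            )

    def test_single_class_rejected(self):
        data = DiagnosticDataset([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="both"):
            optimize_cutoff(data, Method.YOUDEN)

    def test_lr_is_not_a_grid_criterion(self, toy_dataset):
        with pytest.raises(ValueError):
            optimize_cutoff(toy_dataset, Method.LIKELIHOOD_RATIO)


class TestReadDataset:
    def test_comma_with_header(self, tmp_path):
        path = tmp_path / "data.csv"
        path.write_text("value,label\n1.0,0\n2.0,0\n3.0,1\n4.0,1\n")
        data = read_dataset(path)
        np.testing.assert_array_equal(data.values, [1.0, 2.0, 3.0, 4.0])
        np.testing.assert_array_equal(data.labels, [0, 0, 1, 1])

    def test_whitespace_no_header(self, tmp_path):
        path = tmp_path / "data.txt"
        path.write_text("1.5 0\n9.5 1\n")
        data = read_dataset(path)
        np.testing.assert_array_equal(data.values, [1.5, 9.5])

    def test_invert_swaps_labels(self, tmp_path):
        path = tmp_path / "data.csv"
        path.write_text("1.0,1\n9.0,0\n")
        data = read_dataset(path, invert=True)
        np.testing.assert_array_equal(data.labels, [0, 1])

    def test_bad_label_reports_line(self, tmp_path):
        path = tmp_path / "data.csv"
        path.write_text("1.0,0\n2.0,7\n")
        with pytest.raises(ValueError, match=r":2.*label"):
            read_dataset(path)

    def test_wrong_column_count_reports_line(self, tmp_path):
        path = tmp_path / "data.csv"
        path.write_text("1.0,0\n2.0,0,9\n")
        with pytest.raises(ValueError, match=":2"):
            read_dataset(path)

    def test_non_numeric_value_mid_file(self, tmp_path):
        path = tmp_path / "data.csv"
        path.write_text("1.0,0\nabc,1\n")
        with pytest.raises(ValueError, match=":2.*non-numeric"):
            read_dataset(path)
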