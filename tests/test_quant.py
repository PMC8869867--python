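"""Unit and property tests for the spectral-count processing chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteaphagy import quant
from proteaphagy.quant import (
    SpectralCountMatrix,
    StageError,
    aggregate_psm_counts,
    call_detected_proteins,
    densitometry_relative_level,
    log2_with_floor,
    make_sample_metadata,
    quantile_normalize,
    subtract_background,
)

from conftest import random_matrix


class TestAggregation:
    def make_psm(self, rows):
        return pd.DataFrame(rows, columns=["protein_id", "peptide_id", "sample_id", "spectral_count"])

    def test_counts_summed_per_matching_peptide(self):
        samples = make_sample_metadata({"A": 1}, n_controls=1)
        psm = self.make_psm(
            [("P1", "pep1", "A_r1", 3), ("P1", "pep2", "A_r1", 2), ("P1", "pep1", "control_r1", 1)]
        )
        m = aggregate_psm_counts(psm, samples)
        assert m.data.loc["P1", "A_r1"] == 5
        assert m.data.loc["P1", "control_r1"] == 1
        assert m.stage == "raw"

    def test_shared_peptide_counts_toward_every_protein(self):
        samples = make_sample_metadata({"A": 1})
        psm = self.make_psm([("P1", "pepS", "A_r1", 4), ("P2", "pepS", "A_r1", 4)])
        m_all = aggregate_psm_counts(psm, samples, shared_peptides="all")
        assert m_all.data.loc["P1", "A_r1"] == 4 and m_all.data.loc["P2", "A_r1"] == 4
        m_uni = aggregate_psm_counts(psm, samples, shared_peptides="unique")
        assert m_uni.data.empty or (m_uni.data == 0).all().all()

    def test_empty_table_and_missing_samples(self):
        samples = make_sample_metadata({"A": 2})
        m = aggregate_psm_counts(self.make_psm([]), samples)
        assert list(m.data.columns) == list(samples.index)
        assert m.data.shape[0] == 0
        with pytest.raises(ValueError, match="unknown sample"):
            aggregate_psm_counts(self.make_psm([("P1", "pep1", "nope", 1)]), samples)

    def test_protein_absent_from_a_sample_gets_zero(self):
        samples = make_sample_metadata({"A": 2})
        psm = self.make_psm([("P1", "pep1", "A_r1", 7)])
        m = aggregate_psm_counts(psm, samples)
        assert m.data.loc["P1", "A_r2"] == 0


class TestBackgroundSubtraction:
    def test_mean_of_controls_subtracted(self, small_matrix):
        sub = subtract_background(small_matrix)
        # P1: controls (2, 3) -> mean 2.5
        assert sub.data.loc["P1", "A_r1"] == pytest.approx(10 - 2.5)
        assert sub.data.loc["P2", "A_r2"] == pytest.approx(2 - 2.5)  # may go negative
        assert sub.stage == "subtracted"
        assert "control_r1" not in sub.data.columns
        assert sub.controls is not None and "control_r1" in sub.controls.columns

    def test_paired_mode_matches_replicates(self, small_matrix):
        sub = subtract_background(small_matrix, control_mode="paired")
        assert sub.data.loc["P1", "A_r1"] == pytest.approx(10 - 2)
        assert sub.data.loc["P1", "A_r2"] == pytest.approx(12 - 3)

    def test_no_controls_is_an_error(self):
        samples = make_sample_metadata({"A": 2, "B": 2})
        data = pd.DataFrame(np.ones((2, 4)), index=["P1", "P2"], columns=list(samples.index))
        m = SpectralCountMatrix(data=data, samples=samples, stage="raw")
        with pytest.raises(ValueError, match="control"):
            subtract_background(m)


class TestLog2Floor:
    @pytest.mark.parametrize(
        "value,expected", [(-2.0, 0.0), (0.0, 0.0), (8.0, 3.0), (1.0, 0.0), (0.5, 0.0)]
    )
    def test_floor_then_log2(self, small_matrix, value, expected):
        sub = subtract_background(small_matrix)
        sub.data.iloc[0, 0] = value
        out = log2_with_floor(sub)
        assert out.data.iloc[0, 0] == pytest.approx(expected)

    def test_minimum_is_nonnegative_even_for_all_negative_input(self):
        samples = make_sample_metadata({"A": 2, "B": 2})
        data = pd.DataFrame(
            -np.abs(np.random.default_rng(0).normal(5, 2, (10, 4))),
            index=[f"P{i}" for i in range(10)],
            columns=list(samples.index),
        )
        m = SpectralCountMatrix(data=data, samples=samples, stage="subtracted")
        out = log2_with_floor(m)
        assert (out.data.to_numpy() == 0).all()

    def test_stage_order_enforced(self, small_matrix):
        with pytest.raises(StageError):
            log2_with_floor(small_matrix)  # raw, not subtracted
        with pytest.raises(StageError):
            quantile_normalize(subtract_background(small_matrix))  # log2 required


class TestQuantileNormalize:
    def test_hand_computed_rank_means(self):
        samples = make_sample_metadata({"A": 1, "B": 1})
        data = pd.DataFrame(
            {"A_r1": [1.0, 3.0], "B_r1": [2.0, 4.0]}, index=["P1", "P2"]
        )
        m = SpectralCountMatrix(data=data, samples=samples, stage="log2")
        out = quantile_normalize(m)
        expected = pd.DataFrame({"A_r1": [1.5, 3.5], "B_r1": [1.5, 3.5]}, index=["P1", "P2"])
        pd.testing.assert_frame_equal(out.data, expected)

    def test_identical_columns_are_a_fixed_point(self):
        samples = make_sample_metadata({"A": 1, "B": 1})
        col = [0.0, 2.0, 5.0]
        data = pd.DataFrame({"A_r1": col, "B_r1": col}, index=["P1", "P2", "P3"])
        m = SpectralCountMatrix(data=data, samples=samples, stage="log2")
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out.data, data)

    def test_single_column_is_an_error(self):
        samples = make_sample_metadata({"A": 1})
        data = pd.DataFrame({"A_r1": [1.0, 2.0]}, index=["P1", "P2"])
        m = SpectralCountMatrix(data=data, samples=samples, stage="log2")
        with pytest.raises(ValueError, match="two experimental columns"):
            quantile_normalize(m)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_sorted_columns_identical_and_idempotent(self, seed):
        m = random_matrix(np.random.default_rng(seed))
        out = quantile_normalize(m)
        arr = out.data.to_numpy()
        srt = np.sort(arr, axis=0)
        assert np.allclose(srt, srt[:, [0]], atol=0, rtol=0)
        again = quantile_normalize(m.copy_with(out.data, "log2"))
        np.testing.assert_allclose(again.data.to_numpy(), arr, rtol=1e-14, atol=1e-14)


class TestDetection:
    def make(self, values_a, values_b=(5.0, 5.0, 5.0)):
        samples = make_sample_metadata({"A": 3, "B": 3})
        data = pd.DataFrame(
            [list(values_a) + list(values_b)], index=["P1"], columns=list(samples.index)
        )
        return SpectralCountMatrix(data=data, samples=samples, stage="subtracted")

    def test_detected_in_all_replicates(self):
        call = call_detected_proteins(self.make((5, 6, 4)), min_value=1)
        assert bool(call.detected.loc["P1", "A"])

    def test_never_detected_when_all_below_threshold(self):
        call = call_detected_proteins(self.make((-1, 0, -3)), min_value=1)
        assert not bool(call.detected.loc["P1", "A"])

    def test_replicate_requirement_boundary(self):
        m = self.make((5, 0, 4))
        assert bool(call_detected_proteins(m, min_value=1, min_replicates=2).detected.loc["P1", "A"])
        assert not bool(call_detected_proteins(m, min_value=1, min_replicates=3).detected.loc["P1", "A"])
        with pytest.raises(ValueError, match="exceeds"):
            call_detected_proteins(m, min_replicates=4)


class TestDensitometry:
    @pytest.mark.parametrize(
        "args,expected",
        [((2, 1, 1, 1), 2.0), ((5, 2, 5, 2), 1.0), ((3, 2, 6, 4), 1.0)],
    )
    def test_relative_level(self, args, expected):
        assert densitometry_relative_level(*args) == pytest.approx(expected)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            densitometry_relative_level(0, 1, 1, 1)
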