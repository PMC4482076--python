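"""Intronic proportion, filter boundary, per-gene normalization, summaries."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intronscope.read_counting import COUNT_COLUMNS, EndCount
from intronscope.retention_stats import (
    compute_retention,
    condition_contrast,
    filter_min_intronic,
    intron_proportion,
    normalize_per_gene,
    summarize_all,
    summarize_sample,
)


def counts_frame(rows):
    """rows: (gene_id, sample_id, locus, exonic) -> full count table."""
    return pd.DataFrame(
        [(g, s, l, e, l - e) for g, s, l, e in rows], columns=COUNT_COLUMNS
    )


class TestIntronProportion:
    @pytest.mark.parametrize(
        "locus, exonic, expected", [(100, 80, 0.2), (50, 50, 0.0), (4, 1, 0.75)]
    )
    def test_formula(self, locus, exonic, expected):
        assert intron_proportion(locus, exonic) == pytest.approx(expected)
        assert intron_proportion(EndCount("G", "S", locus, exonic)) == pytest.approx(expected)

    def test_zero_locus_reads_is_undefined_not_zero(self):
        assert math.isnan(intron_proportion(0, 0))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            intron_proportion(10, 11)

    @given(st.integers(1, 10_000), st.data())
    @settings(deadline=None, derandomize=True)
    def test_monotone_in_read_class(self, locus, data):
        exonic = data.draw(st.integers(0, locus))
        p = intron_proportion(locus, exonic)
        assert 0.0 <= p <= 1.0
        # one more exonic read never increases the proportion
        assert intron_proportion(locus + 1, exonic + 1) <= p
        # one more intronic read never decreases it
        assert intron_proportion(locus + 1, exonic) >= p


class TestFilterMinIntronic:
    def test_strict_boundary_at_100(self):
        at = counts_frame(
            [("G1", f"s{i}", n + 10, 10) for i, n in enumerate([30, 30, 30, 5, 3, 2])]
        )
        below = counts_frame(
            [("G2", f"s{i}", n + 10, 10) for i, n in enumerate([30, 30, 30, 5, 3, 1])]
        )
        assert filter_min_intronic(at) == {"G1"}  # sum 100 passes
        assert filter_min_intronic(below) == set()  # sum 99 fails
        assert filter_min_intronic(pd.concat([at, below])) == {"G1"}

    def test_empty_table_and_negative_threshold(self):
        assert filter_min_intronic(counts_frame([])) == set()
        with pytest.raises(ValueError):
            filter_min_intronic(counts_frame([]), threshold=-1)

    def test_monotone_in_threshold(self, rng):
        rows = [
            (f"G{g}", f"s{s}", int(l), int(rng.integers(0, l + 1)))
            for g in range(20)
            for s, l in enumerate(rng.integers(1, 200, size=6))
        ]
        table = counts_frame(rows)
        previous = filter_min_intronic(table, threshold=0)
        for threshold in (10, 50, 100, 500):
            current = filter_min_intronic(table, threshold=threshold)
            assert current <= previous
            previous = current

    def test_collapse_replicates_mode(self, default_design):
        design = default_design.to_frame()
        # intronic 40 per sample: all-samples sum 240, condition-mean sum 120
        rows = [("G1", s, 50, 10) for s in design["sample_id"]]
        table = counts_frame(rows)
        assert filter_min_intronic(table, threshold=200) == {"G1"}
        assert (
            filter_min_intronic(table, threshold=200, collapse_replicates=True, design=design)
            == set()
        )
        assert (
            filter_min_intronic(table, threshold=120, collapse_replicates=True, design=design)
            == {"G1"}
        )


class TestNormalizePerGene:
    def test_divides_by_max(self):
        got = normalize_per_gene([0.10, 0.20, 0.40, 0.10, 0.05, 0.20])
        np.testing.assert_allclose(got, [0.25, 0.50, 1.00, 0.25, 0.125, 0.50])

    def test_all_zero_stays_zero(self):
        np.testing.assert_array_equal(normalize_per_gene([0.0, 0.0]), [0.0, 0.0])

    def test_single_defined_value_maps_to_one(self):
        got = normalize_per_gene([np.nan, 0.3, np.nan])
        assert math.isnan(got[0]) and got[1] == 1.0 and math.isnan(got[2])

    def test_all_undefined_passes_through(self):
        got = normalize_per_gene([np.nan, np.nan])
        assert np.isnan(got).all()

    def test_ties_at_max_all_map_to_one(self):
        got = normalize_per_gene([0.4, 0.4, 0.2])
        np.testing.assert_allclose(got, [1.0, 1.0, 0.5])


class TestSummarizeSample:
    def test_median_of_three(self):
        s = summarize_sample([0.0, 0.5, 1.0], "s")
        assert s.median == 0.5 and s.n_genes == 3

    def test_uniform_grid_percentiles(self):
        values = np.arange(1, 1001) / 1000.0  # 0.001 .. 1.000
        s = summarize_sample(values, "s")
        assert abs(s.p5 - 0.050) <= 0.001
        assert abs(s.p95 - 0.950) <= 0.001
        assert s.median == pytest.approx(0.5005)

    def test_degenerate_all_equal(self):
        s = summarize_sample([1.0, 1.0, 1.0], "s")
        assert s.median == s.p5 == s.p95 == 1.0

    def test_nan_excluded_and_empty_errors_with_sample_name(self):
        s = summarize_sample([np.nan, 0.2, 0.4], "sX")
        assert s.n_genes == 2
        with pytest.raises(ValueError, match="sY"):
            summarize_sample([np.nan], "sY")


class TestComputeRetention:
    def test_pipeline_columns_and_invariants(self, rng, default_design):
        design = default_design.to_frame()
        rows = []
        for g in range(30):
            for s in design["sample_id"]:
                locus = int(rng.integers(0, 400))
                exonic = int(rng.integers(0, locus + 1)) if locus else 0
                rows.append((f"G{g:02d}", s, locus, exonic))
        table = counts_frame(rows)
        ret = compute_retention(table, threshold=100)
        # proportions in [0,1] where defined; NaN exactly when locus_count == 0
        defined = ret["proportion"].notna()
        assert (defined == (ret["locus_count"] > 0)).all()
        assert ret.loc[defined, "proportion"].between(0, 1).all()
        # normalized values only for retained genes; per-gene max is exactly 1
        assert ret.loc[~ret["passed_filter"], "normalized_proportion"].isna().all()
        for _, group in ret[ret["passed_filter"]].groupby("gene_id"):
            if group["proportion"].fillna(0).max() > 0:
                assert group["normalized_proportion"].max() == 1.0
            assert group["normalized_proportion"].dropna().between(0, 1).all()

    def test_filter_applied_before_normalization(self):
        # G2 fails the filter: no normalized values even though proportions exist
        rows = [("G1", f"s{i}", 200, 100) for i in range(6)] + [
            ("G2", f"s{i}", 20, 10) for i in range(6)
        ]
        ret = compute_retention(counts_frame(rows), threshold=100)
        assert ret.loc[ret["gene_id"] == "G2", "normalized_proportion"].isna().all()
        assert (ret.loc[ret["gene_id"] == "G1", "normalized_proportion"] == 1.0).all()


class TestConditionContrast:
    def test_deltas_vs_control(self):
        summaries = pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1", "b2"],
                "condition": ["kd", "kd", "ctrl", "ctrl"],
                "replicate": [1, 2, 1, 2],
                "n_genes": [10] * 4,
                "median": [0.8, 0.8, 0.2, 0.2],
                "p5": [0.1] * 4,
                "p95": [0.9] * 4,
            }
        )
        out = condition_contrast(summaries, control_condition="ctrl").set_index("condition")
        assert out.loc["kd", "delta_vs_control"] == pytest.approx(0.6)
        assert out.loc["ctrl", "delta_vs_control"] == 0.0

    def test_single_condition_is_its_own_control(self):
        summaries = pd.DataFrame(
            {
                "sample_id": ["a1"],
                "condition": ["ctrl"],
                "replicate": [1],
                "n_genes": [5],
                "median": [0.4],
                "p5": [0.1],
                "p95": [0.9],
            }
        )
        out = condition_contrast(summaries, control_condition="ctrl")
        assert out["delta_vs_control"].tolist() == [0.0]

    def test_missing_control_is_error(self):
        summaries = pd.DataFrame(
            {"sample_id": ["a"], "condition": ["kd"], "replicate": [1], "n_genes": [1], "median": [0.5], "p5": [0.5], "p95": [0.5]}
        )
        with pytest.raises(ValueError, match="control"):
            condition_contrast(summaries, control_condition="ctrl")


def test_summarize_all_joins_design(default_design):
    design = default_design.to_frame()
    rows = [(f"G{g}", s, 200, 100) for g in range(3) for s in design["sample_id"]]
    ret = compute_retention(counts_frame(rows), threshold=100)
    summaries = summarize_all(ret, design)
    assert set(summaries["sample_id"]) == set(design["sample_id"])
    assert (summaries["n_genes"] == 3).all()
    assert (summaries["p5"] <= summaries["median"]).all()
    assert (summaries["median"] <= summaries["p95"]).all()
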