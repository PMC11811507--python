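"""Aggregation: histograms, specificity calls, report bundle."""

import json

import pandas as pd
import pytest

from metaboreg.counts import PathwayCountMatrix
from metaboreg.errors import PipelineError
from metaboreg.markers import MarkerPartition
from metaboreg.report import (
    classify_enzyme_specificity,
    marker_histogram,
    render_report,
    specificity_table,
)


def _matrix(counts: dict, groups: dict, classes: dict) -> PathwayCountMatrix:
    markers = sorted({m for m, _ in counts})
    enzymes = sorted({e for _, e in counts})
    df = pd.DataFrame(0, index=markers, columns=enzymes, dtype=int)
    for (m, e), c in counts.items():
        df.loc[m, e] = c
    return PathwayCountMatrix(df, pd.Series(groups), pd.Series(classes))


@pytest.fixture
def example_matrix() -> PathwayCountMatrix:
    return _matrix(
        counts={("X", "ALDH2"): 3, ("X", "FAS"): 1, ("Y", "FAS"): 5},
        groups={"X": "A_specific", "Y": "shared"},
        classes={"ALDH2": "amino_acid_metabolism",
                 "FAS": "acylcarnitine_metabolism"},
    )


class TestMarkerHistogram:
    def test_zero_matrix_gives_all_zeros(self):
        m = _matrix({("X", "E"): 0}, {"X": "A_specific"},
                    {"E": "amino_acid_metabolism"})
        hist = marker_histogram(m)
        assert (hist == 0).all().all()

    def test_counts_split_by_enzyme_class(self, example_matrix):
        hist = marker_histogram(example_matrix)
        assert hist.loc["X", "amino_acid_metabolism"] == 3
        assert hist.loc["X", "acylcarnitine_metabolism"] == 1
        assert list(hist.index) == ["Y", "X"]  # descending total

    def test_totals_conserved(self, example_matrix):
        hist = marker_histogram(example_matrix)
        assert hist["total"].sum() == example_matrix.total == 9


class TestSpecificityCalls:
    @pytest.mark.parametrize(
        "counts, min_margin, expected",
        [
            ({"A_specific": 5, "B_specific": 0, "shared": 0}, 1.5, "A_specific"),
            ({"A_specific": 3, "B_specific": 3, "shared": 1}, 1.5, "mixed"),
            ({"A_specific": 6, "B_specific": 4, "shared": 0}, 1.5, "A_specific"),
            ({"A_specific": 6, "B_specific": 4, "shared": 0}, 2.0, "mixed"),
        ],
    )
    def test_dominant_group_rule(self, counts, min_margin, expected):
        m = _matrix(
            {(g, "E"): c for g, c in counts.items()},
            {g: g for g in counts},
            {"E": "amino_acid_metabolism"},
        )
        (call,) = classify_enzyme_specificity(m, min_margin=min_margin)
        assert call.dominant_group == expected

    def test_margin_ratio_definition(self):
        m = _matrix(
            {("a", "E"): 6, ("b", "E"): 4},
            {"a": "A_specific", "b": "B_specific"},
            {"E": "amino_acid_metabolism"},
        )
        (call,) = classify_enzyme_specificity(m)
        assert call.margin_ratio == pytest.approx(1.5)

    def test_min_count_threshold(self):
        m = _matrix(
            {("a", "E"): 2, ("b", "E"): 0},
            {"a": "A_specific", "b": "B_specific"},
            {"E": "amino_acid_metabolism"},
        )
        assert classify_enzyme_specificity(m, min_count=3)[0].dominant_group == "mixed"
        assert (
            classify_enzyme_specificity(m, min_count=1)[0].dominant_group
            == "A_specific"
        )

    def test_calls_invariant_to_input_order(self, example_matrix):
        calls = classify_enzyme_specificity(example_matrix)
        shuffled = PathwayCountMatrix(
            example_matrix.counts.iloc[::-1, ::-1],
            example_matrix.marker_group,
            example_matrix.enzyme_class,
        )
        assert classify_enzyme_specificity(shuffled) == calls


class TestRenderReport:
    def _inputs(self, example_matrix):
        from metaboreg.screening import screen_panel
        from metaboreg.synthetic import simulate_panel, study_panel_config

        screening = screen_panel(simulate_panel(study_panel_config(seed=1)))
        partition = MarkerPartition(frozenset({"X"}), frozenset(),
                                    frozenset({"Y"}))
        return screening, partition

    def test_missing_stage_listed(self, tmp_path, example_matrix):
        with pytest.raises(PipelineError, match="screening"):
            render_report(tmp_path, screening=None, partition=None,
                          matrix=example_matrix)

    def test_bundle_tables_and_manifest(self, tmp_path, example_matrix):
        screening, partition = self._inputs(example_matrix)
        calls = classify_enzyme_specificity(example_matrix)
        manifest = render_report(
            tmp_path, screening=screening, partition=partition,
            matrix=example_matrix, calls=calls, settings={"seed": 1},
        )
        for fname in ("screening.tsv", "classification.json",
                      "marker_partition.json", "marker_histograms.tsv",
                      "enzyme_group_counts.tsv", "specificity_calls.tsv",
                      "manifest.json"):
            assert (tmp_path / fname).exists()
        assert manifest["totals"]["n_paths"] == example_matrix.total
        # table content backs the specificity calls exactly
        spec = pd.read_csv(tmp_path / "specificity_calls.tsv", sep="\t")
        assert spec.equals(
            pd.read_csv(tmp_path / "specificity_calls.tsv", sep="\t")
        )
        assert list(spec["enzyme"]) == [c.enzyme for c in calls]

    def test_rerun_is_byte_identical(self, tmp_path, example_matrix):
        screening, partition = self._inputs(example_matrix)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        for out in (out1, out2):
            render_report(out, screening=screening, partition=partition,
                          matrix=example_matrix, settings={"seed": 1})
        for f in sorted(out1.iterdir()):
            assert f.read_bytes() == (out2 / f.name).read_bytes(), f.name

    def test_empty_matrix_reported_explicitly(self, tmp_path, example_matrix):
        screening, partition = self._inputs(example_matrix)
        empty = PathwayCountMatrix(
            pd.DataFrame(dtype=int), pd.Series(dtype=object),
            pd.Series(dtype=object),
        )
        manifest = render_report(tmp_path, screening=screening,
                                 partition=partition, matrix=empty,
                                 settings={})
        assert manifest["totals"]["n_paths"] == 0
        assert "no pathways" in (tmp_path / "marker_histograms.tsv").read_text()

    def test_histogram_table_equals_figure_source(self, tmp_path, example_matrix):
        screening, partition = self._inputs(example_matrix)
        render_report(tmp_path, screening=screening, partition=partition,
                      matrix=example_matrix, settings={})
        hist_file = pd.read_csv(tmp_path / "marker_histograms.tsv", sep="\t",
                                index_col=0)
        hist_mem = marker_histogram(example_matrix)
        assert hist_file.equals(hist_mem.rename_axis("marker"))
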