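"""Template-constrained pathway enumeration and counting."""

import pytest

from conftest import oracle_template_counts
from metaboreg.counts import count_paths, paths_to_table
from metaboreg.errors import TemplateError
from metaboreg.kgraph import KnowledgeGraph
from metaboreg.markers import MarkerPartition
from metaboreg.templates import (
    default_templates,
    enumerate_all_templates,
    enumerate_template_paths,
    templates_from_yaml,
    templates_to_yaml,
)


def _by_id(templates):
    return {t.id: t for t in templates}


class TestDefaultTemplates:
    def test_exactly_four_templates(self):
        ts = default_templates()
        assert [t.id for t in ts] == ["T1", "T2", "T3", "T4"]

    def test_intermediate_templates_require_at_least_one_mediator(self):
        ts = _by_id(default_templates())
        assert ts["T3"].intermediate.min_repeats == 1
        assert ts["T4"].intermediate.min_repeats == 1
        assert ts["T1"].intermediate is None

    def test_expression_template_needs_gene_nodes(self):
        kg = KnowledgeGraph()
        kg.add_node("M", "protein")
        kg.add_node("E", "protein")
        kg.add_edge("M", "E", "activity_regulation")
        t2 = _by_id(default_templates())["T2"]
        assert enumerate_template_paths(kg, t2, ["M"], ["E"]) == []

    def test_direct_edge_not_double_counted_by_intermediate_template(self):
        kg = KnowledgeGraph()
        kg.add_node("M", "protein")
        kg.add_node("E", "protein")
        kg.add_edge("M", "E", "activity_regulation")
        ts = _by_id(default_templates())
        assert len(enumerate_template_paths(kg, ts["T1"], ["M"], ["E"])) == 1
        assert enumerate_template_paths(kg, ts["T3"], ["M"], ["E"]) == []


class TestEnumeration:
    def test_edgeless_graph_yields_nothing(self):
        kg = KnowledgeGraph()
        kg.add_node("M", "protein")
        kg.add_node("E", "protein")
        for t in default_templates():
            assert enumerate_template_paths(kg, t, ["M"], ["E"]) == []

    def test_single_t4_instance(self, tiny_graph):
        t4 = _by_id(default_templates())["T4"]
        paths = enumerate_template_paths(tiny_graph, t4, ["M"], ["E"])
        assert len(paths) == 1
        (p,) = paths
        assert p.nodes == ("M", "X", "gE", "E")
        assert p.edge_types == ("ppi", "expression_regulation", "encodes")
        assert len(p) == 3

    def test_parallel_edge_of_different_type_gives_second_path(self, tiny_graph):
        tiny_graph.add_edge("M", "X", "activity_regulation")
        t4 = _by_id(default_templates())["T4"]
        paths = enumerate_template_paths(tiny_graph, t4, ["M"], ["E"])
        assert len(paths) == 2
        assert {p.edge_types[0] for p in paths} == {"ppi", "activity_regulation"}

    def test_parallel_edge_of_same_type_does_not_duplicate(self, tiny_graph):
        tiny_graph.g.add_edge("M", "X", edge_type="ppi", sign="up")
        t4 = _by_id(default_templates())["T4"]
        assert len(enumerate_template_paths(tiny_graph, t4, ["M"], ["E"])) == 1

    def test_missing_source_warns_not_fails(self, tiny_graph):
        t1 = _by_id(default_templates())["T1"]
        with pytest.warns(UserWarning, match="ghost"):
            enumerate_template_paths(tiny_graph, t1, ["M", "ghost"], ["E"])

    def test_max_intermediates_below_template_minimum_rejected(self, tiny_graph):
        t3 = _by_id(default_templates())["T3"]
        with pytest.raises(TemplateError, match="intermediates"):
            enumerate_template_paths(tiny_graph, t3, ["M"], ["E"],
                                     max_intermediates=0)

    def test_output_sorted_lexicographically(self, random_graph_factory):
        g = random_graph_factory(2, noise=0.2)
        paths = enumerate_all_templates(
            g, default_templates(), ["M00", "M01", "M02"], ["E00", "E01"]
        )
        per_template = {}
        for p in paths:
            per_template.setdefault(p.template_id, []).append(p.key())
        for keys in per_template.values():
            assert keys == sorted(keys)


class TestOracleEquivalence:
    def test_counts_match_brute_force_on_random_graphs(self, random_graph_factory):
        sources = ["M00", "M01", "M02"]
        targets = ["E00", "E01"]
        templates = default_templates()
        for seed in range(20):
            g = random_graph_factory(seed)
            oracle = oracle_template_counts(g, sources, targets)
            for t in templates:
                got = enumerate_template_paths(g, t, sources, targets)
                got_keys = {(p.nodes, p.edge_types) for p in got}
                assert got_keys == oracle[t.id], f"seed={seed} template={t.id}"

    def test_no_path_emitted_by_two_templates(self, random_graph_factory):
        sources = ["M00", "M01", "M02"]
        targets = ["E00", "E01"]
        for seed in range(10):
            g = random_graph_factory(seed, noise=0.2)
            seen = {}
            for t in default_templates():
                for p in enumerate_template_paths(g, t, sources, targets):
                    assert p.key() not in seen, (
                        f"path {p.nodes} in both {seen.get(p.key())} and {t.id}"
                    )
                    seen[p.key()] = t.id

    def test_adding_an_edge_never_decreases_counts(self, random_graph_factory):
        g = random_graph_factory(4, noise=0.1)
        sources = ["M00", "M01", "M02"]
        targets = ["E00", "E01"]
        before = {
            t.id: len(enumerate_template_paths(g, t, sources, targets))
            for t in default_templates()
        }
        g.add_edge("M00", "X00", "transport_regulation")
        g.add_edge("X00", "E01", "catalysis_regulation")
        after = {
            t.id: len(enumerate_template_paths(g, t, sources, targets))
            for t in default_templates()
        }
        assert all(after[k] >= before[k] for k in before)
        assert after["T3"] > before["T3"]


class TestYaml:
    def test_roundtrip_preserves_templates(self, tmp_path):
        ts = default_templates(max_intermediates=2)
        f = templates_to_yaml(ts, tmp_path / "templates.yaml")
        back = templates_from_yaml(f)
        assert back == ts

    def test_malformed_spec_rejected(self, tmp_path):
        f = tmp_path / "bad.yaml"
        f.write_text("templates:\n  - id: T9\n")
        with pytest.raises(TemplateError):
            templates_from_yaml(f)


class TestCountPaths:
    def test_empty_path_list_gives_zero_matrix(self):
        m = count_paths([])
        assert m.total == 0
        assert m.counts.empty

    def test_column_sum_conservation(self, tiny_graph):
        tiny_graph.add_edge("M", "E", "activity_regulation")
        tiny_graph.add_node("M2", "protein")
        tiny_graph.add_edge("M2", "E", "catalysis_regulation")
        paths = enumerate_all_templates(
            tiny_graph, default_templates(), ["M", "M2"], ["E"]
        )
        with pytest.warns(UserWarning):  # no annotations supplied
            m = count_paths(paths)
        assert m.total == len(paths) == 3
        assert int(m.counts["E"].sum()) == 3

    def test_dedupe_pairs_counts_each_marker_enzyme_once(self, tiny_graph):
        tiny_graph.add_edge("M", "E", "activity_regulation")
        paths = enumerate_all_templates(
            tiny_graph, default_templates(), ["M"], ["E"]
        )
        assert len(paths) == 2  # one T1 + one T4
        part = MarkerPartition(frozenset({"M"}), frozenset(), frozenset())
        with pytest.warns(UserWarning):  # enzyme class unannotated
            m = count_paths(paths, part, None, dedupe="pairs")
        assert m.total == 1

    def test_margins_recount_the_raw_path_list(self, random_graph_factory):
        g = random_graph_factory(7, noise=0.15)
        part = MarkerPartition(
            frozenset({"M00"}), frozenset({"M01"}), frozenset({"M02"})
        )
        paths = enumerate_all_templates(
            g, default_templates(), ["M00", "M01", "M02"], ["E00", "E01"]
        )
        with pytest.warns(UserWarning):  # enzymes unannotated
            m = count_paths(paths, part, None)
        assert m.total == len(paths)
        per_enzyme = m.per_enzyme_by_group()
        for marker_group in per_enzyme.columns:
            for enzyme in per_enzyme.index:
                expected = sum(
                    1
                    for p in paths
                    if p.enzyme == enzyme and part.group_of(p.marker) == marker_group
                )
                assert per_enzyme.loc[enzyme, marker_group] == expected
        assert per_enzyme.to_numpy().sum() == m.per_marker_by_class().to_numpy().sum()

    def test_path_table_has_one_row_per_path(self, tiny_graph):
        paths = enumerate_all_templates(
            tiny_graph, default_templates(), ["M"], ["E"]
        )
        table = paths_to_table(paths)
        assert len(table) == len(paths)
        assert list(table["template"]) == [p.template_id for p in paths]
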