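"""Template-constrained enumeration of regulatory pathways.

A pathway template is a declarative pattern: starting from a marker
protein, a bounded run of intermediate proteins reached over regulatory or
PPI edges, then a terminal segment that lands on a metabolite-converting
enzyme — either directly through a protein-level interaction, or through
expression regulation of the enzyme's gene followed by the gene→protein
``encodes`` link.  The four default templates cover the cross product
{direct, via intermediates} × {protein-level, via gene expression}:

  T1  marker →(protein-level)→ enzyme
  T2  marker →(expression)→ enzyme gene →(encodes)→ enzyme
  T3  marker →(ppi/regulation)→ intermediate⁺ →(protein-level)→ enzyme
  T4  marker →(ppi/regulation)→ intermediate⁺ →(expression)→ enzyme gene
        →(encodes)→ enzyme

Paths are simple (no node revisited); two paths are distinct iff their
(node sequence, edge-type sequence) pairs differ, so parallel edges of
different types yield distinct paths while parallel same-type edges do
not.  All outputs are sorted lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import TemplateError
from .kgraph import (
    EDGE_ENCODES,
    EDGE_EXPRESSION,
    EDGE_PPI,
    EDGE_TYPES,
    KnowledgeGraph,
    NODE_GENE,
    NODE_PROTEIN,
    NODE_TYPES,
    PROTEIN_REGULATION_TYPES,
)

#: Protein-level interaction kinds a marker/intermediate may exert on an enzyme.
DIRECT_EDGE_TYPES = frozenset({EDGE_PPI} | PROTEIN_REGULATION_TYPES)
#: Kinds allowed on marker→intermediate and intermediate→intermediate hops.
INTERMEDIATE_EDGE_TYPES = frozenset(DIRECT_EDGE_TYPES | {EDGE_EXPRESSION})


@dataclass(frozen=True)
class TemplateStep:
    """One hop: the allowed edge kinds and the node type it lands on."""

    edge_types: frozenset[str]
    node_type: str

    def __post_init__(self) -> None:
        unknown = self.edge_types - set(EDGE_TYPES)
        if unknown:
            raise TemplateError(f"unknown edge type(s) in step: {sorted(unknown)}")
        if self.node_type not in NODE_TYPES:
            raise TemplateError(f"unknown node type {self.node_type!r}")


@dataclass(frozen=True)
class IntermediateSegment:
    """A bounded run of intermediate protein hops."""

    edge_types: frozenset[str]
    min_repeats: int
    max_repeats: int

    def __post_init__(self) -> None:
        if self.min_repeats < 0 or self.max_repeats < self.min_repeats:
            raise TemplateError(
                f"need 0 ≤ min_repeats ≤ max_repeats, got "
                f"{self.min_repeats}..{self.max_repeats}"
            )


@dataclass(frozen=True)
class PathTemplate:
    """Declarative pattern for one pathway type.

    ``intermediate`` (optional) precedes ``terminal_steps``; the source is
    always a marker protein and the last step lands on the enzyme protein.
    """

    id: str
    terminal_steps: tuple[TemplateStep, ...]
    intermediate: IntermediateSegment | None = None

    def __post_init__(self) -> None:
        if not self.terminal_steps:
            raise TemplateError(f"template {self.id!r} has no terminal steps")
        if self.terminal_steps[-1].node_type != NODE_PROTEIN:
            raise TemplateError(
                f"template {self.id!r} must terminate on the enzyme protein"
            )

    def step_sequences(self, max_intermediates: int) -> list[tuple[TemplateStep, ...]]:
        """Concrete step sequences for every allowed intermediate count."""
        if self.intermediate is None:
            return [self.terminal_steps]
        seg = self.intermediate
        if max_intermediates < seg.min_repeats:
            raise TemplateError(
                f"template {self.id!r} needs ≥ {seg.min_repeats} intermediates, "
                f"max_intermediates={max_intermediates}"
            )
        hop = TemplateStep(seg.edge_types, NODE_PROTEIN)
        upper = min(seg.max_repeats, max_intermediates)
        return [
            (hop,) * r + self.terminal_steps
            for r in range(seg.min_repeats, upper + 1)
        ]


@dataclass(frozen=True)
class RegulatoryPath:
    """One concrete marker→enzyme pathway instance."""

    template_id: str
    nodes: tuple[str, ...]
    node_types: tuple[str, ...]
    edge_types: tuple[str, ...]
    signs: tuple[str, ...]

    @property
    def marker(self) -> str:
        return self.nodes[0]

    @property
    def enzyme(self) -> str:
        return self.nodes[-1]

    def key(self) -> tuple:
        return (self.nodes, self.edge_types)

    def __len__(self) -> int:
        return len(self.edge_types)


def default_templates(max_intermediates: int = 1) -> list[PathTemplate]:
    """The four default pathway templates (see module docstring)."""
    direct = TemplateStep(DIRECT_EDGE_TYPES, NODE_PROTEIN)
    via_gene = (
        TemplateStep(frozenset({EDGE_EXPRESSION}), NODE_GENE),
        TemplateStep(frozenset({EDGE_ENCODES}), NODE_PROTEIN),
    )
    seg = IntermediateSegment(INTERMEDIATE_EDGE_TYPES, 1, max_intermediates)
    return [
        PathTemplate("T1", (direct,)),
        PathTemplate("T2", via_gene),
        PathTemplate("T3", (direct,), intermediate=seg),
        PathTemplate("T4", via_gene, intermediate=seg),
    ]


def enumerate_template_paths(
    graph: KnowledgeGraph,
    template: PathTemplate,
    sources: Iterable[str],
    targets: Iterable[str],
    max_intermediates: int = 1,
) -> list[RegulatoryPath]:
    """All distinct simple paths matching ``template`` from any source
    marker to any target enzyme.

    Missing source/target ids are ignored with a warning rather than
    failing, so marker lists can be broader than the graph.  Output is
    sorted by (node sequence, edge-type sequence).
    """
    import warnings

    present_sources = []
    for s in sorted(set(sources)):
        if graph.has_node(s):
            present_sources.append(s)
        else:
            warnings.warn(f"source {s!r} not in graph; skipped")
    target_set = set()
    for t in sorted(set(targets)):
        if graph.has_node(t):
            target_set.add(t)
        else:
            warnings.warn(f"target {t!r} not in graph; skipped")

    found: dict[tuple, RegulatoryPath] = {}
    for steps in template.step_sequences(max_intermediates):
        for source in present_sources:
            if graph.node_type(source) != NODE_PROTEIN:
                continue
            _dfs(graph, template.id, steps, 0, source, target_set,
                 [source], [graph.node_type(source)], [], [], found)
    return [found[k] for k in sorted(found)]


def _dfs(
    graph: KnowledgeGraph,
    template_id: str,
    steps: Sequence[TemplateStep],
    depth: int,
    node: str,
    targets: set[str],
    nodes: list[str],
    node_types: list[str],
    edge_types: list[str],
    signs: list[str],
    found: dict,
) -> None:
    if depth == len(steps):
        path = RegulatoryPath(
            template_id, tuple(nodes), tuple(node_types),
            tuple(edge_types), tuple(signs),
        )
        found[path.key()] = path
        return
    step = steps[depth]
    last = depth == len(steps) - 1
    # parallel same-type edges collapse to one branch; keep first sign seen
    branches: dict[tuple[str, str], str] = {}
    for target, etype, sign in graph.out_edges(node):
        if etype not in step.edge_types:
            continue
        if graph.node_type(target) != step.node_type:
            continue
        if target in nodes:  # simple-path constraint
            continue
        if last and target not in targets:
            continue
        branches.setdefault((target, etype), sign)
    for (target, etype), sign in sorted(branches.items()):
        nodes.append(target)
        node_types.append(graph.node_type(target))
        edge_types.append(etype)
        signs.append(sign)
        _dfs(graph, template_id, steps, depth + 1, target, targets,
             nodes, node_types, edge_types, signs, found)
        nodes.pop()
        node_types.pop()
        edge_types.pop()
        signs.pop()


def enumerate_all_templates(
    graph: KnowledgeGraph,
    templates: Sequence[PathTemplate],
    sources: Iterable[str],
    targets: Iterable[str],
    max_intermediates: int = 1,
) -> list[RegulatoryPath]:
    """Concatenated enumeration over several templates (sorted per template)."""
    out: list[RegulatoryPath] = []
    for t in templates:
        out.extend(
            enumerate_template_paths(graph, t, sources, targets, max_intermediates)
        )
    return out


# -- YAML template spec ----------------------------------------------------

def templates_to_yaml(templates: Sequence[PathTemplate], path: str | Path) -> Path:
    doc = {"templates": []}
    for t in templates:
        entry: dict = {
            "id": t.id,
            "terminal_steps": [
                {"edge_types": sorted(s.edge_types), "node_type": s.node_type}
                for s in t.terminal_steps
            ],
        }
        if t.intermediate is not None:
            entry["intermediate"] = {
                "edge_types": sorted(t.intermediate.edge_types),
                "min_repeats": t.intermediate.min_repeats,
                "max_repeats": t.intermediate.max_repeats,
            }
        doc["templates"].append(entry)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def templates_from_yaml(path: str | Path) -> list[PathTemplate]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "templates" not in doc:
        raise TemplateError(f"{path}: expected a top-level 'templates' list")
    out = []
    for entry in doc["templates"]:
        try:
            steps = tuple(
                TemplateStep(frozenset(s["edge_types"]), s["node_type"])
                for s in entry["terminal_steps"]
            )
            seg = None
            if entry.get("intermediate"):
                i = entry["intermediate"]
                seg = IntermediateSegment(
                    frozenset(i["edge_types"]), int(i["min_repeats"]),
                    int(i["max_repeats"]),
                )
            out.append(PathTemplate(entry["id"], steps, intermediate=seg))
        except (KeyError, TypeError) as exc:
            raise TemplateError(f"{path}: malformed template entry: {exc}") from exc
    return out
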