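"""Typed molecular-interaction graphs: the substrate for pathway search.

Nodes are proteins or genes; directed edges carry one of eight interaction
kinds (protein–protein interaction, five flavours of protein-level
regulation, gene expression regulation, and gene→protein ``encodes``
links) plus an optional sign.  PPI edges are stored as two directed edges
so every pathway template is a uniform directed pattern; a simple path can
never traverse both directions of one PPI pair because it never revisits
a node.

Three on-disk dialects are supported: a six-column edge TSV (canonical),
SIF with a ``<path>.nodes.tsv`` sidecar for node types, and GraphML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from .errors import GraphError

NODE_PROTEIN = "protein"
NODE_GENE = "gene"
NODE_TYPES = (NODE_PROTEIN, NODE_GENE)

EDGE_PPI = "ppi"
EDGE_ACTIVITY = "activity_regulation"
EDGE_DEGRADATION = "degradation_regulation"
EDGE_TRANSPORT = "transport_regulation"
EDGE_PROTEOLYSIS = "proteolysis_regulation"
EDGE_CATALYSIS = "catalysis_regulation"
EDGE_EXPRESSION = "expression_regulation"
EDGE_ENCODES = "encodes"

EDGE_TYPES = (
    EDGE_PPI,
    EDGE_ACTIVITY,
    EDGE_DEGRADATION,
    EDGE_TRANSPORT,
    EDGE_PROTEOLYSIS,
    EDGE_CATALYSIS,
    EDGE_EXPRESSION,
    EDGE_ENCODES,
)

#: Protein-level regulation kinds (excludes PPI, expression and encodes).
PROTEIN_REGULATION_TYPES = frozenset(
    {EDGE_ACTIVITY, EDGE_DEGRADATION, EDGE_TRANSPORT, EDGE_PROTEOLYSIS, EDGE_CATALYSIS}
)

SIGNS = ("up", "down", "unknown")

EDGE_TSV_HEADER = ("source", "source_type", "edge_type", "sign", "target", "target_type")


@dataclass
class KnowledgeGraph:
    """Typed directed multigraph over proteins and genes.

    Thin wrapper over :class:`networkx.MultiDiGraph`; every mutation is
    invariant-checked (endpoint typing per edge kind, no self-loops).
    """

    g: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)

    # -- construction -----------------------------------------------------
    def add_node(self, node_id: str, node_type: str) -> None:
        if node_type not in NODE_TYPES:
            raise GraphError(
                f"unknown node type {node_type!r} for {node_id!r}; "
                f"allowed: {NODE_TYPES}"
            )
        existing = self.g.nodes.get(node_id)
        if existing is not None and existing["node_type"] != node_type:
            raise GraphError(
                f"node {node_id!r} redeclared as {node_type!r} "
                f"(was {existing['node_type']!r})"
            )
        self.g.add_node(node_id, node_type=node_type)

    def add_edge(
        self, source: str, target: str, edge_type: str, sign: str = "unknown"
    ) -> None:
        self._check_edge(source, target, edge_type, sign, where=None)
        self.g.add_edge(source, target, edge_type=edge_type, sign=sign)

    def add_ppi(self, a: str, b: str, sign: str = "unknown") -> None:
        """Add an undirected PPI as the directed pair a→b, b→a."""
        self.add_edge(a, b, EDGE_PPI, sign)
        self.add_edge(b, a, EDGE_PPI, sign)

    def _check_edge(
        self, source: str, target: str, edge_type: str, sign: str, where: str | None
    ) -> None:
        loc = f"{where}: " if where else ""
        if edge_type not in EDGE_TYPES:
            raise GraphError(
                f"{loc}unknown edge type {edge_type!r}; allowed: {sorted(EDGE_TYPES)}"
            )
        if sign not in SIGNS:
            raise GraphError(f"{loc}unknown sign {sign!r}; allowed: {SIGNS}")
        for end in (source, target):
            if end not in self.g:
                raise GraphError(f"{loc}dangling endpoint {end!r}")
        if source == target:
            raise GraphError(f"{loc}self-loop on {source!r}")
        st = self.node_type(source)
        tt = self.node_type(target)
        if edge_type == EDGE_EXPRESSION and tt != NODE_GENE:
            raise GraphError(
                f"{loc}expression_regulation must target a gene, "
                f"but {target!r} is a {tt}"
            )
        if edge_type == EDGE_ENCODES and (st != NODE_GENE or tt != NODE_PROTEIN):
            raise GraphError(
                f"{loc}encodes must go gene→protein, got {st}→{tt} "
                f"({source!r}→{target!r})"
            )
        if edge_type == EDGE_PPI and (st != NODE_PROTEIN or tt != NODE_PROTEIN):
            raise GraphError(
                f"{loc}ppi must connect proteins, got {st}→{tt} "
                f"({source!r}→{target!r})"
            )

    # -- queries ----------------------------------------------------------
    def node_type(self, node_id: str) -> str:
        try:
            return self.g.nodes[node_id]["node_type"]
        except KeyError as exc:
            raise GraphError(f"unknown node {node_id!r}") from exc

    def nodes(self) -> list[tuple[str, str]]:
        return sorted((n, d["node_type"]) for n, d in self.g.nodes(data=True))

    def edges(self) -> list[tuple[str, str, str, str]]:
        """Sorted (source, target, edge_type, sign) tuples (multiset view)."""
        return sorted(
            (u, v, d["edge_type"], d["sign"]) for u, v, d in self.g.edges(data=True)
        )

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def out_edges(self, node_id: str) -> Iterator[tuple[str, str, str]]:
        """(target, edge_type, sign) for each outgoing edge."""
        for _, v, d in self.g.out_edges(node_id, data=True):
            yield v, d["edge_type"], d["sign"]

    def has_node(self, node_id: str) -> bool:
        return node_id in self.g

    def validate(self) -> None:
        for u, v, d in self.g.edges(data=True):
            self._check_edge(u, v, d["edge_type"], d.get("sign", "unknown"), None)

    def copy(self) -> "KnowledgeGraph":
        return KnowledgeGraph(self.g.copy())


# -- readers / writers -----------------------------------------------------

def read_graph(path: str | Path, format: str | None = None) -> KnowledgeGraph:
    """Read a knowledge graph (``edge_tsv``, ``sif`` or ``graphml``).

    Invariant violations are reported with the offending line number.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "edge_tsv":
        return _read_edge_tsv(path)
    if fmt == "sif":
        return _read_sif(path)
    if fmt == "graphml":
        return _read_graphml(path)
    raise GraphError(f"unsupported graph format {fmt!r}")


def write_graph(
    graph: KnowledgeGraph, path: str | Path, format: str | None = None
) -> Path:
    """Write a graph with deterministic (lexicographic) ordering."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "edge_tsv":
        _write_edge_tsv(graph, path)
    elif fmt == "sif":
        _write_sif(graph, path)
    elif fmt == "graphml":
        _write_graphml(graph, path)
    else:
        raise GraphError(f"unsupported graph format {fmt!r}")
    return path


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    return {".tsv": "edge_tsv", ".sif": "sif", ".graphml": "graphml"}.get(
        suffix, "edge_tsv"
    )


def _read_edge_tsv(path: Path) -> KnowledgeGraph:
    kg = KnowledgeGraph()
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != EDGE_TSV_HEADER:
            raise GraphError(
                f"{path}:1: expected header {EDGE_TSV_HEADER}, got {tuple(header)}"
            )
        declared: list[tuple[int, str, str]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if line.startswith("#node\t"):
                parts = line.split("\t")
                if len(parts) != 3:
                    raise GraphError(
                        f"{path}:{lineno}: #node line needs id and type"
                    )
                declared.append((lineno, parts[1], parts[2]))
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise GraphError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            rows.append((lineno, parts))
    for lineno, nid, ntype in declared:
        if ntype not in NODE_TYPES:
            raise GraphError(f"{path}:{lineno}: unknown node type {ntype!r}")
        kg.add_node(nid, ntype)
    # declare nodes first so endpoint checks see both ends
    for lineno, (s, st, et, sign, t, tt) in rows:
        where = f"{path}:{lineno}"
        for nid, ntype in ((s, st), (t, tt)):
            if ntype not in NODE_TYPES:
                raise GraphError(f"{where}: unknown node type {ntype!r} for {nid!r}")
            try:
                kg.add_node(nid, ntype)
            except GraphError as exc:
                raise GraphError(f"{where}: {exc}") from None
    for lineno, (s, st, et, sign, t, tt) in rows:
        kg._check_edge(s, t, et, sign, where=f"{path}:{lineno}")
        kg.g.add_edge(s, t, edge_type=et, sign=sign)
    return kg


def _write_edge_tsv(kg: KnowledgeGraph, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(EDGE_TSV_HEADER) + "\n")
        # isolated nodes have no edge row; persist them as declarations
        for n, t in kg.nodes():
            if kg.g.degree(n) == 0:
                fh.write(f"#node\t{n}\t{t}\n")
        for u, v, et, sign in kg.edges():
            fh.write(
                "\t".join((u, kg.node_type(u), et, sign, v, kg.node_type(v))) + "\n"
            )


def _nodes_sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".nodes.tsv")


def _read_sif(path: Path) -> KnowledgeGraph:
    """SIF dialect: ``source<TAB>edge_type[.sign]<TAB>target`` per line.

    Node types come from the ``<path>.nodes.tsv`` sidecar (id<TAB>type);
    without a sidecar every node defaults to protein.
    """
    kg = KnowledgeGraph()
    sidecar = _nodes_sidecar(path)
    declared: dict[str, str] = {}
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise GraphError(f"{sidecar}:{lineno}: expected 2 columns")
                declared[parts[0]] = parts[1]
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise GraphError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            s, rel, t = parts
            et, _, sign = rel.partition(".")
            rows.append((lineno, s, et, sign or "unknown", t))
    for nid, ntype in declared.items():  # sidecar carries isolated nodes too
        kg.add_node(nid, ntype)
    for lineno, s, et, sign, t in rows:
        for nid in (s, t):
            kg.add_node(nid, declared.get(nid, NODE_PROTEIN))
    for lineno, s, et, sign, t in rows:
        kg._check_edge(s, t, et, sign, where=f"{path}:{lineno}")
        kg.g.add_edge(s, t, edge_type=et, sign=sign)
    return kg


def _write_sif(kg: KnowledgeGraph, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, et, sign in kg.edges():
            rel = et if sign == "unknown" else f"{et}.{sign}"
            fh.write(f"{u}\t{rel}\t{v}\n")
    with open(_nodes_sidecar(path), "w", encoding="utf-8") as fh:
        for n, t in kg.nodes():
            fh.write(f"{n}\t{t}\n")


def _read_graphml(path: Path) -> KnowledgeGraph:
    raw = nx.read_graphml(path, force_multigraph=True)
    kg = KnowledgeGraph()
    for n, d in raw.nodes(data=True):
        if "node_type" not in d:
            raise GraphError(f"{path}: node {n!r} lacks a node_type attribute")
        kg.add_node(str(n), d["node_type"])
    for u, v, d in raw.edges(data=True):
        if "edge_type" not in d:
            raise GraphError(f"{path}: edge {u!r}→{v!r} lacks an edge_type attribute")
        kg.add_edge(str(u), str(v), d["edge_type"], d.get("sign", "unknown"))
    return kg


def _write_graphml(kg: KnowledgeGraph, path: Path) -> None:
    ordered = nx.MultiDiGraph()
    for n, t in kg.nodes():
        ordered.add_node(n, node_type=t)
    for u, v, et, sign in kg.edges():
        ordered.add_edge(u, v, edge_type=et, sign=sign)
    nx.write_graphml(ordered, path)


# -- subgraph extraction ---------------------------------------------------

def subgraph_between(
    graph: KnowledgeGraph,
    sources: Iterable[str],
    targets: Iterable[str],
    max_len: int,
) -> KnowledgeGraph:
    """Induced subgraph on nodes lying on ≥1 simple source→target path.

    Paths are directed, simple, and of length ≤ ``max_len`` edges.  The
    result is the node-induced subgraph (all edges among retained nodes).
    """
    if max_len < 1:
        raise GraphError("max_len must be ≥ 1")
    sources = [s for s in sources if graph.has_node(s)]
    target_set = {t for t in targets if graph.has_node(t)}
    keep: set[str] = set()
    for s in sources:
        if not target_set:
            break
        for path in nx.all_simple_paths(graph.g, s, target_set, cutoff=max_len):
            keep.update(path)
    sub = KnowledgeGraph()
    for n in sorted(keep):
        sub.add_node(n, graph.node_type(n))
    for u, v, d in graph.g.edges(data=True):
        if u in keep and v in keep:
            sub.g.add_edge(u, v, edge_type=d["edge_type"], sign=d["sign"])
    return sub
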