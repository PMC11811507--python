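"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by brute force
(permutation enumeration for the rank tests, the raw step-up formula for
BH, exhaustive simple-path search for the template matcher) so they stay
independent of the implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from metaboreg.kgraph import KnowledgeGraph
from metaboreg.synthetic import GraphSimConfig, simulate_knowledge_graph

DIRECT = {
    "ppi",
    "activity_regulation",
    "degradation_regulation",
    "transport_regulation",
    "proteolysis_regulation",
    "catalysis_regulation",
}
INTER = DIRECT | {"expression_regulation"}


# -- statistical oracles ---------------------------------------------------

def mw_enumeration_oracle(x, y) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney p by full enumeration of assignments."""
    from scipy.stats import rankdata

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array(
        [
            ranks[list(c)].sum() - n1 * (n1 + 1) / 2
            for c in itertools.combinations(range(n), n1)
        ]
    )
    p = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
    return float(u_obs), float(p)


def ks_enumeration_oracle(x, y) -> tuple[float, float]:
    """Exact two-sided KS p by full enumeration of group assignments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    grid = np.sort(pooled)

    def d_of(xs, ys):
        cx = np.searchsorted(np.sort(xs), grid, side="right") / len(xs)
        cy = np.searchsorted(np.sort(ys), grid, side="right") / len(ys)
        return np.abs(cx - cy).max()

    d_obs = d_of(x, y)
    ds = []
    idx_all = set(range(n))
    for c in itertools.combinations(range(n), n1):
        rest = sorted(idx_all - set(c))
        ds.append(d_of(pooled[list(c)], pooled[rest]))
    ds = np.array(ds)
    p = float((ds >= d_obs - 1e-12).mean())
    return float(d_obs), p


def bh_formula_oracle(pvals) -> np.ndarray:
    """BH step-up adjusted p-values straight from the definition."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


# -- path-enumeration oracle ----------------------------------------------

def template_matches(tid: str, node_types, edge_types, max_intermediates: int) -> bool:
    """Literal transcription of the four default template definitions."""
    nt, et = tuple(node_types), tuple(edge_types)
    L = len(et)
    if nt[0] != "protein":
        return False
    if tid == "T1":
        return L == 1 and et[0] in DIRECT and nt == ("protein", "protein")
    if tid == "T2":
        return (
            L == 2
            and et == ("expression_regulation", "encodes")
            and nt == ("protein", "gene", "protein")
        )
    if tid == "T3":
        r = L - 1
        return (
            1 <= r <= max_intermediates
            and nt == ("protein",) * (L + 1)
            and all(e in INTER for e in et[:r])
            and et[-1] in DIRECT
        )
    if tid == "T4":
        r = L - 2
        return (
            1 <= r <= max_intermediates
            and nt == ("protein",) * (r + 1) + ("gene", "protein")
            and all(e in INTER for e in et[:r])
            and et[r] == "expression_regulation"
            and et[r + 1] == "encodes"
        )
    raise ValueError(tid)


def all_simple_typed_paths(graph: KnowledgeGraph, source: str, max_len: int):
    """All simple paths from ``source`` up to ``max_len`` edges, distinct by
    (node sequence, edge-type sequence)."""
    out = set()

    def dfs(node, nodes, ntypes, etypes):
        if len(etypes) >= 1:
            out.add((tuple(nodes), tuple(ntypes), tuple(etypes)))
        if len(etypes) == max_len:
            return
        seen_branch = set()
        for target, etype, _sign in graph.out_edges(node):
            if target in nodes or (target, etype) in seen_branch:
                continue
            seen_branch.add((target, etype))
            dfs(
                target,
                nodes + [target],
                ntypes + [graph.node_type(target)],
                etypes + [etype],
            )

    dfs(source, [source], [graph.node_type(source)], [])
    return out


def oracle_template_counts(
    graph: KnowledgeGraph, sources, targets, max_intermediates: int = 1
) -> dict[str, set]:
    """Brute-force enumeration + template filter, per default template id."""
    max_len = max_intermediates + 2
    targets = set(targets)
    found: dict[str, set] = {t: set() for t in ("T1", "T2", "T3", "T4")}
    for s in sources:
        if not graph.has_node(s) or graph.node_type(s) != "protein":
            continue
        for nodes, ntypes, etypes in all_simple_typed_paths(graph, s, max_len):
            if nodes[-1] not in targets:
                continue
            for tid in found:
                if template_matches(tid, ntypes, etypes, max_intermediates):
                    found[tid].add((nodes, etypes))
    return found


# -- fixtures --------------------------------------------------------------

@pytest.fixture
def tiny_graph() -> KnowledgeGraph:
    """Marker M, mediator X, enzyme E with its gene: one T4 instance."""
    kg = KnowledgeGraph()
    kg.add_node("M", "protein")
    kg.add_node("X", "protein")
    kg.add_node("E", "protein")
    kg.add_node("gE", "gene")
    kg.add_edge("M", "X", "ppi")
    kg.add_edge("X", "gE", "expression_regulation")
    kg.add_edge("gE", "E", "encodes")
    return kg


@pytest.fixture
def random_graph_factory():
    """Random typed graphs with a few planted paths, for oracle comparisons."""

    def make(seed: int, noise: float = 0.12) -> KnowledgeGraph:
        cfg = GraphSimConfig(
            n_marker_proteins=3,
            n_enzymes=2,
            n_intermediates=2,
            n_noise_nodes=1,
            planted_paths=(
                ("M00", "E00", "T1"),
                ("M01", "E01", "T2"),
                ("M02", "E00", "T3"),
            ),
            random_edge_prob=noise,
            seed=seed,
        )
        return simulate_knowledge_graph(cfg)

    return make


@pytest.fixture
def small_panel_frame() -> pd.DataFrame:
    """3-sample, 2-metabolite wide table in the canonical layout."""
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "group": ["PD", "VP", "control"],
            "Ala": [110.0, 95.0, 100.0],
            "C2": [1.5, 2.5, 2.0],
        }
    )
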