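"""Synthetic generators for every pipeline input.

These generators define the study conditions the pipeline is tested
under: a 44-metabolite targeted plasma panel (14 amino acids + 30
acylcarnitines) measured in two disease groups of 9 patients each and a
control group of 17, log-normal concentrations with planted group shifts;
gene-marker lists with a controlled overlap; and typed knowledge graphs
with planted template-conforming pathways plus random noise edges.

All randomness flows through explicit integer seeds; identical
configuration + seed yields bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .kgraph import (
    EDGE_ACTIVITY,
    EDGE_ENCODES,
    EDGE_EXPRESSION,
    EDGE_PPI,
    EDGE_TYPES,
    KnowledgeGraph,
    NODE_GENE,
    NODE_PROTEIN,
)
from .profiles import (
    CLASS_ACYLCARNITINE,
    CLASS_AMINO_ACID,
    GROUP_A,
    GROUP_B,
    GROUP_CONTROL,
    MetaboliteProfileSet,
)
from .templates import default_templates

#: 14 amino acids of the targeted HPLC-MS/MS panel.
AMINO_ACIDS = (
    "Ala", "Arg", "Asp", "Glu", "Gly", "Ile", "Leu",
    "Met", "Orn", "Phe", "Pro", "Thr", "Tyr", "Val",
)

#: 30 acylcarnitine species by acyl chain (C0 = free carnitine).
ACYLCARNITINES = (
    "C0", "C2", "C3", "C4", "C5", "C5:1", "C5DC", "C5OH", "C6", "C6DC",
    "C8", "C8:1", "C10", "C10:1", "C10:2", "C12", "C12:1", "C14", "C14:1",
    "C14:2", "C14OH", "C16", "C16:1", "C16OH", "C18", "C18:1", "C18:2",
    "C18OH", "C16:1OH", "C18:1OH",
)

PANEL_METABOLITES = AMINO_ACIDS + ACYLCARNITINES


@dataclass
class PanelSimConfig:
    """Configuration for a simulated concentration panel.

    Group sizes default to the two-disease-plus-control design (9, 9, 17).
    ``effect_metabolites_A``/``_B`` are indices into the metabolite list
    whose log-location is shifted by ``log_fold_shift`` in the respective
    disease group; ``cv`` is the shared log-scale standard deviation.
    """

    group_sizes: tuple[int, int, int] = (9, 9, 17)
    n_metabolites: int = 44
    n_amino_acids: int = 14
    effect_metabolites_A: frozenset[int] = frozenset()
    effect_metabolites_B: frozenset[int] = frozenset()
    log_fold_shift: float = 2.0
    cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.effect_metabolites_A = frozenset(self.effect_metabolites_A)
        self.effect_metabolites_B = frozenset(self.effect_metabolites_B)
        if len(self.group_sizes) != 3 or any(n < 2 for n in self.group_sizes):
            raise ConfigurationError(
                f"need 3 group sizes ≥ 2, got {self.group_sizes}"
            )
        if not 0 <= self.n_amino_acids <= self.n_metabolites:
            raise ConfigurationError(
                "need 0 ≤ n_amino_acids ≤ n_metabolites, got "
                f"{self.n_amino_acids}/{self.n_metabolites}"
            )
        if self.cv <= 0:
            raise ConfigurationError(f"cv must be > 0, got {self.cv}")
        for name, idx in (("A", self.effect_metabolites_A),
                          ("B", self.effect_metabolites_B)):
            bad = [i for i in idx if not 0 <= i < self.n_metabolites]
            if bad:
                raise ConfigurationError(
                    f"effect set {name} indices out of range: {sorted(bad)}"
                )

    def metabolite_ids(self) -> list[str]:
        """Panel metabolite names; generic ids beyond the standard panel."""
        ids: list[str] = []
        aa = [m for m in PANEL_METABOLITES[:14]]
        ac = [m for m in PANEL_METABOLITES[14:]]
        for i in range(self.n_amino_acids):
            ids.append(aa[i] if i < len(aa) else f"AA{i:02d}")
        for i in range(self.n_metabolites - self.n_amino_acids):
            ids.append(ac[i] if i < len(ac) else f"C{30 + i}x")
        return ids


def simulate_panel(config: PanelSimConfig) -> MetaboliteProfileSet:
    """Draw a log-normal concentration panel with planted group shifts.

    Per-metabolite baseline log-locations are drawn once (amino acids
    around 100 µM, acylcarnitines around 1 µM — the concentration scales
    typical of targeted plasma panels); every sample's concentration is
    log-normal around its group's location with log-sd ``cv``.
    """
    rng = np.random.default_rng(config.seed)
    mets = config.metabolite_ids()
    n_a, n_b, n_c = config.group_sizes
    classes = pd.Series(
        [CLASS_AMINO_ACID] * config.n_amino_acids
        + [CLASS_ACYLCARNITINE] * (config.n_metabolites - config.n_amino_acids),
        index=mets, name="class",
    )
    base_mu = np.where(
        classes.to_numpy() == CLASS_AMINO_ACID,
        rng.normal(np.log(100.0), 0.5, size=config.n_metabolites),
        rng.normal(np.log(1.0), 1.0, size=config.n_metabolites),
    )
    shift_a = np.zeros(config.n_metabolites)
    shift_b = np.zeros(config.n_metabolites)
    for i in config.effect_metabolites_A:
        shift_a[i] = config.log_fold_shift
    for i in config.effect_metabolites_B:
        shift_b[i] = config.log_fold_shift

    blocks = []
    sample_ids = []
    groups = []
    for group, n, shift in (
        (GROUP_A, n_a, shift_a),
        (GROUP_B, n_b, shift_b),
        (GROUP_CONTROL, n_c, np.zeros(config.n_metabolites)),
    ):
        z = rng.normal(size=(n, config.n_metabolites))
        blocks.append(np.exp(base_mu + shift + config.cv * z))
        sample_ids.extend(f"{group}_{i + 1:02d}" for i in range(n))
        groups.extend([group] * n)

    conc = pd.DataFrame(
        np.vstack(blocks), index=pd.Index(sample_ids, name="sample_id"),
        columns=mets,
    )
    return MetaboliteProfileSet(
        concentrations=conc,
        groups=pd.Series(groups, index=conc.index, name="group"),
        classes=classes,
    )


def study_panel_config(seed: int = 0, log_fold_shift: float = 2.0,
                       cv: float = 0.3) -> PanelSimConfig:
    """Panel configuration emulating the two-parkinsonism study outcome.

    Plants concentration shifts so that, at strong effect size, screening
    recovers 18 significant metabolites in disease A (5 amino acids —
    alanine, proline, isoleucine, valine, methionine — plus 13
    acylcarnitines), 21 in disease B (the same four shared amino acids,
    the 13 shared acylcarnitines, plus free carnitine C0, C6, C10 and
    C10:1), with 17 shared (4 amino acids + 13 acylcarnitines).
    """
    ids = list(PANEL_METABOLITES)
    shared_aa = ("Ala", "Pro", "Ile", "Val")
    shared_ac = ("C2", "C3", "C4", "C5", "C8", "C12", "C12:1", "C14",
                 "C14:1", "C16", "C16:1", "C18", "C18:1")
    a_only = ("Met",)
    b_only = ("C0", "C6", "C10", "C10:1")
    eff_a = frozenset(ids.index(m) for m in shared_aa + shared_ac + a_only)
    eff_b = frozenset(ids.index(m) for m in shared_aa + shared_ac + b_only)
    return PanelSimConfig(
        effect_metabolites_A=eff_a,
        effect_metabolites_B=eff_b,
        log_fold_shift=log_fold_shift,
        cv=cv,
        seed=seed,
    )


def simulate_marker_lists(
    nA: int, nB: int, n_shared: int, seed: int = 0,
    prefix: str = "GM",
) -> tuple[list[str], list[str]]:
    """Two gene-symbol lists with exactly ``n_shared`` common identifiers."""
    if n_shared > min(nA, nB):
        raise ConfigurationError(
            f"n_shared={n_shared} exceeds min(nA, nB)={min(nA, nB)}"
        )
    if nA < 1 or nB < 1 or n_shared < 0:
        raise ConfigurationError("marker list sizes must be positive")
    rng = np.random.default_rng(seed)
    total = nA + nB - n_shared
    pool = [f"{prefix}{i:04d}" for i in rng.permutation(10 * total)[:total]]
    shared = pool[:n_shared]
    a_only = pool[n_shared : n_shared + (nA - n_shared)]
    b_only = pool[n_shared + (nA - n_shared) :]
    listA = sorted(shared + a_only)
    listB = sorted(shared + b_only)
    return listA, listB


@dataclass
class GraphSimConfig:
    """Configuration for a simulated typed knowledge graph.

    ``planted_paths`` is a list of (marker id, enzyme id, template id)
    triples; each is realised as one exact instance of the named default
    template.  Noise edges are Erdős–Rényi with probability
    ``random_edge_prob`` per ordered node pair, typed uniformly at random
    among the kinds valid for the endpoint types, and never duplicate a
    planted (source, target, type) triple.
    """

    n_marker_proteins: int = 5
    n_enzymes: int = 3
    n_intermediates: int = 3
    n_noise_nodes: int = 0
    planted_paths: tuple[tuple[str, str, str], ...] = ()
    random_edge_prob: float = 0.0
    seed: int = 0
    max_intermediates: int = 1
    #: optional explicit node names (override the generic M##/E## scheme)
    marker_names: tuple[str, ...] | None = None
    enzyme_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.random_edge_prob <= 1.0:
            raise ConfigurationError(
                f"random_edge_prob must be in [0,1], got {self.random_edge_prob}"
            )
        for n in (self.n_marker_proteins, self.n_enzymes, self.n_intermediates,
                  self.n_noise_nodes):
            if n < 0:
                raise ConfigurationError("node counts must be ≥ 0")
        known = {t.id for t in default_templates(self.max_intermediates)}
        for m, e, tid in self.planted_paths:
            if tid not in known:
                raise ConfigurationError(
                    f"unknown template id {tid!r} in planted path; known: "
                    f"{sorted(known)}"
                )

    def marker_ids(self) -> list[str]:
        if self.marker_names is not None:
            return list(self.marker_names)
        return [f"M{i:02d}" for i in range(self.n_marker_proteins)]

    def enzyme_ids(self) -> list[str]:
        if self.enzyme_names is not None:
            return list(self.enzyme_names)
        return [f"E{i:02d}" for i in range(self.n_enzymes)]


def study_graph_config(
    marker_ids: Sequence[str],
    enzyme_ids: Sequence[str],
    seed: int = 0,
    mean_paths_per_enzyme: float = 3.0,
    random_edge_prob: float = 0.0,
    n_noise_nodes: int = 10,
) -> GraphSimConfig:
    """Graph configuration wiring real marker symbols to real enzyme ids.

    For each enzyme a Poisson(``mean_paths_per_enzyme``) number of
    regulatory pathways is planted from markers drawn uniformly, with the
    template cycling over the four defaults — a sparse stand-in for a
    literature-derived interaction network around the panel's enzymes.
    """
    rng = np.random.default_rng(seed)
    markers = sorted(set(marker_ids))
    enzymes = sorted(set(enzyme_ids))
    template_ids = ("T1", "T2", "T3", "T4")
    planted: list[tuple[str, str, str]] = []
    used: set[tuple[str, str, str]] = set()
    k = 0
    for enzyme in enzymes:
        n_paths = max(1, int(rng.poisson(mean_paths_per_enzyme)))
        for _ in range(n_paths):
            marker = markers[int(rng.integers(len(markers)))]
            triple = (marker, enzyme, template_ids[k % 4])
            k += 1
            if triple in used:
                continue
            used.add(triple)
            planted.append(triple)
    return GraphSimConfig(
        n_marker_proteins=len(markers),
        n_enzymes=len(enzymes),
        n_intermediates=0,
        n_noise_nodes=n_noise_nodes,
        planted_paths=tuple(planted),
        random_edge_prob=random_edge_prob,
        seed=seed,
        marker_names=tuple(markers),
        enzyme_names=tuple(enzymes),
    )


def simulate_knowledge_graph(config: GraphSimConfig) -> KnowledgeGraph:
    """Build a typed graph containing every planted path exactly once.

    Planted template instances use dedicated intermediate nodes (one per
    planted T3/T4 path), so in a noise-free graph each planted triple is
    matched by exactly one enumerated path of its template.
    """
    rng = np.random.default_rng(config.seed)
    kg = KnowledgeGraph()
    markers = config.marker_ids()
    enzymes = config.enzyme_ids()
    triples: set[tuple[str, str, str]] = set()
    for m in markers:
        kg.add_node(m, NODE_PROTEIN)
    for e in enzymes:
        kg.add_node(e, NODE_PROTEIN)
        kg.add_node(_gene_of(e), NODE_GENE)
        _plant(kg, triples, _gene_of(e), e, EDGE_ENCODES)
    for i in range(config.n_intermediates):
        kg.add_node(f"X{i:02d}", NODE_PROTEIN)
    for i in range(config.n_noise_nodes):
        kg.add_node(f"N{i:02d}", NODE_PROTEIN)

    plant_counter = 0
    for marker, enzyme, tid in config.planted_paths:
        for nid in (marker, enzyme):
            if not kg.has_node(nid):
                raise ConfigurationError(
                    f"planted path endpoint {nid!r} not among generated nodes"
                )
        gene = _gene_of(enzyme)
        if tid == "T1":
            _plant(kg, triples, marker, enzyme, EDGE_ACTIVITY)
        elif tid == "T2":
            _plant(kg, triples, marker, gene, EDGE_EXPRESSION)
        elif tid in ("T3", "T4"):
            inter = f"P{plant_counter:02d}"  # dedicated mediator per planted path
            plant_counter += 1
            kg.add_node(inter, NODE_PROTEIN)
            _plant(kg, triples, marker, inter, EDGE_PPI)
            _plant(kg, triples, inter, marker, EDGE_PPI)  # PPI is symmetric
            if tid == "T3":
                _plant(kg, triples, inter, enzyme, EDGE_ACTIVITY)
            else:
                _plant(kg, triples, inter, gene, EDGE_EXPRESSION)
        # the gene→enzyme encodes edge for T2/T4 already exists

    if config.random_edge_prob > 0:
        node_ids = sorted(n for n, _ in kg.nodes())
        for u in node_ids:
            for v in node_ids:
                if u == v:
                    continue
                if rng.random() >= config.random_edge_prob:
                    continue
                valid = _valid_edge_types(kg.node_type(u), kg.node_type(v))
                if not valid:
                    continue
                etype = valid[int(rng.integers(len(valid)))]
                if etype == EDGE_ENCODES:
                    continue  # one encodes link per gene keeps genes unambiguous
                _plant(kg, triples, u, v, etype)
                if etype == EDGE_PPI:
                    _plant(kg, triples, v, u, etype)
    return kg


def _gene_of(enzyme_id: str) -> str:
    return f"{enzyme_id}_gene"


def _plant(kg: KnowledgeGraph, triples: set, u: str, v: str, etype: str) -> None:
    if (u, v, etype) not in triples:
        kg.add_edge(u, v, etype)
        triples.add((u, v, etype))


def _valid_edge_types(source_type: str, target_type: str) -> list[str]:
    out = []
    for et in sorted(EDGE_TYPES):
        if et == EDGE_EXPRESSION and target_type != NODE_GENE:
            continue
        if et == EDGE_ENCODES and not (
            source_type == NODE_GENE and target_type == NODE_PROTEIN
        ):
            continue
        if et == EDGE_PPI and not (
            source_type == NODE_PROTEIN and target_type == NODE_PROTEIN
        ):
            continue
        if source_type == NODE_GENE and et != EDGE_ENCODES:
            continue  # genes act only through their product
        out.append(et)
    return out
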