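"""Shared fixtures: an embryo-stage chain ontology and random-graph builders."""

from __future__ import annotations

import numpy as np
import pytest

from stagecomp.ontology import StageGraph, TermRecord, parse_obo

# A synthetic-shaped ontology fixture mirroring the embryo development chain:
# zygote -> proembryo -> globular -> bilateral, which then branches into the
# dicot cotyledonary -> mature path and the monocot coleoptilar -> true-leaf
# path.  Stored with preceded_by edges only; the parser completes inverses.
EMBRYO_CHAIN_OBO = """\
format-version: 1.2
ontology: embryo-chain-fixture

[Term]
id: PO:0009998
name: sporophyte vegetative stage

[Term]
id: PO:0009999
name: plant embryo development stage
is_a: PO:0009998

[Term]
id: PO:0009997
name: plant zygote stage

[Term]
id: PO:0001180
name: plant proembryo stage
is_a: PO:0009999
relationship: preceded_by PO:0009997

[Term]
id: PO:0001185
name: plant embryo globular stage
is_a: PO:0009999
relationship: preceded_by PO:0001180

[Term]
id: PO:0004507
name: plant embryo bilateral stage
is_a: PO:0009999
relationship: preceded_by PO:0001185

[Term]
id: PO:0001078
name: plant embryo cotyledonary stage
is_a: PO:0009999
relationship: preceded_by PO:0004507

[Term]
id: PO:0001094
name: plant embryo coleoptilar stage
is_a: PO:0009999
relationship: preceded_by PO:0004507

[Term]
id: PO:0001081
name: mature plant embryo stage
is_a: PO:0009999
relationship: preceded_by PO:0001078

[Term]
id: PO:0001095
name: plant embryo true leaf formation stage
is_a: PO:0009999
relationship: preceded_by PO:0001094
"""

ZYGOTE = "PO:0009997"
PROEMBRYO = "PO:0001180"
GLOBULAR = "PO:0001185"
BILATERAL = "PO:0004507"
COTYLEDONARY = "PO:0001078"
COLEOPTILAR = "PO:0001094"
MATURE = "PO:0001081"
TRUE_LEAF = "PO:0001095"
EMBRYO_PARENT = "PO:0009999"


@pytest.fixture
def embryo_graph() -> StageGraph:
    return parse_obo(EMBRYO_CHAIN_OBO)


def random_stage_graph(
    rng: np.random.Generator,
    n_terms: int = 30,
    edge_prob: float = 0.12,
    predicates: tuple[str, ...] = ("is_a", "precedes"),
    with_extras: bool = False,
) -> StageGraph:
    """Random acyclic typed graph: edges only from lower to higher term index.

    With ``with_extras`` the terms additionally get synonyms, namespaces,
    obsolete flags, and some unknown-predicate edges (for round-trip tests).
    """
    graph = StageGraph()
    ids = [f"RG:{i:07d}" for i in range(n_terms)]
    for i, tid in enumerate(ids):
        term = TermRecord(tid, name=f"random term {i}")
        if with_extras:
            if rng.random() < 0.3:
                term.synonyms = [f"syn {i} a", f"syn {i} b"][: int(rng.integers(1, 3))]
            if rng.random() < 0.3:
                term.namespace = "stage_fixture"
            if rng.random() < 0.1:
                term.is_obsolete = True
        graph.add_term(term)
    preds = list(predicates) + (["regulates"] if with_extras else [])
    for i in range(n_terms):
        for j in range(i + 1, n_terms):
            if rng.random() < edge_prob:
                graph.add_edge(ids[i], str(rng.choice(preds)), ids[j])
    graph.complete_inverses()
    return graph


def closure_oracle(graph: StageGraph, start: str, predicates: set[str]) -> set[str]:
    """Reachability by exhaustive path extension — independent of the BFS impl."""
    reached: set[str] = set()
    frontier = {start}
    while frontier:
        nxt: set[str] = set()
        for node in frontier:
            for edge in graph.edges:
                if edge.subject == node and edge.predicate in predicates:
                    if edge.object not in reached and edge.object != start:
                        nxt.add(edge.object)
        reached |= nxt
        frontier = nxt
    return reached
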