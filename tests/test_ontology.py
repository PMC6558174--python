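"""Stage-ontology parsing, typed-relation reasoning, and validation."""

import numpy as np
import pytest

from stagecomp.ontology import (
    DuplicateTermError,
    OboParseError,
    OrderingCycleError,
    StageGraph,
    TermRecord,
    UnknownTermError,
    ancestors,
    infer_stage_structure_links,
    parse_obo,
    preceded_by_closure,
    temporal_sort,
    validate,
    write_obo,
)

from .conftest import (
    BILATERAL,
    EMBRYO_CHAIN_OBO,
    EMBRYO_PARENT,
    GLOBULAR,
    PROEMBRYO,
    ZYGOTE,
    closure_oracle,
    random_stage_graph,
)

SUBCLASS_PAIR_OBO = """\
format-version: 1.2

[Term]
id: PO:0009998
name: sporophyte vegetative stage

[Term]
id: PO:0009999
name: plant embryo development stage
is_a: PO:0009998
"""


class TestParseObo:
    def test_subclass_stanza_pair_yields_one_is_a_edge(self):
        graph = parse_obo(SUBCLASS_PAIR_OBO)
        assert len(graph.terms) == 2
        assert [(e.subject, e.predicate, e.object) for e in graph.edges] == [
            ("PO:0009999", "is_a", "PO:0009998")
        ]
        assert graph.terms["PO:0009999"].name == "plant embryo development stage"

    def test_empty_stream_gives_empty_graph(self):
        graph = parse_obo("")
        assert len(graph.terms) == 0 and len(graph.edges) == 0

    def test_stanza_without_id_reports_line_number(self):
        bad = "[Term]\nname: orphan stanza\n"
        with pytest.raises(OboParseError, match="line 1"):
            parse_obo(bad)

    def test_duplicate_id_names_the_term(self):
        dup = "[Term]\nid: PO:0000001\n\n[Term]\nid: PO:0000001\n"
        with pytest.raises(DuplicateTermError, match="PO:0000001"):
            parse_obo(dup)

    def test_inverse_precedes_edges_completed(self):
        graph = parse_obo(EMBRYO_CHAIN_OBO)
        # stored as preceded_by only; precedes must have been materialized
        assert GLOBULAR in graph.out_neighbors(PROEMBRYO, ["precedes"])
        assert PROEMBRYO in graph.out_neighbors(GLOBULAR, ["preceded_by"])

    def test_unknown_predicates_preserved_but_not_reasoned(self):
        text = SUBCLASS_PAIR_OBO + "relationship: regulates PO:0009998\n"
        graph = parse_obo(text)
        assert any(e.predicate == "regulates" for e in graph.edges)
        with pytest.raises(ValueError):
            ancestors(graph, "PO:0009999", {"regulates"})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_write_parse_round_trip_on_random_fixture(self, seed):
        rng = np.random.default_rng(seed)
        graph = random_stage_graph(rng, n_terms=50, with_extras=True)
        reparsed = parse_obo(write_obo(graph))
        assert reparsed.same_structure(graph)
        # twice through the writer is a fixed point
        assert parse_obo(write_obo(reparsed)).same_structure(graph)


class TestAncestors:
    def test_subclass_chain_from_nested_hierarchy(self):
        text = """\
[Term]
id: PO:0025527
name: shoot system development stage

[Term]
id: PO:0025530
name: reproductive shoot system development stage
is_a: PO:0025527

[Term]
id: PO:0007615
name: flower development stage
is_a: PO:0025530
"""
        graph = parse_obo(text)
        assert ancestors(graph, "PO:0007615", {"is_a"}) >= {
            "PO:0025530",
            "PO:0025527",
        }

    def test_root_has_no_ancestors(self, embryo_graph):
        assert ancestors(embryo_graph, "PO:0009998", {"is_a"}) == set()

    def test_unknown_term_raises(self, embryo_graph):
        with pytest.raises(UnknownTermError):
            ancestors(embryo_graph, "PO:9999999", {"is_a"})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reachability_oracle_on_random_dags(self, seed):
        rng = np.random.default_rng(100 + seed)
        graph = random_stage_graph(rng, n_terms=30, predicates=("is_a", "part_of"))
        for tid in graph.terms:
            for preds in ({"is_a"}, {"is_a", "part_of"}):
                assert ancestors(graph, tid, preds) == closure_oracle(
                    graph, tid, preds
                )

    def test_monotone_under_edge_addition(self):
        rng = np.random.default_rng(7)
        graph = random_stage_graph(rng, n_terms=20, predicates=("is_a",))
        before = {t: ancestors(graph, t, {"is_a"}) for t in graph.terms}
        ids = sorted(graph.terms)
        graph.add_edge(ids[3], "is_a", ids[15])  # forward edge keeps acyclicity
        after = {t: ancestors(graph, t, {"is_a"}) for t in graph.terms}
        assert all(after[t] >= before[t] for t in graph.terms)

    def test_obsolete_terms_excluded_from_closures(self):
        graph = StageGraph()
        for tid, obs in [("RG:0000001", False), ("RG:0000002", True), ("RG:0000003", False)]:
            graph.add_term(TermRecord(tid, is_obsolete=obs))
        graph.add_edge("RG:0000001", "is_a", "RG:0000002")
        graph.add_edge("RG:0000002", "is_a", "RG:0000003")
        assert ancestors(graph, "RG:0000001", {"is_a"}) == set()


class TestPrecededByClosure:
    def test_embryo_chain_reaches_zygote(self, embryo_graph):
        assert preceded_by_closure(embryo_graph, BILATERAL) >= {
            GLOBULAR,
            PROEMBRYO,
            ZYGOTE,
        }

    def test_first_stage_has_empty_closure(self, embryo_graph):
        assert preceded_by_closure(embryo_graph, ZYGOTE) == set()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bfs_oracle_on_chains_with_shortcuts(self, seed):
        rng = np.random.default_rng(200 + seed)
        graph = random_stage_graph(rng, n_terms=25, predicates=("precedes",))
        for tid in graph.terms:
            assert preceded_by_closure(graph, tid) == closure_oracle(
                graph, tid, {"preceded_by"}
            )

    @pytest.mark.parametrize("seed", range(3))
    def test_duality_with_precedes_closure(self, seed):
        rng = np.random.default_rng(300 + seed)
        graph = random_stage_graph(rng, n_terms=20, predicates=("precedes",))
        for a in graph.terms:
            for b in closure_oracle(graph, a, {"preceded_by"}):
                assert a in closure_oracle(graph, b, {"precedes"})


class TestTemporalSort:
    def test_embryo_chain_subset_ordered(self, embryo_graph):
        got = temporal_sort(embryo_graph, [BILATERAL, PROEMBRYO, GLOBULAR])
        assert got == [PROEMBRYO, GLOBULAR, BILATERAL]

    def test_single_term(self, embryo_graph):
        assert temporal_sort(embryo_graph, [GLOBULAR]) == [GLOBULAR]

    def test_unrelated_terms_keep_input_order(self, embryo_graph):
        # cotyledonary/coleoptilar are parallel branches with no mutual order
        for perm in (["PO:0001078", "PO:0001094"], ["PO:0001094", "PO:0001078"]):
            assert temporal_sort(embryo_graph, perm) == perm

    @pytest.mark.parametrize("seed", range(5))
    def test_pairwise_constraints_and_idempotence(self, seed):
        rng = np.random.default_rng(400 + seed)
        graph = random_stage_graph(rng, n_terms=20, predicates=("precedes",))
        terms = list(graph.terms)
        rng.shuffle(terms)
        ordered = temporal_sort(graph, terms)
        assert sorted(ordered) == sorted(terms)
        pos = {t: i for i, t in enumerate(ordered)}
        for a in terms:
            for b in closure_oracle(graph, a, {"precedes"}):
                assert pos[a] < pos[b]
        assert temporal_sort(graph, ordered) == ordered

    def test_cycle_raises_naming_members(self):
        graph = StageGraph()
        for tid in ("RG:0000001", "RG:0000002"):
            graph.add_term(TermRecord(tid))
        graph.add_edge("RG:0000001", "precedes", "RG:0000002")
        graph.add_edge("RG:0000002", "precedes", "RG:0000001")
        with pytest.raises(OrderingCycleError, match="RG:0000001"):
            temporal_sort(graph, ["RG:0000001", "RG:0000002"])


class TestStageStructureInference:
    def _participation_graph(self):
        graph = StageGraph()
        for tid, name in [
            ("PO:0000010", "protonema"),
            ("PO:0000020", "gametophyte development stage"),
            ("PO:0000030", "plant spore development stage"),
            ("PO:0000040", "plant spore"),
        ]:
            graph.add_term(TermRecord(tid, name=name))
        graph.add_edge("PO:0000010", "participates_in", "PO:0000020")
        graph.add_edge("PO:0000030", "has_participant", "PO:0000040")
        return graph

    def test_every_some_rule_is_direction_asymmetric(self):
        graph = self._participation_graph()
        # annotated to the structure -> inferred to the stage it participates in
        got = infer_stage_structure_links(graph, [("gene1", "PO:0000010")])
        assert got == [("gene1", "PO:0000020", "PO:0000010 participates_in PO:0000020")]
        # annotated to the stage -> NO converse inference to the structure
        assert infer_stage_structure_links(graph, [("gene2", "PO:0000020")]) == []

    def test_has_participant_infers_structure(self):
        graph = self._participation_graph()
        got = infer_stage_structure_links(graph, [("gene3", "PO:0000030")])
        assert got == [("gene3", "PO:0000040", "PO:0000030 has_participant PO:0000040")]

    def test_no_participation_edges_no_inferences(self, embryo_graph):
        assoc = [("g", GLOBULAR), ("h", EMBRYO_PARENT)]
        assert infer_stage_structure_links(embryo_graph, assoc) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_one_hop_closure_equals_edge_scan_oracle(self, seed):
        rng = np.random.default_rng(500 + seed)
        graph = random_stage_graph(
            rng, n_terms=20, predicates=("participates_in", "has_participant")
        )
        assoc = [(f"g{i}", tid) for i, tid in enumerate(graph.terms)]
        expected = sorted(
            (entity, e.object, f"{e.subject} {e.predicate} {e.object}")
            for entity, term in assoc
            for e in graph.edges
            if e.subject == term
            and e.predicate in ("participates_in", "has_participant")
        )
        assert sorted(infer_stage_structure_links(graph, assoc)) == expected


class TestValidate:
    def test_acyclic_fixture_is_clean(self, embryo_graph):
        assert not validate(embryo_graph).issues

    def test_precedes_cycle_reported(self):
        graph = StageGraph()
        for tid in ("RG:0000001", "RG:0000002"):
            graph.add_term(TermRecord(tid))
        graph.add_edge("RG:0000001", "precedes", "RG:0000002")
        graph.add_edge("RG:0000002", "precedes", "RG:0000001")
        graph.complete_inverses()
        report = validate(graph)
        assert report.count("precedes_cycle") == 1

    def test_dangling_and_self_edges_reported(self):
        graph = StageGraph()
        graph.add_term(TermRecord("RG:0000001"))
        graph.add_edge("RG:0000001", "is_a", "RG:0000099")  # object missing
        graph.add_edge("RG:0000001", "part_of", "RG:0000001")
        report = validate(graph)
        assert report.count("dangling_endpoint") == 1
        assert report.count("self_edge") == 1

    def test_missing_inverse_reported_before_completion(self):
        graph = StageGraph()
        for tid in ("RG:0000001", "RG:0000002"):
            graph.add_term(TermRecord(tid))
        graph.add_edge("RG:0000001", "precedes", "RG:0000002")
        assert validate(graph).count("missing_inverse") == 1
        graph.complete_inverses()
        assert validate(graph).count("missing_inverse") == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_cycle_counts_match_scc_oracle(self, seed):
        rng = np.random.default_rng(600 + seed)
        graph = random_stage_graph(rng, n_terms=30, predicates=("is_a",))
        ids = sorted(graph.terms)
        # force some back-edges to create cycles
        for _ in range(4):
            i, j = rng.integers(0, len(ids), size=2)
            if i != j:
                graph.add_edge(ids[max(i, j)], "is_a", ids[min(i, j)])
        import networkx as nx

        nontrivial = sum(
            1
            for c in nx.strongly_connected_components(graph.predicate_subgraph("is_a"))
            if len(c) > 1
        )
        assert validate(graph).count("is_a_cycle") == nontrivial

    def test_report_tsv_shape(self):
        graph = StageGraph()
        graph.add_term(TermRecord("RG:0000001"))
        graph.add_edge("RG:0000001", "is_a", "RG:0000099")
        lines = validate(graph).to_tsv().strip().splitlines()
        assert lines[0] == "issue_type\tsubject\tobject\tdetail"
        assert len(lines) == 2


def test_obonet_agrees_on_terms_and_is_a_edges(embryo_graph):
    """Independent parser cross-check on the embryo fixture."""
    obonet = pytest.importorskip("obonet")
    import io

    net = obonet.read_obo(io.StringIO(EMBRYO_CHAIN_OBO))
    assert set(net.nodes) == set(embryo_graph.terms)
    ours = {
        (e.subject, e.object) for e in embryo_graph.edges if e.predicate == "is_a"
    }
    theirs = {
        (u, v) for u, v, k in net.edges(keys=True) if k == "is_a"
    }
    assert ours == theirs
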