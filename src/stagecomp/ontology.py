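"""Development-stage ontology as a typed relation graph.

The stage branch of a plant ontology is a set of terms (time intervals in the
life of a plant or plant part) connected by a small vocabulary of typed
relations:

* ``is_a`` — the primary subclass hierarchy (shorter stages under longer ones);
* ``part_of`` — a stage of one structure within a stage of a containing
  structure;
* ``precedes`` / ``preceded_by`` — temporal order: the end of one stage is at
  or before the start of another.  Both are transitive and mutually inverse;
* ``has_participant`` / ``participates_in`` — links between a stage and the
  structure that develops during it, read under the every/some rule: every
  instance of the subject stands in the relation to *some* instance of the
  object, not conversely.

This module parses the OBO flat-file serialization of such an ontology into a
:class:`StageGraph`, materializes ``precedes``/``preceded_by`` as mutual
inverses, and provides the reasoning primitives the comparison workflow needs:
transitive closures over chosen predicates, temporal ordering of stage lists,
one-hop stage/structure inference, and structural validation.
"""

from __future__ import annotations

import io
import re
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

__all__ = [
    "CURIE_RE",
    "REASONING_PREDICATES",
    "CLOSURE_PREDICATES",
    "TermRecord",
    "RelationEdge",
    "StageGraph",
    "OboParseError",
    "DuplicateTermError",
    "UnknownTermError",
    "OrderingCycleError",
    "ValidationIssue",
    "ValidationReport",
    "parse_obo",
    "write_obo",
    "ancestors",
    "descendants",
    "preceded_by_closure",
    "temporal_sort",
    "infer_stage_structure_links",
    "validate",
]

#: CURIE pattern for term identifiers: prefix, colon, exactly seven digits.
CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*:\d{7}$")

#: The six predicates with defined semantics.  Anything else found in an OBO
#: file is preserved on the graph but excluded from reasoning.
REASONING_PREDICATES = frozenset(
    {"is_a", "part_of", "precedes", "preceded_by", "has_participant", "participates_in"}
)

#: Predicates over which transitive closure (``ancestors``) is meaningful.
CLOSURE_PREDICATES = frozenset({"is_a", "part_of", "precedes", "preceded_by"})

_INVERSE = {"precedes": "preceded_by", "preceded_by": "precedes"}


class OboParseError(ValueError):
    """Malformed OBO input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class DuplicateTermError(OboParseError):
    pass


class UnknownTermError(KeyError):
    """A term id was looked up that is not in the graph."""


class OrderingCycleError(ValueError):
    """Temporal sort requested on terms that form a precedes cycle."""

    def __init__(self, cycle: Sequence[str]):
        super().__init__("precedes cycle among input terms: " + " -> ".join(cycle))
        self.cycle = list(cycle)


@dataclass
class TermRecord:
    id: str
    name: str = ""
    namespace: str = ""
    synonyms: list[str] = field(default_factory=list)
    is_obsolete: bool = False


@dataclass(frozen=True)
class RelationEdge:
    subject: str
    predicate: str
    object: str


@dataclass
class StageGraph:
    """Terms plus typed edges, with per-predicate adjacency indices.

    Adjacency is kept in both directions (``_out``/``_in``) so closures and
    validation never scan the full edge list.
    """

    terms: dict[str, TermRecord] = field(default_factory=dict)
    edges: list[RelationEdge] = field(default_factory=list)
    header: str = ""
    _out: dict[str, dict[str, set[str]]] = field(default_factory=dict, repr=False)
    _in: dict[str, dict[str, set[str]]] = field(default_factory=dict, repr=False)

    # -- construction -----------------------------------------------------
    def add_term(self, term: TermRecord) -> None:
        if term.id in self.terms:
            raise ValueError(f"duplicate term id {term.id!r}")
        self.terms[term.id] = term

    def add_edge(self, subject: str, predicate: str, obj: str) -> None:
        # self-edges are storable so that validate() can report them
        edge = RelationEdge(subject, predicate, obj)
        self.edges.append(edge)
        self._out.setdefault(predicate, {}).setdefault(subject, set()).add(obj)
        self._in.setdefault(predicate, {}).setdefault(obj, set()).add(subject)

    def complete_inverses(self) -> int:
        """Materialize missing precedes/preceded_by inverse edges; return count added."""
        added = 0
        for pred, inv in _INVERSE.items():
            for edge in [e for e in self.edges if e.predicate == pred]:
                if edge.subject not in self._out.get(inv, {}).get(edge.object, set()):
                    self.add_edge(edge.object, inv, edge.subject)
                    added += 1
        return added

    # -- queries ----------------------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def require(self, term_id: str) -> TermRecord:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    def out_neighbors(self, term_id: str, predicates: Iterable[str]) -> set[str]:
        found: set[str] = set()
        for pred in predicates:
            found |= self._out.get(pred, {}).get(term_id, set())
        return found

    def in_neighbors(self, term_id: str, predicates: Iterable[str]) -> set[str]:
        found: set[str] = set()
        for pred in predicates:
            found |= self._in.get(pred, {}).get(term_id, set())
        return found

    def edge_multiset(self) -> Counter:
        return Counter(self.edges)

    def predicate_subgraph(self, predicate: str) -> nx.DiGraph:
        """Directed subject→object graph restricted to one predicate."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(
            (e.subject, e.object) for e in self.edges if e.predicate == predicate
        )
        return g

    def same_structure(self, other: "StageGraph") -> bool:
        """Equality on terms (all fields) and the edge multiset; header ignored."""
        if set(self.terms) != set(other.terms):
            return False
        for tid, term in self.terms.items():
            o = other.terms[tid]
            if (term.name, term.namespace, sorted(term.synonyms), term.is_obsolete) != (
                o.name,
                o.namespace,
                sorted(o.synonyms),
                o.is_obsolete,
            ):
                return False
        return self.edge_multiset() == other.edge_multiset()


# ---------------------------------------------------------------------------
# OBO flat-file I/O
# ---------------------------------------------------------------------------

_SYNONYM_RE = re.compile(r'^"(.*)"')


def parse_obo(stream) -> StageGraph:
    """Parse OBO 1.2/1.4 flat text into a :class:`StageGraph`.

    Only ``[Term]`` stanzas are interpreted; the header (everything before the
    first stanza) is preserved verbatim for round-trip writing, and other
    stanza kinds (``[Typedef]`` ...) are skipped.  Relationship predicates
    outside :data:`REASONING_PREDICATES` are stored on the graph but ignored
    by every reasoning operation.  ``precedes``/``preceded_by`` inverses are
    completed after parsing.

    Raises :class:`OboParseError` (with line number) for a stanza missing its
    ``id:`` line and :class:`DuplicateTermError` for a repeated term id.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    header_lines: list[str] = []
    graph = StageGraph()
    pending_edges: list[tuple[str, str, str]] = []

    in_header = True
    stanza_type: str | None = None
    stanza_start = 0
    current: dict | None = None

    def flush(line_no: int) -> None:
        nonlocal current
        if stanza_type != "Term" or current is None:
            current = None
            return
        if current["id"] is None:
            raise OboParseError("[Term] stanza without an id: line", stanza_start)
        tid = current["id"]
        if tid in graph.terms:
            raise DuplicateTermError(f"duplicate term id {tid!r}", line_no)
        graph.add_term(
            TermRecord(
                id=tid,
                name=current["name"],
                namespace=current["namespace"],
                synonyms=current["synonyms"],
                is_obsolete=current["is_obsolete"],
            )
        )
        pending_edges.extend((tid, pred, obj) for pred, obj in current["relations"])
        current = None

    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if stripped.startswith("[") and stripped.endswith("]"):
            flush(line_no)
            in_header = False
            stanza_type = stripped[1:-1]
            stanza_start = line_no
            current = (
                {
                    "id": None,
                    "name": "",
                    "namespace": "",
                    "synonyms": [],
                    "is_obsolete": False,
                    "relations": [],
                }
                if stanza_type == "Term"
                else None
            )
            continue
        if in_header:
            header_lines.append(line)
            continue
        if current is None or not stripped or stripped.startswith("!"):
            continue
        if ":" not in stripped:
            raise OboParseError(f"cannot parse tag line {stripped!r}", line_no)
        tag, _, value = stripped.partition(":")
        tag = tag.strip()
        value = value.split(" !")[0].strip()
        if tag == "id":
            current["id"] = value
        elif tag == "name":
            current["name"] = value
        elif tag == "namespace":
            current["namespace"] = value
        elif tag == "synonym":
            m = _SYNONYM_RE.match(value)
            current["synonyms"].append(m.group(1) if m else value)
        elif tag == "is_obsolete":
            current["is_obsolete"] = value.lower() == "true"
        elif tag == "is_a":
            current["relations"].append(("is_a", value))
        elif tag == "relationship":
            parts = value.split()
            if len(parts) < 2:
                raise OboParseError(f"malformed relationship line {value!r}", line_no)
            current["relations"].append((parts[0], parts[1]))
        # other tags (def, xref, comment, ...) are outside this graph's model
    flush(line_no=stanza_start if current else 0)

    graph.header = "\n".join(header_lines).strip()
    for subject, pred, obj in pending_edges:
        graph.add_edge(subject, pred, obj)
    graph.complete_inverses()
    return graph


def write_obo(graph: StageGraph) -> str:
    """Serialize a :class:`StageGraph` back to OBO flat text.

    The stored header is emitted verbatim, then one ``[Term]`` stanza per term
    in id order, with ``is_a`` lines and ``relationship:`` lines for every
    stored edge (inverse-completed edges included; re-parsing is idempotent).
    """
    out: list[str] = []
    if graph.header:
        out.append(graph.header)
        out.append("")
    by_subject: dict[str, list[RelationEdge]] = {}
    for edge in graph.edges:
        by_subject.setdefault(edge.subject, []).append(edge)
    for tid in sorted(graph.terms):
        term = graph.terms[tid]
        out.append("[Term]")
        out.append(f"id: {tid}")
        if term.name:
            out.append(f"name: {term.name}")
        if term.namespace:
            out.append(f"namespace: {term.namespace}")
        for syn in term.synonyms:
            out.append(f'synonym: "{syn}" RELATED []')
        if term.is_obsolete:
            out.append("is_obsolete: true")
        for edge in sorted(
            by_subject.get(tid, []), key=lambda e: (e.predicate, e.object)
        ):
            if edge.predicate == "is_a":
                out.append(f"is_a: {edge.object}")
            else:
                out.append(f"relationship: {edge.predicate} {edge.object}")
        out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# Reasoning
# ---------------------------------------------------------------------------


def _closure(
    graph: StageGraph,
    start: str,
    predicates: Iterable[str],
    direction: str = "out",
) -> set[str]:
    """Transitive closure by breadth-first search, skipping obsolete terms."""
    graph.require(start)
    step = graph.out_neighbors if direction == "out" else graph.in_neighbors
    preds = list(predicates)
    seen: set[str] = set()
    queue = deque([start])
    while queue:
        node = queue.popleft()
        for nxt in step(node, preds):
            if nxt in seen or nxt == start:
                continue
            if nxt in graph.terms and graph.terms[nxt].is_obsolete:
                continue
            seen.add(nxt)
            queue.append(nxt)
    return seen


def ancestors(graph: StageGraph, term: str, predicates: Iterable[str]) -> set[str]:
    """Terms reachable from ``term`` over the chosen predicates (term excluded).

    ``predicates`` must be a subset of :data:`CLOSURE_PREDICATES`; with
    ``{"is_a"}`` this is the subclass closure used for annotation propagation.
    """
    preds = set(predicates)
    bad = preds - CLOSURE_PREDICATES
    if bad:
        raise ValueError(f"predicates not usable for closure: {sorted(bad)}")
    return _closure(graph, term, preds, "out")


def descendants(graph: StageGraph, term: str, predicates: Iterable[str]) -> set[str]:
    """Inverse of :func:`ancestors`: terms from which ``term`` is reachable."""
    preds = set(predicates)
    bad = preds - CLOSURE_PREDICATES
    if bad:
        raise ValueError(f"predicates not usable for closure: {sorted(bad)}")
    return _closure(graph, term, preds, "in")


def preceded_by_closure(graph: StageGraph, term: str) -> set[str]:
    """All stages that transitively precede ``term`` (via preceded_by edges)."""
    return _closure(graph, term, ["preceded_by"], "out")


def temporal_sort(graph: StageGraph, terms: Sequence[str]) -> list[str]:
    """Order ``terms`` consistently with the transitive precedes relation.

    If ``a`` transitively precedes ``b``, ``a`` appears first; terms with no
    ordering constraint between them keep their input order (stable Kahn
    scheme picking the smallest input index among ready terms).  A precedes
    cycle among the inputs raises :class:`OrderingCycleError` naming it.
    """
    terms = list(terms)
    for t in terms:
        graph.require(t)
    index = {t: i for i, t in enumerate(terms)}
    term_set = set(terms)
    succ: dict[str, set[str]] = {t: set() for t in terms}
    indeg = {t: 0 for t in terms}
    for t in terms:
        later = _closure(graph, t, ["precedes"], "out") & term_set
        later.discard(t)
        for u in later:
            if u not in succ[t]:
                succ[t].add(u)
                indeg[u] += 1
    ordered: list[str] = []
    ready = sorted((t for t in terms if indeg[t] == 0), key=index.__getitem__)
    while ready:
        node = ready.pop(0)
        ordered.append(node)
        changed = False
        for u in succ[node]:
            indeg[u] -= 1
            if indeg[u] == 0:
                ready.append(u)
                changed = True
        if changed:
            ready.sort(key=index.__getitem__)
    if len(ordered) != len(terms):
        remaining = [t for t in terms if indeg[t] > 0]
        cycle = _find_cycle(succ, remaining)
        raise OrderingCycleError(cycle)
    return ordered


def _find_cycle(succ: Mapping[str, set[str]], nodes: Sequence[str]) -> list[str]:
    node_set = set(nodes)
    start = nodes[0]
    path, on_path = [start], {start}
    while True:
        nxt = next(iter(sorted(succ[path[-1]] & node_set)))
        if nxt in on_path:
            return path[path.index(nxt):] + [nxt]
        path.append(nxt)
        on_path.add(nxt)


def infer_stage_structure_links(
    graph: StageGraph, assoc: Iterable[tuple[str, str]]
) -> list[tuple[str, str, str]]:
    """One-hop stage↔structure inference over participation edges.

    For an association of an entity to a stage that ``has_participant`` some
    structure S, infer an association to S; for an association to a structure
    that ``participates_in`` some stage D, infer an association to D.  Both
    follow *outgoing* edges only — the every/some rule makes the converse
    directions unsound (every protonema exists during some gametophyte
    development stage; a given such stage need not involve a protonema).
    Provenance records the edge used.  Unknown terms or missing edges simply
    yield no inferences.
    """
    inferred: list[tuple[str, str, str]] = []
    for entity, term in assoc:
        for pred in ("has_participant", "participates_in"):
            for target in sorted(graph.out_neighbors(term, [pred])):
                inferred.append((entity, target, f"{term} {pred} {target}"))
    return inferred


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationIssue:
    issue_type: str
    subject: str
    object: str
    detail: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.issues)

    def count(self, issue_type: str) -> int:
        return sum(1 for i in self.issues if i.issue_type == issue_type)

    def to_tsv(self) -> str:
        lines = ["issue_type\tsubject\tobject\tdetail"]
        lines += [f"{i.issue_type}\t{i.subject}\t{i.object}\t{i.detail}" for i in self.issues]
        return "\n".join(lines) + "\n"


def validate(graph: StageGraph) -> ValidationReport:
    """Structural checks; reporting only, the graph is not modified.

    Reported issue types: ``is_a_cycle``, ``precedes_cycle`` (one issue per
    strongly connected component of size > 1), ``dangling_endpoint``,
    ``missing_inverse`` (a precedes/preceded_by edge without its mate),
    ``self_edge`` (defensive — construction already rejects them), and
    ``obsolete_with_edges``.
    """
    report = ValidationReport()
    for pred, issue in (("is_a", "is_a_cycle"), ("precedes", "precedes_cycle")):
        sub = graph.predicate_subgraph(pred)
        for comp in nx.strongly_connected_components(sub):
            if len(comp) > 1:
                members = sorted(comp)
                report.issues.append(
                    ValidationIssue(issue, members[0], members[-1], ",".join(members))
                )
    for edge in graph.edges:
        if edge.subject == edge.object:
            report.issues.append(
                ValidationIssue("self_edge", edge.subject, edge.object, edge.predicate)
            )
        for endpoint in (edge.subject, edge.object):
            if endpoint not in graph.terms:
                report.issues.append(
                    ValidationIssue(
                        "dangling_endpoint", edge.subject, edge.object,
                        f"{endpoint} not a term ({edge.predicate})",
                    )
                )
        inv = _INVERSE.get(edge.predicate)
        if inv and edge.subject not in graph._out.get(inv, {}).get(edge.object, set()):
            report.issues.append(
                ValidationIssue(
                    "missing_inverse", edge.subject, edge.object,
                    f"no {edge.object} {inv} {edge.subject}",
                )
            )
        if (
            edge.predicate in REASONING_PREDICATES
            and edge.subject in graph.terms
            and graph.terms[edge.subject].is_obsolete
        ):
            report.issues.append(
                ValidationIssue(
                    "obsolete_with_edges", edge.subject, edge.object, edge.predicate
                )
            )
    return report
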