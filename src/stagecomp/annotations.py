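"""GAF-style association files: reading, evidence filtering, per-stage gene sets.

Annotation databases distribute stage/expression annotations as tab-delimited
``.assoc`` files in the GAF 2.x dialect: one bioentity–term association per
line, 15–17 columns, ``!``-prefixed comment lines.  The columns this package
interprets (1-based GAF positions):

====  ==============  =========================================
col   field           example
====  ==============  =========================================
1     source_db       TAIR
2     object_id       AT1G01040  (gene or gene model — identity key)
3     object_symbol   DCL1
5     term_id         PO:0001185
6     reference       PMID:20039061
7     evidence_code   IEP
13    taxon           taxon:3702
14    date            20171101
====  ==============  =========================================

Bioentity identity is the column-2 object id, not the symbol: annotations are
linked to gene or gene-model names.  Expression-derived comparisons keep only
experimentally grounded records — evidence codes IEP (inferred from expression
pattern) and IDA (inferred from direct assay) by default — and all set
statistics downstream operate on deduplicated identifier sets.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .ontology import CURIE_RE, StageGraph, descendants

__all__ = [
    "GAF_COLUMNS",
    "AnnotationRecord",
    "AnnotationTable",
    "FilterParams",
    "read_assoc",
    "write_assoc",
    "filter_evidence",
    "genes_for_stage",
    "annotation_stats",
]

#: (attribute, 0-based column index) for the interpreted GAF columns.
GAF_COLUMNS = (
    ("source_db", 0),
    ("object_id", 1),
    ("object_symbol", 2),
    ("term_id", 4),
    ("reference", 5),
    ("evidence_code", 6),
    ("taxon", 12),
    ("date", 13),
)

_MIN_COLUMNS = 15
_MAX_COLUMNS = 17


@dataclass(frozen=True, slots=True)
class AnnotationRecord:
    source_db: str
    object_id: str
    object_symbol: str
    term_id: str
    evidence_code: str
    reference: str = ""
    taxon: str = ""
    date: str = ""


@dataclass(frozen=True)
class FilterParams:
    """Evidence-code filter; defaults to the two experimental expression codes."""

    evidence_codes: frozenset[str] = frozenset({"IEP", "IDA"})

    def __post_init__(self):
        object.__setattr__(self, "evidence_codes", frozenset(self.evidence_codes))


@dataclass
class AnnotationTable:
    """Ordered annotation records with term and bioentity indices.

    ``rejects`` holds ``(line_number, reason, raw_line)`` for input lines that
    could not be parsed; they are reported, never silently dropped.
    """

    records: list[AnnotationRecord] = field(default_factory=list)
    rejects: list[tuple[int, str, str]] = field(default_factory=list)
    _by_term: dict[str, list[AnnotationRecord]] | None = field(default=None, repr=False)
    _by_object: dict[str, list[AnnotationRecord]] | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.records)

    def _index(self) -> None:
        if self._by_term is None:
            by_term: dict[str, list[AnnotationRecord]] = {}
            by_object: dict[str, list[AnnotationRecord]] = {}
            for rec in self.records:
                by_term.setdefault(rec.term_id, []).append(rec)
                by_object.setdefault(rec.object_id, []).append(rec)
            self._by_term, self._by_object = by_term, by_object

    def by_term(self, term_id: str) -> list[AnnotationRecord]:
        self._index()
        return list(self._by_term.get(term_id, []))

    def by_object(self, object_id: str) -> list[AnnotationRecord]:
        self._index()
        return list(self._by_object.get(object_id, []))

    def evidence_counts(self) -> Counter:
        return Counter(r.evidence_code for r in self.records)

    def distinct_objects(self) -> set[str]:
        return {r.object_id for r in self.records}

    def rejects_report_tsv(self) -> str:
        lines = ["line\treason\traw"]
        lines += [f"{n}\t{reason}\t{raw}" for n, reason, raw in self.rejects]
        return "\n".join(lines) + "\n"


def read_assoc(stream) -> AnnotationTable:
    """Read a GAF 2.x ``.assoc`` stream into an :class:`AnnotationTable`.

    Lines starting with ``!`` are comments; blank lines are ignored.  A line
    with fewer than 15 columns, a term id that is not a CURIE, or an empty
    evidence code goes to the rejects report with its line number.  Extra
    columns beyond 17 are tolerated and ignored.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    table = AnnotationTable()
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < _MIN_COLUMNS:
            table.rejects.append((line_no, f"{len(cols)} columns (<{_MIN_COLUMNS})", line))
            continue
        fields = {attr: cols[idx].strip() for attr, idx in GAF_COLUMNS}
        if not CURIE_RE.match(fields["term_id"]):
            table.rejects.append((line_no, f"bad term id {fields['term_id']!r}", line))
            continue
        if not fields["evidence_code"]:
            table.rejects.append((line_no, "empty evidence code", line))
            continue
        fields["evidence_code"] = fields["evidence_code"].upper()
        table.records.append(AnnotationRecord(**fields))
    return table


def write_assoc(table: AnnotationTable) -> str:
    """Serialize to 15-column GAF; uninterpreted columns are left empty."""
    out = ["!gaf-version: 2.1"]
    for rec in table.records:
        cols = [""] * _MIN_COLUMNS
        for attr, idx in GAF_COLUMNS:
            cols[idx] = getattr(rec, attr)
        out.append("\t".join(cols))
    return "\n".join(out) + "\n"


def filter_evidence(table: AnnotationTable, params: FilterParams) -> AnnotationTable:
    """Keep exactly the records whose evidence code is in ``params``; order kept."""
    if not params.evidence_codes:
        raise ValueError("empty evidence-code set: filtering intent is ambiguous")
    kept = [r for r in table.records if r.evidence_code in params.evidence_codes]
    return AnnotationTable(records=kept)


def genes_for_stage(
    table: AnnotationTable,
    graph: StageGraph,
    stage: str,
    propagate: bool = False,
) -> set[str]:
    """Distinct bioentities annotated to ``stage``.

    With ``propagate=True`` the true-path rule is applied downward through the
    ``is_a`` hierarchy: bioentities annotated to any is_a descendant of the
    stage count as annotated to the stage itself (searching a grouping stage
    finds everything annotated to its sub-stages).  ``part_of`` is not used
    for propagation.
    """
    graph.require(stage)
    stages = {stage}
    if propagate:
        stages |= descendants(graph, stage, {"is_a"})
    genes: set[str] = set()
    for s in stages:
        genes.update(r.object_id for r in table.by_term(s))
    return genes


def annotation_stats(table: AnnotationTable) -> pd.DataFrame:
    """Per (taxon, source) annotation and distinct-bioentity counts plus totals.

    The totals row's annotation count is the exact column sum; its bioentity
    count is the number of distinct bioentities in the whole table, which can
    legitimately differ from the per-row column sum when an identifier is
    shared across sources.
    """
    ann_counts: Counter = Counter()
    objects: dict[tuple[str, str], set[str]] = {}
    for rec in table.records:
        key = (rec.taxon, rec.source_db)
        ann_counts[key] += 1
        objects.setdefault(key, set()).add(rec.object_id)
    rows = [
        {
            "taxon": taxon,
            "source": source,
            "annotations": ann_counts[(taxon, source)],
            "bioentities": len(objects[(taxon, source)]),
        }
        for taxon, source in sorted(ann_counts, key=lambda k: (-ann_counts[k], k))
    ]
    total_objects = set().union(*objects.values()) if objects else set()
    rows.append(
        {
            "taxon": "total",
            "source": "",
            "annotations": sum(ann_counts.values()),
            "bioentities": len(total_objects),
        }
    )
    return pd.DataFrame(rows, columns=["taxon", "source", "annotations", "bioentities"])
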