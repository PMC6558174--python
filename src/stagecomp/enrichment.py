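"""Slim-mapped term enrichment with Benjamini–Yekutieli control.

A singular enrichment analysis (SEA) asks, for each functional term, whether a
study gene set carries the term more often than expected from a reference
("background") set.  Under sampling without replacement the study count k for
a term with K carriers in a background of N genes follows a hypergeometric
distribution; the one-sided over-representation p-value is

    p = P[X >= k],   X ~ Hypergeometric(N, K, n),

which is exactly the one-sided Fisher exact test on the 2×2 table.  Because
the per-term tests are dependent in unknown ways (terms share genes and
ancestor/descendant structure), the family of p-values is adjusted with the
Benjamini–Yekutieli step-up procedure, which controls the FDR under arbitrary
dependence at the price of the harmonic-sum factor c(m) = Σ_{i≤m} 1/i.

Detailed annotations can first be mapped to a "slim" — a curated subset of
high-level terms — by replacing each term with its *minimal* slim ancestors:
slim terms that subsume it with no other slim term strictly between.  Terms
the slim does not cover are dropped and counted.  Terms mapped by fewer than
``min_mapped`` study genes (default 5) are not tested, mirroring common SEA
practice of pruning untestable terms.

Cross-tabulating several analyses (a SEACOMPARE-style grid) shows which terms
are significant in which gene set, with union and intersection counts.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .ontology import StageGraph, ancestors

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentParams",
    "TermCounts",
    "EnrichmentResult",
    "CompareTable",
    "map_to_slim",
    "minimal_slim_ancestors",
    "hypergeom_pvalue",
    "hypergeom_pvalues",
    "adjust_by",
    "fisher_enrichment",
    "seacompare",
    "read_gene_list",
    "read_gene_terms_tsv",
    "results_to_tsv",
]


@dataclass(frozen=True)
class EnrichmentParams:
    """min_mapped: minimum study genes mapped to a term for it to be tested."""

    min_mapped: int = 5
    alpha: float = 0.05
    adjustment: str = "BY"
    slim_terms: frozenset[str] | None = None

    def __post_init__(self):
        if self.min_mapped < 1:
            raise ValueError("min_mapped must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.adjustment != "BY":
            raise ValueError("only Benjamini-Yekutieli adjustment is supported")


@dataclass(frozen=True)
class TermCounts:
    """2×2 table counts: k of n study genes vs K of N background genes carry the term."""

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self):
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"need 0 <= k <= min(n, K); got {self}")
        if self.n > self.N or self.K > self.N:
            raise ValueError(f"need n <= N and K <= N; got {self}")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    counts: TermCounts
    p_value: float
    fdr: float
    significant: bool


# ---------------------------------------------------------------------------
# Slim mapping
# ---------------------------------------------------------------------------

_SLIM_PREDICATES = frozenset({"is_a", "part_of"})


def minimal_slim_ancestors(
    graph: StageGraph,
    term: str,
    slim_terms: frozenset[str],
    predicates: frozenset[str] = _SLIM_PREDICATES,
) -> set[str]:
    """Slim terms covering ``term`` with no other covering slim term below them.

    A slim term s covers t if s == t or s is an ancestor of t (over ``is_a``
    and ``part_of`` by default).  s is minimal if no other covering slim term
    s' has s among *its* ancestors, i.e. nothing in the slim sits on a path
    between t and s.
    """
    cover = {s for s in slim_terms if s == term or s in ancestors(graph, term, predicates)}
    return {
        s
        for s in cover
        if not any(s in ancestors(graph, s2, predicates) for s2 in cover if s2 != s)
    }


def map_to_slim(
    graph: StageGraph,
    gene_terms: Mapping[str, Iterable[str]],
    slim_terms: Iterable[str],
) -> tuple[dict[str, set[str]], list[str]]:
    """Replace each gene's terms by their minimal slim ancestors.

    Returns ``(mapped, dropped)``: genes none of whose terms has any slim
    ancestor are dropped and listed.  A slim term absent from the graph is an
    error.  A gene counts at most once per slim term.
    """
    slim = frozenset(slim_terms)
    for s in slim:
        if s not in graph:
            raise KeyError(f"slim term {s!r} is not in the ontology graph")
    cache: dict[str, set[str]] = {}
    mapped: dict[str, set[str]] = {}
    dropped: list[str] = []
    for gene, terms in gene_terms.items():
        slimmed: set[str] = set()
        for t in terms:
            if t not in cache:
                cache[t] = (
                    minimal_slim_ancestors(graph, t, slim) if t in graph else set()
                )
            slimmed |= cache[t]
        if slimmed:
            mapped[gene] = slimmed
        else:
            dropped.append(gene)
    if dropped:
        logger.info("%d genes had no slim-mapped terms and were dropped", len(dropped))
    return mapped, dropped


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def hypergeom_pvalues(k, n, K, N) -> np.ndarray:
    """Vectorized one-sided over-representation p-values, P[X >= k].

    Accepts scalars or equal-length arrays.  This is the computation behind
    both :func:`hypergeom_pvalue` and :func:`fisher_enrichment`.
    """
    k = np.atleast_1d(np.asarray(k, dtype=np.int64))
    n = np.atleast_1d(np.asarray(n, dtype=np.int64))
    K = np.atleast_1d(np.asarray(K, dtype=np.int64))
    N = np.atleast_1d(np.asarray(N, dtype=np.int64))
    # survival function is P[X > k-1] = P[X >= k]; k = 0 is identically 1
    # (also sidesteps the degenerate empty-population table)
    with np.errstate(invalid="ignore"):
        p = hypergeom.sf(k - 1, N, K, n)
    p = np.where(k == 0, 1.0, p)
    return np.minimum(p, 1.0)


def hypergeom_pvalue(counts: TermCounts) -> float:
    """One-sided over-representation p-value for a validated 2×2 table."""
    return float(hypergeom_pvalues(counts.k, counts.n, counts.K, counts.N)[0])


def adjust_by(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Yekutieli step-up adjustment, order of input preserved.

    With m tests and c(m) = Σ_{i=1..m} 1/i, the adjusted value for the r-th
    smallest p is min_{j>=r} ( m · c(m) · p_(j) / j ), capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted.tolist()


def fisher_enrichment(
    study: Iterable[str],
    population: Iterable[str],
    gene_terms: Mapping[str, Iterable[str]],
    params: EnrichmentParams = EnrichmentParams(),
) -> list[EnrichmentResult]:
    """Per-term one-sided Fisher enrichment of ``study`` against ``population``.

    Genes with no term mapping are excluded from both N and n (and logged).
    Only terms mapped by at least ``params.min_mapped`` study genes are
    tested; the BY adjustment runs over exactly that tested family.  Results
    are sorted by ascending FDR, then p, then term id.
    """
    study = set(study)
    population = set(population)
    if not study:
        raise ValueError("study set is empty")
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    pop_mapped = {g for g in population if gene_terms.get(g)}
    unmapped = len(population) - len(pop_mapped)
    if unmapped:
        logger.info("%d population genes have no term mapping; excluded", unmapped)
    study_mapped = study & pop_mapped
    N, n = len(pop_mapped), len(study_mapped)

    pop_count: dict[str, int] = {}
    study_count: dict[str, int] = {}
    for g in pop_mapped:
        for t in set(gene_terms[g]):
            pop_count[t] = pop_count.get(t, 0) + 1
            if g in study_mapped:
                study_count[t] = study_count.get(t, 0) + 1

    tested = sorted(t for t, c in study_count.items() if c >= params.min_mapped)
    if not tested:
        return []
    k = [study_count[t] for t in tested]
    K = [pop_count[t] for t in tested]
    pvals = hypergeom_pvalues(k, [n] * len(tested), K, [N] * len(tested))
    fdrs = adjust_by(pvals.tolist())
    results = [
        EnrichmentResult(
            term_id=t,
            counts=TermCounts(k=k[i], n=n, K=K[i], N=N),
            p_value=float(pvals[i]),
            fdr=fdrs[i],
            significant=fdrs[i] <= params.alpha,
        )
        for i, t in enumerate(tested)
    ]
    results.sort(key=lambda r: (r.fdr, r.p_value, r.term_id))
    return results


# ---------------------------------------------------------------------------
# Cross-set comparison
# ---------------------------------------------------------------------------


@dataclass
class CompareTable:
    """Term × gene-set grid of (fdr, significant) with summary counts."""

    fdr: pd.DataFrame          # terms × sets; NaN where a term was not tested
    significant: pd.DataFrame  # boolean, False where not tested
    per_set_significant: dict[str, int] = field(default_factory=dict)
    union_significant: int = 0
    intersection_significant: int = 0

    def to_tsv(self) -> str:
        merged = pd.DataFrame(index=self.fdr.index)
        for col in self.fdr.columns:
            merged[f"{col}_fdr"] = self.fdr[col]
            merged[f"{col}_significant"] = self.significant[col].astype(int)
        return merged.to_csv(sep="\t", index_label="term_id")


def seacompare(
    results_per_set: Mapping[str, Sequence[EnrichmentResult]],
    alpha: float | None = None,
) -> CompareTable:
    """Cross-tabulate several enrichment analyses over the union of tested terms.

    Significance follows each result's flag unless ``alpha`` is given, in
    which case flags are recomputed as fdr <= alpha.  Union counts terms
    significant in at least one set; intersection in every set.
    """
    if len(results_per_set) < 2:
        raise ValueError("seacompare needs at least two result sets")
    labels = list(results_per_set)
    terms = sorted({r.term_id for rs in results_per_set.values() for r in rs})
    fdr = pd.DataFrame(np.nan, index=terms, columns=labels)
    sig = pd.DataFrame(False, index=terms, columns=labels)
    for label, results in results_per_set.items():
        for r in results:
            fdr.loc[r.term_id, label] = r.fdr
            sig.loc[r.term_id, label] = (
                r.fdr <= alpha if alpha is not None else r.significant
            )
    per_set = {label: int(sig[label].sum()) for label in labels}
    union = int(sig.any(axis=1).sum())
    intersection = int(sig.all(axis=1).sum())
    return CompareTable(
        fdr=fdr,
        significant=sig,
        per_set_significant=per_set,
        union_significant=union,
        intersection_significant=intersection,
    )


def read_gene_list(stream) -> set[str]:
    """One identifier per line; blank lines and ``#`` comments ignored."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    return {
        line.strip() for line in stream if line.strip() and not line.startswith("#")
    }


def read_gene_terms_tsv(stream) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, term_id) into a gene→terms map."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    mapping: dict[str, set[str]] = {}
    for line_no, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"line {line_no}: expected gene_id<TAB>term_id")
        mapping.setdefault(parts[0], set()).add(parts[1])
    return mapping


def results_to_tsv(results: Sequence[EnrichmentResult]) -> str:
    lines = ["term_id\tk\tn\tK\tN\tp_value\tfdr\tsignificant"]
    for r in results:
        c = r.counts
        lines.append(
            f"{r.term_id}\t{c.k}\t{c.n}\t{c.K}\t{c.N}"
            f"\t{r.p_value:.6g}\t{r.fdr:.6g}\t{int(r.significant)}"
        )
    return "\n".join(lines) + "\n"
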