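# Methods

This note documents the models, rules, and numerical choices behind
`stagecomp`, and what its synthetic fixtures do and do not establish about
real data.

## The stage graph and its relation semantics

A development-stage ontology is held as a typed multigraph: term records
(CURIE id, label, namespace, synonyms, obsolete flag) plus subject–predicate–
object edges over six interpreted predicates.

* `is_a` is the primary hierarchy: a shorter, more specific stage is a
  subclass of a longer one.  It is the only predicate used for annotation
  propagation (the true-path rule): a gene annotated to a sub-stage counts
  for every `is_a` ancestor when propagation is requested.  `part_of` links a
  stage of one structure to a stage of a containing structure; its closure is
  available (`ancestors(..., {"is_a", "part_of"})`) but deliberately not used
  for propagation — part-whole containment of time intervals does not imply
  that an expression observation in the part holds for the whole's stage
  listing.
* `precedes` / `preceded_by` encode temporal order (the end of one stage at
  or before the start of another).  Both are transitive and mutually
  inverse; the parser materializes whichever inverse is missing, so
  downstream code can follow either direction.  Many branches of real stage
  ontologies carry no temporal edges at all, which is why `temporal_sort` is
  *stable*: terms with no ordering constraint keep their input order, and
  only genuinely ordered pairs are rearranged.  A `precedes` cycle among the
  inputs is an error naming the cycle.
* `has_participant` / `participates_in` connect stages and anatomical
  structures.  They are read under the every/some rule: `A rel B` means
  every instance of A stands in `rel` to *some* instance of B.  Inference is
  therefore one-hop and direction-asymmetric: an annotation to a structure
  that `participates_in` a stage licenses an inferred annotation to the
  stage, and an annotation to a stage that `has_participant` a structure
  licenses one to the structure — never the converse readings.  Inference is
  not chained; re-applying the operation to its own output is the explicit
  way to get a second hop.

Predicates outside these six are preserved on the graph (and round-trip
through the OBO writer) but excluded from all reasoning, for forward
compatibility with richer ontology releases.  Obsolete terms are excluded
from every closure, following standard OBO practice.  The OBO parser is
intentionally written in-package: it reports the line number of a stanza
without an `id:`, rejects duplicate term ids by name, and preserves the
header verbatim so that parse → write → parse is the identity on term count,
edge multiset, and flags.

## Annotations and evidence

GAF 2.x `.assoc` rows are read positionally (db, object id, symbol, term,
reference, evidence, taxon, date at columns 1, 2, 3, 5, 6, 7, 13, 14);
files in the wild vary between 15 and 17 columns, so extras are tolerated.
Malformed rows are never silently dropped — they land in a rejects report
with line numbers.  Bioentity identity is the column-2 gene or gene-model
id, not the display symbol.

The default evidence filter keeps IEP (inferred from expression pattern) and
IDA (inferred from direct assay), the two codes that mark experimentally
grounded expression annotations; IEA (electronic) records are excluded from
comparisons by default.  All overlap and uniqueness statistics run on
deduplicated identifier sets of *direct* annotations, without `is_a`
propagation: the per-stage sets being compared are what the curators
attached to each stage, and propagation would mechanically inflate overlap
between nested stages.  Annotation-count statistics report per
(taxon, source) rows plus a totals row whose annotation count is the exact
column sum; the distinct-bioentity total is computed over the union of ids
and may legitimately differ from the per-row sum when an id is shared
between sources, so it is reported but never asserted against a column sum.

## Homolog clustering

Cross-species comparison requires a shared identifier space.  Clusters are
seeded by reciprocal best hits: after collapsing multiple HSP rows per gene
pair to the maximum-score row (fractions capped at 1) and discarding hits
where either sequence has less than half its length aligned (threshold 0.50,
inclusive — "at least half of both sequences"), gene *a* of species A and
gene *b* of species B seed a cluster iff each is the other's highest-scoring
cross-species hit.  An unseeded gene *g* on A's side joins the cluster
seeded by (a, b) iff score(g, b) ≥ score(a, b) and *b* is *g*'s best
cross-species hit; a gene qualifying for several clusters goes to the
highest qualifying score.  Every tie (equal best scores, equal qualifying
scores) breaks toward the lower lexicographic identifier, making the whole
clustering deterministic and input-order-independent.  A hit observed in
only one direction is treated as symmetric by default (bit-score matrices
are near-symmetric, and tabular exports often keep one direction);
`require_both_directions=True` restores the strict mode.  This is a
deliberately reduced InParanoid: no bootstrap confidence, no resolution of
overlapping clusters beyond best-score assignment, and no statistical
confidence cutoff — the 0.50 mutual-overlap rule is the operative filter.

## Overlap and uniqueness statistics

For identifier sets A and B, percent overlap is |A∩B| / ((|A|+|B|)/2) × 100;
it is symmetric, 100 exactly when the sets are equal (and nonempty), 0
exactly when disjoint, and undefined (an error) when both are empty.  A
stage's unique genes are its set minus the union of every other stage of the
same species; percent unique is reported to two decimals, rounded half away
from zero to match how such tables are conventionally printed.  Stages with
fewer than 50 identifiers trigger a warning — percent statistics on tiny
sets are unstable, and a stage with only a handful of annotated genes is
best excluded from comparison outright (the threshold is configurable).

Contrast sets for enrichment follow four recipes: within one species, the
early-not-late and late-not-early gene sets (Sets 1 and 2); across species,
the clusters hit by species B's analogous stage but not species A's,
back-converted to gene ids of either species (Sets 3A and 3B); and all genes
of species A's reference stage (Set 4).  Cluster-space differences are
pooled per species before subtraction for the pooled-difference statistic,
which satisfies |A\B| = |A| − |A∩B| exactly.

## Enrichment

The over-representation p-value for a term with k of n study genes against K
of N background genes is the hypergeometric tail P[X ≥ k] (equivalently the
one-sided Fisher exact test), computed through `scipy.stats.hypergeom.sf`
with the k = 0 case short-circuited to exactly 1.  Genes with no term
mapping are excluded from both N and n and counted in the log.  Only terms
with at least `min_mapped` (default 5) *study* genes are tested — the
minimum-mapping-entries convention of singular enrichment analysis tools,
applied to the study side because that is the count that makes a term
untestable.  The tested family is then adjusted with Benjamini–Yekutieli:
with m tests and c(m) = Σ 1/i, the adjusted value at rank r is
min over j ≥ r of m·c(m)·p(j)/j, capped at 1.  BY is used rather than BH
because term tests are dependent in unknown ways (terms share genes and
stand in ancestor relations); it controls the FDR under arbitrary
dependence at the cost of conservatism, and it dominates BH on every input.
Only over-representation is tested; depletion is out of scope.

Slim mapping replaces each annotated term by its *minimal* slim ancestors:
slim terms covering the term (over `is_a` and `part_of`) with no other
covering slim term strictly below them.  A gene counts at most once per slim
term; genes none of whose terms reach the slim are dropped and counted.
Cross-tabulating several analyses yields a term × set grid of (FDR,
significant) with per-set, union, and intersection counts.

## Synthetic fixtures: what they emulate, and what they do not

Each generator plants one structural feature with serialized ground truth,
driven by `default_rng([seed, stream_id])` so identical parameters and seed
reproduce fixtures byte for byte.

* `make_stage_ontology` — a linear `precedes` chain of leaf stages under
  `is_a` grouping terms; always passes validation by construction.
* `make_annotation_table` — a core pool of `round(shared_frac ×
  genes_per_stage)` genes annotated to every stage plus stage-specific
  remainders, so each stage pair overlaps by the requested fraction;
  evidence codes are drawn at fixed proportions (IEP 0.60 / IDA 0.25 /
  IEA 0.15).  Real annotation corpora differ: their shared fractions vary
  by pair, their evidence mixes by source, and their per-stage totals are
  unequal.
* `make_stage_map_counts` — per-stage sets with *exact* requested totals and
  unique counts, laid out so every shared identifier occurs in at least two
  stages (requests where that is impossible — e.g. two stages with unequal
  shared counts — are rejected rather than silently mis-planted).
* `make_similarity_fixture` — ortholog pairs scored in [200, 400] in both
  directions; noise hits in [40, 120], half of them failing the overlap
  filter, and every filter-passing noise hit touching planted genes on both
  sides.  The margin between the score bands guarantees by construction
  that no noise hit can displace a best hit or create a spurious reciprocal
  pair, which makes recovery tests deterministic in outcome.  In-paralog
  hits are planted at *exactly* their seed's score with identifiers sorting
  after the seed gene: under the inclusive attachment rule any strictly
  higher score would itself become the reciprocal best hit and displace the
  planted pair, so equality plus the lexicographic tie-break is the one
  configuration in which the pair stays the seed and the paralog still
  attaches.
* `make_enrichment_fixture` — independent per-term Bernoulli background at a
  uniform frequency, and a study set whose carrier count for one term is
  binomially sampled at fold × background frequency.  Real backgrounds have
  heavy-tailed term frequencies and correlated term memberships; the
  uniform-independent model makes power calculations interpretable but
  optimistic.

Passing the planted-truth suites therefore shows that the implementation
applies its own rules exactly under conditions where the answer is forced;
it does not show that those conditions (score margins, uniform term
frequencies, symmetric hit tables) hold in any particular real corpus.

## Problem sizes and numerical choices

The exhaustive hypergeometric check enumerates every valid (N, K, n, k) with
N ≤ 60 — about 1.23 million tables — against exact integer combinatorics
(tail sums of `math.comb` products, divided once at the end), agreeing to
4.5 × 10⁻¹⁶; the recovery, overlap, and power suites use 50, 20, and
100 + 500 seeded runs at 20 pairs, 1,000 genes/stage, and a 5,000-gene
background respectively — sizes chosen so each suite exercises the
statistics at meaningful scale while the whole test run stays under half a
minute.  Percent values are formatted half-up to two decimals only at
reporting boundaries; all internal set arithmetic is exact.  The pipeline
writes a SHA-256 manifest over every output file so reruns can be compared
byte for byte (the report file cannot contain its own checksum and is
hashed after serialization).

## Known limitations

Expression *levels* and directions are invisible to this analysis — stage
annotations are presence/absence, so high overlap between stages does not
imply similar expression profiles.  Clustering is limited to two species and
contains no synteny or tree-aware orthology.  The enrichment module performs
no term-graph traversal beyond slim mapping and no gene-ontology database
retrieval; backgrounds are supplied as explicit gene→term tables.  OWL-level
logical definitions, cross-ontology imports, and taxon constraints are out
of scope for the ontology layer.
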