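"""Cross-species homolog clusters from pairwise similarity, via reciprocal best hits.

Stage annotations name genes in species-specific identifier spaces; comparing
stages *between* species needs a shared space.  Following the InParanoid idea,
clusters are seeded by reciprocal best hits (RBH): two genes, one per species,
that are each other's highest-scoring cross-species match in an all-vs-all
similarity search.  Before seeding, hits must satisfy a mutual-overlap rule —
at least half of *each* sequence aligned to the other (threshold 0.50,
inclusive) — so that fragmentary matches cannot seed clusters.  A remaining
gene joins the cluster seeded by ``(a, b)`` of its own species' side as an
in-paralog when it matches the other species' seed at least as well as the
seed pair matches itself and that seed is its best cross-species hit.

The similarity table is a precomputed BLAST-like tabular file; no aligner is
run here.  Multiple HSP rows for the same gene pair are collapsed to the
maximum-score row, with alignment fractions capped at 1.  By default a hit
observed in only one direction is treated as symmetric (the score matrix of a
bit-score search is near-symmetric); ``require_both_directions=True`` restricts
RBH seeding to pairs hit in both directions.  All tie-breaks are by lower
lexicographic identifier, making the clustering deterministic.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityHit",
    "HomologyParams",
    "HomologCluster",
    "HomologClusterSet",
    "read_hits_tsv",
    "filter_hits",
    "reciprocal_best_pairs",
    "build_clusters",
    "genes_to_clusters",
    "write_clusters_tsv",
]


@dataclass(frozen=True, slots=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    query_species: str
    subject_species: str
    score: float
    query_aln_frac: float
    subject_aln_frac: float

    def __post_init__(self):
        if self.score < 0:
            raise ValueError(f"negative score for {self.query_id}->{self.subject_id}")
        for frac in (self.query_aln_frac, self.subject_aln_frac):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"alignment fraction {frac} outside [0,1]")


@dataclass(frozen=True)
class HomologyParams:
    """``min_overlap_frac``: mutual alignment-coverage threshold (default 0.50)."""

    min_overlap_frac: float = 0.50
    tie_break: str = "lexicographic"

    def __post_init__(self):
        if not 0.0 < self.min_overlap_frac <= 1.0:
            raise ValueError("min_overlap_frac must be in (0, 1]")
        if self.tie_break != "lexicographic":
            raise ValueError(f"unknown tie_break {self.tie_break!r}")


@dataclass
class HomologCluster:
    cluster_id: str
    seed: tuple[str, str]
    members: list[tuple[str, str, bool]]  # (gene_id, species, is_inparalog)


@dataclass
class HomologClusterSet:
    clusters: list[HomologCluster] = field(default_factory=list)
    _gene_to_cluster: dict[str, str] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def add(self, cluster: HomologCluster) -> None:
        for gene, _, _ in cluster.members:
            if gene in self._gene_to_cluster:
                raise ValueError(f"gene {gene!r} already in {self._gene_to_cluster[gene]}")
            self._gene_to_cluster[gene] = cluster.cluster_id
        self.clusters.append(cluster)

    def cluster_of(self, gene: str) -> str | None:
        return self._gene_to_cluster.get(gene)

    def total_genes(self) -> int:
        return len(self._gene_to_cluster)


def read_hits_tsv(
    stream,
    species_of: Mapping[str, str] | Callable[[str], str],
) -> list[SimilarityHit]:
    """Read a BLAST-like tabular file into :class:`SimilarityHit` records.

    The file must carry a header naming at least ``qseqid``, ``sseqid`` and
    ``bitscore``, plus either fraction columns (``qcovfrac``, ``scovfrac``) or
    length columns (``qlen``, ``slen``, ``qalnlen``, ``salnlen``) from which
    fractions are computed and capped at 1.  ``species_of`` maps a gene id to
    its species label.  Multiple rows per (query, subject) are collapsed to
    the maximum-score row.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t")
    required = {"qseqid", "sseqid", "bitscore"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"similarity table missing columns: {sorted(missing)}")
    if {"qcovfrac", "scovfrac"} <= set(df.columns):
        qfrac, sfrac = df["qcovfrac"], df["scovfrac"]
    elif {"qlen", "slen", "qalnlen", "salnlen"} <= set(df.columns):
        qfrac = (df["qalnlen"] / df["qlen"]).clip(upper=1.0)
        sfrac = (df["salnlen"] / df["slen"]).clip(upper=1.0)
    else:
        raise ValueError(
            "similarity table needs qcovfrac/scovfrac or qlen/slen/qalnlen/salnlen"
        )
    df = df.assign(qfrac=qfrac, sfrac=sfrac)
    df = df.loc[df.groupby(["qseqid", "sseqid"])["bitscore"].idxmax()]
    lookup = species_of if callable(species_of) else species_of.__getitem__
    return [
        SimilarityHit(
            query_id=q,
            subject_id=s,
            query_species=lookup(q),
            subject_species=lookup(s),
            score=float(score),
            query_aln_frac=float(qf),
            subject_aln_frac=float(sf),
        )
        for q, s, score, qf, sf in zip(
            df["qseqid"], df["sseqid"], df["bitscore"], df["qfrac"], df["sfrac"]
        )
    ]


def filter_hits(
    hits: Iterable[SimilarityHit], params: HomologyParams
) -> list[SimilarityHit]:
    """Keep hits where *both* aligned fractions reach the threshold (inclusive)."""
    t = params.min_overlap_frac
    return [h for h in hits if h.query_aln_frac >= t and h.subject_aln_frac >= t]


def _cross_scores(
    hits: Iterable[SimilarityHit],
    species_a: str,
    species_b: str,
    require_both_directions: bool,
) -> dict[tuple[str, str], float]:
    """Score per (gene_a, gene_b) cross-species pair, symmetrized over directions."""
    directional: dict[tuple[str, str], float] = {}
    seen_directions: dict[tuple[str, str], set[str]] = {}
    for h in hits:
        if {h.query_species, h.subject_species} != {species_a, species_b}:
            continue
        if h.query_species == species_a:
            key, direction = (h.query_id, h.subject_id), "ab"
        else:
            key, direction = (h.subject_id, h.query_id), "ba"
        directional[key] = max(directional.get(key, 0.0), h.score)
        seen_directions.setdefault(key, set()).add(direction)
    if require_both_directions:
        directional = {
            k: v for k, v in directional.items() if len(seen_directions[k]) == 2
        }
    else:
        one_way = sum(1 for d in seen_directions.values() if len(d) == 1)
        if one_way:
            logger.info(
                "%d gene pairs hit in one direction only; assuming symmetric scores",
                one_way,
            )
    return directional


def _best_partners(scores: Mapping[tuple[str, str], float]) -> tuple[dict, dict]:
    """Best cross-species partner per gene; ties go to the lower lexicographic id."""
    best_a: dict[str, tuple[float, str]] = {}
    best_b: dict[str, tuple[float, str]] = {}
    for (a, b), s in scores.items():
        if a not in best_a or (s, _neg_lex(b)) > (best_a[a][0], _neg_lex(best_a[a][1])):
            best_a[a] = (s, b)
        if b not in best_b or (s, _neg_lex(a)) > (best_b[b][0], _neg_lex(best_b[b][1])):
            best_b[b] = (s, a)
    return best_a, best_b


class _neg_lex(str):
    """String wrapper whose ordering is reversed, for max() tie-breaks."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def reciprocal_best_pairs(
    hits: Sequence[SimilarityHit],
    species_a: str,
    species_b: str,
    require_both_directions: bool = False,
) -> list[tuple[str, str]]:
    """Reciprocal best hit pairs ``(gene_a, gene_b)`` between the two species.

    ``(a, b)`` is returned iff ``b`` is ``a``'s best cross-species hit and
    vice versa, equal scores broken toward the lower lexicographic partner.
    The result is sorted by ``gene_a`` and independent of input order.
    """
    scores = _cross_scores(hits, species_a, species_b, require_both_directions)
    best_a, best_b = _best_partners(scores)
    pairs = [
        (a, b)
        for a, (_, b) in best_a.items()
        if best_b.get(b, (None, None))[1] == a
    ]
    return sorted(pairs)


def build_clusters(
    pairs: Sequence[tuple[str, str]],
    hits: Sequence[SimilarityHit],
    params: HomologyParams,
    species_a: str = "",
    species_b: str = "",
) -> HomologClusterSet:
    """Seed one cluster per RBH pair, then attach in-paralogs.

    An unseeded gene ``g`` on species A's side joins the cluster seeded by
    ``(a, b)`` iff ``score(g, b) >= score(a, b)`` and ``b`` is ``g``'s best
    cross-species hit (mirror rule for species B).  A gene qualifying for
    several clusters goes to the one with the highest qualifying score (then
    lower lexicographic seed).  Every gene ends up in at most one cluster.
    """
    if not species_a or not species_b:
        species = sorted({h.query_species for h in hits} | {h.subject_species for h in hits})
        if len(species) == 2:
            species_a, species_b = species
    hits = filter_hits(hits, params)
    scores = _cross_scores(hits, species_a, species_b, require_both_directions=False)
    best_a, best_b = _best_partners(scores)

    seeded = {g for pair in pairs for g in pair}
    seed_score = {pair: scores.get(pair, 0.0) for pair in pairs}
    cluster_of_seed_a = {a: (a, b) for a, b in pairs}
    cluster_of_seed_b = {b: (a, b) for a, b in pairs}

    # candidate in-paralog attachments: (score, gene, seed_pair, species)
    candidates: list[tuple[float, str, tuple[str, str], str]] = []
    for gene, (s, partner) in best_a.items():
        if gene in seeded or partner not in cluster_of_seed_b:
            continue
        pair = cluster_of_seed_b[partner]
        if s >= seed_score[pair]:
            candidates.append((s, gene, pair, species_a))
    for gene, (s, partner) in best_b.items():
        if gene in seeded or partner not in cluster_of_seed_a:
            continue
        pair = cluster_of_seed_a[partner]
        if s >= seed_score[pair]:
            candidates.append((s, gene, pair, species_b))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    members: dict[tuple[str, str], list[tuple[str, str, bool]]] = {
        pair: [(pair[0], species_a, False), (pair[1], species_b, False)]
        for pair in pairs
    }
    assigned: set[str] = set(seeded)
    for s, gene, pair, species in candidates:
        if gene in assigned:
            continue
        assigned.add(gene)
        members[pair].append((gene, species, True))

    clusters = HomologClusterSet()
    for i, pair in enumerate(sorted(pairs)):
        clusters.add(
            HomologCluster(
                cluster_id=f"HC{i + 1:06d}",
                seed=pair,
                members=sorted(members[pair]),
            )
        )
    return clusters


def genes_to_clusters(
    genes: Iterable[str], clusters: HomologClusterSet
) -> tuple[set[str], int]:
    """Map a gene set into cluster-id space; count (and log) unmapped genes."""
    ids: set[str] = set()
    unmapped = 0
    for g in genes:
        cid = clusters.cluster_of(g)
        if cid is None:
            unmapped += 1
        else:
            ids.add(cid)
    if unmapped:
        logger.info("%d genes had no homolog cluster", unmapped)
    return ids, unmapped


def write_clusters_tsv(clusters: HomologClusterSet) -> str:
    lines = ["cluster_id\tgene_id\tspecies\tis_inparalog"]
    for cluster in clusters:
        for gene, species, is_inp in cluster.members:
            lines.append(f"{cluster.cluster_id}\t{gene}\t{species}\t{int(is_inp)}")
    return "\n".join(lines) + "\n"
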