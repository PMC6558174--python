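"""Stage overlap and uniqueness statistics, within and between species.

The central statistic is the approximate percent overlap between two stages'
identifier sets,

    % overlap = |A ∩ B| / ((|A| + |B|) / 2) × 100,

i.e. shared identifiers over the *average* set size.  Within a species the
identifiers are gene ids; between species each stage's gene set is first
converted to homolog-cluster-id space so that non-orthologous identifier
spaces become comparable.  A stage's *unique* genes are those annotated to no
other stage of the same species; the percent-unique values sit on the
diagonal of the overlap matrix.  All statistics operate on deduplicated
identifier sets, never raw annotation-record counts, and printed percents are
rounded half-up to two decimals.

The module also builds the contrast gene sets used for enrichment comparisons
of an early versus a late stage within one species (Sets 1/2) and of a
monocot-specific versus a dicot-specific stage across species via cluster
space (Sets 3A/3B and 4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

from .annotations import AnnotationTable, genes_for_stage
from .homology import HomologClusterSet, genes_to_clusters
from .ontology import StageGraph

__all__ = [
    "StageGeneMap",
    "OverlapMatrix",
    "ContrastSets",
    "round_percent",
    "percent_overlap",
    "unique_genes",
    "pairwise_overlap",
    "cross_species_overlap",
    "contrast_sets",
    "pooled_cluster_difference",
    "LOW_COUNT_THRESHOLD",
]

#: Stages with fewer distinct genes than this trigger a warning: percent
#: statistics on tiny sets are unstable (a stage with only 10 annotated genes
#: is best excluded from comparison outright).
LOW_COUNT_THRESHOLD = 50


def round_percent(value: float) -> float:
    """Round a percent to 2 decimals, half away from zero (as in printed tables)."""
    return float(
        Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


@dataclass
class StageGeneMap:
    """Per-stage distinct identifier sets for one species.

    ``id_space`` is ``"gene"`` for species-native gene/gene-model ids or
    ``"cluster"`` after conversion to homolog-cluster ids.
    """

    species: str
    id_space: str
    stages: dict[str, frozenset[str]]

    def __post_init__(self):
        if self.id_space not in ("gene", "cluster"):
            raise ValueError(f"id_space must be 'gene' or 'cluster', got {self.id_space!r}")
        self.stages = {s: frozenset(ids) for s, ids in self.stages.items()}

    @classmethod
    def from_annotations(
        cls,
        table: AnnotationTable,
        graph: StageGraph,
        stages: Iterable[str],
        species: str,
        propagate: bool = False,
    ) -> "StageGeneMap":
        return cls(
            species=species,
            id_space="gene",
            stages={
                s: frozenset(genes_for_stage(table, graph, s, propagate)) for s in stages
            },
        )

    def to_cluster_space(self, clusters: HomologClusterSet) -> "StageGeneMap":
        """Convert gene sets to cluster-id sets, dropping unclustered genes."""
        if self.id_space != "gene":
            raise ValueError("already in cluster space")
        converted = {}
        for stage, genes in self.stages.items():
            ids, _ = genes_to_clusters(genes, clusters)
            converted[stage] = frozenset(ids)
        return StageGeneMap(self.species, "cluster", converted)

    def pooled(self) -> frozenset[str]:
        return frozenset().union(*self.stages.values()) if self.stages else frozenset()

    def warn_low_counts(self, threshold: int = LOW_COUNT_THRESHOLD) -> list[str]:
        low = [s for s, ids in self.stages.items() if len(ids) < threshold]
        for s in low:
            warnings.warn(
                f"{self.species}/{s}: only {len(self.stages[s])} identifiers "
                f"(< {threshold}); percent statistics will be unstable",
                stacklevel=2,
            )
        return low


def percent_overlap(a: Iterable[str], b: Iterable[str]) -> float:
    """|A∩B| / mean(|A|, |B|) × 100.  Undefined (error) when both sets are empty."""
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("percent overlap of two empty sets is undefined")
    return len(a & b) / ((len(a) + len(b)) / 2) * 100.0


@dataclass
class UniqueStats:
    unique_ids: frozenset[str]
    count: int
    percent: float  # of the stage's set, rounded to 2 decimals


def unique_genes(stage_map: StageGeneMap) -> dict[str, UniqueStats]:
    """Identifiers occurring in exactly one stage of the map.

    For each stage s:  unique(s) = set(s) minus the union of every other
    stage's set; percent unique = |unique(s)| / |set(s)| × 100 (2 decimals).
    """
    if not stage_map.stages:
        raise ValueError("stage map has no stages")
    stage_map.warn_low_counts()
    out: dict[str, UniqueStats] = {}
    for stage, ids in stage_map.stages.items():
        others: set[str] = set()
        for other, other_ids in stage_map.stages.items():
            if other != stage:
                others |= other_ids
        unique = frozenset(ids - others)
        pct = round_percent(len(unique) / len(ids) * 100.0) if ids else 0.0
        out[stage] = UniqueStats(unique, len(unique), pct)
    return out


@dataclass
class OverlapMatrix:
    """Symmetric percent-overlap matrix with a percent-unique diagonal."""

    stages: list[str]
    percent: pd.DataFrame  # off-diagonal: percent overlap; diagonal: percent unique
    unique: dict[str, UniqueStats] = field(default_factory=dict)

    def to_tsv(self) -> str:
        formatted = self.percent.map(lambda v: f"{round_percent(v):.2f}")
        return formatted.to_csv(sep="\t", index_label="stage")


def pairwise_overlap(stage_map: StageGeneMap) -> OverlapMatrix:
    """All-pairs percent overlap within one species; diagonal from unique_genes."""
    stages = list(stage_map.stages)
    if len(stages) < 2:
        raise ValueError("pairwise overlap needs at least two stages")
    uniq = unique_genes(stage_map)
    mat = pd.DataFrame(0.0, index=stages, columns=stages)
    for i, s in enumerate(stages):
        mat.loc[s, s] = uniq[s].percent
        for t in stages[i + 1:]:
            val = percent_overlap(stage_map.stages[s], stage_map.stages[t])
            mat.loc[s, t] = val
            mat.loc[t, s] = val
    return OverlapMatrix(stages=stages, percent=mat, unique=uniq)


def cross_species_overlap(map_a: StageGeneMap, map_b: StageGeneMap) -> pd.DataFrame:
    """Stage-by-stage percent overlap between two species, in cluster space only."""
    for m in (map_a, map_b):
        if m.id_space != "cluster":
            raise ValueError(
                f"cross-species overlap requires cluster id space; "
                f"{m.species} map is in {m.id_space!r} space"
            )
    mat = pd.DataFrame(
        0.0, index=list(map_a.stages), columns=list(map_b.stages)
    )
    for s, ids_a in map_a.stages.items():
        for t, ids_b in map_b.stages.items():
            mat.loc[s, t] = percent_overlap(ids_a, ids_b)
    return mat


@dataclass
class ContrastSets:
    """The four enrichment contrast sets and their construction recipes.

    * set1 — species-A genes in the early stage but not the late stage;
    * set2 — species-A genes in the late stage but not the early stage;
    * set3a/set3b — clusters hit by species B's analogous stage but not by
      species A's, converted back to species-B / species-A gene ids;
    * set4 — all species-A genes of the cross-species reference stage.
    """

    set1: frozenset[str]
    set2: frozenset[str]
    set3a: frozenset[str]
    set3b: frozenset[str]
    set4: frozenset[str]
    recipes: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, frozenset[str]]:
        return {
            "set1": self.set1,
            "set2": self.set2,
            "set3a": self.set3a,
            "set3b": self.set3b,
            "set4": self.set4,
        }


def contrast_sets(
    map_a: StageGeneMap,
    map_b: StageGeneMap,
    clusters: HomologClusterSet,
    early_stage: str,
    late_stage: str,
    stage_a_cross: str,
    stage_b_cross: str,
) -> ContrastSets:
    """Build the within-species and cross-species contrast sets.

    ``map_a``/``map_b`` are gene-space maps for the two species;
    ``early_stage``/``late_stage`` are species-A stages for the within-species
    contrast; ``stage_a_cross``/``stage_b_cross`` are the analogous (but not
    homologous) stages of species A and B for the cluster-space contrast.
    """
    for m, needed in ((map_a, (early_stage, late_stage, stage_a_cross)),
                      (map_b, (stage_b_cross,))):
        for stage in needed:
            if stage not in m.stages:
                raise KeyError(f"stage {stage!r} not in {m.species} map")
    early = map_a.stages[early_stage]
    late = map_a.stages[late_stage]
    set1 = frozenset(early - late)
    set2 = frozenset(late - early)

    clusters_a, _ = genes_to_clusters(map_a.stages[stage_a_cross], clusters)
    clusters_b, _ = genes_to_clusters(map_b.stages[stage_b_cross], clusters)
    diff = clusters_b - clusters_a
    genes_by_species: dict[str, set[str]] = {map_a.species: set(), map_b.species: set()}
    for cluster in clusters:
        if cluster.cluster_id in diff:
            for gene, species, _ in cluster.members:
                if species in genes_by_species:
                    genes_by_species[species].add(gene)
    set3a = frozenset(genes_by_species[map_b.species])
    set3b = frozenset(genes_by_species[map_a.species])
    set4 = frozenset(map_a.stages[stage_a_cross])
    recipes = {
        "set1": f"{map_a.species}:{early_stage} \\ {map_a.species}:{late_stage} (gene space)",
        "set2": f"{map_a.species}:{late_stage} \\ {map_a.species}:{early_stage} (gene space)",
        "set3a": (
            f"clusters({map_b.species}:{stage_b_cross}) \\ "
            f"clusters({map_a.species}:{stage_a_cross}) -> {map_b.species} gene ids"
        ),
        "set3b": (
            f"clusters({map_b.species}:{stage_b_cross}) \\ "
            f"clusters({map_a.species}:{stage_a_cross}) -> {map_a.species} gene ids"
        ),
        "set4": f"{map_a.species}:{stage_a_cross} (all genes)",
    }
    return ContrastSets(set1, set2, set3a, set3b, set4, recipes)


def pooled_cluster_difference(
    map_a: StageGeneMap, map_b: StageGeneMap
) -> tuple[int, int, int]:
    """(|pooled A|, |pooled B|, |pooled A \\ pooled B|) over all stages, cluster space."""
    for m in (map_a, map_b):
        if m.id_space != "cluster":
            raise ValueError("pooled cluster difference requires cluster id space")
    pooled_a, pooled_b = map_a.pooled(), map_b.pooled()
    return len(pooled_a), len(pooled_b), len(pooled_a - pooled_b)
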