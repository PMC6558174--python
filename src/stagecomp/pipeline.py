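"""End-to-end workflow orchestration: config, run reports, within/between runs.

The two-part workflow compares stage-annotated gene sets either *within* one
species (gene space: overlap matrix, unique-gene lists, early-vs-late
contrast sets, optional enrichment of the contrasts) or *between* two species
(cluster space: reciprocal-best-hit clustering of a similarity table,
conversion of the stage maps, cross-species overlap matrix, stage-difference
contrast gene lists in both species' id conventions).  A run is driven by a
YAML config, writes TSV outputs plus a JSON manifest with SHA-256 checksums,
and is deterministic given the same inputs and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotations as ann
from . import compare, enrichment, homology
from . import ontology as onto

logger = logging.getLogger(__name__)

__all__ = ["WorkflowConfig", "RunReport", "run_within_species", "run_between_species"]


@dataclass
class WorkflowConfig:
    """Paths, parameters, and stage lists for a workflow run.

    ``assoc`` maps species label → GAF path; ``stages`` maps species label →
    stage term ids; ``species_prefix`` maps a gene-id prefix to its species
    (used to label similarity hits).  ``contrasts`` holds the four stage roles
    for contrast-set construction: ``early``/``late`` (within species A) and
    ``cross_a``/``cross_b`` (the analogous stages of species A and B).
    """

    ontology: str
    assoc: dict[str, str]
    stages: dict[str, list[str]]
    species_pair: list[str]
    outdir: str
    similarity: str | None = None
    species_prefix: dict[str, str] = field(default_factory=dict)
    background_map: str | None = None
    contrasts: dict[str, str] = field(default_factory=dict)
    evidence_codes: list[str] = field(default_factory=lambda: ["IEP", "IDA"])
    min_overlap_frac: float = 0.50
    min_mapped: int = 5
    alpha: float = 0.05
    propagate: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def check_paths(self) -> None:
        paths = [self.ontology, *self.assoc.values()]
        for p in (self.similarity, self.background_map):
            if p:
                paths.append(p)
        missing = [p for p in paths if not Path(p).is_file()]
        if missing:
            raise FileNotFoundError(f"config references missing files: {missing}")

    def species_of(self, gene_id: str) -> str:
        for prefix, species in sorted(
            self.species_prefix.items(), key=lambda kv: -len(kv[0])
        ):
            if gene_id.startswith(prefix):
                return species
        raise KeyError(f"no species prefix matches gene id {gene_id!r}")


@dataclass
class RunReport:
    counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    manifest: dict[str, str] = field(default_factory=dict)  # filename -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _write(outdir: Path, name: str, text: str, report: RunReport) -> Path:
    path = outdir / name
    path.write_text(text)
    report.manifest[name] = hashlib.sha256(text.encode()).hexdigest()
    return path


def _load_stage_map(
    config: WorkflowConfig, species: str, graph: onto.StageGraph
) -> tuple[compare.StageGeneMap, RunReport]:
    report = RunReport()
    with open(config.assoc[species]) as fh:
        table = ann.read_assoc(fh)
    report.counts[f"{species}_records_read"] = len(table)
    report.counts[f"{species}_records_rejected"] = len(table.rejects)
    filtered = ann.filter_evidence(
        table, ann.FilterParams(frozenset(config.evidence_codes))
    )
    report.counts[f"{species}_records_after_evidence_filter"] = len(filtered)
    stages = config.stages[species]
    for stage in stages:
        if not filtered.by_term(stage) and not config.propagate:
            raise ValueError(f"no annotations for stage {stage!r} in {species}")
    stage_map = compare.StageGeneMap.from_annotations(
        filtered, graph, stages, species=species, propagate=config.propagate
    )
    for stage, ids in stage_map.stages.items():
        report.counts[f"{species}_genes_{stage}"] = len(ids)
    return stage_map, report


def _merge(into: RunReport, other: RunReport) -> None:
    into.counts.update(other.counts)
    into.warnings.extend(other.warnings)
    into.manifest.update(other.manifest)


def _enrich_and_write(
    outdir: Path,
    label: str,
    study: set[str],
    background: dict[str, set[str]],
    config: WorkflowConfig,
    report: RunReport,
) -> None:
    population = set(background)
    usable = study & population
    if not usable:
        report.warnings.append(f"{label}: no study genes in background; skipped")
        return
    params = enrichment.EnrichmentParams(
        min_mapped=config.min_mapped, alpha=config.alpha
    )
    results = enrichment.fisher_enrichment(usable, population, background, params)
    report.counts[f"{label}_terms_tested"] = len(results)
    report.counts[f"{label}_terms_significant"] = sum(r.significant for r in results)
    _write(outdir, f"enrichment_{label}.tsv", enrichment.results_to_tsv(results), report)


def run_within_species(config: WorkflowConfig, species: str | None = None) -> RunReport:
    """Gene-space comparison of all configured stages of one species.

    Writes the overlap matrix, per-stage unique-gene lists, the early/late
    contrast gene lists, and (when a background map is configured) enrichment
    tables for the two contrast sets.
    """
    config.check_paths()
    species = species or config.species_pair[0]
    if len(config.stages[species]) < 2:
        raise ValueError(f"within-species comparison needs >= 2 stages for {species}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(config.ontology) as fh:
        graph = onto.parse_obo(fh)
    report = RunReport()
    stage_map, load_report = _load_stage_map(config, species, graph)
    _merge(report, load_report)

    matrix = compare.pairwise_overlap(stage_map)
    _write(outdir, f"overlap_{species}.tsv", matrix.to_tsv(), report)
    uniq_lines = ["stage\ttotal\tunique_count\tpercent_unique"]
    for stage, stats in matrix.unique.items():
        uniq_lines.append(
            f"{stage}\t{len(stage_map.stages[stage])}\t{stats.count}\t{stats.percent:.2f}"
        )
        _write(
            outdir,
            f"unique_{species}_{stage.replace(':', '_')}.txt",
            "\n".join(sorted(stats.unique_ids)) + "\n",
            report,
        )
    _write(outdir, f"unique_{species}.tsv", "\n".join(uniq_lines) + "\n", report)

    early, late = config.contrasts.get("early"), config.contrasts.get("late")
    if early and late:
        set1 = stage_map.stages[early] - stage_map.stages[late]
        set2 = stage_map.stages[late] - stage_map.stages[early]
        _write(outdir, "set1.txt", "\n".join(sorted(set1)) + "\n", report)
        _write(outdir, "set2.txt", "\n".join(sorted(set2)) + "\n", report)
        report.counts["set1_genes"] = len(set1)
        report.counts["set2_genes"] = len(set2)
        if config.background_map:
            with open(config.background_map) as fh:
                background = enrichment.read_gene_terms_tsv(fh)
            _enrich_and_write(outdir, "set1", set1, background, config, report)
            _enrich_and_write(outdir, "set2", set2, background, config, report)
    _write(outdir, "report_within.json", report.to_json(), report)
    return report


def run_between_species(config: WorkflowConfig) -> RunReport:
    """Cluster-space comparison of the two configured species.

    Builds homolog clusters from the similarity table, converts each species'
    stage map to cluster ids, and writes the cross-species overlap matrix,
    the pooled cluster difference, and the Set-3-style contrast gene lists in
    both species' id conventions plus the Set-4 reference list.
    """
    config.check_paths()
    if not config.similarity:
        raise ValueError("between-species comparison requires a similarity table")
    sp_a, sp_b = config.species_pair
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(config.ontology) as fh:
        graph = onto.parse_obo(fh)
    report = RunReport()
    map_a, rep_a = _load_stage_map(config, sp_a, graph)
    map_b, rep_b = _load_stage_map(config, sp_b, graph)
    _merge(report, rep_a)
    _merge(report, rep_b)

    with open(config.similarity) as fh:
        hits = homology.read_hits_tsv(fh, config.species_of)
    params = homology.HomologyParams(min_overlap_frac=config.min_overlap_frac)
    kept = homology.filter_hits(hits, params)
    pairs = homology.reciprocal_best_pairs(kept, sp_a, sp_b)
    clusters = homology.build_clusters(pairs, kept, params, sp_a, sp_b)
    report.counts["similarity_hits_read"] = len(hits)
    report.counts["similarity_hits_after_overlap_filter"] = len(kept)
    report.counts["reciprocal_best_pairs"] = len(pairs)
    report.counts["clusters_built"] = len(clusters)
    _write(outdir, "clusters.tsv", homology.write_clusters_tsv(clusters), report)

    cmap_a = map_a.to_cluster_space(clusters)
    cmap_b = map_b.to_cluster_space(clusters)
    matrix = compare.cross_species_overlap(cmap_a, cmap_b)
    _write(
        outdir,
        "cross_species_overlap.tsv",
        matrix.map(lambda v: f"{compare.round_percent(v):.2f}").to_csv(
            sep="\t", index_label=f"{sp_a}\\{sp_b}"
        ),
        report,
    )
    size_a, size_b, diff = compare.pooled_cluster_difference(cmap_a, cmap_b)
    _write(
        outdir,
        "pooled_clusters.tsv",
        "species_a_clusters\tspecies_b_clusters\ta_not_b\n"
        f"{size_a}\t{size_b}\t{diff}\n",
        report,
    )

    c = config.contrasts
    if {"early", "late", "cross_a", "cross_b"} <= set(c):
        sets = compare.contrast_sets(
            map_a, map_b, clusters, c["early"], c["late"], c["cross_a"], c["cross_b"]
        )
        for name, ids in sets.as_dict().items():
            _write(outdir, f"{name}.txt", "\n".join(sorted(ids)) + "\n", report)
            report.counts[f"{name}_genes"] = len(ids)
        _write(
            outdir,
            "contrast_recipes.tsv",
            "set\trecipe\n"
            + "\n".join(f"{k}\t{v}" for k, v in sets.recipes.items())
            + "\n",
            report,
        )
    _write(outdir, "report_between.json", report.to_json(), report)
    return report
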