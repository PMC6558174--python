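"""Seeded synthetic fixtures with the statistical structure the workflow assumes.

Real stage-annotation data have three structural features this package's
statistics depend on: (i) very high between-stage overlap of annotated gene
sets (roughly 86–98%) with small stage-unique fractions, (ii) cross-species
ortholog pairs recoverable as reciprocal best hits against a background of
weaker noise similarity, and (iii) functional terms over-represented in a
study set at some fold relative to a background.  Each generator here plants
exactly one of those features with a known ground truth, serialized alongside
the fixture, so every pipeline stage can be tested end to end without any
download.

Determinism: a single integer seed plus a per-generator stream id feed
``numpy.random.default_rng``; identical ``(params, seed)`` reproduce fixtures
byte-identically.

What these fixtures do *not* emulate: expression levels or microarray noise
(annotations are presence/absence only), inter-annotator evidence biases, and
real sequence-similarity score distributions — scores are drawn from bands
chosen so the reciprocal-best-hit margin holds by construction, making
recovery tests deterministic in outcome though stochastic in values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotations import AnnotationRecord, AnnotationTable
from .homology import SimilarityHit
from .ontology import StageGraph, TermRecord

__all__ = [
    "FixtureTruth",
    "make_stage_ontology",
    "make_annotation_table",
    "make_similarity_fixture",
    "make_enrichment_fixture",
    "make_workflow_fixture",
    "make_stage_map_counts",
    "EVIDENCE_PROPORTIONS",
]

#: Fixed evidence-code proportions for generated annotation records: mostly
#: expression-pattern evidence, some direct assay, a minority electronic.
EVIDENCE_PROPORTIONS = (("IEP", 0.60), ("IDA", 0.25), ("IEA", 0.15))

_STREAMS = {
    "ontology": 11,
    "annotations": 23,
    "similarity": 37,
    "enrichment": 53,
    "workflow": 71,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class FixtureTruth:
    """Ground truth planted in a fixture, serializable next to it."""

    seed: int
    params: dict = field(default_factory=dict)
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    inparalogs: list[tuple[str, str, str]] = field(default_factory=list)  # (gene, seed_a, seed_b)
    enriched_terms: dict[str, float] = field(default_factory=dict)  # term -> fold
    shared_fraction: float | None = None
    stage_genes: dict[str, list[str]] = field(default_factory=dict)
    study_genes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def make_stage_ontology(n_stages: int, n_groups: int = 1, seed: int = 0) -> StageGraph:
    """A valid stage ontology: a precedes chain of leaves under is_a groups.

    ``n_stages`` leaf stages form a linear temporal chain (each precedes the
    next; inverses materialized).  Leaves are partitioned contiguously into
    ``n_groups`` grouping stages, which are subclasses of a single root.  The
    construction is acyclic by design and passes structural validation with
    an empty report.  ``seed`` is accepted for interface uniformity; the
    layout is fully determined by the sizes.
    """
    if n_stages < 1 or n_groups < 1 or n_groups > n_stages:
        raise ValueError("need 1 <= n_groups <= n_stages")
    graph = StageGraph()
    root = "PO:0000001"
    graph.add_term(TermRecord(root, name="whole plant development stage"))
    group_ids = []
    for g in range(n_groups):
        gid = f"PO:{1000 + g:07d}"
        group_ids.append(gid)
        graph.add_term(TermRecord(gid, name=f"stage group {g + 1}"))
        graph.add_edge(gid, "is_a", root)
    leaf_ids = []
    for i in range(n_stages):
        lid = f"PO:{2000 + i:07d}"
        leaf_ids.append(lid)
        graph.add_term(TermRecord(lid, name=f"development stage {i + 1:03d}"))
        graph.add_edge(lid, "is_a", group_ids[i * n_groups // n_stages])
    for a, b in zip(leaf_ids, leaf_ids[1:]):
        graph.add_edge(a, "precedes", b)
    graph.complete_inverses()
    graph.header = "format-version: 1.2\nontology: synthetic-stage-fixture"
    return graph


def make_annotation_table(
    genes_per_stage: int,
    shared_frac: float,
    seed: int = 0,
    n_stages: int = 4,
    stage_ids: Sequence[str] | None = None,
    species: str = "ath",
    source: str = "SYNDB",
    taxon: str = "taxon:0000001",
) -> tuple[AnnotationTable, FixtureTruth]:
    """Annotation table with a controlled shared/unique gene structure.

    A core pool of ``round(shared_frac * genes_per_stage)`` genes is annotated
    to every stage; the remaining genes of each stage are stage-specific, so
    each pair of stages overlaps by ``shared_frac`` of the average stage size.
    One record per gene per stage, with evidence codes drawn from
    :data:`EVIDENCE_PROPORTIONS`.
    """
    if not 0.0 <= shared_frac <= 1.0:
        raise ValueError("shared_frac must be in [0, 1]")
    if genes_per_stage < 1 or n_stages < 1:
        raise ValueError("sizes must be positive")
    rng = _rng(seed, "annotations")
    if stage_ids is None:
        stage_ids = [f"PO:{2000 + i:07d}" for i in range(n_stages)]
    stage_ids = list(stage_ids)
    n_core = round(shared_frac * genes_per_stage)
    core = [f"{species}_core{i:05d}" for i in range(n_core)]
    codes, probs = zip(*EVIDENCE_PROPORTIONS)
    table = AnnotationTable()
    truth = FixtureTruth(
        seed=seed,
        params={
            "genes_per_stage": genes_per_stage,
            "shared_frac": shared_frac,
            "n_stages": len(stage_ids),
        },
        shared_fraction=shared_frac,
    )
    for s_idx, stage in enumerate(stage_ids):
        unique = [
            f"{species}_s{s_idx:02d}u{i:05d}" for i in range(genes_per_stage - n_core)
        ]
        genes = core + unique
        evidence = rng.choice(codes, size=len(genes), p=probs)
        for gene, ev in zip(genes, evidence):
            table.records.append(
                AnnotationRecord(
                    source_db=source,
                    object_id=gene,
                    object_symbol=gene,
                    term_id=stage,
                    evidence_code=str(ev),
                    reference="SYN:0000001",
                    taxon=taxon,
                    date="20171101",
                )
            )
        truth.stage_genes[stage] = genes
    return table, truth


def make_similarity_fixture(
    n_pairs: int,
    n_inparalogs: int = 0,
    n_noise: int = 0,
    seed: int = 0,
    species: tuple[str, str] = ("ath", "zma"),
) -> tuple[list[SimilarityHit], FixtureTruth]:
    """Similarity hits with planted ortholog pairs, in-paralogs, and noise.

    Planted pair i links ``{A}_g{i}`` and ``{B}_g{i}`` with a bit score drawn
    from [200, 400] reported in both directions at full mutual coverage.  An
    in-paralog is an extra same-species gene hitting its seed's cross-species
    partner at exactly the seed score (with an identifier sorting after the
    seed gene's), so it attaches under the inclusive in-paralog rule while
    the lexicographic tie-break keeps the planted pair as the reciprocal best
    hit.  Noise hits score in [40, 120]; half (rounded up) additionally fail
    the 0.50 mutual-overlap rule, and every noise hit that could pass the
    filter has a planted gene on each side, so the margin guarantee holds:
    no noise hit can displace a planted best hit or create a spurious
    reciprocal pair.
    """
    if min(n_pairs, n_inparalogs, n_noise) < 0:
        raise ValueError("sizes must be >= 0")
    if n_inparalogs > 0 and n_pairs == 0:
        raise ValueError("in-paralogs need at least one planted pair")
    rng = _rng(seed, "similarity")
    sp_a, sp_b = species
    hits: list[SimilarityHit] = []
    truth = FixtureTruth(
        seed=seed,
        params={"n_pairs": n_pairs, "n_inparalogs": n_inparalogs, "n_noise": n_noise},
    )

    def both_directions(ga, gb, score, frac_a, frac_b):
        hits.append(SimilarityHit(ga, gb, sp_a, sp_b, score, frac_a, frac_b))
        hits.append(SimilarityHit(gb, ga, sp_b, sp_a, score, frac_b, frac_a))

    pair_score = {}
    for i in range(n_pairs):
        ga, gb = f"{sp_a}_g{i:04d}", f"{sp_b}_g{i:04d}"
        score = float(rng.uniform(200.0, 400.0))
        pair_score[i] = score
        fa, fb = rng.uniform(0.6, 1.0, size=2)
        both_directions(ga, gb, score, float(fa), float(fb))
        truth.ortholog_pairs.append((ga, gb))

    for j in range(n_inparalogs):
        i = int(rng.integers(n_pairs))
        host_a = bool(rng.integers(2))  # paralog on species A's side or B's
        seed_a, seed_b = f"{sp_a}_g{i:04d}", f"{sp_b}_g{i:04d}"
        if host_a:
            gene, partner = f"{sp_a}_p{j:04d}", seed_b
            hits.append(
                SimilarityHit(gene, partner, sp_a, sp_b, pair_score[i],
                              float(rng.uniform(0.6, 1.0)), float(rng.uniform(0.6, 1.0)))
            )
        else:
            gene, partner = f"{sp_b}_p{j:04d}", seed_a
            hits.append(
                SimilarityHit(gene, partner, sp_b, sp_a, pair_score[i],
                              float(rng.uniform(0.6, 1.0)), float(rng.uniform(0.6, 1.0)))
            )
        truth.inparalogs.append((gene, seed_a, seed_b))

    for j in range(n_noise):
        score = float(rng.uniform(40.0, 120.0))
        sub_threshold = j % 2 == 0  # half fail the overlap rule outright
        if sub_threshold:
            # overlap-failing noise may connect any two genes
            ga = f"{sp_a}_n{j:04d}" if rng.integers(2) else f"{sp_a}_g{int(rng.integers(max(n_pairs, 1))):04d}"
            gb = f"{sp_b}_n{j:04d}"
            frac_a, frac_b = float(rng.uniform(0.05, 0.49)), float(rng.uniform(0.3, 1.0))
            hits.append(SimilarityHit(ga, gb, sp_a, sp_b, score, frac_a, frac_b))
        else:
            # filter-passing noise always touches planted genes on both sides
            if n_pairs < 2:
                continue
            i1, i2 = rng.choice(n_pairs, size=2, replace=False)
            ga, gb = f"{sp_a}_g{int(i1):04d}", f"{sp_b}_g{int(i2):04d}"
            frac_a, frac_b = rng.uniform(0.5, 1.0, size=2)
            hits.append(
                SimilarityHit(ga, gb, sp_a, sp_b, score, float(frac_a), float(frac_b))
            )
    return hits, truth


def make_enrichment_fixture(
    n_genes: int,
    n_terms: int,
    enriched_term: str | None = None,
    fold: float = 5.0,
    study_size: int = 200,
    seed: int = 0,
    background_freq: float = 0.05,
) -> tuple[dict[str, set[str]], set[str], FixtureTruth]:
    """Background gene→terms map plus a study set with one term at ``fold`` enrichment.

    Every term independently annotates each background gene with probability
    ``background_freq``.  The study is drawn so genes carrying the enriched
    term appear at ``fold × background_freq`` (binomially sampled carrier
    count, genes chosen without replacement).  ``fold=1`` plants no signal.
    """
    if fold < 1.0:
        raise ValueError("fold must be >= 1")
    if not 0.0 < background_freq < 1.0 or fold * background_freq > 1.0:
        raise ValueError("need 0 < background_freq and fold*background_freq <= 1")
    if study_size > n_genes:
        raise ValueError("study_size cannot exceed n_genes")
    rng = _rng(seed, "enrichment")
    genes = [f"g{i:05d}" for i in range(n_genes)]
    terms = [f"GO:{t + 1:07d}" for t in range(n_terms)]
    if enriched_term is None:
        enriched_term = terms[0]
    if enriched_term not in terms:
        raise ValueError(f"enriched term {enriched_term!r} not among generated terms")

    carrier_matrix = rng.random((n_genes, n_terms)) < background_freq
    gene_terms = {
        g: {terms[t] for t in np.flatnonzero(carrier_matrix[i])}
        for i, g in enumerate(genes)
    }

    e_idx = terms.index(enriched_term)
    carriers = [genes[i] for i in np.flatnonzero(carrier_matrix[:, e_idx])]
    non_carriers = [genes[i] for i in np.flatnonzero(~carrier_matrix[:, e_idx])]
    target_freq = min(fold * background_freq, 1.0)
    n_carriers = int(rng.binomial(study_size, target_freq))
    n_carriers = min(n_carriers, len(carriers))
    n_rest = min(study_size - n_carriers, len(non_carriers))
    study = set(rng.choice(carriers, size=n_carriers, replace=False)) | set(
        rng.choice(non_carriers, size=n_rest, replace=False)
    )
    truth = FixtureTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_terms": n_terms,
            "fold": fold,
            "study_size": study_size,
            "background_freq": background_freq,
        },
        enriched_terms={enriched_term: fold} if fold > 1.0 else {},
        study_genes=sorted(study),
    )
    return gene_terms, study, truth


def make_workflow_fixture(
    outdir,
    seed: int = 0,
    n_pairs: int = 60,
    n_inparalogs: int = 8,
    n_noise: int = 40,
    stages_a: int = 4,
    stages_b: int = 3,
    shared_frac: float = 0.90,
    species: tuple[str, str] = ("ath", "zma"),
) -> dict:
    """Write a coherent fixture directory for a full two-species workflow run.

    The two species' annotation tables draw their gene pools from the planted
    similarity genes (so cluster-space conversion is non-trivial), each stage
    shares ``shared_frac`` of its genes with every other stage of the same
    species, and a background gene→term map over species A's pool allows the
    enrichment step to run.  Files written: ``ontology.obo``,
    ``annotations_{a,b}.assoc``, ``similarity.tsv``, ``background.tsv``,
    ``config.yaml``, ``truth.json``.  Returns the config as a dict.
    """
    import yaml

    from .annotations import write_assoc
    from .ontology import write_obo

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp_a, sp_b = species
    rng = _rng(seed, "workflow")
    n_stage_terms = max(stages_a, stages_b)
    graph = make_stage_ontology(n_stage_terms, n_groups=min(2, n_stage_terms), seed=seed)
    (outdir / "ontology.obo").write_text(write_obo(graph))

    hits, sim_truth = make_similarity_fixture(
        n_pairs, n_inparalogs, n_noise, seed=seed, species=species
    )
    lines = ["qseqid\tsseqid\tbitscore\tqcovfrac\tscovfrac"]
    lines += [
        f"{h.query_id}\t{h.subject_id}\t{h.score:.2f}"
        f"\t{h.query_aln_frac:.4f}\t{h.subject_aln_frac:.4f}"
        for h in hits
    ]
    (outdir / "similarity.tsv").write_text("\n".join(lines) + "\n")

    stage_ids = [f"PO:{2000 + i:07d}" for i in range(n_stage_terms)]
    truth = FixtureTruth(
        seed=seed,
        params={"n_pairs": n_pairs, "stages_a": stages_a, "stages_b": stages_b,
                "shared_frac": shared_frac},
        ortholog_pairs=sim_truth.ortholog_pairs,
        inparalogs=sim_truth.inparalogs,
        shared_fraction=shared_frac,
    )

    def stage_sets(sp: str, planted: list[str], n_stages: int) -> dict[str, list[str]]:
        pool = planted + [f"{sp}_x{i:04d}" for i in range(n_pairs // 2)]
        order = [pool[i] for i in rng.permutation(len(pool))]
        n_core = round(shared_frac * len(order) * 0.8)
        core, rest = order[:n_core], order[n_core:]
        per_stage = max(1, len(rest) // n_stages)
        out = {}
        for j in range(n_stages):
            uniq = rest[j * per_stage:(j + 1) * per_stage]
            out[stage_ids[j]] = core + uniq
        return out

    planted_a = [a for a, _ in sim_truth.ortholog_pairs]
    planted_b = [b for _, b in sim_truth.ortholog_pairs]
    taxa = {sp_a: "taxon:0000001", sp_b: "taxon:0000002"}
    assoc_paths = {}
    for sp, planted, n_stages, fname in (
        (sp_a, planted_a, stages_a, "annotations_a.assoc"),
        (sp_b, planted_b, stages_b, "annotations_b.assoc"),
    ):
        sets = stage_sets(sp, planted, n_stages)
        truth.stage_genes.update({f"{sp}:{k}": sorted(v) for k, v in sets.items()})
        table = AnnotationTable()
        codes, probs = zip(*EVIDENCE_PROPORTIONS)
        for stage, genes in sets.items():
            evidence = rng.choice(codes, size=len(genes), p=probs)
            for gene, ev in zip(genes, evidence):
                table.records.append(
                    AnnotationRecord(
                        source_db="SYNDB", object_id=gene, object_symbol=gene,
                        term_id=stage, evidence_code=str(ev),
                        reference="SYN:0000001", taxon=taxa[sp], date="20171101",
                    )
                )
        (outdir / fname).write_text(write_assoc(table))
        assoc_paths[sp] = str(outdir / fname)

    terms = [f"GO:{t + 1:07d}" for t in range(10)]
    bg_lines = []
    pool_a = sorted({g for k, v in truth.stage_genes.items() if k.startswith(sp_a) for g in v})
    for g in pool_a:
        for t in np.flatnonzero(rng.random(len(terms)) < 0.1):
            bg_lines.append(f"{g}\t{terms[t]}")
    (outdir / "background.tsv").write_text("\n".join(bg_lines) + "\n")

    config = {
        "ontology": str(outdir / "ontology.obo"),
        "assoc": assoc_paths,
        "stages": {sp_a: stage_ids[:stages_a], sp_b: stage_ids[:stages_b]},
        "species_pair": [sp_a, sp_b],
        "outdir": str(outdir / "results"),
        "similarity": str(outdir / "similarity.tsv"),
        "species_prefix": {sp_a: sp_a, sp_b: sp_b},
        "background_map": str(outdir / "background.tsv"),
        "contrasts": {
            "early": stage_ids[0],
            "late": stage_ids[stages_a - 1],
            "cross_a": stage_ids[stages_a - 1],
            "cross_b": stage_ids[stages_b - 1],
        },
        "seed": seed,
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    (outdir / "truth.json").write_text(truth.to_json())
    return config


def make_stage_map_counts(
    totals: dict[str, int],
    uniques: dict[str, int],
    species: str = "sp",
    id_space: str = "gene",
):
    """Stage map with exact per-stage totals and stage-unique counts.

    Emulates the set structure behind published per-stage summary tables:
    each stage s receives ``uniques[s]`` identifiers of its own plus
    ``totals[s] - uniques[s]`` identifiers from a shared pool, laid out as a
    contiguous block on a circular pool so that every shared identifier lands
    in at least two stages (otherwise it would leak into the unique counts;
    infeasible inputs raise ``ValueError``).  ``unique_genes`` on the result
    returns exactly the planted counts, so percent-unique values follow from
    the totals alone.
    """
    from .compare import StageGeneMap

    stages = list(totals)
    if set(uniques) != set(totals):
        raise ValueError("totals and uniques must cover the same stages")
    shared_sizes = {}
    for s in stages:
        if not 0 <= uniques[s] <= totals[s]:
            raise ValueError(f"need 0 <= unique <= total for stage {s!r}")
        shared_sizes[s] = totals[s] - uniques[s]
    pool_size = max(shared_sizes.values(), default=0)
    if len(stages) == 1 and pool_size > 0:
        raise ValueError("a single-stage map cannot have shared identifiers")
    pool = [f"{species}_shared{i:06d}" for i in range(pool_size)]
    coverage = [0] * pool_size
    sets = {}
    for idx, s in enumerate(stages):
        offset = round(idx * pool_size / len(stages))
        block = [pool[(offset + i) % pool_size] for i in range(shared_sizes[s])]
        for i in range(shared_sizes[s]):
            coverage[(offset + i) % pool_size] += 1
        own = [f"{species}_{idx:02d}u{i:06d}" for i in range(uniques[s])]
        sets[s] = frozenset(block) | frozenset(own)
    if any(c == 1 for c in coverage):
        raise ValueError(
            "requested counts leave some shared identifiers in a single stage; "
            "unique counts would not be reproduced"
        )
    return StageGeneMap(species=species, id_space=id_space, stages=sets)
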