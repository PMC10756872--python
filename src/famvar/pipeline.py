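"""End-to-end orchestration: association -> impact -> ontology ->
segregation, followed by tolerance/conservation annotation and
PPI-expanded enrichment, with deterministic report tables and a
machine-readable run summary."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import pandas as pd
import yaml
from Bio.Align import MultipleSeqAlignment

from . import association as assoc
from . import enrichment as enr
from . import impact_annotation as impann
from . import segregation as seg
from . import variant_filter as vf
from .io_formats import variant_sort_key, write_report
from .types import Cohort, CohortError, ConservationAssessment, GeneSetTerm

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every numeric gate of the pipeline, at its published default."""

    alpha: float = 0.05              # association screen, p < alpha
    maf_threshold: float = 0.1       # MODERATE rescue: ASN MAF strictly below
    ppi_min_score: int = 700         # STRING-style combined-score confidence
    padj_threshold: float = 0.01     # enrichment significance on adjusted p
    min_support: int = 1             # segregation support threshold
    conservation_threshold: float = 0.8
    adjust_method: str = "fdr_bh"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise CohortError("alpha must be in (0, 1)")
        if not 0 <= self.maf_threshold <= 1:
            raise CohortError("maf_threshold must be in [0, 1]")
        if not 0 <= self.ppi_min_score <= 1000:
            raise CohortError("ppi_min_score must be in 0-1000")
        if not 0 < self.padj_threshold < 1:
            raise CohortError("padj_threshold must be in (0, 1)")
        if self.min_support < 1:
            raise CohortError("min_support must be >= 1")
        if not 0 <= self.conservation_threshold <= 1:
            raise CohortError("conservation_threshold must be in [0, 1]")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in mapping.items() if k in known})


@dataclass
class PipelineResult:
    subgroups: list
    association_pass: dict[str, bool]
    association_results: list
    segregation_pass: dict[str, bool]
    segregation_results: list
    retained: list
    traces: dict
    constraint_flags: dict[str, bool] = field(default_factory=dict)
    conservation: list[ConservationAssessment] = field(default_factory=list)
    expanded_query: set[str] = field(default_factory=set)
    enrichment: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def run_pipeline(
    cohort: Cohort,
    gene_lists: Mapping[str, set[str]],
    config: PipelineConfig = PipelineConfig(),
    terms: Optional[Sequence[GeneSetTerm]] = None,
    ppi: Optional[nx.Graph] = None,
    loeuf: Optional[Mapping[str, float]] = None,
    alignments: Optional[Mapping[str, MultipleSeqAlignment]] = None,
    conservation_sites: Optional[Mapping[str, tuple[int, str]]] = None,
    human_id: str = "Homo_sapiens",
) -> PipelineResult:
    """Run every stage on an assembled cohort.

    Enrichment runs only when a term collection is provided; tolerance and
    conservation annotation only when their resources are provided.
    """
    log.info(
        "thresholds: alpha=%s maf_threshold=%s ppi_min_score=%s padj_threshold=%s "
        "min_support=%s conservation_threshold=%s",
        config.alpha, config.maf_threshold, config.ppi_min_score,
        config.padj_threshold, config.min_support, config.conservation_threshold,
    )
    subgroups = assoc.assign_subgroups(cohort.pedigree)
    association_pass, association_results = assoc.associate(cohort, subgroups, alpha=config.alpha)
    segregation_pass, segregation_results = seg.segregate(
        cohort, subgroups, min_support=config.min_support
    )
    constraint_flags: dict[str, bool] = {}
    if loeuf is not None:
        cohort.variants, constraint_flags = impann.annotate_tolerance(cohort.variants, loeuf)
    retained, traces = vf.run_cascade(
        cohort, association_pass, gene_lists, segregation_pass,
        maf_threshold=config.maf_threshold,
    )
    for key, trace in traces.items():
        log.debug("trace %s: %s", key,
                  "; ".join(f"{s.stage}={s.decision}({s.reason})" for s in trace.stages))

    conservation: list[ConservationAssessment] = []
    if alignments and conservation_sites:
        for gene in sorted(conservation_sites):
            if gene not in alignments:
                continue
            pos, _res = conservation_sites[gene]
            conservation.append(
                impann.conservation_score(
                    alignments[gene], human_id, pos, gene=gene,
                    threshold=config.conservation_threshold,
                )
            )

    expanded: set[str] = set()
    enrichment_results: list = []
    if terms:
        query = sorted({v.gene.upper() for v in retained})
        expanded = enr.expand_gene_set(query, ppi)
        enrichment_results = enr.enrich(
            expanded, list(terms), padj_threshold=config.padj_threshold,
            method=config.adjust_method,
        )

    # stage pass counts evaluated independently (cascade short-circuiting
    # must not change these or the retention set)
    n = len(cohort.variants)
    impact_pass = sum(
        1 for v in cohort.variants if vf.impact_gate(v, config.maf_threshold)[0] == "pass"
    )
    ontology_pass = sum(
        1 for v in cohort.variants if vf.ontology_gate(v, gene_lists)[0] == "pass"
    )
    summary = {
        "n_variants": n,
        "n_subgroups": len(subgroups),
        "pass_association": sum(association_pass.values()),
        "pass_impact": impact_pass,
        "pass_ontology": ontology_pass,
        "pass_segregation": sum(segregation_pass.values()),
        "n_retained": len(retained),
        "retained_genes": sorted(v.gene for v in retained),
        "n_expanded_query": len(expanded),
        "n_significant_terms": sum(1 for r in enrichment_results if r.significant),
        "thresholds": asdict(config),
    }
    return PipelineResult(
        subgroups=subgroups,
        association_pass=association_pass,
        association_results=association_results,
        segregation_pass=segregation_pass,
        segregation_results=segregation_results,
        retained=retained,
        traces=traces,
        constraint_flags=constraint_flags,
        conservation=conservation,
        expanded_query=expanded,
        enrichment=enrichment_results,
        summary=summary,
    )


def result_tables(cohort: Cohort, result: PipelineResult) -> dict[str, pd.DataFrame]:
    """Assemble the report tables in deterministic row order."""
    ordered = sorted(cohort.variants, key=variant_sort_key)
    key_order = {v.key: i for i, v in enumerate(ordered)}

    candidates = pd.DataFrame(
        [
            {
                "gene": v.gene, "id": v.rsid or "-", "chrom": v.chrom, "pos": v.pos,
                "ref": v.ref, "alt": v.alt, "transcript_id": v.transcript_id or "-",
                "protein_change": v.protein_change or "-", "impact": v.impact,
            }
            for v in sorted(result.retained, key=variant_sort_key)
        ],
        columns=["gene", "id", "chrom", "pos", "ref", "alt", "transcript_id",
                 "protein_change", "impact"],
    )

    trace_rows = []
    for key in sorted(result.traces, key=lambda k: key_order.get(k, 1 << 30)):
        for s in result.traces[key].stages:
            trace_rows.append(
                {"variant_key": key, "stage": s.stage, "decision": s.decision, "reason": s.reason}
            )
    traces = pd.DataFrame(trace_rows, columns=["variant_key", "stage", "decision", "reason"])

    assoc_df = pd.DataFrame(
        [
            {
                "variant_key": r.variant_key, "subgroup": r.subgroup_id,
                "case_alt": r.table.case_alt, "case_ref": r.table.case_ref,
                "ctrl_alt": r.table.ctrl_alt, "ctrl_ref": r.table.ctrl_ref,
                "odds_ratio": r.odds_ratio, "p_value": r.p_value, "passes": r.passes,
            }
            for r in sorted(
                result.association_results,
                key=lambda r: (key_order.get(r.variant_key, 1 << 30), r.subgroup_id),
            )
        ]
    )

    seg_df = pd.DataFrame(
        [
            {
                "variant_key": r.variant_key, "subgroup": r.subgroup_id, "model": r.model,
                "support": r.support, "model_inconsistent_carriers": r.inconsistent_carriers,
            }
            for r in sorted(
                result.segregation_results,
                key=lambda r: (key_order.get(r.variant_key, 1 << 30), r.subgroup_id),
            )
        ]
    )

    cons_by_gene = {c.gene: c for c in result.conservation}
    annotation = pd.DataFrame(
        [
            {
                "gene": v.gene, "variant_key": v.key, "effect": v.effect or "-",
                **impann.summarize_predictions(v),
                "loeuf": v.loeuf if v.loeuf is not None else "-",
                "constraint_evidence": bool(result.constraint_flags.get(v.gene, False)),
                "maf_global": v.maf_global if v.maf_global is not None else "-",
                "maf_asn": v.maf_asn if v.maf_asn is not None else "-",
                "conserved_fraction": (
                    round(cons_by_gene[v.gene].fraction_identical, 4)
                    if v.gene in cons_by_gene else "-"
                ),
            }
            for v in ordered
        ]
    )

    enrich_df = pd.DataFrame(
        [
            {
                "source": r.source, "term": r.name, "term_id": r.term_id,
                "term_size": r.term_size, "overlap": r.overlap,
                "p_value": r.p_value, "p_adjusted": r.p_adjusted,
                "p_adjusted_source": r.p_adjusted_source, "significant": r.significant,
            }
            for r in result.enrichment
        ],
        columns=["source", "term", "term_id", "term_size", "overlap", "p_value",
                 "p_adjusted", "p_adjusted_source", "significant"],
    )

    return {
        "candidate_variants": candidates,
        "genotype_matrix": seg.genotype_matrix(cohort),
        "filter_trace": traces,
        "association": assoc_df,
        "segregation": seg_df,
        "annotation_summary": annotation,
        "enrichment": enrich_df,
    }


def write_results(
    cohort: Cohort, result: PipelineResult, out_dir: str | Path
) -> dict[str, Path]:
    paths = write_report(out_dir, result_tables(cohort, result))
    summary_path = Path(out_dir) / "run_summary.yaml"
    with open(summary_path, "w") as fh:
        yaml.safe_dump(result.summary, fh, sort_keys=True)
    paths["run_summary"] = summary_path
    return paths
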