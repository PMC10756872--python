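"""The annotation filter cascade.

Stage order: association -> impact -> ontology -> segregation. The impact
gate keeps HIGH-impact variants unconditionally and MODERATE variants only
when rescued by a damaging in-silico prediction (any SIFT "D", any
PolyPhen-2 "P" or "D") or by Asian-population rarity (ASN MAF below the
threshold, default 0.1, strict). LOW/MODIFIER variants fail. The ontology
gate keeps variants whose gene lies in the union of the phenotype gene
lists. Each variant accumulates a FilterTrace; once a stage fails, later
stages are recorded as not evaluated.
"""

from __future__ import annotations

from typing import Mapping

from .types import Cohort, FilterTrace, StageRecord, VariantRecord

STAGE_ORDER = ("association", "impact", "ontology", "segregation")

_DAMAGING_POLYPHEN = {"P", "D"}  # possibly / probably damaging


def damaging_any(variant: VariantRecord) -> bool:
    """True when any transcript-level prediction is damaging: SIFT "D", or
    PolyPhen-2 "P" (possibly) or "D" (probably damaging)."""
    return any(c == "D" for c in variant.sift_calls) or any(
        c in _DAMAGING_POLYPHEN for c in variant.polyphen_calls
    )


def impact_gate(variant: VariantRecord, maf_threshold: float = 0.1) -> tuple[str, str]:
    """Impact-class gate with the MODERATE rescue routes.

    Returns (decision, reason). MODERATE variants with neither prediction
    calls nor an ASN MAF fail closed ("insufficient evidence").
    """
    if variant.impact == "HIGH":
        return "pass", "HIGH impact"
    if variant.impact in ("LOW", "MODIFIER"):
        return "fail", f"{variant.impact} impact"
    # MODERATE
    if damaging_any(variant):
        return "pass", "MODERATE with damaging prediction"
    if variant.maf_asn is not None:
        if variant.maf_asn < maf_threshold:
            return "pass", f"MODERATE with ASN MAF {variant.maf_asn} < {maf_threshold}"
        if variant.sift_calls or variant.polyphen_calls:
            return "fail", "MODERATE, tolerated predictions and common in ASN"
        return "fail", f"MODERATE, no damaging prediction, ASN MAF {variant.maf_asn} >= {maf_threshold}"
    if not variant.sift_calls and not variant.polyphen_calls:
        return "fail", "insufficient evidence"
    return "fail", "MODERATE, tolerated predictions, no ASN MAF"


def ontology_gate(variant: VariantRecord, gene_lists: Mapping[str, set[str]]) -> tuple[str, str]:
    """Pass iff the variant's gene is in the union of the phenotype gene
    lists; the reason names every matching source."""
    gene = variant.gene.upper()
    hits = sorted(source for source, genes in gene_lists.items() if gene in genes)
    if hits:
        return "pass", ", ".join(hits)
    return "fail", f"{variant.gene} in no phenotype gene list"


def run_cascade(
    cohort: Cohort,
    association_pass: Mapping[str, bool],
    gene_lists: Mapping[str, set[str]],
    segregation_pass: Mapping[str, bool],
    maf_threshold: float = 0.1,
    short_circuit: bool = True,
) -> tuple[list[VariantRecord], dict[str, FilterTrace]]:
    """Run all gates in pipeline order and produce per-variant traces.

    A variant is retained iff every stage passes. With ``short_circuit``
    (default) stages after the first failure are recorded as
    ``not_evaluated``; the retention set is identical either way because
    the gate decisions are independent given their inputs.
    """
    retained: list[VariantRecord] = []
    traces: dict[str, FilterTrace] = {}
    for v in cohort.variants:
        trace = FilterTrace(variant_key=v.key)
        failed = False

        def record(stage: str, decision: str, reason: str) -> None:
            trace.stages.append(StageRecord(stage=stage, decision=decision, reason=reason))

        for stage in STAGE_ORDER:
            if failed and short_circuit:
                record(stage, "not_evaluated", "earlier stage failed")
                continue
            if stage == "association":
                ok = bool(association_pass.get(v.key, False))
                record(stage, "pass" if ok else "fail",
                       "p < alpha and OR > 1 in >= 1 subgroup" if ok
                       else "no subgroup with p < alpha and OR > 1")
            elif stage == "impact":
                decision, reason = impact_gate(v, maf_threshold=maf_threshold)
                ok = decision == "pass"
                record(stage, decision, reason)
            elif stage == "ontology":
                decision, reason = ontology_gate(v, gene_lists)
                ok = decision == "pass"
                record(stage, decision, reason)
            else:  # segregation
                ok = bool(segregation_pass.get(v.key, False))
                record(stage, "pass" if ok else "fail",
                       "model-consistent affected carrier support" if ok
                       else "no subgroup meets the support threshold")
            failed = failed or not ok
        traces[v.key] = trace
        if not failed:
            retained.append(v)
    return retained, traces
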