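"""Segregation scoring under subgroup-implied inheritance models.

Multiplex families are scored under an autosomal dominant model (affected
carriers: het or hom-alt) and the pooled sporadic cases under an autosomal
recessive model (hom-alt only). Strict co-segregation is not required:
support counting with a minimum-support threshold (default 1) is used, and
the full genotype matrix is always emitted so affected non-carriers and
model-inconsistent carriers stay visible for human review. Only affected
individuals were sequenced, so unaffected relatives never gate retention.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .types import (
    Cohort,
    CohortError,
    GENOTYPE_CLASSES,
    SegregationResult,
    Subgroup,
    genotype_class,
)


def model_for_subgroup(subgroup: Subgroup) -> str:
    """Multiplex families imply dominant inheritance; the sporadic pool
    implies recessive."""
    return "dominant" if subgroup.kind == "multiplex" else "recessive"


_SUPPORT_CLASSES = {"dominant": {"het", "hom_alt"}, "recessive": {"hom_alt"}}


def genotype_support(cohort: Cohort, variant_key: str, subgroup: Subgroup, model: str) -> int:
    """Count of subgroup members whose genotype is consistent with carrying
    the risk allele under ``model``; missing genotypes contribute 0."""
    if model not in _SUPPORT_CLASSES:
        raise CohortError(f"unknown inheritance model {model!r}")
    v = cohort.variant(variant_key)
    classes = _SUPPORT_CLASSES[model]
    return sum(
        1
        for iid in subgroup.members
        if genotype_class(cohort.genotype(iid, variant_key), v.ref, v.alt) in classes
    )


def carrier_count(cohort: Cohort, variant_key: str, classes: set[str]) -> int:
    """Count sequenced individuals whose genotype class is in ``classes``
    (subset of hom_ref/het/hom_alt/missing)."""
    unknown = set(classes) - set(GENOTYPE_CLASSES)
    if unknown:
        raise CohortError(f"unknown genotype classes {sorted(unknown)}")
    v = cohort.variant(variant_key)
    return sum(
        1
        for p in cohort.sequenced_individuals()
        if genotype_class(cohort.genotype(p.individual_id, variant_key), v.ref, v.alt) in classes
    )


def segregate(
    cohort: Cohort,
    subgroups: Sequence[Subgroup],
    min_support: int = 1,
) -> tuple[dict[str, bool], list[SegregationResult]]:
    """Score every (variant, subgroup) pair; a variant passes when the
    support in some subgroup, under that subgroup's model, reaches
    ``min_support``. Het carriers under a recessive model are reported as
    model-inconsistent carriers, never counted as support."""
    if min_support < 1:
        raise CohortError(f"min_support must be >= 1, got {min_support}")
    results: list[SegregationResult] = []
    passes: dict[str, bool] = {}
    for key in cohort.variant_keys:
        v = cohort.variant(key)
        best = 0
        for sg in subgroups:
            model = model_for_subgroup(sg)
            support = genotype_support(cohort, key, sg, model)
            gclasses = {
                iid: genotype_class(cohort.genotype(iid, key), v.ref, v.alt)
                for iid in sg.members
            }
            inconsistent = (
                sum(1 for c in gclasses.values() if c == "het") if model == "recessive" else 0
            )
            results.append(
                SegregationResult(
                    variant_key=key,
                    subgroup_id=sg.subgroup_id,
                    model=model,
                    support=support,
                    inconsistent_carriers=inconsistent,
                    genotype_classes=gclasses,
                )
            )
            best = max(best, support)
        passes[key] = best >= min_support
    return passes, results


#: Alias: the segregation stage as a pipeline gate.
segregation_filter = segregate


def genotype_matrix(cohort: Cohort) -> pd.DataFrame:
    """Genotype-by-participant matrix in the candidate-table layout:
    one row per sequenced individual (family, patient columns), one
    gene-labelled column per variant ("GENE-REF"), allele-pair cells."""
    from .io_formats import variant_sort_key

    variants = sorted(cohort.variants, key=variant_sort_key)
    rows = []
    for p in cohort.sequenced_individuals():
        row: dict[str, object] = {"family": p.family_id, "patient": p.individual_id}
        for v in variants:
            row[f"{v.gene}-{v.ref}"] = cohort.genotype(p.individual_id, v.key)
        rows.append(row)
    return pd.DataFrame(rows)
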