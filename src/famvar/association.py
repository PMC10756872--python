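"""Subgroup construction and case–control allele association.

Sequenced affected members of each multiplex family (two or more affected)
form one subgroup; the sole cases of single-case families are pooled into
one sporadic subgroup. Each variant's allele count in each subgroup is
compared with the control cohort by a two-sided Fisher exact test, and a
variant is called associated when, in at least one subgroup, p < alpha and
the (Haldane–Anscombe-corrected, when a cell is zero) odds ratio exceeds 1.

The raw p < 0.05 screen is deliberately uncorrected for multiple testing:
it is a candidate screen, not an inference.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from math import comb
from typing import Iterable, Sequence

from .types import (
    AssociationResult,
    Cohort,
    CohortError,
    ContingencyTable,
    PedigreeIndividual,
    Subgroup,
    genotype_dosage,
)

log = logging.getLogger(__name__)

SPORADIC_POOL_ID = "sporadic_pool"


def assign_subgroups(pedigree: Iterable[PedigreeIndividual]) -> list[Subgroup]:
    """Group sequenced affected individuals for case–control testing.

    Families with >= 2 sequenced affected members each become one multiplex
    subgroup; families with exactly one become members of a single pooled
    sporadic subgroup. Families without affected sequenced members are
    excluded with a warning.
    """
    by_family: dict[str, list[str]] = defaultdict(list)
    family_order: list[str] = []
    for p in pedigree:
        if p.family_id not in by_family:
            family_order.append(p.family_id)
        members = by_family[p.family_id]
        if p.affected and p.sequenced:
            members.append(p.individual_id)
    subgroups: list[Subgroup] = []
    pool: list[str] = []
    for fam in family_order:
        cases = by_family[fam]
        if len(cases) >= 2:
            subgroups.append(
                Subgroup(subgroup_id=f"multiplex_{fam}", kind="multiplex", members=tuple(cases))
            )
        elif len(cases) == 1:
            pool.extend(cases)
        else:
            log.warning("family %s has no sequenced affected member; excluded", fam)
    if pool:
        subgroups.append(
            Subgroup(subgroup_id=SPORADIC_POOL_ID, kind="sporadic_pool", members=tuple(pool))
        )
    return subgroups


def allele_table(cohort: Cohort, variant_key: str, subgroup: Subgroup) -> ContingencyTable:
    """2x2 allele counts for one variant: subgroup cases vs controls.

    Each member with a non-missing genotype contributes two alleles; missing
    genotypes contribute none (the case allele number shrinks, nothing is
    imputed). Control counts come from the control table.
    """
    v = cohort.variant(variant_key)
    case_alt = 0
    case_ref = 0
    for iid in subgroup.members:
        dosage = genotype_dosage(cohort.genotype(iid, variant_key), v.ref, v.alt)
        if dosage is None:
            continue
        case_alt += dosage
        case_ref += 2 - dosage
    ctrl_alt, ctrl_an = cohort.control_counts(variant_key)
    return ContingencyTable(
        case_alt=case_alt, case_ref=case_ref, ctrl_alt=ctrl_alt, ctrl_ref=ctrl_an - ctrl_alt
    )


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p by the point-probability method: the sum of
    hypergeometric probabilities of all tables (at fixed margins) no more
    probable than the observed one. A zero margin gives p = 1.

    Computed in exact integer arithmetic, so ties in table probability are
    resolved exactly rather than to floating-point tolerance (and a full
    enumeration sweep stays cheap)."""
    a, b, c, d = table.case_alt, table.case_ref, table.ctrl_alt, table.ctrl_ref
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    # unnormalized hypergeometric weights over the support at fixed margins
    weights = [comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)]
    observed = weights[a - lo]
    tail = sum(w for w in weights if w <= observed)
    return min(tail / comb(n, c1), 1.0)


def odds_ratio(table: ContingencyTable) -> float:
    """Sample odds ratio (case_alt*ctrl_ref)/(case_ref*ctrl_alt), adding 0.5
    to every cell first when any cell is zero (Haldane–Anscombe)."""
    a, b, c, d = table.case_alt, table.case_ref, table.ctrl_alt, table.ctrl_ref
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def associate(
    cohort: Cohort,
    subgroups: Sequence[Subgroup],
    alpha: float = 0.05,
) -> tuple[dict[str, bool], list[AssociationResult]]:
    """Run the association screen for every (variant, subgroup) pair.

    Returns the per-variant pass flag (passing in any one subgroup
    suffices) and the full per-pair result list for the audit trail.
    """
    if not 0 < alpha < 1:
        raise CohortError(f"alpha must be in (0, 1), got {alpha}")
    results: list[AssociationResult] = []
    passes: dict[str, bool] = {}
    for key in cohort.variant_keys:
        variant_pass = False
        for sg in subgroups:
            table = allele_table(cohort, key, sg)
            p = fisher_exact_two_sided(table)
            orr = odds_ratio(table)
            ok = p < alpha and orr > 1.0
            variant_pass = variant_pass or ok
            results.append(
                AssociationResult(
                    variant_key=key,
                    subgroup_id=sg.subgroup_id,
                    table=table,
                    odds_ratio=orr,
                    p_value=p,
                    passes=ok,
                )
            )
        passes[key] = variant_pass
    return passes, results


#: Alias: the association stage as a pipeline gate.
association_filter = associate
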