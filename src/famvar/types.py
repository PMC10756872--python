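"""Core domain types shared by every stage of the prioritization pipeline.

Genotypes are carried as unphased allele-pair strings in the dialect of the
candidate-variant genotype table (e.g. ``"C/CGCT"`` for a heterozygous
insertion carrier, ``"./."`` for missing) with a canonical mapping to
0/1/2 alt-allele dosage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import pandas as pd

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")

#: SIFT per-transcript labels: D = damaging, T = tolerated.
SIFT_LABELS = ("D", "T")
#: PolyPhen-2 per-transcript labels: B = benign, P = possibly damaging,
#: D = probably damaging.
POLYPHEN_LABELS = ("B", "P", "D")

MISSING_GT = "./."


class CohortError(ValueError):
    """Raised on malformed or internally inconsistent cohort inputs."""


@dataclass(frozen=True)
class VariantRecord:
    """One annotated alternate allele at a locus.

    ``pos`` is 1-based (VCF convention); indels are left-anchored.
    Prediction call tuples preserve per-transcript order. Frequencies and
    LOEUF may be absent (``None``).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    impact: str
    effect: str = ""
    rsid: Optional[str] = None
    transcript_id: Optional[str] = None
    protein_change: Optional[str] = None
    sift_calls: tuple[str, ...] = ()
    polyphen_calls: tuple[str, ...] = ()
    maf_global: Optional[float] = None
    maf_asn: Optional[float] = None
    loeuf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CohortError(f"position must be >= 1, got {self.pos}")
        if self.impact not in IMPACT_CLASSES:
            raise CohortError(
                f"impact {self.impact!r} not one of {IMPACT_CLASSES}"
            )
        for maf in (self.maf_global, self.maf_asn):
            if maf is not None and not 0.0 <= maf <= 1.0:
                raise CohortError(f"allele frequency {maf} outside [0, 1]")
        if self.loeuf is not None and self.loeuf < 0:
            raise CohortError(f"negative LOEUF score {self.loeuf}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def with_loeuf(self, loeuf: Optional[float]) -> "VariantRecord":
        return replace(self, loeuf=loeuf)


@dataclass(frozen=True)
class PedigreeIndividual:
    """One row of a 6-column pedigree: identity, parent links, sex,
    affection status, plus whether the individual was sequenced."""

    family_id: str
    individual_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: int = 0  # 1 = male, 2 = female, 0 = unknown
    affected: bool = False
    sequenced: bool = False


@dataclass(frozen=True)
class Subgroup:
    """A unit of case–control comparison: one multiplex family's sequenced
    affected members, or the pooled sporadic cases."""

    subgroup_id: str
    kind: str  # "multiplex" | "sporadic_pool"
    members: tuple[str, ...]  # individual ids, sequenced affected only


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 allele-count table: cases (one subgroup) vs the control cohort."""

    case_alt: int
    case_ref: int
    ctrl_alt: int
    ctrl_ref: int

    def __post_init__(self) -> None:
        for name in ("case_alt", "case_ref", "ctrl_alt", "ctrl_ref"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise CohortError(f"{name} must be a nonnegative integer, got {v!r}")

    def as_rows(self) -> list[list[int]]:
        return [[self.case_alt, self.case_ref], [self.ctrl_alt, self.ctrl_ref]]


@dataclass(frozen=True)
class AssociationResult:
    variant_key: str
    subgroup_id: str
    table: ContingencyTable
    odds_ratio: float
    p_value: float
    passes: bool


@dataclass(frozen=True)
class StageRecord:
    stage: str  # association | impact | ontology | segregation
    decision: str  # pass | fail | not_evaluated
    reason: str


@dataclass
class FilterTrace:
    """Ordered audit trail of every gate's decision for one variant."""

    variant_key: str
    stages: list[StageRecord] = field(default_factory=list)

    @property
    def retained(self) -> bool:
        return all(s.decision == "pass" for s in self.stages if s.decision != "not_evaluated") and all(
            s.decision != "fail" for s in self.stages
        )

    def first_fail(self) -> Optional[str]:
        for s in self.stages:
            if s.decision == "fail":
                return s.stage
        return None


@dataclass(frozen=True)
class SegregationResult:
    variant_key: str
    subgroup_id: str
    model: str  # dominant | recessive
    support: int  # affected model-consistent carriers in this subgroup
    inconsistent_carriers: int  # e.g. het carriers under a recessive model
    genotype_classes: Mapping[str, str]  # individual id -> genotype class


@dataclass(frozen=True)
class GeneSetTerm:
    term_id: str
    source: str  # e.g. GO:BP, GO:MF, GO:CC, KEGG, REAC, OT, HPO
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise CohortError(f"term {self.term_id} has an empty gene list")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    source: str
    name: str
    term_size: int  # genes of the term present in the universe
    overlap: int  # genes shared with the query
    p_value: float
    p_adjusted: float  # pooled adjustment across all tested terms
    p_adjusted_source: float  # adjustment within the term's source
    significant: bool


@dataclass(frozen=True)
class ConservationAssessment:
    gene: str
    residue_position: int  # 1-based in the ungapped human sequence
    column: int  # 1-based alignment column
    human_residue: str
    fraction_identical: float  # over non-gap ortholog residues
    conserved: bool
    threshold: float


def genotype_dosage(gt: str, ref: str, alt: str) -> Optional[int]:
    """Alt-allele dosage (0/1/2) of an allele-pair string, ``None`` if missing.

    Raises :class:`CohortError` when an allele matches neither ref nor alt.
    """
    if gt == MISSING_GT or gt in ("", ".", None):
        return None
    try:
        a, b = gt.split("/")
    except ValueError as exc:
        raise CohortError(f"malformed genotype {gt!r}: expected 'A/B'") from exc
    if a == "." or b == ".":
        return None
    dosage = 0
    for allele in (a, b):
        if allele == alt:
            dosage += 1
        elif allele != ref:
            raise CohortError(
                f"genotype {gt!r} carries allele {allele!r} matching neither "
                f"ref {ref!r} nor alt {alt!r}"
            )
    return dosage


def dosage_genotype(dosage: Optional[int], ref: str, alt: str) -> str:
    """Inverse of :func:`genotype_dosage` under the ref-first convention."""
    if dosage is None:
        return MISSING_GT
    if dosage == 0:
        return f"{ref}/{ref}"
    if dosage == 1:
        return f"{ref}/{alt}"
    if dosage == 2:
        return f"{alt}/{alt}"
    raise CohortError(f"dosage must be in {{0,1,2}}, got {dosage}")


GENOTYPE_CLASSES = ("hom_ref", "het", "hom_alt", "missing")


def genotype_class(gt: str, ref: str, alt: str) -> str:
    d = genotype_dosage(gt, ref, alt)
    return {None: "missing", 0: "hom_ref", 1: "het", 2: "hom_alt"}[d]


@dataclass
class Cohort:
    """The single internal representation every stage operates on.

    genotypes: DataFrame indexed by individual id, one column per variant
    key, values allele-pair strings (missing = ``"./."``).
    controls: DataFrame indexed by variant key with integer columns
    ``AC`` (alt allele count) and ``AN`` (total allele number).
    """

    variants: list[VariantRecord]
    genotypes: pd.DataFrame
    pedigree: list[PedigreeIndividual]
    controls: pd.DataFrame

    def __post_init__(self) -> None:
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise CohortError("duplicate variant keys in cohort")

    def variant(self, key: str) -> VariantRecord:
        for v in self.variants:
            if v.key == key:
                return v
        raise KeyError(key)

    @property
    def variant_keys(self) -> list[str]:
        return [v.key for v in self.variants]

    def sequenced_individuals(self) -> list[PedigreeIndividual]:
        return [p for p in self.pedigree if p.sequenced]

    def genotype(self, individual_id: str, variant_key: str) -> str:
        if individual_id not in self.genotypes.index:
            return MISSING_GT
        return str(self.genotypes.at[individual_id, variant_key])

    def control_counts(self, variant_key: str) -> tuple[int, int]:
        if variant_key not in self.controls.index:
            raise CohortError(f"no control allele counts for variant {variant_key}")
        row = self.controls.loc[variant_key]
        return int(row["AC"]), int(row["AN"])


def validate_pedigree(pedigree: Iterable[PedigreeIndividual]) -> None:
    """Check parent-link referential integrity and acyclicity per family."""
    by_family: dict[str, dict[str, PedigreeIndividual]] = {}
    for p in pedigree:
        by_family.setdefault(p.family_id, {})[p.individual_id] = p
    for fam, members in by_family.items():
        for p in members.values():
            for parent in (p.father_id, p.mother_id):
                if parent is not None and parent not in members:
                    raise CohortError(
                        f"individual {p.individual_id} in family {fam} references "
                        f"unknown parent {parent}"
                    )
        # acyclicity over parent links (child -> parent edges), DFS coloring
        state: dict[str, int] = {}  # 1 = on stack, 2 = done

        def _visit(iid: str) -> None:
            state[iid] = 1
            ind = members[iid]
            for parent in (ind.father_id, ind.mother_id):
                if parent is None:
                    continue
                if state.get(parent) == 1:
                    raise CohortError(f"cyclic pedigree in family {fam} at {parent}")
                if state.get(parent) != 2:
                    _visit(parent)
            state[iid] = 2

        for iid in members:
            if state.get(iid) != 2:
                _visit(iid)
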