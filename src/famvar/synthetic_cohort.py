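"""Synthetic pedigreed exome-style cohorts with planted causal variants.

The generator emulates the study design every downstream stage is tested
against: a handful of multiplex families (an affected founder parent plus
affected children, all sequenced) and sporadic families (a single affected,
sequenced child of unaffected parents), a diploid control cohort of 100
individuals, dominant variants planted in multiplex families, recessive
variants planted in sporadic cases, and decoy variants each constructed to
fail exactly one named gate of the filter cascade so stage-level tests can
pin blame. Genotype transmission is Mendelian: founder alleles are drawn
independently at the founder allele frequency and each child receives one
uniformly chosen allele per parent. No read-level simulation, sequencing
error, or linkage structure is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    Cohort,
    CohortError,
    PedigreeIndividual,
    VariantRecord,
    dosage_genotype,
    validate_pedigree,
)

DECOY_KINDS = (
    "fail_association",
    "fail_impact",
    "fail_rescue",  # MODERATE with tolerated predictions and a common ASN MAF
    "fail_ontology",
    "fail_segregation",
)

ANNOTATION_PROFILES = ("high_impact", "moderate_damaging", "moderate_rare")


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a simulated cohort.

    Defaults mirror the study conditions: 3 multiplex + 6 sporadic
    families, a 100-individual diploid control cohort, planted variants
    annotated at ASN MAF 0.005 (rare), decoy/neutral control allele
    frequencies drawn from ``control_af_range``, full penetrance.
    """

    n_multiplex_families: int = 3
    n_sporadic_families: int = 6
    members_per_family: tuple[int, int] = (3, 6)
    n_planted_dominant: int = 3
    n_planted_recessive: int = 2
    n_decoys: int = 20
    control_n: int = 100
    control_af_range: tuple[float, float] = (0.05, 0.4)
    planted_maf_asn: float = 0.005
    penetrance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_multiplex_families", "n_sporadic_families", "n_planted_dominant",
            "n_planted_recessive", "n_decoys",
        ):
            if getattr(self, name) < 0:
                raise CohortError(f"{name} must be >= 0")
        if self.control_n < 1:
            raise CohortError("control_n must be >= 1")
        lo, hi = self.control_af_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise CohortError("control_af_range must lie within [0, 0.5]")
        if self.members_per_family[0] < 1:
            raise CohortError("members_per_family must be >= 1")
        if not 0.0 <= self.penetrance <= 1.0:
            raise CohortError("penetrance must be in [0, 1]")


@dataclass(frozen=True)
class PlantedVariant:
    variant: VariantRecord
    model: str  # dominant | recessive
    target_families: tuple[str, ...]
    annotation_profile: str

    def __post_init__(self) -> None:
        if self.model not in ("dominant", "recessive"):
            raise CohortError(f"unknown model {self.model!r}")
        if self.annotation_profile not in ANNOTATION_PROFILES:
            raise CohortError(f"unknown annotation profile {self.annotation_profile!r}")


# ---------------------------------------------------------------------------
# Pedigree generation

def generate_pedigrees(
    spec: CohortSpec, rng: Optional[np.random.Generator] = None
) -> list[PedigreeIndividual]:
    """Nuclear-family pedigrees: two founder parents plus children.

    Multiplex families ("M1"...) carry an affected founder mother and at
    least one affected child; sporadic families ("S1"...) exactly one
    affected child. Affected individuals are the sequenced ones.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    lo, hi = spec.members_per_family
    ped: list[PedigreeIndividual] = []

    def family(fam: str, multiplex: bool) -> None:
        size = int(rng.integers(lo, hi + 1))
        n_children = max(1, size - 2)
        mother_affected = multiplex
        ped.append(PedigreeIndividual(fam, f"{fam}_I-1", None, None, 1, False, False))
        ped.append(
            PedigreeIndividual(
                fam, f"{fam}_I-2", None, None, 2, mother_affected, mother_affected
            )
        )
        if multiplex:
            n_affected_children = int(rng.integers(1, n_children + 1))
        else:
            n_affected_children = 1
        for c in range(1, n_children + 1):
            affected = c <= n_affected_children
            sex = int(rng.integers(1, 3))
            ped.append(
                PedigreeIndividual(
                    fam, f"{fam}_II-{c}", f"{fam}_I-1", f"{fam}_I-2", sex, affected, affected
                )
            )

    for i in range(1, spec.n_multiplex_families + 1):
        family(f"M{i}", multiplex=True)
    for i in range(1, spec.n_sporadic_families + 1):
        family(f"S{i}", multiplex=False)
    validate_pedigree(ped)
    return ped


def family_members(
    pedigree: Sequence[PedigreeIndividual], family_id: str
) -> list[PedigreeIndividual]:
    return [p for p in pedigree if p.family_id == family_id]


# ---------------------------------------------------------------------------
# Mendelian transmission

def _gamete(dosage: int, rng: np.random.Generator) -> int:
    if dosage == 0:
        return 0
    if dosage == 2:
        return 1
    return int(rng.integers(0, 2))


def transmit_genotypes(
    pedigree: Sequence[PedigreeIndividual],
    founder_af: float,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> dict[str, int]:
    """Alt-allele dosage per individual under neutral Mendelian descent:
    founders draw two independent Bernoulli(founder_af) alleles; each child
    receives one uniformly chosen allele from each parent."""
    if not 0.0 <= founder_af <= 1.0:
        raise CohortError(f"founder_af must be in [0, 1], got {founder_af}")
    validate_pedigree(pedigree)  # rejects cyclic parent links
    rng = rng if rng is not None else np.random.default_rng(seed)
    members = {p.individual_id: p for p in pedigree}
    dosages: dict[str, int] = {}

    def resolve(iid: str) -> int:
        if iid in dosages:
            return dosages[iid]
        p = members[iid]
        if p.father_id is None and p.mother_id is None:
            d = int(rng.random() < founder_af) + int(rng.random() < founder_af)
        else:
            pat = _gamete(resolve(p.father_id), rng) if p.father_id else int(rng.random() < founder_af)
            mat = _gamete(resolve(p.mother_id), rng) if p.mother_id else int(rng.random() < founder_af)
            d = pat + mat
        dosages[iid] = d
        return d

    for p in pedigree:
        resolve(p.individual_id)
    return dosages


def mendelian_violations(
    pedigree: Sequence[PedigreeIndividual], dosages: Mapping[str, Optional[int]]
) -> list[str]:
    """Individuals whose dosage is impossible given both parents' dosages
    (used as an exhaustive per-cohort consistency check)."""
    gametes = {0: {0}, 1: {0, 1}, 2: {1}}
    bad = []
    for p in pedigree:
        d = dosages.get(p.individual_id)
        if d is None or p.father_id is None or p.mother_id is None:
            continue
        df, dm = dosages.get(p.father_id), dosages.get(p.mother_id)
        if df is None or dm is None:
            continue
        possible = {a + b for a in gametes[df] for b in gametes[dm]}
        if d not in possible:
            bad.append(p.individual_id)
    return bad


# ---------------------------------------------------------------------------
# Planting causal genotypes

def plant_causal(
    pedigree: Sequence[PedigreeIndividual],
    planted: PlantedVariant,
    penetrance: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> dict[str, int]:
    """Dosage assignment for one planted variant across the whole cohort.

    Dominant (multiplex targets): the affected founder parent and every
    affected child are heterozygous carriers; unaffected members carry the
    allele at the rate implied by penetrance (a transmitted allele causes
    affection with probability ``penetrance``, so an unaffected child of a
    het parent is a carrier with probability (1-p)/(2-p)). Recessive
    (sporadic targets): the affected child is hom-alt, parents are obligate
    het carriers, unaffected siblings draw from the het-x-het offspring
    distribution conditioned on being unaffected. Everyone outside the
    target families is hom-ref.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    by_family: dict[str, list[PedigreeIndividual]] = {}
    for p in pedigree:
        by_family.setdefault(p.family_id, []).append(p)
    dosages = {p.individual_id: 0 for p in pedigree}
    for fam in planted.target_families:
        if fam not in by_family:
            raise CohortError(f"target family {fam} not in pedigree")
        members = by_family[fam]
        n_affected = sum(1 for m in members if m.affected)
        if planted.model == "dominant":
            if n_affected < 2:
                raise CohortError(
                    f"dominant variant targets non-multiplex family {fam}"
                )
            for m in members:
                if m.affected:
                    dosages[m.individual_id] = 1
                elif m.father_id or m.mother_id:
                    # unaffected child of (potentially) carrier parents
                    carrier_p = (1 - penetrance) / (2 - penetrance) if penetrance < 1 else 0.0
                    dosages[m.individual_id] = int(rng.random() < carrier_p)
        else:  # recessive
            if n_affected != 1:
                raise CohortError(
                    f"recessive variant targets non-sporadic family {fam}"
                )
            for m in members:
                if m.affected:
                    dosages[m.individual_id] = 2
                elif m.father_id is None and m.mother_id is None:
                    dosages[m.individual_id] = 1  # obligate carrier parent
            for m in members:
                if not m.affected and (m.father_id or m.mother_id):
                    # het x het offspring conditioned on unaffected
                    w = np.array([0.25, 0.5, 0.25 * (1 - penetrance)])
                    dosages[m.individual_id] = int(rng.choice(3, p=w / w.sum()))
    return dosages


# ---------------------------------------------------------------------------
# Controls

def generate_controls(
    spec: CohortSpec,
    variants: Sequence[VariantRecord],
    rng: Optional[np.random.Generator] = None,
    af_overrides: Optional[Mapping[str, float]] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Control allele-count table: AN = 2 x control_n everywhere; the alt
    count is Binomial(AN, af) with af taken from (in order of precedence)
    an explicit override, the variant's annotated ASN MAF, or a uniform
    draw from ``control_af_range``."""
    if rng is None:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
    af_overrides = af_overrides or {}
    an = 2 * spec.control_n
    rows = []
    for v in variants:
        if v.key in af_overrides:
            af = af_overrides[v.key]
        elif v.maf_asn is not None:
            af = v.maf_asn
        else:
            af = float(rng.uniform(*spec.control_af_range))
        rows.append({"variant_key": v.key, "AC": int(rng.binomial(an, af)), "AN": an})
    return pd.DataFrame(rows).set_index("variant_key")


# ---------------------------------------------------------------------------
# Full cohort assembly

@dataclass
class SimulatedCohort:
    cohort: Cohort
    gene_lists: dict[str, set[str]]
    planted: list[PlantedVariant]
    decoy_labels: dict[str, str]  # variant key -> decoy kind

    @property
    def planted_keys(self) -> list[str]:
        return [p.variant.key for p in self.planted]


def _planted_annotation(profile: str, spec: CohortSpec) -> dict:
    if profile == "high_impact":
        return {"impact": "HIGH", "effect": "stop_gained", "maf_asn": spec.planted_maf_asn}
    if profile == "moderate_damaging":
        return {
            "impact": "MODERATE", "effect": "missense_variant",
            "sift_calls": ("D", "T"), "polyphen_calls": ("B", "P"),
            "maf_asn": spec.planted_maf_asn,
        }
    return {  # moderate_rare: rescued by ASN rarity alone
        "impact": "MODERATE", "effect": "disruptive_inframe_insertion",
        "maf_asn": spec.planted_maf_asn,
    }


def add_decoys(
    cohort: Cohort,
    gene_lists: Mapping[str, set[str]],
    n_decoys: int,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    low_af: float = 0.005,
    control_af_range: tuple[float, float] = (0.05, 0.4),
) -> tuple[Cohort, dict[str, str]]:
    """Append ``n_decoys`` variants to a cohort, each constructed to fail
    exactly one named gate of the cascade (cycling through
    :data:`DECOY_KINDS`), with matching control-count rows.

    Gate-passing decoys take genes from the supplied phenotype lists (but
    never a gene already carrying a cohort variant); ontology decoys get
    fresh unlisted symbols. Returns a new cohort plus the decoy-kind label
    per variant key; the input cohort is not modified.
    """
    from .association import assign_subgroups

    rng = rng if rng is not None else np.random.default_rng(seed)
    subgroups = assign_subgroups(cohort.pedigree)
    multiplex = [sg for sg in subgroups if sg.kind == "multiplex"]
    pool = next((sg for sg in subgroups if sg.kind == "sporadic_pool"), None)
    used_genes = {v.gene for v in cohort.variants}
    listed_pool = [g for g in sorted(set().union(*gene_lists.values())) if g not in used_genes]
    if not listed_pool:
        raise CohortError("gene lists offer no unused gene symbols for decoys")
    an = int(cohort.controls["AN"].max()) if len(cohort.controls) else 200
    existing_keys = set(cohort.variant_keys)

    variants = list(cohort.variants)
    genotypes = cohort.genotypes.copy()
    control_rows = []
    labels: dict[str, str] = {}
    for i in range(n_decoys):
        kind = DECOY_KINDS[i % len(DECOY_KINDS)]
        loc = {"chrom": "20", "pos": 9_000_000 + 1_000 * i, "ref": "G", "alt": "A"}
        if kind == "fail_ontology":
            gene = f"UNL{i + 1:03d}"
        else:
            gene = listed_pool[i % len(listed_pool)]
        dosages: dict[str, int] = {}
        af = float(rng.uniform(*control_af_range))  # fail_association default
        if kind == "fail_association":
            # absent from every case; moderately common in controls
            v = VariantRecord(gene=gene, impact="HIGH", effect="stop_gained", **loc)
        elif kind == "fail_impact":
            v = VariantRecord(gene=gene, impact="LOW", effect="synonymous_variant", **loc)
        elif kind == "fail_rescue":
            v = VariantRecord(
                gene=gene, impact="MODERATE", effect="missense_variant",
                sift_calls=("T", "T"), polyphen_calls=("B",), maf_asn=0.3, **loc,
            )
        else:  # fail_ontology / fail_segregation
            v = VariantRecord(gene=gene, impact="HIGH", effect="frameshift_variant", **loc)
        if kind in ("fail_impact", "fail_rescue", "fail_ontology"):
            # co-segregating carriers in one multiplex family: association
            # and segregation pass, only the named gate fails. The decoy is
            # rare in the local control cohort even when its annotated ASN
            # MAF is common, so blame stays on the named gate.
            if multiplex:
                for iid in multiplex[i % len(multiplex)].members:
                    dosages[iid] = 1
            af = low_af
        elif kind == "fail_segregation":
            # het carriers among pooled sporadic cases: allele-frequency
            # signal without a single hom-alt (recessive support is zero)
            members = pool.members if pool is not None else ()
            for iid in members[: max(2, len(members) // 2)]:
                dosages[iid] = 1
            af = low_af
        if v.key in existing_keys:
            raise CohortError(f"decoy key collision at {v.key}")
        variants.append(v)
        genotypes[v.key] = [
            dosage_genotype(dosages.get(iid, 0), v.ref, v.alt) for iid in genotypes.index
        ]
        control_rows.append(
            {"variant_key": v.key, "AC": int(rng.binomial(an, af)), "AN": an}
        )
        labels[v.key] = kind
    controls = pd.concat(
        [cohort.controls, pd.DataFrame(control_rows).set_index("variant_key")]
    )
    new_cohort = Cohort(
        variants=variants, genotypes=genotypes, pedigree=list(cohort.pedigree),
        controls=controls,
    )
    return new_cohort, labels


def generate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate the full study-shaped cohort: pedigrees, planted causal
    variants, single-gate decoys, genotypes, controls and phenotype gene
    lists. Identical spec (including seed) gives identical output."""
    rng = np.random.default_rng(spec.seed)
    pedigree = generate_pedigrees(spec, rng)
    multiplex_fams = [f"M{i}" for i in range(1, spec.n_multiplex_families + 1)]
    sporadic_fams = [f"S{i}" for i in range(1, spec.n_sporadic_families + 1)]

    variants: list[VariantRecord] = []
    planted: list[PlantedVariant] = []
    dosage_maps: dict[str, Mapping[str, int]] = {}

    def locus(i: int) -> dict:
        return {"chrom": str((i % 22) + 1), "pos": 1_000_000 + 10_000 * i, "ref": "G", "alt": "A"}

    if spec.n_planted_dominant and not multiplex_fams:
        raise CohortError("dominant variants require at least one multiplex family")
    if spec.n_planted_recessive and not sporadic_fams:
        raise CohortError("recessive variants require at least one sporadic family")
    specs = [("dominant", f"TAD{i + 1:03d}", multiplex_fams, i)
             for i in range(spec.n_planted_dominant)]
    specs += [("recessive", f"TAR{i + 1:03d}", sporadic_fams, i)
              for i in range(spec.n_planted_recessive)]
    for idx, (model, gene, fams, i) in enumerate(specs):
        profile = ANNOTATION_PROFILES[i % len(ANNOTATION_PROFILES)]
        v = VariantRecord(gene=gene, **locus(idx), **_planted_annotation(profile, spec))
        pv = PlantedVariant(v, model, (fams[i % len(fams)],), profile)
        variants.append(v)
        planted.append(pv)
        dosage_maps[v.key] = plant_causal(pedigree, pv, spec.penetrance, rng)

    sequenced = [p.individual_id for p in pedigree if p.sequenced]
    columns = {
        v.key: [dosage_genotype(dosage_maps[v.key].get(iid, 0), v.ref, v.alt)
                for iid in sequenced]
        for v in variants
    }
    genotypes = pd.DataFrame(columns, index=pd.Index(sequenced, name="individual_id"))
    controls = generate_controls(spec, variants, rng)

    # phenotype gene lists: planted genes spread across the three sources,
    # plus inert filler symbols (which decoys may reuse)
    sources: dict[str, set[str]] = {"OT": set(), "GO": set(), "HPO": set()}
    for i, gene in enumerate(sorted(v.gene for v in variants)):
        sources[("OT", "GO", "HPO")[i % 3]].add(gene)
    for source in sources:
        sources[source].update(f"FIL{source}{j}" for j in range(1, 9))

    cohort = Cohort(
        variants=variants, genotypes=genotypes, pedigree=pedigree, controls=controls
    )
    cohort, decoy_labels = add_decoys(
        cohort, sources, spec.n_decoys, rng,
        low_af=min(spec.planted_maf_asn, 0.005),
        control_af_range=spec.control_af_range,
    )
    return SimulatedCohort(
        cohort=cohort, gene_lists=sources, planted=planted, decoy_labels=decoy_labels
    )


# ---------------------------------------------------------------------------
# Random term collections (enrichment null testing)

def random_term_collection(
    n_terms: int,
    universe_size: int,
    term_size_range: tuple[int, int],
    rng: np.random.Generator,
    source: str = "GO:BP",
) -> tuple[list, list[str]]:
    """Random functional terms over a synthetic gene universe, for null
    calibration of the over-representation test."""
    from .types import GeneSetTerm

    universe = [f"G{i:05d}" for i in range(universe_size)]
    arr = np.array(universe)
    terms = []
    for t in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        genes = frozenset(arr[rng.choice(universe_size, size=size, replace=False)])
        terms.append(GeneSetTerm(f"RND:{t:05d}", source, f"random term {t}", genes))
    return terms, universe
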