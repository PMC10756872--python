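# Methods

## Study design the package models

The pipeline targets the smallest realistic family-based exome design: a
few multiplex families (two or more affected members, suggesting dominant
transmission), several sporadic cases (suggesting recessive or de novo
causes; only recessive is modelled, since no unaffected relatives are
sequenced), and an external control cohort summarized as per-variant
allele counts (AC out of AN = 2 × N controls). Only affected individuals
carry genotypes; unaffected relatives appear in the pedigree with missing
genotypes and never gate any decision.

Genotypes travel as unphased allele-pair strings ("C/CGCT", missing
"./.") with a canonical 0/1/2 dosage mapping; coordinates are 1-based
VCF-style with left-anchored indels; gene symbols are the join key
throughout (no identifier-mapping service is consulted). Multiallelic VCF
sites are decomposed to one record per alt allele, with copies of the
other alt counted as reference for each decomposed record. Sidecar
annotation tables override VCF INFO values on conflict, with a logged
warning.

## Association screen

Each (variant, subgroup) pair yields a 2×2 allele-count table: subgroup
members with non-missing genotypes contribute two alleles each (missing
genotypes shrink the case allele number; nothing is imputed). The test is
the two-sided Fisher exact test under the point-probability rule:

p = Σ { P(T) : P(T) ≤ P(observed) } over all tables T with the observed
margins, P hypergeometric.

It is computed with exact integer combinatorics rather than through a
library routine: the weights C(r₁,k)·C(n−r₁,c₁−k) are integers, so ties
in table probability are decided exactly, and a call costs ~10 µs, which
keeps exhaustive verification sweeps and 200-replicate simulations cheap.
scipy's implementation of the same definition is retained as an
independent cross-check in the test suite (agreement ~1e-16 on random
tables; the exact version matches a rational-arithmetic enumeration
oracle with zero error over all 635,375 tables with total ≤ 60). A zero
margin gives p = 1 by convention.

The odds ratio is (case_alt·ctrl_ref)/(case_ref·ctrl_alt); when any cell
is zero, 0.5 is added to all four cells first (Haldane–Anscombe), which
also removes division by zero. The gate is p < α (default 0.05) AND
OR > 1 in at least one subgroup; per-subgroup results are all retained in
the audit trail, because with one multiplex family per subgroup it is
ambiguous whether a cohort-level method should demand a joint signal —
the any-subgroup reading reproduces the reference retention and is the
documented convention. No multiple-testing correction is applied at this
stage: the threshold is a candidate screen, not an inference, and is
documented as such.

Counting is allele-based, not carrier-based, matching the allele-frequency
framing of the comparison.

## Filter cascade

Stage order: association → impact → ontology → segregation. Each variant
accumulates a `FilterTrace` of (stage, decision, reason); after the first
failure later stages are recorded `not_evaluated`. The gates are
independent given their inputs, so retention is identical whether or not
the cascade short-circuits (asserted in tests).

Impact gate: HIGH passes unconditionally; LOW/MODIFIER fail; MODERATE
passes iff any per-transcript prediction is damaging (SIFT "D", or
PolyPhen-2 "P" possibly / "D" probably damaging — "possibly" counts,
because a retained reference candidate carries only P calls) or the
Asian-population MAF is strictly below the threshold (default 0.1; strict
reading of "lower than", boundary configurable). A MODERATE variant with
no predictions and no ASN MAF fails closed ("insufficient evidence") —
the conservative choice for an unspecified case. Ontology gate: union
(not intersection) across the configured phenotype gene lists; the reason
names every matching source.

## Segregation

Subgroup kind implies the model: multiplex → dominant, sporadic pool →
recessive. Support is the count of affected members whose genotype class
is consistent with the model (dominant: het or hom-alt; recessive:
hom-alt only). Heterozygous sporadic cases are surfaced as
"model-inconsistent carriers" but never counted. A variant passes when
max per-subgroup support ≥ min_support (default 1).

Strict co-segregation is intentionally NOT required: the reference cohort
itself contains an affected non-carrier in a multiplex family and a
heterozygous sporadic case for a recessive-pattern variant, so a strict
rule would contradict the printed retention. Support counting with the
full genotype matrix emitted for human review reproduces the retention
while keeping the inconsistencies visible.

## Tolerance and conservation annotation

LOEUF (loss-of-function observed/expected upper bound fraction, lower =
more constrained) is joined by gene symbol from a user-supplied table; a
qualitative flag marks LOEUF < 1 as constraint evidence. LOEUF never
gates retention — no cutoff is defensible from the design — and missing
genes are flagged, not dropped. The shipped fixture table covers only the
three genes with published scores.

Conservation: the 1-based residue position in the ungapped human sequence
is mapped to its alignment column (skipping human gaps); the score is the
fraction of ortholog rows with a non-gap residue identical to the human
residue at that column. Ortholog gaps are excluded from the denominator
(a deliberate choice — a gap is absence of evidence, not mismatch).
Threshold default 0.8 for the boolean "conserved" call; the underlying
fraction is always reported. The fixture's ortholog alignments are
synthetic stand-ins (marked as such in filenames and docstrings)
constructed so the three candidate residues are conserved; they carry the
qualitative claim, not real ortholog sequences.

## Enrichment

Query = genes of the retained variants, expanded one hop in the PPI
network (edges kept at combined score ≥ 700, strict ≥; one hop only, not
transitive closure — expanding an expanded set may grow it further).
Each term is tested by the hypergeometric upper tail
P(overlap ≥ observed) via `scipy.stats.hypergeom.sf`, with the term
intersected with the universe first. The universe defaults to the union
of all term genes (configurable). Benjamini–Hochberg step-up
(statsmodels) is the adjustment — the reference analysis used a
web-service algorithm whose term ensemble is not reproducible offline, so
its printed p-values are explicitly not comparison targets; both a pooled
adjustment across all tested terms and a within-source adjustment are
reported, significance decided on the pooled one at padj < 0.01. Because
"count" columns in published enrichment tables are ambiguous, both the
effective term size and the overlap are emitted under distinct names.

## Synthetic cohort generator

`CohortSpec` defaults are the study conditions: 3 multiplex + 6 sporadic
families, family size 3–6 (two founder parents plus children), a
100-person diploid control cohort (AN = 200), 3 planted dominant + 2
planted recessive variants, 20 decoys, penetrance 1.0, planted-variant
ASN MAF 0.005 (rare), decoy/neutral control allele frequencies uniform on
[0.05, 0.4]. Affected individuals are sequenced; unaffected are not,
mirroring the affected-only sequencing design.

Transmission is Mendelian: founder alleles are independent
Bernoulli(founder_af); each child receives one uniformly chosen allele
per parent. Planting is genotype-level, Mendelian-consistent within the
nuclear families the generator emits: dominant variants make the affected
founder parent and every affected child heterozygous (an unaffected child
of a het parent is a carrier with posterior probability (1−p)/(2−p) at
penetrance p, i.e. never at p = 1); recessive variants make the sporadic
case hom-alt with obligate-carrier parents and siblings drawn from the
het×het offspring distribution conditioned on being unaffected.

Each decoy fails exactly one named gate: `fail_association` (absent from
cases, moderately common in controls), `fail_impact` (LOW impact),
`fail_rescue` (MODERATE, tolerated calls, ASN MAF 0.3 — both rescue
routes closed), `fail_ontology` (unlisted gene), `fail_segregation` (het
carriers among pooled sporadic cases: allele-frequency signal with zero
recessive support). Decoys that must pass the association gate are given
low control allele counts even when their annotated population MAF is
high — the control cohort and the reference-population frequency are
independent quantities (a locally rare, globally common allele), and this
keeps the blame on the named gate. Determinism is a contract: identical
spec (including seed) gives byte-identical files; all randomness flows
from one `numpy` generator.

What the generator does NOT emulate: sequencing error, read-level data,
linkage/haplotype structure, population stratification between cases and
controls, multi-generational pedigrees deeper than the fixture's, or
missing-genotype patterns. Passing simulation tests therefore shows the
decision logic recovers clean planted signals under the stated design; it
does not certify behavior on noisy real call sets.

## Reference fixture

The 14-participant genotype matrix, the five candidate variants with
their annotations, and the three LOEUF scores are transcribed constants.
Control allele counts are a fixture convention (no per-variant control
counts were published): AC = round(ASN MAF × 200) for the three variants
with printed frequencies, AC = 0 for the two loss-of-function variants
without one. Under this convention all five candidates pass the
association gate in at least one subgroup — the CDON missense variant
only via the sporadic pool (p ≈ 0.0095), its best multiplex subgroup
being p ≈ 0.063. Phenotype gene lists, the functional-term collection,
and the PPI edge list are synthetic stand-ins for database resources,
constructed to satisfy the qualitative structure the pipeline consumes
(the five genes are listed; adhesion/calcium-channel terms contain the
candidates and their network neighbors; two PPI edges fall below the 700
threshold on purpose).

## Numerical and scale choices

- Exact-test sweeps: the Fisher implementation is verified against a
  rational-arithmetic enumeration oracle over every 2×2 table with total
  ≤ 60 (~6.4e5 tables, ~35 s); the hypergeometric test against exact draw
  counting over every configuration with universe ≤ 25.
- Simulation study: 200 replicates of the default cohort (~1,000 planted
  variants, 4,000 decoys) — large enough that recovery and exclusion
  rates are stable to well under a percentage point, small enough to run
  in seconds.
- Null calibration of the enrichment test uses universe 3,000, 40 terms
  of size 200–500, query 150, 1,000 replicates. Sizes were chosen for
  near-continuity of the discrete hypergeometric p (realized type-I rate
  ≈ 4%, slightly conservative as expected for a discrete test; much
  smaller terms push the realized rate towards 3%).
- BH adjustment is clipped to [0, 1]; enrichment results sort by pooled
  adjusted p, then term id, for deterministic output.
- Reports sort variants by (chromosome, position, ref, alt) with natural
  chromosome ordering; reruns are byte-identical.

## Limitations

- The association screen is a screen: uncorrected, allele-based, no
  kinship or covariate adjustment — within-family allele counts are not
  independent draws, so p-values are anti-conservative and must not be
  read as population-level inference.
- Recessive logic only covers the homozygous-alt case (no compound
  heterozygotes), and X-linked models are out of scope.
- The ontology gate is only as good as the supplied gene lists; an
  unlisted novel gene cannot be retained.
- Enrichment p-values depend on the chosen universe and term collection;
  published web-service results are not reproducible offline and are not
  comparison targets.
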