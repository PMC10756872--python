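# famvar

Family-based whole-exome rare-variant prioritization for non-syndromic
tooth agenesis (TA) — and, more generally, for small multi-family cohorts
where a handful of multiplex pedigrees and sporadic cases must be screened
against a modest control cohort without the sample sizes that
population-scale association methods assume.

The package implements the complete analysis as a tested library with a
thin CLI: patient subgrouping from pedigrees, case–control allele
association, an annotation-driven filter cascade with a per-variant audit
trail, segregation scoring under inheritance models, tolerance and
ortholog-conservation annotation, and PPI-expanded gene-set enrichment.
A synthetic cohort generator with planted causal variants and
"fail-exactly-one-gate" decoys makes every stage testable end to end, and
a reference cohort transcribed from a published nine-family TA study
(3 multiplex families, 6 sporadic cases, 14 sequenced affected
participants, 5 candidate variants) serves as the worked example.

## The method

**Subgrouping.** Sequenced affected members of each multiplex family
(≥ 2 affected) form one subgroup; the sole cases of single-case families
are pooled into one sporadic subgroup.

**Allele association.** For each variant and subgroup, a 2×2 allele-count
table against the control cohort (each non-missing diploid genotype
contributes two alleles) is tested with the two-sided Fisher exact test by
the point-probability rule — p is the sum of hypergeometric probabilities
of all tables at the observed margins no more probable than the observed
one, computed in exact integer arithmetic. The odds ratio is
OR = (a·d)/(b·c) with the Haldane–Anscombe +0.5 correction when a cell is
zero. A variant passes when p < 0.05 and OR > 1 in at least one subgroup
(a screen, deliberately uncorrected for multiple testing).

**Filter cascade.** association → impact → ontology → segregation, with a
per-variant `FilterTrace` recording every gate's decision and reason.
HIGH-impact variants pass the impact gate unconditionally; MODERATE
variants pass only if some transcript-level prediction is damaging
(SIFT "D", PolyPhen-2 "P"/"D") or the Asian-population allele frequency is
below 0.1 (strict); LOW/MODIFIER fail. The ontology gate requires the gene
to appear in the union of the phenotype gene lists (tooth-agenesis
association, odontogenesis, oligodontia).

**Segregation.** Multiplex subgroups are scored under an autosomal
dominant model (affected het/hom-alt carriers count as support), the
sporadic pool under autosomal recessive (hom-alt only; het carriers are
reported as model-inconsistent, never counted). A variant passes at
support ≥ 1 in some subgroup; the full genotype-by-participant matrix is
always emitted for review.

**Annotation.** LOEUF constraint scores are joined per gene (reported with
a constraint flag at LOEUF < 1, never gating), SIFT/PolyPhen calls are
summarized per transcript, and ortholog conservation at the mutated
residue is the fraction of non-gap ortholog residues matching the human
residue at the mapped alignment column.

**Enrichment.** The retained genes are expanded one hop in a STRING-style
PPI network (combined score ≥ 700), then each functional term is tested by
the hypergeometric upper tail P(X ≥ k) with Benjamini–Hochberg adjustment
(pooled and per-source); significance at adjusted p < 0.01.

## Worked example

```sh
famvar fixture --out fx
famvar run --vcf fx/cohort.vcf --ped fx/cohort.ped --controls fx/controls.tsv \
    --gene-list OT=fx/genes_ot.txt --gene-list GO=fx/genes_go.txt \
    --gene-list HPO=fx/genes_hpo.txt --gmt fx/terms.gmt \
    --ppi fx/ppi_edges.tsv --loeuf fx/loeuf.tsv --out report
```

prints

```
retained 5 of 5 variants: CACNA1S, CDON, ITGA6, MAST4, PITX2
```

and writes the report tables (candidate variants, the 14 × 5 genotype
matrix, per-variant filter traces, association and segregation details,
annotation summary, enrichment) under `report/`. The numbered scripts
under `analysis/` run the same stages as narrative analyses; for example
`python analysis/02_prioritize_variants.py` adds 20 single-gate decoys
before the cascade and prints

```
retained 5 of 25 variants: CACNA1S, CDON, ITGA6, MAST4, PITX2
decoy exclusion gates: {'fail_association': 'association', 'fail_impact': 'impact',
 'fail_rescue': 'impact', 'fail_ontology': 'ontology', 'fail_segregation': 'segregation'}
MAST4 risk-allele carriers: 6 / 14
PITX2 heterozygous carriers: 8 / 14
```

— all 5 candidates survive, every decoy dies at exactly the gate it was
built to fail, and the carrier counts match the source study (the MAST4
in-frame insertion in 6 participants from the three multiplex families,
the PITX2 stop-gain in 8). `analysis/05_simulation_study.py` measures the
operating characteristics on fresh simulated cohorts: ~99.7% of planted
causal variants are recovered over 200 replicates and decoys are excluded
in 100% of cases.

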