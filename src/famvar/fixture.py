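"""The in-study reference cohort, transcribed from the published candidate
tables: nine families (three multiplex, six sporadic), fourteen sequenced
affected individuals, and the five candidate variants with their genotypes,
annotations, and constraint scores.

Control allele counts are a fixture convention, not study data: the study
reports no per-variant control counts, so each variant's control alt count
is its printed Asian-population MAF scaled to the 100-person control
cohort's 200 alleles (zero for the two loss-of-function variants with no
printed MAF).

The phenotype gene lists, functional term collection, PPI edge list, and
ortholog alignments here are SYNTHETIC stand-ins for database resources
(Open Targets / GO / HPO lists, g:Profiler term sets, STRING edges,
ortholog sequence sets), constructed to satisfy the qualitative claims the
pipeline consumes; they are not database extracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import networkx as nx
import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import io_formats
from .types import Cohort, GeneSetTerm, PedigreeIndividual, VariantRecord

HUMAN_ID = "Homo_sapiens"

FIXTURE_VARIANTS: list[VariantRecord] = [
    VariantRecord(
        chrom="5", pos=65892764, ref="C", alt="CGCT", gene="MAST4",
        impact="MODERATE", effect="disruptive_inframe_insertion",
        rsid="rs201910335", transcript_id="ENST00000404260",
        protein_change="Leu95dup", sift_calls=(), polyphen_calls=(),
        maf_global=0.005814, maf_asn=0.01434,
    ),
    VariantRecord(
        chrom="2", pos=173337540, ref="G", alt="GA", gene="ITGA6",
        impact="HIGH", effect="frameshift_variant",
        rsid=None, transcript_id="ENST00000409532", protein_change="Asp114fs",
    ),
    VariantRecord(
        chrom="4", pos=111542154, ref="G", alt="A", gene="PITX2",
        impact="HIGH", effect="stop_gained",
        rsid="rs2278782", transcript_id="ENST00000557119", protein_change="Gln193*",
    ),
    VariantRecord(
        chrom="1", pos=201016296, ref="G", alt="A", gene="CACNA1S",
        impact="MODERATE", effect="missense_variant",
        rsid="rs3850625", transcript_id="ENST00000367338", protein_change="Arg1520Cys",
        sift_calls=("D", "D"), polyphen_calls=("B",),
        maf_global=0.070971, maf_asn=0.041958,
    ),
    VariantRecord(
        chrom="11", pos=125871715, ref="G", alt="A", gene="CDON",
        impact="MODERATE", effect="missense_variant",
        rsid="rs12274923", transcript_id="ENST00000531738", protein_change="Ala63Val",
        sift_calls=("T", "D", "T"), polyphen_calls=("P", "P", "P"),
        maf_global=0.125916, maf_asn=0.062937,
    ),
]

LOEUF_SCORES: dict[str, float] = {"MAST4": 0.38, "CACNA1S": 0.56, "CDON": 0.96}

# Sequenced participants in table order:
# (family, individual, sex, missing teeth, MAST4, ITGA6, PITX2, CACNA1S, CDON)
TABLE_GENOTYPES: list[tuple[str, str, int, int, str, str, str, str, str]] = [
    ("F1", "II-2", 2, 9, "C/CGCT", "G/GA", "G/A", "G/G", "G/A"),
    ("F1", "III-2", 1, 8, "C/CGCT", "G/GA", "G/A", "G/G", "G/G"),
    ("F2", "I-2", 2, 5, "C/C", "G/G", "G/A", "G/G", "G/G"),
    ("F2", "II-1", 1, 3, "C/CGCT", "G/G", "G/A", "G/G", "G/A"),
    ("F2", "III-2", 2, 26, "C/CGCT", "G/G", "G/A", "G/G", "G/A"),
    ("F3", "I-1", 1, 2, "C/C", "G/G", "G/G", "G/A", "G/G"),
    ("F3", "II-1", 2, 6, "C/CGCT", "G/G", "G/A", "G/A", "G/G"),
    ("F3", "II-2", 2, 4, "C/CGCT", "G/G", "G/A", "G/A", "G/G"),
    ("F4", "II-1", 2, 7, "C/C", "G/G", "A/A", "G/G", "G/A"),
    ("F5", "II-7", 1, 6, "C/C", "G/G", "G/G", "G/G", "G/G"),
    ("F6", "II-1", 1, 12, "C/C", "G/G", "G/G", "G/G", "G/G"),
    ("F7", "II-1", 2, 7, "C/C", "G/G", "G/A", "G/G", "G/G"),
    ("F8", "II-3", 2, 6, "C/C", "G/G", "A/A", "G/G", "A/A"),
    ("F9", "II-1", 1, 11, "C/C", "G/G", "G/G", "G/G", "G/A"),
]

#: Gene order of the genotype table columns above.
TABLE_GENE_ORDER = ("MAST4", "ITGA6", "PITX2", "CACNA1S", "CDON")

CONTROL_N = 100

#: Alignment sites assessed for ortholog conservation: gene -> (1-based
#: human residue position, human residue).
CONSERVATION_SITES: dict[str, tuple[int, str]] = {
    "MAST4": (95, "L"),      # duplicated leucine
    "CACNA1S": (1520, "R"),  # Arg1520Cys
    "CDON": (63, "A"),       # Ala63Val
}

# Synthetic stand-in phenotype gene lists (tooth-agenesis association,
# odontogenesis, oligodontia); union covers the five candidate genes.
GENE_LISTS: dict[str, set[str]] = {
    "OT": {"PITX2", "ITGA6", "CACNA1S", "MSX1", "PAX9", "AXIN2", "WNT10A", "EDA", "LRP6"},
    "GO": {"PITX2", "CDON", "MAST4", "MSX1", "PAX9", "BMP4", "SHH", "WNT10B"},
    "HPO": {"PITX2", "CACNA1S", "CDON", "MAST4", "ITGA6", "EDA", "EDAR", "WNT10A"},
}

# Synthetic STRING-style edges (scores 0-1000); two fall below the default
# 700 confidence threshold on purpose.
PPI_EDGES: list[tuple[str, str, int]] = [
    ("CACNA1S", "CACNB1", 900), ("CACNA1S", "CACNG1", 850), ("CACNA1S", "RYR1", 950),
    ("ITGA6", "ITGB1", 980), ("ITGA6", "ITGB4", 990), ("ITGA6", "PTK2", 800),
    ("ITGA6", "LAMA1", 750),
    ("PITX2", "CTNNB1", 820), ("PITX2", "LEF1", 780), ("PITX2", "WNT10A", 650),
    ("CDON", "SHH", 930), ("CDON", "BOC", 940), ("CDON", "GAS1", 880),
    ("MAST4", "CTNNB1", 720), ("MAST4", "APC", 650),
    ("ITGB1", "PTK2", 910), ("CACNB1", "CACNG1", 840),
]

_FIXTURE_SEED = 230515  # fixed: fixture output must be byte-identical across runs


def fixture_pedigree() -> list[PedigreeIndividual]:
    """Nine-family pedigree; only affected members were sequenced, and one
    affected member (F1 I-2) provided no sample."""
    sequenced = {(fam, iid) for fam, iid, *_ in TABLE_GENOTYPES}

    def ind(fam: str, iid: str, fa: str | None, mo: str | None, sex: int, aff: bool) -> PedigreeIndividual:
        qualify = lambda x: f"{fam}_{x}" if x else None
        return PedigreeIndividual(
            family_id=fam,
            individual_id=f"{fam}_{iid}",
            father_id=qualify(fa),
            mother_id=qualify(mo),
            sex=sex,
            affected=aff,
            sequenced=(fam, iid) in sequenced,
        )

    ped: list[PedigreeIndividual] = []
    # multiplex families (mirror the published pedigree topology)
    ped += [
        ind("F1", "I-1", None, None, 1, False),
        ind("F1", "I-2", None, None, 2, True),  # affected, no sample
        ind("F1", "II-1", None, None, 1, False),
        ind("F1", "II-2", "I-1", "I-2", 2, True),
        ind("F1", "III-2", "II-1", "II-2", 1, True),
    ]
    ped += [
        ind("F2", "I-1", None, None, 1, False),
        ind("F2", "I-2", None, None, 2, True),
        ind("F2", "II-1", "I-1", "I-2", 1, True),
        ind("F2", "II-2", None, None, 2, False),
        ind("F2", "III-2", "II-1", "II-2", 2, True),
    ]
    ped += [
        ind("F3", "I-1", None, None, 1, True),
        ind("F3", "I-2", None, None, 2, False),
        ind("F3", "II-1", "I-1", "I-2", 2, True),
        ind("F3", "II-2", "I-1", "I-2", 2, True),
    ]
    # sporadic families: unaffected parents plus the single case
    for fam, iid, sex in [
        ("F4", "II-1", 2), ("F5", "II-7", 1), ("F6", "II-1", 1),
        ("F7", "II-1", 2), ("F8", "II-3", 2), ("F9", "II-1", 1),
    ]:
        ped += [
            ind(fam, "I-1", None, None, 1, False),
            ind(fam, "I-2", None, None, 2, False),
            ind(fam, iid, "I-1", "I-2", sex, True),
        ]
    return ped


def fixture_genotypes() -> pd.DataFrame:
    keys = {v.gene: v.key for v in FIXTURE_VARIANTS}
    rows = {}
    for fam, iid, _sex, _teeth, *gts in TABLE_GENOTYPES:
        rows[f"{fam}_{iid}"] = {keys[g]: gt for g, gt in zip(TABLE_GENE_ORDER, gts)}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "individual_id"
    return df[[v.key for v in FIXTURE_VARIANTS]]


def fixture_controls() -> pd.DataFrame:
    """Control counts from printed ASN MAFs scaled to AN = 2 x 100
    (fixture convention; the study reports no per-variant control counts)."""
    an = 2 * CONTROL_N
    rows = []
    for v in FIXTURE_VARIANTS:
        ac = int(round(v.maf_asn * an)) if v.maf_asn is not None else 0
        rows.append({"variant_key": v.key, "AC": ac, "AN": an})
    return pd.DataFrame(rows).set_index("variant_key")


def fixture_terms() -> list[GeneSetTerm]:
    """Synthetic functional term collection echoing the highlighted
    enrichment categories (calcium channel complex, focal adhesion and
    adhesion-related terms), padded with neutral background terms."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    filler = [f"BG{i:03d}" for i in range(1, 161)]

    def pad(genes: set[str], n: int, salt: int) -> frozenset[str]:
        pool = np.array(filler)
        pick = np.random.default_rng(_FIXTURE_SEED + salt).choice(pool, size=n, replace=False)
        return frozenset(genes | set(pick))

    terms = [
        GeneSetTerm("GO:0005245", "GO:MF", "voltage-gated calcium channel activity",
                    pad({"CACNA1S", "CACNB1", "CACNG1", "RYR1"}, 4, 1)),
        GeneSetTerm("GO:0005178", "GO:MF", "integrin binding",
                    pad({"ITGA6", "ITGB1", "ITGB4", "LAMA1", "PTK2"}, 6, 2)),
        GeneSetTerm("GO:0050839", "GO:MF", "cell adhesion molecule binding",
                    pad({"ITGA6", "ITGB1", "CDON", "BOC"}, 8, 3)),
        GeneSetTerm("GO:0007155", "GO:BP", "cell adhesion",
                    pad({"ITGA6", "ITGB1", "ITGB4", "PTK2", "LAMA1", "CDON", "BOC"}, 12, 4)),
        GeneSetTerm("GO:0005891", "GO:CC", "voltage-gated calcium channel complex",
                    pad({"CACNA1S", "CACNB1", "CACNG1"}, 3, 5)),
        GeneSetTerm("GO:0098797", "GO:CC", "plasma membrane protein complex",
                    pad({"CACNA1S", "CACNB1", "ITGA6", "ITGB1", "SHH"}, 14, 6)),
        GeneSetTerm("GO:0030054", "GO:CC", "cell junction",
                    pad({"ITGA6", "ITGB1", "PTK2", "CTNNB1"}, 12, 7)),
        GeneSetTerm("KEGG:04510", "KEGG", "Focal adhesion",
                    pad({"ITGA6", "ITGB1", "ITGB4", "PTK2", "LAMA1", "CTNNB1"}, 10, 8)),
        GeneSetTerm("REAC:R-HSA-1474244", "REAC", "Extracellular matrix organization",
                    pad({"ITGA6", "ITGB1", "LAMA1"}, 12, 9)),
    ]
    for i in range(1, 7):  # neutral background terms
        size = int(rng.integers(8, 25))
        terms.append(
            GeneSetTerm(f"BGTERM:{i:04d}", "GO:BP", f"background process {i}",
                        pad(set(), size, 100 + i))
        )
    return terms


_SPECIES = (
    "Pan_troglodytes", "Macaca_mulatta", "Mus_musculus", "Rattus_norvegicus",
    "Canis_lupus", "Bos_taurus", "Sus_scrofa", "Equus_caballus",
)

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _synthetic_alignment(
    residue_position: int, residue: str, seed: int, conserved_window: int = 5
) -> MultipleSeqAlignment:
    """Synthetic ortholog alignment: a random template with per-species
    substitutions everywhere except a conserved window around the target
    residue (all orthologs match the human residue there)."""
    rng = np.random.default_rng(seed)
    length = residue_position + 20
    template = _AMINO_ACIDS[rng.integers(0, len(_AMINO_ACIDS), size=length)].copy()
    template[residue_position - 1] = residue
    records = [SeqRecord(Seq("".join(template)), id=HUMAN_ID, description="")]
    for sp in _SPECIES:
        seq = template.copy()
        n_mut = max(1, int(0.08 * length))
        for p in rng.choice(length, size=n_mut, replace=False):
            if abs(int(p) - (residue_position - 1)) <= conserved_window:
                continue
            seq[p] = _AMINO_ACIDS[rng.integers(0, len(_AMINO_ACIDS))]
        records.append(SeqRecord(Seq("".join(seq)), id=sp, description=""))
    return MultipleSeqAlignment(records)


def fixture_alignments() -> dict[str, MultipleSeqAlignment]:
    """Synthetic ortholog alignments for the three missense/in-frame
    candidates, conserved at the mutated residue (stand-ins constructed to
    satisfy the qualitative conservation claim)."""
    return {
        gene: _synthetic_alignment(pos, res, seed=_FIXTURE_SEED + i)
        for i, (gene, (pos, res)) in enumerate(sorted(CONSERVATION_SITES.items()))
    }


@dataclass
class FixtureBundle:
    cohort: Cohort
    gene_lists: dict[str, set[str]]
    loeuf: dict[str, float]
    terms: list[GeneSetTerm]
    ppi: nx.Graph
    ppi_edges: list[tuple[str, str, int]]
    alignments: dict[str, MultipleSeqAlignment] = field(default_factory=dict)


def paper_fixture() -> FixtureBundle:
    """Materialize the full reference cohort and its companion resources."""
    pedigree = fixture_pedigree()
    cohort = Cohort(
        variants=list(FIXTURE_VARIANTS),
        genotypes=fixture_genotypes(),
        pedigree=pedigree,
        controls=fixture_controls(),
    )
    graph = nx.Graph()
    for a, b, s in PPI_EDGES:
        if s >= 700:
            graph.add_edge(a, b, combined_score=s)
    return FixtureBundle(
        cohort=cohort,
        gene_lists={k: set(v) for k, v in GENE_LISTS.items()},
        loeuf=dict(LOEUF_SCORES),
        terms=fixture_terms(),
        ppi=graph,
        ppi_edges=list(PPI_EDGES),
        alignments=fixture_alignments(),
    )


def write_fixture(out_dir: str | Path) -> dict[str, Path]:
    """Write every fixture file (VCF, PED, controls, gene lists, GMT, PPI
    edges, LOEUF table, alignments) under ``out_dir``; byte-identical on
    rerun."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = paper_fixture()
    paths = io_formats.write_cohort(bundle.cohort, out)
    for source, genes in bundle.gene_lists.items():
        p = out / f"genes_{source.lower()}.txt"
        io_formats.write_gene_list(genes, p)
        paths[f"genes_{source}"] = p
    io_formats.write_gmt(bundle.terms, out / "terms.gmt")
    io_formats.write_ppi(bundle.ppi_edges, out / "ppi_edges.tsv")
    io_formats.write_loeuf(bundle.loeuf, out / "loeuf.tsv")
    paths.update(gmt=out / "terms.gmt", ppi=out / "ppi_edges.tsv", loeuf=out / "loeuf.tsv")
    aln_dir = out / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for gene, aln in bundle.alignments.items():
        p = aln_dir / f"{gene}_orthologs.synthetic.fasta"
        with open(p, "w") as fh:
            for rec in aln:
                fh.write(f">{rec.id}\n{rec.seq}\n")
        paths[f"alignment_{gene}"] = p
    return paths
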