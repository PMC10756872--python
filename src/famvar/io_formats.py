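"""Readers and writers for every external format the pipeline touches.

VCF v4.2 via pysam (one internal record per alt allele), 6-column PED,
gene-list text / GMT, STRING-style PPI edge TSV, control allele-count TSV,
LOEUF TSV, and the report tables. All parsers validate and reject rather
than silently coerce.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd
import pysam

from .types import (
    Cohort,
    CohortError,
    GeneSetTerm,
    MISSING_GT,
    PedigreeIndividual,
    VariantRecord,
    dosage_genotype,
    validate_pedigree,
)

log = logging.getLogger(__name__)

_INFO_FIELDS = [
    ("GENE", "1", "String", "Gene symbol"),
    ("IMPACT", "1", "String", "Predicted impact class (HIGH/MODERATE/LOW/MODIFIER)"),
    ("EFFECT", "1", "String", "Variant effect (e.g. missense_variant)"),
    ("TRANSCRIPT", "1", "String", "Transcript identifier"),
    ("PCHANGE", "1", "String", "Protein change"),
    ("SIFT", ".", "String", "Per-transcript SIFT calls (D damaging, T tolerated)"),
    ("POLYPHEN", ".", "String", "Per-transcript PolyPhen-2 calls (B/P/D)"),
    ("MAF", "1", "Float", "Global alternative allele frequency"),
    ("MAF_ASN", "1", "Float", "Asian-population alternative allele frequency"),
    ("LOEUF", "1", "Float", "Loss-of-function observed/expected upper bound fraction"),
]


def chrom_sort_key(chrom: str) -> tuple[int, object]:
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def variant_sort_key(v: VariantRecord) -> tuple:
    return (*chrom_sort_key(v.chrom), v.pos, v.ref, v.alt)


# ---------------------------------------------------------------------------
# PED

def write_ped(pedigree: Sequence[PedigreeIndividual], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in pedigree:
            fh.write(
                "\t".join(
                    [
                        p.family_id,
                        p.individual_id,
                        p.father_id or "0",
                        p.mother_id or "0",
                        str(p.sex),
                        "2" if p.affected else "1",
                    ]
                )
                + "\n"
            )


def read_ped(path: str | os.PathLike) -> list[PedigreeIndividual]:
    """Parse a 6-column pedigree (phenotype: 2=affected, 1=unaffected,
    0/-9=unknown). The ``sequenced`` flag is set later from VCF samples."""
    out: list[PedigreeIndividual] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise CohortError(f"{path}:{lineno}: expected 6 PED columns, got {len(fields)}")
            fam, iid, fa, mo, sex, pheno = fields
            if pheno not in {"2", "1", "0", "-9"}:
                raise CohortError(f"{path}:{lineno}: bad phenotype code {pheno!r}")
            out.append(
                PedigreeIndividual(
                    family_id=fam,
                    individual_id=iid,
                    father_id=None if fa == "0" else fa,
                    mother_id=None if mo == "0" else mo,
                    sex=int(sex),
                    affected=pheno == "2",
                )
            )
    validate_pedigree(out)
    return out


# ---------------------------------------------------------------------------
# VCF

def write_vcf(
    variants: Sequence[VariantRecord],
    genotypes: pd.DataFrame,
    samples: Sequence[str],
    path: str | os.PathLike,
) -> None:
    """Write a VCF v4.2 with one record per alt allele.

    ``genotypes`` holds allele-pair strings indexed by individual id with
    one column per variant key; only ``samples`` become VCF columns.
    """
    header = pysam.VariantHeader()
    for chrom in sorted({v.chrom for v in variants}, key=chrom_sort_key):
        header.contigs.add(chrom)
    for name, number, vtype, desc in _INFO_FIELDS:
        header.info.add(name, number, vtype, desc)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)
    ordered = sorted(variants, key=variant_sort_key)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in ordered:
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt), id=v.rsid
            )
            rec.info["GENE"] = v.gene
            rec.info["IMPACT"] = v.impact
            if v.effect:
                rec.info["EFFECT"] = v.effect
            if v.transcript_id:
                rec.info["TRANSCRIPT"] = v.transcript_id
            if v.protein_change:
                rec.info["PCHANGE"] = v.protein_change
            if v.sift_calls:
                rec.info["SIFT"] = v.sift_calls
            if v.polyphen_calls:
                rec.info["POLYPHEN"] = v.polyphen_calls
            if v.maf_global is not None:
                rec.info["MAF"] = v.maf_global
            if v.maf_asn is not None:
                rec.info["MAF_ASN"] = v.maf_asn
            if v.loeuf is not None:
                rec.info["LOEUF"] = v.loeuf
            for s in samples:
                gt = str(genotypes.at[s, v.key]) if s in genotypes.index else MISSING_GT
                rec.samples[s]["GT"] = _gt_to_indices(gt, v.ref, v.alt)
                rec.samples[s].phased = False
            vcf.write(rec)


def _gt_to_indices(gt: str, ref: str, alt: str) -> tuple[Optional[int], Optional[int]]:
    if gt == MISSING_GT or gt in ("", "."):
        return (None, None)
    alleles = gt.split("/")
    if len(alleles) != 2:
        raise CohortError(f"malformed genotype {gt!r}")
    out = []
    for a in alleles:
        if a == ".":
            out.append(None)
        elif a == ref:
            out.append(0)
        elif a == alt:
            out.append(1)
        else:
            raise CohortError(f"allele {a!r} matches neither {ref!r} nor {alt!r}")
    return tuple(out)  # type: ignore[return-value]


def _round_frequency(x: Optional[float]) -> Optional[float]:
    # pysam stores Float INFO as float32; round back to the printed precision
    return None if x is None else round(float(x), 6)


def read_vcf(path: str | os.PathLike) -> tuple[list[VariantRecord], pd.DataFrame, list[str]]:
    """Read a VCF into variant records and an allele-string genotype frame.

    Multiallelic sites are decomposed into one record per alt allele; for
    each decomposed record, copies of the other alt alleles in a genotype
    are counted as reference.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except Exception as exc:  # pragma: no cover - pysam message varies
        raise CohortError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    variants: list[VariantRecord] = []
    columns: dict[str, list[str]] = {}
    with vcf:
        declared = set(vcf.header.info.keys())

        def info_get(rec, key, default=None):
            # pysam raises on keys absent from the header line
            return rec.info.get(key, default) if key in declared else default

        for rec in vcf:
            if rec.alts is None:
                continue
            for alt_index, alt in enumerate(rec.alts, start=1):
                v = VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    rsid=rec.id,
                    gene=info_get(rec, "GENE", ""),
                    impact=info_get(rec, "IMPACT", "MODIFIER"),
                    effect=info_get(rec, "EFFECT", "") or "",
                    transcript_id=info_get(rec, "TRANSCRIPT"),
                    protein_change=info_get(rec, "PCHANGE"),
                    sift_calls=tuple(info_get(rec, "SIFT", ()) or ()),
                    polyphen_calls=tuple(info_get(rec, "POLYPHEN", ()) or ()),
                    maf_global=_round_frequency(info_get(rec, "MAF")),
                    maf_asn=_round_frequency(info_get(rec, "MAF_ASN")),
                    loeuf=_round_frequency(info_get(rec, "LOEUF")),
                )
                variants.append(v)
                col = []
                for s in samples:
                    indices = rec.samples[s]["GT"]
                    if indices is None or any(i is None for i in indices):
                        col.append(MISSING_GT)
                    else:
                        dosage = sum(1 for i in indices if i == alt_index)
                        col.append(dosage_genotype(dosage, rec.ref, alt))
                columns[v.key] = col
    genotypes = pd.DataFrame(columns, index=pd.Index(samples, name="individual_id"))
    return variants, genotypes, samples


# ---------------------------------------------------------------------------
# Sidecar annotation table

_ANNOTATION_COLUMNS = {
    "gene", "impact", "effect", "transcript_id", "protein_change",
    "sift", "polyphen", "maf_global", "maf_asn", "loeuf", "rsid",
}


def read_annotation_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise CohortError(f"annotation table {path} lacks columns {sorted(missing)}")
    return df


def apply_annotations(variants: list[VariantRecord], table: pd.DataFrame) -> list[VariantRecord]:
    """Overlay sidecar annotations onto variant records; the sidecar wins on
    conflict with VCF INFO values (logged)."""
    from dataclasses import replace

    indexed = table.set_index(
        table["chrom"].astype(str)
        + ":" + table["pos"].astype(str)
        + ":" + table["ref"] + ":" + table["alt"]
    )
    out = []
    for v in variants:
        if v.key not in indexed.index:
            out.append(v)
            continue
        row = indexed.loc[v.key]
        updates: dict = {}
        for col in _ANNOTATION_COLUMNS & set(table.columns):
            raw = row[col]
            if pd.isna(raw) or raw == "":
                continue
            if col in ("sift", "polyphen"):
                value = tuple(x.strip() for x in str(raw).split(",") if x.strip())
                updates[f"{col}_calls"] = value
            elif col in ("maf_global", "maf_asn", "loeuf"):
                updates[col] = float(raw)
            else:
                updates[col] = str(raw)
        for field, new in updates.items():
            old = getattr(v, field)
            if old not in (None, "", ()) and old != new:
                log.warning("annotation conflict for %s.%s: VCF %r overridden by sidecar %r",
                            v.key, field, old, new)
        out.append(replace(v, **updates))
    return out


# ---------------------------------------------------------------------------
# Cohort assembly

def read_controls(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("variant_key", "AC", "AN"):
        if col not in df.columns:
            raise CohortError(f"control table {path} lacks column {col}")
    df = df.set_index("variant_key")[["AC", "AN"]].astype(int)
    if (df["AC"] < 0).any() or (df["AC"] > df["AN"]).any():
        raise CohortError(f"control table {path}: require 0 <= AC <= AN")
    return df


def write_controls(controls: pd.DataFrame, path: str | os.PathLike) -> None:
    controls.rename_axis("variant_key").reset_index().to_csv(path, sep="\t", index=False)


def read_cohort(
    vcf_path: str | os.PathLike,
    ped_path: str | os.PathLike,
    controls_path: str | os.PathLike | None = None,
    annotation_path: str | os.PathLike | None = None,
) -> Cohort:
    """Assemble the internal cohort from VCF + PED (+ optional sidecar
    annotations and control counts). Every VCF sample must exist in the PED;
    PED individuals present in the VCF are flagged as sequenced."""
    pedigree = read_ped(ped_path)
    variants, genotypes, samples = read_vcf(vcf_path)
    ped_ids = {p.individual_id for p in pedigree}
    for s in samples:
        if s not in ped_ids:
            raise CohortError(f"VCF sample {s!r} has no pedigree entry")
    from dataclasses import replace

    pedigree = [replace(p, sequenced=p.individual_id in set(samples)) for p in pedigree]
    if annotation_path is not None:
        variants = apply_annotations(variants, read_annotation_table(annotation_path))
    controls = (
        read_controls(controls_path)
        if controls_path is not None
        else pd.DataFrame(columns=["AC", "AN"]).rename_axis("variant_key")
    )
    return Cohort(variants=variants, genotypes=genotypes, pedigree=pedigree, controls=controls)


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "ped": out / "cohort.ped",
        "controls": out / "controls.tsv",
    }
    samples = [p.individual_id for p in cohort.pedigree if p.sequenced]
    write_vcf(cohort.variants, cohort.genotypes, samples, paths["vcf"])
    write_ped(cohort.pedigree, paths["ped"])
    write_controls(cohort.controls, paths["controls"])
    return paths


# ---------------------------------------------------------------------------
# Gene lists / GMT

def read_gene_list(path: str | os.PathLike) -> set[str]:
    """One symbol per line (or GMT: all member genes pooled); symbols are
    uppercased and deduplicated, blank lines ignored."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if "\t" in line:
                fields = line.split("\t")
                if len(fields) >= 3:  # GMT row: id, description, genes...
                    genes.update(g.strip().upper() for g in fields[2:] if g.strip())
                    continue
            genes.add(line.strip().upper())
    if not genes:
        log.warning("gene list %s is empty", path)
    return genes


def read_gene_lists(paths: Mapping[str, str | os.PathLike]) -> dict[str, set[str]]:
    return {source: read_gene_list(p) for source, p in paths.items()}


def write_gene_list(genes: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(g + "\n")


def read_gmt(path: str | os.PathLike) -> list[GeneSetTerm]:
    """GMT rows: term_id <tab> description <tab> gene...; the description
    field carries ``source|name`` (falling back to the term-id prefix)."""
    terms: list[GeneSetTerm] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CohortError(f"{path}:{lineno}: GMT row needs >= 3 fields")
            term_id, desc = fields[0], fields[1]
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if "|" in desc:
                source, name = desc.split("|", 1)
            else:
                source, name = term_id.split(":", 1)[0], desc
            terms.append(GeneSetTerm(term_id=term_id, source=source, name=name, genes=genes))
    ids = [t.term_id for t in terms]
    if len(set(ids)) != len(ids):
        raise CohortError(f"duplicate term ids in {path}")
    return terms


def write_gmt(terms: Sequence[GeneSetTerm], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, f"{t.source}|{t.name}", *sorted(t.genes)]) + "\n")


# ---------------------------------------------------------------------------
# PPI network

def read_ppi(path: str | os.PathLike, min_score: int = 700) -> nx.Graph:
    """STRING-style edge list (gene_a, gene_b, combined_score in 0-1000);
    edges below ``min_score`` are dropped, the rest form an undirected graph."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_a", "gene_b", "combined_score"):
        if col not in df.columns:
            raise CohortError(f"PPI table {path} lacks column {col}")
    if ((df["combined_score"] < 0) | (df["combined_score"] > 1000)).any():
        raise CohortError(f"PPI table {path}: combined_score outside 0-1000")
    if (df["gene_a"] == df["gene_b"]).any():
        raise CohortError(f"PPI table {path}: self-loop edge")
    graph = nx.Graph()
    kept = df[df["combined_score"] >= min_score]
    for a, b, s in kept.itertuples(index=False):
        graph.add_edge(str(a).upper(), str(b).upper(), combined_score=int(s))
    return graph


def write_ppi(edges: Iterable[tuple[str, str, int]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tcombined_score\n")
        for a, b, s in edges:
            fh.write(f"{a}\t{b}\t{s}\n")


# ---------------------------------------------------------------------------
# LOEUF

def read_loeuf(path: str | os.PathLike) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "loeuf"):
        if col not in df.columns:
            raise CohortError(f"LOEUF table {path} lacks column {col}")
    scores = {str(g).upper(): float(s) for g, s in zip(df["gene"], df["loeuf"])}
    for g, s in scores.items():
        if s < 0:
            raise CohortError(f"negative LOEUF score {s} for {g}")
    return scores


def write_loeuf(scores: Mapping[str, float], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tloeuf\n")
        for g in sorted(scores):
            fh.write(f"{g}\t{scores[g]}\n")


# ---------------------------------------------------------------------------
# Reports

def write_report(out_dir: str | os.PathLike, tables: Mapping[str, pd.DataFrame]) -> dict[str, Path]:
    """Write each result table as TSV under ``out_dir`` with deterministic
    content (callers are responsible for deterministic row order)."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise CohortError(f"cannot create report directory {out}: {exc}") from exc
    paths = {}
    for name, df in tables.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths
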